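import math

import numpy as np
import pytest

from hgtscreen.seqio import Interval, SequenceRecord, reverse_complement
from hgtscreen.simulate import mutate_k2p, random_sequence
from hgtscreen.unit_partition import (
    RepeatUnit,
    differential_similarity,
    extract_units,
    locate_gene,
)


def _panel(gene):
    return [SequenceRecord(id="panel_gene", residues=gene)]


def _unit(seq, gene_len):
    rec = SequenceRecord(id="u", residues=seq)
    return RepeatUnit(
        record=rec,
        gene_iv=Interval("u", 0, gene_len),
        nts_iv=Interval("u", gene_len, len(seq)),
    )


def test_locate_gene_exact_embedding(rng):
    gene = random_sequence(rng, 120)
    unit = SequenceRecord(
        id="u", residues=random_sequence(rng, 100) + gene + random_sequence(rng, 700)
    )
    ru = locate_gene(unit, _panel(gene))
    assert (ru.gene_iv.start, ru.gene_iv.end) == (100, 220)
    assert ru.gene_strand == "+"
    assert ru.provenance == "located"
    assert ru.nts_iv == Interval("u", 220, 920)  # larger flank is the NTS


def test_locate_gene_reverse_complement(rng):
    gene = random_sequence(rng, 120)
    unit = SequenceRecord(
        id="u",
        residues=random_sequence(rng, 50)
        + reverse_complement(gene)
        + random_sequence(rng, 400),
    )
    ru = locate_gene(unit, _panel(gene))
    assert ru.gene_strand == "-"
    assert (ru.gene_iv.start, ru.gene_iv.end) == (50, 170)
    assert ru.gene_seq == gene


def test_locate_gene_not_found_on_random_sequence(rng):
    gene = random_sequence(np.random.default_rng(1), 120)
    unit = SequenceRecord(id="u", residues=random_sequence(rng, 900))
    assert locate_gene(unit, _panel(gene), min_identity=0.6) is None


@pytest.mark.parametrize("divergence", [0.02, 0.05, 0.10])
def test_locate_gene_boundary_recovery_under_divergence(divergence):
    # generator-built units: gene boundaries recovered within +/- 3 bp
    for seed in range(6):
        rng = np.random.default_rng([seed, int(divergence * 100)])
        gene = random_sequence(rng, 120)
        diverged = mutate_k2p(gene, divergence, rng=rng)
        left = int(rng.integers(50, 300))
        unit = SequenceRecord(
            id="u",
            residues=random_sequence(rng, left) + diverged + random_sequence(rng, 600),
        )
        ru = locate_gene(unit, _panel(gene))
        assert ru is not None
        assert abs(ru.gene_iv.start - left) <= 3
        assert abs(ru.gene_iv.end - (left + 120)) <= 3


def test_differential_similarity_identical_units(rng):
    seq = random_sequence(rng, 888)
    d = differential_similarity(_unit(seq, 120), _unit(seq, 120))
    assert d.gene_sim == pytest.approx(100.0)
    assert d.nts_sim == pytest.approx(100.0)
    assert d.overall_sim == pytest.approx(100.0)
    assert d.category == "extended_similarity"


def test_differential_similarity_symmetric(rng):
    a = random_sequence(rng, 500)
    b = mutate_k2p(a, 0.2, rng=rng)
    d1 = differential_similarity(_unit(a, 120), _unit(b, 120))
    d2 = differential_similarity(_unit(b, 120), _unit(a, 120))
    assert d1.gene_sim == pytest.approx(d2.gene_sim)
    assert d1.nts_sim == pytest.approx(d2.nts_sim)
    assert d1.category == d2.category


def test_gene_only_category_for_shared_gene_random_spacers(rng):
    gene = random_sequence(rng, 120)
    u1 = _unit(gene + random_sequence(rng, 600), 120)
    u2 = _unit(gene + random_sequence(rng, 600), 120)
    d = differential_similarity(u1, u2)
    assert d.gene_sim == pytest.approx(100.0)
    assert d.category == "gene_only"
    assert d.nts_sim < 65.0


def test_random_spacer_similarity_concentrates_below_60():
    # unrelated spacers align near the random baseline: < 60% in >= 95% of pairs
    gene = random_sequence(np.random.default_rng(0), 120)
    below = 0
    n = 100
    for i in range(n):
        rng = np.random.default_rng([7, i])
        u1 = _unit(gene + random_sequence(rng, 400), 120)
        u2 = _unit(gene + random_sequence(rng, 400), 120)
        if differential_similarity(u1, u2).nts_sim < 60.0:
            below += 1
    assert below >= 95


def test_extended_similarity_thresholds(rng):
    gene = random_sequence(rng, 120)
    nts = random_sequence(rng, 600)
    u1 = _unit(gene + nts, 120)
    u2 = _unit(
        mutate_k2p(gene, 0.01, rng=rng) + mutate_k2p(nts, 0.2, rng=rng), 120
    )
    d = differential_similarity(u1, u2)
    assert d.category == "extended_similarity"
    assert d.gene_sim >= 90.0
    assert 65.0 <= d.nts_sim < 100.0


def test_extract_units_finds_planted_unit_both_strands(rng):
    gene = random_sequence(rng, 120)
    nts = random_sequence(rng, 500)
    unit_seq = gene + nts
    ref = _unit(unit_seq, 120)
    fwd_bg = random_sequence(rng, 4000)
    contig_fwd = SequenceRecord(id="c1", residues=fwd_bg[:2000] + unit_seq + fwd_bg[2000:])
    contig_rc = SequenceRecord(
        id="c2", residues=fwd_bg[:1000] + reverse_complement(unit_seq) + fwd_bg[1000:]
    )
    units = extract_units([contig_fwd, contig_rc], ref)
    assert len(units) == 2
    for u in units:
        assert u.gene_seq == gene
        assert u.nts_seq == nts
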