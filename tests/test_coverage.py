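import numpy as np
import pytest

from hgtscreen.coverage import (
    GenomeIndex,
    Placement,
    WindowStat,
    annotate_windows,
    map_reads,
    poisson_enrichment,
    window_counts,
)
from hgtscreen.seqio import Interval, ReadRecord, SequenceRecord, reverse_complement
from hgtscreen.simulate import random_sequence

from _oracles import poisson_upper_tail


def _genome(rng, n=50_000, name="chrU"):
    return SequenceRecord(id=name, residues=random_sequence(rng, n))


def test_error_free_read_maps_to_true_position(rng):
    genome = _genome(rng)
    read = ReadRecord(id="r", residues=genome.residues[10_000:10_100])
    placements, unmapped = map_reads([read], [genome])
    assert unmapped == 0
    (p,) = placements
    assert (p.seq_id, p.position, p.strand, p.mismatches) == ("chrU", 10_000, "+", 0)


def test_reverse_strand_read_maps_back(rng):
    genome = _genome(rng)
    read = ReadRecord(id="r", residues=reverse_complement(genome.residues[500:600]))
    (p,), unmapped = map_reads([read], [genome])
    assert (p.position, p.strand) == (500, "-")


def test_read_with_too_many_mismatches_unmapped(rng):
    genome = _genome(rng)
    frag = list(genome.residues[2000:2100])
    for pos in (10, 35, 60, 85):  # max_mismatch + 1 substitutions
        frag[pos] = "ACGT"[("ACGT".index(frag[pos]) + 1) % 4]
    placements, unmapped = map_reads([ReadRecord(id="r", residues="".join(frag))],
                                     [genome], max_mismatch=3)
    assert unmapped == 1 and not placements


def test_mismatches_within_tolerance_mapped(rng):
    genome = _genome(rng)
    frag = list(genome.residues[2000:2100])
    for pos in (10, 50, 90):
        frag[pos] = "ACGT"[("ACGT".index(frag[pos]) + 1) % 4]
    (p,), unmapped = map_reads([ReadRecord(id="r", residues="".join(frag))], [genome])
    assert (p.position, p.mismatches) == (2000, 3)


def test_bulk_error_free_reads_map_uniquely(rng):
    genome = _genome(rng, 80_000)
    starts = rng.integers(0, 80_000 - 100, size=2000)
    reads = [
        ReadRecord(id=f"r{i}", residues=genome.residues[s : s + 100])
        for i, s in enumerate(starts)
    ]
    placements, unmapped = map_reads(reads, [genome], seed=1)
    correct = sum(
        1 for p, s in zip(placements, starts) if p.position == s and p.mismatches == 0
    )
    assert unmapped == 0
    assert correct / len(reads) >= 0.999


def test_multimapping_read_records_multiplicity(rng):
    block = random_sequence(rng, 300)
    genome = SequenceRecord(
        id="g", residues=block + random_sequence(rng, 1000) + block
    )
    read = ReadRecord(id="r", residues=block[50:150])
    (p,), _ = map_reads([read], [genome], seed=3)
    assert p.multiplicity == 2
    assert p.position in (50, 300 + 1000 + 50)


def test_genome_shorter_than_seed_is_error():
    with pytest.raises(ValueError):
        GenomeIndex([SequenceRecord(id="s", residues="ACGTACGT")], k=21)


def test_window_counts_examples():
    lengths = {"chr": 3_000_000}
    placements = [
        Placement(read_id=f"r{i}", seq_id="chr", position=0, strand="+", mismatches=0)
        for i in range(10)
    ]
    stats = window_counts(placements, lengths, width=1_000_000)
    assert [w.count for w in stats] == [10, 0, 0]
    assert window_counts([], lengths, width=1_000_000)[0].count == 0


def test_window_counts_conserve_total(rng):
    lengths = {"c1": 95_000, "c2": 40_000}
    placements = [
        Placement(
            read_id=f"r{i}",
            seq_id="c1" if i % 3 else "c2",
            position=int(rng.integers(0, 40_000)),
            strand="+",
            mismatches=0,
        )
        for i in range(500)
    ]
    for width in (7_000, 10_000, 100_000):
        stats = window_counts(placements, lengths, width=width)
        assert sum(w.count for w in stats) == 500
        # truncated final windows
        last_c1 = [w for w in stats if w.window.seq_id == "c1"][-1]
        assert last_c1.window.end == 95_000


@pytest.mark.parametrize(
    "lam,count,expected",
    [(4.0, 10, 0.008132), (10.0, 10, 0.54207)],
)
def test_poisson_known_tail_values(lam, count, expected):
    stats = [
        WindowStat(window=Interval("c", i * 10, (i + 1) * 10), count=count)
        for i in range(10)
    ]
    # force the target lambda by constructing matching totals
    total = count * 10
    out = poisson_enrichment(stats, alpha=0.01)
    # direct check of the tail function against the value
    from scipy.stats import poisson

    assert float(poisson.sf(count - 1, lam)) == pytest.approx(expected, abs=1e-5)
    assert poisson_upper_tail(count, lam) == pytest.approx(expected, abs=1e-5)
    assert poisson_upper_tail(count, lam) == pytest.approx(
        float(poisson.sf(count - 1, lam)), abs=1e-12
    )


def test_poisson_zero_count_p_is_one():
    stats = [
        WindowStat(window=Interval("c", 0, 10), count=0),
        WindowStat(window=Interval("c", 10, 20), count=8),
    ]
    out = poisson_enrichment(stats)
    assert out[0].p_value == 1.0
    assert not out[0].significant


def test_poisson_zero_total_placements_all_p_one():
    stats = [WindowStat(window=Interval("c", i, i + 1), count=0) for i in range(5)]
    out = poisson_enrichment(stats)
    assert all(w.p_value == 1.0 for w in out)


def test_poisson_length_proportional_lambda_for_truncated_window():
    stats = [
        WindowStat(window=Interval("c", 0, 100), count=6),
        WindowStat(window=Interval("c", 100, 150), count=6),
    ]
    out = poisson_enrichment(stats)
    assert out[0].expected == pytest.approx(12 * 100 / 150)
    assert out[1].expected == pytest.approx(12 * 50 / 150)
    out2 = poisson_enrichment(stats, rate="per_window_mean")
    assert out2[0].expected == pytest.approx(6.0)


def test_annotate_windows_labels_features(rng):
    unit = random_sequence(rng, 700)
    win_seq = random_sequence(rng, 3000) + unit + random_sequence(rng, 3000)
    genome = [
        SequenceRecord(id="chr", residues=win_seq + "AT" * 2000 + random_sequence(rng, 8000))
    ]
    width = len(win_seq)
    sig = [
        WindowStat(window=Interval("chr", 0, width), count=50, significant=True),
        WindowStat(window=Interval("chr", width, width + 4000), count=50, significant=True),
        WindowStat(
            window=Interval("chr", width + 4000, width + 12_000),
            count=50,
            significant=True,
        ),
    ]
    probes = {
        "5S_rDNA": [SequenceRecord(id="unit", residues=unit)],
        "microsatellite": [SequenceRecord(id="at", residues="AT" * 15)],
    }
    anns = annotate_windows(sig, genome, probes)
    assert anns[0].labels == ["5S_rDNA"]
    assert anns[1].labels == ["microsatellite"]
    assert anns[2].labels == ["unexplained"]
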