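import numpy as np
import pytest

from hgtscreen.align import local_search
from hgtscreen.distances import k2p_distance, transition_transversion
from hgtscreen.seqio import SequenceRecord
from hgtscreen.simulate import (
    ScenarioConfig,
    build_host,
    build_parasite,
    canonical_contamination_config,
    canonical_hgt_config,
    generate_scenario,
    mutate_k2p,
    random_sequence,
    simulate_reads,
)
from hgtscreen.unit_partition import differential_similarity, RepeatUnit
from hgtscreen.seqio import Interval


SMALL = dict(
    somatic_copies=5,
    oocyte_major_copies=40,
    oocyte_minor_copies=8,
    rdna40s_copies=5,
    native_copies=5,
    host_unique_block=20_000,
    parasite_contig_lengths=(40_000, 30_000),
    reads_per_library=300,
    te_families={
        "Harbinger": ("high_copy_TE", 6, 400),
        "Tc1Mariner": ("high_copy_TE", 8, 400),
        "Gypsy": ("low_copy_TE", 2, 400),
    },
)


def test_mutate_k2p_zero_divergence_identity(rng):
    seq = random_sequence(rng, 500)
    assert mutate_k2p(seq, 0.0, rng=rng) == seq


def test_mutate_k2p_large_kappa_suppresses_transversions(rng):
    seq = random_sequence(rng, 20_000)
    out = mutate_k2p(seq, 0.2, kappa=1e9, rng=rng)
    p, q, _ = transition_transversion(seq, out)
    assert q == 0.0
    assert p > 0.1


def test_mutate_k2p_realized_distance_tracks_programmed(rng):
    seq = random_sequence(rng, 10_000)
    d = np.mean(
        [k2p_distance(seq, mutate_k2p(seq, 0.3, rng=np.random.default_rng(i))) for i in range(20)]
    )
    assert d == pytest.approx(0.3, abs=0.03)


def test_same_seed_byte_identical_outputs():
    cfg = ScenarioConfig(seed=5, **SMALL)
    d1 = generate_scenario(cfg)
    d2 = generate_scenario(ScenarioConfig(seed=5, **SMALL))
    assert [r.residues for r in d1.host.records] == [r.residues for r in d2.host.records]
    assert [r.residues for r in d1.parasite.records] == [
        r.residues for r in d2.parasite.records
    ]
    assert [r.residues for r in d1.libraries[0]] == [r.residues for r in d2.libraries[0]]
    d3 = generate_scenario(ScenarioConfig(seed=6, **SMALL))
    assert [r.residues for r in d1.host.records] != [r.residues for r in d3.host.records]


def test_host_arrays_match_declared_copy_numbers():
    cfg = ScenarioConfig(seed=1, **{**SMALL, "somatic_copies": 3})
    host = build_host(cfg)
    (iv,) = host.truth.intervals(name="5S_somatic_array")
    unit_len = len(host.somatic_unit.record)
    assert len(iv) == 3 * unit_len  # adjacent head-to-tail copies
    (oiv,) = host.truth.intervals(name="5S_oocyte_major_array")
    assert len(oiv) == 40 * len(host.oocyte_unit.record)
    # within-array homogeneity: each copy close to the consensus
    chrom = next(r for r in host.records if r.id == iv.seq_id)
    copy2 = chrom.residues[iv.start + unit_len : iv.start + 2 * unit_len]
    assert k2p_distance(host.somatic_unit.record.residues, copy2) < 0.03


def test_copy_scale_knob():
    cfg = ScenarioConfig(seed=1, copy_scale=0.5, **SMALL)
    host = build_host(cfg)
    (iv,) = host.truth.intervals(name="5S_oocyte_major_array")
    assert len(iv) == 20 * len(host.oocyte_unit.record)


def test_planted_unit_nts_similarity_near_observed_value():
    sims = []
    gene_sims = []
    for seed in range(8):
        cfg = canonical_hgt_config(seed=seed, **SMALL)
        host = build_host(cfg)
        parasite = build_parasite(cfg, host)
        planted = parasite.planted_unit_seq
        assert planted is not None
        glen = cfg.gene_length
        unit = RepeatUnit(
            record=SequenceRecord(id="planted", residues=planted),
            gene_iv=Interval("planted", 0, glen),
            nts_iv=Interval("planted", glen, len(planted)),
        )
        d = differential_similarity(unit, host.somatic_unit)
        sims.append(d.nts_sim)
        gene_sims.append(d.gene_sim)
    assert np.mean(sims) == pytest.approx(71.28, abs=3.0)
    assert np.mean(gene_sims) >= 97.0


def test_native_gene_similarity_anchored_to_cross_phylum_floor():
    vals = []
    for seed in range(8):
        cfg = ScenarioConfig(seed=seed, **SMALL)
        host = build_host(cfg)
        parasite = build_parasite(cfg, host)
        glen = cfg.gene_length
        native_gene = parasite.native_unit_seq[:glen]
        host_gene = host.parts["5S_gene_somatic"]
        from hgtscreen.distances import p_distance

        vals.append(100 * (1 - p_distance(host_gene, native_gene)))
    assert np.mean(vals) == pytest.approx(67.7, abs=4.0)


def test_no_plant_leaves_no_somatic_nts_trace():
    cfg = ScenarioConfig(seed=3, **SMALL)
    host = build_host(cfg)
    parasite = build_parasite(cfg, host)
    probe = SequenceRecord(id="p", residues=host.parts["somatic_nts"])
    hits = local_search(probe, parasite.records, min_identity=0.9, min_score=30)
    assert not [h for h in hits if h.query_cover >= 0.3]


def test_contaminated_assembly_carries_host_fragments():
    cfg = canonical_contamination_config(seed=2, **SMALL)
    host = build_host(cfg)
    parasite = build_parasite(cfg, host)
    contam = [r for r in parasite.records if r.id.startswith("parasite_contam")]
    assert len(contam) == round(cfg.contaminant_fragments_per_unit_fraction * 0.05)
    # fragments are verbatim host substrings
    frag = contam[0]
    truth = [f for f in parasite.truth.features if f["name"] == "contaminant_fragment"][0]
    src = next(r for r in host.records if r.id == truth["source_seq"])
    assert frag.residues == src.residues[truth["source_start"] : truth["source_start"] + len(frag)]


def test_reads_no_contamination_all_parasite_origin():
    cfg = ScenarioConfig(seed=4, **SMALL)
    data = generate_scenario(cfg)
    origins = {o["genome"] for o in data.read_truth.read_origins.values()}
    assert origins == {"parasite"}


def test_reads_contamination_fraction_binomial():
    cfg = ScenarioConfig(seed=4, contamination_fraction=0.05,
                         **{**SMALL, "reads_per_library": 4000})
    data = generate_scenario(cfg)
    n_host = sum(
        1 for o in data.read_truth.read_origins.values() if o["genome"] == "host"
    )
    n = 2 * 4000
    expect = 0.05 * n
    assert abs(n_host - expect) <= 3 * np.sqrt(n * 0.05 * 0.95) + 1


def test_error_free_reads_are_exact_substrings():
    cfg = ScenarioConfig(seed=8, error_rate=0.0, **SMALL)
    data = generate_scenario(cfg)
    by_id = {r.id: r for r in data.parasite.records + data.host.records}
    from hgtscreen.seqio import reverse_complement

    for read in data.libraries[0][:50]:
        o = data.read_truth.read_origins[read.id]
        frag = by_id[o["seq_id"]].residues[o["start"] : o["start"] + len(read)]
        if o["strand"] == "-":
            frag = reverse_complement(frag)
        assert read.residues == frag


def test_config_validation():
    with pytest.raises(ValueError):
        ScenarioConfig(somatic_copies=-1)
    with pytest.raises(ValueError):
        ScenarioConfig(contamination_fraction=1.5)
    with pytest.raises(ValueError):
        ScenarioConfig(hgt_nts_divergence=-0.1)
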