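"""Synthetic host/parasite genomes, marker sets, and read libraries.

The generator emulates the genomic situation the screening pipeline is
built for, at roughly one tenth of real copy numbers so end-to-end runs
take seconds:

* a **host** genome with two 5S rDNA families of strongly asymmetric copy
  number — a somatic type (768 bp spacer, 40 copies here, ~400 real) and an
  oocyte type (537–701 bp spacer, 2000 major + 130 minor copies here,
  ~20,000 + 1,300 real) — plus a 40S-rDNA-like array, conserved multigene
  clusters (U1, H3), single-copy genes (Rag1, Rhod), high- and low-copy TE
  families, microsatellite and telomere tracts;
* a **parasite** genome with a diverged native 5S array (gene ~68% similar
  to the host gene, anchored to the observed cross-phylum similarity
  floor) and, optionally, one planted host-derived somatic unit whose
  spacer has diverged ~0.36 subst/site since transfer (realized NTS
  similarity ~71%);
* paired read libraries with a configurable host-contamination fraction,
  and — in the contamination scenario — host fragments incorporated into
  the parasite assembly in proportion to copy number (uniform sampling of
  the host genome, which abundant families dominate).

All randomness flows from ``ScenarioConfig.seed``; the same seed produces
byte-identical genomes and libraries.  The substitution process is pure
K2P (no indels), so realized distances are measurable against programmed
divergences.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evidence import MarkerSet
from .seqio import Interval, ReadRecord, SequenceRecord, reverse_complement
from .align import decode_residues, encode_residues
from .unit_partition import RepeatUnit


@dataclass
class ScenarioConfig:
    """All knobs of a synthetic scenario; defaults are the canonical study
    conditions at 1/10 copy-number scale."""

    seed: int = 0
    # 5S families
    gene_length: int = 120
    somatic_nts_length: int = 768
    somatic_copies: int = 40
    oocyte_nts_range: tuple[int, int] = (537, 701)
    oocyte_major_copies: int = 2000
    oocyte_minor_copies: int = 130
    type_divergence: float = 0.015       # somatic vs oocyte gene
    within_array_divergence: float = 0.005  # concerted-evolution homogeneity
    copy_scale: float = 1.0              # multiplies every copy number
    # other repeat/marker content
    rdna40s_copies: int = 50
    rdna40s_gene_length: int = 900
    rdna40s_igs_length: int = 500
    te_families: dict = field(
        default_factory=lambda: {
            "Harbinger": ("high_copy_TE", 60, 500),
            "Tc1Mariner": ("high_copy_TE", 100, 500),
            "Gypsy": ("low_copy_TE", 8, 600),
            "DIRS": ("low_copy_TE", 6, 600),
            "CR1": ("low_copy_TE", 5, 600),
        }
    )
    single_copy_genes: dict = field(
        default_factory=lambda: {"Rag1": 1000, "Rhod": 800}
    )
    multigene_families: dict = field(
        default_factory=lambda: {"U1": (164, 20), "H3": (400, 15)}
    )
    microsat_length: int = 3000
    telomere_repeats: int = 300
    host_unique_block: int = 150_000
    # parasite
    parasite_contig_lengths: tuple[int, ...] = (300_000, 250_000, 150_000)
    native_copies: int = 30
    native_nts_length: int = 500
    native_gene_divergence: float = 0.42  # K2P subs/site; realized sim ~68%
    # scenario switches
    hgt_planted: bool = False
    hgt_gene_divergence: float = 0.01
    hgt_nts_divergence: float = 0.36      # realized NTS similarity ~71%
    contamination_fraction: float = 0.0
    contaminant_fragment_length: int = 1500
    contaminant_fragments_per_unit_fraction: int = 1200  # n = round(this * f)
    # reads
    read_length: int = 100
    reads_per_library: int = 8000
    n_libraries: int = 2
    error_rate: float = 0.001
    kappa: float = 2.0

    def __post_init__(self) -> None:
        counts = (
            self.somatic_copies, self.oocyte_major_copies, self.oocyte_minor_copies,
            self.rdna40s_copies, self.native_copies, self.reads_per_library,
        )
        if any(c < 0 for c in counts):
            raise ValueError("copy numbers and read counts must be >= 0")
        for d in (
            self.type_divergence, self.within_array_divergence,
            self.native_gene_divergence, self.hgt_gene_divergence,
            self.hgt_nts_divergence,
        ):
            if d < 0:
                raise ValueError("divergences must be >= 0")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must be in [0, 1]")

    def scaled(self, n: int) -> int:
        return max(0, int(round(n * self.copy_scale)))


@dataclass
class TruthLog:
    """Ground truth of everything the generator planted."""

    features: list[dict] = field(default_factory=list)
    read_origins: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def add(self, name: str, category: str, seq_id: str, start: int, end: int,
            strand: str = "+", **extra) -> None:
        self.features.append(
            dict(name=name, category=category, seq_id=seq_id, start=start,
                 end=end, strand=strand, **extra)
        )

    def intervals(self, name: Optional[str] = None, category: Optional[str] = None):
        return [
            Interval(f["seq_id"], f["start"], f["end"], strand=f["strand"], name=f["name"])
            for f in self.features
            if (name is None or f["name"] == name)
            and (category is None or f["category"] == category)
        ]

    def dump(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"features": self.features, "params": self.params,
                 "read_origins": self.read_origins},
                fh, indent=1, default=str,
            )


_TS_TARGET = np.array([2, 3, 0, 1])


def mutate_k2p(
    residues: str, d: float, kappa: float = 2.0, rng: Optional[np.random.Generator] = None
) -> str:
    """Evolve a sequence for d expected substitutions/site under K2P.

    Per-site independent substitution using the exact K2P transition
    probabilities (multiple hits included, no indels); N sites are left
    unchanged.  The realized K2P distance estimate of the output against the
    input is a consistent estimator of d.
    """
    if d < 0:
        raise ValueError("divergence must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    arr = encode_residues(residues)
    if d == 0:
        return residues
    e1 = math.exp(-4.0 * d / (kappa + 2.0))
    e2 = math.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    u = rng.random(len(arr))
    out = arr.copy()
    valid = arr < 4
    ts = valid & (u < p_ts)
    tv1 = valid & (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = valid & (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts] = _TS_TARGET[arr[ts]]
    out[tv1] = (arr[tv1] + 1) % 4
    out[tv2] = (arr[tv2] + 3) % 4
    return decode_residues(out)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return decode_residues(rng.integers(0, 4, size=length).astype(np.uint8))


def _tandem_array(
    unit: str, copies: int, jitter: float, kappa: float, rng: np.random.Generator
) -> str:
    """Head-to-tail repeats with small per-copy divergence."""
    block = unit * copies
    return mutate_k2p(block, jitter, kappa, rng)


@dataclass
class HostGenome:
    records: list[SequenceRecord]
    truth: TruthLog
    somatic_unit: RepeatUnit
    oocyte_unit: RepeatUnit
    gene_panel: list[SequenceRecord]
    marker_sets: list[MarkerSet]
    repeat_probes: dict  # family -> (SequenceRecord probe, declared copy number)
    parts: dict          # named consensus sequences


def _segments_to_record(
    seq_id: str,
    segments: list[tuple[str, str, str]],
    truth: TruthLog,
    rng: np.random.Generator,
    group: str,
) -> SequenceRecord:
    """Join (name, category, seq) segments with random background spacers."""
    pieces: list[str] = []
    pos = 0
    for i, (name, category, seq) in enumerate(segments):
        if i > 0:
            spacer = random_sequence(rng, int(rng.integers(2000, 8000)))
            pieces.append(spacer)
            pos += len(spacer)
        if category != "background":
            truth.add(name, category, seq_id, pos, pos + len(seq))
        pieces.append(seq)
        pos += len(seq)
    return SequenceRecord(id=seq_id, residues="".join(pieces), group=group)


def build_host(config: ScenarioConfig) -> HostGenome:
    """Generate the host genome with all repeat families and markers."""
    rng = np.random.default_rng([config.seed, 1])
    truth = TruthLog(params={"component": "host", "seed": config.seed})
    gene = random_sequence(rng, config.gene_length)
    oocyte_gene = mutate_k2p(gene, config.type_divergence, config.kappa, rng)
    somatic_nts = random_sequence(rng, config.somatic_nts_length)
    oo_lo, oo_hi = config.oocyte_nts_range
    oocyte_nts = random_sequence(rng, int(rng.integers(oo_lo, oo_hi + 1)))
    minor_nts = random_sequence(rng, int(rng.integers(oo_lo, oo_hi + 1)))
    somatic_unit_seq = gene + somatic_nts
    oocyte_unit_seq = oocyte_gene + oocyte_nts
    minor_unit_seq = oocyte_gene + minor_nts

    n_som = config.scaled(config.somatic_copies)
    n_major = config.scaled(config.oocyte_major_copies)
    n_minor = config.scaled(config.oocyte_minor_copies)
    jit = config.within_array_divergence

    parts: dict[str, str] = {
        "5S_gene_somatic": gene,
        "5S_gene_oocyte": oocyte_gene,
        "somatic_nts": somatic_nts,
        "oocyte_nts": oocyte_nts,
        "somatic_unit": somatic_unit_seq,
        "oocyte_unit": oocyte_unit_seq,
    }
    te_seqs = {
        name: random_sequence(rng, length)
        for name, (_, _, length) in config.te_families.items()
    }
    parts.update({f"TE_{k}": v for k, v in te_seqs.items()})
    sc_seqs = {
        name: random_sequence(rng, length)
        for name, length in config.single_copy_genes.items()
    }
    mg_seqs = {
        name: random_sequence(rng, length)
        for name, (length, _) in config.multigene_families.items()
    }
    rdna40s_gene = random_sequence(rng, config.rdna40s_gene_length)
    rdna40s_igs = random_sequence(rng, config.rdna40s_igs_length)
    parts["40S_transcribed"] = rdna40s_gene
    parts["40S_igs"] = rdna40s_igs

    telomere = "TTAGGG" * config.telomere_repeats

    def te_segments(names: list[str]) -> list[tuple[str, str, str]]:
        segs = []
        for name in names:
            category, copies, _ = config.te_families[name]
            for c in range(config.scaled(copies)):
                segs.append(
                    (f"TE_{name}", category,
                     mutate_k2p(te_seqs[name], jit, config.kappa, rng))
                )
        return segs

    te_names = list(config.te_families)
    mg_names = list(config.multigene_families)

    def mg_cluster(name: str) -> tuple[str, str, str]:
        length, copies = config.multigene_families[name]
        spacer = random_sequence(rng, max(100, length // 2))
        return (
            f"{name}_cluster", "multigene_conserved",
            _tandem_array(mg_seqs[name] + spacer, config.scaled(copies),
                          jit, config.kappa, rng),
        )

    # chromosome 1: oocyte arrays, half the clusters/TEs, AT microsatellite
    chr1_feats: list[tuple[str, str, str]] = [
        ("5S_oocyte_major_array", "rdna_5S",
         _tandem_array(oocyte_unit_seq, n_major, jit, config.kappa, rng)),
        ("5S_oocyte_minor_array", "rdna_5S",
         _tandem_array(minor_unit_seq, n_minor, jit, config.kappa, rng)),
        ("microsat_AT", "microsatellite", "AT" * (config.microsat_length // 2)),
        ("unique_block_1", "background", random_sequence(rng, config.host_unique_block)),
    ] + [mg_cluster(n) for n in mg_names[0::2]] + te_segments(te_names[0::2])
    rng.shuffle(chr1_feats)
    chr1_feats = (
        [("telomere_L", "telomere", telomere)]
        + chr1_feats
        + [("telomere_R", "telomere", telomere)]
    )
    # chromosome 2: somatic array, 40S array, remaining clusters, single-copy genes
    chr2_feats: list[tuple[str, str, str]] = [
        ("5S_somatic_array", "rdna_5S",
         _tandem_array(somatic_unit_seq, n_som, jit, config.kappa, rng)),
        ("40S_array", "rdna_40S",
         _tandem_array(rdna40s_gene + rdna40s_igs, config.scaled(config.rdna40s_copies),
                       jit, config.kappa, rng)),
        ("microsat_AC", "microsatellite", "AC" * (config.microsat_length // 2)),
        ("unique_block_2", "background", random_sequence(rng, config.host_unique_block)),
    ] + [
        (f"gene_{name}", "single_copy", seq) for name, seq in sc_seqs.items()
    ] + [mg_cluster(n) for n in mg_names[1::2]] + te_segments(te_names[1::2])
    rng.shuffle(chr2_feats)
    chr2_feats = (
        [("telomere_L", "telomere", telomere)]
        + chr2_feats
        + [("telomere_R", "telomere", telomere)]
    )
    records = [
        _segments_to_record("host_chr1", chr1_feats, truth, rng, group="host"),
        _segments_to_record("host_chr2", chr2_feats, truth, rng, group="host"),
    ]

    glen = config.gene_length
    somatic_rec = SequenceRecord(id="host_somatic_unit", residues=somatic_unit_seq, group="host")
    oocyte_rec = SequenceRecord(id="host_oocyte_unit", residues=oocyte_unit_seq, group="host")
    somatic_unit = RepeatUnit(
        record=somatic_rec,
        gene_iv=Interval(somatic_rec.id, 0, glen),
        nts_iv=Interval(somatic_rec.id, glen, len(somatic_rec)),
        provenance="annotated",
    )
    oocyte_unit = RepeatUnit(
        record=oocyte_rec,
        gene_iv=Interval(oocyte_rec.id, 0, glen),
        nts_iv=Interval(oocyte_rec.id, glen, len(oocyte_rec)),
        provenance="annotated",
    )
    gene_panel = [
        SequenceRecord(id="5S_gene_somatic", residues=gene, group="host"),
        SequenceRecord(id="5S_gene_oocyte", residues=oocyte_gene, group="host"),
    ]
    marker_sets = [
        MarkerSet("Rag1", "single_copy",
                  [SequenceRecord(id="Rag1", residues=sc_seqs["Rag1"])]),
        MarkerSet("Rhod", "single_copy",
                  [SequenceRecord(id="Rhod", residues=sc_seqs["Rhod"])]),
        MarkerSet("U1", "multigene_conserved",
                  [SequenceRecord(id="U1", residues=mg_seqs["U1"])]),
        MarkerSet("H3", "multigene_conserved",
                  [SequenceRecord(id="H3", residues=mg_seqs["H3"])]),
        MarkerSet("40S_transcribed", "rdna_transcribed",
                  [SequenceRecord(id="40S_transcribed", residues=rdna40s_gene)],
                  expected_if_contaminated=True),
        MarkerSet("40S_igs", "rdna_spacer",
                  [SequenceRecord(id="40S_igs", residues=rdna40s_igs)]),
    ]
    for name, (category, copies, _) in config.te_families.items():
        marker_sets.append(
            MarkerSet(f"TE_{name}", category,
                      [SequenceRecord(id=f"TE_{name}", residues=te_seqs[name])],
                      expected_if_contaminated=(category == "high_copy_TE"))
        )
    repeat_probes = {
        "oocyte_5S": (
            SequenceRecord(id="oocyte_nts_probe", residues=oocyte_nts),
            n_major + n_minor,
        ),
        "somatic_5S": (
            SequenceRecord(id="somatic_nts_probe", residues=somatic_nts),
            n_som,
        ),
    }
    truth.params.update(
        somatic_copies=n_som, oocyte_major_copies=n_major, oocyte_minor_copies=n_minor
    )
    return HostGenome(
        records=records,
        truth=truth,
        somatic_unit=somatic_unit,
        oocyte_unit=oocyte_unit,
        gene_panel=gene_panel,
        marker_sets=marker_sets,
        repeat_probes=repeat_probes,
        parts=parts,
    )


@dataclass
class ParasiteGenome:
    records: list[SequenceRecord]
    truth: TruthLog
    native_unit_seq: str
    planted_unit_seq: Optional[str]


def build_parasite(config: ScenarioConfig, host: HostGenome) -> ParasiteGenome:
    """Generate the parasite assembly (native 5S array; optional planted unit;
    optional host-derived contaminant contigs)."""
    rng = np.random.default_rng([config.seed, 2])
    truth = TruthLog(params={"component": "parasite", "seed": config.seed})
    gene = host.parts["5S_gene_somatic"]
    native_gene = mutate_k2p(gene, config.native_gene_divergence, config.kappa, rng)
    native_nts = random_sequence(rng, config.native_nts_length)
    native_unit = native_gene + native_nts
    records: list[SequenceRecord] = []
    contigs = [
        random_sequence(rng, length) for length in config.parasite_contig_lengths
    ]
    # native array into contig 1
    array = _tandem_array(
        native_unit, config.scaled(config.native_copies),
        config.within_array_divergence, config.kappa, rng,
    )
    ins = int(rng.integers(0, len(contigs[0])))
    contigs[0] = contigs[0][:ins] + array + contigs[0][ins:]
    truth.add("5S_native_array", "rdna_5S", "parasite_contig1", ins, ins + len(array))

    planted_seq: Optional[str] = None
    if config.hgt_planted:
        glen = config.gene_length
        somatic = host.parts["somatic_unit"]
        planted_gene = mutate_k2p(somatic[:glen], config.hgt_gene_divergence, config.kappa, rng)
        planted_nts = mutate_k2p(somatic[glen:], config.hgt_nts_divergence, config.kappa, rng)
        planted_seq = planted_gene + planted_nts
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = planted_seq if strand == "+" else reverse_complement(planted_seq)
        pos = int(rng.integers(0, len(contigs[1])))
        contigs[1] = contigs[1][:pos] + inserted + contigs[1][pos:]
        truth.add("hgt_unit", "rdna_5S_transferred", "parasite_contig2",
                  pos, pos + len(inserted), strand=strand,
                  gene_divergence=config.hgt_gene_divergence,
                  nts_divergence=config.hgt_nts_divergence)

    for i, seq in enumerate(contigs, start=1):
        records.append(
            SequenceRecord(id=f"parasite_contig{i}", residues=seq, group="parasite")
        )

    f = config.contamination_fraction
    if f > 0:
        n_frag = int(round(config.contaminant_fragments_per_unit_fraction * f))
        host_concat = [(rec.id, rec.residues) for rec in host.records]
        lengths = np.array([len(s) for _, s in host_concat], dtype=float)
        for i in range(n_frag):
            ci = int(rng.choice(len(host_concat), p=lengths / lengths.sum()))
            cid, cseq = host_concat[ci]
            flen = min(config.contaminant_fragment_length, len(cseq))
            start = int(rng.integers(0, len(cseq) - flen + 1))
            frag_id = f"parasite_contam{i + 1}"
            records.append(
                SequenceRecord(id=frag_id, residues=cseq[start : start + flen],
                               group="parasite")
            )
            truth.add("contaminant_fragment", "contamination", frag_id, 0, flen,
                      source_seq=cid, source_start=start)
    truth.params.update(contamination_fraction=f, hgt_planted=config.hgt_planted)
    return ParasiteGenome(
        records=records, truth=truth,
        native_unit_seq=native_unit, planted_unit_seq=planted_seq,
    )


def simulate_reads(
    parasite: Sequence[SequenceRecord],
    host: Sequence[SequenceRecord],
    config: ScenarioConfig,
) -> tuple[list[list[ReadRecord]], TruthLog]:
    """Short-read libraries from the parasite with host contamination.

    Fragment starts are uniform over the source genome; a fraction f of
    reads in every library is drawn from the host genome instead (the
    contamination model).  Libraries use distinct sub-seeds, mirroring
    replicated sequencing runs.
    """
    truth = TruthLog(params={"component": "reads", "seed": config.seed})
    # contaminant contigs are part of the assembly, not of the organism:
    # reads are drawn only from the parasite's own contigs
    own = [rec for rec in parasite if not rec.id.startswith("parasite_contam")]
    libraries: list[list[ReadRecord]] = []
    rl = config.read_length
    for lib in range(config.n_libraries):
        rng = np.random.default_rng([config.seed, 3, lib])
        reads: list[ReadRecord] = []
        from_host = rng.random(config.reads_per_library) < config.contamination_fraction
        for j in range(config.reads_per_library):
            pool = host if from_host[j] else own
            lengths = np.array([len(r) for r in pool], dtype=float)
            ci = int(rng.choice(len(pool), p=lengths / lengths.sum()))
            src = pool[ci]
            start = int(rng.integers(0, len(src) - rl + 1))
            frag = src.residues[start : start + rl]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = reverse_complement(frag)
            if config.error_rate > 0:
                err = rng.random(rl) < config.error_rate
                if err.any():
                    arr = encode_residues(frag)
                    shifts = rng.integers(1, 4, size=int(err.sum()))
                    arr[err] = (arr[err] + shifts) % 4
                    frag = decode_residues(arr)
            rid = f"lib{lib}_r{j}"
            reads.append(ReadRecord(id=rid, residues=frag))
            truth.read_origins[rid] = {
                "genome": "host" if from_host[j] else "parasite",
                "seq_id": src.id,
                "start": start,
                "strand": strand,
                "library": lib,
            }
        libraries.append(reads)
    return libraries, truth


@dataclass
class ScenarioData:
    """Everything one scenario run produces."""

    config: ScenarioConfig
    host: HostGenome
    parasite: ParasiteGenome
    libraries: list[list[ReadRecord]]
    read_truth: TruthLog


def generate_scenario(config: ScenarioConfig) -> ScenarioData:
    host = build_host(config)
    parasite = build_parasite(config, host)
    libraries, read_truth = simulate_reads(parasite.records, host.records, config)
    return ScenarioData(
        config=config, host=host, parasite=parasite,
        libraries=libraries, read_truth=read_truth,
    )


def canonical_hgt_config(seed: int = 0, **overrides) -> ScenarioConfig:
    """The canonical transfer scenario: one planted unit, clean libraries."""
    return ScenarioConfig(seed=seed, hgt_planted=True, **overrides)


def canonical_contamination_config(seed: int = 0, **overrides) -> ScenarioConfig:
    """The canonical contamination scenario: 5% host reads, contaminated assembly."""
    return ScenarioConfig(seed=seed, contamination_fraction=0.05, **overrides)
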