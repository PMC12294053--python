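"""End-to-end orchestration of the similarity and contamination analyses.

Two entry points mirror the workflow's two methodological blocks:

* :func:`run_similarity` — haplotype collapse per group, progressive
  alignment of the gene regions, distance/similarity tables, NJ tree
  (optionally bootstrapped), incongruence scan;
* :func:`screen_assembly` — candidate-unit extraction from the parasite
  assembly, gene/NTS differential similarity against the host reference
  units, marker-based contamination screen, read mapping with windowed
  Poisson enrichment, and the rule-based verdict.

:func:`run_scenario` wires a synthetic scenario through both blocks and is
what the test-suite power checks and the acceptance script drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import coverage as cov
from .align import Alignment, KmerIndex, progressive_msa
from .distances import DistanceMatrix, distance_matrix, group_similarity_table
from .evidence import (
    EvidenceTable,
    RepeatPresence,
    Verdict,
    decide,
    marker_screen,
    repeat_presence,
)
from .haplotypes import HaplotypeSet, collapse_haplotypes
from .phylo import (
    IncongruenceReport,
    bootstrap_support,
    incongruence_scan,
    neighbor_joining,
)
from .seqio import Interval, SequenceRecord
from .simulate import ScenarioConfig, ScenarioData, generate_scenario
from .unit_partition import (
    DifferentialSimilarity,
    RepeatUnit,
    differential_similarity,
    extract_units,
)


@dataclass
class SimilarityResult:
    haplotypes: dict[str, HaplotypeSet]
    representative_of: dict[str, str]  # input id -> representative id
    alignment: Alignment
    groups: dict[str, str]
    dm: DistanceMatrix
    group_table: pd.DataFrame
    tree: object
    incongruence: list[IncongruenceReport]

    @property
    def flagged(self) -> list[str]:
        return [r.leaf_id for r in self.incongruence if r.flagged]


def run_similarity(
    records: Sequence[SequenceRecord],
    bootstrap_reps: int = 0,
    seed: int = 0,
    m: int = 3,
    saturation_cap: float = 5.0,
) -> SimilarityResult:
    """Haplotypes -> alignment -> distances -> tree -> incongruence.

    Records must carry group labels; haplotype collapse is per group so
    identical sequences from different groups stay distinct leaves.  The
    neighborhood size m is clipped to n_leaves - 1.
    """
    records = list(records)
    if any(not r.group for r in records):
        raise ValueError("all records need a group label for the similarity analysis")
    by_group: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_group.setdefault(rec.group, []).append(rec)
    hsets = {g: collapse_haplotypes(rs) for g, rs in by_group.items()}
    representative_of: dict[str, str] = {}
    reps: list[SequenceRecord] = []
    for g, hset in hsets.items():
        for rep, members in zip(hset.haplotypes, hset.members):
            reps.append(rep)
            for mid in members:
                representative_of[mid] = rep.id
    if len(reps) < 3:
        raise ValueError(
            f"degenerate matrix: only {len(reps)} distinct haplotypes; need >= 3"
        )
    alignment = progressive_msa(reps)
    groups = {rec.id: rec.group for rec in reps}
    dm = distance_matrix(alignment, method="k2p", saturation_cap=saturation_cap)
    table = group_similarity_table(alignment, groups)
    if bootstrap_reps > 0:
        tree = bootstrap_support(alignment, n_reps=bootstrap_reps, seed=seed,
                                 saturation_cap=saturation_cap)
    else:
        tree = neighbor_joining(dm)
    m_eff = min(m, len(reps) - 1)
    reports = incongruence_scan(tree, groups, m=m_eff)
    return SimilarityResult(
        haplotypes=hsets,
        representative_of=representative_of,
        alignment=alignment,
        groups=groups,
        dm=dm,
        group_table=table,
        tree=tree,
        incongruence=reports,
    )


@dataclass
class ScreenResult:
    candidates: list[RepeatUnit]
    differentials: dict[str, DifferentialSimilarity]
    similarity: Optional[SimilarityResult]
    marker_table: pd.DataFrame
    presence: dict[str, RepeatPresence]
    window_stats: list[list[cov.WindowStat]]  # one list per library
    annotations: list[cov.WindowAnnotation]
    evidence: list[EvidenceTable]
    verdicts: list[Verdict]
    overall_call: str
    unmapped: list[int] = field(default_factory=list)


def _host_unit_sample(
    host, array_name: str, unit_len: int, n: int, label: str
) -> list[SequenceRecord]:
    """Slice the first n unit copies out of a host tandem array."""
    ivs = host.truth.intervals(name=array_name)
    if not ivs:
        return []
    iv = ivs[0]
    contig = next(r for r in host.records if r.id == iv.seq_id)
    out = []
    for i in range(n):
        start = iv.start + i * unit_len
        end = start + unit_len
        if end > iv.end:
            break
        out.append(
            SequenceRecord(
                id=f"{label}_u{i + 1}",
                residues=contig.residues[start:end],
                group="host",
            )
        )
    return out


def screen_assembly(
    parasite_records: Sequence[SequenceRecord],
    host,
    libraries: Sequence[Sequence] = (),
    window_width: int = 10_000,
    alpha: float = 0.01,
    m: int = 3,
    bootstrap_reps: int = 0,
    seed: int = 0,
    max_candidate_units: int = 12,
    host_units_per_family: int = 6,
    map_k: int = 21,
    max_mismatch: int = 3,
    incongruence_radius: float = 0.15,
) -> ScreenResult:
    """Full contamination-vs-transfer screen of a parasite assembly.

    ``host`` is a :class:`~hgtscreen.simulate.HostGenome`-shaped bundle:
    records, reference units, gene panel, marker sets and repeat probes.
    Windows must be significant in *every* library to count as enriched
    (the replicated-library criterion).

    A candidate counts as incongruently placed only if the scan flags it
    *and* its nearest foreign leaf lies within ``incongruence_radius``
    (patristic, subs/site): transfer-style incongruence means being nested
    inside the foreign clade, whereas a lone diverged native unit also has
    a minority neighborhood but sits far from everyone.
    """
    parasite_records = list(parasite_records)
    pindex = KmerIndex(parasite_records, k=11)

    # --- candidate units ---------------------------------------------------
    candidates = extract_units(
        pindex, host.somatic_unit, max_units=max_candidate_units
    )
    references = {"somatic": host.somatic_unit, "oocyte": host.oocyte_unit}
    differentials: dict[str, DifferentialSimilarity] = {}
    best_ref: dict[str, str] = {}
    for cand in candidates:
        results = {
            name: differential_similarity(cand, ref) for name, ref in references.items()
        }
        chosen = max(results, key=lambda n: results[n].overall_sim)
        differentials[cand.record.id] = results[chosen]
        best_ref[cand.record.id] = chosen

    # --- tree / incongruence ----------------------------------------------
    similarity: Optional[SimilarityResult] = None
    flagged_reps: set[str] = set()
    rep_of: dict[str, str] = {}
    if candidates:
        som_len = len(host.somatic_unit.record)
        oo_len = len(host.oocyte_unit.record)
        glen = len(host.somatic_unit.gene_seq)
        tree_records = (
            _host_unit_sample(host, "5S_somatic_array", som_len,
                              host_units_per_family, "host_somatic")
            + _host_unit_sample(host, "5S_oocyte_major_array", oo_len,
                                host_units_per_family, "host_oocyte")
        )
        gene_records = [
            SequenceRecord(id=rec.id, residues=rec.residues[:glen], group="host")
            for rec in tree_records
        ]
        gene_records += [
            SequenceRecord(id=c.record.id, residues=c.gene_seq, group="parasite")
            for c in candidates
        ]
        try:
            similarity = run_similarity(
                gene_records, bootstrap_reps=bootstrap_reps, seed=seed, m=m
            )
            rep_of = similarity.representative_of
            flagged_reps = {
                r.leaf_id
                for r in similarity.incongruence
                if r.flagged and r.nearest_foreign_distance <= incongruence_radius
            }
        except ValueError:
            similarity = None  # degenerate (everything collapsed); E1 unknown

    # --- marker screen and repeat presence ----------------------------------
    marker_table = marker_screen(pindex, host.marker_sets)
    presence = {
        family: repeat_presence(pindex, probe, family, copies)
        for family, (probe, copies) in host.repeat_probes.items()
    }
    single_copy_found = int(
        marker_table.query("category == 'single_copy' and found").shape[0]
    )
    te_found = int(
        marker_table.query("category == 'high_copy_TE' and found").shape[0]
    )
    abundant = presence["oocyte_5S"].present_strict if "oocyte_5S" in presence else None
    rare = presence["somatic_5S"].present_loose if "somatic_5S" in presence else None

    # --- read mapping / window enrichment -----------------------------------
    window_stats: list[list[cov.WindowStat]] = []
    unmapped_counts: list[int] = []
    annotations: list[cov.WindowAnnotation] = []
    if libraries:
        gindex = cov.GenomeIndex(host.records, k=map_k)
        lengths = {rec.id: len(rec) for rec in host.records}
        for li, reads in enumerate(libraries):
            placements, unmapped = cov.map_reads(
                reads, gindex, k=map_k, max_mismatch=max_mismatch,
                seed=(seed * 1000 + li) % (2**31 - 1),
            )
            stats = cov.window_counts(placements, lengths, width=window_width)
            window_stats.append(cov.poisson_enrichment(stats, alpha=alpha))
            unmapped_counts.append(unmapped)
        sig_keys = None
        for stats in window_stats:
            keys = {
                (w.window.seq_id, w.window.start) for w in stats if w.significant
            }
            sig_keys = keys if sig_keys is None else (sig_keys & keys)
        shared_sig = [
            w
            for w in window_stats[0]
            if (w.window.seq_id, w.window.start) in (sig_keys or set())
        ]
        probes = {
            "5S_somatic": [host.somatic_unit.record],
            "5S_oocyte": [host.oocyte_unit.record],
        }
        for mset in host.marker_sets:
            probes[mset.name] = mset.sequences
        probes["microsatellite"] = [
            SequenceRecord(id="ms_AT", residues="AT" * 30),
            SequenceRecord(id="ms_AC", residues="AC" * 30),
        ]
        probes["telomere"] = [SequenceRecord(id="telomere", residues="TTAGGG" * 10)]
        annotations = cov.annotate_windows(shared_sig, host.records, probes)
    explained_by = sorted({lab for ann in annotations for lab in ann.labels})

    # --- evidence and verdicts ----------------------------------------------
    evidence: list[EvidenceTable] = []
    verdicts: list[Verdict] = []
    for cand in candidates:
        cid = cand.record.id
        diff = differentials[cid]
        rep = rep_of.get(cid)
        incongruent = (rep in flagged_reps) if (similarity and rep) else None
        ev = EvidenceTable(
            candidate_id=cid,
            incongruent_placement=incongruent,
            extended_nts_similarity=diff.category == "extended_similarity",
            gene_similarity=diff.gene_sim,
            nts_similarity=diff.nts_sim,
            nts_not_identical=(diff.nts_sim < 100.0) if not diff.undefined else None,
            single_copy_markers_found=single_copy_found,
            high_copy_te_found=te_found,
            abundant_repeat_type_present=abundant,
            rare_repeat_type_present=rare,
            significant_windows_explained_by=explained_by if libraries else None,
            provenance={
                "reference_unit": best_ref[cid],
                "tree_leaf": rep,
            },
        )
        evidence.append(ev)
        verdicts.append(decide(ev))
    calls = [v.call for v in verdicts]
    if not calls:
        overall = "inconclusive"
    elif "contamination_suspected" in calls:
        overall = "contamination_suspected"
    elif "HGT_candidate" in calls:
        overall = "HGT_candidate"
    else:
        overall = "inconclusive"
    return ScreenResult(
        candidates=candidates,
        differentials=differentials,
        similarity=similarity,
        marker_table=marker_table,
        presence=presence,
        window_stats=window_stats,
        annotations=annotations,
        evidence=evidence,
        verdicts=verdicts,
        overall_call=overall,
        unmapped=unmapped_counts,
    )


@dataclass
class ScenarioResult:
    data: ScenarioData
    screen: ScreenResult

    @property
    def overall_call(self) -> str:
        return self.screen.overall_call


def run_scenario(
    config: ScenarioConfig,
    window_width: int = 10_000,
    with_reads: bool = True,
    bootstrap_reps: int = 0,
    **screen_kwargs,
) -> ScenarioResult:
    """Generate a synthetic scenario and push it through the full screen."""
    data = generate_scenario(config)
    screen = screen_assembly(
        data.parasite.records,
        data.host,
        libraries=data.libraries if with_reads else (),
        window_width=window_width,
        seed=config.seed,
        bootstrap_reps=bootstrap_reps,
        **screen_kwargs,
    )
    return ScenarioResult(data=data, screen=screen)
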