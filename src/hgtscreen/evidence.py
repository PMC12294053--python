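"""Marker-based contamination screen and the HGT-vs-contamination verdict.

The decision logic encodes, as explicit auditable boolean rules, the
qualitative argument that separates genuine horizontal transfer from
assembly contamination:

* under contamination, host DNA enters the parasite library in proportion
  to copy number — so the *abundant* host repeat families (the major oocyte
  5S type, high-copy transposable elements, 40S rDNA) and eventually
  single-copy genes should all be recoverable from the assembly;
* under transfer, only the transferred unit is present, its spacer has had
  time to diverge (non-zero NTS divergence), and it sits incongruently in
  the gene tree while every contamination indicator stays silent.

The verdict is a pure function of the evidence table; every fired rule is
reported with its outcome so the inference can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import pandas as pd

from .align import KmerIndex, local_search
from .seqio import SequenceRecord

MARKER_CATEGORIES = (
    "single_copy",
    "multigene_conserved",
    "high_copy_TE",
    "low_copy_TE",
    "rdna_spacer",
    "rdna_transcribed",
)


@dataclass
class MarkerSet:
    """A named set of probe sequences of one marker category.

    ``expected_if_contaminated`` marks categories abundant enough in the
    host genome that contamination would almost surely carry them over
    (high-copy TEs, abundant rDNA types).
    """

    name: str
    category: str
    sequences: list[SequenceRecord]
    expected_if_contaminated: bool = False

    def __post_init__(self) -> None:
        if self.category not in MARKER_CATEGORIES:
            raise ValueError(f"unknown marker category {self.category!r}")
        if not self.sequences:
            raise ValueError(f"marker set {self.name!r} has no sequences")


DEFAULT_THRESHOLDS = {cat: (0.90, 0.50) for cat in MARKER_CATEGORIES}


def marker_screen(
    target: Sequence[SequenceRecord] | KmerIndex,
    marker_sets: Sequence[MarkerSet],
    thresholds: Optional[dict[str, tuple[float, float]]] = None,
    conserved_subregions: Optional[dict[str, tuple[int, int]]] = None,
    k: int = 11,
) -> pd.DataFrame:
    """Search every marker against the target assembly.

    A marker is "found" iff its best hit clears the per-category
    (min_identity, min_query_cover) thresholds (default 0.90 / 0.50).  When
    a conserved subregion (query-local interval) is supplied for a marker,
    a found hit confined to that subregion is flagged
    ``restricted_to_subregion`` — correspondence limited to the conserved
    core is expected between distant genomes and is not contamination
    evidence.
    """
    if not marker_sets:
        raise ValueError("no marker sets supplied")
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(thresholds or {})
    index = target if isinstance(target, KmerIndex) else KmerIndex(list(target), k=k)
    rows = []
    for mset in marker_sets:
        min_id, min_cover = thr[mset.category]
        for probe in mset.sequences:
            hits = local_search(probe, index, k=k, min_identity=min(min_id, 0.6), min_score=15.0)
            best = hits[0] if hits else None
            found = bool(
                best and best.identity >= min_id and best.query_cover >= min_cover
            )
            restricted = False
            sub = (conserved_subregions or {}).get(probe.id)
            if best is not None and sub is not None:
                margin = 10
                restricted = (
                    best.query_iv.start >= sub[0] - margin
                    and best.query_iv.end <= sub[1] + margin
                )
            rows.append(
                {
                    "marker_set": mset.name,
                    "category": mset.category,
                    "probe_id": probe.id,
                    "found": found,
                    "best_identity": best.identity if best else float("nan"),
                    "best_query_cover": best.query_cover if best else 0.0,
                    "best_subject": best.subject_id if best else "",
                    "restricted_to_subregion": restricted,
                    "expected_if_contaminated": mset.expected_if_contaminated,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RepeatPresence:
    """Presence of a host repeat family in the target assembly, two-level.

    ``present_strict`` (identity >= 0.9, near-verbatim: contamination-grade)
    vs ``present_loose`` (identity >= 0.65: the family is detectable at all,
    e.g. a diverged transferred copy).
    """

    family: str
    declared_copy_number: int
    present_strict: bool
    present_loose: bool
    best_identity: float


def repeat_presence(
    target: Sequence[SequenceRecord] | KmerIndex,
    probe: SequenceRecord,
    family: str,
    declared_copy_number: int,
    strict_identity: float = 0.90,
    loose_identity: float = 0.65,
    min_cover: float = 0.5,
    k: int = 11,
) -> RepeatPresence:
    """Two-level presence call for one repeat family probe (usually an NTS)."""
    index = target if isinstance(target, KmerIndex) else KmerIndex(list(target), k=k)
    hits = local_search(probe, index, k=k, min_identity=loose_identity, min_score=15.0)
    qualifying = [h for h in hits if h.query_cover >= min_cover]
    best_id = max((h.identity for h in qualifying), default=0.0)
    return RepeatPresence(
        family=family,
        declared_copy_number=declared_copy_number,
        present_strict=best_id >= strict_identity,
        present_loose=best_id >= loose_identity,
        best_identity=best_id,
    )


@dataclass
class EvidenceTable:
    """Structured per-candidate evidence feeding the verdict.

    Optional fields left as None mean "unknown" and force an inconclusive
    verdict.  ``provenance`` points each entry at the upstream record that
    produced it.
    """

    candidate_id: str
    incongruent_placement: Optional[bool] = None          # tree scan
    extended_nts_similarity: Optional[bool] = None        # differential similarity
    gene_similarity: Optional[float] = None
    nts_similarity: Optional[float] = None
    nts_not_identical: Optional[bool] = None              # 0 < NTS divergence
    single_copy_markers_found: Optional[int] = None
    high_copy_te_found: Optional[int] = None
    abundant_repeat_type_present: Optional[bool] = None
    rare_repeat_type_present: Optional[bool] = None
    significant_windows_explained_by: Optional[list[str]] = None
    provenance: dict = field(default_factory=dict)

    def complete(self) -> bool:
        required = (
            self.incongruent_placement,
            self.extended_nts_similarity,
            self.nts_not_identical,
            self.single_copy_markers_found,
            self.high_copy_te_found,
            self.abundant_repeat_type_present,
        )
        return all(v is not None for v in required)


@dataclass
class Verdict:
    """The decision for one candidate, with the full rule audit trail."""

    call: str  # HGT_candidate | contamination_suspected | inconclusive
    fired_rules: list[tuple[str, str]]
    narrative: str


def decide(evidence: EvidenceTable) -> Verdict:
    """Combine the evidence table into a verdict (pure, order-independent).

    contamination_suspected iff any contamination indicator fired: a
    single-copy host marker or high-copy host TE recovered from the
    assembly, or the abundant host repeat type present near-verbatim.
    HGT_candidate iff the candidate is incongruently placed, shows extended
    (gene + NTS) similarity, its NTS is measurably diverged, and no
    contamination indicator fired.  Anything else — including unknown
    fields — is inconclusive.
    """
    rules: list[tuple[str, str]] = []
    if not evidence.complete():
        rules.append(("evidence_complete", "failed: unknown fields present"))
        return Verdict(
            call="inconclusive",
            fired_rules=rules,
            narrative="Evidence table incomplete; no call can be made.",
        )
    contamination = False
    if evidence.single_copy_markers_found > 0:
        contamination = True
        rules.append(("single_copy_recovered", f"{evidence.single_copy_markers_found} single-copy host markers in assembly"))
    else:
        rules.append(("single_copy_absence", "no single-copy host gene recovered"))
    if evidence.high_copy_te_found > 0:
        contamination = True
        rules.append(("high_copy_te_recovered", f"{evidence.high_copy_te_found} high-copy host TEs in assembly"))
    else:
        rules.append(("te_absence", "no high-copy host TE recovered (incl. the most abundant family)"))
    if evidence.abundant_repeat_type_present:
        contamination = True
        rules.append(("copy_number_asymmetry", "failed: abundant host repeat type present near-verbatim"))
    else:
        asym = "abundant host type absent"
        if evidence.rare_repeat_type_present:
            asym += "; rare (somatic-type) family detectable"
        rules.append(("copy_number_asymmetry", asym))
    rules.append(
        ("phylogenetic_incongruence",
         "candidate clusters with host sequences" if evidence.incongruent_placement
         else "candidate clusters with its own group")
    )
    rules.append(
        ("extended_nts_similarity",
         "similarity extends into the spacer (against convergence)"
         if evidence.extended_nts_similarity else "spacer similarity absent")
    )
    rules.append(
        ("nts_divergence",
         "spacer measurably diverged (against fresh contamination)"
         if evidence.nts_not_identical else "spacer identical to host")
    )
    if contamination:
        call = "contamination_suspected"
        narrative = (
            "At least one contamination indicator fired: host-derived "
            "high-copy sequence recovered from the assembly in proportion "
            "to copy number, as expected for library contamination."
        )
    elif (
        evidence.incongruent_placement
        and evidence.extended_nts_similarity
        and evidence.nts_not_identical
    ):
        call = "HGT_candidate"
        narrative = (
            "Incongruent tree placement with similarity extending into the "
            "diverged spacer, while every contamination indicator is "
            "silent: consistent with a horizontal transfer event."
        )
    else:
        call = "inconclusive"
        narrative = "Neither the transfer nor the contamination pattern is complete."
    return Verdict(call=call, fired_rules=rules, narrative=narrative)


def write_evidence_json(
    evidence: Sequence[EvidenceTable], verdicts: Sequence[Verdict], path: str
) -> None:
    payload = [
        {"evidence": asdict(ev), "verdict": asdict(v)}
        for ev, v in zip(evidence, verdicts)
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def write_report_md(
    evidence: Sequence[EvidenceTable], verdicts: Sequence[Verdict], path: str
) -> None:
    """Human-readable per-candidate report."""
    with open(path, "w") as fh:
        fh.write("# HGT / contamination screening report\n\n")
        if not evidence:
            fh.write("No candidate units were identified; nothing to evaluate.\n")
        for ev, v in zip(evidence, verdicts):
            fh.write(f"## Candidate `{ev.candidate_id}`: **{v.call}**\n\n")
            fh.write(v.narrative + "\n\n")
            if ev.gene_similarity is not None:
                fh.write(
                    f"- gene similarity {ev.gene_similarity:.2f}%, "
                    f"NTS similarity {ev.nts_similarity:.2f}%\n"
                )
            for rule, outcome in v.fired_rules:
                fh.write(f"- `{rule}`: {outcome}\n")
            fh.write("\n")
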