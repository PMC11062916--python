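"""Candidate prioritization cascade for TF-regulated miRNAs.

The cascade turns independent evidence layers into an auditable ranked list:

1. keep miRNAs with a consensus ChIP peak inside the 10 kb upstream window;
2. intersect with miRNAs significantly differential between driver-high and
   driver-low tumours;
3. annotate tumour-versus-normal cohort direction consistency;
4. apply the transcription-start-site distance rule (binding within 2 kb for
   intergenic loci, 4 kb for intronic loci whose promoter sits in the host
   gene);
5. drop miRNAs on an explicit known-miRNA exclusion list.

Tier 1 candidates pass stages 1-4; tier 2 pass binding, differential
expression and the distance rule but lack cohort confirmation; tier 3 pass
binding and differential expression only. Every record keeps its full
evidence trail so the narrowing is reproducible and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .cohorts import DirectionCall, direction_consistency
from .expression import differential_expression
from .intervals import BindingAssignment

__all__ = [
    "DistanceRule",
    "CandidateRecord",
    "ClinicalAssociation",
    "distance_rule_pass",
    "run_cascade",
    "clinical_association",
]


@dataclass(frozen=True)
class DistanceRule:
    """Maximum peak-to-TSS distance by genomic class (bp)."""

    max_distance_intergenic: int = 2000
    max_distance_intronic: int = 4000

    def __post_init__(self) -> None:
        if self.max_distance_intergenic <= 0 or self.max_distance_intronic <= 0:
            raise ValueError("distance limits must be positive")


@dataclass
class CandidateRecord:
    """One miRNA's complete evidence trail through the cascade."""

    mirna_id: str
    bound: bool = False
    distance_bp: Optional[int] = None
    genomic_class: Optional[str] = None
    de_direction: Optional[str] = None
    de_fdr: Optional[float] = None
    de_significant: bool = False
    cohort_consistent: bool = False
    distance_pass: bool = False
    clinical_flags: set = field(default_factory=set)
    excluded_reason: Optional[str] = None
    tier: Optional[int] = None


def distance_rule_pass(
    bound: bool, distance_bp: Optional[int], genomic_class: Optional[str],
    rule: DistanceRule = DistanceRule(),
) -> bool:
    """Apply the genomic-class TSS-distance rule to a bound locus."""
    if not bound or distance_bp is None:
        return False
    if genomic_class == "intergenic":
        return distance_bp <= rule.max_distance_intergenic
    if genomic_class == "intronic":
        return distance_bp <= rule.max_distance_intronic
    raise ValueError(f"missing or unknown genomic class {genomic_class!r}")


def _tier(rec: CandidateRecord) -> Optional[int]:
    if not (rec.bound and rec.de_significant):
        return None
    if rec.distance_pass and rec.cohort_consistent:
        return 1
    if rec.distance_pass:
        return 2
    return 3


def run_cascade(
    binding: Sequence[BindingAssignment],
    de: pd.DataFrame,
    cohorts: Sequence[DirectionCall],
    genomic_classes: Mapping[str, str],
    rule: DistanceRule = DistanceRule(),
    exclusions: Sequence[str] = (),
) -> tuple[list[CandidateRecord], dict[str, int]]:
    """Run the evidence cascade and rank the surviving candidates.

    ``de`` is the driver-high versus driver-low differential-expression table
    (output of :func:`mirreg.expression.differential_expression`).

    Returns (records, stage_counts). ``records`` holds every bound+DE miRNA:
    ranked candidates first (tier 1, then 2, then 3; within a tier ascending
    FDR then ascending binding distance), followed by excluded entries with
    ``excluded_reason`` set. ``stage_counts`` reports survivors per stage.
    """
    exclusion_set = set(exclusions)
    records: list[CandidateRecord] = []
    for ba in binding:
        if not ba.bound:
            continue
        rec = CandidateRecord(
            mirna_id=ba.mirna_id,
            bound=True,
            distance_bp=ba.distance_bp,
            genomic_class=genomic_classes.get(ba.mirna_id),
        )
        if ba.mirna_id in de.index:
            row = de.loc[ba.mirna_id]
            rec.de_direction = str(row["direction"])
            rec.de_fdr = float(row["fdr"])
            rec.de_significant = bool(row["significant"])
        records.append(rec)
    stage_counts = {"bound": len(records)}

    survivors = [r for r in records if r.de_significant]
    stage_counts["bound_and_de"] = len(survivors)

    for rec in survivors:
        tumour = DirectionCall(rec.mirna_id, rec.de_direction or "up")
        rec.cohort_consistent = direction_consistency(tumour, cohorts)
    stage_counts["cohort_consistent"] = sum(r.cohort_consistent for r in survivors)

    for rec in survivors:
        rec.distance_pass = distance_rule_pass(
            rec.bound, rec.distance_bp, rec.genomic_class, rule
        )
    stage_counts["distance_pass"] = sum(r.distance_pass for r in survivors)

    for rec in survivors:
        rec.tier = _tier(rec)
        if rec.mirna_id in exclusion_set:
            rec.excluded_reason = "known"
    stage_counts["tier1"] = sum(
        r.tier == 1 and r.excluded_reason is None for r in survivors
    )
    stage_counts["excluded_known"] = sum(
        r.excluded_reason == "known" for r in survivors
    )

    ranked = sorted(
        (r for r in survivors if r.excluded_reason is None),
        key=lambda r: (
            r.tier,
            r.de_fdr if r.de_fdr is not None else 1.0,
            r.distance_bp if r.distance_bp is not None else 10**9,
            r.mirna_id,
        ),
    )
    excluded = [r for r in survivors if r.excluded_reason is not None]
    return ranked + excluded, stage_counts


@dataclass
class ClinicalAssociation:
    """Per-feature clinical contrasts and the resulting evidence flags."""

    feature: str
    flags: set
    contrasts: dict[str, Optional[pd.Series]]  # name -> DE row or None


def clinical_association(
    norm: pd.DataFrame,
    meta: pd.DataFrame,
    feature: str,
    alpha: float = 0.05,
) -> ClinicalAssociation:
    """Test a miRNA's association with GCNIS status and disease stage.

    Contrasts: GCNIS present vs absent; stage II vs I; stage III vs I (stage
    I as reference). Each contrast runs the full differential-expression
    machinery over all features so the BH family is consistent, then reads
    off the requested feature's row. ``gcnis_assoc`` is flagged when the
    GCNIS contrast has FDR < alpha; ``stage_assoc`` when either stage
    contrast does. Contrast levels with fewer than 2 samples are reported as
    not evaluable (None).
    """
    if feature not in norm.index:
        raise KeyError(f"feature {feature!r} not in matrix")
    tables = clinical_contrast_tables(norm, meta, alpha=alpha)
    contrasts = {
        name: (t.loc[feature] if t is not None else None)
        for name, t in tables.items()
    }
    flags = flags_from_tables(tables, feature, alpha=alpha)
    return ClinicalAssociation(feature=feature, flags=flags, contrasts=contrasts)


def clinical_contrast_tables(
    norm: pd.DataFrame, meta: pd.DataFrame, alpha: float = 0.05
) -> dict[str, Optional[pd.DataFrame]]:
    """All-feature DE tables for the three clinical contrasts.

    Computes what :func:`clinical_association` needs once for the whole
    matrix, so flagging many candidates costs three tests total instead of
    three per candidate. A contrast with <2 samples in a level is None.
    """
    meta = meta.loc[[s for s in norm.columns if s in meta.index]]

    def contrast(col: str, level_a: str, level_b: str) -> Optional[pd.DataFrame]:
        a = list(meta.index[meta[col] == level_a])
        b = list(meta.index[meta[col] == level_b])
        if len(a) < 2 or len(b) < 2:
            return None
        return differential_expression(norm, a, b, alpha=alpha)

    return {
        "gcnis_present_vs_absent": contrast("gcnis", "present", "absent"),
        "stage_II_vs_I": contrast("stage", "II", "I"),
        "stage_III_vs_I": contrast("stage", "III", "I"),
    }


def flags_from_tables(
    tables: Mapping[str, Optional[pd.DataFrame]], feature: str, alpha: float = 0.05
) -> set:
    """Clinical evidence flags for one feature from precomputed contrasts."""
    flags = set()
    g = tables.get("gcnis_present_vs_absent")
    if g is not None and feature in g.index and g.loc[feature, "fdr"] < alpha:
        flags.add("gcnis_assoc")
    for name in ("stage_II_vs_I", "stage_III_vs_I"):
        t = tables.get(name)
        if t is not None and feature in t.index and t.loc[feature, "fdr"] < alpha:
            flags.add("stage_assoc")
    return flags


def records_frame(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Tabulate cascade records for report output."""
    rows = []
    for r in records:
        rows.append(
            {
                "mirna_id": r.mirna_id,
                "tier": r.tier,
                "bound": r.bound,
                "distance_bp": r.distance_bp,
                "genomic_class": r.genomic_class,
                "de_direction": r.de_direction,
                "de_fdr": r.de_fdr,
                "de_significant": r.de_significant,
                "cohort_consistent": r.cohort_consistent,
                "distance_pass": r.distance_pass,
                "clinical_flags": ";".join(sorted(r.clinical_flags)),
                "excluded_reason": r.excluded_reason or "",
            }
        )
    columns = [
        "mirna_id", "tier", "bound", "distance_bp", "genomic_class",
        "de_direction", "de_fdr", "de_significant", "cohort_consistent",
        "distance_pass", "clinical_flags", "excluded_reason",
    ]
    return pd.DataFrame(rows, columns=columns)
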