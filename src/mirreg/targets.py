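"""Downstream target analysis: prediction consensus, signature overlaps,
cytoband filtering and qPCR relative quantification.

Target predictions from several algorithms are consumed as plain gene
lists and combined by vote counting. Relative quantification follows the
comparative-Ct (delta-delta-Ct) method with amplification efficiency fixed
at 2.0, normalizing a target gene to an endogenous reference whose
stability across samples is ranked by the standard deviation of its Ct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohorts import VennResult, set_overlap

__all__ = [
    "TargetPredictionSet",
    "target_consensus",
    "signature_overlap",
    "parse_cytoband",
    "cytoband_filter",
    "reference_stability",
    "ddct_fold_change",
]


@dataclass
class TargetPredictionSet:
    """One prediction algorithm's gene list."""

    algorithm_name: str
    targets: set

    def __post_init__(self) -> None:
        self.targets = {str(g) for g in self.targets}
        if any(not g for g in self.targets):
            raise ValueError(f"{self.algorithm_name}: empty gene id")


def target_consensus(
    sets: Sequence[TargetPredictionSet], min_votes: int = 2
) -> pd.DataFrame:
    """Genes predicted by at least ``min_votes`` algorithms, with vote counts.

    Returns a DataFrame indexed by gene with columns ``votes`` and
    ``algorithms`` (semicolon-joined supporter names), sorted by descending
    votes then gene id.
    """
    if not 1 <= min_votes <= len(sets):
        raise ValueError(
            f"min_votes={min_votes} out of range for {len(sets)} prediction sets"
        )
    votes: dict[str, list[str]] = {}
    for ps in sets:
        for gene in ps.targets:
            votes.setdefault(gene, []).append(ps.algorithm_name)
    rows = [
        {"gene": g, "votes": len(algs), "algorithms": ";".join(sorted(algs))}
        for g, algs in votes.items()
        if len(algs) >= min_votes
    ]
    df = pd.DataFrame(rows, columns=["gene", "votes", "algorithms"])
    return df.sort_values(["votes", "gene"], ascending=[False, True]).set_index("gene")


def signature_overlap(
    downregulated: Iterable, predicted_targets: Iterable, signature: Iterable
) -> VennResult:
    """Three-way overlap of downregulated genes, predicted targets and a
    cell-type signature.

    The triple intersection is the "direct target in signature" set — genes
    both predicted and observed to fall, inside the signature of interest.
    """
    return set_overlap(
        {
            "downregulated": downregulated,
            "predicted_targets": predicted_targets,
            "signature": signature,
        }
    )


_BAND_RE = re.compile(r"^(?P<chrom>\d{1,2}|X|Y)(?P<arm>[pq])(?P<band>[\d.]*)$")


def parse_cytoband(label: str) -> tuple[str, str, str]:
    """Split a cytoband label like '12p13.31' into (chromosome, arm, band)."""
    m = _BAND_RE.match(label.strip())
    if not m:
        raise ValueError(f"unparseable cytoband label {label!r}")
    return m.group("chrom"), m.group("arm"), m.group("band")


def cytoband_filter(
    genes: Iterable, band_map: Mapping[str, str], band_prefix: str = "12p"
) -> tuple[set, set]:
    """Select genes mapping to a cytoband prefix (e.g. the 12p arm).

    Returns (matching genes, unmapped genes). Genes absent from the map are
    reported, never silently dropped.
    """
    parse_cytoband(band_prefix)  # validates chromosome + arm (+ optional sub-band)
    kept: set = set()
    unmapped: set = set()
    for gene in genes:
        band = band_map.get(gene)
        if band is None:
            unmapped.add(gene)
        elif band.startswith(band_prefix):
            kept.add(gene)
    return kept, unmapped


def _mean_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates: (sample, gene) -> mean Ct."""
    required = {"sample", "gene", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    vals = ct["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("Ct values must be finite and positive")
    return ct.groupby(["sample", "gene"], sort=True)["ct"].mean().unstack("gene")


def reference_stability(
    ct: pd.DataFrame, candidate_refs: Sequence[str]
) -> pd.DataFrame:
    """Rank candidate endogenous-control genes by Ct stability.

    Replicates are averaged first; per candidate the standard deviation and
    coefficient of variation of Ct across samples are computed, and
    candidates are ranked ascending by SD (ties by CV, then name). A
    candidate measured in fewer than half the samples is excluded with a
    reason instead of being ranked.
    """
    wide = _mean_ct(ct)
    n_samples = wide.shape[0]
    rows = []
    for gene in candidate_refs:
        if gene not in wide.columns:
            rows.append({"gene": gene, "sd": np.nan, "cv": np.nan,
                         "n_samples": 0, "excluded": "absent from table"})
            continue
        vals = wide[gene].dropna()
        if len(vals) < 2 or len(vals) <= n_samples / 2:
            rows.append({"gene": gene, "sd": np.nan, "cv": np.nan,
                         "n_samples": len(vals),
                         "excluded": "measured in <=50% of samples"})
            continue
        sd = float(vals.std(ddof=1))
        cv = sd / float(vals.mean())
        rows.append({"gene": gene, "sd": sd, "cv": cv,
                     "n_samples": len(vals), "excluded": ""})
    df = pd.DataFrame(rows)
    ranked = df[df["excluded"] == ""].sort_values(
        ["sd", "cv", "gene"], kind="stable"
    )
    excluded = df[df["excluded"] != ""]
    out = pd.concat([ranked, excluded], ignore_index=True)
    out["rank"] = [i + 1 if not e else None for i, e in enumerate(out["excluded"])]
    return out.set_index("gene")


def ddct_fold_change(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    control_group: Sequence[str],
    treated_group: Sequence[str],
) -> tuple[pd.Series, dict[str, float]]:
    """Comparative-Ct relative quantification of ``target`` against
    ``reference``.

    Per sample (replicates averaged): dCt = Ct_target - Ct_reference;
    ddCt = dCt - mean(dCt over control group); fold = 2**(-ddCt).

    Returns per-treated-sample fold changes and a summary dict with the
    treated-group mean and SD.
    """
    if not list(control_group):
        raise ValueError("control group is empty")
    wide = _mean_ct(ct)
    for gene in (target, reference):
        if gene not in wide.columns:
            raise KeyError(f"gene {gene!r} absent from Ct table")
    involved = list(control_group) + list(treated_group)
    sub = wide.loc[involved, [target, reference]]
    if sub.isna().any().any():
        missing = sub[sub.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing Ct for samples {missing}")
    dct = sub[target] - sub[reference]
    calibrator = dct.loc[list(control_group)].mean()
    ddct = dct.loc[list(treated_group)] - calibrator
    fold = np.power(2.0, -ddct).rename("fold_change")
    summary = {
        "mean": float(fold.mean()),
        "sd": float(fold.std(ddof=1)) if len(fold) > 1 else 0.0,
        "n": int(len(fold)),
    }
    return fold, summary
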