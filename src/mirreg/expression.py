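"""Normalization, driver-gene stratification and differential expression.

The count matrix is a pandas DataFrame with features as rows and samples as
columns. Normalization is counts-per-million followed by log2(x+1); tumours
are stratified into high/medium/low strata on a driver gene (for testicular
germ cell tumours, the pluripotency factor NANOG) either by expression
tertiles or by explicit cutoffs. Differential expression between strata uses
a two-sided rank-sum test on the normalized values with Benjamini-Hochberg
false-discovery control; a feature is called significant only when its mean
log2 normalized expression additionally clears an expression floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "SampleMetadata",
    "Stratification",
    "normalize_log2",
    "stratify_tertiles",
    "stratify_by_cutoff",
    "bh_adjust",
    "differential_expression",
    "spearman_matrix",
    "cluster_order",
    "pca_scores",
]

SUBTYPES = ("SEM", "EC", "TERA", "YST", "mixed")
GCNIS_LEVELS = ("present", "absent", "unknown")
STAGES = ("I", "II", "III", "unknown")


@dataclass(frozen=True)
class SampleMetadata:
    """Clinical annotations for one tumour sample."""

    sample_id: str
    subtype: str
    gcnis: str = "unknown"
    stage: str = "unknown"

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"{self.sample_id}: unknown subtype {self.subtype!r}")
        if self.gcnis not in GCNIS_LEVELS:
            raise ValueError(f"{self.sample_id}: unknown GCNIS status {self.gcnis!r}")
        if self.stage not in STAGES:
            raise ValueError(f"{self.sample_id}: unknown stage {self.stage!r}")


@dataclass
class Stratification:
    """Assignment of samples to driver-expression strata (H/M/L or H/L)."""

    driver: str
    assignments: dict[str, str]  # sample_id -> stratum
    cutoffs: tuple[float, ...] = field(default_factory=tuple)

    def samples_in(self, stratum: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == stratum]


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate feature ids in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")


def normalize_log2(counts: pd.DataFrame) -> pd.DataFrame:
    """Library-size normalize to counts-per-million, then log2(x + 1).

    Deterministic; the pseudo-count of 1 is applied after CPM scaling so a
    feature holding 1023 counts of a one-million-read library maps to 10.0.
    """
    _check_counts(counts)
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {', '.join(map(str, zero.index))}")
    cpm = counts.div(libsize, axis=1) * 1e6
    return np.log2(cpm + 1.0)


def stratify_tertiles(expr: pd.Series, driver: str = "driver") -> Stratification:
    """Split samples into H/M/L thirds by descending driver expression.

    Ties at the boundaries are broken by stable sample-id order. When the
    sample count is not divisible by 3 the highest stratum absorbs the
    remainder first (sizes differ by at most one).
    """
    n = len(expr)
    if n < 3:
        raise ValueError("tertile stratification requires at least 3 samples")
    order = sorted(expr.index, key=lambda s: (-expr[s], str(s)))
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n), 3)]
    assignments: dict[str, str] = {}
    bounds: list[float] = []
    pos = 0
    for stratum, size in zip(("H", "M", "L"), sizes):
        block = order[pos : pos + size]
        for s in block:
            assignments[s] = stratum
        if stratum != "L":
            bounds.append(float(expr[block[-1]]))
        pos += size
    return Stratification(driver=driver, assignments=assignments, cutoffs=tuple(bounds))


def stratify_by_cutoff(
    expr: pd.Series, cutoffs: Sequence[float], driver: str = "driver"
) -> Stratification:
    """Stratify by explicit boundary value(s); boundaries go to the upper stratum.

    One cutoff yields {H, L}; two cutoffs (ascending) yield {H, M, L}.
    """
    cuts = sorted(float(c) for c in cutoffs)
    if len(cuts) not in (1, 2):
        raise ValueError("expected one or two cutoff values")
    assignments: dict[str, str] = {}
    for s, v in expr.items():
        if len(cuts) == 1:
            assignments[s] = "H" if v >= cuts[0] else "L"
        else:
            if v >= cuts[1]:
                assignments[s] = "H"
            elif v >= cuts[0]:
                assignments[s] = "M"
            else:
                assignments[s] = "L"
    return Stratification(driver=driver, assignments=assignments, cutoffs=tuple(cuts))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def differential_expression(
    norm: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    expression_floor: float = 1.0,
) -> pd.DataFrame:
    """Per-feature rank-sum differential expression between two sample groups.

    Returns a DataFrame indexed by feature with columns ``log2fc`` (mean A
    minus mean B on the log2 scale), ``mean_log2`` (mean over both groups),
    ``p``, ``fdr`` (BH across all tested features), ``direction`` and
    ``significant`` (mean_log2 > expression_floor AND fdr < alpha).
    """
    a, b = list(group_a), list(group_b)
    if set(a) & set(b):
        raise ValueError("groups overlap")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = (set(a) | set(b)) - set(norm.columns)
    if missing:
        raise KeyError(f"samples absent from matrix: {sorted(missing)}")
    xa = norm[a].to_numpy(dtype=float)
    xb = norm[b].to_numpy(dtype=float)
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    mean_log2 = np.concatenate([xa, xb], axis=1).mean(axis=1)
    pvals = np.ones(norm.shape[0])
    for i in range(norm.shape[0]):
        if np.all(xa[i] == xa[i][0]) and np.all(xb[i] == xb[i][0]) and xa[i][0] == xb[i][0]:
            pvals[i] = 1.0  # degenerate: identical constant values
            continue
        pvals[i] = stats.mannwhitneyu(xa[i], xb[i], alternative="two-sided").pvalue
    fdr = bh_adjust(pvals)
    direction = np.where(log2fc < 0, "down", "up")
    significant = (mean_log2 > expression_floor) & (fdr < alpha)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "mean_log2": mean_log2,
            "p": pvals,
            "fdr": fdr,
            "direction": direction,
            "significant": significant,
        },
        index=pd.Index(norm.index, name="feature_id"),
    )


def spearman_matrix(norm: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Spearman correlation (average ranks for ties).

    Constant (zero-variance) samples yield NaN rows/columns and a warning;
    the diagonal is forced to exactly 1.
    """
    if norm.shape[1] < 2 or norm.shape[0] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    constant = [c for c in norm.columns if norm[c].nunique() == 1]
    if constant:
        warnings.warn(
            f"constant sample(s), correlation undefined: {constant}", UserWarning
        )
    rho = stats.spearmanr(norm.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=norm.columns, columns=norm.columns)


def cluster_order(corr: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Complete-linkage agglomeration on distance 1 - rho.

    Returns the dendrogram leaf order (sample ids) and the scipy linkage
    matrix (merge heights in column 2 are non-decreasing).
    """
    mat = corr.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("correlation matrix is not symmetric")
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    leaves = hierarchy.leaves_list(linkage)
    return [str(corr.columns[i]) for i in leaves], linkage


def pca_scores(norm: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Principal-component scores of samples from feature-centred data.

    Component signs are fixed by making each component's largest-magnitude
    feature loading positive, so results are reproducible across runs.
    """
    if norm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = norm.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = (u * s) * flip
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores[:, :n_components], index=norm.columns, columns=cols)


def metadata_frame(meta: Mapping[str, SampleMetadata]) -> pd.DataFrame:
    """Tabulate SampleMetadata records (sample_id index)."""
    rows = [
        {"sample_id": m.sample_id, "subtype": m.subtype, "gcnis": m.gcnis, "stage": m.stage}
        for m in meta.values()
    ]
    return pd.DataFrame(rows).set_index("sample_id")
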