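"""Synthetic data with planted ground truth for the full pipeline.

The generator emulates the statistical structure of the real inputs: a
miRNA locus annotation on a synthetic chromosome, replicate ChIP peak sets
with binding planted at controlled distances upstream of chosen loci,
negative-binomial miRNA counts across four tumour subtypes coupled to a
continuous driver-gene (NANOG-like) expression axis, two microarray-like
tumour-versus-normal fold-change cohorts, and clinical covariates (GCNIS,
stage) whose probabilities shift with the expression of the planted
candidates. Every artifact is a pure function of the configuration: the
same seed reproduces every table bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohorts import FoldChangeTable
from .intervals import GenomicInterval, MirnaLocus, PeakSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedBundle",
    "gen_annotation",
    "gen_ground_truth",
    "gen_chip_replicates",
    "gen_tumour_counts",
    "gen_normal_cohorts",
    "simulate_bundle",
]

# per-stage rng streams so regenerating one artifact never perturbs another
_STREAMS = {"annotation": 11, "truth": 23, "chip": 37, "counts": 53, "cohorts": 71}

_SLOT = 50_000  # bp reserved per locus on the synthetic chromosome
_SLOT_OFFSET = 30_000  # locus position inside its slot (leaves room for peaks)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 0
    n_mirnas: int = 200
    fraction_intronic: float = 0.3
    n_planted_regulated: int = 30
    planted_log2fc: float = 2.0  # magnitude; sign negative for repressed
    nb_dispersion: float = 0.3
    n_samples_per_subtype: tuple = (("SEM", 40), ("EC", 30), ("TERA", 10), ("YST", 10))
    driver_effect: float = 1.5  # slope of driver-percentile coupling
    planted_distance_range: tuple = (0, 1800)  # bp upstream, true regulation
    decoy_distance_range: tuple = (3000, 20000)  # bp upstream, decoy binding
    n_decoy_bound: int = 30
    replicate_jitter_bp: int = 50
    n_chip_replicates: int = 3
    peak_width_range: tuple = (200, 500)
    cohort_noise_sd: float = 0.2  # on log2 fold changes
    clinical_coupling: float = 0.55  # probability shift strength
    n_clinical_associated: int = 6
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.n_planted_regulated > self.n_mirnas:
            raise ValueError("more planted miRNAs than loci")
        if not 0 <= self.fraction_intronic <= 1:
            raise ValueError("fraction_intronic must be in [0,1]")
        if 2 * self.replicate_jitter_bp >= self.peak_width_range[0]:
            raise ValueError(
                "replicate jitter too large: strict-intersection consensus "
                "would vanish (need 2*jitter < minimum peak width)"
            )


@dataclass
class GroundTruth:
    """What was planted: the answer key for recovery tests."""

    planted_regulated: dict[str, float]  # mirna_id -> signed log2 effect
    planted_bound: dict[str, int]  # mirna_id -> true upstream distance (bp)
    clinical_associated: set = field(default_factory=set)

    @property
    def tier1_truth(self) -> set:
        """miRNAs planted as both proximally bound and driver-regulated."""
        return set(self.planted_regulated)


def _rng(cfg: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stage], cfg.seed])


def gen_annotation(cfg: SimulationConfig) -> list[MirnaLocus]:
    """Non-overlapping miRNA loci on one synthetic chromosome.

    Loci sit one per 50 kb slot with jittered position, random strand and
    random length (60-150 bp); each is intronic with probability
    ``fraction_intronic`` (and then gets a synthetic host gene).
    """
    rng = _rng(cfg, "annotation")
    loci: list[MirnaLocus] = []
    for i in range(cfg.n_mirnas):
        start = _SLOT * i + _SLOT_OFFSET + int(rng.integers(0, 8000))
        length = int(rng.integers(60, 151))
        strand = "+" if rng.random() < 0.5 else "-"
        intronic = rng.random() < cfg.fraction_intronic
        mirna_id = f"mir-s{i:03d}"
        loci.append(
            MirnaLocus(
                interval=GenomicInterval(cfg.chrom, start, start + length, strand, mirna_id),
                mirna_id=mirna_id,
                genomic_class="intronic" if intronic else "intergenic",
                host_gene=f"HOSTG{i:03d}" if intronic else None,
            )
        )
    prev_end = -1
    for locus in loci:
        if locus.interval.start <= prev_end:
            raise RuntimeError("loci overlap at requested density")
        prev_end = locus.interval.end
    return loci


def gen_ground_truth(cfg: SimulationConfig, annotation: list[MirnaLocus]) -> GroundTruth:
    """Choose planted regulated / decoy-bound loci and their true distances."""
    rng = _rng(cfg, "truth")
    ids = [loc.mirna_id for loc in annotation]
    chosen = rng.permutation(len(ids))
    regulated_idx = chosen[: cfg.n_planted_regulated]
    decoy_idx = chosen[
        cfg.n_planted_regulated : cfg.n_planted_regulated + cfg.n_decoy_bound
    ]
    planted_regulated: dict[str, float] = {}
    planted_bound: dict[str, int] = {}
    for j, idx in enumerate(regulated_idx):
        sign = -1.0 if j < cfg.n_planted_regulated // 2 else 1.0
        planted_regulated[ids[idx]] = sign * cfg.planted_log2fc
        lo, hi = cfg.planted_distance_range
        planted_bound[ids[idx]] = int(rng.integers(lo, hi + 1))
    for idx in decoy_idx:
        lo, hi = cfg.decoy_distance_range
        planted_bound[ids[idx]] = int(rng.integers(lo, hi + 1))
    repressed = sorted(m for m, e in planted_regulated.items() if e < 0)
    picks = rng.permutation(len(repressed))[: cfg.n_clinical_associated]
    clinical = {repressed[i] for i in picks}
    return GroundTruth(planted_regulated, planted_bound, clinical)


def gen_chip_replicates(
    cfg: SimulationConfig,
    annotation: list[MirnaLocus],
    truth: GroundTruth,
    factor: str = "NANOG",
) -> list[PeakSet]:
    """Replicate peak sets whose strict-intersection consensus realizes the
    planted distances.

    Each planted locus receives one peak whose near edge lies at the true
    distance from the 5' end; replicates shift the peak independently within
    ±``replicate_jitter_bp``, so the consensus edge moves by at most the
    jitter. Background peaks far from every upstream window are added to all
    replicates as realistic clutter.
    """
    rng = _rng(cfg, "chip")
    by_id = {loc.mirna_id: loc for loc in annotation}
    cores: list[tuple[int, int]] = []
    for mirna_id, dist in sorted(truth.planted_bound.items()):
        locus = by_id[mirna_id]
        width = int(rng.integers(*cfg.peak_width_range))
        five = locus.five_prime
        if locus.interval.strand == "+":
            end = five - dist
            cores.append((max(0, end - width), max(1, end)))
        else:
            start = five + dist
            cores.append((start, start + width))
    # background clutter in the dead zone of random slots (outside all windows)
    n_bg = cfg.n_mirnas // 4
    for slot in rng.choice(cfg.n_mirnas, size=n_bg, replace=False):
        pos = _SLOT * int(slot) + int(rng.integers(0, 4000))
        cores.append((pos, pos + int(rng.integers(*cfg.peak_width_range))))
    replicates: list[PeakSet] = []
    shifts = rng.integers(
        -cfg.replicate_jitter_bp,
        cfg.replicate_jitter_bp + 1,
        size=(cfg.n_chip_replicates, len(cores)),
    )
    for r in range(cfg.n_chip_replicates):
        peaks = [
            GenomicInterval(cfg.chrom, max(0, s + int(shifts[r, k])), e + int(shifts[r, k]))
            for k, (s, e) in enumerate(cores)
        ]
        replicates.append(PeakSet(factor=factor, replicate_id=f"rep{r + 1}", peaks=peaks))
    return replicates


def gen_tumour_counts(
    cfg: SimulationConfig,
    annotation: list[MirnaLocus],
    truth: GroundTruth,
    driver_name: str = "NANOG",
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial miRNA counts coupled to a driver expression axis.

    Returns (counts features x samples, driver log2 expression per sample,
    sample metadata). Driver expression is high in SEM/EC and low in
    TERA/YST; each planted miRNA's log2 mean moves linearly with the
    sample's driver percentile, signed by its planted effect. GCNIS and
    stage probabilities shift with the expression percentile of the planted
    clinically-associated (repressed) candidates: the lower their
    expression, the likelier GCNIS presence and higher stage.
    """
    rng = _rng(cfg, "counts")
    subtype_driver_mean = {"SEM": 13.5, "EC": 13.0, "TERA": 10.5, "YST": 10.5}
    sample_ids: list[str] = []
    subtypes: list[str] = []
    driver_vals: list[float] = []
    for subtype, n in cfg.n_samples_per_subtype:
        for k in range(n):
            sample_ids.append(f"{subtype}_{k:02d}")
            subtypes.append(subtype)
            driver_vals.append(subtype_driver_mean[subtype] + rng.normal(0, 0.8))
    driver = pd.Series(driver_vals, index=sample_ids, name=driver_name)
    n_samples = len(sample_ids)
    pct = driver.rank(method="average").to_numpy() / n_samples - 0.5 / n_samples

    base = rng.uniform(3.0, 9.0, size=cfg.n_mirnas)
    ids = [loc.mirna_id for loc in annotation]
    mu = np.tile(base[:, None], (1, n_samples))
    for i, mirna_id in enumerate(ids):
        eff = truth.planted_regulated.get(mirna_id)
        if eff is not None:
            mu[i] += eff * cfg.driver_effect * (pct - 0.5)
    mean_counts = np.maximum(2.0**mu - 1.0, 0.05)
    n_param = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(n_param, n_param / (n_param + mean_counts))
    counts_df = pd.DataFrame(
        counts, index=pd.Index(ids, name="feature_id"), columns=sample_ids
    )

    # clinical covariates coupled to planted-candidate expression percentiles
    if truth.clinical_associated:
        rows = [ids.index(m) for m in sorted(truth.clinical_associated)]
        cand = counts_df.iloc[rows]
        cand_pct = cand.rank(axis=1, method="average").to_numpy() / n_samples
        progression = 1.0 - cand_pct.mean(axis=0)
    else:
        progression = np.full(n_samples, 0.5)
    c = cfg.clinical_coupling
    p_gcnis = np.clip(0.5 + c * (progression - 0.5) * 2.0, 0.05, 0.95)
    gcnis = np.where(rng.random(n_samples) < p_gcnis, "present", "absent")
    g_noisy = progression + rng.normal(0, 0.12, size=n_samples)
    stage = np.where(g_noisy > 0.62, "III", np.where(g_noisy > 0.48, "II", "I"))
    meta = pd.DataFrame(
        {"subtype": subtypes, "gcnis": gcnis, "stage": stage},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return counts_df, driver, meta


def gen_normal_cohorts(
    cfg: SimulationConfig,
    truth: GroundTruth,
    annotation: Optional[list[MirnaLocus]] = None,
) -> tuple[FoldChangeTable, FoldChangeTable]:
    """Two tumour-versus-normal fold-change cohorts with shared planted effects.

    Planted miRNAs draw one log2 effect of magnitude 1-2 in their planted
    direction, observed in each cohort with independent Gaussian noise;
    unplanted miRNAs scatter around a ratio of 1.
    """
    rng = _rng(cfg, "cohorts")
    ids = (
        [loc.mirna_id for loc in annotation]
        if annotation is not None
        else [f"mir-s{i:03d}" for i in range(cfg.n_mirnas)]
    )
    tables = []
    effects = {}
    for mirna_id in ids:
        eff = truth.planted_regulated.get(mirna_id)
        if eff is not None:
            effects[mirna_id] = np.sign(eff) * rng.uniform(1.0, 2.0)
        else:
            effects[mirna_id] = 0.0
    for cohort_id in ("cohortA", "cohortB"):
        entries = {
            m: float(2.0 ** (effects[m] + rng.normal(0, cfg.cohort_noise_sd)))
            for m in ids
        }
        tables.append(FoldChangeTable(cohort_id=cohort_id, entries=entries))
    return tables[0], tables[1]


@dataclass
class SimulatedBundle:
    """Everything one pipeline run needs, plus the answer key."""

    config: SimulationConfig
    annotation: list[MirnaLocus]
    truth: GroundTruth
    chip_replicates: list[PeakSet]
    counts: pd.DataFrame
    driver: pd.Series
    metadata: pd.DataFrame
    cohorts: tuple[FoldChangeTable, FoldChangeTable]


def simulate_bundle(cfg: SimulationConfig) -> SimulatedBundle:
    """Generate the full input bundle for one seed."""
    annotation = gen_annotation(cfg)
    truth = gen_ground_truth(cfg, annotation)
    chip = gen_chip_replicates(cfg, annotation, truth)
    counts, driver, meta = gen_tumour_counts(cfg, annotation, truth)
    cohorts = gen_normal_cohorts(cfg, truth, annotation)
    return SimulatedBundle(cfg, annotation, truth, chip, counts, driver, meta, cohorts)
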