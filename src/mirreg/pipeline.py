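"""End-to-end pipeline driver.

Reads an input bundle (annotation, replicate ChIP BED files, counts, driver
expression, clinical metadata, cohort fold-change tables), executes
consensus -> upstream-window binding -> normalization -> stratification ->
differential expression -> cohort consolidation -> prioritization cascade
-> clinical association, and writes TSV reports plus a JSON audit log.
Outputs are a pure function of the inputs and the configuration: a rerun
with the same config hash is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as mio
from .cohorts import consolidate_cohorts, fold_change_filter
from .expression import (
    differential_expression,
    normalize_log2,
    stratify_by_cutoff,
    stratify_tertiles,
)
from .intervals import assign_binding, consensus_across_replicates, PeakSet
from .prioritize import (
    DistanceRule,
    clinical_contrast_tables,
    flags_from_tables,
    records_frame,
    run_cascade,
)
from .simulate import SimulatedBundle

__all__ = ["write_bundle", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def write_bundle(bundle: SimulatedBundle, outdir: str | Path) -> None:
    """Write a simulated input bundle (plus answer key) to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_mirna_annotation(out / "annotation.tsv", bundle.annotation)
    for rep in bundle.chip_replicates:
        mio.write_bed(out / f"chip_{rep.factor}_{rep.replicate_id}.bed", rep.peaks)
    mio.write_counts(out / "counts.tsv", bundle.counts)
    bundle.driver.rename_axis("sample_id").to_csv(out / "driver.tsv", sep="\t")
    mio.write_metadata(out / "metadata.tsv", bundle.metadata)
    for table in bundle.cohorts:
        mio.write_fold_changes(out / f"cohort_{table.cohort_id}.tsv", table)
    truth = {
        "planted_regulated": bundle.truth.planted_regulated,
        "planted_bound": bundle.truth.planted_bound,
        "clinical_associated": sorted(bundle.truth.clinical_associated),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "sim_config.json", "w") as fh:
        json.dump(asdict(bundle.config), fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")


def run_pipeline(
    input_dir: str | Path,
    output_dir: str | Path,
    config: Optional[mio.PipelineConfig] = None,
) -> dict:
    """Run every stage on a bundle directory and write reports.

    Returns the audit dictionary (also written to ``audit.json``).
    """
    config = config or mio.PipelineConfig()
    indir, outdir = Path(input_dir), Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    audit: dict = {"config": config.to_dict(), "config_hash": mio.config_hash(config)}

    # --- binding ---------------------------------------------------------
    try:
        loci = mio.read_mirna_annotation(
            indir / "annotation.tsv", basis=config.coordinate_basis
        )
        bed_paths = sorted(indir.glob("chip_*.bed"))
        if not bed_paths:
            raise FileNotFoundError("no chip_*.bed replicate files")
        replicates = [
            PeakSet(factor="TF", replicate_id=p.stem, peaks=mio.read_bed(p))
            for p in bed_paths
        ]
        consensus = consensus_across_replicates(
            replicates, min_fraction=config.consensus_min_fraction
        )
        binding = assign_binding(
            loci,
            consensus,
            windows_kb=config.windows_kb,
            min_overlap_bp=config.min_overlap_bp,
        )
    except (OSError, ValueError, FileNotFoundError) as exc:
        raise PipelineError("binding", str(exc)) from exc
    binding_df = pd.DataFrame(
        {
            "mirna_id": [b.mirna_id for b in binding],
            "bound": [b.bound for b in binding],
            "smallest_window_kb": [b.smallest_window_kb for b in binding],
            "distance_bp": [b.distance_bp for b in binding],
        }
    )
    binding_df.to_csv(outdir / "binding.tsv", sep="\t", index=False)
    audit["n_consensus_peaks"] = len(consensus)
    audit["n_bound"] = int(binding_df["bound"].sum())

    # --- stratification + differential expression -----------------------
    try:
        counts = mio.read_counts(indir / "counts.tsv")
        driver = pd.read_csv(indir / "driver.tsv", sep="\t", index_col=0).iloc[:, 0]
        norm = normalize_log2(counts)
        if config.driver_cutoffs:
            strat = stratify_by_cutoff(driver, config.driver_cutoffs, driver.name)
        else:
            strat = stratify_tertiles(driver, driver.name or "driver")
        high, low = strat.samples_in("H"), strat.samples_in("L")
        de = differential_expression(
            norm, high, low,
            alpha=config.alpha, expression_floor=config.expression_floor,
        )
    except FileNotFoundError as exc:
        raise PipelineError("stratification", str(exc)) from exc
    de.to_csv(outdir / "de_high_vs_low.tsv", sep="\t")
    audit["strata_sizes"] = {s: len(strat.samples_in(s)) for s in ("H", "M", "L")}
    audit["driver_cutoffs"] = list(strat.cutoffs)
    audit["n_de_significant"] = int(de["significant"].sum())
    audit["n_de_up"] = int((de["significant"] & (de["direction"] == "up")).sum())
    audit["n_de_down"] = int((de["significant"] & (de["direction"] == "down")).sum())

    # --- cohort consolidation -------------------------------------------
    try:
        cohort_paths = sorted(indir.glob("cohort_*.tsv"))
        tables = [mio.read_fold_changes(p) for p in cohort_paths]
        calls = [
            fold_change_filter(t, threshold=config.fold_change_threshold)
            for t in tables
        ]
        unified = consolidate_cohorts(calls)
    except (OSError, ValueError) as exc:
        raise PipelineError("cohorts", str(exc)) from exc
    audit["n_cohort_calls"] = len(unified)
    audit["n_cohort_discordant"] = sum(c.discordant for c in unified)

    # --- cascade ---------------------------------------------------------
    rule = DistanceRule(config.max_distance_intergenic, config.max_distance_intronic)
    classes = {l.mirna_id: l.genomic_class for l in loci}
    records, stage_counts = run_cascade(
        binding, de, unified, classes, rule=rule, exclusions=config.exclusion_list
    )
    audit["stage_counts"] = stage_counts

    # --- clinical association for tier-1 candidates ---------------------
    meta_path = indir / "metadata.tsv"
    if not meta_path.exists():
        raise PipelineError("clinical", f"missing metadata file {meta_path}")
    meta = mio.read_metadata(meta_path)
    tables = clinical_contrast_tables(norm, meta, alpha=config.alpha)
    for rec in records:
        if rec.tier == 1 and rec.excluded_reason is None:
            rec.clinical_flags |= flags_from_tables(tables, rec.mirna_id, config.alpha)
    report = records_frame(records)
    report.insert(0, "config_hash", audit["config_hash"])
    report.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    audit["n_candidates"] = int((report["excluded_reason"] == "").sum())
    audit["tier_counts"] = {
        str(t): int((report.loc[report["excluded_reason"] == "", "tier"] == t).sum())
        for t in (1, 2, 3)
    }
    mio.write_audit(outdir / "audit.json", audit)
    return audit
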