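"""Readers and writers for the pipeline's interchange formats.

Everything is plain text: BED3/BED6 for peaks, TSV for annotation tables,
count matrices, metadata, fold changes, aliases, target lists, cytoband
maps and Ct tables, YAML for configuration and JSON for the audit log.
Coordinates are converted to the internal 0-based half-open convention on
read; a declared ``basis`` of "1-based" shifts starts down by one.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .cohorts import AliasTable, FoldChangeTable
from .intervals import GenomicInterval, MirnaLocus, PeakSet
from .targets import TargetPredictionSet

__all__ = [
    "PipelineConfig",
    "read_bed",
    "write_bed",
    "read_mirna_annotation",
    "write_mirna_annotation",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_fold_changes",
    "write_fold_changes",
    "read_alias_table",
    "read_target_set",
    "read_cytoband_map",
    "read_ct_table",
    "load_config",
    "config_hash",
    "write_audit",
]

PathLike = Union[str, Path]


@dataclass
class PipelineConfig:
    """Every threshold and convention of the pipeline in one document.

    The defaults are the published operating point: BH alpha 0.05 with a
    mean-log2 expression floor of 1, a 1.5-fold cross-cohort rule, graded
    1/2/5/10 kb upstream windows, and TSS-distance limits of 2 kb
    (intergenic) / 4 kb (intronic). ``driver_cutoffs`` switches the
    stratification from tertiles to fixed boundaries (e.g. [12.288]).
    """

    alpha: float = 0.05
    expression_floor: float = 1.0
    fold_change_threshold: float = 1.5
    windows_kb: tuple = (1, 2, 5, 10)
    max_distance_intergenic: int = 2000
    max_distance_intronic: int = 4000
    driver_cutoffs: Optional[tuple] = None
    min_votes: int = 2
    min_overlap_bp: int = 1
    consensus_min_fraction: float = 1.0
    coordinate_basis: str = "0-based"
    chrom_aliasing: bool = False
    exclusion_list: tuple = ()
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["windows_kb"] = list(self.windows_kb)
        d["exclusion_list"] = list(self.exclusion_list)
        d["driver_cutoffs"] = (
            list(self.driver_cutoffs) if self.driver_cutoffs is not None else None
        )
        return d


def load_config(path: PathLike) -> PipelineConfig:
    """Load a YAML config document; missing keys fall back to defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in PipelineConfig.__dataclass_fields__:
        if key in doc:
            value = doc[key]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _shift(start: int, basis: str) -> int:
    if basis == "0-based":
        return start
    if basis == "1-based":
        return start - 1
    raise ValueError(f"unknown coordinate basis {basis!r}")


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' so 'chr5' and '5' compare equal (opt-in)."""
    return name[3:] if name.lower().startswith("chr") else name


def read_bed(path: PathLike, basis: str = "0-based") -> list[GenomicInterval]:
    """Parse BED3/BED6; malformed lines are rejected with their line number."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(cols)}")
            try:
                start = _shift(int(cols[1]), basis)
                end = int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 else "."
            try:
                intervals.append(GenomicInterval(cols[0], start, end, strand, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(path: PathLike, intervals: Sequence[GenomicInterval]) -> None:
    """Write BED6 (BED3 when no interval carries name or strand)."""
    six = any(iv.name or iv.strand != "." for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            if six:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


ANNOTATION_COLUMNS = ["mirna_id", "chrom", "start", "end", "strand", "genomic_class", "host_gene"]


def read_mirna_annotation(path: PathLike, basis: str = "0-based") -> list[MirnaLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"host_gene": "string"})
    missing = set(ANNOTATION_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    loci = []
    for row in df.itertuples(index=False):
        host = getattr(row, "host_gene", None)
        host = None if pd.isna(host) else str(host)
        loci.append(
            MirnaLocus(
                interval=GenomicInterval(
                    str(row.chrom), _shift(int(row.start), basis), int(row.end),
                    str(row.strand), str(row.mirna_id),
                ),
                mirna_id=str(row.mirna_id),
                genomic_class=str(row.genomic_class),
                host_gene=host,
            )
        )
    return loci


def write_mirna_annotation(path: PathLike, loci: Sequence[MirnaLocus]) -> None:
    rows = [
        {
            "mirna_id": l.mirna_id,
            "chrom": l.interval.chrom,
            "start": l.interval.start,
            "end": l.interval.end,
            "strand": l.interval.strand,
            "genomic_class": l.genomic_class,
            "host_gene": l.host_gene or "",
        }
        for l in loci
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts(path: PathLike) -> pd.DataFrame:
    """Count matrix TSV: first column feature id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "feature_id"
    return df


def write_counts(path: PathLike, counts: pd.DataFrame) -> None:
    counts.rename_axis("feature_id").to_csv(path, sep="\t")


def read_metadata(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subtype", "gcnis", "stage"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    return df.set_index("sample_id")


def write_metadata(path: PathLike, meta: pd.DataFrame) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


def read_fold_changes(path: PathLike, cohort_id: Optional[str] = None) -> FoldChangeTable:
    """TSV ``mirna_id\tfold_change``; cohort id from a ``# cohort:`` header
    comment or the filename stem."""
    header_cohort = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "cohort" in first:
            header_cohort = first.split(":", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    cid = cohort_id or header_cohort or Path(path).stem
    return FoldChangeTable(
        cohort_id=cid,
        entries={str(r.mirna_id): float(r.fold_change) for r in df.itertuples(index=False)},
    )


def write_fold_changes(path: PathLike, table: FoldChangeTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cohort: {table.cohort_id}\n")
        fh.write("mirna_id\tfold_change\n")
        for mirna, fc in table.entries.items():
            fh.write(f"{mirna}\t{fc!r}\n")


def read_alias_table(path: PathLike) -> AliasTable:
    df = pd.read_csv(path, sep="\t")
    return AliasTable.from_pairs(
        (str(r.raw_name), str(r.canonical_id)) for r in df.itertuples(index=False)
    )


def read_target_set(path: PathLike, algorithm_name: Optional[str] = None) -> TargetPredictionSet:
    """One algorithm's predictions: ``gene_id`` column, name in a header comment."""
    header_name = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "algorithm" in first:
            header_name = first.split(":", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    return TargetPredictionSet(
        algorithm_name=algorithm_name or header_name or Path(path).stem,
        targets=set(df["gene_id"].astype(str)),
    )


def read_cytoband_map(path: PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.gene_id): str(r.band) for r in df.itertuples(index=False)}


def read_ct_table(path: PathLike) -> pd.DataFrame:
    """Long-format qPCR table: ``sample  gene  replicate  ct``."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "replicate", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: Ct table needs columns {sorted(required)}")
    return df


def write_audit(path: PathLike, audit: dict) -> None:
    """Audit log: JSON, sorted keys, no timestamps (reruns stay identical)."""
    with open(path, "w") as fh:
        json.dump(audit, fh, indent=2, sort_keys=True)
        fh.write("\n")
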