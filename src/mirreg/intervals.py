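"""Genomic interval algebra for ChIP-peak consensus and upstream-window binding.

All coordinates are 0-based half-open (BED convention). Intersection ignores
strand; upstream windows are strand-aware and abut, but never include, the
locus they belong to. Binding of a transcription factor to a miRNA locus is
graded by the smallest upstream window (1/2/5/10 kb by default) that its
consensus peak set touches, together with the gap between the nearest peak
edge and the locus 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "MirnaLocus",
    "PeakSet",
    "BindingAssignment",
    "interval_length",
    "merge_intervals",
    "intersect_interval_sets",
    "consensus_across_replicates",
    "upstream_window",
    "assign_binding",
]

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval (end <= start): {self.chrom}:{self.start}-{self.end}"
                + (f" [{self.name}]" if self.name else "")
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MirnaLocus:
    """A miRNA genomic locus with its genomic class.

    Intergenic miRNAs carry their own promoters; intronic miRNAs sit inside a
    host gene, which relaxes how far upstream their transcription start site
    may lie.
    """

    interval: GenomicInterval
    mirna_id: str
    genomic_class: str  # "intergenic" | "intronic"
    host_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.genomic_class not in {"intergenic", "intronic"}:
            raise ValueError(
                f"{self.mirna_id}: genomic_class must be intergenic/intronic, "
                f"got {self.genomic_class!r}"
            )

    @property
    def five_prime(self) -> int:
        """5' end coordinate (start on +, end on -)."""
        if self.interval.strand == "+":
            return self.interval.start
        if self.interval.strand == "-":
            return self.interval.end
        raise ValueError(f"{self.mirna_id}: strand '.' has no defined 5' end")


@dataclass
class PeakSet:
    """One replicate's ChIP-seq peak calls for one transcription factor."""

    factor: str
    replicate_id: str
    peaks: list[GenomicInterval] = field(default_factory=list)


@dataclass(frozen=True)
class BindingAssignment:
    """Consensus-peak binding evidence for one miRNA locus.

    ``smallest_window_kb`` is None when no peak touches the largest window;
    ``distance_bp`` is the gap from the nearest qualifying peak edge to the
    locus 5' end, 0 when a peak overlaps the 5' end itself.
    """

    mirna_id: str
    bound: bool
    smallest_window_kb: Optional[int]
    distance_bp: Optional[int]
    factor: str = ""


def interval_length(i: GenomicInterval) -> int:
    """Length in bp of a half-open interval (end - start)."""
    return i.length


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in out.values():
        spans.sort()
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping/adjacent intervals per chromosome.

    Strand and names are dropped: the result is an unstranded footprint.
    """
    by_chrom = _by_chrom(intervals)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = by_chrom[chrom]
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:  # adjacency merges: half-open [a,b)+[b,c) = [a,c)
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def intersect_interval_sets(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Exact per-base intersection of two interval collections.

    Each side is first merged, then swept with two pointers per chromosome.
    Output intervals are sorted, merged and maximal; strand is ignored.
    """
    ma, mb = merge_intervals(a), merge_intervals(b)
    a_chroms = _by_chrom(ma)
    b_chroms = _by_chrom(mb)
    out: list[GenomicInterval] = []
    for chrom in sorted(set(a_chroms) & set(b_chroms)):
        sa, sb = a_chroms[chrom], b_chroms[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i][0], sb[j][0])
            hi = min(sa[i][1], sb[j][1])
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if sa[i][1] < sb[j][1]:
                i += 1
            else:
                j += 1
    return out


def consensus_across_replicates(
    replicates: Sequence[PeakSet], min_fraction: float = 1.0
) -> list[GenomicInterval]:
    """Consensus peaks across replicates.

    With the default ``min_fraction=1.0`` this is the strict intersection
    (bases present in every replicate), computed as a left fold of pairwise
    intersection; a single replicate returns its own sorted/merged peaks.
    With ``min_fraction < 1`` a base qualifies when covered by at least
    ``ceil(min_fraction * n_replicates)`` replicates (sweep-line count).
    """
    if not replicates:
        raise ValueError("consensus requires at least one replicate")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if min_fraction >= 1.0 or len(replicates) == 1:
        acc = merge_intervals(replicates[0].peaks)
        for rep in replicates[1:]:
            acc = intersect_interval_sets(acc, rep.peaks)
            if not acc:
                break
        return acc
    import math

    need = max(1, math.ceil(min_fraction * len(replicates)))
    events: dict[str, list[tuple[int, int]]] = {}
    for rep in replicates:
        for iv in merge_intervals(rep.peaks):
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        depth = 0
        open_at = None
        for pos, delta in sorted(events[chrom]):
            before = depth
            depth += delta
            if before < need <= depth:
                open_at = pos
            elif before >= need > depth and open_at is not None:
                if pos > open_at:
                    out.append(GenomicInterval(chrom, open_at, pos))
                open_at = None
    return merge_intervals(out) if out else []


def upstream_window(locus: MirnaLocus, k: int) -> Optional[GenomicInterval]:
    """Strand-aware window of k bp immediately upstream of the locus 5' end.

    On + the window is [max(0, start-k), start); on - it is [end, end+k).
    Returns None when clipping at the chromosome origin leaves nothing.
    """
    if k <= 0:
        raise ValueError("window size must be positive")
    iv = locus.interval
    if iv.strand == "+":
        lo = max(0, iv.start - k)
        if lo >= iv.start:
            return None
        return GenomicInterval(iv.chrom, lo, iv.start, "+", locus.mirna_id)
    if iv.strand == "-":
        return GenomicInterval(iv.chrom, iv.end, iv.end + k, "-", locus.mirna_id)
    raise ValueError(f"{locus.mirna_id}: upstream window undefined for strand '.'")


def _overlaps(spans: list[tuple[int, int]], lo: int, hi: int) -> bool:
    return any(max(s, lo) < min(e, hi) for s, e in spans)


def assign_binding(
    loci: Iterable[MirnaLocus],
    peaks: Iterable[GenomicInterval],
    windows_kb: Sequence[int] = (1, 2, 5, 10),
    factor: str = "",
    min_overlap_bp: int = 1,
) -> list[BindingAssignment]:
    """Grade consensus-peak binding into nested upstream windows per locus.

    A locus is bound when any peak overlaps its largest window by at least
    ``min_overlap_bp`` bases; ``smallest_window_kb`` reports the tightest
    window still touched, and ``distance_bp`` the gap between the nearest
    qualifying peak edge and the locus 5' end (0 when the peak covers it).
    """
    windows_kb = sorted(windows_kb)
    peak_by_chrom = _by_chrom(merge_intervals(peaks)) if peaks else {}
    out: list[BindingAssignment] = []
    for locus in loci:
        if locus.interval.strand not in {"+", "-"}:
            raise ValueError(f"{locus.mirna_id}: locus strand is required for binding")
        chrom_peaks = peak_by_chrom.get(locus.interval.chrom, [])
        max_win = upstream_window(locus, windows_kb[-1] * 1000)
        smallest: Optional[int] = None
        distance: Optional[int] = None
        if max_win is not None and chrom_peaks:
            qualifying = [
                (s, e)
                for s, e in chrom_peaks
                if min(e, max_win.end) - max(s, max_win.start) >= min_overlap_bp
            ]
            if qualifying:
                five = locus.five_prime
                if locus.interval.strand == "+":
                    distance = min(max(0, five - e) for _, e in qualifying)
                else:
                    distance = min(max(0, s - five) for s, _ in qualifying)
                for k in windows_kb:
                    win = upstream_window(locus, k * 1000)
                    if win is not None and _overlaps(qualifying, win.start, win.end):
                        smallest = k
                        break
        out.append(
            BindingAssignment(
                mirna_id=locus.mirna_id,
                bound=smallest is not None,
                smallest_window_kb=smallest,
                distance_bp=distance if smallest is not None else None,
                factor=factor,
            )
        )
    return out
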