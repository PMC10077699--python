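"""Genomic interval arithmetic: peak-panel merging, coverage, set comparison.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``. GTF input (1-based, closed) is converted at the I/O
boundary in :mod:`meripkit.annotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakPanel",
    "IntervalValidationError",
    "merge_intervals",
    "coverage_sum",
    "count_overlapping_reads",
    "venn_counts",
    "read_bed",
    "write_bed",
]


class IntervalValidationError(ValueError):
    """Raised when an interval record is malformed (e.g. start >= end)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded). Strand is
    ignored by merging, matching the unstranded nature of MACS2 peaks.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IntervalValidationError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise IntervalValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakPanel:
    """Merged, disjoint reference peaks with per-peak provenance.

    ``peaks`` are sorted by (chrom, start) and pairwise disjoint,
    non-bookended within a chromosome. ``provenance[i]`` is the set of
    source labels whose input intervals contributed to peak *i*.
    ``ids[i]`` is a stable identifier ``peak_<i+1>``.
    """

    peaks: list[GenomicInterval]
    provenance: list[set[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [set() for _ in self.peaks]
        if len(self.provenance) != len(self.peaks):
            raise ValueError("provenance length must match peaks")

    @property
    def ids(self) -> list[str]:
        return [f"peak_{i + 1}" for i in range(len(self.peaks))]

    def __len__(self) -> int:
        return len(self.peaks)

    def lengths(self) -> list[int]:
        return [len(p) for p in self.peaks]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "id": self.ids,
                "sources": [",".join(sorted(s)) for s in self.provenance],
            }
        )


def merge_intervals(
    intervals: Sequence[GenomicInterval],
    max_gap: int = 0,
    sources: Sequence[str] | None = None,
) -> PeakPanel:
    """Merge intervals into a disjoint reference panel (bedtools-merge semantics).

    Two intervals end up in the same output peak when their gap is
    ``<= max_gap``; with the default ``max_gap=0`` overlapping *and*
    bookended intervals merge, exactly like ``bedtools merge -d 0``.

    Parameters
    ----------
    intervals : input intervals in any order.
    max_gap : largest inter-interval gap (in bases) still merged.
    sources : optional per-interval source label (e.g. ``"High"``/``"Low"``)
        propagated into the panel's provenance.

    Returns
    -------
    PeakPanel with peaks sorted by (chrom, start).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if sources is not None and len(sources) != len(intervals):
        raise ValueError("sources must align with intervals")
    tagged = [
        (iv, sources[i] if sources is not None else None) for i, iv in enumerate(intervals)
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))

    merged: list[GenomicInterval] = []
    contrib: list[set[str]] = []
    for iv, src in tagged:
        if merged and iv.chrom == merged[-1].chrom and iv.start - merged[-1].end <= max_gap:
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
            if src is not None:
                contrib[-1].add(src)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
            contrib.append({src} if src is not None else set())
    return PeakPanel(peaks=merged, provenance=contrib)


def coverage_sum(reads: Iterable[GenomicInterval], region: GenomicInterval) -> int:
    """Sum of per-base read depth over ``region`` (samtools-bedcov semantics).

    Equals the total number of (read, base) incidences inside the region,
    i.e. the sum over reads of their overlap length with the region.
    """
    return sum(r.overlap(region) for r in reads)


def count_overlapping_reads(reads: Iterable[GenomicInterval], region: GenomicInterval) -> int:
    """Number of reads overlapping ``region`` by at least one base."""
    return sum(1 for r in reads if r.overlap(region) > 0)


def venn_counts(
    set_a: Iterable[Hashable], set_b: Iterable[Hashable]
) -> tuple[int, int, int]:
    """Return (unique to A, shared, unique to B) for two identifier sets."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(a & b), len(b - a)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file (tab-separated, no header) into intervals.

    Only the first three columns are used; a sixth column, when present,
    supplies the strand.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IntervalValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            except (ValueError, IntervalValidationError) as exc:
                raise IntervalValidationError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, names: Sequence[str] | None = None) -> None:
    """Write intervals as BED3 (or BED4 when ``names`` given)."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                fields.append(str(names[i]))
            fh.write("\t".join(fields) + "\n")
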