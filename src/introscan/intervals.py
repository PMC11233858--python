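"""Genomic interval sets with bedtools-style merge/overlap algebra.

Coordinates are 0-based half-open ``[start, end)`` throughout, the BED
convention; the VCF-side 1-based positions are converted at the module
boundaries that emit intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass
class IntervalSet:
    """Sorted, merged, non-overlapping half-open intervals with a label."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    label: str = "custom"

    @classmethod
    def from_raw(cls, raw: Iterable[tuple[str, int, int]], label: str = "custom") -> "IntervalSet":
        """Build a set from possibly overlapping intervals, merging them."""
        return cls(merge_intervals(raw), label)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_span(self) -> int:
        """Total bp covered (exact, since intervals are merged)."""
        return sum(e - s for _, s, e in self.intervals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) on chrom overlaps any interval by >= 1 bp."""
        return any(c == chrom and s < end and start < e for c, s, e in self.intervals)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e in self.intervals:
                fh.write(f"{c}\t{s}\t{e}\t{self.label}\n")

    @classmethod
    def from_bed(cls, path, label: str | None = None) -> "IntervalSet":
        raw, seen_label = [], None
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                raw.append((parts[0], int(parts[1]), int(parts[2])))
                if len(parts) > 3:
                    seen_label = parts[3]
        return cls.from_raw(raw, label or seen_label or "custom")


def merge_intervals(raw: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Sort-and-sweep merge of overlapping AND bookended intervals.

    Bookended intervals ([0,10) + [10,20)) are joined, matching the default
    behaviour of ``bedtools merge``.
    """
    items = sorted(raw)
    for c, s, e in items:
        if s >= e:
            raise ValueError(f"invalid interval {c}:{s}-{e} (start >= end)")
    merged: list[list] = []
    for c, s, e in items:
        if merged and merged[-1][0] == c and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([c, s, e])
    return [tuple(iv) for iv in merged]


def span_of_windows(windows: Sequence[tuple[str, int, int]]) -> int:
    """Summed (possibly double-counted) bp of a raw window list."""
    return sum(e - s for _, s, e in windows)
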