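"""Genomic interval sets in 0-based half-open (BED) coordinates."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = ["RegionSet"]

Interval = tuple[str, int, int]


def _normalize(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort intervals and merge overlapping or bookended ones per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if start >= end:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        cur_s = cur_e = None
        for s, e in sorted(by_chrom[chrom]):
            if cur_e is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


@dataclass
class RegionSet:
    """A named set of non-overlapping intervals with fast point queries."""

    name: str
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = _normalize(self.intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, start, end in self.intervals:
            self._starts.setdefault(chrom, [])
            self._ends.setdefault(chrom, [])
        for chrom in self._starts:
            pairs = [(s, e) for c, s, e in self.intervals if c == chrom]
            self._starts[chrom] = np.array([p[0] for p in pairs])
            self._ends[chrom] = np.array([p[1] for p in pairs])

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position (half-open convention)."""
        starts = self._starts.get(str(chrom))
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < self._ends[str(chrom)][i]

    def chromosomes(self) -> set[str]:
        return set(self._starts)

    def padded(self, pad_bp: int, name: str | None = None) -> "RegionSet":
        """Return a copy with every interval widened by ``pad_bp`` on each side."""
        if pad_bp < 0:
            raise ValueError("pad_bp must be >= 0")
        return RegionSet(
            name or f"{self.name}+{pad_bp}bp",
            [(c, max(0, s - pad_bp), e + pad_bp) for c, s, e in self.intervals],
        )

    def total_span(self) -> int:
        return sum(e - s for _, s, e in self.intervals)
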