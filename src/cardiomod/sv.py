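"""Structural-variant consensus calling across callers.

Short-read SV callers disagree often, so high-confidence events are defined by
agreement: an event is kept when it is called by a designated trusted
(conservative) caller, or when calls from at least two distinct callers show
strictly more than 50% reciprocal overlap.  Consensus events seen in more than
20% of cohort samples are removed as likely artefacts or common polymorphisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SVCall",
    "ConsensusSV",
    "reciprocal_overlap",
    "merge_calls",
    "frequency_filter",
]

SV_TYPES = ("DEL", "DUP", "INV", "OTHER")


@dataclass(frozen=True)
class SVCall:
    """A caller-attributed interval call (0-based half-open)."""

    chrom: str
    start: int
    end: int
    sv_type: str
    caller: str
    sample: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty SV interval {self.chrom}:{self.start}-{self.end}")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"sv_type must be one of {SV_TYPES}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ConsensusSV:
    """A merged high-confidence event with its supporting evidence."""

    chrom: str
    start: int
    end: int
    sv_type: str
    supporting_callers: frozenset[str]
    samples: frozenset[str]
    rule: str  # trusted_caller | reciprocal_overlap
    members: tuple[SVCall, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.supporting_callers:
            raise ValueError("consensus event without supporting callers")
        if self.rule == "reciprocal_overlap" and len(self.supporting_callers) < 2:
            raise ValueError("reciprocal-overlap consensus needs >= 2 callers")


def reciprocal_overlap(
    a: tuple[str, int, int] | SVCall, b: tuple[str, int, int] | SVCall
) -> float:
    """min(shared/len(a), shared/len(b)); 0 for different chromosomes."""
    ca, sa, ea = (a.chrom, a.start, a.end) if isinstance(a, SVCall) else a
    cb, sb, eb = (b.chrom, b.start, b.end) if isinstance(b, SVCall) else b
    if sa >= ea or sb >= eb:
        raise ValueError("zero-length interval")
    if ca != cb:
        return 0.0
    shared = min(ea, eb) - max(sa, sb)
    if shared <= 0:
        return 0.0
    return min(shared / (ea - sa), shared / (eb - sb))


def _single_linkage(calls: Sequence[SVCall], ro_threshold: float) -> list[list[int]]:
    """Connected components of the RO > threshold graph (leftmost-start order)."""
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if reciprocal_overlap(calls[i], calls[j]) > ro_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return [comps[r] for r in sorted(comps)]


def merge_calls(
    callsets: Mapping[str, Iterable[SVCall]] | Iterable[SVCall],
    trusted_caller: str | None = None,
    ro_threshold: float = 0.5,
) -> list[ConsensusSV]:
    """Merge per-caller SV calls into consensus events.

    Calls are matched within the same sample and SV type only.  Clusters are
    single-linkage components of the strict reciprocal-overlap graph; a cluster
    becomes a consensus event when it contains >= 2 distinct callers
    (rule ``reciprocal_overlap``) or contains the trusted caller
    (rule ``trusted_caller``).  The consensus interval is the union span of the
    member calls.  No call contributes to two events; output ordering is
    deterministic and independent of input ordering.
    """
    if not 0.0 <= ro_threshold <= 1.0:
        raise ValueError("ro_threshold must lie in [0, 1]")
    if isinstance(callsets, Mapping):
        calls = [c for caller in callsets for c in callsets[caller]]
    else:
        calls = list(callsets)
    groups: dict[tuple[str, str, str], list[SVCall]] = {}
    for c in calls:
        groups.setdefault((c.sample, c.sv_type, c.chrom), []).append(c)

    out: list[ConsensusSV] = []
    for key in sorted(groups):
        members_all = sorted(
            groups[key], key=lambda c: (c.start, c.end, c.caller)
        )
        for comp in _single_linkage(members_all, ro_threshold):
            sub = [members_all[i] for i in comp]
            callers = frozenset(c.caller for c in sub)
            if len(callers) >= 2:
                rule = "reciprocal_overlap"
            elif trusted_caller is not None and trusted_caller in callers:
                rule = "trusted_caller"
            else:
                continue
            out.append(
                ConsensusSV(
                    chrom=sub[0].chrom,
                    start=min(c.start for c in sub),
                    end=max(c.end for c in sub),
                    sv_type=sub[0].sv_type,
                    supporting_callers=callers,
                    samples=frozenset(c.sample for c in sub),
                    rule=rule,
                    members=tuple(sub),
                )
            )
    out.sort(key=lambda e: (e.chrom, e.start, e.end, e.sv_type, sorted(e.samples)))
    return out


def frequency_filter(
    consensus_list: Sequence[ConsensusSV],
    n_samples: int,
    max_fraction: float = 0.20,
) -> list[ConsensusSV]:
    """Remove events recurring in more than ``max_fraction`` of samples.

    Events from different samples count as the same underlying SV when they
    share type and have reciprocal overlap > 0.5 (single linkage).  The cap is
    inclusive: an event in exactly the cap fraction of samples is retained.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    events = list(consensus_list)
    n = len(events)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = events[i], events[j]
            if a.sv_type != b.sv_type or a.chrom != b.chrom:
                continue
            if reciprocal_overlap((a.chrom, a.start, a.end), (b.chrom, b.start, b.end)) > 0.5:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    keep: list[ConsensusSV] = []
    for comp in clusters.values():
        shared_samples = set()
        for i in comp:
            shared_samples.update(events[i].samples)
        if len(shared_samples) / n_samples <= max_fraction:
            keep.extend(events[i] for i in comp)
    keep.sort(key=lambda e: (e.chrom, e.start, e.end, e.sv_type, sorted(e.samples)))
    return keep
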