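"""Half-open millisecond interval algebra.

Every timed annotation in the package — smiles, prosocial behaviors,
unobservable-face fragments, analysis windows — is a half-open interval
``[onset_ms, offset_ms)`` on the session clock (0-based milliseconds).
The helpers here keep interval lists sorted, non-overlapping and merged,
and provide the intersection/duration arithmetic the rest of the
pipeline builds on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

Interval = tuple[float, float]


def validate_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Return a sorted copy, rejecting negative times and inverted bounds."""
    out = []
    for onset, offset in intervals:
        if onset < 0:
            raise ValueError(f"negative onset {onset!r}")
        if offset < onset:
            raise ValueError(f"offset {offset!r} precedes onset {onset!r}")
        out.append((float(onset), float(offset)))
    return sorted(out)


def merge_intervals(intervals: Iterable[Interval], gap_ms: float = 0.0) -> list[Interval]:
    """Union of intervals; adjacent or < ``gap_ms``-separated ones are merged.

    With the default ``gap_ms=0`` intervals sharing an endpoint merge
    (half-open adjacency) but a positive gap is preserved.
    """
    merged: list[Interval] = []
    for onset, offset in validate_intervals(intervals):
        if merged and onset - merged[-1][1] <= gap_ms:
            prev_on, prev_off = merged[-1]
            merged[-1] = (prev_on, max(prev_off, offset))
        else:
            merged.append((onset, offset))
    return [iv for iv in merged if iv[1] > iv[0]]


def total_duration_ms(intervals: Iterable[Interval]) -> float:
    return sum(off - on for on, off in merge_intervals(intervals))


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Pairwise intersection of two interval lists (each merged first)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        on = max(a[i][0], b[j][0])
        off = min(a[i][1], b[j][1])
        if off > on:
            out.append((on, off))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def clip_to(intervals: Iterable[Interval], window: Interval) -> list[Interval]:
    return intersect(intervals, [window])


def overlap_ms(intervals: Iterable[Interval], window: Interval) -> float:
    return total_duration_ms(clip_to(intervals, window))


def is_subset(inner: Iterable[Interval], outer: Iterable[Interval]) -> bool:
    """True iff the union of ``inner`` lies within the union of ``outer``."""
    inner = merge_intervals(inner)
    return total_duration_ms(intersect(inner, outer)) == total_duration_ms(inner)


def jaccard(a: Iterable[Interval], b: Iterable[Interval]) -> float:
    """Interval Jaccard index: |A∩B| / |A∪B|; 1.0 when both are empty."""
    inter = total_duration_ms(intersect(a, b))
    union = total_duration_ms(list(a) + list(b))
    return 1.0 if union == 0 else inter / union


@dataclass
class SmileTrack:
    """Sorted, non-overlapping smile intervals with their provenance.

    ``source`` tags every interval as coming from video annotation
    (``"video"``) or from the EMG classifier (``"emg"``); a fused track
    uses ``"fused"`` at the track level while per-interval sources are
    kept in ``sources``.
    """

    intervals: list[Interval] = field(default_factory=list)
    source: str = "video"
    sources: list[str] | None = None

    def __post_init__(self) -> None:
        ivs = validate_intervals(self.intervals)
        if self.sources is None:
            self.intervals = merge_intervals(ivs)
            self.sources = [self.source] * len(self.intervals)
        else:
            if len(self.sources) != len(ivs):
                raise ValueError("sources length must match intervals")
            self.intervals = ivs

    @property
    def total_ms(self) -> float:
        return total_duration_ms(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)
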