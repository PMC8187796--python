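"""Behavioral video-annotation model and procedures.

Two trained coders annotate each therapy session video with labeled
millisecond intervals (smiles, prosocial behaviors, unobservable-face
fragments, robot events...).  This module holds the timeline container
and the analysis steps built on it:

* TSV timeline I/O (lossless round trip, validated on read),
* EMG/video synchronization via the logged time tag,
* fusion of video smile annotation with EMG-estimated smiles,
* the six per-session analysis windows (a)–(f),
* per-second coding of the 10 s preceding a prosocial behavior,
* the smile × prosocial-behavior case quadrants A–D,
* two-coder intraclass correlation (ICC(2,1), absolute agreement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    Interval,
    SmileTrack,
    intersect,
    is_subset,
    merge_intervals,
    overlap_ms,
)

LABELS = frozenset(
    {
        "smile",
        "prosocial_walk",
        "prosocial_fall",
        "unobservable_face",
        "robot_movement",
        "robot_fall_start",
        "robot_adjusted",
        "session_start",
        "prompt",
        "head_toward_robot",
        "approach_robot",
        "other",
    }
)

MINUTE_MS = 60_000.0
PRE_WINDOW_MS = 10_000.0


@dataclass
class AnnotationTimeline:
    """One coder's labeled intervals and events for one session."""

    session_id: str = ""
    participant_id: str = ""
    group: str = ""                      # "ASD" or "TD"
    coder_id: str = "coder1"
    intervals: list[tuple[float, float, str]] = field(default_factory=list)
    events: list[tuple[float, str]] = field(default_factory=list)
    session_end_ms: float | None = None

    def __post_init__(self) -> None:
        errors = []
        for row, (on, off, label) in enumerate(self.intervals):
            if label not in LABELS:
                errors.append(f"row {row}: unknown label {label!r}")
            if on < 0:
                errors.append(f"row {row}: negative onset {on}")
            if off < on:
                errors.append(f"row {row}: offset {off} precedes onset {on}")
        for row, (t, label) in enumerate(self.events):
            if label not in LABELS:
                errors.append(f"event row {row}: unknown label {label!r}")
            if t < 0:
                errors.append(f"event row {row}: negative time {t}")
        by_label: dict[str, list[Interval]] = {}
        for on, off, label in self.intervals:
            by_label.setdefault(label, []).append((on, off))
        for label, ivs in by_label.items():
            ivs = sorted(ivs)
            for (a_on, a_off), (b_on, b_off) in zip(ivs, ivs[1:]):
                if b_on < a_off:
                    errors.append(
                        f"label {label!r}: overlapping intervals "
                        f"[{a_on}, {a_off}) and [{b_on}, {b_off})"
                    )
        if errors:
            raise ValueError("invalid timeline:\n  " + "\n  ".join(errors))
        self.intervals = sorted(self.intervals)
        self.events = sorted(self.events)

    # -- queries -----------------------------------------------------------
    def label_intervals(self, label: str) -> list[Interval]:
        return [(on, off) for on, off, lab in self.intervals if lab == label]

    def label_events(self, label: str) -> list[float]:
        return [t for t, lab in self.events if lab == label]

    def span(self) -> Interval:
        times = [0.0]
        times += [off for _, off, _ in self.intervals]
        times += [t for t, _ in self.events]
        end = self.session_end_ms if self.session_end_ms is not None else max(times)
        return (0.0, float(end))

    def smile_track(self) -> SmileTrack:
        return SmileTrack(intervals=self.label_intervals("smile"), source="video")


TSV_HEADER = "onset_ms\toffset_ms\tlabel\tcoder"


def write_timeline(timeline: AnnotationTimeline, path: str | Path) -> None:
    """Write the TSV dialect: events are zero-length rows (offset = onset)."""
    lines = [TSV_HEADER]
    rows = [(on, off, lab) for on, off, lab in timeline.intervals]
    rows += [(t, t, lab) for t, lab in timeline.events]
    for on, off, lab in sorted(rows):
        lines.append(f"{_fmt_ms(on)}\t{_fmt_ms(off)}\t{lab}\t{timeline.coder_id}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _fmt_ms(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_timeline(
    path: str | Path,
    session_id: str = "",
    participant_id: str = "",
    group: str = "",
    session_end_ms: float | None = None,
) -> AnnotationTimeline:
    """Parse and validate a timeline TSV; errors list the offending rows."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != TSV_HEADER:
        raise ValueError(f"{path}: missing or malformed header (expected {TSV_HEADER!r})")
    intervals, events, coders, errors = [], [], set(), []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 4:
            errors.append(f"line {i}: expected 4 tab-separated fields, got {len(parts)}")
            continue
        try:
            on, off = float(parts[0]), float(parts[1])
        except ValueError:
            errors.append(f"line {i}: non-numeric time in {parts[:2]}")
            continue
        lab, coder = parts[2], parts[3]
        coders.add(coder)
        if off == on:
            events.append((on, lab))
        else:
            intervals.append((on, off, lab))
    if errors:
        raise ValueError(f"{path}: invalid rows:\n  " + "\n  ".join(errors))
    if len(coders) > 1:
        raise ValueError(f"{path}: one file per coder expected, found coders {sorted(coders)}")
    coder = coders.pop() if coders else "coder1"
    return AnnotationTimeline(
        session_id=session_id,
        participant_id=participant_id,
        group=group,
        coder_id=coder,
        intervals=intervals,
        events=events,
        session_end_ms=session_end_ms,
    )


def write_smile_track(track: SmileTrack, path: str | Path) -> None:
    lines = ["onset_ms\toffset_ms\tsource"]
    for (on, off), src in zip(track.intervals, track.sources):
        lines.append(f"{_fmt_ms(on)}\t{_fmt_ms(off)}\t{src}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_smile_track(path: str | Path) -> SmileTrack:
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines or lines[0] != "onset_ms\toffset_ms\tsource":
        raise ValueError(f"{path}: malformed smile-track header")
    ivs, srcs = [], []
    for line in lines[1:]:
        on, off, src = line.split("\t")
        ivs.append((float(on), float(off)))
        srcs.append(src)
    source = srcs[0] if len(set(srcs)) == 1 and srcs else "fused"
    return SmileTrack(intervals=ivs, source=source, sources=srcs)


# ---------------------------------------------------------------------------
# synchronization and fusion


def synchronize(recording, timeline: AnnotationTimeline) -> float:
    """Offset (ms) mapping EMG recording time to session time.

    ``session_ms = emg_ms + offset``.  The therapist's time-tagger press
    (a marked sample in the EMG) coincides with the ``session_start``
    event of the annotation, which pins the offset.
    """
    starts = timeline.label_events("session_start")
    if not starts:
        raise ValueError("timeline has no session_start event")
    if len(starts) > 1:
        raise ValueError(f"timeline has {len(starts)} session_start events; expected one")
    if recording.time_tag_sample is None:
        raise ValueError("recording has no time tag")
    tag_ms = recording.time_tag_sample / recording.sample_rate * 1000.0
    return starts[0] - tag_ms


def fuse_smiles(
    video: SmileTrack, emg: SmileTrack, unobservable: Sequence[Interval]
) -> SmileTrack:
    """Combine video smiles (observable segments) with EMG smiles.

    The EMG track must lie entirely inside the unobservable fragments and
    the video track entirely outside them, so the fused total duration is
    exactly the sum of the two — smile time is conserved, never double
    counted.
    """
    unobservable = merge_intervals(unobservable)
    if not is_subset(emg.intervals, unobservable):
        raise ValueError("EMG smile intervals extend outside the unobservable fragments")
    if intersect(video.intervals, unobservable):
        raise ValueError("video smile intervals overlap unobservable fragments")
    tagged = [((on, off), "video") for on, off in video.intervals]
    tagged += [((on, off), "emg") for on, off in emg.intervals]
    tagged.sort()
    merged: list[Interval] = []
    sources: list[str] = []
    for (on, off), src in tagged:
        if merged and on <= merged[-1][1]:
            prev_on, prev_off = merged[-1]
            merged[-1] = (prev_on, max(prev_off, off))
            if sources[-1] != src:
                sources[-1] = "video+emg"
        else:
            merged.append((on, off))
            sources.append(src)
    return SmileTrack(intervals=merged, source="fused", sources=sources)


# ---------------------------------------------------------------------------
# analysis windows


@dataclass
class SegmentWindow:
    """One of the six analysis windows (a)–(f).

    (a), (b), (c), (d) and (f) are exactly one minute before clipping to
    session bounds; (e) is the first smile while the robot is down, so
    its length equals that smile's duration (possibly zero).
    """

    kind: str
    start_ms: float
    end_ms: float
    clipped: bool = False
    note: str = ""

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class SegmentSet:
    windows: dict[str, SegmentWindow]
    missing: dict[str, str]              # kind -> reason the anchor is absent

    def __getitem__(self, kind: str) -> SegmentWindow:
        return self.windows[kind]

    def __contains__(self, kind: str) -> bool:
        return kind in self.windows


def _first_onset(timeline: AnnotationTimeline, label: str) -> float | None:
    ivs = timeline.label_intervals(label)
    return ivs[0][0] if ivs else None


def _minute_window(kind, anchor, before, span) -> SegmentWindow:
    start, end = (anchor - MINUTE_MS, anchor) if before else (anchor, anchor + MINUTE_MS)
    c_start, c_end = max(start, span[0]), min(end, span[1])
    clipped = (c_start, c_end) != (start, end)
    note = "clipped to session bounds" if clipped else ""
    return SegmentWindow(kind, c_start, c_end, clipped=clipped, note=note)


def extract_segments(
    timeline: AnnotationTimeline, fall_anchor: str = "prosocial"
) -> SegmentSet:
    """Build the analysis windows present in a session.

    Only the first walking and first falling episode of a session is
    used.  ``fall_anchor`` selects the anchor of window (d): the default
    ``"prosocial"`` anchors one minute before the first falling-situation
    prosocial behavior; ``"robot_fall"`` anchors one minute before the
    robot's fall itself (the alternative reading of the published timing
    table) — the chosen anchor is recorded in the window note.
    """
    if fall_anchor not in ("prosocial", "robot_fall"):
        raise ValueError("fall_anchor must be 'prosocial' or 'robot_fall'")
    starts = timeline.label_events("session_start")
    if len(starts) != 1:
        raise ValueError("timeline must contain exactly one session_start event")
    span = timeline.span()
    windows: dict[str, SegmentWindow] = {}
    missing: dict[str, str] = {}

    windows["a"] = _minute_window("a", starts[0], before=False, span=span)

    walk_on = _first_onset(timeline, "prosocial_walk")
    if walk_on is None:
        missing["b"] = missing["c"] = "no prosocial behavior in the walking situation"
    else:
        windows["b"] = _minute_window("b", walk_on, before=True, span=span)
        windows["c"] = _minute_window("c", walk_on, before=False, span=span)

    fall_events = timeline.label_events("robot_fall_start")
    adjusted = timeline.label_events("robot_adjusted")
    fall_on = _first_onset(timeline, "prosocial_fall")

    d_anchor = fall_on if fall_anchor == "prosocial" else (fall_events[0] if fall_events else None)
    if d_anchor is None:
        missing["d"] = (
            "no prosocial behavior in the falling situation"
            if fall_anchor == "prosocial"
            else "no robot fall in session"
        )
    else:
        windows["d"] = _minute_window("d", d_anchor, before=True, span=span)
        windows["d"].note = (windows["d"].note + f" anchor={fall_anchor}").strip()

    if fall_events and adjusted:
        falling = (fall_events[0], adjusted[0])
        smiles = [
            iv for iv in timeline.label_intervals("smile")
            if min(iv[1], falling[1]) > max(iv[0], falling[0])
        ]
        if smiles:
            on, off = smiles[0]
            windows["e"] = SegmentWindow("e", on, off)
        else:
            windows["e"] = SegmentWindow(
                "e", fall_events[0], fall_events[0], note="no smile during falling"
            )
    else:
        missing["e"] = "robot_fall_start/robot_adjusted anchors absent"

    if adjusted:
        windows["f"] = _minute_window("f", adjusted[0], before=False, span=span)
    else:
        missing["f"] = "robot_adjusted anchor absent"
    return SegmentSet(windows=windows, missing=missing)


def smile_duration_in(track: SmileTrack, window: SegmentWindow) -> float:
    """Smile seconds inside a window (millisecond precision)."""
    return overlap_ms(track.intervals, (window.start_ms, window.end_ms)) / 1000.0


# ---------------------------------------------------------------------------
# 10-s pre-prosocial coding and case records


@dataclass
class PreWindowCodes:
    """Per-second head/face/movement codes over the 10 s before onset."""

    codes: pd.DataFrame           # index: second offset (-10..-1); cols head/face/movement
    window: Interval
    clipped: bool


def code_pre_window(
    timeline: AnnotationTimeline,
    pb_onset_ms: float,
    smile_track: SmileTrack | None = None,
    overlap_threshold_ms: float = 500.0,
) -> PreWindowCodes:
    """Code head direction, facial expression and movement every second.

    A second is coded positive for a behavior if that behavior's
    intervals cover at least ``overlap_threshold_ms`` of it.  The face
    column uses ``smile_track`` when given (e.g. the fused video+EMG
    track) and the timeline's own smile annotation otherwise.
    """
    win_start = pb_onset_ms - PRE_WINDOW_MS
    clipped = win_start < 0
    smiles = smile_track.intervals if smile_track is not None else timeline.label_intervals("smile")
    rows = {}
    for k in range(-10, 0):
        sec = (pb_onset_ms + k * 1000.0, pb_onset_ms + (k + 1) * 1000.0)
        if sec[1] <= 0:
            rows[k] = {"head": 0, "face": 0, "movement": 0}
            continue
        rows[k] = {
            "head": int(overlap_ms(timeline.label_intervals("head_toward_robot"), sec)
                        >= overlap_threshold_ms),
            "face": int(overlap_ms(smiles, sec) >= overlap_threshold_ms),
            "movement": int(overlap_ms(timeline.label_intervals("approach_robot"), sec)
                            >= overlap_threshold_ms),
        }
    codes = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return PreWindowCodes(codes=codes, window=(win_start, pb_onset_ms), clipped=clipped)


@dataclass
class CaseRecord:
    """One walking or falling episode reduced to binary flags.

    ``S`` smile, ``H`` heading toward the robot (maintained), ``A``
    approaching the robot, ``P`` prompting by therapist/parent, ``PB``
    prosocial behavior, all coded over the 10 s preceding the (actual or
    expected) prosocial-behavior onset.
    """

    participant_id: str
    group: str
    session: int
    situation: str               # "walking" | "falling"
    S: int
    H: int
    A: int
    P: int
    PB: int

    def __post_init__(self) -> None:
        for name in ("S", "H", "A", "P", "PB"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"flag {name} must be 0/1, got {v!r}")
        if self.situation not in ("walking", "falling"):
            raise ValueError(f"unknown situation {self.situation!r}")

    @property
    def voluntary(self) -> int:
        return int(self.PB == 1 and self.P == 0)


def classify_case(case: CaseRecord) -> str:
    """Quadrant of the smile × prosocial-behavior outcome."""
    if case.S and case.PB:
        return "A"
    if not case.S and not case.PB:
        return "B"
    if case.S and not case.PB:
        return "C"
    return "D"


_PB_LABEL = {"walking": "prosocial_walk", "falling": "prosocial_fall"}
_ANCHOR_EVENT = {"walking": "robot_movement", "falling": "robot_fall_start"}


def build_case(
    timeline: AnnotationTimeline,
    situation: str,
    session: int = 1,
    smile_track: SmileTrack | None = None,
    heading_min_seconds: int = 8,
) -> CaseRecord:
    """Reduce one situation's episode to a :class:`CaseRecord`.

    The coding window is the 10 s before the first prosocial-behavior
    onset of that situation; when no prosocial behavior occurred, the
    10 s after the robot's movement anchor (the moment the chain could
    have started) is used instead.  ``H`` requires head-toward-robot in
    at least ``heading_min_seconds`` of the 10 coded seconds ("maintained"
    head direction); ``S``/``A`` require any ≥ 500 ms-per-second overlap;
    ``P`` requires a prompt event inside the window.
    """
    pb_on = _first_onset(timeline, _PB_LABEL[situation])
    if pb_on is not None:
        onset, pb = pb_on, 1
    else:
        anchors = timeline.label_events(_ANCHOR_EVENT[situation])
        if not anchors:
            raise ValueError(
                f"timeline has neither a {_PB_LABEL[situation]} interval nor a "
                f"{_ANCHOR_EVENT[situation]} event; cannot place the coding window"
            )
        onset, pb = anchors[0] + PRE_WINDOW_MS, 0
    coded = code_pre_window(timeline, onset, smile_track=smile_track)
    window = coded.window
    prompts = [t for t in timeline.label_events("prompt") if window[0] <= t < window[1]]
    return CaseRecord(
        participant_id=timeline.participant_id,
        group=timeline.group,
        session=session,
        situation=situation,
        S=int(coded.codes["face"].any()),
        H=int(coded.codes["head"].sum() >= heading_min_seconds),
        A=int(coded.codes["movement"].any()),
        P=int(bool(prompts)),
        PB=pb,
    )


# ---------------------------------------------------------------------------
# duration summaries and inter-rater reliability

SEGMENT_TIMING = {
    "a": "1 min after entering the intervention room",
    "b": "1 min before walking with the robot",
    "c": "1 min after starting walking with the robot",
    "d": "1 min before prosocial behavior in the falling situation",
    "e": "While the robot was falling",
    "f": "1 min after the fallen robot was adjusted",
}


def summarize_segment_durations(durations: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sample-SD smile seconds per timing per group/session.

    ``durations`` columns: participant, group, session, kind, smile_s.
    SD uses n−1 (sample SD).  Output one row per (group, session, kind)
    with mean, sd and a formatted ``mean ± sd`` string.
    """
    g = durations.groupby(["group", "session", "kind"])["smile_s"]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["timing"] = out["kind"].map(SEGMENT_TIMING)
    out["summary"] = [
        f"{m:.1f} ± {s:.1f}" if not math.isnan(s) else f"{m:.1f}"
        for m, s in zip(out["mean"], out["sd"])
    ]
    return out


@dataclass
class ICCResult:
    icc: float
    f_statistic: float
    df1: int
    df2: int
    ci95: tuple[float, float]
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci95[0] <= self.icc <= self.ci95[1]):
            raise ValueError("ICC must lie inside its confidence interval")


def icc_two_coders(ratings: np.ndarray) -> ICCResult:
    """ICC(2,1) — two-way random effects, absolute agreement, single measure.

    ``ratings`` is items × 2 coders.  With two coders the F test has
    df1 = items − 1 and df2 = items − 1.
    """
    import pingouin as pg

    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] != 2:
        raise ValueError("ratings must be an items × 2 matrix")
    n = ratings.shape[0]
    if n < 3:
        raise ValueError("need at least 3 items for ICC")
    if np.isclose(ratings.var(), 0):
        raise ValueError("zero variance across items: ICC undefined")
    long = pd.DataFrame(
        {
            "item": np.repeat(np.arange(n), 2),
            "coder": np.tile([0, 1], n),
            "rating": ratings.ravel(),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # perfect-agreement inputs divide by a zero error mean square
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=long, targets="item", raters="coder", ratings="rating"
        ).set_index("Type")
    # two-way random, absolute agreement, single measure
    key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    row = table.loc[key]
    icc = float(row["ICC"])
    if not np.isfinite(icc):
        raise ValueError("ICC undefined for these ratings (zero between-item variance)")
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    lo, hi = (float(v) for v in row[ci_col])
    if np.isnan(lo) or np.isnan(hi):       # perfect agreement degenerates the CI
        lo = hi = icc
    # numerical round-off can push the point estimate a hair outside
    lo, hi = min(lo, icc), max(hi, icc)
    return ICCResult(
        icc=icc,
        f_statistic=float(row["F"]),
        df1=int(row["df1"]),
        df2=int(row["df2"]),
        ci95=(lo, hi),
        p_value=float(row["pval"]),
    )
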