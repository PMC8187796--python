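"""Synthetic study generator.

Real sessions comprise (1) 4-channel facial-EMG recordings and (2)
coder-annotated behavior timelines.  Neither is redistributable here, so
this module simulates both with known ground truth:

* :func:`generate_emg` builds a recording as a fixed linear mixture of
  latent sources — two smile-muscle burst sources active only inside the
  simulated smile intervals, one always-on tonic source — plus additive
  broadband noise and high-amplitude low-frequency motion artifacts.
  The true smile intervals come back as a :class:`~prosmile.intervals.SmileTrack`.

* :func:`generate_session` simulates one therapy session as a discrete
  1-s behavior chain: the robot moves, the child may smile, a smiling
  child may keep heading toward the robot, approach it and help it
  (voluntary prosocial behavior); a non-smiling child may be prompted by
  the therapist or a parent and then help.  The chain's smile ×
  prosocial-behavior joint distribution is available in closed form
  (:func:`closed_form_joint`), and the default probabilities are
  calibrated so that closed form equals the published 2×2 table.

* :func:`generate_case_table` materializes an exact-count case table
  from a 2×2 joint via largest-remainder rounding.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
import yaml
from numpy.random import SeedSequence, default_rng
from scipy import signal as sps

from .annotation import AnnotationTimeline, CaseRecord
from .emg import EMGRecording, N_CHANNELS
from .intervals import Interval, SmileTrack

# 2x2 joint over (S, PB) in cell order (S∧PB, S∧¬PB, ¬S∧PB, ¬S∧¬PB),
# as published from the 36 observed cases.
STUDY_JOINT = (0.42, 0.08, 0.22, 0.28)


# ---------------------------------------------------------------------------
# EMG generator


@dataclass
class SyntheticEMGConfig:
    """Conditions for one synthetic EMG recording.

    ``snr_db`` is the ratio, per channel, of smile-burst power to the
    additive broadband noise power.  Defaults describe a clean wearable
    recording: 1 kHz sampling (comfortably above twice the 350 Hz upper
    band edge), a few smiles and motion artifacts per minute.
    """

    duration_s: float = 120.0
    sample_rate: float = 1000.0
    n_channels: int = N_CHANNELS
    smile_rate: float = 4.0                       # smiles per minute
    smile_duration_range: tuple[float, float] = (1.0, 4.0)
    source_band: tuple[float, float] = (50.0, 350.0)
    artifact_rate: float = 3.0                    # motion artifacts per minute
    artifact_band: tuple[float, float] = (1.0, 15.0)
    snr_db: float = 15.0
    mixing_seed: int = 7
    noise_seed: int = 11

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_channels != N_CHANNELS:
            raise ValueError(f"n_channels must be {N_CHANNELS}")
        if self.sample_rate <= 700.0:
            raise ValueError(
                "sample_rate must exceed 700 Hz (twice the 350 Hz smile-band edge)"
            )
        if self.sample_rate <= 2 * self.source_band[1]:
            raise ValueError("sample_rate must exceed twice the upper source band edge")
        if self.artifact_band[1] >= 20.0:
            raise ValueError("artifact band must stay below 20 Hz")
        if self.smile_rate < 0 or self.artifact_rate < 0:
            raise ValueError("rates must be non-negative")
        lo, hi = self.smile_duration_range
        if not (0 < lo <= hi):
            raise ValueError("smile_duration_range must be 0 < lo <= hi")


def _band_noise(rng, n, sample_rate, band) -> np.ndarray:
    sos = sps.butter(4, band, btype="bandpass", fs=sample_rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt((x**2).mean())
    return x / rms if rms > 0 else x


def _sample_smile_intervals(rng, cfg: SyntheticEMGConfig) -> list[Interval]:
    expected = cfg.smile_rate * cfg.duration_s / 60.0
    n = rng.poisson(expected)
    onsets = np.sort(rng.uniform(0, cfg.duration_s, n))
    durations = rng.uniform(*cfg.smile_duration_range, n)
    out_s: list[Interval] = []
    for on, dur in zip(onsets, durations):
        off = min(on + dur, cfg.duration_s)
        if out_s and on < out_s[-1][1] + 0.3:  # keep smiles separable (>=300 ms apart)
            continue
        if off - on >= 0.4:
            out_s.append((on, off))
    return [(on * 1000.0, off * 1000.0) for on, off in out_s]


def generate_emg(config: SyntheticEMGConfig) -> tuple[EMGRecording, SmileTrack]:
    """Simulate a recording plus its ground-truth smile track.

    Channels are a fixed linear mixture (drawn once from
    ``mixing_seed``) of three latent sources: two unit-RMS smile-muscle
    burst sources gated by the smile intervals and one always-on tonic
    source, plus white noise at ``snr_db`` and low-frequency artifact
    bursts.  Bit-identical output for identical config and seeds.
    """
    rng_mix = default_rng(config.mixing_seed)
    rng = default_rng(config.noise_seed)
    n = int(round(config.duration_s * config.sample_rate))
    fs = config.sample_rate

    smiles = _sample_smile_intervals(rng, config)
    gate = np.zeros(n)
    for on_ms, off_ms in smiles:
        i0, i1 = int(on_ms / 1000 * fs), int(off_ms / 1000 * fs)
        w = sps.windows.tukey(max(i1 - i0, 2), alpha=0.2)
        gate[i0:i1] = w[: i1 - i0]

    s1 = _band_noise(rng, n, fs, config.source_band) * gate
    s2 = _band_noise(rng, n, fs, config.source_band) * gate
    tonic = 0.35 * _band_noise(rng, n, fs, config.source_band)
    sources = np.stack([s1, s2, tonic], axis=1)          # (n, 3)

    mixing = rng_mix.uniform(0.3, 1.0, size=(N_CHANNELS, 3))
    mixing[:, :2] *= rng_mix.choice([-1.0, 1.0], size=(N_CHANNELS, 2))
    x = sources @ mixing.T                               # (n, 4)

    burst_amp = np.sqrt((mixing[:, :2] ** 2).sum(axis=1))   # per-channel burst RMS
    sigma = burst_amp / (10.0 ** (config.snr_db / 20.0))
    x += rng.standard_normal((n, N_CHANNELS)) * sigma

    n_art = rng.poisson(config.artifact_rate * config.duration_s / 60.0)
    for _ in range(n_art):
        dur = rng.uniform(0.3, 1.0)
        start = rng.uniform(0, max(config.duration_s - dur, 0))
        i0, i1 = int(start * fs), int((start + dur) * fs)
        if i1 - i0 < 8:
            continue
        burst = _band_noise(rng, i1 - i0, fs, config.artifact_band)
        burst *= sps.windows.tukey(i1 - i0, alpha=0.5)
        gains = rng.uniform(0.5, 1.5, N_CHANNELS) * 5.0 * burst_amp
        x[i0:i1] += np.outer(burst, gains)

    recording = EMGRecording(
        samples=x,
        sample_rate=fs,
        time_tag_sample=0,
        participant_id="synthetic",
        meta={"generator": asdict(config)},
    )
    return recording, SmileTrack(intervals=smiles, source="truth")


# ---------------------------------------------------------------------------
# session / behavior-chain generator


@dataclass
class SyntheticSessionConfig:
    """Conditions of the simulated therapy study.

    The participant design mirrors the study: 6 children per group, two
    analyzed sessions for the ASD group and one for the TD group, each
    session containing one walking and one falling situation — which
    yields 6×2×2 + 6×1×2 = 36 cases.  Chain probabilities default to the
    values that make :func:`closed_form_joint` equal ``STUDY_JOINT``.
    """

    n_per_group: int = 6
    sessions_per_group: dict = field(
        default_factory=lambda: {"ASD": 2, "TD": 1}
    )
    situations: tuple[str, ...] = ("walking", "falling")
    p_smile_given_robot_movement: float = 0.5
    p_head_given_smile: float = 0.9
    p_head_given_no_smile: float = 0.3
    p_approach_given_head: float = 14.0 / 15.0
    p_pb_given_approach: float = 1.0
    p_prompt_given_no_smile: float = 0.55
    p_pb_given_prompt: float = 0.8
    step_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("need at least one participant per group")
        for name, v in self.probabilities().items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")

    def probabilities(self) -> dict[str, float]:
        return {
            "p_smile_given_robot_movement": self.p_smile_given_robot_movement,
            "p_head_given_smile": self.p_head_given_smile,
            "p_head_given_no_smile": self.p_head_given_no_smile,
            "p_approach_given_head": self.p_approach_given_head,
            "p_pb_given_approach": self.p_pb_given_approach,
            "p_prompt_given_no_smile": self.p_prompt_given_no_smile,
            "p_pb_given_prompt": self.p_pb_given_prompt,
        }


def closed_form_joint(config: SyntheticSessionConfig) -> tuple[float, float, float, float]:
    """Exact smile × PB joint implied by the chain parameters.

    Smiling children reach prosocial behavior only through the
    head→approach chain; non-smiling children only through prompting, so

    ``P(S∧PB) = pS·pH|S·pA|H·pPB|A`` and
    ``P(S̄∧PB) = (1−pS)·pPr|S̄·pPB|Pr``.
    """
    ps = config.p_smile_given_robot_movement
    p_spb = ps * config.p_head_given_smile * config.p_approach_given_head * config.p_pb_given_approach
    p_nspb = (1 - ps) * config.p_prompt_given_no_smile * config.p_pb_given_prompt
    return (p_spb, ps - p_spb, p_nspb, (1 - ps) - p_nspb)


def _draw_chain(rng, cfg: SyntheticSessionConfig) -> dict[str, int]:
    s = int(rng.random() < cfg.p_smile_given_robot_movement)
    if s:
        h = int(rng.random() < cfg.p_head_given_smile)
        a = int(h and rng.random() < cfg.p_approach_given_head)
        pb = int(a and rng.random() < cfg.p_pb_given_approach)
        p = 0
    else:
        h = int(rng.random() < cfg.p_head_given_no_smile)
        p = int(rng.random() < cfg.p_prompt_given_no_smile)
        pb = int(p and rng.random() < cfg.p_pb_given_prompt)
        a = pb
    return {"S": s, "H": h, "A": a, "P": p, "PB": pb}


# fixed session layout (ms): anchors chosen so every coding window and
# analysis window fits inside a 5-minute session
_SESSION_END = 300_000.0
_WALK_ANCHOR = 90_000.0
_FALL_ANCHOR = 210_000.0
_PB_LABEL = {"walking": "prosocial_walk", "falling": "prosocial_fall"}


def _materialize_episode(chain, anchor, situation, rng, intervals, events) -> None:
    """Place intervals/events so the per-second coder recovers the chain flags.

    The coding window is [anchor, anchor+10 s); a prosocial onset, when
    drawn, sits exactly at anchor+10 s.
    """
    if situation == "walking":
        events.append((anchor, "robot_movement"))
    else:
        events.append((anchor, "robot_fall_start"))
        events.append((anchor + 18_000.0, "robot_adjusted"))
    if chain["S"]:
        dur = rng.uniform(2000.0, 4000.0)
        intervals.append((anchor + 1000.0, anchor + 1000.0 + dur, "smile"))
    if chain["H"]:
        intervals.append((anchor + 1000.0, anchor + 10_000.0, "head_toward_robot"))
    else:
        intervals.append((anchor + 1000.0, anchor + 3000.0, "head_toward_robot"))
    if chain["A"]:
        intervals.append((anchor + 7000.0, anchor + 9500.0, "approach_robot"))
    if chain["P"]:
        events.append((anchor + 5000.0, "prompt"))
    if chain["PB"]:
        dur = rng.uniform(4000.0, 8000.0)
        intervals.append((anchor + 10_000.0, anchor + 10_000.0 + dur, _PB_LABEL[situation]))


def generate_session(
    config: SyntheticSessionConfig,
    participant_id: str = "ASD-P1",
    group: str = "ASD",
    session: int = 1,
    seed: int | None = None,
) -> tuple[AnnotationTimeline, list[CaseRecord]]:
    """Simulate one participant-session: a timeline and its two cases.

    The case records report the chain draws; by construction the flags
    recomputed from the timeline window (``annotation.build_case``)
    agree with them.
    """
    rng = default_rng(config.seed if seed is None else seed)
    intervals: list[tuple[float, float, str]] = []
    events: list[tuple[float, str]] = [(0.0, "session_start")]

    # encounter smile in the first minute (smile at the greeting)
    if rng.random() < config.p_smile_given_robot_movement:
        intervals.append((4000.0, 4000.0 + rng.uniform(2000.0, 5000.0), "smile"))

    anchors = {"walking": _WALK_ANCHOR, "falling": _FALL_ANCHOR}
    cases = []
    for situation in config.situations:
        chain = _draw_chain(rng, config)
        _materialize_episode(chain, anchors[situation], situation, rng, intervals, events)
        cases.append(
            CaseRecord(
                participant_id=participant_id,
                group=group,
                session=session,
                situation=situation,
                **chain,
            )
        )
    timeline = AnnotationTimeline(
        session_id=f"{participant_id}-s{session}",
        participant_id=participant_id,
        group=group,
        coder_id="coder1",
        intervals=intervals,
        events=events,
        session_end_ms=_SESSION_END,
    )
    return timeline, cases


def generate_study(
    config: SyntheticSessionConfig,
) -> tuple[list[AnnotationTimeline], list[CaseRecord]]:
    """Simulate the full participant × session design."""
    ss = SeedSequence(config.seed)
    timelines, cases = [], []
    children = [
        (f"{grp}-P{i + 1}", grp)
        for grp in config.sessions_per_group
        for i in range(config.n_per_group)
    ]
    seeds = ss.spawn(sum(config.sessions_per_group[g] for _, g in children))
    k = 0
    for pid, grp in children:
        for sess in range(1, config.sessions_per_group[grp] + 1):
            child_seed = int(seeds[k].generate_state(1)[0] % (2**31))
            k += 1
            tl, cs = generate_session(config, pid, grp, sess, seed=child_seed)
            timelines.append(tl)
            cases.extend(cs)
    return timelines, cases


# ---------------------------------------------------------------------------
# exact-count case tables


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Integer cell counts summing exactly to ``n``.

    Floors each ``n × p`` then hands the remaining units to the cells
    with the largest fractional remainders (ties broken by cell order).
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()!r}, expected 1")
    raw = n * p
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    return [int(c) for c in counts]


def generate_case_table(
    n: int,
    joint: Sequence[float] = STUDY_JOINT,
    seed: int = 0,
    n_participants: int = 12,
) -> list[CaseRecord]:
    """Exactly ``n`` cases whose (S, PB) counts match ``joint``.

    ``joint`` is in cell order (S∧PB, S∧¬PB, S̄∧PB, S̄∧¬PB).  The
    remaining flags follow the behavior chain: voluntary helpers (S∧PB)
    head and approach without prompting; prompted helpers (S̄∧PB) carry a
    prompt.  Cases are shuffled and dealt round-robin to participants
    (first half ASD, second half TD), so every participant owns a mix of
    quadrants — what subject-wise cross-validation needs.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    counts = largest_remainder_counts(n, joint)
    rng = default_rng(seed)
    quadrant_flags = {
        0: dict(S=1, PB=1),   # smiled, helped (voluntary)
        1: dict(S=1, PB=0),
        2: dict(S=0, PB=1),   # prompted help
        3: dict(S=0, PB=0),
    }
    cases = []
    for cell, count in enumerate(counts):
        for _ in range(count):
            f = dict(quadrant_flags[cell])
            if cell == 0:
                f.update(H=1, A=1, P=0)
            elif cell == 1:
                f.update(H=int(rng.random() < 0.5), A=0, P=0)
            elif cell == 2:
                f.update(H=int(rng.random() < 0.7), A=1, P=1)
            else:
                f.update(H=int(rng.random() < 0.3), A=0, P=int(rng.random() < 0.3))
            cases.append(f)
    rng.shuffle(cases)
    out = []
    seen: dict[str, int] = {}
    for i, f in enumerate(cases):
        pidx = i % n_participants
        group = "ASD" if pidx < (n_participants + 1) // 2 else "TD"
        pid = f"{group}-P{pidx + 1}" if group == "ASD" else f"TD-P{pidx + 1 - (n_participants + 1) // 2}"
        count = seen.get(pid, 0)
        seen[pid] = count + 1
        out.append(
            CaseRecord(
                participant_id=pid,
                group=group,
                session=count // 2 + 1,
                situation=("walking", "falling")[count % 2],
                **f,
            )
        )
    return out


# ---------------------------------------------------------------------------
# file formats


def write_emg(recording: EMGRecording, path: str | Path) -> None:
    """Delimited text (time_s, ch1..ch4) plus a JSON metadata sidecar."""
    path = Path(path)
    t = np.arange(recording.n_samples) / recording.sample_rate
    df = pd.DataFrame(
        {"time_s": t, **{f"ch{i+1}": recording.samples[:, i] for i in range(N_CHANNELS)}}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {
        "sample_rate": recording.sample_rate,
        "time_tag_sample": recording.time_tag_sample,
        "participant_id": recording.participant_id,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True), encoding="utf-8"
    )


def read_emg(path: str | Path) -> EMGRecording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    expected = ["time_s"] + [f"ch{i+1}" for i in range(N_CHANNELS)]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text(encoding="utf-8"))
    return EMGRecording(
        samples=df[expected[1:]].to_numpy(),
        sample_rate=float(sidecar["sample_rate"]),
        time_tag_sample=sidecar.get("time_tag_sample"),
        participant_id=sidecar.get("participant_id", ""),
    )


def save_config(config, path: str | Path) -> None:
    d = asdict(config)
    d["__type__"] = type(config).__name__
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")


def load_config(path: str | Path):
    d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    kind = d.pop("__type__")
    cls = {"SyntheticEMGConfig": SyntheticEMGConfig, "SyntheticSessionConfig": SyntheticSessionConfig}[kind]
    for key in ("smile_duration_range", "source_band", "artifact_band", "situations"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return cls(**d)
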