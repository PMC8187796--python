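"""Facial-EMG smile estimation.

Surface EMG recorded from the cheek and eye regions (zygomaticus major,
orbicularis oculi) carries smile-related muscle bursts mixed with tonic
activity, broadband noise and low-frequency motion artifacts.  The chain
implemented here recovers smile intervals from a 4-channel recording:

1. zero-phase 50–350 Hz band-pass (removes motion artifacts and drift),
2. ICA unmixing into four independent component signals,
3. RMS envelope over non-overlapping 100 ms frames,
4. a per-participant feed-forward network trained on coder-labeled
   frames, with the neutral baseline period forced negative,
5. interval post-smoothing (merge < 200 ms gaps, drop < 300 ms blips).

The trained :class:`SmileClassifier` stores the band, the unmixing
matrix and the network weights together, so inference on later portions
of the same recording reuses exactly the transform seen in training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from sklearn.decomposition import FastICA
from sklearn.neural_network import MLPClassifier

from .intervals import Interval, SmileTrack, intersect, is_subset, merge_intervals

N_CHANNELS = 4
DEFAULT_BAND = (50.0, 350.0)
DEFAULT_ORDER = 4


@dataclass
class EMGRecording:
    """Multichannel differential facial-EMG trace.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, 4)
        Raw amplitudes, arbitrary units.
    sample_rate : float
        Sampling frequency in Hz.
    time_tag_sample : int or None
        Sample index of the synchronization tag logged at session start
        (the therapist's time-tagger press); ``None`` if absent.
    participant_id : str
    meta : dict
        Free-form provenance (filter band, generator config, ...).
    """

    samples: np.ndarray
    sample_rate: float
    time_tag_sample: int | None = None
    participant_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(
                f"expected (n_samples, {N_CHANNELS}) array, got {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.time_tag_sample is not None and not (
            0 <= self.time_tag_sample < self.n_samples
        ):
            raise ValueError("time_tag_sample outside recording")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class FrameFeatures:
    """Per-frame RMS features of the independent components."""

    values: np.ndarray            # (n_frames, 4), RMS units, >= 0
    frame_times: np.ndarray       # frame onset, ms from session zero
    frame_ms: float = 100.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape[0] != self.frame_times.shape[0]:
            raise ValueError("values and frame_times disagree on n_frames")
        if self.values.size and self.values.min() < 0:
            raise ValueError("RMS values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def _design_bandpass(low: float, high: float, sample_rate: float, order: int):
    nyq = sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz violates 0 < low < high < Nyquist ({nyq} Hz)"
        )
    return sps.butter(order, [low, high], btype="bandpass", fs=sample_rate, output="sos")


def bandpass(
    recording: EMGRecording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> EMGRecording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward and backward (``sosfiltfilt``) so the
    output has no phase lag — smile onsets in the envelope line up with
    the raw burst, which matters when comparing against millisecond
    video annotation.
    """
    sos = _design_bandpass(low, high, recording.sample_rate, order)
    filtered = sps.sosfiltfilt(sos, recording.samples, axis=0)
    meta = dict(recording.meta)
    meta["bandpass"] = {"low_hz": low, "high_hz": high, "order": order, "zero_phase": True}
    return EMGRecording(
        samples=filtered,
        sample_rate=recording.sample_rate,
        time_tag_sample=recording.time_tag_sample,
        participant_id=recording.participant_id,
        meta=meta,
    )


def _check_full_rank(x: np.ndarray) -> None:
    variances = x.var(axis=0)
    scale = max(variances.max(), 1.0)
    dead = np.flatnonzero(variances <= 1e-12 * scale)
    if dead.size:
        raise ValueError(
            "rank-deficient recording: channel(s) "
            f"{[int(c) for c in dead]} have (near-)zero variance"
        )
    cov = np.cov(x, rowvar=False)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 1e-10 * eigvals[-1]:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            (i, j)
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 0.9999
        ]
        raise ValueError(
            f"rank-deficient covariance; (near-)duplicate channel pairs: {pairs}"
        )


def unmix(recording: EMGRecording, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """ICA-unmix the filtered channels into 4 independent components.

    Uses deflation-mode FastICA with seeded initialization.  To make the
    decomposition reproducible up to nothing (rather than up to
    permutation and sign), components are ordered by descending share of
    reconstructed signal variance and their signs are fixed so each
    component's skewness is non-negative.

    Returns
    -------
    components : ndarray, shape (n_samples, 4)
    unmixing : ndarray, shape (4, 4)
        Applied as ``components = (x - mean) @ unmixing.T`` where *mean*
        is the stored channel mean; returned matrix already includes the
        ordering/sign convention.
    """
    x = recording.samples
    _check_full_rank(x)
    ica = FastICA(
        n_components=N_CHANNELS,
        algorithm="deflation",
        whiten="unit-variance",
        random_state=seed,
        max_iter=1000,
        tol=1e-5,
    )
    sources = ica.fit_transform(x)
    unmixing = ica.components_.copy()      # (4 comps, 4 channels)
    mixing = ica.mixing_.copy()            # (4 channels, 4 comps)

    # descending explained variance: with unit-variance sources the
    # variance a component injects into the channels is ||mixing col||^2
    contrib = (mixing**2).sum(axis=0)
    order = np.argsort(contrib)[::-1]
    sources = sources[:, order]
    unmixing = unmixing[order]

    skew = spstats.skew(sources, axis=0)
    flip = np.where(skew < 0, -1.0, 1.0)
    sources = sources * flip
    unmixing = unmixing * flip[:, None]
    return sources, unmixing


def apply_unmixing(
    recording: EMGRecording, unmixing: np.ndarray, channel_mean: np.ndarray
) -> np.ndarray:
    """Project a recording through a previously fitted unmixing matrix."""
    return (recording.samples - channel_mean) @ np.asarray(unmixing).T


def rms_envelope(
    components: np.ndarray,
    sample_rate: float,
    frame_ms: float = 100.0,
    start_ms: float = 0.0,
) -> FrameFeatures:
    """RMS over consecutive non-overlapping frames.

    The trailing partial frame is discarded, so
    ``n_frames = floor(n_samples / frame_length)``.
    """
    if frame_ms <= 0:
        raise ValueError("frame_ms must be positive")
    comp = np.atleast_2d(np.asarray(components, dtype=float))
    if comp.ndim != 2:
        raise ValueError("components must be 2-D (n_samples, n_components)")
    frame_len = int(round(frame_ms * sample_rate / 1000.0))
    if frame_len < 1:
        raise ValueError("frame shorter than one sample")
    n_frames = comp.shape[0] // frame_len
    trimmed = comp[: n_frames * frame_len]
    framed = trimmed.reshape(n_frames, frame_len, comp.shape[1])
    values = np.sqrt((framed**2).mean(axis=1))
    times = start_ms + np.arange(n_frames) * frame_ms
    return FrameFeatures(values=values, frame_times=times, frame_ms=frame_ms)


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class SmileClassifier:
    """Per-participant smile detector: preprocessing + network in one bag.

    Inference is a plain numpy forward pass through the stored weights,
    which keeps classification deterministic and the model serializable
    as JSON.
    """

    band: tuple[float, float] = DEFAULT_BAND
    filter_order: int = DEFAULT_ORDER
    unmixing: np.ndarray | None = None          # (4, 4)
    channel_mean: np.ndarray | None = None      # (4,)
    coefs: list[np.ndarray] = field(default_factory=list)
    intercepts: list[np.ndarray] = field(default_factory=list)
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    threshold: float = 0.5
    frame_ms: float = 100.0
    training_seed: int = 0
    training_accuracy: float | None = None
    merge_gap_ms: float = 200.0
    min_duration_ms: float = 300.0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.unmixing is not None:
            u = np.asarray(self.unmixing, dtype=float)
            if u.shape != (N_CHANNELS, N_CHANNELS):
                raise ValueError("unmixing must be 4x4")
            if abs(np.linalg.det(u)) < 1e-12:
                raise ValueError("unmixing matrix must be invertible")
            self.unmixing = u

    # -- inference ---------------------------------------------------------
    def predict_proba(self, features: FrameFeatures) -> np.ndarray:
        if features.n_frames == 0:
            return np.empty(0)
        x = features.values
        if x.shape[1] != self.coefs[0].shape[0]:
            raise ValueError(
                f"feature dimensionality {x.shape[1]} does not match model "
                f"input width {self.coefs[0].shape[0]}"
            )
        x = (x - self.feature_mean) / self.feature_scale
        h = np.maximum(x @ self.coefs[0] + self.intercepts[0], 0.0)
        z = (h @ self.coefs[1] + self.intercepts[1]).ravel()
        return _logistic(z)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "band": list(self.band),
            "filter_order": self.filter_order,
            "unmixing": None if self.unmixing is None else self.unmixing.tolist(),
            "channel_mean": None if self.channel_mean is None else list(self.channel_mean),
            "coefs": [c.tolist() for c in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "feature_mean": list(self.feature_mean),
            "feature_scale": list(self.feature_scale),
            "threshold": self.threshold,
            "frame_ms": self.frame_ms,
            "training_seed": self.training_seed,
            "training_accuracy": self.training_accuracy,
            "merge_gap_ms": self.merge_gap_ms,
            "min_duration_ms": self.min_duration_ms,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SmileClassifier":
        d = json.loads(text)
        return cls(
            band=tuple(d["band"]),
            filter_order=d["filter_order"],
            unmixing=None if d["unmixing"] is None else np.array(d["unmixing"]),
            channel_mean=None if d["channel_mean"] is None else np.array(d["channel_mean"]),
            coefs=[np.array(c) for c in d["coefs"]],
            intercepts=[np.array(b) for b in d["intercepts"]],
            feature_mean=np.array(d["feature_mean"]),
            feature_scale=np.array(d["feature_scale"]),
            threshold=d["threshold"],
            frame_ms=d["frame_ms"],
            training_seed=d["training_seed"],
            training_accuracy=d["training_accuracy"],
            merge_gap_ms=d["merge_gap_ms"],
            min_duration_ms=d["min_duration_ms"],
        )


def train_smile_classifier(
    features: FrameFeatures,
    labels: Sequence[float],
    baseline_interval: Interval | None = None,
    seed: int = 0,
    *,
    hidden_width: int = 16,
    threshold: float = 0.5,
    unmixing: np.ndarray | None = None,
    channel_mean: np.ndarray | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    filter_order: int = DEFAULT_ORDER,
    noisy_power_quantile: float = 0.99,
) -> SmileClassifier:
    """Train the per-participant network on coder-labeled frames.

    ``labels`` holds one entry per frame: 1 (smile), 0 (no smile) or NaN
    for frames without a video label (face unobservable).  Frames inside
    ``baseline_interval`` — the neutral-image period recorded before the
    session — are forced to be negative examples.  Frames whose broadband
    power exceeds the ``noisy_power_quantile`` quantile are excluded from
    training (noisy/artifact-laden stretches make poor teaching signal).

    Training is an MLP with one hidden layer (default width 16, rectified
    units) and a logistic output, fitted with L-BFGS under a small L2
    penalty — full-batch optimization is exact and fast at the few
    hundred to few thousand frames a session yields.  Identical inputs
    and seed give identical weights.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.shape[0] != features.n_frames:
        raise ValueError("one label per frame required (NaN for unlabeled)")

    y = labels.copy()
    if baseline_interval is not None:
        on, off = baseline_interval
        in_base = (features.frame_times >= on) & (features.frame_times + features.frame_ms <= off)
        y[in_base] = 0.0

    usable = ~np.isnan(y)
    power = (features.values**2).mean(axis=1)
    if usable.sum() > 10:
        cut = np.quantile(power[usable], noisy_power_quantile)
        usable &= power <= cut

    x_train = features.values[usable]
    y_train = y[usable].astype(int)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("training labels contain a single class; need smile and no-smile frames")
    if x_train.shape[0] < hidden_width:
        raise ValueError(
            f"only {x_train.shape[0]} usable frames for a hidden width of {hidden_width}"
        )

    mean = x_train.mean(axis=0)
    scale = x_train.std(axis=0)
    scale[scale == 0] = 1.0
    xs = (x_train - mean) / scale

    net = MLPClassifier(
        hidden_layer_sizes=(hidden_width,),
        activation="relu",
        solver="lbfgs",
        alpha=1e-4,
        max_iter=1000,
        random_state=seed,
    )
    net.fit(xs, y_train)
    acc = float(net.score(xs, y_train))

    return SmileClassifier(
        band=band,
        filter_order=filter_order,
        unmixing=None if unmixing is None else np.asarray(unmixing, dtype=float),
        channel_mean=None if channel_mean is None else np.asarray(channel_mean, dtype=float),
        coefs=[c.copy() for c in net.coefs_],
        intercepts=[b.copy() for b in net.intercepts_],
        feature_mean=mean,
        feature_scale=scale,
        threshold=threshold,
        frame_ms=features.frame_ms,
        training_seed=seed,
        training_accuracy=acc,
    )


def frame_labels_from_track(
    track: SmileTrack,
    frame_times: np.ndarray,
    frame_ms: float,
    min_overlap_ms: float = 50.0,
) -> np.ndarray:
    """Per-frame 0/1 teaching signal from an interval track.

    A frame is positive when smile intervals cover at least
    ``min_overlap_ms`` of it (default: half a 100 ms frame).
    """
    from .intervals import overlap_ms

    labels = np.zeros(len(frame_times), dtype=float)
    for i, t in enumerate(np.asarray(frame_times, dtype=float)):
        if overlap_ms(track.intervals, (t, t + frame_ms)) >= min_overlap_ms:
            labels[i] = 1.0
    return labels


def classify_frames(
    model: SmileClassifier, features: FrameFeatures
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame smile probability and thresholded flag."""
    proba = model.predict_proba(features)
    return proba, (proba > model.threshold).astype(int)


def flags_to_intervals(
    flags: np.ndarray,
    frame_times: np.ndarray,
    frame_ms: float,
    merge_gap_ms: float = 200.0,
    min_duration_ms: float = 300.0,
) -> list[Interval]:
    """Turn per-frame flags into smoothed smile intervals.

    Runs of positive frames become intervals; intervals separated by less
    than ``merge_gap_ms`` are merged (frame flicker across a brief dip),
    then intervals shorter than ``min_duration_ms`` are dropped (a smile
    shorter than ~1/3 s is below annotation resolution).
    """
    flags = np.asarray(flags).astype(bool)
    raw = [
        (float(frame_times[i]), float(frame_times[i]) + frame_ms)
        for i in np.flatnonzero(flags)
    ]
    # merge is strict (< gap): a gap of exactly merge_gap_ms stays split
    merged = merge_intervals(raw, gap_ms=merge_gap_ms - 1e-9)
    return [iv for iv in merged if iv[1] - iv[0] >= min_duration_ms]


def detect_smiles(
    model: SmileClassifier,
    recording: EMGRecording,
    session_offset_ms: float = 0.0,
) -> SmileTrack:
    """Run the full stored chain on a recording and return smile intervals.

    ``session_offset_ms`` maps recording time to session time (see
    :func:`prosmile.annotation.synchronize`).
    """
    if model.unmixing is None or model.channel_mean is None:
        raise ValueError("model carries no unmixing matrix; train it from a recording")
    filtered = bandpass(recording, *model.band, order=model.filter_order)
    comps = apply_unmixing(filtered, model.unmixing, model.channel_mean)
    feats = rms_envelope(
        comps, recording.sample_rate, frame_ms=model.frame_ms, start_ms=session_offset_ms
    )
    _, flags = classify_frames(model, feats)
    ivs = flags_to_intervals(
        flags, feats.frame_times, model.frame_ms, model.merge_gap_ms, model.min_duration_ms
    )
    return SmileTrack(intervals=ivs, source="emg")


def estimate_unobserved(
    model: SmileClassifier,
    recording: EMGRecording,
    video_smiles: SmileTrack,
    unobservable: Sequence[Interval],
    session_offset_ms: float = 0.0,
) -> SmileTrack:
    """Estimate smiles inside the video-unobservable fragments only.

    The detector runs over the whole recording but the returned track is
    clipped to ``unobservable``; segments the coders could see keep their
    video annotation untouched.
    """
    unobservable = merge_intervals(unobservable)
    session_span = (
        session_offset_ms,
        session_offset_ms + recording.duration_s * 1000.0,
    )
    if not is_subset(unobservable, [session_span]):
        raise ValueError(
            f"unobservable intervals extend outside the session span {session_span}"
        )
    if intersectable := [
        iv for iv in video_smiles if any(
            min(iv[1], u[1]) > max(iv[0], u[0]) for u in unobservable
        )
    ]:
        raise ValueError(
            f"video smile intervals overlap unobservable fragments: {intersectable}"
        )
    if not unobservable:
        return SmileTrack(intervals=[], source="emg")
    detected = detect_smiles(model, recording, session_offset_ms)
    clipped = intersect(detected.intervals, unobservable)
    return SmileTrack(intervals=clipped, source="emg")
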