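"""End-to-end orchestration: simulate → detect → fuse → segment → model.

`run_pipeline` drives the whole analysis on synthetic data and emits a
single JSON-serializable report: smile-detection quality against ground
truth, per-window smile-duration summaries, the case table with its A–D
quadrants, joint/conditional probability tables in both arithmetic
modes, the LOO-CV accuracy matrix, the voluntary-behavior consistency
tabulation, and a provenance block (config hash, seeds, versions).
Identical configs and seeds give byte-identical reports.

`verify_published_numbers` recomputes the published desk-scale quantities
from the built-in 36-case fixture and the participant roster and
reports expected vs computed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.random import SeedSequence

from . import __version__
from .annotation import build_case, extract_segments, fuse_smiles, smile_duration_in
from .bayes import SmileProsocialModel, cases_to_dataframe, write_case_table, round_half_up
from .emg import (
    bandpass,
    estimate_unobserved,
    frame_labels_from_track,
    rms_envelope,
    train_smile_classifier,
    unmix,
)
from .intervals import SmileTrack, clip_to, jaccard
from .study import age_summary, design_case_count, observed_case_fixture
from .synth import (
    SyntheticEMGConfig,
    SyntheticSessionConfig,
    generate_emg,
    generate_study,
)
from .bayes import build_joint_table, conditional_probability, smile_share_of_pb


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Everything a full synthetic run needs, seeds included."""

    seed: int = 0
    session: SyntheticSessionConfig = field(default_factory=SyntheticSessionConfig)
    emg: SyntheticEMGConfig = field(default_factory=SyntheticEMGConfig)
    n_emg_demos: int = 1                 # recordings pushed through the detector
    round_decimals: int = 2
    heading_min_seconds: int = 8
    classifier_threshold: float = 0.5
    output_dir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


@_stage("detect")
def _emg_demo(cfg: PipelineConfig, seed: int) -> dict:
    """Simulate one recording, train the detector on the observable part,
    estimate smiles in a held-out 'unobservable' fragment, and fuse."""
    emg_cfg = SyntheticEMGConfig(
        **{**asdict(cfg.emg), "mixing_seed": seed, "noise_seed": seed + 1}
    )
    recording, truth = generate_emg(emg_cfg)
    total_ms = emg_cfg.duration_s * 1000.0

    # video cameras lose the face for the stretch from 60% to 80% of the session
    unobservable = [(0.6 * total_ms, 0.8 * total_ms)]
    video_track = SmileTrack(
        intervals=[
            iv
            for iv in truth.intervals
            if not any(min(iv[1], u[1]) > max(iv[0], u[0]) for u in unobservable)
        ],
        source="video",
    )

    filtered = bandpass(recording)
    comps, w = unmix(filtered, seed=seed)
    feats = rms_envelope(comps, recording.sample_rate)
    labels = frame_labels_from_track(truth, feats.frame_times, feats.frame_ms)
    # frames the video cannot see are unlabeled for training
    for i, t in enumerate(feats.frame_times):
        if any(u[0] <= t < u[1] for u in unobservable):
            labels[i] = np.nan
    model = train_smile_classifier(
        feats,
        labels,
        seed=seed,
        threshold=cfg.classifier_threshold,
        unmixing=w,
        channel_mean=recording.samples.mean(axis=0),
    )
    emg_track = estimate_unobserved(model, recording, video_track, unobservable)
    fused = fuse_smiles(video_track, emg_track, unobservable)

    truth_unobs = [
        iv for u in unobservable for iv in clip_to(truth.intervals, u)
    ]
    return {
        "truth_smile_s": truth.total_ms / 1000.0,
        "video_smile_s": video_track.total_ms / 1000.0,
        "emg_estimated_smile_s": emg_track.total_ms / 1000.0,
        "fused_smile_s": fused.total_ms / 1000.0,
        "unobservable_jaccard": round(jaccard(emg_track.intervals, truth_unobs), 4),
        "training_accuracy": round(model.training_accuracy, 4),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic data; return (and optionally write) the report."""
    ss = SeedSequence(config.seed)
    session_seed, emg_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    session_cfg = SyntheticSessionConfig(
        **{**asdict(config.session), "seed": session_seed}
    )

    try:
        timelines, cases = generate_study(session_cfg)
    except Exception as exc:
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

    emg_reports = [
        _emg_demo(config, emg_seed + 97 * k) for k in range(config.n_emg_demos)
    ]

    # segments & durations ------------------------------------------------
    try:
        seg_rows = []
        seg_missing: dict[str, list[str]] = {}
        for tl in timelines:
            segs = extract_segments(tl)
            track = tl.smile_track()
            for kind, win in segs.windows.items():
                seg_rows.append(
                    {
                        "participant": tl.participant_id,
                        "group": tl.group,
                        "session": int(tl.session_id.rsplit("s", 1)[-1]),
                        "kind": kind,
                        "smile_s": smile_duration_in(track, win),
                    }
                )
            for kind, reason in segs.missing.items():
                seg_missing.setdefault(f"{tl.session_id}:{kind}", []).append(reason)
        import pandas as pd
        from .annotation import summarize_segment_durations

        seg_df = pd.DataFrame(seg_rows)
        seg_summary = summarize_segment_durations(seg_df)
        durations_table = [
            {
                "group": r.group,
                "session": int(r.session),
                "kind": r.kind,
                "timing": r.timing,
                "mean_s": round(r.mean, 2),
                "sd_s": None if np.isnan(r.sd) else round(r.sd, 2),
                "summary": r.summary,
                "n": int(r.n),
            }
            for r in seg_summary.itertuples()
        ]
    except Exception as exc:
        raise PipelineError(f"stage 'segments' failed: {exc}") from exc

    # cases & model --------------------------------------------------------
    try:
        recomputed = []
        for tl in timelines:
            sess = int(tl.session_id.rsplit("s", 1)[-1])
            for situation in session_cfg.situations:
                recomputed.append(
                    build_case(
                        tl, situation, session=sess,
                        heading_min_seconds=config.heading_min_seconds,
                    )
                )
        mismatches = sum(
            a.__dict__ != b.__dict__ for a, b in zip(cases, recomputed)
        )
    except Exception as exc:
        raise PipelineError(f"stage 'cases' failed: {exc}") from exc

    try:
        results = SmileProsocialModel(cases).fit(round_decimals=config.round_decimals)
        model_report = results.to_report()
        cv_all = results.loo_cv()
        cv = {"all": dict(zip(cv_all["subset"], cv_all["accuracy"].round(4)))}
        for grp in sorted({c.group for c in cases}):
            try:
                cv_g = results.loo_cv(group_filter=grp)
                cv[grp] = dict(zip(cv_g["subset"], cv_g["accuracy"].round(4)))
            except ValueError:
                cv[grp] = None
        consistency = results.voluntary_consistency()
    except Exception as exc:
        raise PipelineError(f"stage 'model' failed: {exc}") from exc

    report = {
        "provenance": {
            "prosmile_version": __version__,
            "seed": config.seed,
            "derived_seeds": {"session": session_seed, "emg": emg_seed},
            "config_hash": config.config_hash(),
            "rounding": {"decimals": config.round_decimals, "mode": "half-up"},
        },
        "design": {
            "n_timelines": len(timelines),
            "n_cases": len(cases),
            "case_recompute_mismatches": mismatches,
        },
        "smile_detection": emg_reports,
        "segment_durations": durations_table,
        "segment_windows_missing": seg_missing,
        "cases": cases_to_dataframe(cases).to_dict(orient="records"),
        "model": model_report,
        "loo_cv_accuracy": cv,
        "voluntary_consistency": consistency,
    }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True), encoding="utf-8"
        )
        write_case_table(cases, out / "cases.tsv")
    return report


# ---------------------------------------------------------------------------
# built-in verification of the published desk-scale numbers


def verify_published_numbers(cases: Sequence | None = None) -> dict:
    """Expected vs computed for every published desk-scale quantity.

    Uses the built-in 36-case fixture (cell counts 15/3/8/10) and the
    participant roster; returns a pass/fail table that is valid JSON.
    """
    if cases is None:
        cases = observed_case_fixture(seed=0)
    table = build_joint_table(cases, ("S", "PB"))
    ages = age_summary()

    checks: dict[str, dict] = {}

    def check(name, expected, computed, tol=0.0):
        ok = abs(computed - expected) <= tol
        checks[name] = {"expected": expected, "computed": computed, "pass": bool(ok)}

    r = table.rounded
    check("P(S,PB) rounded", 0.42, float(r[1, 1]))
    check("P(S,!PB) rounded", 0.08, float(r[1, 0]))
    check("P(!S,PB) rounded", 0.22, float(r[0, 1]))
    check("P(!S,!PB) rounded", 0.28, float(r[0, 0]))
    check("P(S) rounded", 0.5, table.marginal("S", use_rounded=True))
    check("P(PB) rounded", 0.64, table.marginal("PB", use_rounded=True))
    check("P(PB|S) rounded-mode", 0.84, conditional_probability(table, "PB", {"S": 1}, True), tol=1e-12)
    check("P(PB|!S) rounded-mode", 0.44, conditional_probability(table, "PB", {"S": 0}, True), tol=1e-12)
    check("smile share of PB (%)", 66, smile_share_of_pb(table, use_rounded=True))
    check("n cases", 36, len(list(cases)))
    check("design case count", 36, design_case_count())
    check("ASD age mean", 9.67, round_half_up(ages.loc["ASD", "mean"], 2))
    check("ASD age SD", 3.50, round_half_up(ages.loc["ASD", "sd"], 2))
    check("TD age mean", 9.83, round_half_up(ages.loc["TD", "mean"], 2))
    check("TD age SD", 2.04, round_half_up(ages.loc["TD", "sd"], 2))

    return {"checks": checks, "all_pass": all(c["pass"] for c in checks.values())}
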