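"""Timelines, synchronization, fusion, windows, coding, cases, ICC."""

import numpy as np
import pytest

from prosmile.annotation import (
    AnnotationTimeline,
    CaseRecord,
    build_case,
    classify_case,
    code_pre_window,
    extract_segments,
    fuse_smiles,
    icc_two_coders,
    read_smile_track,
    read_timeline,
    smile_duration_in,
    summarize_segment_durations,
    synchronize,
    write_smile_track,
    write_timeline,
    SegmentWindow,
)
from prosmile.emg import EMGRecording
from prosmile.intervals import SmileTrack


def _tl(intervals=(), events=(("0", "session_start"),), **kw):
    events = [(float(t), lab) for t, lab in events]
    return AnnotationTimeline(intervals=list(intervals), events=events, **kw)


class TestTimelineValidation:
    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            _tl([(0, 100, "grin")])

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError, match="precedes"):
            _tl([(100, 50, "smile")])

    def test_same_label_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            _tl([(0, 1000, "smile"), (500, 1500, "smile")])

    def test_different_labels_may_overlap(self):
        tl = _tl([(0, 1000, "smile"), (500, 1500, "head_toward_robot")])
        assert len(tl.intervals) == 2

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            _tl([(-5, 100, "smile")])


class TestTimelineIO:
    def test_roundtrip_lossless(self, tmp_path):
        tl = _tl(
            [(0, 1200, "smile"), (5000, 9000, "prosocial_walk")],
            events=[(0, "session_start"), (4000, "prompt")],
            coder_id="coder2",
        )
        p = tmp_path / "session.tsv"
        write_timeline(tl, p)
        back = read_timeline(p)
        assert back.intervals == tl.intervals
        assert back.events == tl.events
        assert back.coder_id == "coder2"

    def test_empty_file_with_header_is_valid(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("onset_ms\toffset_ms\tlabel\tcoder\n")
        tl = read_timeline(p)
        assert tl.intervals == [] and tl.events == []

    def test_bad_row_reported_with_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("onset_ms\toffset_ms\tlabel\tcoder\nx\t100\tsmile\tc1\n")
        with pytest.raises(ValueError, match="line 2"):
            read_timeline(p)

    def test_offset_before_onset_rejected(self, tmp_path):
        p = tmp_path / "inv.tsv"
        p.write_text("onset_ms\toffset_ms\tlabel\tcoder\n100\t50\tsmile\tc1\n")
        with pytest.raises(ValueError, match="precedes"):
            read_timeline(p)

    def test_mixed_coders_rejected(self, tmp_path):
        p = tmp_path / "mix.tsv"
        p.write_text(
            "onset_ms\toffset_ms\tlabel\tcoder\n"
            "0\t100\tsmile\tc1\n200\t300\tsmile\tc2\n"
        )
        with pytest.raises(ValueError, match="one file per coder"):
            read_timeline(p)

    def test_smile_track_roundtrip(self, tmp_path):
        track = SmileTrack(intervals=[(0, 500), (900, 1400)], source="emg")
        p = tmp_path / "track.tsv"
        write_smile_track(track, p)
        back = read_smile_track(p)
        assert back.intervals == track.intervals
        assert back.sources == ["emg", "emg"]


class TestSynchronize:
    @staticmethod
    def _rec(tag, n=5000, fs=1000.0):
        x = np.random.default_rng(0).normal(size=(n, 4))
        return EMGRecording(samples=x, sample_rate=fs, time_tag_sample=tag)

    def test_aligned_at_zero(self):
        assert synchronize(self._rec(0), _tl()) == 0.0

    def test_offset_arithmetic(self):
        # tag at sample 2000 @ 1 kHz is 2000 ms; session_start at 500 ms
        tl = _tl(events=[(500, "session_start")])
        assert synchronize(self._rec(2000), tl) == -1500.0

    def test_two_session_starts_rejected(self):
        tl = _tl(events=[(0, "session_start"), (100, "session_start")])
        with pytest.raises(ValueError, match="session_start"):
            synchronize(self._rec(0), tl)

    def test_missing_tag_rejected(self):
        rec = EMGRecording(
            samples=np.zeros((100, 4)), sample_rate=1000.0, time_tag_sample=None
        )
        with pytest.raises(ValueError, match="time tag"):
            synchronize(rec, _tl())


class TestFusion:
    def test_empty_emg_returns_video(self):
        video = SmileTrack(intervals=[(0, 1000)])
        fused = fuse_smiles(video, SmileTrack(intervals=[], source="emg"), [(2000, 3000)])
        assert fused.intervals == [(0, 1000)]

    def test_durations_add_exactly(self):
        video = SmileTrack(intervals=[(0, 1000)])
        emg = SmileTrack(intervals=[(1200, 1800)], source="emg")
        fused = fuse_smiles(video, emg, [(1000, 2000)])
        assert fused.total_ms == 1600.0

    def test_adjacent_intervals_merge_into_one(self):
        video = SmileTrack(intervals=[(0, 1000)])
        emg = SmileTrack(intervals=[(1000, 1500)], source="emg")
        fused = fuse_smiles(video, emg, [(1000, 2000)])
        assert fused.intervals == [(0, 1500)]
        assert fused.sources == ["video+emg"]

    def test_emg_outside_unobservable_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fuse_smiles(
                SmileTrack(intervals=[]),
                SmileTrack(intervals=[(0, 500)], source="emg"),
                [(1000, 2000)],
            )

    def test_video_inside_unobservable_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            fuse_smiles(
                SmileTrack(intervals=[(1100, 1300)]),
                SmileTrack(intervals=[], source="emg"),
                [(1000, 2000)],
            )

    def test_conservation_on_synthetic_tracks(self):
        """Fused total equals video total + EMG total, exactly."""
        rng = np.random.default_rng(8)
        unobs = [(10_000.0, 20_000.0), (40_000.0, 45_000.0)]
        video, emg = [], []
        t = 0.0
        while t < 60_000:
            # integer milliseconds, as annotation tools emit
            on = t + round(rng.uniform(200, 2000))
            off = on + round(rng.uniform(300, 1500))
            inside = any(u0 <= on and off <= u1 for u0, u1 in unobs)
            outside = all(off <= u0 or on >= u1 for u0, u1 in unobs)
            if inside:
                emg.append((on, off))
            elif outside:
                video.append((on, off))
            t = off
        v = SmileTrack(intervals=video)
        e = SmileTrack(intervals=emg, source="emg")
        fused = fuse_smiles(v, e, unobs)
        assert fused.total_ms == v.total_ms + e.total_ms


class TestSegments:
    @staticmethod
    def _session(with_fall=True, fall_smile=True):
        intervals = [
            (5_000, 12_000, "smile"),
            (300_000, 310_000, "prosocial_walk"),
        ]
        events = [(0, "session_start"), (240_000, "robot_movement")]
        if with_fall:
            events += [(400_000, "robot_fall_start"), (430_000, "robot_adjusted")]
            intervals += [(410_000, 418_000, "prosocial_fall")]
            if fall_smile:
                intervals += [(402_000, 405_000, "smile")]
        return AnnotationTimeline(
            intervals=intervals, events=events, session_end_ms=600_000
        )

    def test_minute_windows_anchor_arithmetic(self):
        segs = extract_segments(self._session())
        assert (segs["a"].start_ms, segs["a"].end_ms) == (0, 60_000)
        assert (segs["b"].start_ms, segs["b"].end_ms) == (240_000, 300_000)
        assert (segs["c"].start_ms, segs["c"].end_ms) == (300_000, 360_000)
        assert (segs["d"].start_ms, segs["d"].end_ms) == (350_000, 410_000)
        assert (segs["f"].start_ms, segs["f"].end_ms) == (430_000, 490_000)
        for k in "abdf":
            assert segs[k].duration_ms == 60_000

    def test_fall_smile_window_is_first_falling_smile(self):
        segs = extract_segments(self._session())
        assert (segs["e"].start_ms, segs["e"].end_ms) == (402_000, 405_000)

    def test_no_fall_smile_gives_zero_length_window(self):
        segs = extract_segments(self._session(fall_smile=False))
        assert "e" in segs
        assert segs["e"].duration_ms == 0

    def test_no_falling_episode_drops_d_e_f(self):
        segs = extract_segments(self._session(with_fall=False))
        assert set(segs.windows) == {"a", "b", "c"}
        assert set(segs.missing) == {"d", "e", "f"}

    def test_robot_fall_anchor_variant(self):
        segs = extract_segments(self._session(), fall_anchor="robot_fall")
        assert (segs["d"].start_ms, segs["d"].end_ms) == (340_000, 400_000)
        assert "anchor=robot_fall" in segs["d"].note

    def test_window_clipped_at_session_bounds(self):
        tl = AnnotationTimeline(
            intervals=[(20_000, 30_000, "prosocial_walk")],
            events=[(0.0, "session_start")],
            session_end_ms=100_000,
        )
        segs = extract_segments(tl)
        assert segs["b"].clipped
        assert (segs["b"].start_ms, segs["b"].end_ms) == (0, 20_000)

    def test_smile_duration_in_window(self):
        window = SegmentWindow("a", 0, 60_000)
        full = SmileTrack(intervals=[(0, 60_000)])
        assert smile_duration_in(full, window) == 60.0
        partial = SmileTrack(intervals=[(10_000, 20_000), (55_000, 70_000)])
        assert smile_duration_in(partial, window) == 15.0
        assert smile_duration_in(SmileTrack(intervals=[]), window) == 0.0

    def test_duration_summary_uses_sample_sd(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "participant": ["p1", "p2", "p3"],
                "group": ["ASD"] * 3,
                "session": [1] * 3,
                "kind": ["a"] * 3,
                "smile_s": [10.0, 20.0, 30.0],
            }
        )
        out = summarize_segment_durations(df)
        assert out.loc[0, "mean"] == 20.0
        assert out.loc[0, "sd"] == pytest.approx(10.0)   # ddof=1


class TestPreWindowCoding:
    @staticmethod
    def _tl_with(intervals):
        return AnnotationTimeline(
            intervals=intervals, events=[(0.0, "session_start")], session_end_ms=60_000
        )

    def test_full_cover_smile_codes_ten_seconds(self):
        tl = self._tl_with([(10_000, 20_000, "smile")])
        coded = code_pre_window(tl, 20_000)
        assert coded.codes["face"].sum() == 10

    def test_no_annotation_all_negative(self):
        coded = code_pre_window(self._tl_with([]), 20_000)
        assert coded.codes.to_numpy().sum() == 0

    def test_half_second_threshold(self):
        # 600 ms smile split 200/400 across two seconds: neither reaches 500 ms
        tl = self._tl_with([(16_800, 17_400, "smile")])
        coded = code_pre_window(tl, 20_000)
        assert coded.codes["face"].sum() == 0
        # 500 ms inside one second codes exactly that second
        tl = self._tl_with([(17_000, 17_500, "smile")])
        coded = code_pre_window(tl, 20_000)
        assert coded.codes["face"].sum() == 1
        assert coded.codes.loc[-3, "face"] == 1

    def test_clipped_window_flagged(self):
        coded = code_pre_window(self._tl_with([]), 5_000)
        assert coded.clipped

    def test_explicit_smile_track_overrides_timeline(self):
        tl = self._tl_with([])
        track = SmileTrack(intervals=[(10_000, 20_000)])
        coded = code_pre_window(tl, 20_000, smile_track=track)
        assert coded.codes["face"].sum() == 10


class TestCases:
    def test_quadrants(self):
        base = dict(participant_id="p", group="ASD", session=1, situation="walking",
                    H=0, A=0, P=0)
        assert classify_case(CaseRecord(**base, S=1, PB=1)) == "A"
        assert classify_case(CaseRecord(**base, S=0, PB=0)) == "B"
        assert classify_case(CaseRecord(**base, S=1, PB=0)) == "C"
        assert classify_case(CaseRecord(**base, S=0, PB=1)) == "D"

    def test_voluntary_requires_pb_without_prompt(self):
        base = dict(participant_id="p", group="ASD", session=1, situation="walking",
                    S=1, H=1, A=1)
        assert CaseRecord(**base, P=0, PB=1).voluntary == 1
        assert CaseRecord(**base, P=1, PB=1).voluntary == 0
        assert CaseRecord(**base, P=0, PB=0).voluntary == 0

    def test_nonbinary_flag_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            CaseRecord(participant_id="p", group="ASD", session=1,
                       situation="walking", S=2, H=0, A=0, P=0, PB=0)

    def test_build_case_without_anchor_rejected(self):
        tl = AnnotationTimeline(events=[(0.0, "session_start")], session_end_ms=60_000)
        with pytest.raises(ValueError, match="coding window"):
            build_case(tl, "walking")

    def test_build_case_no_pb_uses_post_anchor_window(self):
        tl = AnnotationTimeline(
            intervals=[(11_000, 14_000, "smile")],
            events=[(0.0, "session_start"), (10_000.0, "robot_movement")],
            session_end_ms=60_000,
        )
        case = build_case(tl, "walking")
        assert (case.S, case.PB) == (1, 0)


class TestICC:
    @staticmethod
    def _anova_icc(ratings):
        """Textbook two-way mean squares -> ICC(2,1) and ICC(3,1)."""
        x = np.asarray(ratings, float)
        n, k = x.shape
        grand = x.mean()
        rows = x.mean(axis=1)
        cols = x.mean(axis=0)
        msr = k * ((rows - grand) ** 2).sum() / (n - 1)
        msc = n * ((cols - grand) ** 2).sum() / (k - 1)
        sse = ((x - rows[:, None] - cols[None, :] + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        icc2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        icc3 = (msr - mse) / (msr + (k - 1) * mse)
        return icc2, icc3

    def test_identical_columns_icc_one(self):
        x = np.arange(10.0)
        res = icc_two_coders(np.column_stack([x, x]))
        assert res.icc == pytest.approx(1.0)

    def test_matches_textbook_mean_squares(self):
        rng = np.random.default_rng(10)
        truth = rng.normal(size=30)
        ratings = np.column_stack(
            [truth + rng.normal(0, 0.3, 30), truth + rng.normal(0, 0.3, 30)]
        )
        res = icc_two_coders(ratings)
        icc2, _ = self._anova_icc(ratings)
        assert res.icc == pytest.approx(icc2, abs=1e-10)
        assert res.df1 == 29 and res.df2 == 29

    def test_systematic_shift_hurts_agreement_not_consistency(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=40)
        ratings = np.column_stack([a, a + 5.0])
        res = icc_two_coders(ratings)
        icc2, icc3 = self._anova_icc(ratings)
        assert res.icc == pytest.approx(icc2, abs=1e-10)
        assert res.icc < icc3          # absolute agreement < consistency
        assert icc3 == pytest.approx(1.0)

    def test_independent_noise_icc_near_zero(self):
        rng = np.random.default_rng(12)
        res = icc_two_coders(rng.normal(size=(1000, 2)))
        assert abs(res.icc) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_two_coders(np.ones((10, 2)))

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError, match="3 items"):
            icc_two_coders(np.array([[1.0, 2.0], [2.0, 3.0]]))

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(13)
        truth = rng.normal(size=50)
        ratings = np.column_stack(
            [truth + rng.normal(0, 0.5, 50), truth + rng.normal(0, 0.5, 50)]
        )
        res = icc_two_coders(ratings)
        assert res.ci95[0] <= res.icc <= res.ci95[1]
        assert res.f_statistic > 1
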