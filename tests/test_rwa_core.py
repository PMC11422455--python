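import numpy as np
import pytest

from rwakit import rwa_core, synth
from rwakit.io_psg import EmgSignal, Hypnogram, PSGRecording
from rwakit.rwa_core import (
    AmplitudeCurve,
    BaselineCurve,
    DetectionConfig,
    MotorActivityEvent,
    automatic_rwa,
    compute_amplitude_curve,
    detect_events,
    estimate_baseline,
    merge_events,
    score_mini_epochs,
    stage_metrics,
)
from conftest import SHORT_BLOCKS, score_spec

RATE = 256.0


def make_ac(values):
    return AmplitudeCurve(values=np.asarray(values, float), rate=RATE)


def make_base(values):
    return BaselineCurve(values=np.asarray(values, float), rate=RATE)


def seconds(n_s):
    return int(round(n_s * RATE))


class TestAmplitudeCurve:
    def test_constant_signal_gives_zero(self):
        sig = EmgSignal(np.full(1000, 3.7), RATE)
        ac = compute_amplitude_curve(sig)
        assert np.all(ac.values == 0)

    def test_fast_sine_gives_peak_to_peak(self):
        # 25 Hz period (~10 samples) fits many times in the 51-sample window
        t = np.arange(seconds(4)) / RATE
        sig = EmgSignal(8.0 * np.sin(2 * np.pi * 25 * t), RATE)
        ac = compute_amplitude_curve(sig)
        interior = ac.values[100:-100]
        assert np.all(np.abs(interior - 16.0) / 16.0 < 0.02)

    def test_impulse_occupies_exactly_window_samples(self):
        x = np.zeros(600)
        x[300] = 5.0
        ac = compute_amplitude_curve(EmgSignal(x, RATE))
        # brute-force truncated-window oracle
        w = 51
        expected = np.array([
            np.ptp(x[max(0, i - w // 2): min(x.size, i + w // 2 + 1)])
            for i in range(x.size)
        ])
        np.testing.assert_array_equal(ac.values, expected)
        assert (ac.values == 5.0).sum() == w

    def test_signal_shorter_than_window_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_amplitude_curve(EmgSignal(np.zeros(50), RATE))


class TestBaseline:
    @pytest.mark.parametrize("mode", ["adaptive", "percentile"])
    def test_constant_ac(self, mode):
        cfg = DetectionConfig(baseline_mode=mode)
        base = estimate_baseline(make_ac(np.full(seconds(60), 2.0)), cfg)
        np.testing.assert_allclose(base.values, 2.0)

    @pytest.mark.parametrize("mode", ["adaptive", "percentile"])
    def test_zero_ac_clamped_to_floor(self, mode):
        cfg = DetectionConfig(baseline_mode=mode)
        base = estimate_baseline(make_ac(np.zeros(seconds(60))), cfg)
        np.testing.assert_allclose(base.values, cfg.baseline_floor_uv)

    @pytest.mark.parametrize("mode", ["adaptive", "percentile"])
    def test_sparse_bursts_do_not_lift_baseline(self, mode, rng):
        # 1 µV floor with 5 % of samples at 20 µV: P5 stays at the floor.
        v = np.full(seconds(120), 1.0)
        idx = rng.choice(v.size, size=v.size // 20, replace=False)
        v[idx] = 20.0
        cfg = DetectionConfig(baseline_mode=mode)
        base = estimate_baseline(make_ac(v), cfg)
        assert np.all(base.values <= 1.0 + 1e-9)
        assert np.all(base.values >= cfg.baseline_floor_uv)

    def test_adaptive_holds_floor_through_long_activity(self):
        # 60 s of quiet then 120 s of sustained 30 µV activity: the causal
        # exclusion baseline must not climb to activity level.
        v = np.concatenate([np.full(seconds(60), 2.0),
                            np.full(seconds(120), 30.0)])
        base = estimate_baseline(make_ac(v), DetectionConfig())
        assert np.all(base.values[seconds(70):] <= 2.0 + 1e-9)

    def test_empty_ac_rejected(self):
        with pytest.raises(ValueError):
            AmplitudeCurve(values=np.array([]), rate=RATE)


class TestDetectEvents:
    def _detect(self, ac_intervals, n_s=20.0, level=5.0):
        v = np.ones(seconds(n_s))
        for a, b in ac_intervals:
            v[seconds(a):seconds(b)] = level
        return detect_events(make_ac(v), make_base(np.ones(v.size)))

    def test_never_above_threshold(self):
        ac = make_ac(np.full(seconds(20), 4.0))   # exactly 4x, not strictly >
        assert detect_events(ac, make_base(np.ones(seconds(20)))) == []

    def test_single_event(self):
        events = self._detect([(10.0, 10.5)])
        assert events == [MotorActivityEvent(10.0, 10.5)]

    def test_merge_within_iei(self):
        # gap 0.25 s < IEI 0.5 s: merged into one event
        events = self._detect([(10.0, 10.5), (10.75, 11.25)])
        assert events == [MotorActivityEvent(10.0, 11.25)]

    def test_short_event_dropped(self):
        # 0.25 s < the 0.3-s minimum event duration
        assert self._detect([(10.0, 10.25)]) == []

    def test_merge_then_filter_order(self):
        # two 0.25-s bursts 0.25 s apart survive as one merged 0.75-s event
        events = self._detect([(10.0, 10.25), (10.5, 10.75)])
        assert events == [MotorActivityEvent(10.0, 10.75)]

    def test_gap_at_iei_not_merged(self):
        # gap exactly 0.5 s is NOT below the IEI: two separate events
        events = self._detect([(10.0, 10.5), (11.0, 11.5)])
        assert len(events) == 2

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError, match="grid"):
            detect_events(make_ac(np.ones(100)), make_base(np.ones(99)))

    def test_merge_idempotent(self, rng):
        starts = np.sort(rng.uniform(0, 100, size=30))
        evs = [MotorActivityEvent(s, s + rng.uniform(0.05, 2.0))
               for s in starts]
        once = merge_events(evs, 0.5)
        assert merge_events(once, 0.5) == once


class TestMiniEpochs:
    HYP = Hypnogram(stages=("W", "REM", "REM"))

    def test_full_coverage(self):
        minis = score_mini_epochs([MotorActivityEvent(30.0, 33.0)], self.HYP)
        first_rem = [m for m in minis if m.stage == "REM"][0]
        assert first_rem.occupancy == 1.0 and first_rem.positive

    def test_exactly_half_is_negative(self):
        minis = score_mini_epochs([MotorActivityEvent(30.0, 31.5)], self.HYP)
        m = [m for m in minis if m.stage == "REM"][0]
        assert m.occupancy == 0.5 and not m.positive

    def test_just_over_half_is_positive(self):
        minis = score_mini_epochs([MotorActivityEvent(30.0, 31.6)], self.HYP)
        assert [m for m in minis if m.stage == "REM"][0].positive

    def test_no_events(self):
        minis = score_mini_epochs([], self.HYP)
        assert all(m.occupancy == 0 and not m.positive for m in minis)
        assert len(minis) == 30


class TestAutomaticRwa:
    def _minis(self, n_pos, n_total):
        return [
            rwa_core.MiniEpoch(start=3.0 * i, stage="REM",
                               occupancy=1.0 if i < n_pos else 0.0,
                               positive=i < n_pos)
            for i in range(n_total)
        ]

    @pytest.mark.parametrize("n_pos,expected", [(0, 0.0), (40, 1.0), (12, 0.3)])
    def test_count_ratio(self, n_pos, expected):
        assert automatic_rwa(self._minis(n_pos, 40)) == pytest.approx(expected)

    def test_no_rem_errors(self):
        minis = [rwa_core.MiniEpoch(0.0, "S2", 0.0, False)]
        with pytest.raises(ValueError, match="no REM"):
            automatic_rwa(minis)


class TestStageMetrics:
    HYP = Hypnogram(stages=("S2", "S2", "REM", "S1", "S3"))

    def test_pct_duration(self):
        # 15 s of events inside 60 s of S2
        events = [MotorActivityEvent(5.0, 15.0), MotorActivityEvent(40.0, 45.0)]
        m = stage_metrics(events, self.HYP, stage="S2")
        assert m.duration_s == pytest.approx(15.0)
        assert m.pct_duration == pytest.approx(25.0)

    def test_no_events_all_zero(self):
        for stage in ("REM", "S1", "S2", "S3", "NREM"):
            m = stage_metrics([], self.HYP, stage=stage)
            assert (m.pct_miniepochs, m.duration_s, m.pct_duration) == (0, 0, 0)

    def test_nrem_additivity(self):
        events = [MotorActivityEvent(10.0, 12.0),    # S2
                  MotorActivityEvent(95.0, 97.0),    # S1
                  MotorActivityEvent(130.0, 133.0)]  # S3
        parts = sum(stage_metrics(events, self.HYP, stage=s).duration_s
                    for s in ("S1", "S2", "S3"))
        nrem = stage_metrics(events, self.HYP, stage="NREM").duration_s
        assert nrem == pytest.approx(parts)

    def test_absent_stage_warns_and_zeroes(self):
        hyp = Hypnogram(stages=("S2", "REM"))
        with pytest.warns(UserWarning, match="absent"):
            m = stage_metrics([], hyp, stage="S3")
        assert not m.present


class TestScoreRecording:
    def test_atonia_only_scores_zero(self, atonia_recording):
        rec, _ = atonia_recording
        res = rwa_core.score_recording(rec)
        assert res.auto_rwa == 0.0
        assert res.n_events == 0

    def test_sustained_tone_scores_one(self, short_blocks):
        from conftest import REM_SPAN
        rem_start, rem_end = REM_SPAN
        spec = synth.SynthSignalSpec(
            hypnogram_spec=short_blocks,
            tonic_segments=((rem_start, rem_end, 6.0),), seed=11)
        res, _ = score_spec(spec)
        assert res.auto_rwa == 1.0

    def test_planted_occupancy_recovered(self, short_blocks):
        spec = synth.SynthSignalSpec(hypnogram_spec=short_blocks,
                                     target_occupancy=0.3, seed=5)
        res, truth = score_spec(spec)
        assert res.auto_rwa == pytest.approx(0.30, abs=0.05)
        assert len(truth.positive_minis) == 30  # 30 % of 100 REM minis

    def test_summary_mentions_score(self, atonia_recording):
        rec, _ = atonia_recording
        res = rwa_core.score_recording(rec)
        assert "automatic RWA score : 0.000" in res.summary()

    def test_flat_dict_has_stage_keys(self, atonia_recording):
        rec, _ = atonia_recording
        flat = rwa_core.score_recording(rec).to_flat_dict()
        for stage in ("REM", "S1", "S2", "S3", "NREM"):
            assert f"{stage}_pct_duration" in flat


class TestInvariants:
    def test_amplitude_equivariance(self, short_blocks):
        # threshold is a ratio: scaling the EMG leaves events unchanged as
        # long as the baseline floor is not engaged
        spec = synth.SynthSignalSpec(hypnogram_spec=short_blocks,
                                     target_occupancy=0.2, seed=3)
        sig, hyp, _ = synth.generate_signal(spec)
        cfg = DetectionConfig()

        def events_of(x):
            filtered = rwa_core.preprocess(
                EmgSignal(x, sig.rate, label=sig.label), cfg)
            ac = compute_amplitude_curve(filtered, cfg)
            base = estimate_baseline(ac, cfg)
            assert np.all(base.values > cfg.baseline_floor_uv)
            return detect_events(ac, base, cfg)

        e1 = events_of(sig.samples)
        e3 = events_of(3.0 * sig.samples)
        assert len(e1) == len(e3)
        for a, b in zip(e1, e3):
            assert a.start == pytest.approx(b.start, abs=2 / RATE)
            assert a.end == pytest.approx(b.end, abs=2 / RATE)

    def test_raising_madt_never_adds_event_time(self, short_blocks):
        spec = synth.SynthSignalSpec(hypnogram_spec=short_blocks,
                                     burst_rate_per_min=4.0,
                                     burst_amp_ratio=6.0, seed=9)
        sig, hyp, _ = synth.generate_signal(spec)
        totals = []
        for factor in (2.0, 4.0, 8.0):
            cfg = DetectionConfig(madt_factor=factor)
            filtered = rwa_core.preprocess(sig, cfg)
            ac = compute_amplitude_curve(filtered, cfg)
            base = estimate_baseline(ac, cfg)
            events = detect_events(ac, base, cfg)
            totals.append(sum(e.duration for e in events))
        assert totals[0] >= totals[1] >= totals[2]

    def test_event_list_invariants_on_noise(self, rng):
        v = np.abs(rng.normal(size=seconds(60))) * 3
        cfg = DetectionConfig()
        base = make_base(np.full(v.size, 0.8))
        events = detect_events(make_ac(v), base, cfg)
        for k, e in enumerate(events):
            assert e.duration >= cfg.min_event_s - 1e-9
            if k:
                assert e.start - events[k - 1].end >= cfg.iei_s - 1e-9


def test_config_validation():
    with pytest.raises(ValueError):
        DetectionConfig(window_samples=50)       # must be odd
    with pytest.raises(ValueError):
        DetectionConfig(occupancy_threshold=1.5)
    with pytest.raises(ValueError):
        DetectionConfig(baseline_mode="median")
    with pytest.raises(ValueError):
        DetectionConfig(exclusions="artifact")
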