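"""TIRF segmentation: pause/burst detection, events, and summaries."""

import numpy as np
import pytest

import formin_kinetics as fk
from formin_kinetics.datatypes import SUBUNITS_PER_UM, FormEvent
from formin_kinetics.simulate import FilamentKineticsParams
from formin_kinetics.tirf import (
    TraceSegmenter,
    count_filaments,
    event_statistics,
    extract_events,
    match_events,
    segment_trace,
)


def synthetic_pause_burst_trace(
    pause_start=100.0, pause_dur=8.0, run_um=1.0, rate=39.0,
    v_free=10.0, dt=2.5, duration=400.0, dim_factor=0.5, noise=0.0, seed=0,
):
    """Hand-built trace: free growth, one pause, one burst, free again."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    burst_dur = run_um * SUBUNITS_PER_UM / rate
    t_burst_end = pause_start + pause_dur + burst_dur
    length_sub = np.empty_like(t)
    intensity = np.ones_like(t)
    for i, ti in enumerate(t):
        if ti <= pause_start:
            length_sub[i] = v_free * ti
        elif ti <= pause_start + pause_dur:
            length_sub[i] = v_free * pause_start
        elif ti <= t_burst_end:
            length_sub[i] = v_free * pause_start + rate * (ti - pause_start - pause_dur)
            intensity[i] = dim_factor
        else:
            length_sub[i] = (
                v_free * pause_start + rate * burst_dur + v_free * (ti - t_burst_end)
            )
    length_um = length_sub / SUBUNITS_PER_UM
    if noise > 0:
        length_um = length_um + rng.normal(0, noise, size=t.size)
    return fk.FilamentTrace("hand", t, length_um, intensity_au=intensity)


class TestSegmentTrace:
    def test_pure_linear_trace_is_one_free_segment(self):
        t = np.arange(0.0, 200.0, 2.5)
        tr = fk.FilamentTrace("lin", t, (10.0 * t) / SUBUNITS_PER_UM)
        segs = segment_trace(tr)
        assert len(segs) == 1
        assert segs[0].kind == "free"
        assert segs[0].slope == pytest.approx(10.0, rel=1e-6)

    def test_planted_pause_and_burst_recovered(self):
        tr = synthetic_pause_burst_trace(pause_dur=8.0, run_um=1.0, rate=39.0)
        segs = segment_trace(tr)
        kinds = [s.kind for s in segs]
        assert kinds.count("pause") == 1
        assert kinds.count("burst") == 1
        pause = next(s for s in segs if s.kind == "pause")
        assert pause.duration_s == pytest.approx(8.0, abs=2.5)
        burst = next(s for s in segs if s.kind == "burst")
        assert burst.slope == pytest.approx(39.0, rel=0.05)
        assert burst.r2 > 0.5

    def test_three_second_pause_rejected_by_minimum(self):
        # below the 5-s minimum duration rule
        tr = synthetic_pause_burst_trace(pause_dur=3.0, run_um=2.0)
        segs = segment_trace(tr)
        assert all(s.kind != "pause" for s in segs)

    def test_tiling_disjoint_and_exhaustive(self):
        p = FilamentKineticsParams()
        for seed in range(5):
            tr = fk.simulate_filament_trace(p, seed=seed)
            segs = segment_trace(tr)
            assert segs[0].t_start == pytest.approx(tr.time_s[0])
            assert segs[-1].t_end == pytest.approx(tr.time_s[-1])
            for a, b in zip(segs[:-1], segs[1:]):
                assert b.t_start == pytest.approx(a.t_end, abs=1e-9)

    def test_unit_round_trip_subunits_vs_um(self):
        t = np.arange(0.0, 200.0, 2.5)
        tr_um = fk.FilamentTrace("um", t, 0.05 * t)
        (seg,) = segment_trace(tr_um)
        assert seg.slope == pytest.approx(0.05 * 370.0, rel=1e-9)

    def test_too_few_samples(self):
        t = np.arange(0.0, 12.6, 2.5)
        tr = fk.FilamentTrace("short", t, t / 370.0)
        with pytest.raises(ValueError, match=">= 8 samples"):
            segment_trace(tr)

    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 2.5, 5.0, 7.5, 11.0, 13.5, 16.0, 18.5, 21.0])
        tr = fk.FilamentTrace("jitter", t, t / 370.0)
        with pytest.raises(ValueError, match="uniform"):
            segment_trace(tr)

    def test_slope_only_mode_detects_post_pause_burst(self):
        tr = synthetic_pause_burst_trace(pause_dur=10.0, run_um=2.0)
        tr_no_int = fk.FilamentTrace("noint", tr.time_s, tr.length_um)
        segs = segment_trace(tr_no_int)
        kinds = [s.kind for s in segs]
        assert "pause" in kinds and "burst" in kinds


class TestExtractEvents:
    def test_burst_with_preceding_pause_pairs(self):
        tr = synthetic_pause_burst_trace()
        events = extract_events(segment_trace(tr), tr)
        assert len(events) == 1
        ev = events[0]
        assert ev.pause_duration_s is not None
        assert not ev.censored
        assert ev.run_length_um == pytest.approx(1.0, abs=0.15)

    def test_burst_at_movie_end_is_censored(self):
        tr = synthetic_pause_burst_trace(pause_start=300.0, pause_dur=10.0,
                                         run_um=30.0, duration=400.0)
        events = extract_events(segment_trace(tr), tr)
        assert len(events) == 1
        assert events[0].censored

    def test_no_bursts_gives_empty_list(self):
        t = np.arange(0.0, 200.0, 2.5)
        tr = fk.FilamentTrace("lin", t, (10.0 * t) / SUBUNITS_PER_UM)
        assert extract_events(segment_trace(tr), tr) == []

    def test_baseline_return_true_for_clean_trace(self):
        tr = synthetic_pause_burst_trace(noise=0.01, seed=3)
        events = extract_events(segment_trace(tr), tr)
        assert len(events) == 1
        assert events[0].baseline_return in (True, None)


class TestEventStatistics:
    def test_exponential_mle_equals_sample_mean(self):
        events = [
            FormEvent("f", 39.0, 1.0, 0.9, censored=False) for _ in range(3)
        ]
        s = event_statistics(events, frame_interval_s=0.0)
        assert s.run_length_mean == pytest.approx(1.0)
        assert s.run_length_char == pytest.approx(1.0)  # zero floor at dt=0

    def test_all_censored_warns(self):
        events = [FormEvent("f", 39.0, 1.0, 0.9, censored=True)]
        with pytest.warns(UserWarning, match="censored"):
            s = event_statistics(events, frame_interval_s=2.5)
        assert np.isnan(s.run_length_mean)

    def test_zero_events_summary(self):
        s = event_statistics([], traces=None, frame_interval_s=2.5)
        assert s.n_events == 0
        assert np.isnan(s.burst_rate_mean)

    def test_recovery_of_generating_means(self):
        # detection-floor-corrected estimators recover the generating
        # exponential means within 2 SEM on a large planted ensemble
        p = FilamentKineticsParams()
        traces = fk.simulate_filament_ensemble(p, 120, seed=21)
        seg = TraceSegmenter()
        events = []
        for tr in traces:
            events.extend(extract_events(seg.transform(tr), tr))
        assert len(events) >= 300
        s = event_statistics(events, traces)
        sem_rate = s.burst_rate_sd / np.sqrt(s.n_events)
        assert abs(s.burst_rate_char - p.v_burst_mean) < 2 * sem_rate
        sem_run = s.run_length_sd / np.sqrt(s.n_uncensored)
        assert abs(s.run_length_char - p.runlength_char) < 2 * sem_run
        sem_pause = s.pause_sd / np.sqrt(s.n_paired_pauses)
        assert abs(s.pause_char - p.pause_mean) < 2 * sem_pause + p.frame_interval


class TestRecoveryInvariant:
    def test_sensitivity_and_fdr_on_resolvable_events(self):
        # planted pauses >= 7.5 s and bursts >= 0.5 um: sensitivity >= 0.9
        # and false discovery <= 0.1 against planted truth
        p = FilamentKineticsParams()
        traces = fk.simulate_filament_ensemble(p, 50, seed=31)
        seg = TraceSegmenter()
        n_qual = n_hit = n_det = n_false = 0
        for tr in traces:
            events = extract_events(seg.transform(tr), tr)
            pairs = match_events(events, tr.truth_events)
            matched_det = {i for i, _ in pairs}
            matched_tru = {j for _, j in pairs}
            for j, t in enumerate(tr.truth_events):
                resolvable = (
                    (t.t_pause_end - t.t_pause_start) >= 7.5
                    and t.run_length >= 0.5
                    and t.t_burst_end < p.duration - 1e-9
                )
                if resolvable:
                    n_qual += 1
                    n_hit += j in matched_tru
            n_det += len(events)
            n_false += sum(1 for i in range(len(events)) if i not in matched_det)
        assert n_qual > 30
        assert n_hit / n_qual >= 0.9
        assert n_false / max(n_det, 1) <= 0.1

    def test_no_formin_null_event_rate(self):
        # without formin the dim-velocity control: virtually no events
        p = FilamentKineticsParams(k_attach=0.0)
        traces = fk.simulate_filament_ensemble(p, 60, seed=41)
        seg = TraceSegmenter()
        n_events = sum(len(extract_events(seg.transform(tr), tr)) for tr in traces)
        assert n_events / len(traces) < 0.05


class TestCountFilaments:
    @staticmethod
    def _fov_with_filaments(n, length_px=12, size=256, seed=0):
        rng = np.random.default_rng(seed)
        img = np.full((size, size), 100.0)
        rows = rng.choice(np.arange(8, size - 8, 8), size=n, replace=False)
        for r in rows:
            c0 = rng.integers(5, size - length_px - 5)
            img[r, c0 : c0 + length_px] = 1000.0
        return img

    def test_planted_count_recovered(self):
        img = self._fov_with_filaments(25, length_px=12)  # 12 px * 0.16 = 1.92 um
        assert count_filaments(img, min_length_um=1.0, pixel_size_um=0.16) == 25

    def test_blank_image_zero(self):
        assert count_filaments(np.zeros((64, 64)), 1.0, 0.16) == 0

    def test_short_filament_filtered(self):
        img = self._fov_with_filaments(1, length_px=4)  # 0.64 um < 1 um
        assert count_filaments(img, min_length_um=1.0, pixel_size_um=0.16) == 0
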