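"""Membrane-potential analysis: baseline extraction, spike and IPSP
detection, tuning curves, jump statistics and lag correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pflsteer.behavior import JumpEvent
from pflsteer.ephys import (
    baseline_vm,
    detect_spikes,
    detect_ipsps,
    preferred_direction_tuning,
    ipsp_jump_response,
    tuning_by_goal_offset,
    brown_forsythe,
    jump_dvm_stats,
    unbalanced_two_factor_anova,
    dvm_speed_lag_correlation,
)
from pflsteer.synth import synth_vm

FS = 1000.0


def _spiky_trace(n=20000, n_spikes=10, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    vm = np.full(n, -50.0)
    if noise:
        vm += noise * rng.standard_normal(n)
    times = np.linspace(2000, n - 2000, n_spikes).astype(int)
    for t in times:
        vm[t : t + 2] += [35.0, 12.0]  # 2 ms spike template
    return vm, times / FS


class TestBaseline:
    def test_spike_free_trace_preserved(self, rng):
        vm = -50.0 + np.sin(np.arange(5000) / 500.0) * 5.0
        base = baseline_vm(vm)
        assert np.max(np.abs(base - vm)) < 0.1

    def test_spikes_removed(self):
        vm, _ = _spiky_trace()
        base = baseline_vm(vm)
        assert np.max(np.abs(base - (-50.0))) < 0.5

    def test_step_overshoot_bounded_by_smoother_tolerance(self):
        vm = np.concatenate([np.full(3000, -60.0), np.full(3000, -40.0)])
        base = baseline_vm(vm)
        # local quadratic regression rings by at most ~10% of the step
        assert base.min() >= -62.0 and base.max() <= -38.0
        # flat away from the transition
        np.testing.assert_allclose(base[:2900], -60.0, atol=1e-9)
        np.testing.assert_allclose(base[3100:], -40.0, atol=1e-9)

    def test_too_short_trace(self):
        with pytest.raises(ValueError):
            baseline_vm(np.zeros(10))


class TestSpikes:
    def test_counts_injected_templates(self):
        vm, true_times = _spiky_trace(noise=0.3)
        st, rate = detect_spikes(vm, threshold_sd=5.0)
        assert len(st) == len(true_times)
        assert np.max(np.abs(np.asarray(st) - true_times)) < 0.003
        # 100 ms boxcar rate integrates to the spike count
        assert np.sum(rate) / FS == pytest.approx(len(true_times), rel=0.01)

    def test_noise_only_low_false_positive_rate(self, rng):
        vm = -50.0 + 0.5 * rng.standard_normal(int(60 * FS))
        st, _ = detect_spikes(vm)
        assert len(st) / 60.0 < 1.0  # < 1 Hz false positives

    def test_refractory_merges_doublet(self):
        rng = np.random.default_rng(4)
        vm = -50.0 + 0.2 * rng.standard_normal(8000)
        vm[4000:4002] += 35.0
        vm[4001:4003] += 35.0  # second event 1 ms later
        st, _ = detect_spikes(vm, threshold_sd=5.0)
        assert len(st) == 1


class TestIpsps:
    def test_noiseless_exact_count(self):
        heading = np.zeros(60 * 30 + 1)
        vmtr, truth = synth_vm(
            heading, 40.0, ipsp_rate_law="uniform", ipsp_rate_hz=0.7,
            ipsp_amp_range_mv=(1.0, 1.0), noise_sd_mv=0.0, seed=3,
        )
        events = detect_ipsps(vmtr.vm)
        assert len(events) == len(truth.ipsp_times)
        for e in events:
            assert e.derivative_peak < 0 and e.detrended_peak < 0

    def test_noisy_recall_and_precision(self):
        """1 mV IPSPs in 0.2 mV RMS noise: recall and precision >= 0.9."""
        heading = np.zeros(60 * 120 + 1)
        vmtr, truth = synth_vm(
            heading, 40.0, ipsp_rate_law="uniform", ipsp_rate_hz=8.0,
            ipsp_amp_range_mv=(1.0, 1.0), noise_sd_mv=0.2, seed=11,
        )
        det = np.array([e.time for e in detect_ipsps(vmtr.vm)])
        true_t = truth.ipsp_times
        tol = 0.015
        recall = np.mean([np.any(np.abs(det - t) < tol) for t in true_t])
        precision = np.mean([np.any(np.abs(true_t - t) < tol) for t in det])
        assert recall >= 0.9 and precision >= 0.9

    @pytest.mark.parametrize("rate", [2.0, 8.0, 20.0])
    def test_rate_recovery(self, rate):
        """Detected event rate within 10% of the generated rate."""
        heading = np.zeros(60 * 120 + 1)
        vmtr, truth = synth_vm(
            heading, 40.0, ipsp_rate_law="uniform", ipsp_rate_hz=rate,
            ipsp_amp_range_mv=(1.0, 1.0), noise_sd_mv=0.2, seed=11,
        )
        n_det = len(detect_ipsps(vmtr.vm))
        assert n_det == pytest.approx(len(truth.ipsp_times), rel=0.10)

    def test_slow_dip_rejected_by_coincidence_window(self):
        """A gradual hyperpolarization whose derivative minimum leads the
        trough by ~50 ms is not scored as an IPSP, while a sharp event is."""
        n = int(30 * FS)
        t = np.arange(n) / FS
        vm = np.full(n, -50.0)
        # slow Gaussian dip, sigma 50 ms: derivative peak 50 ms before trough
        vm -= 1.5 * np.exp(-0.5 * ((t - 10.0) / 0.05) ** 2)
        # sharp drop + exponential recovery at t = 20 s
        sharp = t >= 20.0
        vm[sharp] -= 1.5 * np.exp(-(t[sharp] - 20.0) / 0.015)
        events = detect_ipsps(vm)
        times = np.array([e.time for e in events])
        assert np.any(np.abs(times - 20.0) < 0.05)
        assert not np.any(np.abs(times - 10.0) < 0.2)

    def test_min_separation_enforced(self):
        heading = np.zeros(60 * 60 + 1)
        vmtr, _ = synth_vm(
            heading, 40.0, ipsp_rate_law="uniform", ipsp_rate_hz=12.0,
            noise_sd_mv=0.2, seed=2,
        )
        times = np.array([e.time for e in detect_ipsps(vmtr.vm)])
        assert np.all(np.diff(times) >= 0.02 - 1e-9)

    def test_no_quiescent_samples(self):
        with pytest.raises(ValueError, match="quiescent"):
            detect_ipsps(np.zeros(5000), quiescent_mask=np.zeros(5000, dtype=bool))


class TestTuning:
    def test_cosine_tuning_recovered(self):
        rng = np.random.default_rng(1)
        th = rng.uniform(-180, 180, 20000)
        vm = -50.0 + 5.0 * np.cos(np.deg2rad(th - 40.0))
        tc = preferred_direction_tuning(vm, th)
        assert 30.0 <= tc.preferred <= 50.0  # the bin containing 40
        assert tc.amplitude == pytest.approx(10.0, abs=0.5)

    def test_flat_ties_break_to_smallest_bin(self):
        th = np.linspace(-179, 179, 3600)
        tc = preferred_direction_tuning(np.full(3600, -55.0), th)
        assert tc.preferred == -170.0
        assert tc.amplitude == pytest.approx(0.0, abs=1e-12)

    def test_sparse_coverage_warns(self):
        with pytest.warns(UserWarning, match="sparse"):
            preferred_direction_tuning(np.ones(100), np.full(100, 5.0))

    def test_snr_recovery_monte_carlo(self):
        """theta_p recovered within one 20-degree bin for cosine tuning at
        SNR >= 2 in >= 95% of simulated cells."""
        rng = np.random.default_rng(5)
        hits = 0
        n_cells = 200
        for _ in range(n_cells):
            theta_p = rng.uniform(-180, 180)
            th = rng.uniform(-180, 180, 3000)
            amp = 4.0
            vm = -50 + (amp / 2) * np.cos(np.deg2rad(th - theta_p))
            vm += (amp / 4) * rng.standard_normal(3000)  # SNR 2
            tc = preferred_direction_tuning(vm, th)
            from pflsteer.circular import circ_dist_signed

            if abs(circ_dist_signed(tc.preferred, theta_p)) <= 20.0:
                hits += 1
        assert hits / n_cells >= 0.95


class TestIpspJumpResponse:
    def _simulate(self, sign=+1, seed=4):
        """Heading jumps every 30 s; IPSP rate r0 * (1 + sign*cos(theta - theta_p))."""
        rng = np.random.default_rng(seed)
        fs = FS
        n = int(600 * fs)
        theta_p = 0.0
        jumps = np.arange(30.0, 590.0, 30.0)
        heading = np.zeros(n)
        cur = 0.0
        bounds = [0] + [int(j * fs) for j in jumps] + [n]
        vals = []
        for _ in range(len(bounds) - 1):
            vals.append(cur)
            cur = rng.uniform(-180, 180)
        for (a, b), v in zip(zip(bounds[:-1], bounds[1:]), vals):
            heading[a:b] = v
        rate = 5.0 * (1.0 + sign * np.cos(np.deg2rad(heading - theta_p)))
        ev = np.flatnonzero(rng.random(n) < rate / fs) / fs
        return ev, jumps, heading, theta_p

    def test_rate_coupled_to_preferred_direction(self):
        """With IPSP rate highest at theta_p, jumps that move the heading
        away from theta_p reduce IPSP frequency: negative correlation
        between delta|theta - theta_p| and delta frequency... with the rate
        rising toward theta_p the correlation is negative."""
        ev, jumps, heading, theta_p = self._simulate(sign=+1)
        res = ipsp_jump_response(ev, jumps, heading, theta_p)
        assert res.r < -0.5 and res.slope < 0

    def test_null_rate_uncorrelated(self):
        rng = np.random.default_rng(9)
        n = int(600 * FS)
        heading = np.repeat(rng.uniform(-180, 180, 20), n // 20)
        ev = np.flatnonzero(rng.random(n) < 5.0 / FS) / FS
        jumps = np.arange(30.0, 590.0, 30.0)
        res = ipsp_jump_response(ev, jumps, heading, 0.0)
        assert abs(res.r) < 0.35

    def test_too_few_jumps(self):
        with pytest.raises(ValueError):
            ipsp_jump_response(np.array([1.0]), np.array([2.0]), np.zeros(int(20 * FS)), 0.0)


class TestGoalOffsetTuning:
    def _population(self, amplitude_fn, n_cells=40, seed=6):
        """One segment per cell; goal fixed at 0, theta_p tiling the circle."""
        rng = np.random.default_rng(seed)
        cells = []
        for i in range(n_cells):
            theta_p = -180.0 + 360.0 * (i + 0.5) / n_cells
            th = rng.uniform(-180, 180, 2000)
            amp = amplitude_fn(theta_p)
            vm = -50.0 + (amp / 2) * np.cos(np.deg2rad(th - theta_p))
            cells.append(
                {"values": vm, "heading": th, "theta_g": 0.0, "theta_p": theta_p,
                 "rho": 0.9}
            )
        return cells

    def test_antigoal_cells_have_largest_amplitude(self):
        """Mimicking the model: the goal bias makes cells preferring the
        anti-goal the most strongly tuned."""
        from pflsteer.circular import circ_dist_signed

        amp = lambda tp: 2.0 + 8.0 * (1 - np.cos(np.deg2rad(tp - 0.0))) / 2.0
        out = tuning_by_goal_offset(self._population(amp))
        spans = {k: np.nanmax(v["mean"]) - np.nanmin(v["mean"]) for k, v in out.items()}
        best = max(spans, key=spans.get)
        assert abs(circ_dist_signed(best, 180.0)) <= 72.0

    def test_uniform_population_flat_across_bins(self):
        out = tuning_by_goal_offset(self._population(lambda tp: 6.0))
        spans = [np.nanmax(v["mean"]) - np.nanmin(v["mean"]) for v in out.values()]
        assert np.ptp(spans) < 0.5

    def test_min_subtraction_arithmetic(self):
        cells = self._population(lambda tp: 6.0, n_cells=5)
        on = tuning_by_goal_offset(cells, subtract_min=True)
        off = tuning_by_goal_offset(cells, subtract_min=False)
        for k in on:
            assert np.nanmin(on[k]["mean"]) == pytest.approx(0.0, abs=1e-9)
            assert not np.allclose(on[k]["mean"], off[k]["mean"])

    def test_low_rho_segments_excluded(self):
        cells = self._population(lambda tp: 6.0, n_cells=5)
        for c in cells:
            c["rho"] = 0.5
        assert tuning_by_goal_offset(cells) == {}

    def test_pfl3l_bins_mirrored(self):
        cells = self._population(lambda tp: 6.0, n_cells=8)
        for c in cells:
            c["cell_type"] = "PFL3L"
        out_l = tuning_by_goal_offset(cells)
        for c in cells:
            c["cell_type"] = "PFL3R"
        out_r = tuning_by_goal_offset(cells)
        # mirrored offsets: the left cells populate the negated bins
        offs_l = sorted(out_l)
        offs_r = sorted(-o for o in out_r)
        assert offs_l == pytest.approx(offs_r)


class TestBrownForsythe:
    def test_closed_form_small_example(self):
        """Hand-computable check: the Brown-Forsythe statistic is a one-way
        ANOVA F on absolute deviations from group medians."""
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([10.0, 11.0, 12.0, 20.0])
        zx = np.abs(x - np.median(x))
        zy = np.abs(y - np.median(y))
        f_manual, p_manual = sps.f_oneway(zx, zy)
        stat, p = brown_forsythe(x, y)
        assert stat == pytest.approx(f_manual)
        assert p == pytest.approx(p_manual)

    def test_identical_groups_zero_statistic(self):
        g = np.array([1.0, 3.0, 5.0, 7.0])
        stat, _ = brown_forsythe(g, g)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_power_against_variance_ratio(self):
        """Variance ratio 4:1, n = 30 per group: rejection rate well above
        the nominal 5% level."""
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 400
        for _ in range(reps):
            _, p = brown_forsythe(
                2.0 * rng.standard_normal(30), rng.standard_normal(30)
            )
            rejections += p < 0.05
        assert rejections / reps > 0.5

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            brown_forsythe(np.array([1.0]), np.array([1.0, 2.0]))


class TestJumpDvm:
    def _jumps(self, times, corrected, high):
        out = []
        for t, c, h in zip(times, corrected, high):
            jp = JumpEvent(time=t, magnitude=90.0)
            jp.corrected, jp.high_rho, jp.excluded = c, h, False
            out.append(jp)
        return out

    def test_group_assembly_and_statistic(self, rng):
        fs = FS
        n = int(300 * fs)
        vm = -50 + 0.5 * rng.standard_normal(n)
        times = np.arange(10.0, 290.0, 10.0)
        # big jump-locked deflections on half the jumps
        corrected = [i % 2 == 0 for i in range(len(times))]
        for t, c in zip(times, corrected):
            if c:
                j = int(t * fs)
                vm[j : j + 1000] += rng.choice([-1, 1]) * 4.0
        jumps = self._jumps(times, corrected, corrected)
        res = jump_dvm_stats(vm, jumps)
        assert len(res.dvm_corrected_high) == sum(corrected)
        assert res.dvm_corrected_high.std() > res.dvm_uncorrected_low.std()
        assert res.p_value < 0.05

    def test_insufficient_group(self):
        vm = np.zeros(int(100 * FS))
        jumps = self._jumps([10.0, 20.0], [True, True], [True, True])
        with pytest.raises(ValueError):
            jump_dvm_stats(vm, jumps)


def test_two_factor_anova_detects_main_effect():
    rng = np.random.default_rng(3)
    a = np.repeat(["near", "far"], 40)
    b = rng.choice(["f1", "f2", "f3"], 80)
    y = rng.standard_normal(80) + np.where(a == "far", 2.0, 0.0)
    table = unbalanced_two_factor_anova(y, a, b)
    assert table.loc["C(a, Sum)", "PR(>F)"] < 1e-6
    assert table.loc["C(b, Sum)", "PR(>F)"] > 0.01


class TestLagCorrelation:
    def test_lag_grid_has_201_points(self, rng):
        n = int(100 * FS)
        vm = rng.standard_normal(n)
        sp = rng.standard_normal(n)
        out = dvm_speed_lag_correlation(vm, sp, [30.0, 50.0, 70.0])
        assert len(out) == 201
        assert out["lag_s"].iloc[0] == pytest.approx(-1.0)
        assert out["lag_s"].iloc[-1] == pytest.approx(1.0)

    def test_vm_leading_speed_peaks_at_positive_lag(self):
        """Membrane-potential changes built to lead rotational speed by
        300 ms produce a correlation peak at a positive (vm-leads) lag."""
        rng = np.random.default_rng(12)
        n = int(400 * FS)
        drive = np.convolve(rng.standard_normal(n), np.ones(500) / 500, mode="same")
        vm = -50 + 5 * np.abs(drive)
        lead = int(0.3 * FS)
        speed = np.roll(np.abs(drive), lead) * 50.0
        jumps = np.arange(20.0, 380.0, 20.0)
        out = dvm_speed_lag_correlation(vm, speed, jumps)
        peak_lag = out.loc[out["mean_r"].idxmax(), "lag_s"]
        assert 0.1 <= peak_lag <= 0.5

    def test_independent_signals_flat(self, rng):
        n = int(200 * FS)
        vm = rng.standard_normal(n)
        sp = rng.standard_normal(n)
        out = dvm_speed_lag_correlation(vm, sp, np.arange(20.0, 180.0, 20.0))
        assert np.nanmax(np.abs(out["mean_r"])) < 0.1

    def test_no_qualifying_jumps(self):
        with pytest.raises(ValueError):
            dvm_speed_lag_correlation(np.zeros(1000), np.zeros(1000), [100.0])
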