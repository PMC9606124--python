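"""Kinetic inference: phase annotation, mitotic masking, synthesis-rate
and half-life estimation, activity computation, mitosis alignment."""

import math

import numpy as np
import pytest
from scipy import stats

from ligaseflux.kinetics import (
    align_to_mitosis,
    annotate_phases,
    compute_activity,
    estimate_half_life,
    estimate_synthesis_rate,
    mask_mitotic_frames,
)
from ligaseflux.synth import (
    simulate_geminin_trace,
    simulate_phase_schedule,
    simulate_reporter_trace,
)
from ligaseflux.types import KineticParams, Perturbation, ReporterTrace


def flat_trace(n=60, value=40.0, dt=0.2, mitoses=()):
    return ReporterTrace(
        cell_id="t", times=dt * np.arange(n), R=np.full(n, value),
        phase=np.array(["G1"] * n, dtype=object), mitosis_frames=list(mitoses),
    )


class TestAnnotatePhases:
    def test_zero_geminin_stays_g1(self, cycling_schedule):
        sched = cycling_schedule(25.0)
        tr = simulate_reporter_trace(sched, KineticParams(noise_cv=0.0))
        gem = ReporterTrace(
            cell_id="g", times=tr.times, R=np.zeros(tr.n_frames), phase=tr.phase
        )
        labels = annotate_phases(tr, gem)
        non_m = np.asarray([i not in tr.mitosis_frames for i in range(tr.n_frames)])
        assert set(labels[non_m]) == {"G1"}

    def test_ramp_onset_matches_brute_force_threshold_scan(self):
        """Onset frame from the annotator equals a direct scan for the
        first frame above baseline + 0.2*(max-baseline) rising 3 frames."""
        n = 100
        times = 0.2 * np.arange(n)
        g = np.zeros(n)
        j = 37
        g[j:] = np.linspace(0.0, 50.0, n - j)
        tr = flat_trace(n)
        gem = ReporterTrace(cell_id="g", times=times, R=g, phase=tr.phase)
        labels = annotate_phases(tr, gem, onset_fraction=0.2, persistence_frames=3)

        thresh = g.min() + 0.2 * (g.max() - g.min())
        expected = next(
            i for i in range(n - 3)
            if g[i] > thresh and np.all(np.diff(g[i : i + 4]) > 0)
        )
        onset = int(np.argmax(labels == "SG2"))
        assert onset == expected

    def test_trace_ending_before_onset_is_all_g1(self):
        n = 20
        tr = flat_trace(n)
        gem = ReporterTrace(
            cell_id="g", times=tr.times, R=np.zeros(n), phase=tr.phase
        )
        assert set(annotate_phases(tr, gem)) == {"G1"}

    def test_simulated_cycle_annotation_agrees_with_truth(self, cycling_schedule):
        sched = cycling_schedule(39.0)
        tr = simulate_reporter_trace(sched, KineticParams(noise_cv=0.0))
        gem = simulate_geminin_trace(sched)
        labels = annotate_phases(tr, gem)
        truth_sg2 = np.isin(tr.phase, ["S", "G2"])
        agreement = np.mean((labels == "SG2") == truth_sg2)
        assert agreement > 0.8  # threshold rule lags true S entry slightly

    def test_mismatched_grids_raise(self):
        tr = flat_trace(10)
        gem = flat_trace(12)
        with pytest.raises(ValueError):
            annotate_phases(tr, gem)


class TestMitoticMask:
    def test_no_mitoses_no_mask(self):
        assert mask_mitotic_frames(flat_trace()).masked_frames is None

    def test_margin_arithmetic(self):
        tr = flat_trace(100, mitoses=[50])
        out = mask_mitotic_frames(tr, margin_frames=2)
        assert list(out.masked_frames) == [48, 49, 50, 51, 52]

    def test_masking_removes_spike_excursions_from_activity(self, cycling_schedule):
        sched = cycling_schedule(39.0)
        p = KineticParams(noise_cv=0.0, mitotic_spike=1.8)
        tr = simulate_reporter_trace(sched, p)
        a_raw = compute_activity(tr, p.s).A
        a_masked = compute_activity(mask_mitotic_frames(tr, 3), p.s).A
        iqr = stats.iqr(a_masked[np.isfinite(a_masked)])
        med = np.nanmedian(a_masked)
        for m in tr.mitosis_frames:
            lo, hi = max(0, m - 4), min(len(a_raw), m + 5)
            assert np.nanmax(np.abs(a_raw[lo:hi] - med)) > 3 * iqr  # spike visible unmasked
            window = a_masked[lo:hi]
            finite = window[np.isfinite(window)]
            if finite.size:
                assert np.abs(finite - med).max() <= 3 * iqr


class TestSynthesisRate:
    def _mln_trace(self, k, noise_cv, seed, s=10.0, duration=12.0):
        sched = simulate_phase_schedule(1, {"G0": 1.0}, duration=duration, seed=0)[0]
        p = KineticParams(s=s, k_by_phase={"G0": k}, noise_cv=noise_cv)
        return simulate_reporter_trace(
            sched, p, [Perturbation.mln4924(2.0)], seed=seed
        )

    def test_noiseless_full_block_slope_exact(self):
        tr = self._mln_trace(0.25, 0.0, 0)
        s, slopes, flags = estimate_synthesis_rate([tr])
        assert s == pytest.approx(10.0, abs=1e-9)
        assert not flags.any()

    def test_noisy_cohort_median_within_two_percent(self):
        traces = [self._mln_trace(0.25, 0.05, i) for i in range(100)]
        s, _, _ = estimate_synthesis_rate(traces)
        assert abs(s - 10.0) / 10.0 < 0.02

    def test_residual_degradation_flagged(self):
        sched = simulate_phase_schedule(1, {"G0": 1.0}, duration=20.0, seed=0)[0]
        p = KineticParams(s=10.0, k_by_phase={"G0": 0.25}, noise_cv=0.0)
        tr = simulate_reporter_trace(sched, p, [Perturbation.mln4924(2.0, residual=0.5)])
        s, slopes, flags = estimate_synthesis_rate([tr])
        assert flags[0]
        assert s < 10.0  # residual decay biases the slope low

    def test_missing_event_raises(self):
        with pytest.raises(ValueError):
            estimate_synthesis_rate([flat_trace()])


class TestComputeActivity:
    def test_constant_trace_activity_equals_synthesis(self):
        at = compute_activity(flat_trace(value=40.0), s=5.0)
        np.testing.assert_allclose(at.A[2:-2], 5.0, atol=1e-9)

    def test_full_inhibition_gives_zero_activity(self):
        sched = simulate_phase_schedule(1, {"G0": 1.0}, duration=12.0, seed=0)[0]
        p = KineticParams(s=10.0, k_by_phase={"G0": 0.0}, noise_cv=0.0, R0=0.0)
        tr = simulate_reporter_trace(sched, p)
        at = compute_activity(tr, 10.0)
        np.testing.assert_allclose(at.A[2:-2], 0.0, atol=1e-9)

    def test_ode_identity_a_equals_kr(self, quiescent_schedule):
        """A = s - dR/dt = kR on noiseless traces, within O(dt^2)."""
        p = KineticParams(s=10.0, k_by_phase={"G0": 0.25}, noise_cv=0.0, R0=100.0)
        tr = simulate_reporter_trace(quiescent_schedule(20.0), p)
        at = compute_activity(tr, 10.0)
        expected = 0.25 * tr.latent
        interior = slice(3, -3)
        rel = np.abs(at.A[interior] - expected[interior]) / expected[interior]
        assert np.nanmax(rel) < 0.01

    def test_k_specific_recovers_decay_constant(self, quiescent_schedule):
        p = KineticParams(s=10.0, k_by_phase={"G0": 0.25}, noise_cv=0.0, R0=100.0)
        tr = simulate_reporter_trace(quiescent_schedule(20.0), p)
        at = compute_activity(tr, 10.0)
        assert np.nanmedian(at.k_specific) == pytest.approx(0.25, rel=0.01)

    def test_all_masked_raises(self):
        tr = flat_trace(10)
        tr.masked_frames = np.arange(10)
        with pytest.raises(ValueError):
            compute_activity(tr, 5.0)

    def test_mln_limit_median_activity_near_zero(self, quiescent_schedule):
        """After complete inhibition, |median A| < 0.05 s despite noise."""
        sched = quiescent_schedule(16.0)
        p = KineticParams(s=10.0, k_by_phase={"G0": 0.25}, noise_cv=0.05)
        post = []
        for i in range(40):
            tr = simulate_reporter_trace(sched, p, [Perturbation.mln4924(4.0)], seed=i)
            at = compute_activity(tr, 10.0)
            post.append(np.nanmedian(at.A[tr.times > 5.0]))
        assert abs(np.median(post)) < 0.05 * 10.0

    def test_phase_contrast_sign_test(self):
        """With k_G1 > k_SG2, per-cell median activity is higher in G1
        (sign test p < 0.01 over 100 cells)."""
        n_cells = 100
        wins = 0
        for i in range(n_cells):
            sched = simulate_phase_schedule(
                1, None, duration=39.0, seed=1000 + i, duration_cv=0.1
            )[0]
            p = KineticParams(noise_cv=0.05)  # k_G1=0.2521 > k_SG2=0.077
            tr = simulate_reporter_trace(sched, p, seed=i)
            masked = mask_mitotic_frames(tr, 2)
            at = compute_activity(masked, p.s)
            g1 = np.asarray([ph == "G1" for ph in tr.phase])
            sg2 = np.isin(tr.phase, ["S", "G2"])
            a_g1 = np.nanmedian(at.A[g1])
            a_sg2 = np.nanmedian(at.A[sg2])
            if np.isfinite(a_g1) and np.isfinite(a_sg2) and a_g1 > a_sg2:
                wins += 1
        assert stats.binomtest(wins, n_cells, 0.5, alternative="greater").pvalue < 0.01


class TestHalfLife:
    def _chx_trace(self, k, noise_cv=0.0, seed=0, duration=12.0, r0=100.0):
        sched = simulate_phase_schedule(1, {"G0": 1.0}, duration=duration, seed=0)[0]
        p = KineticParams(s=0.0, k_by_phase={"G0": k}, noise_cv=noise_cv, R0=r0)
        return simulate_reporter_trace(sched, p, [Perturbation.chx(0.0)], seed=seed)

    def test_exact_exponential_recovers_half_life(self):
        fit = estimate_half_life(self._chx_trace(math.log(2) / 3))
        assert fit.t_half == pytest.approx(3.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_trace_flags_no_decay(self):
        tr = flat_trace()
        tr.perturbations.append(Perturbation.chx(0.0))
        fit = estimate_half_life(tr)
        assert fit.no_decay and math.isinf(fit.t_half)

    def test_noisy_cohort_median_within_five_percent(self):
        fits = [
            estimate_half_life(self._chx_trace(0.2521, 0.05, seed=i, duration=8.0))
            for i in range(50)
        ]
        med = np.median([f.t_half for f in fits])
        assert abs(med - math.log(2) / 0.2521) / (math.log(2) / 0.2521) < 0.05

    def test_too_few_frames_raises(self):
        tr = self._chx_trace(0.25, duration=0.6)
        with pytest.raises(ValueError):
            estimate_half_life(tr)


class TestAlignToMitosis:
    def test_shift_arithmetic(self):
        tr = flat_trace(100, mitoses=[50])
        al = align_to_mitosis([tr], window_h=(-2, 2), min_count=1)
        zero = np.argmin(np.abs(al.relative_time))
        assert al.relative_time[zero] == 0.0
        assert np.isfinite(al.matrix[0, zero])

    def test_traces_without_mitosis_excluded(self):
        with_m = flat_trace(100, mitoses=[50])
        without = flat_trace(100)
        al = align_to_mitosis([with_m, without], window_h=(-1, 1), min_count=1)
        assert al.matrix.shape[0] == 1

    def test_no_usable_traces_raises(self):
        with pytest.raises(ValueError):
            align_to_mitosis([flat_trace(20)])

    def test_aligned_median_peaks_at_mitosis(self):
        """The mitotic-spike artifact places the cohort median maximum
        within one frame of relative time zero."""
        scheds = simulate_phase_schedule(30, None, duration=40.0, seed=2, duration_cv=0.1)
        p = KineticParams(noise_cv=0.02, mitotic_spike=1.8)
        traces = [simulate_reporter_trace(s, p, seed=i) for i, s in enumerate(scheds)]
        al = align_to_mitosis(traces, window_h=(-2, 2), min_count=5)
        peak_t = al.relative_time[np.nanargmax(al.median)]
        assert abs(peak_t) <= 0.2 + 1e-9
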