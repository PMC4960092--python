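"""Slice-stack volumetry, the phase-correspondence window, and parabolic peak fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pfrkit import (DerivativeCurve, InputError, NoConcavePeakError, PhantomSpec,
                    SegmentationStack, TimeVolumeCurve, derivative_curve,
                    du_bois_bsa, fit_parabola, global_indices,
                    make_volume_waveform, pfr_ssfp, phase_window_from_pc_peak,
                    render_ssfp_stack, stack_volume, temporal_blur, true_pfr)


def normal_equations_quadratic(t, y):
    """Brute-force least-squares oracle: form X'X beta = X'y on the raw (uncentered)
    design and eliminate in extended precision, since the raw normal equations are
    ill-conditioned for times in the hundreds of ms."""
    t = np.asarray(t, dtype=np.longdouble)
    y = np.asarray(y, dtype=np.longdouble)
    X = np.column_stack([t * t, t, np.ones_like(t)])
    A = X.T @ X
    b = X.T @ y
    # Gaussian elimination with partial pivoting (np.linalg has no longdouble path)
    M = np.hstack([A, b[:, None]])
    for i in range(3):
        p = i + int(np.argmax(np.abs(M[i:, i])))
        M[[i, p]] = M[[p, i]]
        M[i] = M[i] / M[i, i]
        for j in range(3):
            if j != i:
                M[j] = M[j] - M[j, i] * M[i]
    return M[:, 3].astype(float)


class TestStackVolume:
    def test_slice_summation_arithmetic(self):
        # 10 slices x 600 pixels x 2.25 mm^2, thickness 8 mm, no gap -> 108.0 mL
        masks = np.zeros((1, 10, 40, 40), dtype=bool)
        masks[0, :, :20, :30] = True  # 600 pixels per slice
        stack = SegmentationStack(masks=masks, pixel_size=1.5, slice_thickness=8.0,
                                  slice_gap=0.0, phase_times=np.array([0.0]))
        assert stack_volume(stack, 1) == pytest.approx(108.0)

    def test_empty_masks_give_zero(self):
        stack = SegmentationStack(masks=np.zeros((1, 4, 8, 8), bool), pixel_size=1.0,
                                  slice_thickness=8.0, slice_gap=0.0,
                                  phase_times=np.array([0.0]))
        assert stack_volume(stack, 1) == 0.0

    def test_volume_additive_over_disjoint_slices(self, rng):
        masks = rng.random((1, 6, 16, 16)) > 0.5
        stack = SegmentationStack(masks=masks, pixel_size=1.2, slice_thickness=6.0,
                                  slice_gap=2.0, phase_times=np.array([0.0]))
        parts = []
        for s in range(6):
            solo = np.zeros_like(masks)
            solo[0, s] = masks[0, s]
            parts.append(stack_volume(SegmentationStack(
                masks=solo, pixel_size=1.2, slice_thickness=6.0, slice_gap=2.0,
                phase_times=np.array([0.0])), 1))
        assert stack_volume(stack, 1) == pytest.approx(sum(parts), rel=1e-12)

    def test_exact_area_mode_reproduces_blurred_volume(self, small_spec, exact_stack):
        wf = make_volume_waveform(small_spec)
        vol_b = temporal_blur(wf.volume, small_spec.true_temporal_resolution_ssfp)
        for p in (1, 9, 19, 32):
            expected = vol_b(np.array([exact_stack.phase_times[p - 1]]))[0]
            assert stack_volume(exact_stack, p) == pytest.approx(expected, rel=1e-6)

    def test_basal_fraction_scales_first_slice_only(self, exact_stack):
        full = stack_volume(exact_stack, 1)
        half = stack_volume(exact_stack, 1, basal_fraction=0.5)
        basal = exact_stack.analytic_slice_areas[0, 0] * (
            exact_stack.slice_thickness + exact_stack.slice_gap) / 1000.0
        assert full - half == pytest.approx(0.5 * basal)

    def test_invalid_phase_rejected(self, exact_stack):
        with pytest.raises(InputError):
            stack_volume(exact_stack, 0)
        with pytest.raises(InputError):
            stack_volume(exact_stack, exact_stack.n_phases + 1)


class TestPhaseWindow:
    def test_odd_peak_maps_to_five_phases(self):
        assert phase_window_from_pc_peak(7, 64, 32) == [2, 3, 4, 5, 6]

    def test_even_peak_maps_to_six_phases(self):
        assert phase_window_from_pc_peak(8, 64, 32) == [2, 3, 4, 5, 6, 7]

    @pytest.mark.parametrize("peak", [1, 2, 3, 62, 63, 64])
    def test_windows_near_cycle_boundary_refused(self, peak):
        with pytest.raises(InputError):
            phase_window_from_pc_peak(peak, 64, 32)

    def test_phase_count_ratio_enforced(self):
        with pytest.raises(InputError):
            phase_window_from_pc_peak(10, 64, 30)

    @pytest.mark.parametrize("peak", range(5, 60))
    def test_window_centered_on_corresponding_phase(self, peak):
        w = phase_window_from_pc_peak(peak, 64, 32)
        n = (peak + 1) // 2
        assert len(w) == (5 if peak % 2 else 6)
        assert w[0] == n - 2 and w == list(range(w[0], w[-1] + 1))


class TestDerivativeCurve:
    def test_two_point_rate(self):
        tvc = TimeVolumeCurve(phase_times=np.array([0.0, 30.0]),
                              volumes=np.array([100.0, 110.0]),
                              phase_indices=np.array([1, 2]))
        dc = derivative_curve(tvc)
        assert dc.midpoint_times == pytest.approx([15.0])
        assert dc.rates == pytest.approx([1000.0 / 3.0])

    def test_constant_volume_gives_zero_rates(self):
        tvc = TimeVolumeCurve(phase_times=np.linspace(0, 120, 5),
                              volumes=np.full(5, 80.0), phase_indices=np.arange(1, 6))
        assert np.all(derivative_curve(tvc).rates == 0.0)

    def test_midpoint_rule_second_order_on_cubic(self):
        # central differences of a cubic are exact up to the quadratic term
        t = np.linspace(100, 300, 7)
        V = 1e-6 * t**3 - 4e-4 * t**2 + 0.1 * t + 50
        dVdt = (3e-6 * t**2 - 8e-4 * t + 0.1) * 1000  # mL/s at each t
        tvc = TimeVolumeCurve(phase_times=t, volumes=V, phase_indices=np.arange(1, 8))
        dc = derivative_curve(tvc)
        mids = (t[:-1] + t[1:]) / 2
        exact = (3e-6 * mids**2 - 8e-4 * mids + 0.1) * 1000
        h = t[1] - t[0]
        assert np.allclose(dc.rates, exact, atol=1e-6 * h**2 * 1000)

    def test_too_short_curve_rejected(self):
        with pytest.raises(InputError):
            derivative_curve(TimeVolumeCurve(phase_times=np.array([0.0]),
                                             volumes=np.array([100.0]),
                                             phase_indices=np.array([1])))


class TestFitParabola:
    def test_exact_points_interpolated(self):
        t = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        y = -((t - 5.0) ** 2) + 25.0
        fit = fit_parabola(DerivativeCurve(midpoint_times=t, rates=y))
        assert fit.vertex_time == pytest.approx(5.0)
        assert fit.vertex_rate == pytest.approx(25.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(4, 7)
            t = np.sort(rng.uniform(300, 700, n))
            y = rng.uniform(-100, 500, n)
            try:
                fit = fit_parabola(DerivativeCurve(midpoint_times=t, rates=y))
            except NoConcavePeakError:
                a, _, _ = normal_equations_quadratic(t, y)
                assert a >= 0
                continue
            a, b, c = normal_equations_quadratic(t, y)
            assert fit.a == pytest.approx(a, rel=1e-8)
            assert fit.b == pytest.approx(b, rel=1e-8)
            assert fit.c == pytest.approx(c, rel=1e-8)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_centering_is_mathematically_transparent(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        t = np.sort(rng.uniform(0, 1000, n))
        if np.min(np.diff(t)) < 1e-3:
            return
        y = -rng.uniform(0.001, 0.1) * (t - rng.uniform(200, 800)) ** 2 \
            + rng.uniform(100, 500) + rng.normal(0, 5, n)
        fit = fit_parabola(DerivativeCurve(midpoint_times=t, rates=y))
        a, b, c = normal_equations_quadratic(t, y)
        assert np.allclose([fit.a, fit.b, fit.c], [a, b, c], rtol=1e-7, atol=1e-10)

    def test_convex_data_has_no_peak(self):
        t = np.arange(5.0)
        with pytest.raises(NoConcavePeakError):
            fit_parabola(DerivativeCurve(midpoint_times=t, rates=2.0 * t + 1.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            fit_parabola(DerivativeCurve(midpoint_times=np.array([0.0, 1.0]),
                                         rates=np.array([1.0, 2.0])))


class TestPfrSsfp:
    def test_recovers_phantom_peak_within_ten_percent(self, small_spec, exact_stack):
        wf = make_volume_waveform(small_spec)
        truth = true_pfr(wf)
        pc_peak = int(round(wf.e_peak_ms / (wf.rr_ms / small_spec.n_phases_pc))) + 1
        res = pfr_ssfp(exact_stack, pc_peak)
        assert 0.0 < (truth - res.pfr) / truth < 0.10
        assert abs(res.peak_filling_time - wf.e_peak_ms) < 60.0

    def test_offset_invariance_of_pfr(self, small_spec, exact_stack):
        shifted = SegmentationStack(
            masks=exact_stack.masks, pixel_size=exact_stack.pixel_size,
            slice_thickness=exact_stack.slice_thickness, slice_gap=exact_stack.slice_gap,
            phase_times=exact_stack.phase_times,
            analytic_slice_areas=exact_stack.analytic_slice_areas
            + 625.0 / exact_stack.n_slices)  # +5 mL total at dz 8 mm
        r0 = pfr_ssfp(exact_stack, 37)
        r1 = pfr_ssfp(shifted, 37)
        assert r1.pfr == pytest.approx(r0.pfr, rel=1e-9)
        assert r1.peak_filling_time == pytest.approx(r0.peak_filling_time, rel=1e-9)

    def test_scaling_volumes_scales_pfr(self, exact_stack):
        scaled = SegmentationStack(
            masks=exact_stack.masks, pixel_size=exact_stack.pixel_size,
            slice_thickness=exact_stack.slice_thickness, slice_gap=exact_stack.slice_gap,
            phase_times=exact_stack.phase_times,
            analytic_slice_areas=exact_stack.analytic_slice_areas * 1.7)
        assert pfr_ssfp(scaled, 37).pfr == pytest.approx(
            1.7 * pfr_ssfp(exact_stack, 37).pfr, rel=1e-9)

    def test_flat_heart_has_no_concave_peak(self):
        spec = PhantomSpec(edv=120.0, esv=120.0, matrix=96)
        stack = render_ssfp_stack(spec, mode="exact")
        with pytest.raises(NoConcavePeakError):
            pfr_ssfp(stack, 37)


class TestGlobalIndices:
    def test_ef_arithmetic(self):
        areas = np.array([[100.0 * 1000 / 8 / 4] * 4, [50.0 * 1000 / 8 / 4] * 4])
        stack = SegmentationStack(masks=np.ones((2, 4, 4, 4), bool), pixel_size=1.0,
                                  slice_thickness=8.0, slice_gap=0.0,
                                  phase_times=np.array([0.0, 100.0]),
                                  analytic_slice_areas=areas)
        gi = global_indices(stack, height_cm=170.0, weight_kg=60.0)
        assert gi.edv == pytest.approx(100.0)
        assert gi.esv == pytest.approx(50.0)
        assert gi.ef == pytest.approx(50.0)

    def test_cohort_mean_volume_ratio(self, small_spec):
        # a heart with EDV 149.5 / ESV 65.1 has a volume-ratio EF of 56.5 %
        spec = small_spec.with_(edv=149.5, esv=65.1,
                                true_temporal_resolution_ssfp=0.0)
        stack = render_ssfp_stack(spec, mode="exact")
        gi = global_indices(stack, height_cm=169.5, weight_kg=60.2)
        assert gi.ef == pytest.approx(100 * (149.5 - 65.1) / 149.5, abs=0.1)

    def test_du_bois_formula(self):
        assert du_bois_bsa(169.5, 60.2) == pytest.approx(1.69, abs=0.01)
        # indexing the cohort-mean volumes by the cohort-mean BSA lands near
        # the reported per-BSA means (within a few percent)
        bsa = du_bois_bsa(169.5, 60.2)
        assert 149.5 / bsa == pytest.approx(88.8, rel=0.02)
        assert 65.1 / bsa == pytest.approx(38.5, rel=0.02)

    def test_rejects_bad_anthropometrics(self):
        with pytest.raises(InputError):
            du_bois_bsa(0.0, 60.0)
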