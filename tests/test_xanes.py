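import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf

from coccoquant import phantom, xanes


def erf_edge_spectrum(e0=4048.0, step=2.4, width=2.0, baseline=(0.2, 0.001)):
    """Raw test spectrum: erf edge (whose tail settles fast, so the quadratic
    post-edge extrapolation is exact) plus a linear baseline."""
    e = np.arange(4000.0, 4141.0, 0.5)
    mu = step * 0.5 * (1 + erf((e - e0) / width)) + baseline[0] + baseline[1] * (e - 4000.0)
    return xanes.Spectrum(e, mu)


def three_peak_spectrum(e0=4048.0, shift=0.0):
    """Two pre-edge bumps + arctan main edge: the third derivative peak sits
    at the edge center."""
    e = np.arange(4000.0, 4141.0, 0.5) + shift
    mu = (
        0.18 * np.exp(-0.5 * ((e - (4035.0 + shift)) / 1.2) ** 2)
        + 0.22 * np.exp(-0.5 * ((e - (4041.0 + shift)) / 1.2) ** 2)
        + 1.5 * (0.5 + np.arctan((e - (e0 + shift)) / 1.0) / np.pi)
    )
    return xanes.Spectrum(e, mu)


class TestAverageScans:
    def test_single_scan_unchanged(self):
        s = erf_edge_spectrum()
        avg = xanes.average_scans([s])
        np.testing.assert_allclose(avg.intensity, s.intensity)
        assert avg.state == "averaged"

    def test_opposite_offsets_cancel(self):
        s = erf_edge_spectrum()
        up = xanes.Spectrum(s.energies_eV, s.intensity + 0.3)
        down = xanes.Spectrum(s.energies_eV, s.intensity - 0.3)
        avg = xanes.average_scans([up, down])
        np.testing.assert_allclose(avg.intensity, s.intensity, atol=1e-12)

    def test_residual_shrinks_like_sqrt_n(self):
        s = erf_edge_spectrum()
        rng = np.random.default_rng(0)

        def resid_sd(n):
            scans = [
                xanes.Spectrum(s.energies_eV, s.intensity + rng.normal(0, 0.05, s.intensity.shape))
                for _ in range(n)
            ]
            return (xanes.average_scans(scans).intensity - s.intensity).std()

        r1 = np.mean([resid_sd(1) for _ in range(30)])
        r16 = np.mean([resid_sd(16) for _ in range(30)])
        assert r1 / r16 == pytest.approx(4.0, rel=0.3)

    def test_incompatible_grids_rejected_without_interpolation(self):
        a = erf_edge_spectrum()
        b = xanes.Spectrum(a.energies_eV + 0.25, a.intensity)
        with pytest.raises(xanes.SpectrumError):
            xanes.average_scans([a, b])
        avg = xanes.average_scans([a, b], interpolate=True)
        assert avg.energies_eV.shape == a.energies_eV.shape


class TestFindEdge:
    def test_third_derivative_peak_is_main_edge(self):
        e0 = xanes.find_edge(three_peak_spectrum())
        assert e0 == pytest.approx(4048.0, abs=0.5)

    def test_pure_edge_falls_back_with_warning(self):
        e = np.arange(4000.0, 4141.0, 0.5)
        s = xanes.Spectrum(e, 0.5 + np.arctan((e - 4048.0) / 1.0) / np.pi)
        with pytest.warns(UserWarning, match="falling back"):
            e0 = xanes.find_edge(s)
        assert e0 == pytest.approx(4048.0, abs=0.5)

    def test_energy_shift_equivariance(self):
        e0 = xanes.find_edge(three_peak_spectrum())
        e0_shifted = xanes.find_edge(three_peak_spectrum(shift=2.0))
        assert e0_shifted - e0 == pytest.approx(2.0, abs=0.25)


class TestNormalize:
    def test_post_edge_level_is_unity(self):
        n = xanes.normalize(erf_edge_spectrum(), 4048.0)
        e = n.energies_eV
        post = n.intensity[(e >= 4048 + 26) & (e <= 4048 + 90)]
        assert post.mean() == pytest.approx(1.0, abs=1e-6)
        assert n.state == "normalized"

    def test_idempotent_on_normalized_step(self):
        n = xanes.normalize(erf_edge_spectrum(), 4048.0)
        again = xanes.normalize(n, 4048.0)
        np.testing.assert_allclose(again.intensity, n.intensity, atol=1e-9)

    def test_invariant_to_linear_baseline(self):
        s = erf_edge_spectrum(baseline=(0.0, 0.0))
        with_base = xanes.Spectrum(
            s.energies_eV, s.intensity + 1.7 + 0.004 * (s.energies_eV - 4000.0)
        )
        n1 = xanes.normalize(s, 4048.0)
        n2 = xanes.normalize(with_base, 4048.0)
        np.testing.assert_allclose(n1.intensity, n2.intensity, atol=1e-9)

    def test_invariant_to_edge_step_scale(self):
        s = erf_edge_spectrum()
        doubled = xanes.Spectrum(s.energies_eV, 2.0 * s.intensity)
        n1 = xanes.normalize(s, 4048.0)
        n2 = xanes.normalize(doubled, 4048.0)
        np.testing.assert_allclose(n1.intensity, n2.intensity, atol=1e-9)

    def test_insufficient_span_names_window(self):
        e = np.arange(4040.0, 4100.0, 0.5)
        s = xanes.Spectrum(e, 0.5 * (1 + erf((e - 4048.0) / 2.0)))
        with pytest.raises(xanes.SpectrumError, match="pre-edge"):
            xanes.normalize(s, 4048.0)


def simplex_grid_oracle(target, refs, resolution=0.01):
    """Brute-force LCF oracle: exhaustive search over the 2-simplex."""
    y = target.intensity
    A = np.column_stack([r.intensity for r in refs])
    best, best_res = None, np.inf
    steps = int(round(1.0 / resolution))
    for i in range(steps + 1):
        for j in range(steps + 1 - i):
            w = np.array([i, j, steps - i - j]) / steps
            res = np.sum((y - A @ w) ** 2)
            if res < best_res:
                best, best_res = w, res
    return best


class TestLCF:
    def test_pure_reference_gets_weight_one(self):
        target, refs = phantom.synth_kedge_mixture((0.0, 1.0, 0.0))
        res = xanes.lcf(target, refs)
        assert res.weights["acc"] == pytest.approx(1.0, abs=1e-9)
        assert res.residual == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery_noise_free(self):
        target, refs = phantom.synth_kedge_mixture((0.5, 0.3, 0.2))
        res = xanes.lcf(target, refs)
        assert res.weights["calcite"] == pytest.approx(0.5, abs=1e-6)
        assert res.weights["acc"] == pytest.approx(0.3, abs=1e-6)
        assert res.weights["free_ion"] == pytest.approx(0.2, abs=1e-6)

    def test_noisy_fit_matches_grid_search_oracle(self):
        target, refs = phantom.synth_kedge_mixture((0.5, 0.3, 0.2), noise_sd=0.01, seed=11)
        res = xanes.lcf(target, refs, window_eV=(4000.0, 4140.0))
        oracle = simplex_grid_oracle(target, refs)
        for w, o in zip(res.weights.values(), oracle):
            assert w == pytest.approx(o, abs=0.011)  # grid resolution

    def test_identical_references_warn(self):
        target, refs = phantom.synth_kedge_mixture((1.0, 0.0, 0.0))
        with pytest.warns(UserWarning, match="ill-conditioned"):
            res = xanes.lcf(target, [refs[0], refs[0]])
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-6)

    def test_unnormalized_input_rejected(self):
        target, refs = phantom.synth_kedge_mixture((1.0, 0.0, 0.0))
        raw = xanes.Spectrum(target.energies_eV, target.intensity, state="raw")
        with pytest.raises(xanes.SpectrumError, match="not normalized"):
            xanes.lcf(raw, refs)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.tuples(st.floats(0, 1), st.floats(0, 1)).filter(lambda t: t[0] + t[1] <= 1.0),
           st.integers(0, 1000))
    def test_simplex_constraint_always_holds(self, w2, seed):
        weights = (w2[0], w2[1], 1.0 - w2[0] - w2[1])
        target, refs = phantom.synth_kedge_mixture(weights, noise_sd=0.02, seed=seed)
        res = xanes.lcf(target, refs)
        assert all(w >= 0 for w in res.weights.values())
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-6)

    def test_weight_bias_vanishes_with_noise(self):
        biases = []
        for noise in (0.05, 0.02, 0.005):
            errs = []
            for seed in range(15):
                target, refs = phantom.synth_kedge_mixture((0.5, 0.3, 0.2), noise, seed)
                res = xanes.lcf(target, refs)
                errs.append(abs(res.weights["calcite"] - 0.5))
            biases.append(np.mean(errs))
        assert biases[0] > biases[2]
        assert biases[2] < 0.01


class TestCompareReferenceSets:
    def test_generating_set_ranks_first(self):
        target, refs = phantom.synth_kedge_mixture((0.4, 0.35, 0.25), noise_sd=0.005, seed=1)
        wrong = [refs[0], refs[2]]  # missing the ACC component
        ranked = xanes.compare_reference_sets(target, [wrong, refs])
        assert len(ranked[0][0]) == 3  # full set wins

    def test_tie_broken_toward_fewer_references(self):
        target, refs = phantom.synth_kedge_mixture((0.6, 0.0, 0.4))  # no ACC content
        nested = [refs, [refs[0], refs[2]]]
        ranked = xanes.compare_reference_sets(target, nested, tie_tol=1e-6)
        assert len(ranked[0][0]) == 2

    def test_acc_bearing_set_beats_acc_free_on_acc_target(self):
        target, refs = phantom.synth_kedge_mixture((0.4, 0.3, 0.3), noise_sd=0.01, seed=5)
        acc_free = [refs[0], refs[2]]
        ranked = xanes.compare_reference_sets(target, [acc_free, refs])
        labels = {r.label for r in ranked[0][0]}
        assert "acc" in labels
        assert ranked[0][1].residual < ranked[1][1].residual


class TestScanDifference:
    def test_identical_scans_differ_by_zero(self):
        s = erf_edge_spectrum()
        assert xanes.scan_difference(s, s) == 0.0

    def test_radiation_damage_detected(self):
        s = erf_edge_spectrum()
        damaged = xanes.Spectrum(s.energies_eV, s.intensity * 0.95)
        assert xanes.scan_difference(s, damaged) > 0.05
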