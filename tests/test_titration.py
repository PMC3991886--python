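import numpy as np
import pytest

from ssbkit.titration import (
    BindingFit,
    TitrationCurve,
    TitrationNotSaturatedError,
    bound_fraction,
    compare_salt_modes,
    fit_site_size,
    model_fluorescence,
    simulate_titration,
)

# Study geometry: 1.5 nmol tetramer titrated with a 76-nt oligonucleotide.
P, L = 1.5, 76


def tight_curve(n=32.0, q=0.93, grid=None):
    if grid is None:
        grid = np.linspace(0.0, 1.2, 25)
    return simulate_titration(n, q, None, P, L, grid)


class TestForwardModel:
    def test_tight_binding_breakpoint_closed_form(self):
        # K -> inf: linear decline to the plateau, breakpoint at n*P/L
        n, q = 32.0, 0.93
        d_break = n * P / L  # 0.6316 nmol
        curve = tight_curve(n, q)
        d = np.array(curve.added_oligo)
        f = np.array(curve.relative_fluorescence)
        expected = np.maximum(1.0 - q * d / d_break, 1.0 - q)
        assert f == pytest.approx(expected)
        assert f[-1] == pytest.approx(0.07)

    def test_zero_quench_is_flat(self):
        curve = tight_curve(q=0.0)
        assert np.array(curve.relative_fluorescence) == pytest.approx(1.0)

    def test_finite_k_lies_above_tight_limit_before_breakpoint(self):
        grid = np.linspace(0.0, 1.2, 20)
        tight = model_fluorescence(grid, 32.0, 0.93, None, P, L)
        loose = model_fluorescence(grid, 32.0, 0.93, 5.0, P, L)
        pre = grid[1:] < 32.0 * P / L
        assert np.all(loose[1:][pre] > tight[1:][pre])

    @pytest.mark.parametrize("k", [0.1, 10.0, 1e4, None])
    def test_bound_fraction_and_signal_stay_in_unit_interval(self, k):
        grid = np.linspace(0.0, 5.0, 40)
        theta = bound_fraction(grid, 32.0, k, P, L)
        assert np.all((theta >= 0) & (theta <= 1))
        f = model_fluorescence(grid, 32.0, 0.93, k, P, L)
        assert np.all((f >= 0) & (f <= 1))

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            simulate_titration(32, 0.9, None, P, L, np.array([0.0, 0.2, 0.1]))


class TestFit:
    def test_noiseless_tight_curve_inverts_exactly(self):
        fit = fit_site_size(tight_curve(32.0, 0.93))
        assert fit.site_size_n == pytest.approx(32.0, abs=1e-6)
        assert fit.quench_q == pytest.approx(0.93, abs=1e-6)

    def test_equilibrium_mode_converges_to_breakpoint_at_large_k(self):
        curve = simulate_titration(32.0, 0.93, 1e9, P, L, np.linspace(0, 1.2, 25))
        bp = fit_site_size(curve, mode="breakpoint")
        eq = fit_site_size(curve, mode="equilibrium")
        assert eq.site_size_n == pytest.approx(bp.site_size_n, abs=0.1)
        assert eq.k_obs > 1e6

    def test_truncated_titration_raises(self):
        grid = np.linspace(0.0, 0.5, 10)  # stops before the 0.63 breakpoint
        curve = simulate_titration(32.0, 0.93, None, P, L, grid)
        with pytest.raises(TitrationNotSaturatedError, match="not saturated"):
            fit_site_size(curve)

    def test_too_few_points_rejected(self):
        curve = TitrationCurve(
            protein_total=P, oligo_length=L,
            added_oligo=(0.0, 0.3, 0.7, 1.0),
            relative_fluorescence=(1.0, 0.6, 0.1, 0.1),
        )
        with pytest.raises(ValueError, match="6"):
            fit_site_size(curve)

    @pytest.mark.parametrize("n_true,q_true", [(30, 0.93), (45, 0.81), (65, 0.53)])
    def test_recovery_from_noisy_curves(self, n_true, q_true):
        grid = np.linspace(0.0, 2.4 * n_true * P / L, 25)
        hits = 0
        for seed in range(10):
            curve = simulate_titration(
                n_true, q_true, None, P, L, grid, noise_sd=0.02, seed=seed
            )
            fit = fit_site_size(curve)
            if abs(fit.site_size_n - n_true) <= 2 and abs(fit.quench_q - q_true) <= 0.03:
                hits += 1
        assert hits >= 9


class TestSaltModes:
    def make_fit(self, n, salt, ci=2.0):
        return BindingFit(site_size_n=n, quench_q=0.9, k_obs=None, ci_n=ci,
                          mode="breakpoint", salt_mM=salt)

    def test_consistent_fits_are_salt_independent(self):
        fits = [self.make_fit(32, 2), self.make_fit(32, 100), self.make_fit(33, 300)]
        assert compare_salt_modes(fits).verdict == "salt-independent"

    def test_low_high_salt_transition_detected(self):
        fits = [self.make_fit(31, 2), self.make_fit(45, 300)]
        verdict = compare_salt_modes(fits)
        assert verdict.verdict == "mode transition"
        assert (verdict.low_salt_n, verdict.high_salt_n) == (31, 45)

    def test_identical_fits_are_salt_independent(self):
        fits = [self.make_fit(32, 2), self.make_fit(32, 300)]
        assert compare_salt_modes(fits).verdict == "salt-independent"

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError, match="2"):
            compare_salt_modes([self.make_fit(32, 2)])
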