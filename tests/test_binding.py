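"""Exact equilibrium models and FP fitting."""

import numpy as np
import pytest

from sh2screen import (
    TitrationDataset,
    TitrationTruth,
    ValidationError,
    bound_fraction_direct,
    fit_competition,
    fit_direct,
    fold_change,
    free_species_competition,
    simulate_titration,
)
from sh2screen.binding import BindingFit

from conftest import mass_action_oracle


class TestBoundFractionDirect:
    def test_trace_probe_at_kd_gives_half_occupancy(self):
        assert bound_fraction_direct(1.0, 1e-9, 1.0) == pytest.approx(
            0.5, rel=1e-6
        )

    def test_stoichiometric_limit_saturates(self):
        assert bound_fraction_direct(10.0, 1.0, 1e-9) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_symmetric_case_satisfies_equilibrium_equation(self):
        # R = L = Kd = 1: bound = (3 - sqrt(5))/2
        frac = bound_fraction_direct(1.0, 1.0, 1.0)
        bound = frac * 1.0
        assert frac == pytest.approx((3 - np.sqrt(5)) / 2, abs=1e-12)
        residual = (1.0 - bound) * (1.0 - bound) / bound - 1.0
        assert abs(residual) < 1e-12

    def test_monotone_decreasing_in_kd(self):
        kds = np.logspace(-3, 3, 25)
        fracs = bound_fraction_direct(1.0, 0.1, kds)
        assert np.all(np.diff(fracs) < 0)


class TestFreeSpeciesCompetition:
    def test_zero_competitor_reduces_to_direct(self):
        R, L, Kd = 2.0, 0.5, 1.0
        _, probe_bound, comp_bound = free_species_competition(
            R, L, 0.0, Kd, 5.0
        )
        direct = bound_fraction_direct(R, L, Kd) * L
        assert comp_bound == 0.0
        assert probe_bound == pytest.approx(direct, abs=1e-9)

    def test_inert_competitor_reduces_to_direct(self):
        R, L, Kd = 2.0, 0.5, 1.0
        _, probe_bound, _ = free_species_competition(R, L, 10.0, Kd, 1e12)
        direct = bound_fraction_direct(R, L, Kd) * L
        assert probe_bound == pytest.approx(direct, abs=1e-9)

    def test_monotone_decreasing_in_competitor(self):
        comp = np.logspace(-2, 3, 30)
        _, probe_bound, _ = free_species_competition(
            1.0, 0.05, comp, 1.0, 2.0
        )
        assert np.all(np.diff(probe_bound) < 0)

    def test_agrees_with_mass_action_oracle(self):
        rng = np.random.default_rng(2)
        n = 500
        R, L, I = (10.0 ** rng.uniform(-3, 3, n) for _ in range(3))
        Kd, Ki = (10.0 ** rng.uniform(-3, 3, n) for _ in range(2))
        Rf, pb, cb = free_species_competition(R, L, I, Kd, Ki)
        Rf_oracle = mass_action_oracle(R, L, I, Kd, Ki)
        scale = np.maximum(R, 1.0)
        assert np.all(np.abs(Rf - Rf_oracle) <= 1e-9 * scale)
        # mass balance for all three species
        assert np.all(np.abs(Rf + pb + cb - R)
                      <= 1e-9 * np.maximum(R, 1.0))
        Lf = L - pb
        assert np.all(np.abs(Lf + pb - L) <= 1e-9 * np.maximum(L, 1.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            free_species_competition(-1.0, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValidationError):
            free_species_competition(1.0, 1.0, 1.0, 0.0, 1.0)


def _direct_dataset(kd=1.0, noise_sd=0.0, seed=0):
    truth = TitrationTruth("direct", {
        "kd": kd, "probe_total": 0.01,
        "signal_free": 60.0, "signal_bound": 210.0,
    }, noise_sd=noise_sd, seed=seed)
    conc = np.logspace(-2.5, 2.5, 12)
    return simulate_titration(truth, conc)


def _competition_dataset(ki=5.0, noise_sd=0.0, seed=0):
    truth = TitrationTruth("competition", {
        "ki": ki, "probe_kd": 0.5, "receptor_total": 1.0,
        "probe_total": 0.01, "signal_free": 60.0, "signal_bound": 210.0,
    }, noise_sd=noise_sd, seed=seed)
    conc = np.concatenate([[0.0], np.logspace(-2, 3.5, 11)])
    return simulate_titration(truth, conc)


class TestFitDirect:
    def test_noiseless_recovery_to_1e6_relative(self):
        fit = fit_direct(_direct_dataset(kd=1.0))
        assert fit.converged
        assert fit.constant == pytest.approx(1.0, rel=1e-6)
        assert fit.signal_free == pytest.approx(60.0, rel=1e-6)
        assert fit.signal_bound == pytest.approx(210.0, rel=1e-6)

    def test_flat_signal_flags_nonconvergence(self):
        conc = np.logspace(-2, 2, 8)
        ds = TitrationDataset("direct", conc, np.full(8, 100.0),
                              probe_total=0.01)
        fit = fit_direct(ds)
        assert not fit.converged

    def test_noisy_estimate_close_to_truth(self):
        fit = fit_direct(_direct_dataset(kd=1.0, noise_sd=2.0, seed=3))
        assert fit.converged
        assert fit.constant == pytest.approx(1.0, rel=0.25)
        assert fit.se_constant > 0


class TestFitCompetition:
    def test_noiseless_recovery_to_1e6_relative(self):
        fit = fit_competition(_competition_dataset(ki=5.0))
        assert fit.converged
        assert fit.constant == pytest.approx(5.0, rel=1e-6)

    def test_fitted_endpoints_bracket_saturating_data(self):
        ds = _competition_dataset(ki=5.0, noise_sd=1.0, seed=1)
        fit = fit_competition(ds)
        lo = min(fit.signal_free, fit.signal_bound)
        hi = max(fit.signal_free, fit.signal_bound)
        assert lo <= ds.signal.min() + 3.0
        assert hi >= ds.signal.max() - 3.0

    def test_missing_probe_kd_rejected(self):
        with pytest.raises(ValidationError, match="probe_kd"):
            TitrationDataset("competition", [1.0], [1.0], probe_total=0.01,
                             receptor_total=1.0)

    def test_seeded_noisy_median_relative_error_below_10pct(self):
        errors = []
        for seed in range(20):
            ds = _competition_dataset(ki=5.0, noise_sd=1.5, seed=seed)
            fit = fit_competition(ds)
            errors.append(abs(fit.constant - 5.0) / 5.0)
        assert np.median(errors) < 0.10


class TestFoldChange:
    def _fit(self, kd):
        return BindingFit(kd, 60.0, 210.0, 0.1 * kd, 1.0, 1.0, 0.0, True, 12)

    def test_single_fit_ratio(self):
        fc = fold_change([self._fit(10.0)], [self._fit(2.0)])
        assert fc.fold == pytest.approx(5.0)
        assert fc.p_value is None

    def test_identical_replicates_fold_one_p_near_one(self):
        fits = [self._fit(k) for k in (1.0, 1.2, 0.9)]
        fc = fold_change(fits, list(fits))
        assert fc.fold == pytest.approx(1.0)
        assert fc.p_value > 0.95
        assert fc.ci_low <= 1.0 <= fc.ci_high

    def test_geometric_mean_ratio_with_replicates(self):
        ref = [self._fit(k) for k in (8.0, 12.0, 10.0)]
        var = [self._fit(k) for k in (2.0, 2.5, 1.6)]
        gm = lambda xs: np.exp(np.mean(np.log(xs)))
        fc = fold_change(ref, var)
        assert fc.fold == pytest.approx(
            gm([8, 12, 10]) / gm([2, 2.5, 1.6])
        )
        assert fc.p_value < 0.01
        assert fc.ci_low < fc.fold < fc.ci_high
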