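"""State assignment, dwell extraction and exponential rate estimation."""

import numpy as np
import pytest

from auroraloop import dwell as dw
from auroraloop.histogram import TwoLogNormalFit, fit_two_lognormals, pool_histogram
from auroraloop.simulate import IntensityTrace, TwoStateRates


def _fit(mode_low=1.0, mode_high=10.0, shape_low=0.15, shape_high=0.15, area_low=0.5):
    return TwoLogNormalFit(
        mode_low=mode_low, shape_low=shape_low, area_low=area_low,
        mode_high=mode_high, shape_high=shape_high, area_high=1 - area_low,
        area_low_err=0.01, area_high_err=0.01, converged=True,
        residual_norm=0.0, redchi=1.0, n_frames_total=1000,
    )


def _trace(values, dt=0.08):
    return IntensityTrace(molecule_id=0, intensities=np.asarray(values, float), frame_interval=dt)


def _dwell_set(durations, censored=None, dt=0.08, state="low"):
    durations = np.asarray(durations, float)
    if censored is None:
        censored = np.zeros(len(durations), bool)
    return dw.DwellTimeSet(durations=durations, censored=np.asarray(censored, bool),
                           state=state, frame_interval=dt)


class TestThreshold:
    def test_symmetric_components_cross_near_geometric_midpoint(self):
        # equal shapes s: the density crossing of two mode-parameterized
        # log-normals is the geometric mean of the *medians*, i.e.
        # sqrt(m_low * m_high) * exp(s^2) — within a few percent of sqrt(10)
        thr = dw.threshold_from_fit(_fit())
        assert thr == pytest.approx(np.sqrt(10.0) * np.exp(0.15**2), rel=1e-6)
        assert thr == pytest.approx(np.sqrt(10.0), rel=0.03)

    def test_no_crossing_falls_back_to_geometric_mean(self):
        # extreme shape mismatch: the narrow low component still dominates at the
        # high mode, so no crossing exists between the modes
        fit = _fit(mode_low=1.0, mode_high=1.3, shape_low=0.4, shape_high=1.2, area_low=0.95)
        with pytest.warns(UserWarning, match="geometric mean"):
            thr = dw.threshold_from_fit(fit)
        assert thr == pytest.approx(np.sqrt(1.3), rel=1e-6)

    def test_degenerate_fit_rejected(self):
        fit = _fit(area_low=0.005)
        with pytest.raises(ValueError, match="degenerate"):
            dw.threshold_from_fit(fit)

    def test_misclassification_below_2pct_for_separated_peaks(self, well_separated_ensemble):
        """Framewise accuracy against generator ground truth at 10:1 contrast."""
        fit = fit_two_lognormals(pool_histogram(well_separated_ensemble.traces))
        thr = dw.threshold_from_fit(fit)
        err = n = 0
        for tr in well_separated_ensemble.traces:
            truth = tr.true_inactive_fraction
            pure = (truth < 0.01) | (truth > 0.99)  # judge only transition-free frames
            want_low = truth[pure] > 0.5
            got_low = ~dw.assign_states(tr, thr).labels[pure]
            err += int((want_low != got_low).sum())
            n += int(pure.sum())
        assert err / n < 0.02


class TestAssignExtract:
    def test_threshold_splits_levels(self):
        path = dw.assign_states(_trace([1, 1, 9, 9]), threshold=3.16)
        assert list(path.state_labels()) == ["low", "low", "high", "high"]

    def test_all_above_threshold_warns_and_is_all_high(self):
        with pytest.warns(UserWarning, match="outside"):
            path = dw.assign_states(_trace([5, 6, 7]), threshold=1.0)
        assert path.labels.all()

    def test_interior_run_is_one_complete_dwell(self):
        path = dw.StatePath(labels=np.array([True, False, False, True]), threshold=3.0,
                            frame_interval=0.08)
        ds = dw.extract_dwells(path, "low")
        assert ds.n_complete == 1
        assert ds.complete[0] == pytest.approx(0.16)

    def test_full_trace_run_is_censored(self):
        path = dw.StatePath(labels=np.zeros(4, bool), threshold=3.0, frame_interval=0.08)
        ds = dw.extract_dwells(path, "low")
        assert len(ds.durations) == 1
        assert ds.censored.all()
        assert ds.n_complete == 0

    def test_boundary_runs_censored_interior_not(self):
        labels = np.array([False, True, True, False, True, False])  # low at 0, 3, 5
        ds = dw.extract_dwells(dw.StatePath(labels, 3.0, 0.08), "low")
        assert list(ds.censored) == [True, False, True]

    def test_zero_noise_assignment_matches_truth_on_pure_frames(self):
        from auroraloop.simulate import (
            EmissionModel, SimulationConfig, integrate_to_frames, sample_state_path,
        )

        cfg = SimulationConfig(
            rates=TwoStateRates(2.1, 2.4),
            emission=EmissionModel(shape_high=0.0, shape_low=0.0),
            n_molecules=1, seed=0,
        )
        path = sample_state_path(cfg.rates, cfg.duration, rng=8)
        tr = integrate_to_frames(path, cfg, rng=9)
        got_low = ~dw.assign_states(tr, np.sqrt(3.0)).labels
        pure = (tr.true_inactive_fraction < 1e-9) | (tr.true_inactive_fraction > 1 - 1e-9)
        assert np.array_equal(got_low[pure], tr.true_inactive_fraction[pure] > 0.5)


class TestRateFit:
    def test_mle_exact_on_exponential_quantiles(self):
        # deterministic sample with sample mean forced to 1/2.1 via inverse CDF
        n = 200
        q = (np.arange(n) + 0.5) / n
        t = -np.log(1 - q) / 2.1
        t *= (1 / 2.1) / t.mean()  # pin the mean exactly
        est = dw.fit_single_exponential(_dwell_set(t), method="mle")
        assert est.k == pytest.approx(2.1, rel=1e-12)
        assert est.stderr == pytest.approx(2.1 / np.sqrt(n))

    def test_equal_durations_give_reciprocal_mean(self):
        est = dw.fit_single_exponential(_dwell_set(np.full(20, 0.4)), method="mle")
        assert est.k == pytest.approx(2.5)

    @pytest.mark.parametrize("method", ["mle", "binned_lsq"])
    def test_simulated_dwells_recovered_within_10pct(self, method, rng):
        t = rng.exponential(1 / 2.1, size=1000)
        est = dw.fit_single_exponential(_dwell_set(t), method=method)
        assert est.k == pytest.approx(2.1, rel=0.10)

    def test_methods_agree_within_joint_errors_on_large_samples(self, rng):
        t = rng.exponential(1 / 2.1, size=5000)
        ds = _dwell_set(t)
        a = dw.fit_single_exponential(ds, method="mle")
        b = dw.fit_single_exponential(ds, method="binned_lsq")
        joint = np.hypot(a.stderr, b.stderr)
        assert abs(a.k - b.k) < 2 * joint

    def test_censored_dwells_excluded_from_fit(self, rng):
        t = rng.exponential(1 / 2.1, size=500)
        censored = np.zeros(500, bool)
        censored[:100] = True
        ds = _dwell_set(np.concatenate([np.full(100, 50.0), t[100:]]), censored)
        est = dw.fit_single_exponential(ds, method="mle")
        assert est.n_dwells == 400
        assert est.k == pytest.approx(2.1, rel=0.15)

    def test_too_few_dwells_rejected_with_count(self):
        with pytest.raises(ValueError, match="got 5"):
            dw.fit_single_exponential(_dwell_set(np.full(5, 0.2)))


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "k_active,keq,expected_1dp",
        [
            (2.1, 52 / 46, 2.4),   # unphosphorylated
            (2.3, 23 / 77, 0.7),   # phosphorylated
        ],
    )
    def test_detailed_balance_k_inactive(self, k_active, keq, expected_1dp):
        est = dw.derived_k_inactive(k_active, keq)
        assert round(est.k, 1) == expected_1dp

    def test_keq_of_one_returns_k_active(self):
        assert dw.derived_k_inactive(1.7, 1.0).k == pytest.approx(1.7)

    def test_error_propagation_quadrature(self):
        est = dw.derived_k_inactive(2.0, 1.0, keq_err=0.1, k_active_err=0.2)
        assert est.stderr == pytest.approx(2.0 * np.hypot(0.1, 0.1 / 1.0 * 1.0))

    @pytest.mark.parametrize(
        "rates,expected",
        [
            (TwoStateRates(2.1, 2.37), (0.5, 0.4)),   # unphosphorylated residence times
            (TwoStateRates(2.3, 0.687), (0.4, 1.5)),  # phosphorylated
        ],
    )
    def test_residence_times_round_to_reported_values(self, rates, expected):
        tau_inactive, tau_active = dw.residence_times(rates)
        assert (round(tau_inactive, 1), round(tau_active, 1)) == expected

    def test_zero_k_inactive_has_no_active_residence_time(self):
        with pytest.raises(ValueError):
            dw.residence_times(TwoStateRates(2.1, 0.0))


class TestEndToEndKinetics:
    def test_k_active_recovery_and_detailed_balance(self, ensemble_unphos):
        """Threshold -> dwells -> exponential fit recovers k_active; histogram K_eq
        agrees with the true rate ratio (detailed-balance consistency)."""
        from auroraloop.histogram import fit_two_lognormals_mle, pool_intensities

        fit = fit_two_lognormals_mle(pool_intensities(ensemble_unphos.traces))
        thr = dw.threshold_from_fit(fit)
        pooled = None
        for tr in ensemble_unphos.traces:
            ds = dw.extract_dwells(dw.assign_states(tr, thr), "low")
            pooled = ds if pooled is None else pooled.extend(ds)
        est = dw.fit_single_exponential(pooled)
        assert est.k == pytest.approx(2.1, rel=0.15)
        # mean complete low dwell near 1/k_active (within censoring/merging bias)
        assert pooled.complete.mean() == pytest.approx(1 / 2.1, rel=0.20)
        # K_eq from fitted areas vs true k_inactive/k_active = 2.4/2.1
        keq_hist = fit.area_low / fit.area_high
        assert keq_hist == pytest.approx(2.4 / 2.1, rel=0.12)
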