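"""Conformational-selection binding model and the K_d,overall surface."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from auroraloop.binding import (
    contour_gap_distances,
    equidistant_line,
    kd_overall,
    kd_overall_mass_balance,
    kd_surface,
    ligand_discrimination,
    log_axis,
    log_sensitivities,
    plateau_mask,
    required_discrimination,
)

KEQ_PHOS = 23 / 77
KEQ_UNPHOS = 52 / 46
KEQ_PHOS_TPX2 = 14 / 86

pos = st.floats(min_value=1.0, max_value=1e4)
keq_st = st.floats(min_value=0.05, max_value=20.0)


class TestDiscrimination:
    def test_saturating_ligand_discrimination_from_equilibrium_shift(self):
        res = ligand_discrimination(KEQ_PHOS, 99.0)
        assert res.discrimination == pytest.approx(0.003017, abs=1e-5)
        assert res.display_fold == 331

    def test_non_discriminating_ligand(self):
        res = ligand_discrimination(0.5, 0.5)
        assert res.discrimination == 1.0
        assert res.fold_preference == 1.0

    def test_partial_discrimination_from_measured_shift(self):
        # CD532 on the phosphorylated enzyme: K_eq 23/77 -> 64/36
        res = ligand_discrimination(KEQ_PHOS, 64 / 36)
        assert res.discrimination == pytest.approx(0.168, abs=0.001)
        assert res.display_fold == 6

    @given(keq_st, keq_st)
    def test_fold_preference_is_reciprocal(self, a, b):
        res = ligand_discrimination(a, b)
        assert res.discrimination * res.fold_preference == pytest.approx(1.0)


# required discrimination over starting state x target inactive population
# (discrimination display, fold display)
REQUIRED_TABLE = {
    ("phos", 0.99): (0.003, 331), ("phos", 0.95): (0.016, 64), ("phos", 0.90): (0.033, 30),
    ("unphos", 0.99): (0.011, 88), ("unphos", 0.95): (0.059, 17), ("unphos", 0.90): (0.125, 8),
    ("phos_tpx2", 0.99): (0.002, 608), ("phos_tpx2", 0.95): (0.009, 117),
    ("phos_tpx2", 0.90): (0.018, 55),
}
KEQ_START = {"phos": KEQ_PHOS, "unphos": KEQ_UNPHOS, "phos_tpx2": KEQ_PHOS_TPX2}


class TestRequiredDiscrimination:
    @pytest.mark.parametrize("cond,target", sorted(REQUIRED_TABLE), ids=str)
    def test_reproduces_reported_table(self, cond, target):
        expected_disc, expected_fold = REQUIRED_TABLE[(cond, target)]
        res = required_discrimination(KEQ_START[cond], target)
        assert res.display_fold == expected_fold
        assert res.display_discrimination == expected_disc

    def test_already_at_target_needs_no_discrimination(self):
        keq = 0.75
        res = required_discrimination(keq, keq / (1 + keq))
        assert res.fold_preference == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_endpoint_targets_rejected(self, bad):
        with pytest.raises(ValueError):
            required_discrimination(1.0, bad)

    def test_inverted_tpx2_convention(self):
        # the published unphosphorylated+TPX2 row matches only the inverse
        # of the measured 46/56 equilibrium constant
        res = required_discrimination(56 / 46, 0.99)
        assert res.display_fold == 81
        res_direct = required_discrimination(46 / 56, 0.99)
        assert res_direct.display_fold == 121  # inconsistent with the printed 81


class TestKdOverall:
    def test_indistinguishable_conformers(self):
        for keq in (0.01, 1.0, 50.0):
            assert kd_overall(120.0, 120.0, keq) == pytest.approx(120.0)

    def test_known_value_phosphorylated(self):
        assert kd_overall(200.0, 50.0, KEQ_PHOS) == pytest.approx(118.34, abs=0.01)

    def test_single_conformer_limits(self):
        assert kd_overall(200.0, 50.0, 0.0) == pytest.approx(200.0)
        assert kd_overall(200.0, 50.0, 1e12) == pytest.approx(50.0, rel=1e-6)

    @given(pos, pos, keq_st)
    def test_bounded_by_conformer_constants(self, ka, ki, keq):
        v = kd_overall(ka, ki, keq)
        assert min(ka, ki) - 1e-9 <= v <= max(ka, ki) + 1e-9

    @given(pos, pos, keq_st)
    def test_matches_mass_balance_oracle(self, ka, ki, keq):
        assert kd_overall(ka, ki, keq) == pytest.approx(
            kd_overall_mass_balance(ka, ki, keq), rel=1e-6
        )

    def test_saturating_shift_consistency_with_oracle(self):
        """K_eq under saturating ligand equals the bound-state population ratio
        from the four-species balance: K_eq,ligand = K_eq,free / D."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            ka, ki = rng.uniform(10, 1e4, 2)
            keq = rng.uniform(0.05, 20)
            # bound species at saturating ligand L: [IL]/[AL] = (Keq * Kda / Kdi) * 1
            ratio_bound = keq * ka / ki
            d = ki / ka
            assert ratio_bound == pytest.approx(keq / d, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            kd_overall(-1.0, 50.0, 1.0)
        with pytest.raises(ValueError):
            kd_overall_mass_balance(10.0, 10.0, 0.0)


class TestSurface:
    def test_monotone_along_both_axes(self):
        grid = kd_surface(log_axis(1, 1e4, 50), log_axis(1, 1e4, 50), KEQ_PHOS)
        assert np.all(np.diff(grid.values, axis=1) >= -1e-12)
        assert np.all(np.diff(grid.values, axis=0) >= -1e-12)

    def test_keq_one_surface_symmetric_under_axis_swap(self):
        ax = log_axis(1, 1e4, 40)
        grid = kd_surface(ax, ax, 1.0)
        np.testing.assert_allclose(grid.values, grid.values.T, rtol=1e-12)

    def test_plateau_along_weak_axis(self):
        # where K_d,active << K_d,inactive / K_eq the overall constant is set by
        # the active conformation and is insensitive to K_d,inactive
        _, s_inactive = log_sensitivities(10.0, 5000.0, KEQ_PHOS)
        assert s_inactive < 0.25

    def test_sensitivities_sum_to_one(self):
        s_a, s_i = log_sensitivities(np.array([10.0, 100.0]), np.array([50.0, 5.0]), 0.7)
        np.testing.assert_allclose(s_a + s_i, 1.0)

    def test_sensitivity_to_inactive_vanishes_as_keq_to_zero(self):
        _, s_i = log_sensitivities(100.0, 100.0, 1e-9)
        assert s_i < 1e-6

    def test_zero_threshold_mask_empty(self):
        grid = kd_surface(log_axis(1, 1e4, 10), log_axis(1, 1e4, 10), KEQ_PHOS)
        mask = plateau_mask(grid, threshold=0.0)
        assert not mask.combined.any()

    def test_plateau_mask_flags_expected_region(self):
        grid = kd_surface(log_axis(1, 1e4, 30), log_axis(1, 1e4, 30), KEQ_PHOS)
        mask = plateau_mask(grid, threshold=0.25)
        # the corner with tight K_d,active and weak K_d,inactive is a plateau
        # w.r.t. K_d,inactive
        assert mask.insensitive_inactive[-1, 0]
        assert not mask.insensitive_inactive[0, -1]

    def test_fivefold_active_improvement_brings_little_overall_change(self):
        # along K_d,inactive = 50 nM: 1 uM -> 200 nM in K_d,active changes
        # K_d,overall by less than 2x for the phosphorylated enzyme
        ratio = kd_overall(1000.0, 50.0, KEQ_PHOS) / kd_overall(200.0, 50.0, KEQ_PHOS)
        assert 1.0 < ratio < 2.0


class TestContourGeometry:
    def test_point_on_contour_has_zero_distances(self):
        c = kd_overall(300.0, 80.0, KEQ_PHOS)
        g = contour_gap_distances(300.0, 80.0, c, KEQ_PHOS)
        assert g.delta_active == pytest.approx(0.0, abs=1e-9)
        assert g.delta_inactive == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_point_at_keq_one(self):
        g = contour_gap_distances(1000.0, 1000.0, 100.0, 1.0)
        assert g.delta_active == pytest.approx(g.delta_inactive, rel=1e-12)

    def test_agrees_with_bisection_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            ka, ki = rng.uniform(10, 1e4, 2)
            keq = rng.uniform(0.05, 20)
            c = kd_overall(ka, ki, keq) * rng.uniform(0.05, 0.95)
            g = contour_gap_distances(ka, ki, c, keq)

            def by_bisection(fixed_ki=None, fixed_ka=None):
                if fixed_ki is not None:
                    f = lambda x: kd_overall(x, fixed_ki, keq) - c
                else:
                    f = lambda y: kd_overall(fixed_ka, y, keq) - c
                if f(1e-12) >= 0:
                    return math.inf
                return brentq(f, 1e-12, ka if fixed_ki is not None else ki, rtol=1e-13)

            ta = by_bisection(fixed_ki=ki)
            ti = by_bisection(fixed_ka=ka)
            if math.isfinite(ta):
                assert g.delta_active == pytest.approx(ka - ta, rel=1e-6)
            else:
                assert math.isinf(g.delta_active)
            if math.isfinite(ti):
                assert g.delta_inactive == pytest.approx(ki - ti, rel=1e-6)
            else:
                assert math.isinf(g.delta_inactive)

    def test_unreachable_contour_flagged_infinite(self):
        # a contour above the column's asymptote ki*(1+K)/K cannot be reached by
        # improving K_d,active alone; the inversion flags it as infinite.  For
        # any point *uphill* of a contour both axis distances are finite, since
        # the uphill condition caps the contour below both asymptotes.
        from auroraloop.binding import _kd_active_on_contour, _kd_inactive_on_contour

        assert math.isinf(_kd_active_on_contour(2000.0, 100.0, 10.0))
        assert math.isinf(_kd_inactive_on_contour(2000.0, 100.0, 10.0))
        g = contour_gap_distances(100.0, 1000.0, 50.0, keq_free=10.0)
        assert math.isfinite(g.delta_active) and math.isfinite(g.delta_inactive)

    def test_downhill_point_rejected(self):
        with pytest.raises(ValueError, match="below"):
            contour_gap_distances(10.0, 10.0, 100.0, 1.0)


class TestEquidistantLine:
    def test_keq_one_locus_is_the_diagonal(self):
        curve = equidistant_line(100.0, 1.0)
        assert len(curve.points) > 10
        assert curve.max_log_deviation_from_diagonal() < 1e-9

    def test_defining_residual_satisfied(self):
        curve = equidistant_line(100.0, KEQ_PHOS)
        for ka, ki in curve.points:
            g = contour_gap_distances(ka, ki, 100.0, KEQ_PHOS)
            assert abs(g.delta_active - g.delta_inactive) < 1e-6 * 100.0

    def test_approaches_diagonal_as_contour_decreases(self):
        devs = [
            equidistant_line(c, KEQ_PHOS).log_deviation_at(3000.0)
            for c in (1000.0, 100.0, 10.0)
        ]
        assert devs[0] > devs[1] > devs[2]

    def test_empty_locus_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            curve = equidistant_line(1e6, KEQ_PHOS, domain=(1.0, 100.0))
        assert len(curve.points) == 0

    def test_log_metric_also_traces_a_locus(self):
        curve = equidistant_line(100.0, KEQ_PHOS, metric="log")
        assert curve.metric == "log"
        assert len(curve.points) > 5
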