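"""Kinetic model unit tests: steady states, chase solutions, half-lives."""

import math

import numpy as np
import pytest

from padk import kinetic_core as kc
from padk.kinetic_core import AbundanceState, ModelSpec, TailProfile


def rel_err(a, b, floor):
    return np.abs(a - b) / np.maximum(np.abs(b), floor)


class TestSteadyState:
    @pytest.mark.parametrize(
        "kind, ka, kd, expected",
        [
            # set the ODE derivatives to zero and solve by hand
            ("serial", 0.25, 0.5, (4.0, 4.0, 2.0)),
            ("parallel", 0.5, 0.5, (1.0, 0.5, 0.5)),
        ],
    )
    def test_fixed_point(self, kind, ka, kd, expected):
        ss = kc.steady_state(ModelSpec(kind, ka, kd, production=1.0))
        assert ss.as_array() == pytest.approx(expected, rel=1e-12)

    def test_no_production_empty_fixed_point(self):
        ss = kc.steady_state(ModelSpec("serial", 0.3, 0.2, production=0.0))
        assert ss.total == 0.0

    @pytest.mark.parametrize("kind", ["serial", "parallel"])
    def test_numeric_integration_converges_to_fixed_point(self, kind):
        """Integrating with production on from empty reaches the steady state."""
        spec = ModelSpec(kind, 0.08, 0.3)
        horizon = 50.0 / min(spec.ka, spec.kd)
        curve = kc.numeric_chase(
            spec,
            AbundanceState(0.0, 0.0, 0.0, 0.0),
            np.array([0.0, horizon]),
            production=True,
        )
        ss = kc.steady_state(spec)
        assert curve.state_at(-1).as_array() == pytest.approx(
            ss.as_array(), rel=1e-6
        )

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("serial", -0.1, 0.5)
        with pytest.raises(ValueError):
            ModelSpec("serial", 0.1, 0.0)
        with pytest.raises(ValueError):
            ModelSpec("circular", 0.1, 0.5)


class TestAnalyticChase:
    def test_degenerate_equal_rates_total(self):
        """ka == kd collapses to the polynomial-times-exponential form.

        Hand integration of the cascade with ka = kd = 0.5 from (2, 2, 2):
        total(t) = exp(-t/2) (6 + 2 t + t²/4).
        """
        t = np.linspace(0.0, 20.0, 41)
        curve = kc.analytic_chase(
            ModelSpec("serial", 0.5, 0.5), AbundanceState(0, 2, 2, 2), t
        )
        expected = np.exp(-0.5 * t) * (6 + 2 * t + 0.25 * t**2)
        assert curve.total == pytest.approx(expected, rel=1e-12)

    def test_distinct_rates_total(self):
        """Variation of constants, serial ka=0.25, kd=0.5 from steady state:
        total(t) = (8 + 2t) e^(-t/4) + 2 e^(-t/2)."""
        spec = ModelSpec("serial", 0.25, 0.5)
        t = np.linspace(0.0, 40.0, 81)
        curve = kc.analytic_chase(spec, kc.steady_state(spec), t)
        expected = (8 + 2 * t) * np.exp(-0.25 * t) + 2 * np.exp(-0.5 * t)
        assert curve.total == pytest.approx(expected, rel=1e-12)

    def test_zero_initial_state_stays_zero(self):
        curve = kc.analytic_chase(
            ModelSpec("parallel", 0.2, 0.4), AbundanceState(0, 0, 0, 0),
            np.array([0.0, 5.0, 10.0]),
        )
        assert np.all(curve.total == 0.0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            kc.analytic_chase(
                ModelSpec("serial", 0.1, 0.2), AbundanceState(0, 1, 1, 1),
                np.array([-1.0, 0.0, 1.0]),
            )

    @pytest.mark.parametrize("kind", ["serial", "parallel"])
    def test_agrees_with_numeric_integration(self, kind):
        """Closed form vs stiff integration for random rate pairs, incl. ka=kd."""
        rng = np.random.default_rng(7)
        for i in range(10):
            ka = 10.0 ** rng.uniform(-2, 0.5)
            kd = ka if i % 3 == 0 else 10.0 ** rng.uniform(-2, 0.5)
            spec = ModelSpec(kind, ka, kd)
            init = kc.steady_state(spec)
            t = np.linspace(0.0, 10.0 / min(ka, kd), 30)
            ana = kc.analytic_chase(spec, init, t)
            num = kc.numeric_chase(spec, init, t, rtol=1e-11, atol=1e-15 * init.total)
            floor = math.exp(-10) * init.total
            assert rel_err(num.total, ana.total, floor).max() < 1e-6

    @pytest.mark.parametrize("kind", ["serial", "parallel"])
    def test_mass_monotone_and_nonnegative(self, kind):
        spec = ModelSpec(kind, 0.13, 0.31)
        t = np.linspace(0.0, 60.0, 200)
        curve = kc.analytic_chase(spec, kc.steady_state(spec), t)
        assert np.all(np.diff(curve.total) < 0)
        for species in (curve.pa_long, curve.pa_mid, curve.pa_short):
            assert np.all(species >= 0)

    def test_parallel_small_ka_is_single_exponential(self):
        spec = ModelSpec("parallel", 1e-9, 0.2)
        t = np.linspace(0.0, 30.0, 31)
        curve = kc.analytic_chase(spec, kc.steady_state(spec), t)
        expected = curve.total[0] * np.exp(-0.2 * t)
        assert curve.total == pytest.approx(expected, rel=1e-6)


class TestMeanTail:
    @pytest.mark.parametrize(
        "ka, kd, expected",
        [
            (0.25, 0.5, 46.0),   # fastest-decaying corner of the grid
            (0.25, 0.1, 30.0),
        ],
    )
    def test_serial_steady_state_values(self, ka, kd, expected):
        ss = kc.steady_state(ModelSpec("serial", ka, kd))
        assert kc.mean_tail(ss) == pytest.approx(expected, abs=1e-12)

    def test_single_species(self):
        assert kc.mean_tail(AbundanceState(0, 1, 0, 0)) == 70.0

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            kc.mean_tail(AbundanceState(0, 0, 0, 0))

    def test_closed_form_matches_weighted_mean(self):
        for ka, kd in [(0.03, 0.7), (0.25, 0.02), (0.4, 0.4)]:
            ss = kc.steady_state(ModelSpec("serial", ka, kd))
            assert kc.serial_mean_tail(ka, kd) == pytest.approx(
                kc.mean_tail(ss), rel=1e-12
            )

    def test_monotone_in_rates_with_limits(self):
        """Serial mean tail rises with kd, falls with ka; limits 55 and 10 nt."""
        kds = np.logspace(-4, 3, 40)
        tails_kd = [kc.serial_mean_tail(0.1, kd) for kd in kds]
        assert np.all(np.diff(tails_kd) > 0)

        kas = np.logspace(-5, 3, 40)
        tails_ka = [kc.serial_mean_tail(ka, 0.1) for ka in kas]
        assert np.all(np.diff(tails_ka) < 0)

        profile = TailProfile()
        assert tails_ka[0] == pytest.approx((profile.long + profile.mid) / 2, rel=1e-3)
        assert kc.serial_mean_tail(0.1, 1e-7) == pytest.approx(profile.short, rel=1e-3)

    def test_invariant_to_production(self):
        for p in (0.5, 1.0, 7.0):
            ss = kc.steady_state(ModelSpec("serial", 0.05, 0.1, production=p))
            assert kc.mean_tail(ss) == pytest.approx(kc.serial_mean_tail(0.05, 0.1))


class TestHalfLife:
    def test_crossing_values(self):
        """Crossing times frozen from an independent symbolic solution
        (dsolve of the cascade + nsolve of total(t) = total(0)/2)."""
        assert kc.half_life_crossing(ModelSpec("serial", 0.25, 0.5)) == pytest.approx(
            5.41060068939418, abs=1e-6
        )
        assert kc.half_life_crossing(ModelSpec("serial", 0.25, 0.02)) == pytest.approx(
            35.5735332690608, abs=1e-6
        )

    def test_parallel_small_ka_limit(self):
        assert kc.half_life_crossing(
            ModelSpec("parallel", 1e-9, 0.35)
        ) == pytest.approx(math.log(2) / 0.35, rel=1e-6)

    def test_invariant_to_production_and_tails(self):
        base = kc.half_life_crossing(ModelSpec("serial", 0.05, 0.1, production=1.0))
        assert kc.half_life_crossing(
            ModelSpec("serial", 0.05, 0.1, production=42.0)
        ) == pytest.approx(base, rel=1e-9)

    def test_expfit_pure_exponential_is_exact(self):
        spec = ModelSpec("parallel", 1e-9, 0.1)
        est = kc.half_life_expfit(spec, np.arange(0.0, 41.0, 2.0))
        assert est == pytest.approx(math.log(2) / 0.1, rel=1e-6)

    def test_expfit_near_crossing_and_deterministic(self):
        """The window-dependent fit estimator stays near the crossing time.

        For a fast serial RNA the log-curve is concave, so the fitted slope
        is steeper than the initial shoulder and the fit half-life comes out
        slightly below the crossing; for slow deadenylation on a short
        window it comes out above.  Either way the two estimators agree to
        within 25% here, and the fit is deterministic.
        """
        grid = np.arange(0.0, 61.0, 2.0)
        for ka, kd in [(0.25, 0.5), (0.01, 0.5)]:
            spec = ModelSpec("serial", ka, kd)
            crossing = kc.half_life_crossing(spec)
            fit = kc.half_life_expfit(spec, grid)
            assert abs(fit - crossing) / crossing < 0.25
            assert kc.half_life_expfit(spec, grid) == fit


class TestGridScan:
    def test_default_grid_shape_and_values(self):
        grid = kc.grid_scan("serial")
        assert len(grid) == 9
        assert set(grid["ka_per_min"]) == set(kc.DEFAULT_KA_GRID)

        def cell(ka, kd):
            row = grid[(grid.ka_per_min == ka) & (grid.kd_per_min == kd)]
            return row.iloc[0]

        # slowest corner: 54.55 -> 55 nt; shortest-tail corner: 16.2 -> 16 nt
        assert round(cell(0.01, 0.5).mean_tail_nt) == 55
        assert round(cell(0.25, 0.02).mean_tail_nt) == 16

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            kc.grid_scan("serial", ka_values=[], kd_values=[0.1])
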