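"""Closed-form cap distribution, velocities, force response and phases."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fibriltip.errors import (
    InsufficientDataError,
    InvalidParameterError,
    NoGrowthError,
    NoSaturationWarning,
    NotAnalyticError,
)
from fibriltip.model import Conditions, RateSet
from fibriltip import theory
from fibriltip.theory import (
    beta_velocity,
    cap_distribution,
    classify_phase,
    critical_velocity_default,
    estimate_switching_rate,
    filament_velocity,
    force_velocity_curve,
    phase_diagram,
    q_probability,
    saturation_velocity,
    stall_force,
)

from conftest import random_regime1_rates

RATES = RateSet(k_p_cc=2.0, k_d_cc=50.0, k_p_bc=0.5, k_d_bc=10.0, s_cb=5.0)

rate_sets = st.builds(
    RateSet,
    k_p_cc=st.floats(0.5, 5.0),
    k_d_cc=st.floats(10.0, 200.0),
    k_p_bc=st.floats(0.1, 2.0),
    k_d_bc=st.floats(1.0, 50.0),
    s_cb=st.floats(0.5, 50.0),
)


class TestCapDistribution:
    def test_zero_concentration_empties_cap(self):
        d = cap_distribution(RATES, 0.0)
        assert d.p[0] == 1.0 and d.q == 0.0 and d.regime == 1

    def test_nonanalytic_rates_rejected(self):
        with pytest.raises(NotAnalyticError):
            cap_distribution(RATES.replace(s_bc=1.0), 1.0)
        with pytest.raises(NotAnalyticError):
            q_probability(RATES.replace(k_d_bb=1.0), 1.0)

    def test_plain_birth_death_limit_is_geometric(self):
        """With no switching and no B-end binding the cap (started >=1) is a
        textbook birth-death chain; compare against a numerically solved
        truncated transition matrix."""
        rates = RateSet(k_p_cc=2.0, k_d_cc=10.0, k_p_bc=0.5, k_d_bc=10.0,
                        s_cb=0.0)
        conc = 2.0  # ratio 0.4
        d = cap_distribution(rates, conc)
        # independent oracle: dense generator, stationary by linear solve
        n = 80
        Q = np.zeros((n, n))
        for k in range(n):
            up = (rates.k_p_bc if k == 0 else rates.k_p_cc) * conc if k < n - 1 else 0.0
            down = rates.k_d_bc if k == 1 else (rates.k_d_cc if k >= 2 else 0.0)
            if k < n - 1:
                Q[k + 1, k] += up
            if k >= 1:
                Q[k - 1, k] += down
            Q[k, k] -= up + down
        A = Q.copy()
        A[0, :] = 1.0
        b = np.zeros(n)
        b[0] = 1.0
        p_num = np.linalg.solve(A, b)
        m = min(d.p.size, n)
        assert np.abs(d.p[:m] - p_num[:m]).max() < 1e-10
        # geometric ratio within the cap
        ratio = d.p[3] / d.p[2]
        assert ratio == pytest.approx(rates.k_p_cc * conc / rates.k_d_cc)

    @given(rates=rate_sets, u=st.floats(0.05, 0.95))
    def test_normalization_and_q_consistency(self, rates, u):
        conc = u * cap_distribution(rates, 0.0).conc_starstar
        d = cap_distribution(rates, conc)
        assert d.regime == 1
        assert d.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert (d.p >= 0).all()
        assert d.q == pytest.approx(1.0 - d.p[0], abs=1e-12)
        assert d.q == pytest.approx(q_probability(rates, conc), abs=1e-12)

    def test_regime2_flagged_nonstationary(self):
        css = cap_distribution(RATES, 0.0).conc_starstar
        d = cap_distribution(RATES, 1.5 * css)
        assert d.regime == 2 and not d.stationary and d.p.size == 0
        assert d.q == 1.0

    def test_q_monotone_in_concentration(self):
        css = cap_distribution(RATES, 0.0).conc_starstar
        grid = np.linspace(0.0, 2.0 * css, 400)
        qs = [q_probability(RATES, c) for c in grid]
        assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(q_probability(RATES, c) == 1.0 for c in grid if c >= css)


class TestVelocities:
    def test_zero_concentration_zero_velocity(self):
        assert filament_velocity(RATES, 0.0).v_f == 0.0
        assert beta_velocity(RATES, 0.0) == 0.0

    def test_switching_off_means_no_beta_growth(self):
        assert beta_velocity(RATES.replace(s_cb=0.0), 5.0) == 0.0
        assert saturation_velocity(RATES.replace(s_cb=0.0))[0] == 0.0

    @given(rates=rate_sets, u=st.floats(0.01, 3.0))
    def test_beta_velocity_bounded_by_switching_rate(self, rates, u):
        conc = u * cap_distribution(rates, 0.0).conc_starstar
        vb = beta_velocity(rates, conc)
        assert 0.0 <= vb <= rates.s_cb + 1e-12
        pt = filament_velocity(rates, conc)
        if pt.regime == 2:
            assert pt.v_beta == rates.s_cb

    @given(rates=rate_sets, u=st.floats(0.05, 0.95))
    def test_regime1_velocity_equals_locking_flux(self, rates, u):
        """Stationary cap: every net length gain is a switch-locked monomer,
        so the term-by-term flux must equal s_cb * q."""
        conc = u * cap_distribution(rates, 0.0).conc_starstar
        pt = filament_velocity(rates, conc)
        assert pt.v_f == pytest.approx(rates.s_cb * q_probability(rates, conc),
                                       rel=1e-9, abs=1e-12)
        assert pt.v_f == pytest.approx(pt.v_beta, rel=1e-9, abs=1e-12)

    @given(rates=rate_sets)
    def test_branches_continuous_and_saturate_at_ceiling(self, rates):
        s, css = saturation_velocity(rates)
        assert s == rates.s_cb
        v2 = filament_velocity(rates, css).v_f
        assert v2 == pytest.approx(s, rel=1e-9, abs=1e-9)
        v1 = filament_velocity(rates, css * (1 - 1e-12)).v_f
        assert abs(v1 - v2) <= 1e-9 * max(s, 1.0)
        assert beta_velocity(rates, css) == pytest.approx(s, abs=1e-12)

    def test_regime2_linear_in_concentration(self):
        css = cap_distribution(RATES, 0.0).conc_starstar
        c1, c2 = 1.2 * css, 1.7 * css
        v1 = filament_velocity(RATES, c1).v_f
        v2 = filament_velocity(RATES, c2).v_f
        assert (v2 - v1) / (c2 - c1) == pytest.approx(RATES.k_p_cc)


class TestForce:
    COND = Conditions(conc=150.0)

    def test_unloaded_point_matches_filament_velocity(self, fig3):
        curve = force_velocity_curve(fig3.rates, 150.0, [0.0, 1.0], self.COND)
        assert curve[0][1] == filament_velocity(fig3.rates, 150.0).v_f

    def test_velocity_nonincreasing_in_force(self, fig3):
        forces = np.linspace(0.0, 40.0, 400)
        curve = force_velocity_curve(fig3.rates, 150.0, forces, self.COND)
        vs = [v for _, v in curve]
        assert all(b <= a + 1e-9 for a, b in zip(vs, vs[1:]))
        assert all(v > 0 for v in vs)  # beta core never shrinks

    def test_concave_at_saturated_concentration(self, fig3):
        forces = np.linspace(0.0, 3.0, 13)
        vs = [v for _, v in force_velocity_curve(fig3.rates, 90.0, forces,
                                                 Conditions(conc=90.0))]
        assert (np.diff(vs, 2) <= 1e-9).all()

    def test_unsorted_or_negative_forces_rejected(self, fig3):
        with pytest.raises(InvalidParameterError):
            force_velocity_curve(fig3.rates, 90.0, [1.0, 0.5])
        with pytest.raises(InvalidParameterError):
            force_velocity_curve(fig3.rates, 90.0, [-1.0, 0.5])

    def test_stall_matches_grid_scan(self, fig3):
        F = stall_force(fig3.rates, 150.0, self.COND, tol=1e-4)
        # independent oracle: fine grid sign change of v(F) - 5% v(0)
        grid = np.linspace(0.0, 20.0, 10_000)
        v0 = filament_velocity(fig3.rates, 150.0).v_f
        vals = np.array([
            filament_velocity(fig3.rates, 150.0,
                              self.COND.replace(force=f)).v_f - 0.05 * v0
            for f in grid
        ])
        idx = int(np.nonzero(np.diff(np.sign(vals)))[0][0])
        assert grid[idx] <= F <= grid[idx + 1] + (grid[1] - grid[0])

    def test_stall_undefined_without_growth(self):
        rates = RATES.replace(s_cb=0.0, k_p_bc=0.0)
        with pytest.raises(NoGrowthError):
            stall_force(rates, 0.0, Conditions(conc=0.0))

    def test_stall_invariant_under_switching_rate(self, fig3):
        stalls = [
            stall_force(fig3.rates.replace(s_cb=s), 150.0, self.COND)
            for s in (15.0, 30.0, 60.0)
        ]
        assert max(stalls) - min(stalls) < 0.15 * np.mean(stalls)


class TestPhases:
    VC = 0.5

    def test_classification_rules(self):
        # below the visible-growth cutoff
        assert classify_phase(0.3 * self.VC, 0.0, self.VC) == "no-aggregation"
        # aggregate grows, beta content does not
        assert classify_phase(2.0, 0.1, self.VC) == "disordered"
        # both grow but aggregate outruns beta by > 2x
        assert classify_phase(2.0, 0.6, self.VC) == "partially-ordered"
        # beta growth keeps pace
        assert classify_phase(1.0, 0.8, self.VC) == "ordered"
        with pytest.raises(InvalidParameterError):
            classify_phase(-1.0, 0.0, self.VC)

    def test_default_critical_velocity(self):
        assert critical_velocity_default() == pytest.approx(1000.0 / 24.0)

    def test_wide_grid_produces_all_four_phases(self, fig3):
        pd_ = phase_diagram(fig3.rates, np.geomspace(1, 1000, 10),
                            np.geomspace(1, 1000, 12))
        assert set(pd_.labels.ravel()) == {
            "no-aggregation", "disordered", "partially-ordered", "ordered"
        }

    def test_no_switching_row_never_ordered(self, fig3):
        pd_ = phase_diagram(fig3.rates, [0.0], np.geomspace(1, 500, 20))
        labels = set(pd_.labels.ravel())
        assert "ordered" not in labels and "partially-ordered" not in labels

    def test_no_aggregation_never_reappears_with_concentration(self, fig3):
        pd_ = phase_diagram(fig3.rates, np.geomspace(1, 300, 6),
                            np.geomspace(0.5, 500, 40))
        for row in pd_.labels:
            seen_growth = False
            for lab in row:
                if lab != "no-aggregation":
                    seen_growth = True
                else:
                    assert not seen_growth


class TestSwitchingRateEstimation:
    def test_recovers_known_rate_from_noisy_curve(self, fig3):
        rng = np.random.default_rng(12)
        concs = [5, 12, 20, 30, 42, 55, 65, 75, 83, 90, 94, 97, 98.5, 99.5]
        curve = [
            (c, filament_velocity(fig3.rates, c).v_f
             * (1 + 0.01 * rng.standard_normal()))
            for c in concs
        ]
        est = estimate_switching_rate(curve)
        assert est.saturated
        assert est.s_cb == pytest.approx(fig3.rates.s_cb, rel=0.05)

    def test_constant_curve_returns_its_level(self):
        est = estimate_switching_rate([(1, 5.0), (2, 5.0), (3, 5.0), (4, 5.0)])
        assert est.s_cb == pytest.approx(5.0)

    def test_linear_curve_warns_no_saturation(self):
        with pytest.warns(NoSaturationWarning):
            est = estimate_switching_rate(
                [(c, 2.0 * c) for c in (1, 2, 3, 4, 5)]
            )
        assert not est.saturated and est.method == "lower-bound"
        assert est.s_cb == pytest.approx(10.0, rel=0.2)  # lower bound near top

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_switching_rate([(1, 1.0), (2, 2.0), (3, 3.0)])
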