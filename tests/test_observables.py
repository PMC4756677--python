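"""Velocity estimators, heterogeneity curves and stop-go dwell analysis."""

import numpy as np
import pytest

from fibriltip.errors import InsufficientDataError
from fibriltip.kmc import EnsembleStats, Trajectory, run_ensemble
from fibriltip.observables import (
    STOP_THRESHOLD_DEFAULT,
    DwellSegments,
    dwell_statistics,
    ensemble_velocity,
    initial_velocity,
    length_heterogeneity,
    segment_stop_go,
    steady_velocity,
    tau_vs_switching,
)


def make_traj(times, lengths):
    """Synthetic all-beta trajectory with prescribed lengths."""
    times = np.asarray(times, dtype=float)
    lengths = np.asarray(lengths, dtype=np.int64)
    return Trajectory(
        times=times, n_beta=lengths, cap_k=np.zeros_like(lengths),
        rng_seed=0, t_end=float(times[-1]),
    )


class TestVelocityEstimators:
    def test_exact_linear_slope(self):
        t = np.linspace(0, 10, 101)
        tr = make_traj(t, np.round(7 * t).astype(int) + 1)
        est = steady_velocity(tr)
        assert est.value == pytest.approx(7.0, rel=0.01)

    def test_constant_length_zero_slope(self):
        tr = make_traj(np.linspace(0, 5, 20), np.full(20, 10))
        assert steady_velocity(tr).value == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_after_tmin(self):
        tr = make_traj([0.0, 1.0, 2.0], [1, 2, 3])
        with pytest.raises(InsufficientDataError):
            steady_velocity(tr, t_min=1.5)

    def test_initial_velocity_of_linear_run_matches_slope(self):
        t = np.linspace(0, 10, 1001)
        tr = make_traj(t, np.round(50 * t).astype(int) + 1)
        assert initial_velocity(tr) == pytest.approx(
            steady_velocity(tr).value, rel=0.05
        )

    def test_initial_velocity_undefined_for_flat_run(self):
        tr = make_traj(np.linspace(0, 5, 10), np.full(10, 40))
        with pytest.raises(InsufficientDataError):
            initial_velocity(tr)

    def test_decelerating_run_initial_exceeds_late_steady(self):
        t = np.linspace(0, 100, 2001)
        L = np.round(300 * np.sqrt(t)).astype(int) + 1  # concave growth
        tr = make_traj(t, L)
        assert initial_velocity(tr) > steady_velocity(tr, t_min=90.0).value

    def test_ensemble_velocity_needs_lengths(self):
        st = EnsembleStats(time_grid=np.linspace(0, 1, 5),
                           mean_length=np.zeros(5), sigma=np.zeros(5),
                           n_runs=3, lengths=None)
        with pytest.raises(InsufficientDataError):
            ensemble_velocity(st)


class TestHeterogeneity:
    def _stats(self, lengths, grid=None):
        lengths = np.asarray(lengths, dtype=float)
        grid = np.linspace(0, 1, lengths.shape[1]) if grid is None else grid
        return EnsembleStats(
            time_grid=grid, mean_length=lengths.mean(axis=0),
            sigma=lengths.std(axis=0), n_runs=lengths.shape[0],
            lengths=lengths,
        )

    def test_identical_runs_have_no_heterogeneity(self):
        with pytest.warns(UserWarning, match="runs"):
            het = length_heterogeneity(self._stats(np.ones((5, 30))))
        assert (het.sigma == 0).all() and het.tau_max is None

    def test_sigma_invariant_under_relabeling_and_shift(self):
        rng = np.random.default_rng(0)
        L = rng.normal(100, 10, size=(25, 40)).cumsum(axis=1)
        a = length_heterogeneity(self._stats(L))
        b = length_heterogeneity(self._stats(L[::-1] + 1000.0))
        assert np.allclose(a.sigma, b.sigma)

    def test_constant_c_sigma_nondecreasing(self, fig3):
        """Without depletion the ensemble spread keeps widening."""
        grid = np.linspace(0.0, 30.0, 60)
        st_, _ = run_ensemble(fig3.rates, 60.0, 30.0, grid, 100,
                              base_rng_seed=6)
        het = length_heterogeneity(st_, smoothing_window=9)
        s = het.sigma_smooth
        # coarse monotonicity: each quarter of the run exceeds the previous
        q = [s[i] for i in (5, 20, 40, 59)]
        assert q[0] < q[1] < q[2] < q[3]

    def test_mass_conserved_sigma_rises_peaks_declines(self, fig3):
        grid = np.linspace(0.0, 90.0, 300)
        st_, _ = run_ensemble(fig3.rates, 90.0, 90.0, grid, 32,
                              base_rng_seed=3, mode="mass-conserved",
                              n_total=800)
        het = length_heterogeneity(st_)
        peak = het.sigma.max()
        assert het.tau_max is not None and 0 < het.tau_max < 90.0
        assert het.sigma[-1] < 0.3 * peak
        assert het.sigma[0] < 0.3 * peak

    def test_tau_inverse_in_switching_rate(self, fig3):
        sweep = tau_vs_switching(
            fig3.rates, [7.5, 15.0, 30.0, 60.0, 120.0], conc0=90.0,
            n_total=800, n_runs=32, base_rng_seed=0,
        )
        assert (np.diff(sweep.tau) < 0).all()
        assert sweep.slope == pytest.approx(-1.0, abs=0.15)

    def test_fewer_than_two_runs_rejected(self):
        with pytest.raises(InsufficientDataError):
            length_heterogeneity(self._stats(np.ones((1, 10))))


class TestStopGo:
    def test_constructed_stop_then_go(self):
        """2 h flat then 2 h far above threshold: exactly one stop segment
        followed by one go segment, boundaries within one window."""
        t = np.linspace(0, 4, 4001)
        L = np.where(t < 2, 10, 10 + (t - 2) * 2000).astype(int)
        segs = segment_stop_go(make_traj(t, L), t_max=4.0)
        assert [s[2] for s in segs.segments] == ["stop", "go"]
        assert segs.segments[0][1] == pytest.approx(2.0, abs=segs.window)
        # tiling invariant
        total = sum(b - a for a, b, _ in segs.segments)
        assert total == pytest.approx(segs.span)

    def test_uniformly_fast_run_has_no_stops(self):
        t = np.linspace(0, 10, 1001)
        tr = make_traj(t, (t * 2 * STOP_THRESHOLD_DEFAULT).astype(int) + 1)
        segs = segment_stop_go(tr, t_max=10.0)
        assert [s[2] for s in segs.segments] == ["go"]

    def test_short_trajectory_rejected(self):
        tr = make_traj([0.0, 0.1], [1, 2])
        with pytest.raises(InsufficientDataError):
            segment_stop_go(tr)

    def test_exponential_dwells_recovered(self):
        """Known exponential dwell generator: the MLE rate comes back
        within 5% at n = 1000 and the KS test does not reject."""
        rng = np.random.default_rng(8)
        w = 1.0 / 6.0
        rate_go, rate_stop = 0.4, 0.3
        segs = []
        t = 0.0
        rows = []
        for _ in range(1000):
            for phase, rate in (("go", rate_go), ("stop", rate_stop)):
                # windowed observation: a dwell spanning part of a window is
                # reported as the whole window
                dur = w * np.ceil(rng.exponential(1.0 / rate) / w)
                rows.append((t, t + dur, phase))
                t += dur
        segs = [DwellSegments(segments=rows, threshold=240.0, window=w,
                              span=t)]
        d = dwell_statistics(segs)
        assert d.go.rate == pytest.approx(rate_go, rel=0.05)
        assert d.stop.rate == pytest.approx(rate_stop, rel=0.05)
        assert d.go.ks_p > 0.01 and d.stop.ks_p > 0.01

    def test_too_few_dwells_rejected(self):
        rows = [(0, 1, "go"), (1, 2, "stop"), (2, 3, "go"), (3, 4, "stop")]
        segs = [DwellSegments(segments=rows, threshold=240.0, window=1 / 6,
                              span=4.0)]
        with pytest.raises(InsufficientDataError):
            dwell_statistics(segs)

    def test_fig7_preset_alternates_with_comparable_counts(self, fig7):
        from fibriltip.kmc import simulate_constant_c

        segs = []
        for i in range(12):
            tr = simulate_constant_c(fig7.rates, fig7.conditions.conc, 60.0,
                                     rng_seed=300 + i)
            segs.append(segment_stop_go(tr))
        d = dwell_statistics(segs)
        assert d.go.n > 50 and d.stop.n > 50
        # alternation makes the two phase counts comparable
        assert 0.7 < d.go.n / d.stop.n < 1.4
        # stop phases are memoryless waits for tip re-activation
        assert d.stop.ks_p > 0.01
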