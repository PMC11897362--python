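"""Unit tests for a_p sampling, reactivity differencing, bootstrap summaries
and the receptor-density correlation."""

import numpy as np
import pytest

from wbhopf import (
    APSampling,
    BifurcationSchedule,
    ConstantPostSchedule,
    ParameterError,
    ReactivityCurve,
    ReactivitySurface,
    ReceptorMap,
    RSNPartition,
    correlate_receptors,
    delta_chi,
    peak_reactivity,
    reactivity,
    rho_vs_intensity,
    sample_ap,
)


def _toy_partition():
    return RSNPartition({"Vis": (0, 1), "ES": (2, 3, 4), "Aud": (5,),
                         "SM": (6, 7), "DM": (8, 9, 10), "EC": (11,)})


def _surface_from_M(M: np.ndarray, fext: np.ndarray, times=None, rsn="Vis", rsn_size=2):
    """Wrap a (runs, times, fext) response array as a ReactivitySurface."""
    M = np.asarray(M, dtype=float)
    times = np.asarray(times if times is not None else 10.0 * np.arange(M.shape[1]))
    return ReactivitySurface(M, times, fext, rsn, rsn_size)


class TestAPSampling:
    def test_constant_schedule_gives_constant_ap(self):
        sched = ConstantPostSchedule(a0=0.07, t_inject=480.0, a_post=0.07)
        ap = sample_ap(sched, n=10, span=1200.0, t_inject=480.0)
        assert np.allclose(ap.a_values, 0.07)

    def test_42_samples_span_20_minutes_evenly(self):
        sched = BifurcationSchedule(a0=0.07, t_inject=480.0, lam=159.3, beta=284.0)
        ap = sample_ap(sched, n=42, span=1200.0)
        assert ap.n == 42
        spacing = np.diff(ap.times)
        assert np.allclose(spacing, 1200.0 / 42)
        assert ap.times[-1] == pytest.approx(480.0 + 1200.0)

    def test_deepest_ap_lands_nearest_injection_plus_beta(self):
        sched = BifurcationSchedule(a0=0.07, t_inject=480.0, lam=159.3, beta=284.0)
        ap = sample_ap(sched, n=42, span=1200.0)
        t_min = ap.times[np.argmin(ap.a_values)]
        spacing = 1200.0 / 42
        assert abs(t_min - (480.0 + 284.0)) <= spacing / 2 + 1e-9

    def test_invalid_span_rejected(self):
        with pytest.raises(ParameterError):
            sample_ap(ConstantPostSchedule(), n=5, span=0.0)


class TestReactivityDifferencing:
    def test_flat_response_gives_zero_chi(self):
        fext = 0.001 * np.arange(5)
        M = np.full((1, 4, 5), 0.3)
        curve = reactivity(_surface_from_M(M, fext), at_fext=0.002)
        assert np.allclose(curve.values, 0.0)

    def test_linear_response_is_exact_before_baseline_subtraction(self):
        # M = c * F: the second-order scheme is exact for polynomials of
        # degree <= 2, so chi = c / n_rsn at every grid point including edges
        c = 7.5
        fext = 0.001 * np.arange(5)
        M = np.broadcast_to(c * fext, (2, 3, 5)).copy()
        for j in [0, 2, 4]:
            curve = reactivity(_surface_from_M(M, fext, rsn_size=4), at_fext=fext[j],
                               baseline_subtract=False)
            assert np.allclose(curve.values, c / 4, atol=1e-12)

    def test_quadratic_response_is_exact(self):
        c = 300.0
        fext = 0.001 * np.arange(7)
        M = np.broadcast_to(c * fext**2, (1, 2, 7)).copy()
        for j in [0, 3, 6]:
            curve = reactivity(_surface_from_M(M, fext, rsn_size=1), at_fext=fext[j],
                               baseline_subtract=False)
            assert np.allclose(curve.values, 2 * c * fext[j], atol=1e-9)

    def test_baseline_subtraction_zeroes_first_sample(self):
        rng = np.random.default_rng(0)
        fext = 0.001 * np.arange(5)
        M = rng.random((3, 6, 5))
        curve = reactivity(_surface_from_M(M, fext), at_fext=0.001)
        assert curve.values[0] == pytest.approx(0.0, abs=1e-15)
        assert np.allclose(curve.per_run[:, 0], 0.0)

    def test_rsn_normalization_cancels_proportional_response(self):
        # doubling the stimulated network while the response scales with the
        # node count leaves normalized chi unchanged
        fext = 0.001 * np.arange(5)
        base = np.broadcast_to(5.0 * fext, (1, 3, 5)).copy()
        small = reactivity(_surface_from_M(base, fext, rsn_size=2), at_fext=0.002,
                           baseline_subtract=False)
        large = reactivity(_surface_from_M(2.0 * base, fext, rsn_size=4), at_fext=0.002,
                           baseline_subtract=False)
        assert np.allclose(small.values, large.values, atol=1e-12)

    def test_off_grid_amplitude_rejected(self):
        fext = 0.001 * np.arange(5)
        M = np.zeros((1, 2, 5))
        with pytest.raises(ParameterError):
            reactivity(_surface_from_M(M, fext), at_fext=0.0005)

    def test_too_few_grid_points_rejected(self):
        with pytest.raises(ParameterError):
            _surface_from_M(np.zeros((1, 2, 2)), np.array([0.0, 0.001]))
            reactivity(_surface_from_M(np.zeros((1, 2, 2)), np.array([0.0, 0.001])), 0.0)


def _curve(per_run, times=None):
    per_run = np.asarray(per_run, dtype=float)
    times = np.asarray(times if times is not None else 10.0 * np.arange(per_run.shape[1]))
    return ReactivityCurve(values=per_run.mean(axis=0), per_run=per_run, times=times,
                           rsn="Vis", rsn_size=2, at_fext=0.005)


class TestPeakBootstrap:
    def test_constant_curves_give_exact_peak_and_zero_width(self):
        mean, ci, dist = peak_reactivity(_curve(np.full((4, 5), 2.5)), n_boot=50, seed=1)
        assert mean == pytest.approx(2.5)
        assert ci == (pytest.approx(2.5), pytest.approx(2.5))

    def test_two_run_bootstrap_support_and_mean(self):
        # runs with maxima {1, 3}: resample means lie in {1, 2, 3} and the
        # bootstrap mean approaches 2
        curve = _curve(np.vstack([np.full(4, 1.0), np.full(4, 3.0)]))
        mean, _, dist = peak_reactivity(curve, n_boot=4000, seed=7)
        assert set(np.round(dist, 12)) <= {1.0, 2.0, 3.0}
        assert mean == pytest.approx(2.0, abs=0.05)

    def test_seeded_bootstrap_is_reproducible(self):
        curve = _curve(np.random.default_rng(3).random((5, 6)))
        _, _, d1 = peak_reactivity(curve, n_boot=100, seed=11)
        _, _, d2 = peak_reactivity(curve, n_boot=100, seed=11)
        assert np.array_equal(d1, d2)

    def test_ci_covers_known_truth_in_most_trials(self):
        # known-distribution stub: per-run curves are constant c ~ N(5, 1);
        # the statistic max_t mean_runs = mean of c's, true value 5.
        rng = np.random.default_rng(2024)
        n_runs, covered = 12, 0
        for _ in range(100):
            c = 5.0 + rng.standard_normal(n_runs)
            curve = _curve(np.tile(c[:, None], (1, 4)))
            _, (lo, hi), _ = peak_reactivity(curve, n_boot=200, seed=int(rng.integers(2**31)))
            covered += lo <= 5.0 <= hi
        assert covered >= 90


class TestDeltaChi:
    def test_identical_curves_cancel(self):
        c = _curve(np.random.default_rng(1).random((3, 5)))
        assert np.allclose(delta_chi(c, c).values, 0.0)

    def test_antisymmetry(self):
        a = _curve(np.random.default_rng(2).random((3, 5)))
        b = _curve(np.random.default_rng(3).random((3, 5)))
        assert np.allclose(delta_chi(a, b).values, -delta_chi(b, a).values)

    def test_peak_bounded_by_extremes(self):
        a = _curve(np.random.default_rng(4).random((3, 5)))
        b = _curve(np.random.default_rng(5).random((3, 5)))
        d = delta_chi(a, b)
        assert d.values.max() <= a.values.max() - b.values.min() + 1e-12

    def test_mismatched_time_axes_rejected(self):
        a = _curve(np.zeros((2, 5)))
        b = _curve(np.zeros((2, 5)), times=np.arange(5.0) * 7)
        with pytest.raises(ParameterError):
            delta_chi(a, b)


class TestReceptorCorrelation:
    def test_linear_relationship_gives_rho_one(self):
        part = _toy_partition()
        rmap = ReceptorMap(np.linspace(0.5, 2.0, 12))
        dens = rmap.network_means(part)
        res = correlate_receptors(3.0 * dens + 1.0, rmap, part, n_boot=50, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)
        assert res.intercept == pytest.approx(1.0)

    def test_negated_relationship_gives_rho_minus_one(self):
        part = _toy_partition()
        rmap = ReceptorMap(np.linspace(0.5, 2.0, 12))
        dens = rmap.network_means(part)
        res = correlate_receptors(-2.0 * dens, rmap, part, n_boot=50, seed=0)
        assert res.rho == pytest.approx(-1.0)

    def test_matches_direct_summation_oracle_on_toy_table(self):
        part = _toy_partition()
        rmap = ReceptorMap(np.array([1.0, 3.0, 2.0, 2.0, 5.0, 4.0, 1.0, 2.0, 6.0, 5.0, 4.0, 2.0]))
        peaks = np.array([0.9, 2.2, 4.4, 1.4, 5.2, 1.9])
        res = correlate_receptors(peaks, rmap, part, n_boot=10, seed=0)
        x = rmap.network_means(part)
        n = 6
        mx, my = x.mean(), peaks.mean()
        cov = sum((a - mx) * (b - my) for a, b in zip(x, peaks))
        rho_oracle = cov / (sum((a - mx) ** 2 for a in x) ** 0.5 * sum((b - my) ** 2 for b in peaks) ** 0.5)
        assert res.rho == pytest.approx(rho_oracle, abs=1e-10)

    def test_zero_variance_rejected(self):
        part = _toy_partition()
        rmap = ReceptorMap(np.ones(12))
        with pytest.raises(ParameterError):
            correlate_receptors(np.arange(6.0), rmap, part, n_boot=10, seed=0)

    def test_bootstrap_mean_near_rho_for_strong_relationship(self):
        part = _toy_partition()
        rmap = ReceptorMap(np.linspace(0.5, 2.0, 12))
        dens = rmap.network_means(part)
        rng = np.random.default_rng(8)
        res = correlate_receptors(dens + 0.01 * rng.standard_normal(6), rmap, part,
                                  n_boot=1000, seed=1)
        assert res.boot_mean == pytest.approx(res.rho, abs=0.1)


class TestRhoVsIntensity:
    def test_planted_mid_grid_coupling_yields_inverted_u(self):
        # dM/dF tracks receptor density only at mid-grid amplitudes; at the
        # edges it tracks an anticorrelated pattern, so rho(F) peaks mid-grid
        part = _toy_partition()
        rmap = ReceptorMap(np.linspace(0.5, 2.0, 12))
        dens = rmap.network_means(part)
        anti = dens.max() + dens.min() - dens  # reversed ranking
        fext = 0.001 * np.arange(9)
        bump = np.exp(-((fext - fext[4]) ** 2) / (2 * (0.0015) ** 2))
        times = 10.0 * np.arange(3)
        ramp = np.array([0.0, 1.0, 2.0])
        surf_a, surf_b = {}, {}
        for k, name in enumerate(part.networks):
            n_rsn = part.size(name)
            slope = bump * dens[k] + (1 - bump) * anti[k]
            dM = np.concatenate([[0.0], np.cumsum((slope[1:] + slope[:-1]) / 2 * np.diff(fext))])
            M = ramp[None, :, None] * dM[None, None, :] * n_rsn
            surf_a[name] = ReactivitySurface(np.tile(M, (2, 1, 1)), times, fext, name, n_rsn)
            surf_b[name] = ReactivitySurface(np.zeros((2, 3, 9)), times, fext, name, n_rsn)
        grid, means, sds = rho_vs_intensity(surf_a, surf_b, rmap, part, n_boot=100, seed=5)
        assert grid.size == 9 and means.size == 9
        interior = means[2:7]
        assert np.nanargmax(means) in range(2, 7)
        assert np.nanmax(interior) > 0.8
        assert means[0] < 0.0 and means[-1] < 0.5

    def test_constant_response_is_flagged_not_raised(self):
        part = _toy_partition()
        rmap = ReceptorMap(np.linspace(0.5, 2.0, 12))
        fext = 0.001 * np.arange(5)
        times = 10.0 * np.arange(3)
        flat = {n: ReactivitySurface(np.zeros((1, 3, 5)), times, fext, n, part.size(n))
                for n in part.networks}
        with pytest.warns(UserWarning, match="rho undefined"):
            grid, means, sds = rho_vs_intensity(flat, flat, rmap, part, n_boot=10, seed=0)
        assert np.all(np.isnan(means))


class TestPerturbationSurfaceProtocol:
    def test_stub_simulator_reproduces_planted_distances(self):
        # inject a stub integrator whose output depends only on (a_post,
        # amplitude): the surface must equal the independently computed FCD
        # distances, with the F_ext = 0 column matching unperturbed runs
        from wbhopf import BOLDLikeSeries, WindowSpec, compute_fcd, fcd_distance, make_connectome, make_frequencies
        from wbhopf.reactivity import perturbation_surface

        net = make_connectome(6, seed=1)
        freqs = make_frequencies(6, seed=2)
        part = RSNPartition({"Vis": (0, 1), "ES": (2, 3), "Aud": (4, 5)})
        spec = WindowSpec(30.0, 10.0)
        calls = []

        def stub(net_, freqs_, sched, cfg, pert=None):
            calls.append((sched, pert))
            key = abs(hash((round(sched.a_post, 9), round(pert.amplitude, 9)))) % 2**31
            rng = np.random.default_rng(key)
            return BOLDLikeSeries(rng.standard_normal((6, 60)), tr=2.0)

        target = compute_fcd(BOLDLikeSeries(np.random.default_rng(0).standard_normal((6, 60)), tr=2.0), spec)
        ap = APSampling(np.array([100.0, 110.0, 120.0]), np.array([0.05, 0.02, -0.01]))
        fext = np.array([0.0, 0.005, 0.01])
        surf = perturbation_surface(net, freqs, target, ap, fext, "ES", part,
                                    n_runs=1, seed=4, t_inject=96.0, a0=0.07,
                                    simulate_fn=stub)
        assert surf.values.shape == (1, 3, 3)
        # protocol: constant-post schedules at each a_p, forcing on ES from t_inject
        scheds = [c[0] for c in calls]
        perts = [c[1] for c in calls]
        assert {s.a_post for s in scheds} == {0.05, 0.02, -0.01}
        assert all(s.a0 == 0.07 and s.t_inject == 96.0 for s in scheds)
        assert all(p.target_nodes == (2, 3) and p.onset == 96.0 for p in perts)
        # planted distances reproduced cell by cell
        for i, a_p in enumerate(ap.a_values):
            for j, f in enumerate(fext):
                key = abs(hash((round(a_p, 9), round(f, 9)))) % 2**31
                rng = np.random.default_rng(key)
                series = BOLDLikeSeries(rng.standard_normal((6, 60)), tr=2.0)
                expected = fcd_distance(compute_fcd(series, spec), target, normalized=True)
                assert surf.values[0, i, j] == pytest.approx(expected, abs=1e-12)
        # F_ext = 0 column is independent of forcing by construction
        assert np.all(np.isfinite(surf.values[:, :, 0]))

    def test_nonuniform_or_missing_zero_grid_rejected(self):
        from wbhopf import make_connectome, make_frequencies
        from wbhopf.reactivity import perturbation_surface

        net = make_connectome(4, seed=1)
        freqs = make_frequencies(4, seed=2)
        part = RSNPartition({"Vis": (0, 1), "ES": (2, 3)})
        ap = APSampling(np.array([10.0, 20.0]), np.array([0.05, 0.02]))
        target = None
        with pytest.raises(ParameterError):
            perturbation_surface(net, freqs, target, ap, np.array([0.0, 0.001, 0.004]),
                                 "Vis", part)
        with pytest.raises(ParameterError):
            perturbation_surface(net, freqs, target, ap, np.array([0.001, 0.002, 0.003]),
                                 "Vis", part)
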