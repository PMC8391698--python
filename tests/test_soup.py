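"""Soup simulation, Markovian partition, canonical correlation,
synchronisation manifold, event-related averaging."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from bayesmech.soup import (
    ERPResult,
    SoupConfig,
    SoupState,
    SyncManifold,
    cca,
    cca_internal_external,
    erp_timelock,
    fit_sync_manifold,
    isolated_chem_trajectory,
    partition_soup,
    permutation_null_cca,
    select_events,
    simulate_soup,
    timelock_average,
)


def static_state(positions, coupling_length=1.0, chem=None):
    """Synthetic SoupState with frozen geometry (for partition tests)."""
    positions = np.asarray(positions, float)
    n = positions.shape[0]
    T = 4
    cfg = SoupConfig(
        n_molecules=n,
        coupling_length=coupling_length,
        dt=0.5,
        t_total=1.5,
        analysis_window=1.5,
    )
    pos = np.broadcast_to(positions, (T, n, 2)).copy()
    chem_arr = np.zeros((T, n, 3)) if chem is None else chem
    return SoupState(
        times=0.5 * np.arange(T),
        positions=pos,
        velocities=np.zeros((T, n, 2)),
        chem=chem_arr,
        config=cfg,
    )


class TestSimulateSoup:
    def test_decoupled_limit_reproduces_isolated_streams(self):
        cfg = dataclasses.replace(
            SoupConfig().mini(seed=3), coupling_scale=0.0, force_gain=0.0,
            t_total=4.0, analysis_window=2.0,
        )
        state = simulate_soup(cfg)
        for molecule in (0, 4, 8):
            iso = isolated_chem_trajectory(cfg, molecule)
            np.testing.assert_array_equal(state.chem[:, molecule, :], iso)

    def test_decoupled_cross_covariance_vanishes(self):
        cfg = dataclasses.replace(
            SoupConfig().mini(seed=7), coupling_scale=0.0, force_gain=0.0,
        )
        state = simulate_soup(cfg)
        sl = state.analysis_slice()
        # subsample past the Lorenz decorrelation time (~1 unit)
        sub = state.chem[sl][:: int(2.0 / cfg.dt)]
        n = sub.shape[0]
        z = (sub[:, :, 2] - sub[:, :, 2].mean(0)) / sub[:, :, 2].std(0)
        for i, j in ((0, 4), (2, 7), (3, 8)):
            r = np.mean(z[:, i] * z[:, j])
            assert abs(r) < 3.0 / np.sqrt(n)

    def test_noise_free_molecule_matches_reference_lorenz(self):
        def lorenz(t, c):
            x, y, z = c
            return [10.0 * (y - x), x * (28.0 - z) - y, x * y - 8.0 / 3.0 * z]

        def max_error(dt, horizon):
            cfg = SoupConfig(
                n_molecules=1, chem_noise=0.0, motion_noise=0.0,
                coupling_scale=0.0, force_gain=0.0,
                dt=dt, t_total=horizon, analysis_window=horizon / 2, seed=0,
            )
            state = simulate_soup(cfg)
            sol = solve_ivp(lorenz, (0, horizon), state.chem[0, 0],
                            t_eval=state.times, rtol=1e-11, atol=1e-12)
            return np.max(np.abs(state.chem[:, 0, :] - sol.y.T))

        # accurate at a short horizon, and first-order convergent in dt
        # (chaos amplifies the residual error exponentially beyond that)
        assert max_error(1e-4, 1.0) < 0.15
        ratio = max_error(2e-4, 2.0) / max_error(1e-4, 2.0)
        assert 1.6 < ratio < 2.4

    def test_seed_determinism_end_to_end(self, mini_soup_state):
        state2 = simulate_soup(SoupConfig().mini(seed=1))
        np.testing.assert_array_equal(mini_soup_state.chem, state2.chem)
        np.testing.assert_array_equal(mini_soup_state.positions, state2.positions)
        part1 = partition_soup(mini_soup_state)
        part2 = partition_soup(state2)
        assert part1.labels == part2.labels
        m1 = cca_internal_external(mini_soup_state, part1)
        m2 = cca_internal_external(state2, part2)
        np.testing.assert_array_equal(
            m1.canonical_correlations, m2.canonical_correlations
        )

    def test_mini_run_stays_within_guard(self, mini_soup_state):
        assert not mini_soup_state.diverged
        cfg = mini_soup_state.config
        window = mini_soup_state.analysis_slice()
        assert (window.stop - window.start) * cfg.dt == pytest.approx(
            cfg.analysis_window, rel=0.01
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SoupConfig(dt=-0.1)
        with pytest.raises(ValueError):
            SoupConfig(analysis_window=100.0, t_total=10.0)


class TestPartitionSoup:
    def test_chain_labels_follow_chain_order(self):
        state = static_state([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0), (3.0, 0.0)])
        part = partition_soup(state)
        assert part.labels == ("internal", "active", "sensory", "external")

    def test_permuting_molecules_permutes_labels(self):
        pts = [(0.0, 0.0), (1.0, 0.0), (2.0, 0.0), (3.0, 0.0), (4.0, 0.0)]
        perm = [3, 0, 4, 1, 2]
        part1 = partition_soup(static_state(pts))
        part2 = partition_soup(static_state([pts[i] for i in perm]))
        assert tuple(part1.labels[i] for i in perm) == part2.labels

    def test_coincident_geometry_rejected(self):
        state = static_state([(0.0, 0.0)] * 5)
        with pytest.raises(ValueError, match="degenerate"):
            partition_soup(state)

    def test_rod_run_produces_all_roles(self, mini_soup_state):
        part = partition_soup(mini_soup_state)
        roles = set(part.labels)
        assert roles == {"internal", "active", "sensory", "external"}

    def test_empirical_precision_respects_blanket_sparsity(self, mini_soup_state):
        # Gaussian approximation on subsampled chem states: the partial
        # correlations between internal and external molecules are much
        # weaker than the strongest direct couplings (loose tolerance)
        state = mini_soup_state
        part = partition_soup(state)
        sl = state.analysis_slice()
        sub = state.chem[sl][:: int(0.1 / state.config.dt)]
        flat = sub.reshape(sub.shape[0], -1)
        P = np.linalg.inv(np.cov(flat.T))
        D = np.sqrt(np.diag(P))
        pc = np.abs(P / np.outer(D, D))
        np.fill_diagonal(pc, 0.0)
        sp = part.to_state_partition(3)
        cross = pc[np.ix_(list(sp.mu), list(sp.eta))]
        assert cross.max() < 0.5 * pc.max()

    def test_to_state_partition_maps_blocks(self):
        state = static_state([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0), (3.0, 0.0)])
        part = partition_soup(state)
        sp = part.to_state_partition(states_per_molecule=3)
        assert sp.mu == (0, 1, 2)
        assert sp.a == (3, 4, 5)
        assert sp.s == (6, 7, 8)
        assert sp.eta == (9, 10, 11)


class TestCCA:
    def test_exact_linear_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((500, 4))
        M = rng.standard_normal((4, 3))
        Y = X @ M
        corr, _, _ = cca(X, Y)
        assert corr[0] == pytest.approx(1.0, abs=1e-10)

    def test_population_value_recovered_under_noise(self):
        # linear mixing plus noise: compare the sample estimate to the
        # population canonical correlation of the constructed covariance
        rng = np.random.default_rng(5)
        p, n = 6, 10_000
        M = rng.standard_normal((p, p)) * 0.4
        sd = 0.5
        X = rng.standard_normal((n, p))
        Y = X @ M.T + sd * rng.standard_normal((n, p))
        Cxx = np.eye(p)
        Cyy = M @ M.T + sd**2 * np.eye(p)
        Cxy = M.T
        # population first canonical correlation from the generalized
        # eigenproblem Cxx^-1 Cxy Cyy^-1 Cyx
        vals = np.linalg.eigvals(
            np.linalg.inv(Cxx) @ Cxy @ np.linalg.inv(Cyy) @ Cxy.T
        )
        rho_pop = np.sqrt(np.max(vals.real))
        corr, _, _ = cca(X, Y)
        assert abs(corr[0] - rho_pop) < 0.02

    def test_independent_noise_below_permutation_null(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((10_000, 6))
        Y = rng.standard_normal((10_000, 6))
        corr, _, _ = cca(X, Y)
        null = permutation_null_cca(X, Y, n_perm=300, seed=1)
        assert corr[0] < np.quantile(null, 0.95)

    def test_agrees_with_sklearn_reference(self):
        from sklearn.cross_decomposition import CCA as SkCCA

        rng = np.random.default_rng(12)
        X = rng.standard_normal((2000, 4))
        Y = 0.5 * X @ rng.standard_normal((4, 3)) + rng.standard_normal((2000, 3))
        corr, a, b = cca(X, Y)
        sk = SkCCA(n_components=1, scale=True).fit(X, Y)
        u, v = sk.transform(X, Y)
        r_sk = np.corrcoef(u[:, 0], v[:, 0])[0, 1]
        assert corr[0] == pytest.approx(abs(r_sk), abs=1e-4)

    def test_loading_sign_convention(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((300, 3))
        Y = X @ rng.standard_normal((3, 2)) + 0.1 * rng.standard_normal((300, 2))
        _, a, _ = cca(X, Y)
        for j in range(a.shape[1]):
            nz = np.flatnonzero(np.abs(a[:, j]) > 1e-12)
            assert a[nz[0], j] > 0

    def test_rank_deficiency_warns(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((200, 3))
        X = np.column_stack([X, X[:, 0]])  # duplicate channel
        Y = rng.standard_normal((200, 2))
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            cca(X, Y)

    def test_synchronisation_exceeds_null_on_default_soup(self, mini_soup_state):
        part = partition_soup(mini_soup_state)
        manifold = cca_internal_external(mini_soup_state, part)
        sl = mini_soup_state.analysis_slice()
        internal = part.molecules("internal")
        external = part.molecules("external")
        X = mini_soup_state.chem[sl][:, internal, :].reshape(
            sl.stop - sl.start, -1
        )
        Y = mini_soup_state.velocities[sl][:, external, :].reshape(
            sl.stop - sl.start, -1
        )
        null = permutation_null_cca(X, Y, n_perm=300, seed=2)
        assert manifold.canonical_correlations[0] > np.quantile(null, 0.95)


class TestSyncManifold:
    def _manifold(self, x, y):
        k = 1
        return SyncManifold(
            canonical_correlations=np.array([1.0]),
            internal_loadings=np.zeros((1, k)),
            external_loadings=np.zeros((1, k)),
            internal_variates=np.asarray(x)[:, None],
            external_variates=np.asarray(y)[:, None],
        )

    def test_exact_linear_zero_residual(self):
        x = np.linspace(-2, 2, 100)
        y = 3.0 * x + 1.0
        man = fit_sync_manifold(self._manifold(x, y), order=1)
        assert man.residual_sd == pytest.approx(0.0, abs=1e-10)
        yhat, half = man.predict(x, with_interval=True)
        np.testing.assert_allclose(yhat, y, atol=1e-10)
        assert np.max(half) < 1e-8

    def test_cubic_recovery_and_interval_coverage(self):
        rng = np.random.default_rng(21)
        truth = lambda x: 1.0 + 0.5 * x - 0.3 * x**2 + 0.2 * x**3
        n, sd = 2000, 0.1
        x = rng.uniform(-2, 2, n)
        man = fit_sync_manifold(
            self._manifold(x, truth(x) + sd * rng.standard_normal(n)), order=5
        )
        grid = np.linspace(-1.8, 1.8, 50)
        assert np.max(np.abs(man.predict(grid) - truth(grid))) < 0.05
        # pooled coverage of the 90% prediction interval over replicates
        hits = total = 0
        for rep in range(60):
            y = truth(x) + sd * rng.standard_normal(n)
            man = fit_sync_manifold(self._manifold(x, y), order=5)
            y_new = truth(x) + sd * rng.standard_normal(n)
            yhat, half = man.predict(x, with_interval=True)
            hits += np.sum(np.abs(y_new - yhat) <= half)
            total += n
        assert 0.87 <= hits / total <= 0.93

    def test_residual_smaller_than_marginal_on_soup_run(self, mini_soup_state):
        part = partition_soup(mini_soup_state)
        man = cca_internal_external(mini_soup_state, part)
        man = fit_sync_manifold(man, order=5)
        marginal_sd = man.external_variates[:, 0].std()
        assert man.residual_sd < marginal_sd

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            fit_sync_manifold(self._manifold([0, 1, 2], [0, 1, 2]), order=5)


class TestEventAveraging:
    def test_identical_epochs_average_equals_epoch(self):
        template = np.sin(np.linspace(0, 4 * np.pi, 200))[:, None]
        sig = np.tile(template, (8, 1))
        events = [200 * k + 100 for k in range(1, 7)]
        epochs, avg = timelock_average(sig, events, pre=50, post=50)
        for ep in epochs:
            np.testing.assert_array_equal(ep, epochs[0])
        np.testing.assert_allclose(avg, epochs[0], rtol=0, atol=1e-14)

    def test_average_is_pointwise_mean_of_epochs(self):
        rng = np.random.default_rng(3)
        sig = rng.standard_normal((5000, 2))
        events = [500, 1500, 2500, 3500]
        epochs, avg = timelock_average(sig, events, pre=100, post=100)
        np.testing.assert_array_equal(avg, epochs.mean(axis=0))

    def test_noise_reduction_factor_root_k(self):
        rng = np.random.default_rng(33)
        W, K = 2000, 6
        template = np.sin(np.linspace(0, 6 * np.pi, W))
        epochs = template + rng.standard_normal((K, W))
        avg = epochs.mean(axis=0)
        resid_sd = (avg - template).std()
        expected = 1.0 / np.sqrt(K)
        se = expected / np.sqrt(2 * W)
        assert abs(resid_sd - expected) < 3 * se

    def test_select_events_exclusion_radius(self):
        t = np.arange(3000)
        sig = np.sin(2 * np.pi * t / 100.0)  # peaks every 100 samples
        events = select_events(sig, n_events=6, exclusion=250)
        assert len(events) <= 6
        assert np.all(np.diff(events) >= 250)

    def test_too_close_events_are_dropped_with_warning(self):
        # strictly sloped baseline so only the spikes are local maxima
        sig = -0.01 * np.arange(500.0)
        sig[100] += 3.0
        sig[120] += 2.9
        sig[140] += 2.8
        with pytest.warns(RuntimeWarning, match="separable"):
            events = select_events(sig, n_events=3, exclusion=100)
        assert len(events) == 1
        assert events[0] == 100

    def test_erp_pipeline_on_soup_run(self, mini_soup_state):
        part = partition_soup(mini_soup_state)
        man = cca_internal_external(mini_soup_state, part)
        man = fit_sync_manifold(man)
        erp = erp_timelock(mini_soup_state, part, man, n_events=6,
                           window=(0.5, 1.5))
        assert isinstance(erp, ERPResult)
        assert erp.epochs.shape[0] >= 1
        np.testing.assert_allclose(erp.average, erp.epochs.mean(axis=0))
        assert erp.epochs.shape[1] == len(erp.time_axis)
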