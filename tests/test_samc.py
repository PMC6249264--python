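import numpy as np
import pytest

import permherit as ph
from permherit.derivative import DerivativeContext
from permherit.samc import SAMCState, _samc_kernel, _xi_matrix


class TestMakePartition:
    def test_standard_partition(self):
        part = ph.make_partition(0.5, 50)
        assert len(part.edges) == 52
        widths = np.diff(part.edges[:51])
        np.testing.assert_allclose(widths, 0.01)
        assert part.edges[-2:].tolist() == [0.5, 1.0]

    def test_degenerate_two_interval_partition(self):
        part = ph.make_partition(0.4, 1)
        np.testing.assert_allclose(part.edges, [0.0, 0.4, 1.0])

    def test_small_example_edges(self):
        part = ph.make_partition(0.3, 3)
        np.testing.assert_allclose(part.edges, [0.0, 0.1, 0.2, 0.3, 1.0])

    @pytest.mark.parametrize("H2", [0.0, 1.0])
    def test_boundary_anchor_rejected(self, H2):
        with pytest.raises(ValueError, match="interior"):
            ph.make_partition(H2, 10)


class TestProposePermutation:
    def test_n_two_always_swaps(self, rng):
        tau = ph.propose_permutation(np.array([0, 1]), rng)
        np.testing.assert_array_equal(tau, [1, 0])

    def test_exactly_one_transposition(self, rng):
        perm = rng.permutation(9)
        tau = ph.propose_permutation(perm, rng)
        assert int((perm != tau).sum()) == 2

    def test_chain_reaches_all_permutations(self, rng):
        # transpositions generate S_4: a long walk visits all 24 states
        perm = np.arange(4)
        seen = {tuple(perm)}
        for _ in range(2000):
            perm = ph.propose_permutation(perm, rng)
            seen.add(tuple(perm))
        assert len(seen) == 24

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError, match="n < 2"):
            ph.propose_permutation(np.array([0]), rng)


@pytest.fixture(scope="module")
def samc_instance():
    """n=20 centered kinship with an interior-anchor phenotype."""
    Z = ph.simulate_genotypes(ph.SimConfig(n=20, m=40, seed=6))
    eig = ph.eigendecompose(ph.build_kinship(Z))
    ctx = DerivativeContext.build(eig)
    for k in range(50):
        y = ph.simulate_lmm_phenotype(eig, None, None, 0.7, 1.0, seed=600 + k)
        H2 = ph.reml_fit(ph.PhenotypeStudy(y), eig).h2_hat
        if 0.15 < H2 < 0.95:
            return ph.PhenotypeStudy(y), eig, ctx, H2
    raise RuntimeError("no interior-anchor instance found")


def _fresh_state(study, ctx, part, rng, t0=1000):
    perm = rng.permutation(study.n)
    u = ctx.basis.T @ study.y[perm]
    J = ph.interval_of(study.y[perm], part, ctx)
    return SAMCState(
        theta=np.zeros(part.D + 2 - 1), perm=perm, u_rot=u, t=1, t0=t0, J_current=J
    )


class TestIntervalOf:
    def test_flat_likelihood_goes_to_interval_one(self):
        # centering-projector kinship: every retained eigenvalue is 1, the
        # likelihood is flat and all xi vanish -> the <=0-at-zero rule
        n = 10
        C = np.eye(n) - np.ones((n, n)) / n
        eig = ph.eigendecompose(C)
        ctx = DerivativeContext.build(eig)
        part = ph.make_partition(0.5, 5)
        y = np.random.default_rng(0).normal(size=n)
        assert ph.interval_of(y, part, ctx) == 1

    def test_original_phenotype_lands_in_last_interval(self, samc_instance):
        study, eig, ctx, H2 = samc_instance
        part = ph.make_partition(H2, 10)
        assert ph.interval_of(study.y, part, ctx) == part.D + 1

    def test_matches_full_reml_interval(self, samc_instance, rng):
        study, eig, ctx, H2 = samc_instance
        part = ph.make_partition(H2, 10)
        checked = 0
        for _ in range(300):
            yp = study.y[rng.permutation(study.n)]
            h2p = ph.reml_fit(ph.PhenotypeStudy(yp), eig).h2_hat
            # exact boundary estimates have well-defined intervals; skip
            # only interior estimates within tolerance of an edge
            if h2p not in (0.0, 1.0) and np.min(np.abs(part.edges - h2p)) < 1e-6:
                continue
            checked += 1
            expected = int(np.searchsorted(part.edges[1:-1], h2p, side="right")) + 1
            assert ph.interval_of(yp, part, ctx, check_unimodal=True) == expected
        assert checked > 250

    def test_unimodality_check_agrees_with_fast_path(self, samc_instance, rng):
        study, eig, ctx, H2 = samc_instance
        part = ph.make_partition(H2, 10)
        for _ in range(50):
            yp = study.y[rng.permutation(study.n)]
            assert ph.interval_of(yp, part, ctx, check_unimodal=True) == ph.interval_of(
                yp, part, ctx
            )


class TestMhStep:
    def test_uniform_theta_always_accepts(self, samc_instance, rng):
        study, eig, ctx, H2 = samc_instance
        part = ph.make_partition(H2, 10)
        state = _fresh_state(study, ctx, part, rng)
        for _ in range(50):
            new = ph.mh_step(state, part, ctx, rng, study.y)
            assert not np.array_equal(new.perm, state.perm)  # always moved
            state = new

    def test_incremental_rotation_stays_consistent(self, samc_instance, rng):
        study, eig, ctx, H2 = samc_instance
        part = ph.make_partition(H2, 10)
        state = _fresh_state(study, ctx, part, rng)
        for _ in range(200):
            state = ph.mh_step(state, part, ctx, rng, study.y)
        np.testing.assert_allclose(
            state.u_rot, ctx.basis.T @ study.y[state.perm], atol=1e-8
        )

    def test_biased_theta_rejects_overweighted_moves(self, samc_instance, rng):
        study, eig, ctx, H2 = samc_instance
        part = ph.make_partition(H2, 10)
        state = _fresh_state(study, ctx, part, rng)
        # make every other interval massively overweighted: moves out of
        # the current interval are (almost) never accepted
        state.theta[:] = 50.0
        state.theta[state.J_current - 1] = 0.0
        stuck = 0
        for _ in range(100):
            new = ph.mh_step(state, part, ctx, rng, study.y)
            stuck += new.J_current == state.J_current
            state = new
        assert stuck == 100


class TestSamcUpdate:
    def _state(self, t, t0=1000, D=4):
        return SAMCState(
            theta=np.zeros(D + 1), perm=np.arange(3), u_rot=np.zeros(3),
            t=t, t0=t0, J_current=1,
        )

    def test_gain_is_one_before_pivot(self):
        new = ph.samc_update(self._state(t=500), 2)
        assert new.theta[1] == pytest.approx(1.0 - 1.0 / 5)

    def test_gain_halves_at_twice_pivot(self):
        new = ph.samc_update(self._state(t=2000), 2)
        assert new.theta[1] == pytest.approx(0.5 * (1.0 - 1.0 / 5))

    def test_theta_sum_conserved(self, rng):
        state = self._state(t=1)
        for _ in range(10_000):
            state = ph.samc_update(state, int(rng.integers(1, 6)))
        assert abs(state.theta.sum()) < 1e-9

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            ph.samc_update(self._state(t=1), 7)


class TestSamcPvalue:
    def test_uniform_initial_estimate(self, samc_instance):
        study, eig, ctx, H2 = samc_instance
        res = ph.samc_pvalue(study, ctx, H2, D=10, n_iter=0, seed=0)
        assert res.p_value == pytest.approx(1.0 / 11)

    def test_deterministic_given_seed(self, samc_instance):
        study, eig, ctx, H2 = samc_instance
        a = ph.samc_pvalue(study, ctx, H2, D=10, n_iter=20_000, seed=5)
        b = ph.samc_pvalue(study, ctx, H2, D=10, n_iter=20_000, seed=5)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_estimate_invariant_to_theta_shift(self, samc_instance):
        study, eig, ctx, H2 = samc_instance
        res = ph.samc_pvalue(study, ctx, H2, D=10, n_iter=20_000, seed=5)
        from permherit.samc import _theta_to_p

        assert _theta_to_p(res.theta + 7.3) == pytest.approx(res.p_value, rel=1e-12)

    def test_theta_sum_near_zero_after_long_run(self, samc_instance):
        study, eig, ctx, H2 = samc_instance
        res = ph.samc_pvalue(study, ctx, H2, D=10, n_iter=200_000, seed=3)
        assert abs(res.theta.sum()) < 1e-8

    def test_matches_exhaustive_truth_within_factor_two(self):
        Z = ph.simulate_genotypes(ph.SimConfig(n=7, m=30, seed=16))
        eig = ph.eigendecompose(ph.build_kinship(Z))
        ctx = DerivativeContext.build(eig)
        for k in range(60):
            y = ph.simulate_lmm_phenotype(eig, None, None, 0.9, 1.0, seed=200 + k)
            study = ph.PhenotypeStudy(y)
            H2 = ph.reml_fit(study, eig).h2_hat
            if 0.1 < H2 < 0.95:
                break
        p_true = ph.exhaustive_permutation_pvalue(study, eig, anchor=H2)
        res = ph.samc_pvalue(study, ctx, H2, D=10, t0=1000, n_iter=50_000, seed=1)
        assert p_true / 2 <= res.p_value <= 2 * p_true

    def test_all_nonempty_intervals_visited(self, samc_instance):
        study, eig, ctx, H2 = samc_instance
        res = ph.samc_pvalue(study, ctx, H2, D=10, n_iter=100_000, seed=2)
        # intervals the chain found occupied must all keep being revisited
        assert res.visits[-1] > 0  # the p-value interval itself
        assert (res.visits > 0).sum() >= 2


class TestDetailedBalance:
    def test_frozen_theta_visits_match_enumeration(self):
        """At frozen theta the chain's stationary visit frequencies over an
        exhaustively enumerable n=6 space match exp(-theta_J) |S_J| / Z."""
        Z = ph.simulate_genotypes(ph.SimConfig(n=6, m=25, seed=23))
        eig = ph.eigendecompose(ph.build_kinship(Z))
        ctx = DerivativeContext.build(eig)
        for k in range(50):
            y = ph.simulate_lmm_phenotype(eig, None, None, 0.8, 1.0, seed=700 + k)
            H2 = ph.reml_fit(ph.PhenotypeStudy(y), eig).h2_hat
            if 0.2 < H2 < 0.95:
                break
        study = ph.PhenotypeStudy(y)
        D = 3
        part = ph.make_partition(H2, D)
        # exact subset sizes from full REML on all 720 permutations
        _, ests = ph.exhaustive_permutation_pvalue(
            study, eig, anchor=H2, return_estimates=True
        )
        counts = np.array([
            ((ests >= part.edges[j]) & (ests < part.edges[j + 1])).sum()
            for j in range(D)
        ] + [(ests >= part.edges[D]).sum()], dtype=float)
        xi_edges = np.ascontiguousarray(_xi_matrix(part, ctx))
        theta, n_acc, ckpts, visits = _samc_kernel(
            np.ascontiguousarray(ctx.basis), np.ascontiguousarray(study.y),
            xi_edges, D, 1000.0, 1_000_000, 12345, 10_000, 10, True,
        )
        # frozen theta == 0: stationary distribution proportional to |S_J|
        expected = counts / counts.sum()
        observed = visits / visits.sum()
        mask = expected > 0.02
        np.testing.assert_allclose(observed[mask], expected[mask], rtol=0.05)
        assert visits[expected == 0].sum() <= visits.sum() * 1e-3
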