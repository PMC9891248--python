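import math

import numpy as np
import pytest
from scipy.special import logsumexp

from dedumi.candidates import CandidateSet, admissible_pairs, initialize_params
from dedumi.error_model import ErrorProfile, emission_logprob
from dedumi.model_em import (
    GAMMA_TOL,
    ModelParams,
    PenaltyConfig,
    compute_emissions,
    deduplicate,
    e_step,
    fit_em,
    log_likelihood,
    m_step,
    optimize_gamma_row,
    penalty_value,
)

from conftest import make_readset

PROFILE = ErrorProfile.phred_default()


def small_instance(seed=0, n=30):
    """Random small dataset with 3 UMIs x 3 haplotypes and scattered errors."""
    rng = np.random.default_rng(seed)
    umis = ["AAAA", "CCCC", "GGGG"]
    haps = ["ACGTACGT", "TTTTCCCC", "GGGGAAAA"]
    triples = []
    for _ in range(n):
        u = umis[rng.integers(3)]
        h = haps[rng.integers(3)]
        # sprinkle an occasional error into the observed copies
        if rng.random() < 0.2:
            pos = rng.integers(len(h))
            h = h[:pos] + "ACGT"[rng.integers(4)] + h[pos + 1 :]
        triples.append((u, h, int(rng.integers(20, 41))))
    rs = make_readset(triples)
    U = CandidateSet(umis, [10, 10, 10], "umi")
    H = CandidateSet(haps, [10, 10, 10], "haplotype")
    mask = np.ones((3, 3), dtype=bool)
    eta = np.array([0.5, 0.3, 0.2])
    gamma = rng.dirichlet(np.ones(3), size=3)
    params = ModelParams(eta, gamma, umis, haps, mask)
    return rs, U, H, params


def brute_force_loglik(params, rs, profile):
    """Dense double-loop oracle for the observed log likelihood."""
    total = 0.0
    for r in rs.reads:
        terms = []
        for s, u in enumerate(params.umis):
            lb = emission_logprob(r.umi, r.umi_quals, u, profile, allow_indels=False)
            for k, h in enumerate(params.haplotypes):
                if not params.mask[s, k] or params.gamma[s, k] == 0:
                    continue
                lr = emission_logprob(r.seq, r.quals, h, profile, allow_indels=True)
                terms.append(
                    math.log(params.eta[s]) + lb + math.log(params.gamma[s, k]) + lr
                )
        total += logsumexp(terms)
    return total


class TestLogLikelihood:
    def test_single_component_collapse(self):
        rs = make_readset([("AAAA", "ACGTACGT")])
        params = ModelParams(
            np.array([1.0]), np.array([[1.0]]), ["AAAA"], ["ACGTACGT"], np.ones((1, 1), bool)
        )
        ll = log_likelihood(params, rs, PROFILE)
        r = rs.reads[0]
        expected = emission_logprob(r.umi, r.umi_quals, "AAAA", PROFILE, allow_indels=False)
        expected += emission_logprob(r.seq, r.quals, "ACGTACGT", PROFILE, allow_indels=True)
        assert ll == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_oracle(self, seed):
        rs, _, _, params = small_instance(seed)
        assert log_likelihood(params, rs, PROFILE) == pytest.approx(
            brute_force_loglik(params, rs, PROFILE), abs=1e-9
        )

    def test_invariant_to_read_order(self):
        rs, _, _, params = small_instance(3)
        perm = np.random.default_rng(0).permutation(rs.n)
        assert log_likelihood(params, rs, PROFILE) == pytest.approx(
            log_likelihood(params, rs.subset(perm), PROFILE), abs=1e-9
        )


class TestPenalty:
    def test_zero_gamma_zero_penalty(self):
        assert penalty_value(np.zeros((3, 4)), PenaltyConfig(rho=5.0)) == 0.0

    def test_single_entry_closed_form(self):
        cfg = PenaltyConfig(rho=2.0, omega=1e-6)
        g = np.zeros((2, 2))
        g[0, 0] = 1e-6
        assert penalty_value(g, cfg) == pytest.approx(2.0 * math.log(2.0), abs=1e-12)

    def test_monotone_in_each_entry(self):
        cfg = PenaltyConfig(rho=3.0)
        g = np.full((2, 2), 0.25)
        base = penalty_value(g, cfg)
        g2 = g.copy()
        g2[1, 1] += 0.1
        assert penalty_value(g2, cfg) > base


class TestEStep:
    def test_truncation_noop_when_T_covers_all_pairs(self):
        rs, _, _, params = small_instance(4)
        full = e_step(params, rs, PROFILE, T=9)
        trunc = e_step(params, rs, PROFILE, T=100)
        assert np.allclose(full.probs, trunc.probs, atol=1e-12)

    def test_posterior_rows_sum_to_one(self):
        rs, _, _, params = small_instance(5)
        post = e_step(params, rs, PROFILE, T=3)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)
        assert (np.count_nonzero(post.probs, axis=1) <= 3).all()

    def test_matches_dense_posterior_oracle(self):
        rs, _, _, params = small_instance(6)
        post = e_step(params, rs, PROFILE, T=100)
        for i, r in enumerate(rs.reads):
            logs = np.full((3, 3), -np.inf)
            for s, u in enumerate(params.umis):
                lb = emission_logprob(r.umi, r.umi_quals, u, PROFILE, allow_indels=False)
                for k, h in enumerate(params.haplotypes):
                    lr = emission_logprob(r.seq, r.quals, h, PROFILE, allow_indels=True)
                    logs[s, k] = (
                        math.log(params.eta[s]) + lb + math.log(params.gamma[s, k]) + lr
                    )
            expected = np.exp(logs - logsumexp(logs))
            dense = np.zeros((3, 3))
            dense[post.pair_s, post.pair_k] = post.probs[i]
            assert np.allclose(dense, expected, atol=1e-9)

    def test_exact_umi_match_dominates(self):
        rs = make_readset([("AAAA", "ACGTACGT")])
        params = ModelParams(
            np.array([0.5, 0.5]),
            np.array([[1.0], [1.0]]),
            ["AAAA", "ATTA"],
            ["ACGTACGT"],
            np.ones((2, 1), bool),
        )
        post = e_step(params, rs, PROFILE, T=10)
        dense = np.zeros(2)
        dense[post.pair_s] = post.probs[0]
        assert dense[0] > 0.999  # ratio (1-p)^2 vs (p/3)^2 at Q40


def grid_row_objective(c, gamma, cfg):
    """Penalized expected complete-data row objective (for the grid oracle)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(c > 0, c * np.log(gamma), 0.0)
    if np.any((c > 0) & (gamma == 0)):
        return -np.inf
    return ll.sum() - cfg.rho * np.log1p(gamma / cfg.omega).sum()


def grid_search_row(c, cfg, step=1e-3):
    """1-simplex grid maximizer of the penalized row objective."""
    ts = np.arange(0.0, 1.0 + step / 2, step)
    best_t, best_f = None, -np.inf
    for t in ts:
        f = grid_row_objective(np.asarray(c), np.array([t, 1.0 - t]), cfg)
        if f > best_f:
            best_t, best_f = t, f
    return np.array([best_t, 1.0 - best_t])


class TestMStep:
    def test_penalty_off_gives_multinomial_mle(self):
        c = np.array([3.0, 7.0, 10.0])
        g = optimize_gamma_row(c, PenaltyConfig(rho=0.0))
        assert np.allclose(g, c / c.sum(), atol=1e-12)

    def test_small_count_entry_eliminated(self):
        g = optimize_gamma_row(np.array([30.0, 2.0]), PenaltyConfig(rho=10.0))
        assert np.allclose(g, [1.0, 0.0], atol=1e-9)

    def test_collision_kept_when_both_counts_exceed_rho(self):
        g = optimize_gamma_row(np.array([30.0, 25.0]), PenaltyConfig(rho=10.0))
        assert g[0] > 0 and g[1] > 0
        # omega -> 0 limit: proportional to (c - rho)+
        assert np.allclose(g, [20 / 35, 15 / 35], atol=1e-6)

    @pytest.mark.parametrize(
        "c,rho",
        [((30.0, 2.0), 10.0), ((30.0, 25.0), 10.0), ((3.0, 1.0), 5.0), ((10.0, 0.0), 3.0), ((6.0, 5.9), 5.0)],
    )
    def test_matches_simplex_grid_oracle(self, c, rho):
        cfg = PenaltyConfig(rho=rho)
        ours = optimize_gamma_row(np.array(c), cfg)
        grid = grid_search_row(c, cfg, step=1e-3)
        # clamped-to-zero entries correspond to grid points at the boundary
        assert np.abs(ours - grid).max() <= 2e-3

    def test_all_counts_below_rho_keeps_argmax(self):
        g = optimize_gamma_row(np.array([3.0, 1.0, 2.0]), PenaltyConfig(rho=5.0))
        assert np.allclose(g, [1.0, 0.0, 0.0])

    def test_mstep_updates_eta_from_posterior_mass(self):
        rs, _, _, params = small_instance(7)
        post = e_step(params, rs, PROFILE, T=100)
        new = m_step(post, rs, params, PenaltyConfig(rho=0.0))
        assert new.eta.sum() == pytest.approx(1.0, abs=1e-9)
        c = post.expected_counts(3, 3)
        assert np.allclose(new.eta, c.sum(axis=1) / rs.n, atol=1e-12)
        new.validate()


class TestFitEm:
    def test_error_free_input_converges_fast_with_binary_gamma(self):
        triples = (
            [("AAAA", "ACGTACGT")] * 12
            + [("CCCC", "ACGTACGT")] * 9
            + [("GGGG", "TTTTCCCC")] * 10
        )
        rs = make_readset(triples)
        from dedumi.candidates import denoise_umis, denoise_haplotypes

        U = denoise_umis(rs)
        H = denoise_haplotypes(rs, PROFILE)
        fit = fit_em(rs, U, H, PROFILE, PenaltyConfig(rho=2.0))
        assert fit.converged and fit.iterations <= 3
        assert np.all((fit.params.gamma < 1e-9) | (fit.params.gamma > 1 - 1e-9))
        res = deduplicate(fit.params, rs.n)
        assert res.abundance_profile() == {"ACGTACGT": 2, "TTTTCCCC": 1}

    def test_trace_monotone_at_full_truncation(self, sim_tiny_noisy):
        """Exact EM (T covering all admissible pairs) never decreases the
        penalized observed log likelihood."""
        rs = sim_tiny_noisy.readset
        from dedumi.pipeline import build_candidates

        U, H, profile = build_candidates(rs)
        fit = fit_em(rs, U, H, profile, PenaltyConfig(rho=3.0), T=len(U) * len(H))
        diffs = np.diff(fit.trace)
        assert diffs.min() >= -1e-6 * max(1.0, np.abs(fit.trace).max())

    def test_sum_dedup_equals_positive_pairs(self, sim_tiny_noisy):
        rs = sim_tiny_noisy.readset
        from dedumi.pipeline import run_pipeline

        res = run_pipeline(rs, rho=3.0)
        params = res.fit.params
        n_positive = sum(
            int((params.gamma[s] > GAMMA_TOL).sum())
            for s in range(params.n_umis)
            if rs.n * params.eta[s] >= 1.0 - 1e-9
        )
        assert int(res.result.full_abundance.sum()) == n_positive


class TestDeduplicate:
    def _params(self, eta, gamma, umis=None, haps=None):
        gamma = np.asarray(gamma, dtype=float)
        N, K = gamma.shape
        return ModelParams(
            np.asarray(eta, dtype=float),
            gamma,
            umis or [f"U{s}" for s in range(N)],
            haps or [f"H{k}" for k in range(K)],
            np.ones((N, K), bool),
        )

    def test_formula(self):
        params = self._params([0.5, 0.5], [[1.0, 0.0], [1.0, 0.0]])
        res = deduplicate(params, n=10)
        assert list(res.full_abundance) == [2, 0]
        assert res.haplotypes == ["H0"]

    def test_collision_counts_both_unless_ncollision(self):
        params = self._params([1.0], [[0.6, 0.4]])
        both = deduplicate(params, n=10)
        assert list(both.full_abundance) == [1, 1]
        assert both.collisions == ["U0"]
        one = deduplicate(params, n=10, ncollision=True)
        assert list(one.full_abundance) == [1, 0]
        assert one.collisions == []

    def test_low_expected_abundance_umi_contributes_nothing(self):
        params = self._params([0.08, 0.92], [[1.0, 0.0], [0.0, 1.0]])
        res = deduplicate(params, n=10)  # n*eta_0 = 0.8 < 1
        assert list(res.full_abundance) == [0, 1]
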