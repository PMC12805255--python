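"""Cox partial-likelihood machinery: Breslow value/gradient, the MCP
coordinate-descent path, BIC selection, and the Newton refit, each checked
against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy.optimize import brentq
from sksurv.linear_model import CoxnetSurvivalAnalysis

from coxmds import coxpen


class TestPartialLikelihood:
    def test_null_model_closed_form(self, small_cox_problem):
        # at beta=0 the npll is the sum of log risk-set sizes over events
        prob = small_cox_problem
        n = len(prob["times"])
        design = np.column_stack([prob["P"], prob["U"]])
        v, _ = coxpen.neg_log_partial_likelihood(
            np.zeros(design.shape[1]), prob["times"], prob["events"], design
        )
        order = np.argsort(prob["times"])
        ev_sorted = prob["events"][order]
        expected = sum(np.log(n - i) for i in range(n) if ev_sorted[i])
        assert v == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        n, m = 30, 4
        X = rng.standard_normal((n, m))
        t = rng.exponential(1, n)
        ev = rng.binomial(1, 0.7, n)
        ev[0] = 1
        b = 0.3 * rng.standard_normal(m)
        _, g = coxpen.neg_log_partial_likelihood(b, t, ev, X)
        eps = 1e-6
        for j in range(m):
            bp, bm = b.copy(), b.copy()
            bp[j] += eps
            bm[j] -= eps
            vp, _ = coxpen.neg_log_partial_likelihood(bp, t, ev, X)
            vm, _ = coxpen.neg_log_partial_likelihood(bm, t, ev, X)
            assert g[j] == pytest.approx((vp - vm) / (2 * eps), rel=1e-5,
                                         abs=1e-6)

    def test_breslow_ties_match_brute_force(self, rng):
        # brute-force risk-set enumeration on a duplicated 5-subject
        # instance, where every event time is tied
        def brute(b, t, ev, X):
            eta = X @ b
            eta = eta - eta.mean()
            return sum(
                -(eta[i] - np.log(np.exp(eta[t >= t[i]]).sum()))
                for i in range(len(t))
                if ev[i]
            )

        X = rng.standard_normal((5, 2))
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ev = np.array([1, 1, 0, 1, 1])
        b = np.array([0.4, -0.2])
        t2, ev2, X2 = np.tile(t, 2), np.tile(ev, 2), np.vstack([X, X])
        for tt, ee, XX in ((t, ev, X), (t2, ev2, X2)):
            v, _ = coxpen.neg_log_partial_likelihood(b, tt, ee, XX)
            assert v == pytest.approx(brute(b, tt, ee, XX), rel=1e-10)

    def test_no_events_raises(self, rng):
        with pytest.raises(ValueError, match="no events"):
            coxpen.neg_log_partial_likelihood(
                np.zeros(2), rng.exponential(1, 10), np.zeros(10),
                rng.standard_normal((10, 2)),
            )


class TestNewtonRefit:
    def test_matches_lifelines(self, small_cox_problem):
        prob = small_cox_problem
        fit = coxpen.refit_unpenalized(
            prob["times"], prob["events"], prob["P"], prob["U"][:, 0],
            prob["U"][:, 1:],
        )
        df = pd.DataFrame(
            np.column_stack([prob["P"], prob["U"]]),
            columns=[f"x{i}" for i in range(8)],
        )
        df["T"], df["E"] = prob["times"], prob["events"]
        cph = CoxPHFitter().fit(df, "T", "E")
        mine = np.concatenate(
            [fit.beta_mediators, [fit.gamma_hat], fit.theta_hat]
        )
        np.testing.assert_allclose(mine, cph.params_.values, atol=1e-5)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)
        assert fit.converged

    def test_three_subject_analytic_score_root(self):
        # times (1,2,3), events (1,1,0), x=(0,1,0): the score equation
        # of the partial likelihood has a 1-d root we can find directly
        t = np.array([1.0, 2.0, 3.0])
        ev = np.array([1, 1, 0])
        x = np.array([0.0, 1.0, 0.0])

        def score(b):
            # event 1: risk {1,2,3}; event 2: risk {2,3}
            e = np.exp(b * x)
            s1 = x[0] - (x * e).sum() / e.sum()
            s2 = x[1] - (x[1:] * e[1:]).sum() / e[1:].sum()
            return s1 + s2

        root = brentq(score, -10, 10)
        fit = coxpen.refit_unpenalized(
            t, ev, np.empty((3, 0)), x, np.empty((3, 0))
        )
        assert fit.gamma_hat == pytest.approx(root, abs=1e-6)

    def test_empty_mediator_block(self, small_cox_problem):
        prob = small_cox_problem
        fit = coxpen.refit_unpenalized(
            prob["times"], prob["events"], np.empty((len(prob["times"]), 0)),
            prob["U"][:, 0], prob["U"][:, 1:],
        )
        assert fit.beta_mediators.shape == (0,)
        assert np.isfinite(fit.loglik)

    def test_separation_capped_and_flagged(self):
        # a perfectly separating covariate drives beta to +inf
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        ev = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = coxpen.refit_unpenalized(
            t, ev, np.empty((6, 0)), x, np.empty((6, 0))
        )
        assert not fit.converged
        assert abs(fit.gamma_hat) <= 20.0


class TestMcpPath:
    def test_lambda_max_zeroes_penalized_block(self, small_cox_problem):
        prob = small_cox_problem
        path = coxpen.fit_cox_mcp(
            prob["times"], prob["events"], prob["P"], prob["U"]
        )
        assert np.all(path.coefficients[0] == 0)
        assert np.all(np.diff(path.lambdas) < 0)

    def test_lambda_to_zero_matches_newton_mle(self, small_cox_problem):
        prob = small_cox_problem
        path = coxpen.fit_cox_mcp(
            prob["times"], prob["events"], prob["P"], prob["U"],
            lambda_seq=np.array([1e-6]),
        )
        fit = coxpen.refit_unpenalized(
            prob["times"], prob["events"], prob["P"], prob["U"][:, 0],
            prob["U"][:, 1:],
        )
        np.testing.assert_allclose(
            path.coefficients[0], fit.beta_mediators, atol=1e-4
        )

    def test_lasso_limit_matches_coxnet_oracle(self, rng):
        # with a -> inf the MCP solution solves the lasso-Cox problem;
        # standardize columns so the two penalty conventions coincide
        n, d = 200, 5
        P = rng.standard_normal((n, d))
        beta = np.array([0.8, -0.6, 0, 0, 0.4])
        tt = rng.exponential(np.exp(-(P @ beta)))
        cc = rng.exponential(2, n)
        T, E = np.minimum(tt, cc), (tt <= cc).astype(int)
        P = (P - P.mean(0)) / P.std(0)
        lam = 0.1
        path = coxpen.fit_cox_mcp(
            T, E, P, None, lambda_seq=np.array([lam]), a_mcp=1e12, tol=1e-9
        )
        y = np.array(
            [(bool(e), t) for e, t in zip(E, T)],
            dtype=[("e", bool), ("t", float)],
        )
        ref = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=[lam], normalize=False,
            fit_baseline_model=False, tol=1e-12, max_iter=100_000,
        ).fit(P, y)
        np.testing.assert_allclose(
            path.coefficients[0], ref.coef_.ravel(), atol=1e-4
        )

    def test_kkt_at_solution(self, small_cox_problem):
        # zero coordinates must satisfy |score_j| <= lam under the
        # (1/n)-scaled working objective, up to MCP's relaxed region
        prob = small_cox_problem
        n = len(prob["times"])
        Pstd = (prob["P"] - prob["P"].mean(0)) / prob["P"].std(0)
        lam = 0.15
        path = coxpen.fit_cox_mcp(
            prob["times"], prob["events"], Pstd, prob["U"],
            lambda_seq=np.array([lam]), tol=1e-9,
        )
        coef = np.concatenate([path.coefficients[0], path.unpenalized[0]])
        design = np.column_stack([Pstd, prob["U"] - prob["U"].mean(0)])
        _, g = coxpen.neg_log_partial_likelihood(
            coef, prob["times"], prob["events"], design
        )
        g = g / n
        d = Pstd.shape[1]
        zero = path.coefficients[0] == 0
        assert np.all(np.abs(g[:d][zero]) <= lam + 1e-6)

    def test_path_continuity_in_convex_limit(self, small_cox_problem):
        # the lasso path (a -> inf) is continuous in lambda; finite-a MCP
        # may jump where the penalty concavity exceeds the coordinate
        # curvature, so continuity is asserted on the convex limit
        prob = small_cox_problem
        path = coxpen.fit_cox_mcp(
            prob["times"], prob["events"], prob["P"], prob["U"],
            a_mcp=1e12, n_lambda=60,
        )
        jumps = np.abs(np.diff(path.coefficients, axis=0)).max()
        assert jumps < 0.5

    def test_single_lambda_is_chosen(self, small_cox_problem):
        prob = small_cox_problem
        path = coxpen.fit_cox_mcp(
            prob["times"], prob["events"], prob["P"], prob["U"],
            lambda_seq=np.array([0.05]),
        )
        _, _ = coxpen.select_lambda(path)
        assert path.chosen_index == 0

    def test_invalid_a_rejected(self, small_cox_problem):
        prob = small_cox_problem
        with pytest.raises(ValueError, match="a must exceed 1"):
            coxpen.fit_cox_mcp(
                prob["times"], prob["events"], prob["P"], prob["U"], a_mcp=1.0
            )


class TestBicSelection:
    def test_strong_signal_recovers_support(self, rng):
        hits = 0
        reps = 40
        for _ in range(reps):
            n, d = 250, 5
            P = rng.standard_normal((n, d))
            beta = np.array([1.0, 1.0, 1.0, 0.0, 0.0])
            tt = rng.exponential(np.exp(-(P @ beta)))
            cc = rng.exponential(np.exp(-(P @ beta).mean()) * 2, n)
            T, E = np.minimum(tt, cc), (tt <= cc).astype(int)
            path = coxpen.fit_cox_mcp(T, E, P, None)
            _, active = coxpen.select_lambda(path)
            hits += set(active.tolist()) >= {0, 1, 2}
        assert hits >= int(0.95 * reps)

    def test_pure_noise_selects_nearly_nothing(self, rng):
        sizes = []
        for _ in range(40):
            n, d = 250, 20
            P = rng.standard_normal((n, d))
            tt = rng.exponential(1.0, n)
            cc = rng.exponential(2.0, n)
            T, E = np.minimum(tt, cc), (tt <= cc).astype(int)
            path = coxpen.fit_cox_mcp(T, E, P, None)
            _, active = coxpen.select_lambda(path)
            sizes.append(len(active))
        assert np.median(sizes) <= 2
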