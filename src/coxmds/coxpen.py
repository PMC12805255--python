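"""Cox partial-likelihood machinery.

Two solvers built on the Breslow partial likelihood:

* :func:`fit_cox_mcp` — coordinate descent on an iteratively reweighted
  quadratic approximation, with the minimax concave penalty (MCP) on the
  mediator block and the exposure/covariate block always unpenalized.
  Used on Group I of every data split.
* :func:`refit_unpenalized` — exact-Hessian Newton-Raphson with
  step-halving.  Used on Group II and for the final joint refit.

The baseline hazard is never estimated; everything works through risk
sets.  Ties are handled with the Breslow convention, which is exact for
the simulator's continuous event times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numba
import numpy as np

logger = logging.getLogger(__name__)

_COEF_CAP = 20.0  # |beta| beyond this flags monotone likelihood / separation
_ETA_CLIP = 100.0  # linear-predictor guard after centering; keeps exp() finite


@dataclass
class CoxFit:
    """Unpenalized Cox fit on (mediators, exposure, covariates)."""

    beta_mediators: np.ndarray
    gamma_hat: float
    theta_hat: np.ndarray
    loglik: float
    converged: bool
    n_events: int


@dataclass
class McpPath:
    """MCP-Cox solution path over a decreasing penalty sequence."""

    lambdas: np.ndarray
    coefficients: np.ndarray  # n_lambda x d, original mediator scale
    unpenalized: np.ndarray  # n_lambda x u (exposure first, then covariates)
    loglik: np.ndarray
    criterion: np.ndarray  # BIC per lambda
    converged: np.ndarray
    n_events: int
    chosen_index: int | None = field(default=None)


def _sorted_views(times: np.ndarray, events: np.ndarray):
    """Ascending-time ordering plus tie-block boundaries."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    first = np.searchsorted(t, t, side="left")
    last = np.searchsorted(t, t, side="right") - 1
    return order, first, last


def cox_quantities(
    eta: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    views: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow negative log partial likelihood, its eta-gradient, and
    the diagonal of its eta-Hessian.

    All three are returned in the original subject order.  Risk sums use
    one descending-time scan (a reversed cumulative sum after sorting).
    ``views`` lets callers reuse the time ordering across evaluations.
    """
    if events.sum() < 1:
        raise ValueError("no events in this split")
    order, first, last = _sorted_views(times, events) if views is None else views
    n = len(times)
    # the partial likelihood is invariant to shifting eta; center and clip
    # so that suffix risk sums can neither overflow nor underflow to zero
    eta = eta - eta.mean()
    eta_s = np.clip(eta[order], -_ETA_CLIP, _ETA_CLIP)
    d_s = events[order].astype(float)
    shift = eta_s.max()
    es = np.exp(eta_s - shift)
    suffix = np.cumsum(es[::-1])[::-1]
    S = suffix[first]  # risk-set sum for each subject's tie block

    npll = -float(np.sum(d_s * (eta_s - shift - np.log(S))))

    # prefix sums of event contributions 1/S and 1/S^2, evaluated at the
    # *end* of each subject's tie block (tied events keep the subject in
    # the risk set)
    inv = d_s / S
    inv2 = d_s / S**2
    cum1 = np.cumsum(inv)
    cum2 = np.cumsum(inv2)
    A = cum1[last]
    Bq = cum2[last]
    grad_s = -(d_s - es * A)
    w_s = es * A - es**2 * Bq

    grad = np.empty(n)
    w = np.empty(n)
    grad[order] = grad_s
    w[order] = np.maximum(w_s, 0.0)
    return npll, grad, w


def neg_log_partial_likelihood(
    coefs: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    design: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Value and exact gradient of the Breslow negative log partial
    likelihood at ``coefs``."""
    eta = design @ coefs
    npll, grad_eta, _ = cox_quantities(eta, times, events)
    return npll, design.T @ grad_eta


def _cox_hessian(
    eta: np.ndarray, times: np.ndarray, events: np.ndarray, design: np.ndarray
) -> np.ndarray:
    """Full Hessian of the Breslow negative log partial likelihood."""
    order, first, _ = _sorted_views(times, events)
    eta = eta - eta.mean()
    eta_s = np.clip(eta[order], -_ETA_CLIP, _ETA_CLIP)
    x_s = design[order]
    d_s = events[order].astype(bool)
    shift = eta_s.max()
    es = np.exp(eta_s - shift)
    s0 = np.cumsum(es[::-1])[::-1]
    wx = es[:, None] * x_s
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    xx = x_s[:, :, None] * x_s[:, None, :]
    s2 = np.cumsum((es[:, None, None] * xx)[::-1], axis=0)[::-1]
    ev = first[d_s]
    r0 = s0[ev]
    r1 = s1[ev] / r0[:, None]
    H = np.einsum("ijk,i->jk", s2[ev], 1.0 / r0) - np.einsum("ij,ik->jk", r1, r1)
    return H


def newton_cox(
    times: np.ndarray,
    events: np.ndarray,
    design: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    cap: float = _COEF_CAP,
) -> tuple[np.ndarray, float, bool]:
    """Newton-Raphson with step-halving on the Breslow partial likelihood.

    Returns (coefficients, log partial likelihood, converged).  Diverging
    coefficients (monotone likelihood / separation) are capped at
    ``cap`` in absolute value and the fit is flagged.
    """
    n, m = design.shape
    if events.sum() < 1:
        raise ValueError("no events in this split")
    if m == 0:
        npll, _, _ = cox_quantities(np.zeros(n), times, events)
        return np.zeros(0), -npll, True
    center = design.mean(axis=0)
    Xc = design - center  # centering leaves partial likelihood invariant
    beta = np.zeros(m)
    npll, grad_eta, _ = cox_quantities(Xc @ beta, times, events)
    converged = False
    for _ in range(max_iter):
        grad = Xc.T @ grad_eta
        H = _cox_hessian(Xc @ beta, times, events, Xc)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(m), -grad)
        except np.linalg.LinAlgError:
            step = -grad
        # step-halving keeps the log partial likelihood non-decreasing
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            try:
                new_npll, new_grad_eta, _ = cox_quantities(
                    Xc @ cand, times, events
                )
            except FloatingPointError:  # pragma: no cover
                scale *= 0.5
                continue
            if new_npll <= npll + 1e-12:
                break
            scale *= 0.5
        delta = np.max(np.abs(cand - beta))
        beta, npll, grad_eta = cand, new_npll, new_grad_eta
        if np.max(np.abs(beta)) > cap:
            logger.warning(
                "Cox coefficient diverged past %.0f; capping (separation?)", cap
            )
            beta = np.clip(beta, -cap, cap)
            npll, grad_eta, _ = cox_quantities(Xc @ beta, times, events)
            converged = False
            break
        if delta < tol:
            converged = True
            break
    return beta, -npll, converged


def refit_unpenalized(
    times: np.ndarray,
    events: np.ndarray,
    selected_mediators: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> CoxFit:
    """Unpenalized Cox fit of (selected mediators, exposure, covariates).

    The selected-mediator block may be empty, in which case only the
    exposure and covariates are fitted.
    """
    selected_mediators = np.atleast_2d(np.asarray(selected_mediators, dtype=float))
    if selected_mediators.size == 0:
        selected_mediators = np.empty((len(times), 0))
    elif selected_mediators.shape[0] != len(times):
        selected_mediators = selected_mediators.T
    d = selected_mediators.shape[1]
    design = np.column_stack([selected_mediators, X, Z])
    coefs, loglik, converged = newton_cox(
        times, events, design, tol=tol, max_iter=max_iter
    )
    return CoxFit(
        beta_mediators=coefs[:d],
        gamma_hat=float(coefs[d]),
        theta_hat=coefs[d + 1:],
        loglik=loglik,
        converged=converged,
        n_events=int(events.sum()),
    )


def _mcp_coordinate_update(u: float, v: float, lam: float, a: float) -> float:
    """Exact minimizer of (v/2)t^2 - u t + MCP(|t|; lam, a) over t.

    MCP(t) = lam|t| - t^2/(2a) for |t| <= a*lam, else a*lam^2/2.
    """
    if v <= 0:
        return 0.0
    z = u / v
    if abs(z) >= a * lam:
        return z
    if v > 1.0 / a + 1e-12:
        s = np.sign(u) * max(abs(u) - lam, 0.0) / (v - 1.0 / a)
        return s
    # quadratic curvature below the penalty concavity: compare the two
    # candidate minimizers (origin vs. the flat-region boundary) directly
    t = np.sign(u) * a * lam
    g_boundary = 0.5 * v * t * t - u * t + 0.5 * a * lam * lam
    return t if g_boundary < 0.0 else 0.0


@numba.njit(cache=True)
def _cd_cycles(
    G: np.ndarray,
    r: np.ndarray,
    beta: np.ndarray,
    lam: float,
    a: float,
    d: int,
    tol: float,
    max_inner: int,
) -> None:
    """Cyclic coordinate descent on the working quadratic (in place).

    ``r`` holds b - G @ beta and is kept in sync.  Coordinates below
    ``d`` get the exact MCP update (mirrors
    :func:`_mcp_coordinate_update`); the rest are unpenalized.
    """
    m = G.shape[0]
    for _ in range(max_inner):
        delta = 0.0
        for j in range(m):
            old = beta[j]
            v = G[j, j]
            if v <= 0.0:
                continue
            u = r[j] + v * old
            if j < d:
                if lam == np.inf:
                    new = 0.0
                else:
                    z = u / v
                    if abs(z) >= a * lam:
                        new = z
                    elif v > 1.0 / a + 1e-12:
                        au = abs(u) - lam
                        new = (np.sign(u) * au / (v - 1.0 / a)) if au > 0 else 0.0
                    else:
                        t = np.sign(u) * a * lam
                        gb = 0.5 * v * t * t - u * t + 0.5 * a * lam * lam
                        new = t if gb < 0.0 else 0.0
            else:
                new = u / v
            if new != old:
                diff = new - old
                for k in range(m):
                    r[k] -= G[k, j] * diff
                beta[j] = new
                ad = abs(diff)
                if ad > delta:
                    delta = ad
        if delta < tol:
            break


def fit_cox_mcp(
    times: np.ndarray,
    events: np.ndarray,
    penalized_block: np.ndarray,
    unpenalized_block: np.ndarray | None = None,
    lambda_seq: np.ndarray | None = None,
    a_mcp: float = 3.0,
    n_lambda: int = 30,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-6,
    max_outer: int = 1000,
    max_inner: int = 200,
) -> McpPath:
    """MCP-penalized Cox regression along a decreasing penalty path.

    The objective is (1/n) * negative log partial likelihood plus MCP on
    the penalized (mediator) block only.  Mediator columns are
    standardized internally and coefficients are reported on the original
    scale.  Each path point warm-starts from the previous one; the path
    runs log-spaced from lambda_max (smallest penalty with an all-zero
    mediator block) down to ``lambda_min_ratio * lambda_max`` unless an
    explicit ``lambda_seq`` is given.
    """
    if a_mcp <= 1:
        raise ValueError("MCP concavity parameter a must exceed 1")
    P = np.asarray(penalized_block, dtype=float)
    if P.ndim != 2 or P.shape[1] < 1:
        raise ValueError("penalized_block must have at least one column")
    n, d = P.shape
    n_events = int(events.sum())
    if n_events < 1:
        raise ValueError("no events in this split")
    U = (
        np.empty((n, 0))
        if unpenalized_block is None
        else np.asarray(unpenalized_block, dtype=float).reshape(n, -1)
    )
    u_cols = U.shape[1]

    p_mean = P.mean(axis=0)
    p_sd = P.std(axis=0)
    p_sd[p_sd == 0] = 1.0  # constant columns can never enter
    Xs = np.column_stack([(P - p_mean) / p_sd, U - U.mean(axis=0)])
    m = d + u_cols

    views = _sorted_views(times, events)

    def irls_solve(beta: np.ndarray, lam: float) -> tuple[np.ndarray, float, bool]:
        """Outer IRLS loop at one lambda; returns (beta, npll, converged)."""
        npll = np.inf
        for _outer in range(max_outer):
            eta = Xs @ beta
            npll, grad_eta, w = cox_quantities(eta, times, events, views)
            g = grad_eta / n
            wq = np.maximum(w / n, 1e-12)
            z = eta - g / wq
            G = Xs.T @ (wq[:, None] * Xs)
            b = Xs.T @ (wq * z)
            r = b - G @ beta
            beta_prev = beta.copy()
            _cd_cycles(G, r, beta, lam, a_mcp, d, 0.1 * tol, max_inner)
            # separation guard on the standardized scale
            np.clip(beta, -50.0, 50.0, out=beta)
            if np.max(np.abs(beta - beta_prev)) < tol:
                return beta, npll, True
        logger.warning("MCP-Cox did not converge at lambda=%.4g", lam)
        return beta, npll, False

    # null (mediator-free) fit gives lambda_max and the warm start
    beta = np.zeros(m)
    beta, _, _ = irls_solve(beta, np.inf)
    if lambda_seq is None:
        eta = Xs @ beta
        _, grad_eta, _ = cox_quantities(eta, times, events, views)
        score = np.abs(Xs[:, :d].T @ grad_eta) / n
        lam_max = max(float(score.max()), 1e-8)
        lambda_seq = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)
    else:
        lambda_seq = np.asarray(lambda_seq, dtype=float)
        if len(lambda_seq) > 1 and np.any(np.diff(lambda_seq) >= 0):
            raise ValueError("lambda_seq must be strictly decreasing")

    L = len(lambda_seq)
    coefs = np.zeros((L, d))
    unpen = np.zeros((L, u_cols))
    logliks = np.zeros(L)
    criterion = np.zeros(L)
    conv = np.zeros(L, dtype=bool)
    for i, lam in enumerate(lambda_seq):
        beta, npll, ok = irls_solve(beta, float(lam))
        coefs[i] = beta[:d] / p_sd  # back to original mediator scale
        unpen[i] = beta[d:]
        logliks[i] = -npll
        active = int(np.count_nonzero(beta[:d]))
        criterion[i] = 2.0 * npll + np.log(n_events) * active
        conv[i] = ok
    return McpPath(
        lambdas=np.asarray(lambda_seq, dtype=float),
        coefficients=coefs,
        unpenalized=unpen,
        loglik=logliks,
        criterion=criterion,
        converged=conv,
        n_events=n_events,
    )


def select_lambda(path: McpPath) -> tuple[np.ndarray, np.ndarray]:
    """Pick the BIC-minimizing path point.

    Returns (mediator coefficients on the original scale, active-set
    indices); ties break toward the larger (sparser) penalty.  Sets
    ``path.chosen_index`` in place.
    """
    idx = int(np.argmin(path.criterion))
    path.chosen_index = idx
    beta = path.coefficients[idx]
    return beta, np.flatnonzero(beta)


def select_lambda_cv(
    times: np.ndarray,
    events: np.ndarray,
    penalized_block: np.ndarray,
    unpenalized_block: np.ndarray | None,
    path: McpPath,
    rng: np.random.Generator,
    n_folds: int = 5,
    a_mcp: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the path point maximizing the cross-validated partial likelihood.

    Uses the Verweij-van Houwelingen criterion: for each fold, refit the
    whole path on the remaining data and score
    ``loglik(all data) - loglik(training data)`` at each penalty, which
    stays well defined even when a left-out fold holds few events.
    Returns the full-data coefficients at the winning penalty and sets
    ``path.chosen_index``.
    """
    n = len(times)
    P = np.asarray(penalized_block, dtype=float)
    U = (
        np.empty((n, 0))
        if unpenalized_block is None
        else np.asarray(unpenalized_block, dtype=float).reshape(n, -1)
    )
    design = np.column_stack([P, U])
    folds = rng.permutation(n) % n_folds
    cvl = np.zeros(len(path.lambdas))
    for f in range(n_folds):
        train = folds != f
        if events[train].sum() < 1 or events[~train].sum() < 1:
            continue
        sub = fit_cox_mcp(
            times[train], events[train], P[train], U[train],
            lambda_seq=path.lambdas, a_mcp=a_mcp,
        )
        for i in range(len(path.lambdas)):
            coef = np.concatenate([sub.coefficients[i], sub.unpenalized[i]])
            eta = design @ coef
            l_all, _, _ = cox_quantities(eta, times, events)
            l_tr, _, _ = cox_quantities(eta[train], times[train], events[train])
            cvl[i] += -l_all + l_tr  # loglik difference
    idx = int(np.argmax(cvl))
    path.chosen_index = idx
    beta = path.coefficients[idx]
    return beta, np.flatnonzero(beta)
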