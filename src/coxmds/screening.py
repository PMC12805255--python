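"""Candidate mediator filtering (Step 1).

For every mediator M_j, fit ordinary least squares of M_j on an
intercept, the exposure X and the covariates Z, take the two-sided
t-test p-value on the exposure coefficient, and keep the mediators that
survive Benjamini-Hochberg selection at level q1.  All p regressions
share one design-matrix factorization, so the whole screen is a handful
of matrix products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simdata import MediationDataset

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Per-mediator exposure coefficients, p-values, and BH selection."""

    alpha_hat: np.ndarray
    pvalues: np.ndarray
    q1: float
    selected: np.ndarray  # 0-based candidate indices, ascending

    @property
    def d(self) -> int:
        return len(self.selected)


def fit_exposure_mediator(
    dataset: MediationDataset,
) -> tuple[np.ndarray, np.ndarray]:
    """OLS exposure coefficients and two-sided t p-values for all mediators.

    Returns ``(alpha_hat, pvalues)``, each of length p.  The exposure
    coefficient sits after the intercept in the design (1, X, Z).
    """
    n = dataset.n
    D = np.column_stack([np.ones(n), dataset.X, dataset.Z])
    k = D.shape[1]
    if n <= k:
        raise ValueError(f"need n > {k} subjects for the screening regression")
    # rank / collinearity diagnostics with the offending column named
    names = ["intercept", "exposure"] + [f"Z{i + 1}" for i in range(dataset.Z.shape[1])]
    if np.ptp(dataset.X) == 0:
        raise ValueError("exposure column is constant; screening design is singular")
    rank = np.linalg.matrix_rank(D)
    if rank < k:
        for j in range(k):
            sub = np.delete(D, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(
                    f"screening design is rank-deficient; column {names[j]!r} "
                    "is collinear with the others"
                )
        raise ValueError("screening design is rank-deficient")

    DtD_inv = np.linalg.inv(D.T @ D)
    coefs = DtD_inv @ (D.T @ dataset.M)  # k x p
    resid = dataset.M - D @ coefs
    dof = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    alpha_hat = coefs[1]
    se = np.sqrt(np.maximum(sigma2 * DtD_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, alpha_hat / se, np.inf * np.sign(alpha_hat))
    pvalues = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pvalues = np.where(se > 0, pvalues, 0.0)
    return alpha_hat, pvalues


def bh_select(pvalues: np.ndarray, q1: float) -> np.ndarray:
    """Classic step-up Benjamini-Hochberg selection.

    Returns the 0-based indices j with p_j at or below the BH cutoff
    p_(k*), where k* = max{k : p_(k) <= q1*k/p}; empty when no k
    qualifies.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([], dtype=int)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = (np.arange(1, m + 1) / m) * q1
    passing = np.flatnonzero(sorted_p <= thresholds)
    if len(passing) == 0:
        return np.array([], dtype=int)
    cutoff = sorted_p[passing[-1]]
    return np.flatnonzero(p <= cutoff)


def screen(dataset: MediationDataset, q1: float = 0.2) -> ScreenResult:
    """Step 1: screen all mediators and BH-select candidates at level q1."""
    alpha_hat, pvalues = fit_exposure_mediator(dataset)
    selected = bh_select(pvalues, q1)
    logger.info("screening kept %d of %d mediators at q1=%g", len(selected),
                dataset.p, q1)
    return ScreenResult(alpha_hat=alpha_hat, pvalues=pvalues, q1=q1,
                        selected=selected)
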