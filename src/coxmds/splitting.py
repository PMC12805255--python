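"""Multiple data splitting (Step 2).

The sample is randomly halved B times.  On Group I an MCP-penalized Cox
model selects a sparse working set of candidate mediators; Group II
refits those mediators without penalty.  The two coefficient vectors are
combined into mirror statistics

    Q_j = sign(beta1_j * beta2_j) * (|beta1_j| + |beta2_j|),

which are symmetric about zero for null mediators because the two groups
are independent, and tend to be large and positive for true signals.
Each split then selects Q_j >= tau where tau is the smallest threshold
whose estimated false discovery proportion

    FDP(tau) = #{Q_j <= -tau} / max(#{Q_j >= tau}, 1)

stays at or below the per-split target q2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import coxpen
from .simdata import MediationDataset

logger = logging.getLogger(__name__)


@dataclass
class SplitResult:
    """Per-split coefficients, mirror statistics and selection."""

    split_id: int
    group1_idx: np.ndarray
    group2_idx: np.ndarray
    beta1: np.ndarray  # Group-I MCP coefficients, length d
    beta2: np.ndarray  # Group-II refit coefficients, length d (0 outside S)
    Q: np.ndarray
    tau: float
    selected: np.ndarray  # 0-based indices into the candidate list


def split_indices(
    n: int,
    proportion: float,
    rng: np.random.Generator,
    events: np.ndarray | None = None,
    max_tries: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random partition with Group I holding round(proportion*n).

    When ``events`` is given, redraws (up to ``max_tries``) until both
    groups hold at least two subjects and one event.
    """
    if not 0 < proportion < 1:
        raise ValueError("split proportion must lie in (0, 1)")
    n1 = int(round(proportion * n))
    if n1 < 2 or n - n1 < 2:
        raise ValueError("both groups need at least two subjects")
    for _ in range(max_tries):
        perm = rng.permutation(n)
        g1, g2 = np.sort(perm[:n1]), np.sort(perm[n1:])
        if events is None or (events[g1].sum() >= 1 and events[g2].sum() >= 1):
            return g1, g2
    raise RuntimeError("insufficient events for splitting")


def mirror_statistics(beta1: np.ndarray, beta2: np.ndarray) -> np.ndarray:
    """Elementwise mirror statistic; sign(0) = 0 zeroes out any mediator
    absent from either group's fit."""
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    if beta1.shape != beta2.shape:
        raise ValueError("coefficient vectors must have equal length")
    return np.sign(beta1 * beta2) * (np.abs(beta1) + np.abs(beta2))


def fdp_threshold(Q: np.ndarray, q2: float) -> tuple[float, np.ndarray]:
    """Smallest threshold tau with estimated FDP <= q2, and the selection.

    Candidate thresholds are the observed non-zero |Q| values (the
    infimum over continuous tau is attained there).  Returns
    (inf, empty) when no threshold qualifies.
    """
    if not 0 < q2 < 1:
        raise ValueError("q2 must lie in (0, 1)")
    Q = np.asarray(Q, dtype=float)
    taus = np.unique(np.abs(Q[Q != 0]))
    if len(taus) == 0:
        return np.inf, np.array([], dtype=int)
    sorted_Q = np.sort(Q)
    n_neg = np.searchsorted(sorted_Q, -taus, side="right")
    n_pos = len(Q) - np.searchsorted(sorted_Q, taus, side="left")
    fdp = n_neg / np.maximum(n_pos, 1)
    ok = np.flatnonzero(fdp <= q2)
    if len(ok) == 0:
        return np.inf, np.array([], dtype=int)
    tau = float(taus[ok[0]])
    return tau, np.flatnonzero(Q >= tau)


def _one_split(
    dataset: MediationDataset,
    candidates: np.ndarray,
    split_id: int,
    q2: float,
    proportion: float,
    rng: np.random.Generator,
    mcp_a: float,
    n_lambda: int,
    lambda_min_ratio: float,
    tuning: str,
) -> SplitResult:
    g1, g2 = split_indices(dataset.n, proportion, rng, events=dataset.event)
    Mc = dataset.M[:, candidates]
    XZ = np.column_stack([dataset.X, dataset.Z])
    path = coxpen.fit_cox_mcp(
        dataset.time[g1],
        dataset.event[g1],
        Mc[g1],
        XZ[g1],
        a_mcp=mcp_a,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
    )
    if tuning == "cv":
        beta1, active = coxpen.select_lambda_cv(
            dataset.time[g1], dataset.event[g1], Mc[g1], XZ[g1], path, rng,
            a_mcp=mcp_a,
        )
    elif tuning == "bic":
        beta1, active = coxpen.select_lambda(path)
    else:
        raise ValueError(f"unknown tuning rule {tuning!r}; use 'bic' or 'cv'")
    beta2 = np.zeros_like(beta1)
    if len(active) > 0:
        fit = coxpen.refit_unpenalized(
            dataset.time[g2],
            dataset.event[g2],
            Mc[g2][:, active],
            dataset.X[g2],
            dataset.Z[g2],
        )
        beta2[active] = fit.beta_mediators
    Q = mirror_statistics(beta1, beta2)
    tau, selected = fdp_threshold(Q, q2)
    logger.debug(
        "split %d: |S|=%d tau=%.3g |H1|=%d", split_id, len(active), tau,
        len(selected),
    )
    return SplitResult(
        split_id=split_id,
        group1_idx=g1,
        group2_idx=g2,
        beta1=beta1,
        beta2=beta2,
        Q=Q,
        tau=tau,
        selected=selected,
    )


def run_splits(
    dataset: MediationDataset,
    candidates: np.ndarray,
    q2: float = 0.1,
    B: int = 25,
    proportion: float = 0.5,
    rng: np.random.Generator | int | None = None,
    mcp_a: float = 3.0,
    n_lambda: int = 30,
    lambda_min_ratio: float = 0.01,
    tuning: str = "bic",
    max_redraws: int = 3,
) -> list[SplitResult]:
    """B independent half-split analyses of the candidate mediators.

    Each split draws from its own child stream of the master seed, so
    results are reproducible and order-independent.  A split that fails
    (e.g. no events in a group, numerical breakdown) is redrawn up to
    ``max_redraws`` times and then recorded as an empty selection, which
    keeps B fixed.
    """
    candidates = np.asarray(candidates, dtype=int)
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    if B < 1:
        raise ValueError("B must be at least 1")
    if isinstance(rng, np.random.Generator):
        master = rng
    else:
        master = np.random.default_rng(rng)
    streams = master.spawn(B)
    results: list[SplitResult] = []
    d = len(candidates)
    for b, stream in enumerate(streams):
        last_err: Exception | None = None
        for attempt in range(1 + max_redraws):
            try:
                results.append(
                    _one_split(
                        dataset, candidates, b, q2, proportion, stream,
                        mcp_a, n_lambda, lambda_min_ratio, tuning,
                    )
                )
                break
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as err:
                last_err = err
                logger.warning(
                    "split %d attempt %d failed (%s); redrawing", b, attempt, err
                )
        else:
            logger.warning(
                "split %d failed %d times (%s); recording empty selection",
                b, 1 + max_redraws, last_err,
            )
            results.append(
                SplitResult(
                    split_id=b,
                    group1_idx=np.array([], dtype=int),
                    group2_idx=np.array([], dtype=int),
                    beta1=np.zeros(d),
                    beta2=np.zeros(d),
                    Q=np.zeros(d),
                    tau=np.inf,
                    selected=np.array([], dtype=int),
                )
            )
    return results
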