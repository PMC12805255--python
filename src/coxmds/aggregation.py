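"""Aggregation of per-split selections (Step 3).

Two aggregators turn the B per-split results into one final selection
with target false discovery rate q2:

* inclusion-rate aggregation (IRA, the default): each mediator's
  importance is its selection frequency across splits, down-weighted by
  the size of each split's selection set, V_j = (1/B) sum_b
  1{j in H1_b} / max(|H1_b|, 1).  Sorting the rates ascending and
  accumulating until the budget q2 is spent gives a cutoff; everything
  strictly above it is selected.
* quantile aggregation (QA): per split, each positive mirror statistic
  is converted to a rank-based score delta_j^b; the eta-quantile of the
  B scores (scaled by 1/eta and capped at 1) gives a p-value-like
  statistic that is thresholded with Benjamini-Hochberg.

IRA keeps finite-sample FDR control even under strong mediator
correlation; QA can over-select in that regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .splitting import SplitResult


@dataclass
class SelectionResult:
    """Aggregated importance scores and the final selected candidate set."""

    method: str  # "ira" or "qa"
    scores: np.ndarray  # V_j for ira, delta-bar_j for qa
    cutoff: float
    selected: np.ndarray  # 0-based indices into the candidate list


def inclusion_rates(
    selection_sets: Iterable[Sequence[int]], B: int, d: int
) -> np.ndarray:
    """Inclusion rate V_j over B selection sets on [d].

    Each split contributes at most 1/B in total, so sum_j V_j <= 1.
    """
    V = np.zeros(d)
    count = 0
    for sel in selection_sets:
        sel = np.asarray(sel, dtype=int)
        count += 1
        if len(sel) > 0:
            V[sel] += 1.0 / len(sel)
    if count != B:
        raise ValueError(f"expected {B} selection sets, got {count}")
    return V / B


def ira_select(V: np.ndarray, q2: float) -> SelectionResult:
    """Inclusion-rate aggregation selection at target FDR q2.

    Sort rates ascending, find the largest l with V_(1)+...+V_(l) <= q2,
    and keep mediators with V_j strictly above V_(l).  When even V_(1)
    exceeds q2 (l = 0) everything with positive rate is kept.
    """
    if not 0 < q2 < 1:
        raise ValueError("q2 must lie in (0, 1)")
    V = np.asarray(V, dtype=float)
    sorted_V = np.sort(V)
    csum = np.cumsum(sorted_V)
    under = np.flatnonzero(csum <= q2)
    if len(under) == 0:
        cutoff = 0.0
    else:
        cutoff = float(sorted_V[under[-1]])
    selected = np.flatnonzero(V > cutoff)
    return SelectionResult(method="ira", scores=V, cutoff=cutoff, selected=selected)


def qa_intermediate(Q_b: np.ndarray, d: int | None = None) -> np.ndarray:
    """Rank-based per-split score delta_j^b in (0, 1].

    delta_j = (1 + #{k : Q_k <= -Q_j}) / d for positive mirror
    statistics, 1 otherwise.
    """
    Q_b = np.asarray(Q_b, dtype=float)
    if d is None:
        d = len(Q_b)
    elif d != len(Q_b):
        raise ValueError("d must match the length of Q_b")
    sorted_Q = np.sort(Q_b)
    counts = np.searchsorted(sorted_Q, -Q_b, side="right")
    delta = np.ones(d)
    pos = Q_b > 0
    delta[pos] = (1.0 + counts[pos]) / d
    return delta


def mcs(delta_matrix: np.ndarray, eta: float = 0.05) -> np.ndarray:
    """Multiple Cox Statistic: capped scaled eta-quantile of the per-split
    scores, delta-bar_j = min{1, Q_eta(delta_j^.) / eta}.

    Uses the linear-interpolation (type-7) sample quantile.
    """
    if not 0 < eta < 1:
        raise ValueError("eta must lie in (0, 1)")
    delta_matrix = np.atleast_2d(np.asarray(delta_matrix, dtype=float))
    q = np.quantile(delta_matrix, eta, axis=0, method="linear")
    return np.minimum(1.0, q / eta)


def qa_select(delta_bar: np.ndarray, q2: float) -> SelectionResult:
    """Benjamini-Hochberg step-up on the MCS values at level q2."""
    if not 0 < q2 < 1:
        raise ValueError("q2 must lie in (0, 1)")
    delta_bar = np.asarray(delta_bar, dtype=float)
    d = len(delta_bar)
    sorted_d = np.sort(delta_bar)
    thresholds = q2 * np.arange(1, d + 1) / d
    passing = np.flatnonzero(sorted_d <= thresholds)
    if len(passing) == 0:
        return SelectionResult(
            method="qa", scores=delta_bar, cutoff=0.0,
            selected=np.array([], dtype=int),
        )
    cutoff = float(sorted_d[passing[-1]])
    return SelectionResult(
        method="qa", scores=delta_bar, cutoff=cutoff,
        selected=np.flatnonzero(delta_bar <= cutoff),
    )


def aggregate(
    split_results: list[SplitResult],
    d: int,
    method: str = "ira",
    q2: float = 0.1,
    eta: float = 0.05,
) -> SelectionResult:
    """Aggregate B split results into the final candidate selection."""
    B = len(split_results)
    if method == "ira":
        V = inclusion_rates((s.selected for s in split_results), B, d)
        return ira_select(V, q2)
    if method == "qa":
        deltas = np.vstack([qa_intermediate(s.Q, d) for s in split_results])
        return qa_select(mcs(deltas, eta), q2)
    raise ValueError(f"unknown aggregation method {method!r}; use 'ira' or 'qa'")
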