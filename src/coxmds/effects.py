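"""Mediation effect estimates for the final selected set.

On the log-hazard scale the working models give, for an exposure
contrast x - x*:

    NDE   = gamma * (x - x*)
    NIE_j = alpha_j * beta_j * (x - x*)

alpha_j comes from the full-sample screening regression of M_j on
(1, X, Z); beta_j and gamma come from one joint full-sample Cox refit
containing the exposure, covariates and all selected mediators.  This is
a post-selection summary — no post-selection p-values are attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coxpen, screening
from .simdata import MediationDataset


def natural_indirect_effect(
    alpha_hat: float | np.ndarray,
    beta_hat: float | np.ndarray,
    contrast: float = 1.0,
) -> float | np.ndarray:
    """Product-of-coefficients NIE on the log-hazard scale."""
    return alpha_hat * beta_hat * contrast


@dataclass
class EffectTable:
    """Per-mediator effect estimates plus the direct effect."""

    table: pd.DataFrame  # columns: mediator_id, alpha_hat, beta_hat, nie
    gamma_hat: float
    contrast: float

    @property
    def nde(self) -> float:
        return self.gamma_hat * self.contrast

    @property
    def total_nie(self) -> float:
        return float(self.table["nie"].sum())

    @property
    def total_effect(self) -> float:
        return self.nde + self.total_nie


def estimate_effects(
    dataset: MediationDataset,
    selected: np.ndarray,
    contrast: float = 1.0,
    alpha_hat: np.ndarray | None = None,
) -> EffectTable:
    """Joint effect estimates for the selected mediators.

    ``selected`` holds 0-based column indices into ``dataset.M``.  Pass
    ``alpha_hat`` to reuse screening coefficients already computed on the
    full sample.  An empty selection still yields the direct effect from
    an exposure/covariate-only Cox fit.
    """
    selected = np.asarray(selected, dtype=int)
    if alpha_hat is None:
        alpha_hat, _ = screening.fit_exposure_mediator(dataset)
    fit = coxpen.refit_unpenalized(
        dataset.time,
        dataset.event,
        dataset.M[:, selected] if len(selected) else np.empty((dataset.n, 0)),
        dataset.X,
        dataset.Z,
    )
    a = alpha_hat[selected]
    b = fit.beta_mediators
    table = pd.DataFrame(
        {
            "mediator_id": [dataset.mediator_ids[j] for j in selected],
            "alpha_hat": a,
            "beta_hat": b,
            "nie": natural_indirect_effect(a, b, contrast),
        }
    )
    return EffectTable(table=table, gamma_hat=fit.gamma_hat, contrast=contrast)
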