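"""Simulation-study harness: replicate a scenario cell and report the
mean false discovery rate (FDR) and true positive proportion (TPP).

FDP = #(selected and null) / max(#selected, 1); TPP = #(selected and
true) / #true.  Replicates draw independent child seeds from the master
seed, so a cell is deterministic given (scenario, reps, seed) and
independent of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import simdata
from .pipeline import run_coxmds
from .simdata import SimConfig, SimTruth

logger = logging.getLogger(__name__)


def fdp_tpp(selected: np.ndarray, truth: SimTruth) -> tuple[float, float]:
    """Realized false discovery proportion and true positive proportion."""
    if len(truth.H1) == 0:
        raise ValueError("truth has an empty H1; TPP is undefined")
    selected = np.asarray(selected, dtype=int)
    n_sel = len(selected)
    n_false = len(np.intersect1d(selected, truth.H0))
    n_true = len(np.intersect1d(selected, truth.H1))
    fdp = n_false / max(n_sel, 1)
    tpp = n_true / len(truth.H1)
    return fdp, tpp


@dataclass
class ReplicationCell:
    """Mean FDR/TPP with Monte-Carlo standard errors for one scenario cell."""

    params: dict
    reps: int
    fdr_mean: float
    tpp_mean: float
    fdr_se: float
    tpp_se: float
    fdps: np.ndarray = field(repr=False)
    tpps: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "reps": self.reps,
            "fdr_mean": self.fdr_mean,
            "tpp_mean": self.tpp_mean,
            "fdr_se": self.fdr_se,
            "tpp_se": self.tpp_se,
        }


def replicate_cell(
    config: SimConfig | str,
    reps: int = 100,
    seed: int = 0,
    q1: float = 0.2,
    q2: float = 0.1,
    B: int = 25,
    split_prop: float = 0.5,
    aggregation_method: str = "ira",
    eta: float = 0.05,
    tuning: str = "bic",
    overrides: dict | None = None,
    progress: bool = False,
) -> ReplicationCell:
    """Run the full procedure on ``reps`` fresh datasets and summarize.

    ``config`` may be a :class:`SimConfig` or a scenario name (with
    ``overrides`` merged on top).  Censoring is calibrated once per cell
    and shared by all replicates.
    """
    if isinstance(config, str):
        config = simdata.scenario_config(config, **(overrides or {}))
    if reps < 1:
        raise ValueError("reps must be at least 1")
    c0 = simdata.calibrate_censoring(config)
    master = np.random.default_rng(seed)
    streams = master.spawn(2 * reps)
    fdps = np.full(reps, np.nan)
    tpps = np.full(reps, np.nan)
    for r in range(reps):
        try:
            data, truth = simdata.simulate_dataset(config, seed=streams[2 * r], c0=c0)
            result = run_coxmds(
                data, q1=q1, q2=q2, B=B, split_prop=split_prop,
                aggregation_method=aggregation_method, eta=eta,
                tuning=tuning, seed=streams[2 * r + 1],
                compute_effects=False,
            )
            fdps[r], tpps[r] = fdp_tpp(result.selected_indices, truth)
        except Exception as err:  # pragma: no cover - defensive
            logger.warning("replicate %d failed: %s", r, err)
        if progress and (r + 1) % 10 == 0:
            logger.info("replicate %d/%d done", r + 1, reps)
    ok = ~np.isnan(fdps)
    achieved = int(ok.sum())
    if achieved == 0:
        raise RuntimeError("all replicates failed")
    fdps, tpps = fdps[ok], tpps[ok]
    params = {
        "n": config.n, "p": config.p, "rho": config.rho,
        "kappa_alpha": config.kappa_alpha, "kappa_beta": config.kappa_beta,
        "censoring": config.target_censoring,
        "family": config.mediator_family, "q1": q1, "q2": q2, "B": B,
        "split_prop": split_prop, "aggregation": aggregation_method,
        "seed": seed,
    }
    return ReplicationCell(
        params=params,
        reps=achieved,
        fdr_mean=float(fdps.mean()),
        tpp_mean=float(tpps.mean()),
        fdr_se=float(fdps.std(ddof=1) / np.sqrt(achieved)) if achieved > 1 else 0.0,
        tpp_se=float(tpps.std(ddof=1) / np.sqrt(achieved)) if achieved > 1 else 0.0,
        fdps=fdps,
        tpps=tpps,
    )
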