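"""End-to-end orchestration of the three-step procedure.

screen (BH at q1) -> B data splits with mirror statistics -> aggregation
at target FDR q2 -> optional joint effect estimation on the final set.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np

from . import aggregation, effects, screening, splitting
from .simdata import MediationDataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything produced by one run of the full procedure."""

    screen: screening.ScreenResult
    splits: list[splitting.SplitResult]
    selection: aggregation.SelectionResult | None
    selected_indices: np.ndarray  # 0-based indices into the full mediator set
    selected_ids: list[str]
    effect_table: effects.EffectTable | None
    manifest: dict = field(default_factory=dict)

    @property
    def status(self) -> str:
        return self.manifest.get("status", "ok")


def run_coxmds(
    dataset: MediationDataset,
    q1: float = 0.2,
    q2: float = 0.1,
    B: int = 25,
    split_prop: float = 0.5,
    aggregation_method: str = "ira",
    eta: float = 0.05,
    seed: int | np.random.Generator | None = None,
    contrast: float = 1.0,
    mcp_a: float = 3.0,
    n_lambda: int = 30,
    lambda_min_ratio: float = 0.01,
    tuning: str = "bic",
    compute_effects: bool = True,
) -> PipelineResult:
    """Run screening, multiple data splitting and aggregation.

    Deterministic given the dataset, the configuration and ``seed``.
    An empty screening result short-circuits with a "no candidates"
    status rather than raising.
    """
    t0 = _time.perf_counter()
    scr = screening.screen(dataset, q1=q1)
    manifest: dict = {
        "q1": q1, "q2": q2, "B": B, "split_prop": split_prop,
        "aggregation": aggregation_method, "eta": eta, "mcp_a": mcp_a,
        "n_lambda": n_lambda, "tuning": tuning, "contrast": contrast,
        "seed": None if isinstance(seed, np.random.Generator) else seed,
        "n": dataset.n, "p": dataset.p, "d": scr.d,
        "n_events": int(dataset.event.sum()),
    }
    if scr.d == 0:
        logger.info("no candidates passed screening at q1=%g; stopping", q1)
        manifest.update(status="no-candidates", wall_time_s=_time.perf_counter() - t0)
        return PipelineResult(
            screen=scr, splits=[], selection=None,
            selected_indices=np.array([], dtype=int), selected_ids=[],
            effect_table=None, manifest=manifest,
        )

    splits = splitting.run_splits(
        dataset, scr.selected, q2=q2, B=B, proportion=split_prop,
        rng=seed, mcp_a=mcp_a, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio, tuning=tuning,
    )
    sel = aggregation.aggregate(
        splits, scr.d, method=aggregation_method, q2=q2, eta=eta
    )
    selected_indices = scr.selected[sel.selected]
    selected_ids = [dataset.mediator_ids[j] for j in selected_indices]
    manifest.update(
        status="ok" if len(selected_indices) else "no-discoveries",
        split_selection_sizes=[len(s.selected) for s in splits],
        n_selected=len(selected_indices),
    )

    effect_table = None
    if compute_effects:
        effect_table = effects.estimate_effects(
            dataset, selected_indices, contrast=contrast,
            alpha_hat=scr.alpha_hat,
        )
    manifest["wall_time_s"] = _time.perf_counter() - t0
    return PipelineResult(
        screen=scr, splits=splits, selection=sel,
        selected_indices=selected_indices, selected_ids=selected_ids,
        effect_table=effect_table, manifest=manifest,
    )
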