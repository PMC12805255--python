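"""Reading and writing the TSV/CSV interchange formats.

The mediator matrix ships as samples x mediators with mediator IDs as
column headers and sample IDs in the first column; the phenotype table
carries observed time, event indicator, exposure and covariates keyed by
the same sample IDs.  Rows are aligned by ID, so the two files may be in
different orders.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import MediationDataset, SimTruth


class InputError(ValueError):
    """Malformed or inconsistent input files."""


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_inputs(
    mediators_path: str | Path,
    pheno_path: str | Path,
    time_col: str = "time",
    event_col: str = "event",
    exposure_col: str = "exposure",
    covariate_cols: list[str] | None = None,
    id_col: str = "id",
    transpose: bool = False,
) -> MediationDataset:
    """Load and align the mediator matrix and phenotype table by sample ID."""
    med = _read_table(mediators_path)
    pheno = _read_table(pheno_path)
    if transpose:
        med = med.set_index(med.columns[0]).T.reset_index(names=id_col)
    if id_col not in med.columns:
        # fall back to the first column as the sample identifier
        med = med.rename(columns={med.columns[0]: id_col})
    for col in (id_col, time_col, event_col, exposure_col):
        if col not in pheno.columns:
            raise InputError(f"phenotype table is missing column {col!r}")
    covariate_cols = covariate_cols or []
    missing = [c for c in covariate_cols if c not in pheno.columns]
    if missing:
        raise InputError(f"phenotype table is missing covariate columns {missing}")

    med = med.set_index(id_col)
    pheno = pheno.set_index(id_col)
    if set(med.index) != set(pheno.index):
        raise InputError(
            "sample IDs differ between mediator and phenotype tables "
            f"({len(med)} vs {len(pheno)} rows; "
            f"{len(set(med.index) & set(pheno.index))} shared)"
        )
    med = med.loc[pheno.index]  # realign by ID

    M = med.to_numpy(dtype=float, na_value=np.nan)
    if np.isnan(M).any():
        rows, cols = np.nonzero(np.isnan(M))
        raise InputError(
            "mediator matrix contains missing values, e.g. sample "
            f"{med.index[rows[0]]!r} / mediator {med.columns[cols[0]]!r}"
        )
    time = pheno[time_col].to_numpy(dtype=float)
    event = pheno[event_col].to_numpy()
    if not np.isin(event, (0, 1)).all():
        bad = sorted(set(event) - {0, 1})
        raise InputError(f"event column must be 0/1; found {bad}")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise InputError("observed times must be positive and non-missing")
    X = pheno[exposure_col].to_numpy(dtype=float)
    Z = (
        pheno[covariate_cols].to_numpy(dtype=float)
        if covariate_cols
        else np.empty((len(pheno), 0))
    )
    if np.isnan(X).any() or np.isnan(Z).any():
        raise InputError("exposure/covariate columns contain missing values")
    return MediationDataset(
        X=X, Z=Z, M=M, time=time, event=event.astype(int),
        mediator_ids=list(med.columns),
    )


def write_dataset(
    dataset: MediationDataset,
    out_prefix: str | Path,
    truth: SimTruth | None = None,
) -> dict[str, Path]:
    """Write ``<prefix>_mediators.tsv``, ``<prefix>_pheno.tsv`` and, when
    truth is given, ``<prefix>_truth.json``; returns the paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ids = [f"S{i + 1}" for i in range(dataset.n)]
    med = pd.DataFrame(dataset.M, columns=dataset.mediator_ids)
    med.insert(0, "id", ids)
    med_path = out_prefix.parent / f"{out_prefix.name}_mediators.tsv"
    med.to_csv(med_path, sep="\t", index=False)

    pheno = pd.DataFrame({"id": ids, "time": dataset.time,
                          "event": dataset.event, "exposure": dataset.X})
    for k in range(dataset.Z.shape[1]):
        pheno[f"z{k + 1}"] = dataset.Z[:, k]
    pheno_path = out_prefix.parent / f"{out_prefix.name}_pheno.tsv"
    pheno.to_csv(pheno_path, sep="\t", index=False)

    paths = {"mediators": med_path, "pheno": pheno_path}
    if truth is not None:
        truth_path = out_prefix.parent / f"{out_prefix.name}_truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "alpha": truth.alpha.tolist(),
                    "beta": truth.beta.tolist(),
                    "H1_1based": (truth.H1 + 1).tolist(),
                    "H1_ids": truth.h1_labels,
                },
                indent=2,
            )
        )
        paths["truth"] = truth_path
    return paths
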