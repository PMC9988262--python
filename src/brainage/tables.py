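"""Shared tabular containers.

A :class:`FeatureTable` is the unit flowing through harmonization and age
modelling: one modality's participants × named-features matrix together with
the site/scanner batch label of every participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class FeatureTable:
    """Participants × features for one modality, with batch labels.

    Parameters
    ----------
    data
        DataFrame indexed by participant id; columns are named features.
    batch
        Series of site/scanner batch labels aligned to ``data.index``.
    modality
        Free-form tag, conventionally ``"FC"``, ``"S"`` or ``"S+FC"``.
    """

    data: pd.DataFrame
    batch: pd.Series
    modality: str = ""

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.batch.index):
            self.batch = self.batch.reindex(self.data.index)
        if self.batch.isna().any():
            missing = self.batch.index[self.batch.isna()].tolist()
            raise ValueError(f"batch label missing for participants {missing[:5]}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("feature table contains non-finite values")

    @property
    def ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, ids) -> "FeatureTable":
        """Row-subset preserving feature order and batch alignment."""
        return FeatureTable(self.data.loc[ids], self.batch.loc[ids], self.modality)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "batch", self.batch)
        out.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path, modality: str = "") -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="id")
        if "batch" not in df.columns:
            raise ValueError(f"{path}: expected a 'batch' column")
        batch = df.pop("batch").astype(str)
        return cls(df.astype(float), batch, modality)


@dataclass
class ModelPerformance:
    """Merged cross-validated (or held-out) age-prediction metrics."""

    r: float
    r2: float
    mae: float
    rmse: float
    n: int
    context: str = "train-CV"

    def __post_init__(self) -> None:
        if self.rmse + 1e-12 < self.mae:
            raise ValueError("RMSE must be >= MAE")

    def as_dict(self) -> dict:
        return {"r": self.r, "R2": self.r2, "MAE": self.mae,
                "RMSE": self.rmse, "n": self.n, "context": self.context}


def performance_from_predictions(y_true, y_pred, context: str = "train-CV") -> ModelPerformance:
    """r, R² (1 − SS_res/SS_tot, not r²), MAE and RMSE on one merged vector."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between true and predicted ages")
    resid = y_true - y_pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r = float(np.corrcoef(y_true, y_pred)[0, 1]) if y_true.std() > 0 and y_pred.std() > 0 else 0.0
    return ModelPerformance(
        r=r,
        r2=1.0 - ss_res / ss_tot,
        mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=int(y_true.size),
        context=context,
    )
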