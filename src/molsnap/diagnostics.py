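"""PCA of the descriptor table and distance-to-model (DModX) diagnostics.

Principal components are fitted on centered, unit-variance descriptor
columns (correlation-matrix PCA: descriptor scales are arbitrary).  The
distance of an observation to the A-component model plane is

    DModX = sqrt( sum_k e_k**2 / (K - A) )

where e is the residual of the scaled observation after projection onto
the retained loadings, K the number of variables and A the number of
components.  Comparing the DModX distributions of training and test
partitions checks that the test molecules lie inside the chemical space
spanned by the training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .evalmetrics import mann_whitney

__all__ = ["PCAModel", "fit_pca", "dmodx", "dmodx_table", "compare_partitions"]


@dataclass(frozen=True)
class PCAModel:
    """Loadings and column statistics of a correlation-matrix PCA.

    ``loadings`` is (A, K) orthonormal; ``explained`` the per-component
    explained-variance fractions (non-increasing); ``columns`` the kept
    variable names (constant columns are dropped before fitting).
    """

    loadings: np.ndarray
    explained: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        a, k = self.loadings.shape
        if a < 1 or k < 1:
            raise ValueError("empty PCA model")
        if np.any(np.diff(self.explained) > 1e-9):
            raise ValueError("explained fractions must be non-increasing")
        if self.explained.sum() > 1.0 + 1e-9:
            raise ValueError("explained fractions sum above 1")
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(a), atol=1e-8):
            raise ValueError("loadings are not orthonormal")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_variables(self) -> int:
        return self.loadings.shape[1]

    def scale(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.std


def fit_pca(table: pd.DataFrame, n_components: int) -> PCAModel:
    """Correlation-matrix PCA of a descriptor table.

    Columns are centered and scaled to unit variance; constant columns
    are dropped with a warning.  Loading signs are fixed by making each
    loading's largest-magnitude entry positive, so the fit is fully
    deterministic and row-order invariant.
    """
    if len(table) < 2:
        raise ValueError("PCA needs at least 2 observations")
    values = table.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("descriptor table contains non-finite entries")
    std = values.std(axis=0, ddof=1)
    keep = std > 0
    if not keep.all():
        dropped = [c for c, k in zip(table.columns, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} constant columns", stacklevel=2)
    values = values[:, keep]
    std = std[keep]
    if values.shape[1] == 0:
        raise ValueError("no non-constant columns to fit")
    if not (1 <= n_components <= min(values.shape[0] - 1, values.shape[1])):
        raise ValueError(
            f"n_components={n_components} outside [1, {min(values.shape[0] - 1, values.shape[1])}]"
        )
    mean = values.mean(axis=0)
    scaled = (values - mean) / std
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(scaled)
    loadings = pca.components_.copy()
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(
        loadings=loadings,
        explained=pca.explained_variance_ratio_.copy(),
        mean=mean,
        std=std,
        columns=tuple(c for c, k in zip(table.columns, keep) if k),
    )


def dmodx(model: PCAModel, observation: Sequence[float]) -> float:
    """Distance of one observation to the model plane.

    sqrt( sum(e**2) / (K - A) ) with e the residual of the scaled
    observation after projection onto the A retained components.  Zero
    iff the observation lies exactly in the model plane; scaling the
    residual by c scales DModX by |c|.
    """
    k, a = model.n_variables, model.n_components
    if k <= a:
        raise ValueError(f"DModX undefined for K={k} <= A={a}")
    x = model.scale(np.asarray(observation, dtype=float))
    if x.shape != (k,):
        raise ValueError(f"observation must have K={k} variables")
    resid = x - model.loadings.T @ (model.loadings @ x)
    return float(np.sqrt(np.sum(resid**2) / (k - a)))


def dmodx_table(model: PCAModel, table: pd.DataFrame,
                partitions: Sequence[str]) -> pd.DataFrame:
    """Per-observation DModX with a Tra/Test partition tag.

    Returns a frame ``id, partition, dmodx`` (id from the table index),
    ready for CSV export and for :func:`compare_partitions`.
    """
    if len(partitions) != len(table):
        raise ValueError("partition tags must align with table rows")
    sub = table[list(model.columns)]
    values = [dmodx(model, row) for row in sub.to_numpy(dtype=float)]
    return pd.DataFrame({
        "id": table.index, "partition": list(partitions), "dmodx": values,
    })


def compare_partitions(report: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of DModX per partition plus a Mann-Whitney two-sided p.

    ``report`` is the output of :func:`dmodx_table` with exactly two
    distinct partition tags (typically "tra" and "test").  The p-value
    is attached to every row of the summary for CSV convenience.
    """
    parts = report["partition"].unique()
    if len(parts) != 2:
        raise ValueError(f"expected exactly 2 partitions, got {list(parts)}")
    a = report.loc[report["partition"] == parts[0], "dmodx"].to_numpy()
    b = report.loc[report["partition"] == parts[1], "dmodx"].to_numpy()
    _, p = mann_whitney(a, b)
    rows = []
    for tag, vals in ((parts[0], a), (parts[1], b)):
        rows.append({
            "partition": tag, "n": len(vals), "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "p_value": p,
        })
    return pd.DataFrame(rows)
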