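"""Developmental expression trajectories of module hub genes.

Expression from arrays spanning fetal to adult ages is normalized with a
two-stage compound z-score — each array column is standardized first
(removing global array effects), then each gene row is standardized across
arrays (removing gene-level offset and scale).  The trajectory of a hub
gene set is the per-age mean (over arrays of that age) of the mean
normalized score across the hub genes, overlaid with a cubic smoothing
spline whose penalty is chosen by generalized cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline


def compound_zscore(expr: pd.DataFrame) -> pd.DataFrame:
    """Two-stage standardization: arrays (columns) first, then genes (rows).

    Columns or rows with zero standard deviation map to 0 rather than NaN.
    Requires at least 2 arrays and 2 genes.
    """
    if expr.shape[1] < 2 or expr.shape[0] < 2:
        raise ValueError("need at least 2 genes and 2 arrays")
    X = expr.to_numpy(dtype=float)
    col_sd = X.std(axis=0)
    safe = np.where(col_sd == 0, 1.0, col_sd)
    Z = (X - X.mean(axis=0)) / safe
    Z[:, col_sd == 0] = 0.0
    row_sd = Z.std(axis=1)
    safe = np.where(row_sd == 0, 1.0, row_sd)
    Z = (Z - Z.mean(axis=1, keepdims=True)) / safe[:, None]
    Z[row_sd == 0, :] = 0.0
    return pd.DataFrame(Z, index=expr.index, columns=expr.columns)


@dataclass
class Trajectory:
    ages_days: np.ndarray
    age_labels: list[str]
    mean_score: np.ndarray
    smooth_ages: np.ndarray
    smooth_values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_days": self.ages_days,
                "age_label": self.age_labels,
                "mean_score": self.mean_score,
            }
        )


def hub_trajectory(
    normalized: pd.DataFrame, metadata: pd.DataFrame, hub_genes
) -> Trajectory:
    """Mean normalized hub-gene score per age, with a smoothed overlay.

    ``metadata`` (indexed by array) needs ``age_days`` plus ``age_value`` /
    ``age_unit`` for labels.  Hub genes absent from the matrix are dropped
    (all absent is an error).
    """
    present = [g for g in hub_genes if g in normalized.index]
    if not present:
        raise ValueError("no hub genes present in the expression set")
    per_array = normalized.loc[present].mean(axis=0)
    meta = metadata.loc[per_array.index]
    by_age = per_array.groupby(meta["age_days"]).mean()
    ages = by_age.index.to_numpy(dtype=float)
    labels = [
        f"{v:g} {u}"
        for v, u in (
            meta.drop_duplicates("age_days")
            .sort_values("age_days")[["age_value", "age_unit"]]
            .itertuples(index=False)
        )
    ]
    values = by_age.to_numpy()
    grid, smoothed = smooth_curve(ages, values)
    return Trajectory(ages, labels, values, grid, smoothed)


def smooth_curve(
    ages: np.ndarray, values: np.ndarray, n_grid: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic smoothing spline (GCV penalty) evaluated on a dense age grid.

    Duplicate ages are averaged first.  With fewer than 4 distinct ages the
    curve falls back to linear interpolation (with a warning).
    """
    df = pd.DataFrame({"age": np.asarray(ages, float), "y": np.asarray(values, float)})
    agg = df.groupby("age")["y"].mean()
    x, y = agg.index.to_numpy(), agg.to_numpy()
    grid = np.linspace(x.min(), x.max(), n_grid)
    if len(x) < 4:
        warnings.warn("fewer than 4 distinct ages: returning linear interpolation")
        return grid, np.interp(grid, x, y)
    if len(x) == 4:  # GCV needs >= 5 points; use the zero-penalty limit
        from scipy.interpolate import CubicSpline

        return grid, CubicSpline(x, y, bc_type="natural")(grid)
    spline = make_smoothing_spline(x, y)
    return grid, spline(grid)
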