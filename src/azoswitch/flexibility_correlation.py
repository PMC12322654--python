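"""Pearson correlation between structural flexibility and photo-properties.

Quantifies how the cosine-transformed dihedral angles of a conformer
ensemble shape the vertical excitation energy and oscillator strength: a
strongly negative r between the ring-planarity feature and the excitation
energy means in-plane configurations red-shift the transition, and the
magnitude of r grows with the electron-withdrawing strength of the para
substituent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "pearson_matrix",
    "energy_feature_scatter",
    "heatmap_export",
    "matrix_from_csv",
    "DEFAULT_COLUMN_ORDER",
]

#: canonical column ordering so heatmaps are comparable across compounds
DEFAULT_COLUMN_ORDER = (
    "energy_eV",
    "osc_strength",
    "cos_psi",
    "abs_cos_phi1",
    "abs_cos_phi2",
)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix with its variable labels and sample count."""

    labels: list[str]
    r: pd.DataFrame  # labels x labels; NaN marks undefined (constant column)
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("correlation requires at least 3 samples")
        vals = self.r.to_numpy(float)
        finite = np.isfinite(vals)
        if np.any(np.abs(vals[finite]) > 1 + 1e-12):
            raise ValueError("|r| must not exceed 1")

    def get(self, a: str, b: str) -> float:
        return float(self.r.loc[a, b])


def _order_columns(columns: Sequence[str]) -> list[str]:
    head = [c for c in DEFAULT_COLUMN_ORDER if c in columns]
    tail = [c for c in columns if c not in DEFAULT_COLUMN_ORDER]
    return head + tail


def pearson_matrix(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Product-moment correlation matrix over the selected numeric columns.

    Rows containing NaN are handled pairwise-complete; their counts are
    logged.  Constant columns yield NaN correlations (undefined, not zero)
    with a warning.
    """
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c not in ("frame_index", "frame", "isomer") and pd.api.types.is_numeric_dtype(table[c])
        ]
    columns = _order_columns(list(columns))
    missing = set(columns) - set(table.columns)
    if missing:
        raise KeyError(f"columns not in table: {sorted(missing)}")
    data = table[columns].astype(float)
    if len(data) < 3:
        raise ValueError("pearson_matrix requires at least 3 rows")

    n_dropped = int(data.isna().any(axis=1).sum())
    if n_dropped:
        logger.info("%d rows contain NaN; correlations are pairwise-complete", n_dropped)
    constant = [c for c in columns if data[c].nunique(dropna=True) <= 1]
    if constant:
        logger.warning("constant columns have undefined correlations: %s", constant)

    r = data.corr(method="pearson", min_periods=3)
    for c in constant:  # pandas leaves NaN already; make the diagonal explicit
        r.loc[c, :] = np.nan
        r.loc[:, c] = np.nan
    for c in set(columns) - set(constant):
        r.loc[c, c] = 1.0
    return CorrelationMatrix(columns, r, n=len(data))


def energy_feature_scatter(
    table: pd.DataFrame,
    feature: str,
    target: str = "energy_eV",
    path: str | Path | None = None,
) -> dict:
    """Paired (target, feature) export with a least-squares line and r.

    Returns a dict with the selected ``data`` frame, fitted ``slope``,
    ``intercept`` and ``r``; optionally writes the pairs as CSV.
    """
    for col in (feature, target):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
    data = table[[target, feature]].dropna()
    if data.empty:
        raise ValueError("no complete rows for the requested columns")
    x = data[target].to_numpy(float)
    y = data[feature].to_numpy(float)
    if len(data) >= 2 and np.ptp(x) > 0:
        slope, intercept = np.polyfit(x, y, 1)
        r = float(np.corrcoef(x, y)[0, 1]) if np.ptp(y) > 0 else float("nan")
    else:
        slope = intercept = r = float("nan")
    if path is not None:
        data.to_csv(path, index=False)
    return {"data": data, "slope": float(slope), "intercept": float(intercept), "r": r}


def heatmap_export(
    mat: CorrelationMatrix,
    png_path: str | Path | None = None,
    csv_path: str | Path | None = None,
):
    """Write the matrix as CSV and/or a diverging-scale heatmap image.

    The color scale is centered at 0 and spans [-1, 1]: brown tones for
    strong positive, turquoise for strong negative correlation; missing
    (undefined) cells are left blank.  Returns the matplotlib figure when an
    image is drawn, else None.
    """
    if csv_path is not None:
        mat.r.to_csv(csv_path)
    fig = None
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vals = np.ma.masked_invalid(mat.r.to_numpy(float))
        fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(mat.labels),) * 2)
        im = ax.imshow(vals, cmap="BrBG_r", vmin=-1, vmax=1)
        ax.set_xticks(range(len(mat.labels)), mat.labels, rotation=45, ha="right")
        ax.set_yticks(range(len(mat.labels)), mat.labels)
        for i in range(len(mat.labels)):
            for j in range(len(mat.labels)):
                if np.isfinite(mat.r.iat[i, j]):
                    ax.text(j, i, f"{mat.r.iat[i, j]:+.2f}", ha="center", va="center", fontsize=7)
        fig.colorbar(im, ax=ax, label="Pearson r")
        ax.set_title(f"n = {mat.n}")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return fig


def matrix_from_csv(path: str | Path, n: int) -> CorrelationMatrix:
    """Round-trip loader for matrices written by :func:`heatmap_export`."""
    r = pd.read_csv(path, index_col=0)
    return CorrelationMatrix(list(r.columns), r, n=n)
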