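"""Per-spot cell-type abundance weights.

Spots are decomposed against cell-type mean reference profiles by
nonnegative least squares on library-size-scaled counts; the resulting
weights are normalized to sum to 1 per spot and thresholded (weights below
tau masked to NaN) into assigned cell-type sets. A calibration utility picks
tau so the number of assigned types per spot tracks an externally supplied
cells-per-spot count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import nnls

DEFAULT_TAU = 0.01
DEFAULT_MAX_CELLS_PER_TYPE = 7500


@dataclass
class WeightMatrix:
    """Spot × cell-type weights. `weights` rows sum to 1 (pre-mask);
    `masked()` returns the thresholded view with entries < tau as NaN."""

    weights: pd.DataFrame
    tau: float = DEFAULT_TAU
    cells_per_spot: pd.Series | None = None
    flagged_spots: list = field(default_factory=list)

    def assigned_mask(self, tau: float | None = None) -> pd.DataFrame:
        t = self.tau if tau is None else t_check(tau)
        return self.weights >= t

    def masked(self, tau: float | None = None) -> pd.DataFrame:
        t = self.tau if tau is None else t_check(tau)
        return self.weights.where(self.weights >= t)

    def assigned_sets(self, tau: float | None = None) -> pd.Series:
        mask = self.assigned_mask(tau)
        return pd.Series(
            [tuple(mask.columns[row]) for row in mask.to_numpy()],
            index=mask.index,
        )


def t_check(tau: float) -> float:
    if not 0 <= tau < 1:
        raise ValueError(f"tau must be in [0, 1), got {tau}")
    return tau


def build_reference_profiles(
    atlas, max_cells_per_type: int = DEFAULT_MAX_CELLS_PER_TYPE, seed: int = 0
) -> pd.DataFrame:
    """Cell-type × gene mean raw-count profiles, seeded downsampling to at
    most `max_cells_per_type` cells per type."""
    types = sorted(atlas.obs["cell_type"].unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types for reference profiles")
    rng = np.random.default_rng(seed)
    X = sparse.csr_matrix(atlas.X)
    rows = []
    for t in types:
        idx = np.where((atlas.obs["cell_type"] == t).to_numpy())[0]
        if len(idx) == 0:
            raise ValueError(f"cell type {t!r} has 0 cells")
        if len(idx) > max_cells_per_type:
            idx = rng.choice(idx, size=max_cells_per_type, replace=False)
        rows.append(np.asarray(X[idx].mean(axis=0)).ravel())
    return pd.DataFrame(rows, index=types, columns=list(atlas.var_names))


def decompose_spot(counts: np.ndarray, profiles: pd.DataFrame) -> np.ndarray:
    """Weight vector for one spot: NNLS fit of the library-size-scaled spot
    vector against library-size-scaled profiles, renormalized to sum to 1.
    An all-zero spot yields a uniform row (caller flags it)."""
    P = profiles.to_numpy(dtype=float)
    psum = P.sum(axis=1)
    if np.any(psum <= 0):
        bad = [profiles.index[i] for i in np.where(psum <= 0)[0]]
        raise ValueError(f"all-zero reference profile(s): {bad}")
    A = (P / psum[:, None]).T
    y = np.asarray(counts, dtype=float).ravel()
    tot = y.sum()
    if tot == 0:
        return np.full(P.shape[0], 1.0 / P.shape[0])
    w, _ = nnls(A, y / tot)
    s = w.sum()
    if s == 0:
        return np.full(P.shape[0], 1.0 / P.shape[0])
    return w / s


def decompose(
    spots, profiles: pd.DataFrame, tau: float = DEFAULT_TAU,
    cells_per_spot: pd.Series | None = None,
) -> WeightMatrix:
    """Decompose every spot of an AnnData (or spot×gene DataFrame) against
    the reference profiles; genes are intersected and aligned."""
    t_check(tau)
    if hasattr(spots, "var_names"):
        genes = list(spots.var_names)
        X = sparse.csr_matrix(spots.X).toarray()
        index = list(spots.obs_names)
    else:
        genes = list(spots.columns)
        X = spots.to_numpy(dtype=float)
        index = list(spots.index)
    common = [g for g in genes if g in set(profiles.columns)]
    if not common:
        raise ValueError("no genes shared between spots and reference profiles")
    prof = profiles[common]
    gidx = [genes.index(g) for g in common]
    Xc = X[:, gidx]
    W = np.vstack([decompose_spot(Xc[i], prof) for i in range(Xc.shape[0])])
    flagged = [index[i] for i in np.where(Xc.sum(axis=1) == 0)[0]]
    weights = pd.DataFrame(W, index=index, columns=list(profiles.index))
    return WeightMatrix(weights, tau=tau, cells_per_spot=cells_per_spot,
                        flagged_spots=flagged)


def threshold_assign(wm: WeightMatrix, tau: float | None = None) -> pd.Series:
    """Assigned cell-type set per spot: types with weight >= tau (entries
    strictly below tau are masked; a weight exactly at tau is kept)."""
    return wm.assigned_sets(tau)


def calibrate_threshold(
    wm: WeightMatrix, cells_per_spot: pd.Series | None = None,
    tau_grid=None,
) -> pd.DataFrame:
    """For each tau in the grid, mean |#assigned types − cells/spot|; the
    report is sorted as given, with the optimum in `.attrs['best_tau']`."""
    cps = cells_per_spot if cells_per_spot is not None else wm.cells_per_spot
    if cps is None:
        raise ValueError(
            "cells_per_spot is required: supply per-spot cell counts "
            "(e.g. from image segmentation or simulation ground truth)"
        )
    if tau_grid is None:
        tau_grid = np.round(np.arange(0.0, 0.201, 0.005), 3)
    tau_grid = list(tau_grid)
    if len(tau_grid) == 0:
        raise ValueError("empty tau grid")
    cps = cps.reindex(wm.weights.index)
    rows = []
    for tau in tau_grid:
        n_assigned = wm.assigned_mask(t_check(float(tau))).sum(axis=1)
        rows.append(
            {"tau": float(tau),
             "mean_abs_error": float((n_assigned - cps).abs().mean()),
             "mean_assigned": float(n_assigned.mean())}
        )
    report = pd.DataFrame(rows)
    report.attrs["best_tau"] = float(report.loc[report["mean_abs_error"].idxmin(), "tau"])
    return report


def read_weights_tsv(path) -> WeightMatrix:
    """Adapter for externally computed weight tables (spots × types TSV with
    a header row of type names); rows are renormalized to sum to 1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    rows = df.sum(axis=1)
    if (rows <= 0).any():
        raise ValueError("external weight table has non-positive row sums")
    return WeightMatrix(df.div(rows, axis=0))


def write_weights_tsv(wm: WeightMatrix, path) -> None:
    wm.weights.to_csv(path, sep="\t")
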