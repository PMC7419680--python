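"""Immune deconvolution by nu-support-vector regression.

Bulk expression is modeled as a non-negative combination of cell-type
reference profiles (an LM22-like signature matrix). For each sample a
linear-kernel nu-SVR of the (z-scored) mixture on the (z-scored) reference
columns is fitted over a small nu grid; negative coefficients are
truncated at zero and the rest renormalized to fractions summing to one.
The nu with the lowest reconstruction RMSE wins. Significance comes from
a permutation null: random mixtures drawn from the dataset's expression
values are deconvolved the same way, and a sample's p-value is the
fraction of null fits whose correlation reaches its observed one.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_GENE_OVERLAP = 0.5
DEFAULT_NU_GRID = (0.25, 0.5, 0.75)


def read_signature_matrix(path) -> pd.DataFrame:
    """Read a gene-by-celltype reference matrix (TSV, gene ids first column)."""
    ref = pd.read_csv(path, sep="\t", index_col=0)
    ref.index = [str(g).strip().upper() for g in ref.index]
    _validate_reference(ref)
    return ref


def _validate_reference(ref: pd.DataFrame) -> None:
    if ref.shape[1] < 2:
        raise ValueError("signature matrix needs at least two cell types")
    if ref.columns.has_duplicates:
        raise ValueError("duplicate cell-type names in signature matrix")
    if ref.isna().any().any():
        raise ValueError("signature matrix must not contain missing values")


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant vector/matrix")
    return (a - a.mean()) / sd


def _fit_one(X: np.ndarray, y: np.ndarray, nu_grid: Sequence[float]):
    """Best-RMSE nu-SVR fit; returns (fractions, rmse, corr, nu)."""
    best = None
    for nu in nu_grid:
        model = NuSVR(nu=nu, C=1.0, kernel="linear")
        model.fit(X, y)
        coef = np.asarray(model.coef_).ravel()
        w = np.clip(coef, 0.0, None)
        if w.sum() == 0:  # degenerate fit: fall back to the largest coefficient
            w = np.zeros_like(coef)
            w[int(np.argmax(coef))] = 1.0
        fitted = X @ w + model.intercept_
        rmse = float(np.sqrt(np.mean((fitted - y) ** 2)))
        corr = float(np.corrcoef(fitted, y)[0, 1]) if fitted.std() > 0 else 0.0
        if best is None or rmse < best[1]:
            best = (w / w.sum(), rmse, corr, nu)
    return best


def deconvolve(
    m: ExpressionMatrix,
    ref: pd.DataFrame,
    nu_grid: Sequence[float] = DEFAULT_NU_GRID,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate relative immune cell-type fractions for every sample.

    Returns a DataFrame indexed by sample with one fraction column per cell
    type (non-negative, summing to 1) plus ``rmse``, ``corr``, ``p`` and
    ``nu``. Requires at least half the reference genes to be measured.
    ``n_perm`` random mixtures (resampled from the dataset's own expression
    values) build a single shared null of fit correlations.
    """
    _validate_reference(ref)
    shared = [g for g in ref.index if g in m.gene_ids]
    overlap = len(shared) / ref.shape[0]
    if overlap < MIN_GENE_OVERLAP:
        raise ValueError(
            f"only {len(shared)}/{ref.shape[0]} reference genes in the matrix "
            f"(need >= {MIN_GENE_OVERLAP:.0%})"
        )
    X = _zscore(ref.loc[shared].to_numpy(dtype=float))
    records = []
    for sample in m.sample_ids:
        y = _zscore(m.values.loc[shared, sample].to_numpy(dtype=float))
        frac, rmse, corr, nu = _fit_one(X, y, nu_grid)
        records.append((frac, rmse, corr, nu))

    rng = np.random.default_rng(seed)
    pool = m.values.to_numpy(dtype=float).ravel()
    null_corr = np.empty(n_perm)
    for b in range(n_perm):
        y_star = rng.choice(pool, size=len(shared), replace=True)
        if y_star.std() == 0:
            null_corr[b] = 0.0
            continue
        _, _, null_corr[b], _ = _fit_one(X, _zscore(y_star), nu_grid)

    out = pd.DataFrame(
        [f for f, *_ in records], index=m.sample_ids, columns=ref.columns
    )
    out["rmse"] = [r for _, r, *_ in records]
    out["corr"] = [c for *_, c, _ in records]
    out["p"] = [(null_corr >= c).mean() for *_, c, _ in records]
    out["nu"] = [nu for *_, nu in records]
    return out
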