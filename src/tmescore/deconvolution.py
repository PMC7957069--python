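"""Signature-based immune-cell deconvolution of bulk expression.

Estimates per-sample relative proportions of the 22 leukocyte types by
regressing each bulk marker-gene vector on the signature basis, in the
style of support-vector deconvolution: nu-SVR on standardized features
with a nu grid, keeping the fit with the lowest reconstruction RMSE, or a
dependency-light non-negative least squares fallback. Either way,
negative coefficients are zeroed and the remainder renormalized to the
simplex, so only relative abundances are produced.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls as _nnls
from sklearn.svm import NuSVR

from .datatypes import ExpressionMatrix, FractionMatrix, SignatureMatrix

logger = logging.getLogger("tmescore")

NU_GRID = (0.25, 0.5, 0.75)


class DeconvolutionError(ValueError):
    pass


def _solve_nnls(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    w, _ = _nnls(S, b)
    return w


def _solve_nusvr(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    # Standardize: signature globally, each mixture vector on its own
    # mean/sd — this makes the result invariant to bulk rescaling.
    Sz = (S - S.mean()) / S.std()
    bz = (b - b.mean()) / b.std()
    best_w, best_rmse = None, np.inf
    for nu in NU_GRID:
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        model.fit(Sz, bz)
        w = model.coef_.ravel()
        rmse = float(np.sqrt(np.mean((model.predict(Sz) - bz) ** 2)))
        if rmse < best_rmse:
            best_w, best_rmse = w, rmse
    return best_w


def estimate_fractions(
    bulk: ExpressionMatrix,
    signature: SignatureMatrix,
    method: str = "nu-svr",
) -> FractionMatrix:
    """Estimate cell-type proportions for every bulk sample.

    Requires linear-scale bulk expression and at least 50% of the
    signature's marker genes present in the bulk matrix; markers absent
    from the bulk are dropped with a log message, never imputed.
    """
    if method not in ("nu-svr", "nnls"):
        raise ValueError(f"unknown method {method!r}")
    if bulk.scale != "linear":
        raise DeconvolutionError("bulk expression must be on the linear scale")
    markers = [g for g in signature.marker_genes if g in bulk.data.index]
    overlap = len(markers) / len(signature.marker_genes)
    if overlap < 0.5:
        raise DeconvolutionError(
            f"only {overlap:.0%} of signature marker genes present in bulk (< 50%)"
        )
    if overlap < 1.0:
        logger.info(
            "deconvolution: %d/%d marker genes absent from bulk, dropped",
            len(signature.marker_genes) - len(markers), len(signature.marker_genes),
        )
    S = signature.data.loc[markers].to_numpy(dtype=float)
    B = bulk.data.loc[markers].to_numpy(dtype=float)

    solver = _solve_nnls if method == "nnls" else _solve_nusvr
    rows = []
    for j, sample in enumerate(bulk.sample_ids):
        b = B[:, j]
        if not b.any():
            raise DeconvolutionError(f"sample {sample!r} is all-zero on marker genes")
        w = np.clip(solver(S, b), 0.0, None)
        total = w.sum()
        if total <= 0:
            raise DeconvolutionError(
                f"sample {sample!r}: no non-negative support in the signature basis"
            )
        rows.append(w / total)
    frame = pd.DataFrame(np.vstack(rows), index=bulk.sample_ids,
                         columns=signature.cell_types)
    return FractionMatrix(frame)


def fraction_correlations(fractions: FractionMatrix):
    """All pairwise Pearson correlations between cell-type fraction profiles.

    Returns ``(r, p)`` DataFrames (cell types x cell types). ``p`` comes
    from the t-distribution transform of r with n - 2 degrees of freedom.
    A zero-variance cell type yields NaN (undefined, flagged by a warning),
    never 0.
    """
    X = fractions.data.to_numpy(dtype=float)
    n, k = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for correlations")
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "fraction_correlations: zero-variance cell type(s) %s -> r undefined",
            [c for c, d in zip(fractions.cell_types, degenerate) if d],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, np.where(degenerate, np.nan, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    p[np.isnan(r)] = np.nan
    cols = fractions.cell_types
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )
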