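"""Two-group differential expression with empirical-Bayes moderation.

Per gene, the ordinary pooled two-sample t ingredients are computed on
log2(x + 1) values; residual variances are then shrunk toward a common
prior estimated from the marginal distribution of the gene-wise sample
variances by moment matching. Under the hierarchical model

    s_g^2 | sigma_g^2 ~ sigma_g^2 * chi^2_d / d,
    1 / sigma_g^2 ~ chi^2_d0 / (d0 * s0^2),

the marginal of s_g^2 is s0^2 * F(d, d0), whose first two moments give
closed-form estimates of (d0, s0^2). The moderated statistic

    t_g = (mean_a - mean_b) / (s_tilde_g * sqrt(1/n_a + 1/n_b)),
    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),

is referred to a t distribution with d + d0 degrees of freedom, and
Benjamini-Hochberg adjustment is applied across all tested genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["moderated_de_test", "adjust_bh", "filter_degs", "estimate_prior"]

_MAX_DF = 1e7  # stands in for an infinite prior df


def estimate_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-matched (d0, s0^2) of the scaled-F marginal of sample variances.

    ``c = Var(s^2) / E(s^2)^2`` relates to the F moments as
    ``c = 2 (d + d0 - 2) / (d (d0 - 4))``; solving gives
    ``d0 = (4 c d + 2 d - 4) / (c d - 2)``. When ``c d <= 2`` the observed
    spread is below the pure sampling spread and the prior df is infinite
    (complete shrinkage to the mean variance).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if len(positive) < 2:
        return _MAX_DF, float(s2.mean()) if len(s2) else 1.0
    m = float(positive.mean())
    c = float(positive.var(ddof=1)) / m**2
    if c * d <= 2.0:
        return _MAX_DF, m
    d0 = (4.0 * c * d + 2.0 * d - 4.0) / (c * d - 2.0)
    d0 = min(max(d0, 1e-3), _MAX_DF)
    s0_sq = m * (d0 - 2.0) / d0 if d0 > 2 else m
    return float(d0), float(s0_sq)


def moderated_de_test(expr, groups, group_order=None) -> pd.DataFrame:
    """Moderated-t differential expression between two sample groups.

    Parameters
    ----------
    expr : ExpressionMatrix
        Transformed to log2(x + 1) internally when on the linear scale.
    groups : mapping or Series
        Sample id -> group label (exactly two levels, each with >= 2
        samples).
    group_order : optional pair
        Which level is "a" (log2fc = mean_a - mean_b). Defaults to order
        of first appearance.

    Returns a per-gene frame with mean_a, mean_b, log2fc, t, df, p, p_adj
    and a ``flag`` column ("zero_variance" where both groups are constant;
    such genes get p = 1).
    """
    log_expr = expr.to_log2p1()
    groups = pd.Series(groups).reindex(log_expr.sample_ids)
    if groups.isna().any():
        raise ValueError("groups missing for some samples")
    levels = list(pd.unique(groups)) if group_order is None else list(group_order)
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    mask_a = (groups == levels[0]).to_numpy()
    mask_b = (groups == levels[1]).to_numpy()
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    X = log_expr.data.to_numpy(dtype=float)
    A, B = X[:, mask_a], X[:, mask_b]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ss = A.var(axis=1, ddof=1) * (n_a - 1) + B.var(axis=1, ddof=1) * (n_b - 1)
    d = n_a + n_b - 2
    s2 = ss / d
    d0, s0_sq = estimate_prior(s2, d)
    s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
    se = np.sqrt(s2_tilde * (1.0 / n_a + 1.0 / n_b))
    diff = mean_a - mean_b
    # genes constant within both groups carry no testable variance signal
    zero_var = (s2 == 0) | (se == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, diff / np.where(se == 0, 1.0, se))
    df_total = min(d + d0, _MAX_DF)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(zero_var, 1.0, p)
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": diff,
            "t": t,
            "df": df_total,
            "p": p,
            "flag": np.where(zero_var, "zero_variance", ""),
        },
        index=log_expr.gene_ids,
    )
    out["p_adj"] = adjust_bh(out["p"].to_numpy())
    return out


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(de: pd.DataFrame, p_adj_max: float = 0.05,
                lfc_min: float = float(np.log2(1.5))) -> list[str]:
    """Features passing BOTH strict thresholds: p_adj < p_adj_max and
    |log2fc| > lfc_min. ``lfc_min`` may be 0 (p-only filtering)."""
    if p_adj_max <= 0 or lfc_min < 0:
        raise ValueError("thresholds must be positive (lfc_min may be 0)")
    keep = (de["p_adj"] < p_adj_max) & (de["log2fc"].abs() > lfc_min)
    return list(de.index[keep])
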