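"""Subtype characterization: cell network, group tests, mutations, ROC.

Covers the comparisons run once the TMEscore subtypes exist: the
cell-cell correlation network annotated with per-cell-type prognostic
direction, rank-based comparisons of continuous measures (TIDE-like
response scores, fractions, TMEscore by MSI status), per-gene Fisher
tests of mutation frequency, variant-allele-fraction comparisons, tumor
mutation burden, and the paired ROC comparison of TMEscore against TMB
with the DeLong test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ClinicalTable, FractionMatrix, MafTable
from .survival import cox_univariate

logger = logging.getLogger("tmescore")

__all__ = [
    "CellNetwork",
    "RocResult",
    "build_cell_network",
    "group_compare",
    "compute_tmb",
    "mutation_frequency_test",
    "vaf_compare",
    "roc_curve_points",
    "roc_compare",
]


@dataclass
class CellNetwork:
    """Node table (cell type, cluster, OS direction) + edge table (r, p)."""

    nodes: pd.DataFrame
    edges: pd.DataFrame


def build_cell_network(
    fractions: FractionMatrix,
    clinical: ClinicalTable,
    cell_clusters: pd.Series | None = None,
    r_min: float = 0.2,
) -> CellNetwork:
    """Cell-cell correlation network with per-type prognostic annotation.

    Edges keep pairs with ``|pearson_r| >= r_min`` (i < j, each pair
    once); every pairwise r is computed first, the threshold is a display
    filter. Node OS direction comes from a univariate Cox fit on each
    cell type's fraction: "favorable" for beta < 0 with p < 0.05, "risk"
    for beta > 0 with p < 0.05, "ns" otherwise.
    """
    from .deconvolution import fraction_correlations

    clin = clinical.aligned(fractions.sample_ids)
    times = clin.data["os_time"].to_numpy(dtype=float)
    events = clin.data["os_event"].to_numpy(dtype=int)
    node_rows = []
    for ct in fractions.cell_types:
        frac = fractions.data[ct].to_numpy(dtype=float)
        if frac.std() == 0:
            direction, p, beta = "ns", np.nan, np.nan
        else:
            fit = cox_univariate(times, events, frac)
            beta, p = fit.beta, fit.p
            if p < 0.05:
                direction = "favorable" if beta < 0 else "risk"
            else:
                direction = "ns"
        node_rows.append(
            {
                "cell_type": ct,
                "cell_cluster": (cell_clusters.get(ct, "")
                                 if cell_clusters is not None else ""),
                "os_direction": direction,
                "os_beta": beta,
                "os_p": p,
            }
        )
    nodes = pd.DataFrame(node_rows)

    r, p = fraction_correlations(fractions)
    edge_rows = []
    types = fractions.cell_types
    for i in range(len(types)):
        for j in range(i + 1, len(types)):
            rij = r.iloc[i, j]
            if np.isfinite(rij) and abs(rij) >= r_min:
                edge_rows.append(
                    {"cell_type_a": types[i], "cell_type_b": types[j],
                     "pearson_r": rij, "p": p.iloc[i, j]}
                )
    edges = pd.DataFrame(edge_rows,
                         columns=["cell_type_a", "cell_type_b", "pearson_r", "p"])
    return CellNetwork(nodes=nodes, edges=edges)


def group_compare(values, labels):
    """Two-sided Wilcoxon rank-sum comparison of two groups.

    Exact enumeration when the combined size is <= 20 and the data are
    tie-free; otherwise the tie-corrected normal approximation. Returns
    ``(statistic, p, median_a, median_b)`` where the statistic is the
    Mann-Whitney U of the first group.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(values)) < len(values)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        # all observations identical; no evidence either way
        return float(len(a) * len(b) / 2.0), 1.0, float(a[0]), float(b[0])
    method = "exact" if (len(a) + len(b) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0)), float(np.median(a)), float(np.median(b))


def compute_tmb(maf: MafTable, sample_ids, exome_mb: float = 38.0,
                nonsyn_only: bool = True) -> pd.Series:
    """Tumor mutation burden: mutations per megabase of exome.

    Restricted to protein-altering variant classes by default. Samples
    absent from the MAF get TMB 0 (logged).
    """
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    rows = maf.nonsilent() if nonsyn_only else maf.data
    counts = rows.groupby("sample_id").size()
    tmb = counts.reindex(list(sample_ids), fill_value=0) / exome_mb
    absent = [s for s in sample_ids if s not in counts.index]
    if absent:
        logger.info("compute_tmb: %d sample(s) absent from MAF -> TMB 0", len(absent))
    return tmb.rename("tmb")


def mutation_frequency_test(maf: MafTable, subtypes: pd.Series) -> pd.DataFrame:
    """Per-gene Fisher exact test of mutation frequency between subtypes.

    A sample counts as mutated once per gene regardless of how many rows
    it contributes. Two-sided p sums the hypergeometric probabilities of
    all tables (at fixed margins) no more likely than the observed one.
    A BH-adjusted column is attached alongside the raw p.
    """
    from .diffexpr import adjust_bh

    subtypes = pd.Series(subtypes)
    levels = sorted(subtypes.unique())
    if len(levels) != 2:
        raise ValueError("need exactly two subtypes")
    grp_a = set(subtypes.index[subtypes == levels[0]])
    grp_b = set(subtypes.index[subtypes == levels[1]])
    known = grp_a | grp_b
    rows = maf.data[maf.data["sample_id"].isin(known)]
    mutated = rows.groupby("hugo_symbol")["sample_id"].agg(set)
    records = []
    for gene, carriers in mutated.items():
        ma, mb = len(carriers & grp_a), len(carriers & grp_b)
        table = [[ma, len(grp_a) - ma], [mb, len(grp_b) - mb]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        records.append({"gene": gene, f"n_mut_{levels[0]}": ma,
                        f"n_mut_{levels[1]}": mb, "fisher_p": p})
    out = pd.DataFrame(records).set_index("gene")
    if len(out):
        out["fisher_p_adj"] = adjust_bh(out["fisher_p"].to_numpy())
        out = out.sort_values("fisher_p")
    return out


def vaf_compare(maf: MafTable, subtypes: pd.Series, genes=None) -> pd.DataFrame:
    """Per-gene comparison of variant allele fractions between subtypes.

    Each mutation row contributes one VAF. Genes without at least one
    mutation in each subtype are skipped and flagged.
    """
    subtypes = pd.Series(subtypes)
    levels = sorted(subtypes.unique())
    if len(levels) != 2:
        raise ValueError("need exactly two subtypes")
    data = maf.data.copy()
    data["vaf"] = maf.vaf
    data["subtype"] = data["sample_id"].map(subtypes)
    data = data.dropna(subset=["subtype"])
    if genes is None:
        genes = sorted(data["hugo_symbol"].unique())
    records = []
    for gene in genes:
        rows = data[data["hugo_symbol"] == gene]
        a = rows.loc[rows["subtype"] == levels[0], "vaf"].to_numpy()
        b = rows.loc[rows["subtype"] == levels[1], "vaf"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            records.append({"gene": gene, "skipped": True,
                            f"median_vaf_{levels[0]}": np.nan,
                            f"median_vaf_{levels[1]}": np.nan, "p": np.nan})
            continue
        _, p, med_a, med_b = group_compare(
            np.concatenate([a, b]), np.array([levels[0]] * len(a) + [levels[1]] * len(b))
        )
        records.append({"gene": gene, "skipped": False,
                        f"median_vaf_{levels[0]}": med_a,
                        f"median_vaf_{levels[1]}": med_b, "p": p})
    return pd.DataFrame(records).set_index("gene")


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _auc_rank(score, label):
    """AUC via the Mann-Whitney identity; tied scores count 1/2."""
    ranks = stats.rankdata(score)
    n1 = int(label.sum())
    n0 = len(label) - n1
    rank_sum = ranks[label == 1].sum()
    return (rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def roc_curve_points(score, label) -> RocResult:
    """ROC curve of a score against a binary label (1 = positive).

    The curve runs from (0, 0) to (1, 1); the AUC is the rank-statistic
    (Mann-Whitney) value, exactly the trapezoidal area of the curve.
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label, dtype=int)
    if set(np.unique(label)) - {0, 1} or label.min() == label.max():
        raise ValueError("label must be binary with both classes present")
    order = np.argsort(-score, kind="stable")
    s, y = score[order], label[order]
    distinct = np.r_[np.diff(s) != 0, True]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    thresholds = np.r_[np.inf, s[distinct]]
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr,
                     auc=float(_auc_rank(score, label)))


def _delong_components(score, label):
    """Structural components V10 (positives) and V01 (negatives)."""
    pos = score[label == 1]
    neg = score[label == 0]
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / len(neg)
                    for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / len(pos)
                    for x in neg])
    return v10, v01


def roc_compare(score_a, score_b, label):
    """Paired ROC comparison by the DeLong test.

    Returns ``(roc_a, roc_b, delta_auc, p)`` with ``delta_auc = AUC_a -
    AUC_b`` and a two-sided p from the structural-components variance of
    the paired AUC difference. Comparing a score against itself yields
    p = 1 by convention (zero variance).
    """
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    label = np.asarray(label, dtype=int)
    if len(score_a) != len(score_b) or len(score_a) != len(label):
        raise ValueError("scores and label must be paired on the same samples")
    roc_a = roc_curve_points(score_a, label)
    roc_b = roc_curve_points(score_b, label)
    va10, va01 = _delong_components(score_a, label)
    vb10, vb01 = _delong_components(score_b, label)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    delta = roc_a.auc - roc_b.auc
    if var_delta <= 1e-300:
        p = 1.0
    else:
        z = delta / np.sqrt(var_delta)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return roc_a, roc_b, float(delta), p
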