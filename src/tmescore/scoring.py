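"""TMEscore model: signature genes -> Cox-sign split -> score -> subtypes.

The construction mirrors the published procedure: differentially
expressed genes between TME clusters define sample classes; a random
forest reduces them to a non-redundant cluster-signature set; a
univariate Cox screen splits the signature by the SIGN of the
coefficient (only the sign is used, never the magnitude); the per-sample
score is

    TMEscore = sum_{g in X} log2(x_g + 1) - sum_{g in Y} log2(y_g + 1)

and a maximally selected rank statistic dichotomizes the score into
TMEscore-high / TMEscore-low subtypes.

Orientation: the score-positive X set holds the PROTECTIVE genes (Cox
beta < 0) and the score-negative Y set the hazard-increasing genes
(beta > 0), so a higher TMEscore means a more favorable, immune-active
microenvironment and the TMEscore-high subtype carries the better
prognosis — the direction the construction is defined to produce and the
one its external validations rest on. See docs/methods.md.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .datatypes import ClinicalTable, ExpressionMatrix
from .survival import cox_univariate, maxstat_cutpoint

logger = logging.getLogger("tmescore")

__all__ = [
    "TMEModel",
    "derive_cluster_signature",
    "split_by_cox_sign",
    "compute_tmescore",
    "dichotomize",
    "apply_model",
]

HIGH_LABEL = "TMEscore-high"
LOW_LABEL = "TMEscore-low"


@dataclass
class TMEModel:
    """Frozen scoring artifact: gene sets plus the score cutpoint.

    ``positive_genes`` contribute positively to the score (the X set;
    protective, Cox beta < 0 in training), ``negative_genes`` negatively
    (the Y set; hazard-increasing genes). The JSON round trip is
    bit-exact, so reloaded models reproduce scores to the last bit.
    """

    positive_genes: list[str]
    negative_genes: list[str]
    cutpoint: float | None = None
    signature_genes: list[str] = field(default_factory=list)
    gene_stats: dict[str, dict] = field(default_factory=dict)
    trained_on: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.positive_genes) & set(self.negative_genes)
        if overlap:
            raise ValueError(f"gene(s) in both score sets: {sorted(overlap)[:5]}")
        if not self.signature_genes:
            self.signature_genes = list(self.positive_genes) + list(self.negative_genes)

    def to_json(self, path=None) -> str:
        payload = {
            "positive_genes": list(self.positive_genes),
            "negative_genes": list(self.negative_genes),
            "cutpoint": self.cutpoint,
            "signature_genes": list(self.signature_genes),
            "gene_stats": self.gene_stats,
            "trained_on": self.trained_on,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TMEModel":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            source = Path(source).read_text()
        payload = json.loads(source)
        return cls(**payload)


def derive_cluster_signature(
    expr: ExpressionMatrix,
    class_labels,
    n_trees: int = 1000,
    retain_rule: str = "decoy",
    top_n: int | None = None,
    n_repeats: int = 5,
    seed: int = 0,
) -> list[str]:
    """Reduce a DEG set to non-redundant cluster-signature genes.

    A random forest is trained to predict the K >= 2 sample classes from
    DEG expression on a stratified half of the cohort; genes are ranked
    by permutation importance of the log-loss on the held-out half (a
    forest saturates its training accuracy, which would flatten
    importances computed in-sample). Under the default ``"decoy"`` rule a
    second forest is fit on shuffled labels and genes are retained when
    their importance exceeds the decoy importance mean + 1 sd — the
    importance level the procedure achieves on pure noise. The
    ``"top-n"`` rule keeps the ``top_n`` best-ranked genes instead.
    """
    labels = pd.Series(class_labels).reindex(expr.sample_ids)
    if labels.isna().any():
        raise ValueError("class labels missing for some samples")
    if labels.nunique() < 2:
        raise ValueError("need at least 2 classes")
    X = expr.to_log2p1().data.to_numpy(dtype=float).T  # samples x genes
    y = labels.to_numpy()
    rng = np.random.default_rng(seed)

    # stratified half split: importance is evaluated out of sample
    train = np.zeros(len(y), dtype=bool)
    for level in np.unique(y):
        idx = np.flatnonzero(y == level)
        train[rng.choice(idx, size=max(len(idx) // 2, 1), replace=False)] = True
    if len(np.unique(y[~train])) < 2:
        train = rng.random(len(y)) < 0.5  # tiny degenerate inputs

    def _importances(target):
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X[train], target[train])
        result = permutation_importance(
            forest, X[~train], target[~train], n_repeats=n_repeats,
            scoring="neg_log_loss",
            random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
        )
        return result.importances_mean

    importance = _importances(y)
    genes = np.asarray(expr.gene_ids)
    order = np.argsort(-importance, kind="stable")
    if retain_rule == "top-n":
        if not top_n or top_n < 1:
            raise ValueError("top-n rule requires a positive top_n")
        keep = order[: min(top_n, len(genes))]
        return list(genes[np.sort(keep)])
    if retain_rule != "decoy":
        raise ValueError(f"unknown retain_rule {retain_rule!r}")
    decoy = _importances(rng.permutation(y))
    threshold = decoy.mean() + decoy.std(ddof=0)
    keep = importance > threshold
    if not keep.any():
        # fall back to the single best gene rather than an empty signature
        logger.warning("derive_cluster_signature: decoy threshold retains no "
                       "gene; keeping the top-ranked gene")
        keep[order[0]] = True
    return list(genes[keep])


def split_by_cox_sign(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    signature_genes,
    p_max: float = 1.0,
):
    """Split signature genes by the sign of their univariate Cox coefficient.

    Each gene is fit alone on its log2(x + 1) expression. Returns
    ``(hazard_positive, hazard_negative, stats)`` where ``stats`` is a
    per-gene frame (beta, se, p, converged, low_confidence). Genes with a
    non-convergent fit or beta exactly 0 are excluded (logged); genes
    with p > ``p_max`` are excluded when ``p_max < 1`` (the default keeps
    every gene — the published construction applies no p filter).
    """
    clin = clinical.aligned(expr.sample_ids)
    times = clin.data["os_time"].to_numpy(dtype=float)
    events = clin.data["os_event"].to_numpy(dtype=int)
    log_expr = expr.to_log2p1()
    hazard_pos, hazard_neg = [], []
    records = {}
    for gene in signature_genes:
        x = log_expr.data.loc[gene].to_numpy(dtype=float)
        if x.std() == 0:
            logger.warning("split_by_cox_sign: %s has zero variance, excluded", gene)
            continue
        fit = cox_univariate(times, events, x)
        records[gene] = {
            "beta": fit.beta, "se": fit.se, "p": fit.p,
            "converged": fit.converged, "low_confidence": fit.p > 0.05,
        }
        if not fit.converged or fit.beta == 0.0:
            logger.warning("split_by_cox_sign: %s excluded (converged=%s, beta=%g)",
                           gene, fit.converged, fit.beta)
            continue
        if p_max < 1.0 and fit.p > p_max:
            continue
        (hazard_pos if fit.beta > 0 else hazard_neg).append(gene)
    stats = pd.DataFrame.from_dict(records, orient="index")
    return hazard_pos, hazard_neg, stats


def compute_tmescore(expr: ExpressionMatrix, model: TMEModel) -> pd.Series:
    """Per-sample TMEscore from linear-scale expression.

    ``sum over X of log2(x + 1) - sum over Y of log2(y + 1)``. Genes of
    the model absent from the matrix are dropped with a warning; an
    entirely missing X or Y set is an error.
    """
    log_data = expr.to_log2p1().data
    pos = [g for g in model.positive_genes if g in log_data.index]
    neg = [g for g in model.negative_genes if g in log_data.index]
    dropped = (len(model.positive_genes) - len(pos)) + (len(model.negative_genes) - len(neg))
    if dropped:
        logger.warning("compute_tmescore: %d model gene(s) absent from input", dropped)
    if not pos or not neg:
        raise ValueError("no gene of the positive and/or negative set present")
    score = log_data.loc[pos].sum(axis=0) - log_data.loc[neg].sum(axis=0)
    return score.rename("tmescore")


def dichotomize(
    scores: pd.Series,
    clinical: ClinicalTable,
    minprop: float = 0.1,
    n_perm: int = 0,
    seed: int = 0,
):
    """Find the survival-optimal score cutpoint and label the samples.

    Returns ``(cutpoint_result, score_table)``; the score table holds
    ``tmescore`` and ``subtype`` (TMEscore-high iff score > cutpoint).
    """
    clin = clinical.aligned(list(scores.index))
    result = maxstat_cutpoint(
        clin.data["os_time"].to_numpy(dtype=float),
        clin.data["os_event"].to_numpy(dtype=int),
        scores.to_numpy(dtype=float),
        minprop=minprop, n_perm=n_perm, seed=seed,
    )
    table = label_scores(scores, result.cutpoint)
    return result, table


def label_scores(scores: pd.Series, cutpoint: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tmescore": scores,
            "subtype": np.where(scores > cutpoint, HIGH_LABEL, LOW_LABEL),
        },
        index=scores.index,
    )


def apply_model(expr_new: ExpressionMatrix, model: TMEModel,
                min_overlap: float = 0.5) -> pd.DataFrame:
    """Score a new cohort with a FROZEN model (gene sets and cutpoint).

    Requires at least ``min_overlap`` of each gene set to be present in
    the new matrix; overlap fractions are logged.
    """
    if model.cutpoint is None:
        raise ValueError("model has no cutpoint; fit dichotomize first")
    present = set(expr_new.gene_ids)
    for name, genes in (("positive", model.positive_genes),
                        ("negative", model.negative_genes)):
        frac = len(present.intersection(genes)) / len(genes) if genes else 0.0
        logger.info("apply_model: %s-set overlap %.0f%%", name, 100 * frac)
        if frac < min_overlap:
            raise ValueError(
                f"only {frac:.0%} of {name}-set genes present (< {min_overlap:.0%})"
            )
    scores = compute_tmescore(expr_new, model)
    return label_scores(scores, model.cutpoint)
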