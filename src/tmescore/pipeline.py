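"""End-to-end pipeline orchestration.

Reproduces the model-construction sequence on a cohort (simulated or
loaded): immune-cell deconvolution -> cell clustering and network ->
consensus K selection and K-means TME patterns -> differential
expression -> DEG-based sample re-clustering -> random-forest signature
reduction -> Cox-sign split -> TMEscore -> maxstat dichotomization ->
survival and genomic characterization. Every stage writes its tables
under ``outdir`` and a summary JSON records the headline counts. Runs
are deterministic given (inputs, config): all stage seeds derive from
``config.seed``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .characterization import (
    build_cell_network,
    compute_tmb,
    group_compare,
    mutation_frequency_test,
    roc_compare,
    vaf_compare,
)
from .clustering import (
    consensus_cluster,
    hierarchical_cluster_cells,
    kmeans,
    select_k,
    sse_curve,
)
from .config import RunConfig
from .datatypes import ClinicalTable, ExpressionMatrix, MafTable
from .deconvolution import estimate_fractions
from .diffexpr import filter_degs, moderated_de_test
from .scoring import (
    HIGH_LABEL,
    LOW_LABEL,
    TMEModel,
    compute_tmescore,
    derive_cluster_signature,
    dichotomize,
    split_by_cox_sign,
)
from .simulate import generate_signature_matrix, simulate_cohort
from .survival import km_estimate, logrank_test

logger = logging.getLogger("tmescore")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineResult:
    """All stage outputs of one run, plus the summary dictionary."""

    config: RunConfig
    expression: ExpressionMatrix = None
    signature: object = None
    clinical: ClinicalTable = None
    maf: MafTable = None
    truth: object = None
    fractions: object = None
    cell_clusters: pd.Series = None
    cell_network: object = None
    tme_consensus: object = None
    tme_k: int = None
    tme_labels: pd.Series = None
    de_table: pd.DataFrame = None
    degs: list = field(default_factory=list)
    class_consensus: object = None
    class_k: int = None
    class_labels: pd.Series = None
    model: TMEModel = None
    score_table: pd.DataFrame = None
    survival: dict = field(default_factory=dict)
    characterization: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _stage(name):
    def wrap(fn):
        def inner(result, *args, **kwargs):
            t0 = time.monotonic()
            try:
                out = fn(result, *args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.1fs", name, time.monotonic() - t0)
            return out
        return inner
    return wrap


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, reproducibly derived."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _union_degs(expr, labels, p_adj_max, lfc_min):
    """DEGs between K classes: pairwise union for K=2, one-vs-rest for K>2."""
    levels = sorted(pd.Series(labels).unique())
    if len(levels) == 2:
        de = moderated_de_test(expr, labels, group_order=levels)
        return filter_degs(de, p_adj_max, lfc_min), de
    genes = []
    de_last = None
    for level in levels:
        contrast = pd.Series(np.where(labels == level, "this", "rest"),
                             index=labels.index)
        de = moderated_de_test(expr, contrast, group_order=["this", "rest"])
        genes.extend(filter_degs(de, p_adj_max, lfc_min))
        de_last = de
    return sorted(set(genes)), de_last


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Run every enabled stage; see the module docstring for the sequence."""
    config.validate()
    seeds = _spawn_seeds(config.seed, 10)
    result = PipelineResult(config=config)
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    # ---- inputs -------------------------------------------------------
    sim = config.simulate
    if sim.enabled:
        signature = generate_signature_matrix(
            n_markers_per_type=sim.n_markers_per_type,
            fold=sim.signature_fold, seed=seeds[0],
        )
        expr, clinical, maf, truth = simulate_cohort(
            n_samples=sim.n_samples, signature=signature,
            subtype_composition_shift=sim.subtype_composition_shift,
            concentration=sim.concentration, n_background=sim.n_background,
            n_de_genes=sim.n_de_genes, de_lfc=sim.de_lfc,
            noise_sd=sim.noise_sd, true_beta=sim.true_beta,
            baseline_rate=sim.baseline_rate, censor_rate=sim.censor_rate,
            mut_mean_high=sim.mut_mean_high, mut_mean_low=sim.mut_mean_low,
            population_seed=sim.population_seed,
            seed=seeds[1],
        )
        result.truth = truth
    else:
        expr = tio.read_expression(config.inputs.expression,
                                   orientation=config.inputs.expression_orientation)
        clinical = tio.read_clinical(config.inputs.clinical)
        maf = tio.read_maf(config.inputs.maf) if config.inputs.maf else None
        signature = (tio.read_signature(config.inputs.signature)
                     if config.inputs.signature else None)
        if signature is None:
            raise PipelineError("stage 'inputs' failed: a signature matrix is "
                                "required for deconvolution")
    result.expression, result.clinical, result.maf = expr, clinical, maf
    result.signature = signature

    # ---- deconvolution ------------------------------------------------
    @_stage("deconvolve")
    def _deconvolve(res):
        return estimate_fractions(expr, signature, method=config.deconvolution.method)

    fractions = _deconvolve(result)
    result.fractions = fractions

    # ---- cell clustering + network -----------------------------------
    @_stage("cells")
    def _cells(res):
        clusters = hierarchical_cluster_cells(
            fractions, n_clusters=config.clustering.n_cell_clusters)
        network = build_cell_network(
            fractions, clinical, cell_clusters=clusters,
            r_min=config.characterization.network_r_min)
        return clusters, network

    result.cell_clusters, result.cell_network = _cells(result)

    # ---- TME patterns: consensus K on fractions, then K-means --------
    cl = config.clustering
    k_range = range(cl.k_min, cl.k_max + 1)

    @_stage("tme-patterns")
    def _patterns(res):
        X = fractions.data.to_numpy()
        cons = consensus_cluster(X, k_range, n_reps=cl.n_reps,
                                 subsample=cl.subsample, seed=seeds[2],
                                 inner_restarts=cl.inner_restarts,
                                 sample_ids=fractions.sample_ids)
        sse = sse_curve(X, k_range, n_restarts=cl.kmeans_restarts, seed=seeds[3])
        k = select_k(cons, sse, pac_tol=cl.pac_tol)
        labels, _ = kmeans(X, k, n_restarts=cl.kmeans_restarts, seed=seeds[3])
        labels = pd.Series([f"TMEcluster{int(c) + 1}" for c in labels],
                           index=fractions.sample_ids, name="tme_cluster")
        return cons, k, labels

    result.tme_consensus, result.tme_k, result.tme_labels = _patterns(result)

    # ---- differential expression between TME patterns ----------------
    @_stage("diffexpr")
    def _diffexpr(res):
        return _union_degs(expr, res.tme_labels,
                           config.diffexpr.p_adj_max, config.diffexpr.lfc_min)

    result.degs, result.de_table = _diffexpr(result)
    if not result.degs:
        raise PipelineError("stage 'diffexpr' failed: no DEG passed thresholds")

    # ---- DEG-based sample classes ------------------------------------
    @_stage("classes")
    def _classes(res):
        deg_expr = expr.subset_genes(res.degs).to_log2p1()
        X = deg_expr.data.to_numpy().T
        cons = consensus_cluster(X, k_range, n_reps=cl.n_reps,
                                 subsample=cl.subsample, seed=seeds[4],
                                 inner_restarts=cl.inner_restarts,
                                 sample_ids=expr.sample_ids)
        k = select_k(cons, pac_tol=cl.pac_tol)
        labels, _ = kmeans(X, k, n_restarts=cl.kmeans_restarts, seed=seeds[5])
        return cons, k, pd.Series(labels, index=expr.sample_ids, name="gene_class")

    result.class_consensus, result.class_k, result.class_labels = _classes(result)

    # ---- signature genes, Cox-sign split, TMEscore -------------------
    sc = config.scoring

    @_stage("fit-score")
    def _fit(res):
        signature_genes = derive_cluster_signature(
            expr.subset_genes(res.degs), res.class_labels,
            n_trees=sc.n_trees, retain_rule=sc.retain_rule, top_n=sc.top_n,
            seed=seeds[6],
        )
        hazard_pos, hazard_neg, gene_stats = split_by_cox_sign(
            expr.subset_genes(signature_genes), clinical, signature_genes,
            p_max=sc.cox_p_max,
        )
        if not hazard_pos or not hazard_neg:
            raise ValueError("Cox screen produced an empty hazard sign class")
        # X (score-positive) = protective genes; Y = hazard-increasing.
        model = TMEModel(
            positive_genes=hazard_neg, negative_genes=hazard_pos,
            signature_genes=signature_genes,
            gene_stats={
                g: {"beta": float(row["beta"]), "p": float(row["p"]),
                    "low_confidence": bool(row["low_confidence"])}
                for g, row in gene_stats.iterrows()
            },
            trained_on={"n_samples": len(expr.sample_ids), "seed": config.seed},
        )
        scores = compute_tmescore(expr, model)
        cut, table = dichotomize(scores, clinical, minprop=sc.minprop,
                                 n_perm=sc.maxstat_permutations, seed=seeds[7])
        model.cutpoint = float(cut.cutpoint)
        return model, table

    result.model, result.score_table = _fit(result)

    # ---- survival by subtype -----------------------------------------
    @_stage("survival")
    def _survival(res):
        clin = clinical.aligned(res.score_table.index)
        times = clin.data["os_time"].to_numpy(dtype=float)
        events = clin.data["os_event"].to_numpy(dtype=int)
        is_high = (res.score_table["subtype"] == HIGH_LABEL).to_numpy()
        chi2, p = logrank_test(times, events, is_high)
        return {
            "km_high": km_estimate(times[is_high], events[is_high]),
            "km_low": km_estimate(times[~is_high], events[~is_high]),
            "logrank_chi2": chi2,
            "logrank_p": p,
        }

    result.survival = _survival(result)

    # ---- characterization --------------------------------------------
    @_stage("characterize")
    def _characterize(res):
        out = {}
        subtypes = res.score_table["subtype"]
        clin = clinical.aligned(res.score_table.index).data
        if "response_score" in clin.columns:
            stat, p, med_h, med_l = group_compare(
                clin["response_score"].to_numpy(), subtypes.to_numpy())
            out["response_score"] = {"p": p, "median_by_group": [med_h, med_l]}
        if "msi_status" in clin.columns:
            msi = np.where(clin["msi_status"] == "MSI-H", "MSI-H", "MSI-L/MSS")
            stat, p, med_a, med_b = group_compare(
                res.score_table["tmescore"].to_numpy(), msi)
            out["msi"] = {"p": p, "median_msi_h": med_a if msi[0] == "MSI-H" or True
                          else med_b, "medians": [med_a, med_b]}
        if maf is not None:
            out["tmb"] = compute_tmb(maf, res.score_table.index,
                                     exome_mb=config.characterization.exome_mb,
                                     nonsyn_only=config.characterization.nonsyn_only)
            out["mutation_tests"] = mutation_frequency_test(maf, subtypes)
            out["n_diff_mutated"] = int((out["mutation_tests"]["fisher_p"] < 0.05).sum())
            out["vaf_tests"] = vaf_compare(maf, subtypes)
            if "responder" in clin.columns and clin["responder"].notna().all():
                roc_a, roc_b, delta, p = roc_compare(
                    res.score_table["tmescore"].to_numpy(),
                    out["tmb"].to_numpy(),
                    clin["responder"].to_numpy(dtype=int),
                )
                out["roc"] = {"auc_tmescore": roc_a.auc, "auc_tmb": roc_b.auc,
                              "delta_auc": delta, "delong_p": p}
        return out

    result.characterization = _characterize(result)

    # ---- summary ------------------------------------------------------
    subtype_counts = result.score_table["subtype"].value_counts()
    result.summary = {
        "n_samples": len(expr.sample_ids),
        "tme_k": result.tme_k,
        "tme_pac": {str(k): v for k, v in result.tme_consensus.pac.items()},
        "n_degs": len(result.degs),
        "class_k": result.class_k,
        "n_signature_genes": len(result.model.signature_genes),
        "n_score_positive": len(result.model.positive_genes),
        "n_score_negative": len(result.model.negative_genes),
        "cutpoint": result.model.cutpoint,
        "n_high": int(subtype_counts.get(HIGH_LABEL, 0)),
        "n_low": int(subtype_counts.get(LOW_LABEL, 0)),
        "logrank_p_high_vs_low": result.survival["logrank_p"],
    }
    if "roc" in result.characterization:
        result.summary["auc_tmescore"] = result.characterization["roc"]["auc_tmescore"]
        result.summary["auc_tmb"] = result.characterization["roc"]["auc_tmb"]

    if write:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    tio.write_expression(result.expression, outdir / "expression.tsv")
    tio.write_clinical(result.clinical, outdir / "clinical.tsv")
    if result.maf is not None:
        tio.write_maf(result.maf, outdir / "mutations.maf")
    tio.write_fractions(result.fractions, outdir / "fractions.tsv")
    tio.write_table(result.cell_clusters.to_frame(), outdir / "cell_clusters.tsv",
                    index_label="cell_type")
    tio.write_table(result.cell_network.nodes, outdir / "network_nodes.tsv")
    tio.write_table(result.cell_network.edges, outdir / "network_edges.tsv")
    tio.write_table(result.tme_labels.to_frame(), outdir / "tme_clusters.tsv",
                    index_label="sample_id")
    tio.write_table(result.de_table, outdir / "de_table.tsv", index_label="gene_id")
    (outdir / "degs.txt").write_text("\n".join(result.degs) + "\n")
    tio.write_table(result.score_table, outdir / "scores.tsv",
                    index_label="sample_id")
    result.model.to_json(outdir / "model.json")
    pac = pd.DataFrame({"k": list(result.tme_consensus.pac),
                        "pac_fractions": list(result.tme_consensus.pac.values())})
    tio.write_table(pac, outdir / "pac.tsv")
    if "mutation_tests" in result.characterization:
        tio.write_table(result.characterization["mutation_tests"],
                        outdir / "mutation_tests.tsv", index_label="gene")
        tio.write_table(result.characterization["vaf_tests"],
                        outdir / "vaf_tests.tsv", index_label="gene")
        tio.write_table(result.characterization["tmb"].to_frame(),
                        outdir / "tmb.tsv", index_label="sample_id")
    if result.truth is not None:
        tio.write_fractions(result.truth.true_fractions,
                            outdir / "truth_fractions.tsv")
        tio.write_table(result.truth.true_subtype.to_frame(),
                        outdir / "truth_subtypes.tsv", index_label="sample_id")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
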