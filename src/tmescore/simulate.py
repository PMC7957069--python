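"""Synthetic TCGA-like cohort generator.

Every downstream stage of the pipeline is validated against cohorts drawn
from this module, which plants the statistical structure the analysis
assumes and records it as ground truth:

* per-sample immune composition drawn from subtype-specific Dirichlet
  distributions over 22 leukocyte types (the "high" subtype is enriched in
  CD8 T cells, activated mast cells and neutrophils; the "low" subtype in
  M0/M2 macrophages — the directions the immune-hot / immune-cold contrast
  in bladder cancer suggests);
* bulk expression = signature-basis mixture on marker genes plus a
  background gene block containing planted differentially expressed genes,
  under multiplicative log-normal noise;
* exponential survival with hazard ``h0 * exp(beta * z)`` where ``z`` is
  the hazard-increasing subtype indicator (z = 1 for "low", so "high"
  survives longer), with independent exponential censoring calibrated to a
  target censoring fraction;
* a MAF-style mutation table with subtype-specific mutation loads, a small
  panel of recurrently mutated driver genes, and Beta-distributed variant
  allele fractions scaled by simulated tumor purity;
* a responder flag driven mainly by immune composition and only weakly by
  mutation load, plus a TIDE-like response score (lower = better predicted
  response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    FractionMatrix,
    MafTable,
    SignatureMatrix,
)

__all__ = [
    "CELL_TYPES",
    "SyntheticTruth",
    "generate_signature_matrix",
    "simulate_survival",
    "simulate_cohort",
]

#: The 22 leukocyte types of the standard deconvolution basis.
CELL_TYPES = (
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
)

#: Cell types over-represented in the good-prognosis ("high") subtype.
HIGH_ENRICHED = ("T cells CD8", "Mast cells activated", "Neutrophils")
#: Cell types over-represented in the poor-prognosis ("low") subtype.
LOW_ENRICHED = ("Macrophages M0", "Macrophages M2")

_DRIVER_GENES = (
    "TP53", "TTN", "KMT2D", "KDM6A", "ARID1A", "PIK3CA", "KMT2C", "RB1",
    "EP300", "FGFR3", "STAG2", "ATM", "FAT1", "ELF3", "CREBBP", "ERBB2",
    "SPTAN1", "ERCC2", "KMT2A", "ERBB3", "FBXW7", "NFE2L2", "TSC1", "CDKN1A",
    "RHOB", "HRAS", "KRAS", "NOTCH1", "NOTCH2", "APC", "CTNNB1", "PTEN",
)

#: 200-symbol panel for the simulated mutation table.
MUTATION_PANEL = _DRIVER_GENES + tuple(
    f"PNL{i:03d}" for i in range(1, 201 - len(_DRIVER_GENES) + 1)
)

# (p_mut_high, p_mut_low) per-sample mutation probability for driver genes;
# remaining drivers share a flat background probability.
_DRIVER_PROBS = {
    "TP53": (0.45, 0.50),
    "TTN": (0.45, 0.40),
    "RB1": (0.28, 0.12),
    "KDM6A": (0.32, 0.20),
    "FGFR3": (0.08, 0.22),
    "PIK3CA": (0.28, 0.15),
    "KMT2D": (0.28, 0.26),
}

# VAF Beta(a, b) parameters for genes with planted subtype-specific clonality.
_DRIVER_VAF = {
    "TP53": ((5, 3), (3, 5)),
    "RB1": ((5, 3), (2, 5)),
    "KDM6A": ((4, 3), (2, 4)),
    "PIK3CA": ((5, 3), (2, 5)),
    "KMT2D": ((4, 3), (2, 4)),
}

_VARIANT_CLASSES = (
    "Missense_Mutation", "Silent", "Nonsense_Mutation", "Frame_Shift_Del",
    "Frame_Shift_Ins", "Splice_Site", "In_Frame_Del", "In_Frame_Ins",
    "Nonstop_Mutation", "Translation_Start_Site",
)
_VARIANT_WEIGHTS = (0.58, 0.18, 0.08, 0.04, 0.03, 0.04, 0.02, 0.01, 0.01, 0.01)


@dataclass
class SyntheticTruth:
    """Ground truth recorded before noise is added."""

    true_fractions: FractionMatrix
    true_subtype: pd.Series  # "high" / "low" per sample
    true_de_genes: pd.Series  # gene -> planted log2 effect (high - low)
    true_beta: float  # log hazard ratio per unit of the latent indicator z
    latent_z: pd.Series  # hazard-increasing indicator (1 for "low")
    responder: pd.Series  # planted 0/1 responder flag
    mutation_counts: pd.Series  # per-sample simulated mutation row counts


def generate_signature_matrix(
    n_markers_per_type: int = 10,
    n_types: int = 22,
    fold: float = 4.0,
    seed: int = 0,
    cell_types=None,
) -> SignatureMatrix:
    """Build a marker-gene basis with guaranteed per-type enrichment.

    Each cell type receives ``n_markers_per_type`` dedicated marker genes
    whose expression in that type exceeds the expression in every other
    type by at least ``fold``. The block structure makes the matrix full
    column rank by construction.
    """
    if n_markers_per_type < 5:
        raise ValueError("need at least 5 markers per cell type")
    if fold <= 1:
        raise ValueError("enrichment fold must exceed 1")
    if cell_types is None:
        cell_types = CELL_TYPES[:n_types]
    if len(cell_types) != n_types:
        raise ValueError("cell_types length must equal n_types")

    rng = np.random.default_rng(seed)
    n_genes = n_markers_per_type * n_types
    values = rng.uniform(0.5, 2.0, size=(n_genes, n_types))
    gene_ids = []
    for t in range(n_types):
        rows = slice(t * n_markers_per_type, (t + 1) * n_markers_per_type)
        block = values[rows]
        off_max = np.delete(block, t, axis=1).max(axis=1)
        block[:, t] = fold * off_max * rng.uniform(1.05, 1.6, size=n_markers_per_type)
        gene_ids.extend(f"MK{t:02d}_{i:02d}" for i in range(n_markers_per_type))
    frame = pd.DataFrame(values * 10.0, index=gene_ids, columns=list(cell_types))
    return SignatureMatrix(frame)


def simulate_survival(
    score,
    baseline_rate: float = 1.0 / 1500.0,
    beta: float = 0.0,
    censor_rate: float = 0.3,
    seed: int = 0,
):
    """Exponential survival times under a proportional-hazards truth.

    Event times are Exponential(``baseline_rate * exp(beta * score)``);
    censoring times are an independent Exponential whose rate is solved so
    the expected censoring fraction equals ``censor_rate``.

    Returns ``(os_time, os_event)`` arrays.
    """
    score = np.asarray(score, dtype=float)
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    hazards = baseline_rate * np.exp(beta * score)
    event_times = rng.exponential(1.0 / hazards)
    if censor_rate == 0:
        return event_times, np.ones(len(score), dtype=int)

    # P(censored | hazard h, censor rate c) = c / (c + h); solve the mean.
    def excess(c):
        return float(np.mean(c / (c + hazards))) - censor_rate

    lo, hi = hazards.min() * 1e-8, hazards.max() * 1e8
    c_rate = brentq(excess, lo, hi)
    censor_times = rng.exponential(1.0 / c_rate, size=len(score))
    os_time = np.minimum(event_times, censor_times)
    os_event = (event_times <= censor_times).astype(int)
    return os_time, os_event


def _simulate_mutations(rng, sample_ids, subtype, mut_mean_high, mut_mean_low,
                        dispersion: float = 3.0):
    """Per-sample mutation rows: driver panel + mixed-Poisson background.

    Counts are Poisson given a per-sample rate drawn from a
    subtype-specific Gamma (shape ``dispersion``), reproducing the heavy
    overdispersion of real tumor mutation burdens: the subtype means
    differ, but the within-subtype spread keeps the distributions
    broadly overlapping.
    """
    purity = pd.Series(rng.uniform(0.4, 0.9, size=len(sample_ids)), index=sample_ids)
    background_genes = [g for g in MUTATION_PANEL if g not in _DRIVER_PROBS]
    rows = []
    for sid in sample_ids:
        is_high = subtype[sid] == "high"
        pur = purity[sid]
        for gene, (p_hi, p_lo) in _DRIVER_PROBS.items():
            if rng.random() < (p_hi if is_high else p_lo):
                a, b = _DRIVER_VAF.get(gene, ((2, 2), (2, 2)))[0 if is_high else 1]
                rows.append((sid, gene, rng.beta(a, b) * pur))
        mean = mut_mean_high if is_high else mut_mean_low
        n_bg = rng.poisson(rng.gamma(dispersion, mean / dispersion))
        genes = rng.choice(background_genes, size=n_bg, replace=True)
        vafs = rng.beta(2, 2, size=n_bg) * pur
        rows.extend(zip([sid] * n_bg, genes, vafs))
    frame = pd.DataFrame(rows, columns=["sample_id", "hugo_symbol", "vaf"])
    n = len(frame)
    frame["variant_classification"] = rng.choice(
        _VARIANT_CLASSES, size=n, p=_VARIANT_WEIGHTS
    )
    depth = rng.integers(30, 150, size=n)
    alt = np.clip(np.rint(frame["vaf"].to_numpy() * depth), 1, depth).astype(int)
    frame["t_alt_count"] = alt
    frame["t_depth"] = depth
    maf = MafTable(frame.drop(columns="vaf"))
    return maf


def simulate_cohort(
    n_samples: int = 400,
    signature: SignatureMatrix | None = None,
    subtype_composition_shift: float = 3.0,
    concentration: float = 5.0,
    n_background: int = 1000,
    n_de_genes: int = 100,
    de_lfc: float = 1.0,
    noise_sd: float = 0.1,
    true_beta: float = float(np.log(2.5)),
    baseline_rate: float = 1.0 / 1500.0,
    censor_rate: float = 0.3,
    mut_mean_high: float = 160.0,
    mut_mean_low: float = 110.0,
    seed: int = 7,
    population_seed: int = 0,
):
    """Draw a full synthetic cohort.

    Returns ``(expression, clinical, maf, truth)``. Defaults emulate the
    study cohort scale: 400 samples, two latent TME subtypes of equal
    expected size, hazard ratio exp(``true_beta``) = 2.5 for the "low"
    subtype, ~30% censoring.

    ``subtype_composition_shift`` is added to the Dirichlet base
    concentration (``concentration``, default 5 per cell type) of the
    enriched types of each subtype, so the default shift of 3 yields
    clearly separated but overlapping compositions.

    ``seed`` drives the sample-level randomness; ``population_seed``
    drives the gene-level population parameters (background baseline
    expression levels). Two cohorts with different ``seed`` but the same
    ``population_seed`` and signature are independent draws from the SAME
    generative process — the setting a frozen-model validation transfer
    assumes.
    """
    if signature is None:
        signature = generate_signature_matrix(seed=seed)
    if n_de_genes > n_background:
        raise ValueError("n_de_genes exceeds background gene count")
    rng = np.random.default_rng(seed)
    cell_types = signature.cell_types
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]

    # --- subtypes: exact half/half, shuffled ---
    labels = np.array(["high"] * (n_samples // 2) + ["low"] * (n_samples - n_samples // 2))
    rng.shuffle(labels)
    subtype = pd.Series(labels, index=sample_ids, name="true_subtype")

    # --- compositions ---
    alpha = {}
    for name in ("high", "low"):
        a = np.full(len(cell_types), concentration, dtype=float)
        enriched = HIGH_ENRICHED if name == "high" else LOW_ENRICHED
        for ct in enriched:
            if ct in cell_types:
                a[cell_types.index(ct)] += concentration * subtype_composition_shift
        alpha[name] = a
    fracs = np.vstack([rng.dirichlet(alpha[s]) for s in labels])
    fractions = FractionMatrix(pd.DataFrame(fracs, index=sample_ids, columns=cell_types))

    # --- expression: marker mixture + background with planted DE genes ---
    sig = signature.data.to_numpy()
    marker_part = sig @ fracs.T  # genes x samples
    bg_ids = [f"BG{i:04d}" for i in range(n_background)]
    pop_rng = np.random.default_rng(population_seed)
    base_log2 = pop_rng.uniform(3.0, 9.0, size=n_background)
    bg = np.tile(np.exp2(base_log2)[:, None], (1, n_samples))
    de_effects = np.zeros(n_background)
    de_effects[:n_de_genes] = de_lfc * np.where(np.arange(n_de_genes) % 2 == 0, 1, -1)
    is_high = (labels == "high").astype(float)
    bg *= np.exp2(de_effects[:, None] * is_high[None, :])
    values = np.vstack([marker_part, bg])
    if noise_sd > 0:
        values = values * np.exp(rng.normal(0.0, noise_sd, size=values.shape))
    values = np.clip(values, 0.0, None)
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=signature.marker_genes + bg_ids, columns=sample_ids)
    )
    true_de = pd.Series(de_effects[:n_de_genes], index=bg_ids[:n_de_genes],
                        name="log2_effect")

    # --- survival ---
    z = pd.Series((labels == "low").astype(float), index=sample_ids, name="latent_z")
    os_time, os_event = simulate_survival(
        z.to_numpy(), baseline_rate=baseline_rate, beta=true_beta,
        censor_rate=censor_rate, seed=int(rng.integers(2**31 - 1)),
    )

    # --- mutations ---
    maf = _simulate_mutations(rng, sample_ids, subtype, mut_mean_high, mut_mean_low)
    mut_counts = (
        maf.data.groupby("sample_id").size().reindex(sample_ids, fill_value=0)
    )

    # --- response: composition-driven, weakly TMB-driven ---
    comp = (
        sum(fractions.data[ct] for ct in HIGH_ENRICHED if ct in cell_types)
        - sum(fractions.data[ct] for ct in LOW_ENRICHED if ct in cell_types)
    )
    z_comp = (comp - comp.mean()) / comp.std()
    z_mut = (mut_counts - mut_counts.mean()) / max(mut_counts.std(), 1e-12)
    lin = 1.5 * z_comp + 0.3 * z_mut
    responder = pd.Series(
        rng.binomial(1, expit(lin.to_numpy())), index=sample_ids, name="responder"
    )
    response_score = -lin + rng.normal(0.0, 0.5, size=n_samples)

    msi_p = expit(-2.0 + 0.8 * (labels == "high") + 0.3 * z_mut.to_numpy())
    msi_high = rng.random(n_samples) < msi_p
    msi = np.where(msi_high, "MSI-H", rng.choice(["MSS", "MSI-L"], size=n_samples,
                                                 p=[0.7, 0.3]))
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "stage": rng.choice(["I", "II", "III", "IV"], size=n_samples,
                                    p=[0.1, 0.35, 0.35, 0.2]),
                "msi_status": msi,
                "response_score": response_score.to_numpy(),
                "responder": responder.to_numpy(),
            },
            index=pd.Index(sample_ids),
        )
    )
    truth = SyntheticTruth(
        true_fractions=fractions,
        true_subtype=subtype,
        true_de_genes=true_de,
        true_beta=true_beta,
        latent_z=z,
        responder=responder,
        mutation_counts=mut_counts,
    )
    return expression, clinical, maf, truth
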