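"""Characterization: network, rank tests, mutations, TMB, ROC/DeLong."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmescore.characterization import (
    build_cell_network,
    compute_tmb,
    group_compare,
    mutation_frequency_test,
    roc_compare,
    roc_curve_points,
    vaf_compare,
)
from tmescore.datatypes import ClinicalTable, FractionMatrix, MafTable
from tmescore.simulate import simulate_survival


def _maf(rows):
    return MafTable(pd.DataFrame(
        rows, columns=["sample_id", "hugo_symbol", "variant_classification",
                       "t_alt_count", "t_depth"]))


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(60)
    n = 500
    protective = rng.beta(2, 6, n)
    other = rng.dirichlet(np.ones(3), size=n) * (1 - protective)[:, None]
    frame = pd.DataFrame(
        np.column_stack([protective, other]),
        columns=["Tcell", "A", "B", "C"],
        index=[f"s{i}" for i in range(n)],
    )
    fractions = FractionMatrix(frame)
    times, events = simulate_survival(protective, beta=-3.0,
                                      censor_rate=0.2, seed=1000 + 60)
    clinical = ClinicalTable(pd.DataFrame(
        {"os_time": times, "os_event": events}, index=frame.index))
    return fractions, clinical


class TestCellNetwork:
    def test_protective_type_flagged_favorable(self, planted):
        fractions, clinical = planted
        network = build_cell_network(fractions, clinical)
        node = network.nodes.set_index("cell_type").loc["Tcell"]
        assert node["os_direction"] == "favorable"
        assert node["os_p"] < 0.05

    def test_node_count_equals_cell_types(self, planted):
        fractions, clinical = planted
        network = build_cell_network(fractions, clinical)
        assert len(network.nodes) == len(fractions.cell_types)

    def test_impossible_threshold_empties_edges(self, planted):
        fractions, clinical = planted
        network = build_cell_network(fractions, clinical, r_min=1.01)
        assert network.edges.empty


class TestGroupCompare:
    def test_exact_enumeration_toy(self):
        values = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        _, p, med_a, med_b = group_compare(values, labels)
        assert p == pytest.approx(0.1)  # 2 * (1 / C(6,3))... exhaustive = 0.1
        assert (med_a, med_b) == (2.0, 5.0)

    def test_identical_groups(self):
        values = np.array([2.0, 2.0, 2.0, 2.0])
        labels = np.array(["a", "a", "b", "b"])
        _, p, *_ = group_compare(values, labels)
        assert p == 1.0

    def test_exact_close_to_asymptotic(self):
        """Exact enumeration and the corrected normal agree within 0.02
        at n = 10 + 10 (100 random datasets)."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(61)
        for i in range(100):
            a = rng.normal(size=10)
            b = rng.normal(0.4, 1, size=10)
            labels = np.array(["a"] * 10 + ["b"] * 10)
            # group_compare takes the exact path here (n <= 20, no ties)
            _, exact, *_ = group_compare(np.r_[a, b], labels)
            asymp = mannwhitneyu(a, b, method="asymptotic").pvalue
            assert abs(exact - asymp) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare(np.array([1.0, 2.0]), np.array(["a", "a"]))


class TestTMB:
    def test_per_megabase_arithmetic(self):
        rows = [("S1", f"G{i}", "Missense_Mutation", 5, 10) for i in range(8)]
        tmb = compute_tmb(_maf(rows), ["S1"], exome_mb=38.0)
        assert tmb["S1"] == pytest.approx(8 / 38)

    def test_silent_only_gives_zero(self):
        rows = [("S1", "G1", "Silent", 5, 10), ("S1", "G2", "Silent", 3, 9)]
        tmb = compute_tmb(_maf(rows), ["S1"])
        assert tmb["S1"] == 0.0

    def test_mixed_matches_brute_force(self):
        from tmescore.datatypes import NONSILENT_CLASSES

        rng = np.random.default_rng(62)
        classes = ["Missense_Mutation", "Silent", "Splice_Site", "3'UTR",
                   "Nonsense_Mutation", "Intron"]
        rows = [(f"S{rng.integers(3)}", f"G{i}", classes[rng.integers(len(classes))],
                 2, 10) for i in range(60)]
        maf = _maf(rows)
        samples = ["S0", "S1", "S2", "S_absent"]
        tmb = compute_tmb(maf, samples, exome_mb=38.0)
        for s in samples:
            expected = sum(1 for r in rows
                           if r[0] == s and r[2] in NONSILENT_CLASSES) / 38.0
            assert tmb[s] == pytest.approx(expected)
        assert tmb["S_absent"] == 0.0


class TestMutationFrequency:
    def test_hypergeometric_toy(self):
        """Gene mutated in 3/5 high vs 0/5 low: two-sided p = 1/6."""
        rows = [(f"H{i}", "GENE", "Missense_Mutation", 5, 10) for i in range(3)]
        subtypes = pd.Series(["high"] * 5 + ["low"] * 5,
                             index=[f"H{i}" for i in range(5)]
                             + [f"L{i}" for i in range(5)])
        out = mutation_frequency_test(_maf(rows), subtypes)
        assert out.loc["GENE", "fisher_p"] == pytest.approx(1 / 6)

    def test_equal_rates_give_p_one(self):
        rows = [("H0", "GENE", "Missense_Mutation", 5, 10),
                ("L0", "GENE", "Missense_Mutation", 5, 10)]
        subtypes = pd.Series(["high", "high", "low", "low"],
                             index=["H0", "H1", "L0", "L1"])
        out = mutation_frequency_test(_maf(rows), subtypes)
        assert out.loc["GENE", "fisher_p"] == pytest.approx(1.0)

    def test_sample_counted_once_per_gene(self):
        rows = [("H0", "GENE", "Missense_Mutation", 5, 10),
                ("H0", "GENE", "Nonsense_Mutation", 3, 10)]
        subtypes = pd.Series(["high", "low"], index=["H0", "L0"])
        out = mutation_frequency_test(_maf(rows), subtypes)
        assert out.loc["GENE", "n_mut_high"] == 1

    def test_full_margin_gives_p_one(self):
        rows = [(s, "GENE", "Missense_Mutation", 5, 10)
                for s in ("H0", "H1", "L0", "L1")]
        subtypes = pd.Series(["high", "high", "low", "low"],
                             index=["H0", "H1", "L0", "L1"])
        out = mutation_frequency_test(_maf(rows), subtypes)
        assert out.loc["GENE", "fisher_p"] == pytest.approx(1.0)


class TestVafCompare:
    def test_planted_vaf_shift_detected(self):
        rng = np.random.default_rng(63)
        rows = []
        for i in range(50):
            depth = 100
            rows.append((f"H{i}", "GENE", "Missense_Mutation",
                         int(rng.beta(8, 2) * depth), depth))
            rows.append((f"L{i}", "GENE", "Missense_Mutation",
                         max(int(rng.beta(2, 8) * depth), 1), depth))
        subtypes = pd.Series(["high"] * 50 + ["low"] * 50,
                             index=[f"H{i}" for i in range(50)]
                             + [f"L{i}" for i in range(50)])
        out = vaf_compare(_maf(rows), subtypes, genes=["GENE"])
        assert out.loc["GENE", "p"] < 0.001
        assert out.loc["GENE", "median_vaf_high"] > out.loc["GENE", "median_vaf_low"]

    def test_single_mutation_per_group(self):
        rows = [("H0", "GENE", "Missense_Mutation", 3, 10),
                ("L0", "GENE", "Missense_Mutation", 7, 10)]
        subtypes = pd.Series(["high", "low"], index=["H0", "L0"])
        out = vaf_compare(_maf(rows), subtypes)
        assert out.loc["GENE", "p"] == pytest.approx(1.0)

    def test_gene_absent_from_one_subtype_skipped(self):
        rows = [("H0", "GENE", "Missense_Mutation", 3, 10)]
        subtypes = pd.Series(["high", "low"], index=["H0", "L0"])
        out = vaf_compare(_maf(rows), subtypes)
        assert bool(out.loc["GENE", "skipped"])
        assert np.isnan(out.loc["GENE", "p"])


class TestRoc:
    def test_perfect_separator(self):
        roc = roc_curve_points([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(1.0)
        assert roc.fpr[0] == 0.0 and roc.tpr[-1] == 1.0

    def test_constant_score_half(self):
        roc = roc_curve_points([5, 5, 5, 5], [0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_pair_counting_oracle(self):
        """8-sample toy: AUC = (concordant + ties/2) / (n1 * n0)."""
        score = np.array([0.1, 0.4, 0.35, 0.8, 0.35, 0.9, 0.5, 0.2])
        label = np.array([0, 0, 1, 1, 0, 1, 1, 0])
        pos, neg = score[label == 1], score[label == 0]
        pairs = [(p, q) for p in pos for q in neg]
        expected = (sum(p > q for p, q in pairs)
                    + 0.5 * sum(p == q for p, q in pairs)) / len(pairs)
        assert roc_curve_points(score, label).auc == pytest.approx(expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_negation_symmetry(self, seed):
        """AUC(score) + AUC(-score) = 1."""
        rng = np.random.default_rng(seed)
        score = rng.normal(size=30)
        label = np.r_[np.zeros(15, int), np.ones(15, int)]
        a = roc_curve_points(score, label).auc
        b = roc_curve_points(-score, label).auc
        assert a + b == pytest.approx(1.0)

    def test_delong_self_comparison_p_one(self):
        rng = np.random.default_rng(64)
        score = rng.normal(size=40)
        label = (rng.random(40) < 0.5).astype(int)
        label[:2] = [0, 1]
        _, _, delta, p = roc_compare(score, score, label)
        assert delta == 0.0
        assert p == 1.0

    def test_delong_detects_better_score(self):
        rng = np.random.default_rng(65)
        n = 400
        label = (rng.random(n) < 0.5).astype(int)
        informative = label + rng.normal(0, 0.7, n)
        junk = rng.normal(size=n)
        roc_a, roc_b, delta, p = roc_compare(informative, junk, label)
        assert roc_a.auc > roc_b.auc
        assert delta > 0
        assert p < 0.001

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_points([1.0, 2.0], [1, 1])
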