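"""TMEscore model: signature reduction, Cox-sign split, score, cutpoint."""

import numpy as np
import pandas as pd
import pytest

from tmescore.datatypes import ClinicalTable, ExpressionMatrix
from tmescore.scoring import (
    HIGH_LABEL,
    TMEModel,
    apply_model,
    compute_tmescore,
    derive_cluster_signature,
    dichotomize,
    split_by_cox_sign,
)
from tmescore.simulate import simulate_survival
from tmescore.survival import logrank_test


def _expr_from(values, genes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols))


def _clinical(times, events, sample_ids):
    return ClinicalTable(pd.DataFrame(
        {"os_time": times, "os_event": events},
        index=pd.Index(sample_ids, name="sample_id")))


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(13)
    n, n_noise = 200, 90
    classes = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    rng.shuffle(classes)
    shifted = rng.normal(5, 1, size=(10, n)) + 1.5 * classes[None, :]
    noise = rng.normal(5, 1, size=(n_noise, n))
    values = np.clip(np.exp2(np.vstack([shifted, noise])), 0, None)
    genes = [f"DE{i}" for i in range(10)] + [f"N{i}" for i in range(n_noise)]
    expr = _expr_from(values, genes)
    labels = pd.Series(classes, index=expr.sample_ids)
    return expr, labels


class TestDeriveSignature:
    def test_recovers_planted_genes(self, planted):
        expr, labels = planted
        kept = derive_cluster_signature(expr, labels, n_trees=500, seed=13)
        assert sum(g.startswith("DE") for g in kept) == 10
        assert sum(g.startswith("N") for g in kept) <= 5

    def test_top_n_rule(self, planted):
        expr, labels = planted
        kept = derive_cluster_signature(expr, labels, n_trees=200,
                                        retain_rule="top-n", top_n=5, seed=13)
        assert len(kept) == 5

    def test_output_never_exceeds_input(self, planted):
        expr, labels = planted
        dup = ExpressionMatrix(
            pd.concat([expr.data, expr.data.loc[["DE0"]].rename(index={"DE0": "DE0_copy"})])
        )
        kept = derive_cluster_signature(dup, labels, n_trees=200, seed=13)
        assert len(kept) <= dup.shape[0]

    def test_single_class_rejected(self, planted):
        expr, _ = planted
        ones = pd.Series(1, index=expr.sample_ids)
        with pytest.raises(ValueError, match="2 classes"):
            derive_cluster_signature(expr, ones, n_trees=50)


class TestCoxSignSplit:
    def test_sign_recovery_on_planted_hazard(self):
        """A gene whose high expression doubles the hazard lands in the
        hazard-positive set; an independent gene is low-confidence."""
        rng = np.random.default_rng(30)
        n = 1000
        risk_gene = rng.uniform(0, 4, n)
        noise_gene = rng.uniform(0, 4, n)
        times, events = simulate_survival(
            np.log2(risk_gene + 1), beta=np.log(2), censor_rate=0.2, seed=1000 + 30)
        expr = _expr_from(np.vstack([risk_gene, noise_gene]), ["risk", "noise"])
        clin = _clinical(times, events, expr.sample_ids)
        pos, neg, stats = split_by_cox_sign(expr, clin, ["risk", "noise"])
        assert "risk" in pos
        assert not stats.loc["risk", "low_confidence"]
        assert stats.loc["noise", "low_confidence"]

    def test_zero_variance_excluded(self, caplog):
        rng = np.random.default_rng(31)
        gene = rng.uniform(0, 4, 100)
        times, events = simulate_survival(gene, beta=0.5, censor_rate=0.1, seed=1000 + 31)
        expr = _expr_from(np.vstack([gene, np.full(100, 3.0)]), ["g", "flat"])
        clin = _clinical(times, events, expr.sample_ids)
        with caplog.at_level("WARNING", logger="tmescore"):
            pos, neg, _ = split_by_cox_sign(expr, clin, ["g", "flat"])
        assert "flat" not in pos + neg
        assert "zero variance" in caplog.text


class TestComputeScore:
    def test_exact_hand_cases(self):
        model = TMEModel(positive_genes=["p"], negative_genes=["n"])
        expr = _expr_from([[3.0], [1.0]], ["p", "n"])
        assert compute_tmescore(expr, model).iloc[0] == pytest.approx(1.0)

        zeros = _expr_from([[0.0], [0.0]], ["p", "n"])
        assert compute_tmescore(zeros, model).iloc[0] == pytest.approx(0.0)

        model2 = TMEModel(positive_genes=["p1", "p2"], negative_genes=["n1", "n2"])
        expr2 = _expr_from([[1.0], [3.0], [0.0], [1.0]], ["p1", "p2", "n1", "n2"])
        assert compute_tmescore(expr2, model2).iloc[0] == pytest.approx(2.0)

    def test_monotonicity_under_perturbation(self):
        """Score strictly increases in any positive-set gene and strictly
        decreases in any negative-set gene (1,000 random perturbations)."""
        rng = np.random.default_rng(40)
        genes = [f"p{i}" for i in range(5)] + [f"n{i}" for i in range(5)]
        model = TMEModel(positive_genes=genes[:5], negative_genes=genes[5:])
        base_values = rng.uniform(0, 50, size=(10, 1))
        base = compute_tmescore(_expr_from(base_values, genes), model).iloc[0]
        for _ in range(1000):
            idx = rng.integers(0, 10)
            bump = rng.uniform(0.1, 20)
            perturbed = base_values.copy()
            perturbed[idx, 0] += bump
            new = compute_tmescore(_expr_from(perturbed, genes), model).iloc[0]
            if idx < 5:
                assert new > base
            else:
                assert new < base

    def test_missing_set_rejected(self):
        model = TMEModel(positive_genes=["p"], negative_genes=["n"])
        with pytest.raises(ValueError, match="negative"):
            compute_tmescore(_expr_from([[1.0]], ["p"]), model)

    def test_disjoint_sets_enforced(self):
        with pytest.raises(ValueError, match="both"):
            TMEModel(positive_genes=["a"], negative_genes=["a"])


class TestModelSerialization:
    def test_json_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(41)
        genes = [f"g{i}" for i in range(6)]
        model = TMEModel(positive_genes=genes[:3], negative_genes=genes[3:],
                         cutpoint=0.03537218341, trained_on={"n_samples": 9})
        path = tmp_path / "model.json"
        model.to_json(path)
        back = TMEModel.from_json(path)
        expr = _expr_from(rng.uniform(0, 100, size=(6, 9)), genes)
        a = compute_tmescore(expr, model)
        b = compute_tmescore(expr, back)
        assert (a == b).all()
        assert back.cutpoint == model.cutpoint


class TestDichotomize:
    def test_cutpoint_between_event_blocks(self):
        """Scores 1..10, events only below 5.5: cut lands in (5, 6)."""
        scores = pd.Series(np.arange(1.0, 11.0),
                           index=[f"s{i}" for i in range(10)])
        times = np.r_[np.arange(1, 6), np.full(5, 50.0)]
        events = np.r_[np.ones(5, int), np.zeros(5, int)]
        clin = _clinical(times, events, scores.index)
        cut, table = dichotomize(scores, clin, minprop=0.1)
        assert 5.0 < cut.cutpoint < 6.0
        # relabeling definition: high iff score > cutpoint
        assert (table["subtype"].eq(HIGH_LABEL)
                == (table["tmescore"] > cut.cutpoint)).all()

    def test_bimodal_planted_hazard(self):
        """Low score mode planted with 2.5x hazard: the high group shows
        better survival (log-rank p < 0.01) and the cut separates modes."""
        rng = np.random.default_rng(42)
        n = 300
        is_high = rng.random(n) < 0.5
        scores = pd.Series(np.where(is_high, rng.normal(3, 0.4, n),
                                    rng.normal(0, 0.4, n)),
                           index=[f"s{i}" for i in range(n)])
        times, events = simulate_survival((~is_high).astype(float),
                                          beta=np.log(2.5), censor_rate=0.2,
                                          seed=1000 + 42)
        clin = _clinical(times, events, scores.index)
        cut, table = dichotomize(scores, clin)
        # the cut separates the modes (centers 0 and 3); finite-sample noise
        # may shift it into a mode's tail but never across a center
        assert 0.8 < cut.cutpoint < 2.9
        high = (table["subtype"] == HIGH_LABEL).to_numpy()
        assert (high == is_high).mean() >= 0.9
        chi2, p = logrank_test(times, events, high)
        assert p < 0.01
        km_high = np.median(times[high & (events == 1)]) if (high & (events == 1)).any() else np.inf
        km_low = np.median(times[~high & (events == 1)])
        assert km_high > km_low


class TestApplyModel:
    def _fitted(self):
        rng = np.random.default_rng(50)
        genes = ["p0", "p1", "n0", "n1"]
        expr = _expr_from(rng.uniform(0, 40, size=(4, 60)), genes)
        model = TMEModel(positive_genes=genes[:2], negative_genes=genes[2:],
                         cutpoint=None)
        scores = compute_tmescore(expr, model)
        times, events = simulate_survival(-scores.to_numpy(), beta=0.2,
                                          censor_rate=0.2, seed=50)
        cut, table = dichotomize(scores, _clinical(times, events, expr.sample_ids))
        model.cutpoint = cut.cutpoint
        return expr, model, table

    def test_idempotent_on_training_matrix(self):
        expr, model, table = self._fitted()
        applied = apply_model(expr, model)
        pd.testing.assert_frame_equal(applied, table)

    def test_missing_negative_set_rejected(self):
        expr, model, _ = self._fitted()
        truncated = ExpressionMatrix(expr.data.drop(index=["n0", "n1"]))
        with pytest.raises(ValueError, match="negative"):
            apply_model(truncated, model)
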