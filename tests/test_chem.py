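"""Structure-to-phenotype predictor: fallback embedder, two-stage training,
prediction scoring, and confusion metrics."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

from gastrumap.chem import (
    PredictorConfig,
    confusion_metrics,
    embed_molecule,
    predict_phenotype,
    score_prediction,
    train_structure_model,
)
from gastrumap.records import PhenotypeVector


class TestEmbedMolecule:
    def test_deterministic(self):
        a = embed_molecule("CCO", backend="fallback")
        b = embed_molecule("CCO", backend="fallback")
        np.testing.assert_array_equal(a, b)
        assert a.shape == (768,)

    def test_distinct_smiles_distinct_vectors(self):
        smiles = ["CCO", "c1ccccc1", "CC(=O)O", "NCCN", "ClCCl", "CCCCC"]
        embs = [embed_molecule(s) for s in smiles]
        for i in range(len(embs)):
            for j in range(i + 1, len(embs)):
                assert not np.allclose(embs[i], embs[j])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            embed_molecule("")

    def test_unknown_backend_names_alternatives(self):
        with pytest.raises(ValueError, match="fallback"):
            embed_molecule("CCO", backend="quantum")

    def test_transformer_backend_explains_requirement(self):
        with pytest.raises(RuntimeError, match="fallback"):
            embed_molecule("CCO", backend="transformer")


@pytest.fixture(scope="module")
def trained(compound_library):
    records, templates, failure = compound_library
    cfg = PredictorConfig(seed=0, max_epochs=150)
    model = train_structure_model(records, cfg, failure_clusters=failure)
    return records, model


class TestStructureModel:
    def test_blind_set_accuracy_separable(self, trained):
        records, model = trained
        by_id = {r.compound_id: r for r in records}
        hold = [by_id[i] for i in model.holdout_ids]
        correct = 0
        for r in hold:
            _, cluster, _ = predict_phenotype(model, r.embedding)
            correct += cluster == r.cluster_label
        assert correct / len(hold) >= 0.9

    def test_blind_set_cosine(self, trained):
        records, model = trained
        by_id = {r.compound_id: r for r in records}
        cosines = []
        for i in model.holdout_ids:
            r = by_id[i]
            pred, _, _ = predict_phenotype(model, r.embedding)
            m = score_prediction(pred, r.replicate_phenotypes)
            cosines.append(m.cosine_similarity)
        assert np.mean(cosines) >= 0.85

    def test_holdout_disjoint_from_training(self, trained):
        _, model = trained
        assert not set(model.holdout_ids) & set(model.training_ids)

    def test_prediction_deterministic(self, trained):
        records, model = trained
        emb = records[0].embedding
        a = predict_phenotype(model, emb)
        b = predict_phenotype(model, emb)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        assert a[1] == b[1]

    def test_ridge_shrinks_to_cluster_mean(self, compound_library):
        records, _, _ = compound_library
        cluster0 = [r for r in records if r.cluster_label == 0]
        emb = np.stack([r.embedding for r in cluster0])
        phen = np.stack([r.centroid_phenotype.values for r in cluster0])
        resid = phen - phen.mean(axis=0)
        big = Ridge(alpha=1e9).fit(emb, resid)
        assert np.abs(big.predict(emb)).max() < 1e-3

    def test_single_member_cluster_warns(self):
        from gastrumap.synth import gen_compound_library

        records, _, failure = gen_compound_library(11, 2, sep=8.0, seed=0, reps=2)
        # keep exactly one member of cluster 1
        ones = [r for r in records if r.cluster_label == 1]
        keep = [r for r in records if r.cluster_label == 0] + ones[:1]
        with pytest.warns(UserWarning, match="single member"):
            train_structure_model(keep, PredictorConfig(seed=1, max_epochs=20,
                                                        holdout_frac=0.0))


class TestScorePrediction:
    def test_exact_prediction(self):
        v = PhenotypeVector(np.random.default_rng(0).random(150))
        m = score_prediction(v, [v, v])
        assert m.rmse == pytest.approx(0.0)
        assert m.cosine_similarity == pytest.approx(1.0)
        assert m.frac_within_1sd == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # 3 informative features embedded in a 150-d vector, 2 replicates
        base = np.zeros(150)
        r1, r2 = base.copy(), base.copy()
        r1[:3] = [1.0, 2.0, 3.0]
        r2[:3] = [3.0, 4.0, 1.0]
        mean = (r1[:3] + r2[:3]) / 2  # [2, 3, 2]
        sd = np.std(np.stack([r1[:3], r2[:3]]), axis=0, ddof=1)  # [~1.414, 1.414, 1.414]
        pred = base.copy()
        pred[:3] = [2.0, 5.0, 2.5]
        m = score_prediction(PhenotypeVector(pred),
                             [PhenotypeVector(r1), PhenotypeVector(r2)])
        expected_rmse = np.sqrt(((pred[:3] - mean) ** 2).sum() / 150)
        assert m.rmse == pytest.approx(expected_rmse)
        # features 0 and 2 inside 1 SD, feature 1 outside (|5-3| > 1.414);
        # the 147 zero-SD features have |pred-mean| = 0 <= 0 -> inside
        assert m.frac_within_1sd == pytest.approx(149 / 150)

    def test_single_replicate_sd_undefined(self):
        v = PhenotypeVector(np.ones(150))
        m = score_prediction(v, [v])
        assert m.frac_within_1sd is None

    def test_no_replicates_rejected(self):
        with pytest.raises(ValueError):
            score_prediction(PhenotypeVector(np.ones(150)), [])


class TestConfusionMetrics:
    def test_perfect_calls(self):
        s = confusion_metrics([True, False, True], [True, False, True])
        assert s.accuracy == 1.0

    def test_benchmark_panel_counts(self):
        # tp=16, fp=2, fn=7, tn=8 (n=33)
        calls = [True] * 16 + [True] * 2 + [False] * 7 + [False] * 8
        truth = [True] * 16 + [False] * 2 + [True] * 7 + [False] * 8
        s = confusion_metrics(calls, truth)
        assert s.accuracy * 100 == pytest.approx(72.7, abs=0.05)
        assert s.precision * 100 == pytest.approx(88.9, abs=0.05)
        assert s.sensitivity * 100 == pytest.approx(69.6, abs=0.05)
        assert s.specificity * 100 == pytest.approx(80.0, abs=0.05)
        assert s.balanced_accuracy * 100 == pytest.approx(74.8, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])
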