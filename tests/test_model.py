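"""Two-tier network: training, search, prediction, serialization."""

import numpy as np
import pytest

from metbind import (
    FeatureSchema,
    KmerVocabulary,
    MLPConfig,
    ModelBundle,
    PropertyTable,
    lr_candidates,
    lr_search,
    predict,
    train_tier1,
    train_tier2,
)
from metbind.evaluation import score_curves
from metbind.model import _train_mlp


@pytest.fixture(scope="module")
def separable_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(300, 12))
    w = rng.normal(size=12)
    y = (X @ w > 0).astype(float)
    return X, y


@pytest.fixture(scope="module")
def quick_config():
    return MLPConfig(epochs=60, learning_rate=1e-2, seed=4)


class TestLrSearch:
    def test_candidate_schedule(self):
        cands = lr_candidates(0.5, 10, 5e-7)
        assert cands == pytest.approx([0.5, 5e-2, 5e-3, 5e-4, 5e-5, 5e-6, 5e-7])

    def test_selects_loss_minimizing_candidate(self, separable_data):
        X, y = separable_data
        config = MLPConfig(epochs=15, seed=2)
        chosen = lr_search(X, y, config, floor=5e-5)
        # recompute every candidate's final loss independently
        losses = {}
        for lr in lr_candidates(0.5, 10, 5e-5):
            cfg = MLPConfig(epochs=15, learning_rate=lr, seed=2)
            losses[lr] = _train_mlp(X, y, cfg).loss_curve[-1]
        assert losses[chosen] == min(losses.values())

    def test_same_seed_same_selection(self, separable_data):
        X, y = separable_data
        config = MLPConfig(epochs=10, seed=3)
        assert lr_search(X, y, config, floor=5e-4) == lr_search(
            X, y, config, floor=5e-4
        )

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            lr_search(X, np.ones(10), MLPConfig(epochs=2))


class TestTier1:
    def test_learns_separable_data(self, separable_data, quick_config):
        X, y = separable_data
        model = train_tier1(X, y, quick_config)
        assert model.loss_curve[-1] < model.loss_curve[0]
        auprc = score_curves(model.predict_scores(X), y.astype(int)).auprc
        assert auprc >= 0.95

    def test_identical_labels_rejected(self, quick_config):
        X = np.random.default_rng(1).normal(size=(20, 4))
        with pytest.raises(ValueError, match="single class"):
            train_tier1(X, np.zeros(20), quick_config)

    def test_non_finite_features_rejected(self, quick_config):
        X = np.full((10, 3), np.nan)
        y = np.arange(10) % 2
        with pytest.raises(ValueError, match="finite"):
            train_tier1(X, y, quick_config)

    def test_zero_vector_scores_in_open_interval(self, separable_data, quick_config):
        X, y = separable_data
        model = train_tier1(X, y, quick_config)
        score = model.predict_scores(np.zeros(X.shape[1]))[0]
        assert 0.0 < score < 1.0

    def test_training_deterministic(self, separable_data, quick_config):
        X, y = separable_data
        a = train_tier1(X, y, quick_config)
        b = train_tier1(X, y, quick_config)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
        np.testing.assert_array_equal(
            a.predict_scores(X), b.predict_scores(X)
        )


class TestTier2:
    def test_input_dimension_and_specificity(self, quick_config):
        rng = np.random.default_rng(8)
        n, d = 400, 10
        X = rng.normal(size=(n, d))
        # disjoint planted coordinates decide each ion
        zn = X[:, 0] > 0.5
        fe = (X[:, 1] > 0.5) & ~zn
        y = (zn | fe).astype(float)
        tier1 = train_tier1(X, y, quick_config)
        scores = tier1.predict_scores(X)
        models = train_tier2(
            X, scores, {"Zn": zn, "Fe": fe}, quick_config
        )
        assert set(models) == {"Zn", "Fe"}
        for model in models.values():
            assert model.input_dim == d + 1
        Xe = np.hstack([X, scores[:, None]])
        for ion, truth in (("Zn", zn), ("Fe", fe)):
            auroc = score_curves(models[ion].predict_scores(Xe), truth.astype(int)).auroc
            assert auroc >= 0.9

    def test_rare_ion_skipped_with_warning(self, quick_config, caplog):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 4))
        labels = np.zeros(30, dtype=bool)
        labels[0] = True  # a single positive
        with caplog.at_level("WARNING"):
            models = train_tier2(X, np.full(30, 0.5), {"Ni": labels}, quick_config)
        assert models == {}
        assert "skipped" in caplog.text


def tiny_bundle(config=None) -> tuple[ModelBundle, list[tuple[str, str]]]:
    config = config or MLPConfig(epochs=40, learning_rate=1e-2, seed=5)
    table = PropertyTable.default()
    vocab = KmerVocabulary(
        k=5, per_ion={"Zn": frozenset({"CHHCC"}), "Fe": frozenset({"HEDEH"})}
    )
    schema = FeatureSchema.for_model(table, vocab)
    rng = np.random.default_rng(6)
    from conftest import random_protein
    from metbind import featurize_many

    seqs, labels, zn, fe = [], [], [], []
    for i in range(120):
        base = random_protein(rng, 60)
        if i % 2 == 0:
            motif = "CHHCC" if i % 4 == 0 else "HEDEH"
            base = base[:20] + motif + base[25:]
            labels.append(1.0)
            zn.append(motif == "CHHCC")
            fe.append(motif == "HEDEH")
        else:
            labels.append(0.0)
            zn.append(False)
            fe.append(False)
        seqs.append(base)
    X = featurize_many(seqs, schema, vocab, table)
    y = np.array(labels)
    tier1 = train_tier1(X, y, config, schema_digest=schema.digest())
    scores = tier1.predict_scores(X)
    tier2 = train_tier2(
        X, scores, {"Zn": np.array(zn), "Fe": np.array(fe)}, config
    )
    bundle = ModelBundle(
        tier1=tier1, tier2=tier2, vocab=vocab, schema=schema, property_table=table
    )
    queries = [(f"q{i}", s) for i, s in enumerate(seqs[:20])]
    return bundle, queries


class TestBundle:
    def test_validator_rejects_wrong_tier2_dimension(self):
        bundle, _ = tiny_bundle()
        bad_tier2 = {"Zn": bundle.tier1}  # input dim D instead of D+1
        with pytest.raises(ValueError, match="tier-2"):
            ModelBundle(
                tier1=bundle.tier1,
                tier2=bad_tier2,
                vocab=bundle.vocab,
                schema=bundle.schema,
                property_table=bundle.property_table,
            )

    def test_save_load_round_trip_scores(self, tmp_path):
        bundle, queries = tiny_bundle()
        path = tmp_path / "bundle.zip"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        before = predict(queries, bundle)
        after = predict(queries, loaded)
        for x, z in zip(before, after):
            assert abs(x.tier1_score - z.tier1_score) <= 1e-12
            for ion in x.ion_scores:
                assert abs(x.ion_scores[ion] - z.ion_scores[ion]) <= 1e-12
        assert loaded.cutoff_tier1 == bundle.cutoff_tier1

    def test_prediction_boundary_and_monotone_cutoff(self):
        bundle, queries = tiny_bundle()
        results = predict(queries, bundle)
        # score exactly at the cutoff counts as positive
        at_cutoff = predict(
            queries, bundle, cutoff_tier1=results[0].tier1_score
        )
        assert at_cutoff[0].tier1_call is True
        counts = []
        for cutoff in (0.1, 0.3, 0.5, 0.7, 0.9):
            res = predict(queries, bundle, cutoff_tier1=cutoff)
            counts.append(sum(r.tier1_call for r in res))
        assert counts == sorted(counts, reverse=True)

    def test_inference_pure_function(self):
        bundle, queries = tiny_bundle()
        one = predict(queries, bundle)
        two = predict(queries, bundle)
        for a, b in zip(one, two):
            assert a.tier1_score == b.tier1_score
            assert a.ion_scores == b.ion_scores

    def test_degenerate_sequence_skipped(self, caplog):
        bundle, _ = tiny_bundle()
        with caplog.at_level("WARNING"):
            results = predict([("bad", "XXXX")], bundle)
        assert results == []
        assert "skipped" in caplog.text
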