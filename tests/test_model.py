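"""Transformer forward/backward correctness, training behavior, tuning."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from rarept import (
    AgeScaler,
    CorpusConfig,
    DiseaseSpec,
    ModelConfig,
    ModelError,
    PhecodeVocabulary,
    build_corpus,
    generate_cohort,
    load_checkpoint,
    predict_all,
    save_checkpoint,
    train,
    tune,
)
from rarept.model import _backward, bce_loss, forward, init_params

from conftest import make_vocab, signature_specs


@pytest.fixture(scope="module")
def tiny_params():
    rng = np.random.default_rng(0)
    vocab = make_vocab(8)
    cfg = ModelConfig(embed_dim=4, n_heads=2, feedforward_dim=8, n_decoder_blocks=2)
    return init_params(cfg, vocab, AgeScaler(50.0, 10.0), rng)


@pytest.fixture(scope="module")
def trained_setup():
    """Signature cohort + corpus + model trained on 4 of 5 folds."""
    vocab = make_vocab(40)
    specs = signature_specs(vocab, 3, prevalence=0.05)
    cohort = generate_cohort(specs, 2500, vocab, seed=31)
    corpus = build_corpus(cohort, CorpusConfig(k=40, n_folds=5, seed=31))
    train_corpus = corpus[corpus["fold"] != 0].reset_index(drop=True)
    params, history = train(ModelConfig(seed=31), cohort, train_corpus, seed=31, test_fold=0)
    return cohort, specs, corpus, params, history


class TestForward:
    def test_scores_lie_in_unit_interval(self, tiny_params):
        rng = np.random.default_rng(1)
        diag = (rng.random((16, 8)) < 0.4).astype(float)
        s = forward(tiny_params, diag, rng.integers(0, 8, 16), rng.standard_normal((16, 2)))
        assert np.all((s >= 0) & (s <= 1))

    def test_forward_is_deterministic_in_eval_mode(self, tiny_params):
        rng = np.random.default_rng(2)
        diag = (rng.random((4, 8)) < 0.4).astype(float)
        q = np.array([0, 1, 2, 3])
        d = rng.standard_normal((4, 2))
        np.testing.assert_array_equal(
            forward(tiny_params, diag, q, d), forward(tiny_params, diag, q, d)
        )

    def test_batching_does_not_change_scores(self, tiny_params):
        rng = np.random.default_rng(3)
        diag = (rng.random((10, 8)) < 0.4).astype(float)
        q = rng.integers(0, 8, 10)
        d = rng.standard_normal((10, 2))
        full = forward(tiny_params, diag, q, d)
        singles = np.concatenate(
            [forward(tiny_params, diag[i : i + 1], q[i : i + 1], d[i : i + 1]) for i in range(10)]
        )
        np.testing.assert_allclose(full, singles, rtol=0, atol=1e-12)

    def test_shape_mismatch_raises(self, tiny_params):
        with pytest.raises(ModelError, match="width"):
            forward(tiny_params, np.zeros((2, 5)), np.array([0, 1]), np.zeros((2, 2)))

    def test_gradients_match_finite_differences(self, tiny_params):
        rng = np.random.default_rng(4)
        diag = (rng.random((3, 8)) < 0.5).astype(float)
        q = np.array([0, 3, 7])
        demo = rng.standard_normal((3, 2))
        y = np.array([1.0, 0.0, 1.0])
        s, cache = forward(tiny_params, diag, q, demo, want_cache=True)
        grads = _backward(tiny_params, cache, (s - y) / 3)
        eps = 1e-6
        for name in ("W_in", "W_out", "W_dem", "lno_g", "b0_ff_W1", "b1_ca_Wv", "b0_sa_Wo"):
            w = tiny_params.weights[name]
            ix = tuple(rng.integers(0, d) for d in w.shape)
            old = w[ix]
            w[ix] = old + eps
            lp = bce_loss(forward(tiny_params, diag, q, demo), y)
            w[ix] = old - eps
            lm = bce_loss(forward(tiny_params, diag, q, demo), y)
            w[ix] = old
            assert grads[name][ix] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-9)


class TestMaskingInvariance:
    def test_score_unchanged_by_masked_codes_and_code_order(self, trained_setup):
        from rarept.phenotypes import encode
        from rarept import ParticipantRecord

        cohort, specs, _, params, _ = trained_setup
        vocab = cohort.vocab
        query = specs[0].phecode
        base = {vocab.codes[20], vocab.codes[25]}
        r1 = ParticipantRecord("x", 55.0, "F", "white", frozenset(base))
        r2 = ParticipantRecord("x", 55.0, "F", "white", frozenset(base | {query}))
        e1 = encode(r1, query, vocab, params.scaler)
        e2 = encode(r2, query, vocab, params.scaler)  # query code masked away
        s1 = forward(params, e1.diagnoses[None], np.array([vocab.index(query)]), e1.demographics[None])
        s2 = forward(params, e2.diagnoses[None], np.array([vocab.index(query)]), e2.demographics[None])
        assert s1[0] == pytest.approx(s2[0], abs=1e-12)


class TestTraining:
    def test_no_signal_corpus_plateaus_near_ln2(self):
        vocab = make_vocab(10)
        cohort = generate_cohort(
            [DiseaseSpec(phecode=vocab.codes[0], prevalence=0.5)], 600, vocab, seed=5
        )
        corpus = build_corpus(cohort, CorpusConfig(k=100, n_folds=2, seed=5))
        rng = np.random.default_rng(5)
        shuffled = rng.permutation(corpus["label"].to_numpy()).astype(float)
        _, hist = train(ModelConfig(seed=5), cohort, corpus, seed=5, labels_override=shuffled)
        assert hist["best_val_loss"] == pytest.approx(np.log(2), abs=0.12)

    def test_planted_deterministic_signature_beats_095_accuracy(self):
        # signature code present iff case: both the model and a one-feature
        # logistic oracle should classify held-out examples near perfectly
        vocab = make_vocab(10)
        n = 1200
        cohort = generate_cohort(
            [DiseaseSpec(phecode=vocab.codes[0], prevalence=0.4)], n, vocab, seed=6
        )
        truth = cohort.truth[vocab.codes[0]].to_numpy()
        cohort.code_matrix[:, vocab.index(vocab.codes[5])] = truth  # deterministic signature
        corpus = build_corpus(cohort, CorpusConfig(k=100, n_folds=2, seed=6))
        tr = corpus[corpus["fold"] != 0].reset_index(drop=True)
        te = corpus[corpus["fold"] == 0].reset_index(drop=True)
        te = te[te["query"] == vocab.codes[0]]
        params, _ = train(ModelConfig(seed=6), cohort, tr, seed=6, test_fold=0)
        scores = predict_all(params, cohort, [vocab.codes[0]], set(tr["participant_id"]))
        by_id = scores.set_index("participant_id")["score"]
        pred = (by_id.reindex(te["participant_id"]).to_numpy() > 0.5).astype(int)
        acc = (pred == te["label"].to_numpy()).mean()

        feat = cohort.code_matrix[:, vocab.index(vocab.codes[5])].astype(float)
        clf = LogisticRegression().fit(
            feat[tr[tr["query"] == vocab.codes[0]]["row"]].reshape(-1, 1),
            tr[tr["query"] == vocab.codes[0]]["label"],
        )
        oracle_acc = clf.score(
            feat[te["row"]].reshape(-1, 1), te["label"]
        )
        assert oracle_acc > 0.95
        assert acc > 0.95

    def test_same_seed_reproduces_loss_history(self):
        vocab = make_vocab(12)
        specs = signature_specs(vocab, 1, n_sig=3, prevalence=0.2)
        cohort = generate_cohort(specs, 500, vocab, seed=7)
        corpus = build_corpus(cohort, CorpusConfig(k=50, n_folds=2, seed=7))
        cfg = ModelConfig(seed=7, max_final_epochs=6)
        _, h1 = train(cfg, cohort, corpus, seed=7)
        _, h2 = train(cfg, cohort, corpus, seed=7)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_training_loss_running_minimum_non_increasing(self, trained_setup):
        _, _, _, _, history = trained_setup
        losses = history["train_loss"]
        running = np.minimum.accumulate(losses)
        assert all(running[i] <= running[i - 1] + 1e-12 for i in range(1, len(running)))

    def test_corpus_containing_test_fold_is_rejected(self, trained_setup):
        cohort, _, corpus, _, _ = trained_setup
        with pytest.raises(ModelError, match="test fold"):
            train(ModelConfig(seed=0), cohort, corpus, test_fold=0)


class TestTune:
    def test_single_candidate_returned_without_training(self, trained_setup):
        cohort, _, corpus, _, _ = trained_setup
        cfg = ModelConfig(seed=1)
        assert tune([cfg], cohort, corpus.head(0)) is cfg

    def test_zero_learning_rate_candidate_loses(self):
        vocab = make_vocab(12)
        specs = signature_specs(vocab, 1, n_sig=3, prevalence=0.2)
        cohort = generate_cohort(specs, 600, vocab, seed=8)
        corpus = build_corpus(cohort, CorpusConfig(k=60, n_folds=2, seed=8))
        good = ModelConfig(learning_rate=1e-2, max_tuning_epochs=6)
        dead = ModelConfig(learning_rate=1e-12, max_tuning_epochs=6)
        assert tune([dead, good], cohort, corpus) is good

    def test_selection_invariant_to_candidate_order(self):
        vocab = make_vocab(12)
        specs = signature_specs(vocab, 1, n_sig=3, prevalence=0.2)
        cohort = generate_cohort(specs, 500, vocab, seed=9)
        corpus = build_corpus(cohort, CorpusConfig(k=40, n_folds=2, seed=9))
        space = [
            ModelConfig(learning_rate=lr, embed_dim=e, max_tuning_epochs=4)
            for lr, e in [(1e-2, 16), (1e-3, 16), (1e-2, 8), (3e-3, 8)]
        ]
        a = tune(space, cohort, corpus, budget_epochs=4)
        b = tune(list(reversed(space)), cohort, corpus, budget_epochs=4)
        assert a == b

    def test_empty_space_raises(self, trained_setup):
        cohort, _, corpus, _, _ = trained_setup
        with pytest.raises(ModelError):
            tune([], cohort, corpus)


class TestPredictAll:
    def test_empty_query_list_gives_empty_table(self, trained_setup):
        cohort, _, _, params, _ = trained_setup
        assert predict_all(params, cohort, [], set()).empty

    def test_training_participants_flagged_not_dropped(self, trained_setup):
        cohort, specs, corpus, params, _ = trained_setup
        train_ids = set(corpus[corpus["fold"] != 0]["participant_id"])
        table = predict_all(params, cohort, [specs[0].phecode], train_ids)
        assert len(table) == cohort.n
        assert table["in_training"].sum() == len(train_ids & set(cohort.participant_ids))

    def test_batch_size_does_not_change_scores(self, trained_setup):
        cohort, specs, _, params, _ = trained_setup
        a = predict_all(params, cohort, [specs[0].phecode], set(), batch_size=7)
        b = predict_all(params, cohort, [specs[0].phecode], set(), batch_size=4096)
        np.testing.assert_allclose(a["score"], b["score"], atol=1e-12)


def test_checkpoint_round_trip(tmp_path, trained_setup):
    cohort, specs, _, params, _ = trained_setup
    path = tmp_path / "model.npz"
    save_checkpoint(params, path)
    loaded = load_checkpoint(path)
    assert loaded.config == params.config
    assert loaded.vocab.codes == params.vocab.codes
    table_a = predict_all(params, cohort, [specs[0].phecode], set())
    table_b = predict_all(loaded, cohort, [specs[0].phecode], set())
    np.testing.assert_allclose(table_a["score"], table_b["score"], atol=1e-12)


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(embed_dim=30, n_heads=4)
    with pytest.raises(ValueError):
        ModelConfig(validation_fraction=1.0)
    with pytest.raises(ValueError):
        ModelConfig(dropout=1.0)
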