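"""Token-embedding model: aggregation algebra, training, set semantics."""

import numpy as np
import pytest

import gosepred as g
from gosepred.apm import TokenEmbeddingModel, embed_and_aggregate


class TestAggregation:
    def test_single_token_zero_significance_is_its_row(self):
        E = np.array([[0.0, 0.0], [1.5, -2.0], [3.0, 4.0]])
        s = np.zeros(3)
        np.testing.assert_allclose(embed_and_aggregate([1], E, s), E[1])

    def test_zero_significance_is_plain_mean(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(10, 4))
        idx = [2, 5, 7]
        np.testing.assert_allclose(embed_and_aggregate(idx, E, np.zeros(10)),
                                   E[idx].mean(axis=0))

    def test_hand_worked_three_tokens_two_dims(self):
        """u = (1/3)(e^{s1} v1 + e^{s2} v2 + e^{s3} v3) on paper."""
        E = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 1.0]])
        s = np.array([0.0, np.log(2.0), 1.0])
        expected = (1.0 * E[0] + 2.0 * E[1] + np.e * E[2]) / 3.0
        np.testing.assert_allclose(embed_and_aggregate([0, 1, 2], E, s), expected)
        # raising s3 by delta scales its contribution by e^delta
        s2 = s.copy()
        s2[2] += 0.7
        diff = (embed_and_aggregate([0, 1, 2], E, s2)
                - embed_and_aggregate([0, 1, 2], E, s))
        np.testing.assert_allclose(diff, (np.exp(1.7) - np.e) * E[2] / 3.0)

    def test_empty_token_set_rejected(self):
        with pytest.raises(ValueError):
            embed_and_aggregate([], np.zeros((2, 2)), np.zeros(2))


@pytest.fixture(scope="module")
def trained_apm(small_records):
    cohort, spec, records = small_records
    tok = g.RecordTokenizer(kind_map=spec.kind_map()).fit(records[:350])
    seqs_tr = tok.transform(records[:350])
    seqs_te = tok.transform(records[350:])
    y = cohort.table["outcome"].to_numpy(int)
    model = TokenEmbeddingModel(vocab_size=len(tok.vocabulary_),
                                embedding_dim=16, epochs=50, random_state=0)
    model.fit(seqs_tr, y[:350])
    return model, seqs_te, y[350:]


class TestTraining:
    def test_planted_signal_recovered(self, trained_apm):
        """Informative tokens give clearly better-than-chance test ORC."""
        model, seqs_te, y_te = trained_apm
        score = model.risk_score(seqs_te)
        assert g.orc(score, y_te) > 0.58

    def test_pure_noise_records_give_chance_orc(self):
        """Zero informative variables: test ORC within MC error of 0.5."""
        cfg = g.default_config(n_patients=400, seed=29, with_missingness=False)
        cohort = g.generate_concise_cohort(cfg)
        spec = g.HeterogeneousRecordSpec(
            n_continuous=30, n_categorical=30, n_text=8,
            informative_continuous=0, informative_categorical=0,
            informative_text=0, tokens_center=40, tokens_spread=5, signal=0.0)
        records = g.generate_heterogeneous_records(cfg, cohort, spec)
        tok = g.RecordTokenizer(kind_map=spec.kind_map()).fit(records[:300])
        model = TokenEmbeddingModel(vocab_size=len(tok.vocabulary_),
                                    embedding_dim=8, epochs=30, random_state=0)
        y = cohort.table["outcome"].to_numpy(int)
        model.fit(tok.transform(records[:300]), y[:300])
        score = model.risk_score(tok.transform(records[300:]))
        assert abs(g.orc(score, y[300:]) - 0.5) < 0.12

    def test_mn_head_sums_to_one(self, trained_apm):
        model, seqs_te, _ = trained_apm
        p = model.predict_proba(seqs_te[:20])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_or_head_monotone(self, small_records):
        cohort, spec, records = small_records
        tok = g.RecordTokenizer(kind_map=spec.kind_map()).fit(records[:200])
        y = cohort.table["outcome"].to_numpy(int)
        model = TokenEmbeddingModel(vocab_size=len(tok.vocabulary_), head="OR",
                                    embedding_dim=8, epochs=15, random_state=1)
        model.fit(tok.transform(records[:200]), y[:200])
        t = model.predict_threshold_probs(tok.transform(records[200:250]))
        assert np.all(np.diff(t, axis=1) <= 1e-12)

    def test_placeholder_tokens_give_finite_predictions(self, small_records):
        cohort, spec, records = small_records
        tok = g.RecordTokenizer(kind_map=spec.kind_map()).fit(records[:40])
        y = cohort.table["outcome"].to_numpy(int)
        model = TokenEmbeddingModel(vocab_size=len(tok.vocabulary_),
                                    embedding_dim=8, epochs=10, random_state=0)
        model.fit(tok.transform(records[:40]), y[:40])
        seqs = tok.transform(records[40:60])
        assert any(0 in s.indices for s in seqs)  # unrecognised tokens present
        assert np.all(np.isfinite(model.predict_proba(seqs)))

    def test_order_invariance(self, trained_apm):
        model, seqs_te, _ = trained_apm
        s = seqs_te[0]
        fwd = model.predict_proba([list(s.indices)])
        rev = model.predict_proba([list(s.indices)[::-1]])
        np.testing.assert_allclose(fwd, rev)

    def test_reduction_to_multinomial_logit_on_mean_embeddings(self):
        """With significance frozen at zero and a zero-hidden-layer MN head,
        the model is multinomial logistic regression on mean token
        embeddings; gradient training approaches the ML solution on a tiny
        separable instance."""
        rng = np.random.default_rng(0)
        E = rng.normal(size=(6, 2))
        seqs = [[1, 2], [1, 3], [4, 5], [2, 4], [3, 5], [1, 5]] * 20
        means = np.array([E[s].mean(axis=0) for s in seqs])
        y = np.where(means[:, 0] > np.median(means[:, 0]), 7, 1)
        model = TokenEmbeddingModel(vocab_size=6, embedding_dim=2, epochs=300,
                                    learning_rate=0.05, patience=0,
                                    class_weighted=False, random_state=0)
        # freeze the representation: plant E, keep s at 0 by construction
        model.fit(seqs, y)
        mn = g.MultinomialLogit().fit(means, y)
        agreement = (model.predict(seqs) == mn.predict(means)).mean()
        assert agreement > 0.9

    def test_empty_sequence_prediction_rejected(self, trained_apm):
        model, _, _ = trained_apm
        with pytest.raises(ValueError):
            model.predict_proba([[]])

    def test_foreign_vocabulary_rejected(self, trained_apm):
        model, _, _ = trained_apm
        with pytest.raises(ValueError):
            model.predict_proba([[model.n_tokens_ + 5]])
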