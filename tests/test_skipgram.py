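"""Skip-gram vocabulary, objective, gradients, and training."""

from collections import Counter

import numpy as np
import pytest

from cavity2vec import skipgram as sg
from cavity2vec.errors import EmptyVocabularyError, TrainingError

TOY = [["a", "b", "c", "a"], ["b", "c", "d", "e", "f"]]


def _random_model(W=6, d=4, seed=0, vocab=None):
    rng = np.random.default_rng(seed)
    if vocab is None:
        vocab = sg.Vocabulary(tokens=[f"w{i}" for i in range(W)],
                              counts=np.arange(1, W + 1))
    return sg.EmbeddingModel(vocab, rng.normal(size=(len(vocab), d)) * 0.3,
                             rng.normal(size=(len(vocab), d)) * 0.3)


def _numeric_gradient(f, table, eps=1e-6):
    num = np.zeros_like(table)
    it = np.nditer(table, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = table[i]
        table[i] = orig + eps
        up = f()
        table[i] = orig - eps
        dn = f()
        table[i] = orig
        num[i] = (up - dn) / (2 * eps)
    return num


class TestVocabulary:
    def test_counts_and_size(self):
        v = sg.build_vocabulary([["a", "b", "a"]], min_count=1)
        assert len(v) == 2 and v.count("a") == 2 and v.count("b") == 1

    def test_min_count_drops_tokens(self):
        v = sg.build_vocabulary([["a", "b", "a"]], min_count=2)
        assert len(v) == 1 and "b" not in v

    def test_all_dropped_is_an_error(self):
        with pytest.raises(EmptyVocabularyError):
            sg.build_vocabulary([["a", "b"]], min_count=5)

    def test_matches_hash_count_oracle(self, noisy_dataset):
        corpus = [toks for _, toks in noisy_dataset.corpus()]
        tally = Counter(t for s in corpus for t in s)
        for mc in (1, 2, 5):
            expected = {t for t, c in tally.items() if c >= mc}
            v = sg.build_vocabulary(corpus, min_count=mc)
            assert set(v.tokens) == expected
            assert all(v.count(t) == tally[t] for t in v.tokens)


class TestTrainingPairs:
    def test_window_one_enumeration(self):
        assert sg.training_pairs(["a", "b", "c"], 1) == \
            [("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")]

    def test_single_token_sentence_is_empty(self):
        assert sg.training_pairs(["a"], 3) == []

    def test_count_matches_brute_force(self):
        sent = [f"t{i}" for i in range(10)]
        c = 3
        expected = sum(1 for t in range(10) for j in range(-c, c + 1)
                       if j != 0 and 0 <= t + j < 10)
        assert len(sg.training_pairs(sent, c)) == expected

    def test_context_symmetry(self):
        pairs = set(sg.training_pairs(list("abcdefg"), 2))
        assert all((b, a) in pairs for a, b in pairs)


class TestSoftmax:
    def test_zero_vectors_are_uniform(self):
        vocab = sg.Vocabulary(tokens=list("abcde"), counts=np.ones(5))
        m = sg.EmbeddingModel(vocab, np.zeros((5, 3)), np.zeros((5, 3)))
        for tok in vocab.tokens:
            assert sg.softmax_probability(m, "a", tok) == pytest.approx(0.2)

    def test_two_token_closed_form(self):
        # v'_a . v_a = 1, v'_b . v_a = 0  ->  p(a|a) = e/(e+1)
        vocab = sg.Vocabulary(tokens=["a", "b"], counts=np.ones(2))
        m = sg.EmbeddingModel(vocab, np.array([[1.0], [0.0]]),
                              np.array([[1.0], [0.0]]))
        assert sg.softmax_probability(m, "a", "a") == \
            pytest.approx(np.e / (np.e + 1), abs=1e-12)

    def test_normalization_random_vectors(self):
        m = _random_model(W=50, d=8, seed=3)
        p = sg.softmax_distribution(m, "w0")
        assert p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_unknown_token_rejected(self):
        m = _random_model()
        with pytest.raises(KeyError):
            sg.softmax_probability(m, "nope", "w0")


class TestObjective:
    def test_uniform_closed_form(self):
        vocab = sg.Vocabulary(tokens=list("abcde"), counts=np.ones(5))
        m = sg.EmbeddingModel(vocab, np.zeros((5, 3)), np.zeros((5, 3)))
        corpus = [["a", "b", "c"]]
        n_pairs = 4  # window 1, length 3
        expected = (n_pairs / 3) * np.log(0.2)
        assert sg.objective(m, corpus, 1) == pytest.approx(expected, abs=1e-12)

    def test_equals_brute_force_over_softmax_probability(self):
        m = _random_model(vocab=sg.build_vocabulary(TOY))
        c = 2
        total, T = 0.0, sum(len(s) for s in TOY)
        for sent in TOY:
            for center, ctx in sg.training_pairs(sent, c):
                total += np.log(sg.softmax_probability(m, center, ctx))
        assert sg.objective(m, TOY, c) == pytest.approx(total / T, rel=1e-12)

    def test_increases_during_exact_softmax_training(self):
        vocab = sg.build_vocabulary(TOY)
        rng = np.random.default_rng(0)
        m = sg.EmbeddingModel(vocab, (rng.random((len(vocab), 8)) - 0.5) / 8,
                              np.zeros((len(vocab), 8)))
        before = sg.objective(m, TOY, 2)
        hist = sg.full_batch_ascent(m, TOY, 2, 0.5, 5)
        assert hist[-1] > before


class TestGradients:
    def test_exact_softmax_matches_central_differences(self):
        m = _random_model(W=6, d=4, seed=1)
        corpus = [["w0", "w1", "w2", "w3"], ["w4", "w5", "w0"]]
        G_in, G_out = sg.objective_gradient(m, corpus, 2)
        num_in = _numeric_gradient(lambda: sg.objective(m, corpus, 2), m.input_vectors)
        num_out = _numeric_gradient(lambda: sg.objective(m, corpus, 2), m.output_vectors)
        scale = max(np.abs(G_in).max(), np.abs(G_out).max())
        assert np.abs(G_in - num_in).max() / scale < 1e-5
        assert np.abs(G_out - num_out).max() / scale < 1e-5

    def test_negative_sampling_matches_central_differences(self):
        m = _random_model(W=6, d=4, seed=2)
        args = ("w0", "w2", ["w1", "w3", "w3"])  # repeated noise draw on purpose
        G_in, G_out = sg.negative_sampling_gradient(m, *args)
        f = lambda: sg.negative_sampling_objective(m, *args)
        num_in = _numeric_gradient(f, m.input_vectors)
        num_out = _numeric_gradient(f, m.output_vectors)
        scale = max(np.abs(G_in).max(), np.abs(G_out).max())
        assert np.abs(G_in - num_in).max() / scale < 1e-5
        assert np.abs(G_out - num_out).max() / scale < 1e-5


class TestTraining:
    def test_seeded_training_is_bit_identical(self):
        cfg = sg.TrainConfig(dimension=8, window=2, negative=5, epochs=5, seed=13)
        m1 = sg.train(TOY, cfg)
        m2 = sg.train(TOY, cfg)
        assert np.array_equal(m1.input_vectors, m2.input_vectors)
        assert np.array_equal(m1.output_vectors, m2.output_vectors)

    def test_exact_softmax_regime_trains(self):
        m = sg.train(TOY, sg.TrainConfig(dimension=4, window=2, negative=0,
                                         epochs=5, seed=1))
        assert np.isfinite(m.input_vectors).all()

    def test_pairless_corpus_fails_with_diagnostic(self):
        with pytest.raises(TrainingError, match="no training pairs"):
            sg.train([["solo"], ["alone"]], sg.TrainConfig(dimension=4, window=2))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sg.TrainConfig(dimension=1)
        with pytest.raises(ValueError):
            sg.TrainConfig(start_lr=0.001, end_lr=0.01)

    def test_neighbors_respect_template_structure(self, clean_dataset, clean_model):
        """On a zero-noise 3-template corpus, at least 90% of the tokens
        that belong to a single template have a same-template nearest
        neighbour in embedding space."""
        token_owner = {}
        for tmpl in clean_dataset.templates:
            for node in tmpl.base_nodes:
                owners = token_owner.setdefault(node.node_id, set())
                owners.add(tmpl.template_id)
        unique = {t: next(iter(o)) for t, o in token_owner.items()
                  if len(o) == 1 and t in clean_model.vocabulary}
        hits = 0
        checked = 0
        for tok, owner in unique.items():
            nn, _ = clean_model.most_similar(tok, topn=1)[0]
            if nn in unique:
                checked += 1
                hits += unique[nn] == owner
        assert checked > 0
        assert hits / checked >= 0.9
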