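"""Bag-of-words model, word generation, DRM lists and recall estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semcomp import text_domain as td
from semcomp.bvae import NotTrainedError, train
from semcomp.synthetic import LdaParams, generate_lda_corpus


@pytest.fixture(scope="module")
def tiny_vocab():
    return td.Vocabulary(words=tuple(f"w{i}" for i in range(8)),
                         counts=(900, 800, 700, 600, 40, 30, 20, 10))


@pytest.fixture(scope="module")
def tiny_text_model():
    """Small trained text model on a 30-word synthetic corpus."""
    corpus, _, _ = generate_lda_corpus(
        LdaParams(vocab_size=30, n_topics=3, n_docs=300, doc_length=15, seed=5)
    )
    vocab = td.Vocabulary.from_corpus(corpus)
    cfg = td.text_train_config(beta=0.5, seed=0, n_steps=400)
    model = td.build_text_vae(cfg, vocab)
    model, _ = train(model, corpus.astype(np.float32), cfg)
    return model, vocab


class TestVocabulary:
    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            td.Vocabulary(words=("a", "a"), counts=(1, 1))

    def test_lookup(self, tiny_vocab):
        assert tiny_vocab.index("w3") == 3
        assert tiny_vocab.count("w0") == 900
        assert "w7" in tiny_vocab and "zzz" not in tiny_vocab
        with pytest.raises(KeyError):
            tiny_vocab.index("zzz")

    def test_from_corpus_counts(self):
        counts = np.array([[1, 2], [3, 0]])
        v = td.Vocabulary.from_corpus(counts)
        assert v.counts == (4, 2)


class TestBow:
    def test_basic_counting(self, tiny_vocab):
        out = td.bow_vectorize(["w0", "w1", "w0"], tiny_vocab)
        np.testing.assert_array_equal(out[:3], [2, 1, 0])

    def test_empty_tokens(self, tiny_vocab):
        assert td.bow_vectorize([], tiny_vocab).sum() == 0

    def test_oov_dropped(self, tiny_vocab):
        out = td.bow_vectorize(["w0", "nope"], tiny_vocab)
        assert out.sum() == 1


class TestWordProbabilities:
    def test_zero_code_uniform(self):
        params = td.WordGenParams(R=np.zeros((3, 5)), b=np.zeros(5))
        np.testing.assert_allclose(
            td.word_probabilities(np.zeros(3), params), np.full(5, 0.2)
        )

    def test_hand_softmax(self):
        params = td.WordGenParams(R=np.array([[1.0, -1.0]]), b=np.zeros(2))
        p = td.word_probabilities(np.array([1.0]), params)
        e = np.exp([-1.0, 1.0])
        np.testing.assert_allclose(p, e / e.sum(), rtol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_normalisation(self, seed):
        rng = np.random.default_rng(seed)
        d, v = rng.integers(1, 6), rng.integers(2, 20)
        params = td.WordGenParams(R=rng.normal(size=(d, v)) * 3, b=rng.normal(size=v))
        p = td.word_probabilities(rng.normal(size=d), params)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p > 0)

    def test_shape_mismatch(self):
        params = td.WordGenParams(R=np.zeros((3, 5)), b=np.zeros(5))
        with pytest.raises(ValueError):
            td.word_probabilities(np.zeros(4), params)


class TestModelPreset:
    def test_full_preset(self):
        cfg = td.text_train_config(preset="full")
        assert cfg.latent_dim == 100
        assert cfg.hidden_widths == (2000, 2000)
        assert cfg.learning_rate == 1e-5
        assert cfg.batch_size == 100
        assert cfg.beta == 0.5


class TestReconstructWordList:
    def test_distinct_and_correct_length(self, tiny_text_model):
        model, vocab = tiny_text_model
        drm = td.DrmList(lure=vocab.words[0], studied=tuple(vocab.words[1:7]))
        samples = td.reconstruct_word_list(drm, model, vocab, n_samples=50,
                                           rng=np.random.default_rng(3))
        for s in samples:
            assert len(s) == 6
            assert len(set(s)) == 6

    def test_seeded_reproducible(self, tiny_text_model):
        model, vocab = tiny_text_model
        drm = td.DrmList(lure=vocab.words[0], studied=tuple(vocab.words[1:7]))
        a = td.reconstruct_word_list(drm, model, vocab, 5, np.random.default_rng(4))
        b = td.reconstruct_word_list(drm, model, vocab, 5, np.random.default_rng(4))
        assert a == b

    def test_forced_mass_limits_support(self, tiny_text_model, monkeypatch):
        model, vocab = tiny_text_model
        logits = np.full(len(vocab), -np.inf)
        logits[0], logits[1] = np.log(0.9), np.log(0.1)
        monkeypatch.setattr(model, "decode_logits", lambda z: logits[None, :])
        drm = td.DrmList(lure=vocab.words[5], studied=(vocab.words[2], vocab.words[3]))
        samples = td.reconstruct_word_list(drm, model, vocab, 20,
                                           np.random.default_rng(5))
        for s in samples:
            assert set(s) == {vocab.words[0], vocab.words[1]}

    def test_untrained_rejected(self, tiny_text_model):
        _, vocab = tiny_text_model
        cfg = td.text_train_config(n_steps=0)
        fresh = td.build_text_vae(cfg, vocab)
        drm = td.DrmList(lure=vocab.words[0], studied=tuple(vocab.words[1:4]))
        with pytest.raises(NotTrainedError):
            td.reconstruct_word_list(drm, fresh, vocab, 1, np.random.default_rng(0))

    def test_overlong_list_rejected(self, tiny_text_model):
        model, vocab = tiny_text_model
        drm = td.DrmList(lure="x", studied=tuple(f"y{i}" for i in range(len(vocab) + 1)))
        with pytest.raises(ValueError):
            td.reconstruct_word_list(drm, model, vocab, 1, np.random.default_rng(0))


class TestRecallFrequencies:
    def test_membership_fractions(self):
        drm = td.DrmList(lure="l", studied=("a", "b"))
        samples = [["a", "b"], ["a", "l"], ["a", "c"], ["c", "d"]]
        freqs = td.recall_frequencies(samples, drm)
        assert freqs["a"] == 0.75
        assert freqs["b"] == 0.25
        assert freqs["l"] == 0.25

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            td.recall_frequencies([], td.DrmList(lure="l", studied=("a",)))


class TestDrmFiltering:
    def test_rare_lure_excluded(self, tiny_vocab):
        lists = [td.DrmList(lure="w4", studied=tuple(f"w{i}" for i in (0, 1, 2)))]
        assert td.filter_drm_lists(lists, tiny_vocab, min_lure_count=2000,
                                   min_word_count=100, min_length=2) == []

    def test_rare_words_deleted_then_length_check(self):
        words = tuple(f"w{i}" for i in range(16))
        counts = (5000,) + (500,) * 11 + (50,) * 4
        vocab = td.Vocabulary(words=words, counts=counts)
        lists = [td.DrmList(lure="w0", studied=words[1:16])]
        out = td.filter_drm_lists(lists, vocab, min_lure_count=2000,
                                  min_word_count=100, min_length=12)
        assert out == []  # 11 survivors < 12
        out = td.filter_drm_lists(lists, vocab, min_lure_count=2000,
                                  min_word_count=100, min_length=11)
        assert len(out) == 1 and len(out[0].studied) == 11

    def test_clean_list_unchanged(self, tiny_vocab):
        drm = td.DrmList(lure="w0", studied=("w1", "w2", "w3"))
        out = td.filter_drm_lists([drm], tiny_vocab, min_lure_count=500,
                                  min_word_count=100, min_length=3)
        assert out == [drm]


class TestNearestAssociates:
    def test_duplicate_column_ranked_first(self):
        rng = np.random.default_rng(6)
        R = rng.normal(size=(4, 6))
        R[:, 3] = R[:, 0] * 2.0  # same direction as word 0
        vocab = td.Vocabulary(words=tuple("abcdef"), counts=(1,) * 6)
        params = td.WordGenParams(R=R, b=np.zeros(6))
        assert td.nearest_associates(params, "a", vocab, k=2)[0] == "d"

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        n = 50
        R = rng.normal(size=(8, n))
        words = tuple(f"w{i:02d}" for i in range(n))
        vocab = td.Vocabulary(words=words, counts=(1,) * n)
        params = td.WordGenParams(R=R, b=np.zeros(n))
        qi = 17
        norm = R / np.linalg.norm(R, axis=0)
        sims = norm.T @ norm[:, qi]
        sims[qi] = -np.inf
        expect = [words[i] for i in np.argsort(-sims, kind="stable")[:15]]
        assert td.nearest_associates(params, words[qi], vocab) == expect

    def test_unknown_word_and_bad_k(self, tiny_vocab):
        params = td.WordGenParams(R=np.zeros((2, 8)), b=np.zeros(8))
        with pytest.raises(KeyError):
            td.nearest_associates(params, "zzz", tiny_vocab, k=2)
        with pytest.raises(ValueError):
            td.nearest_associates(params, "w0", tiny_vocab, k=8)


class TestSyntheticLists:
    def test_rare_lures_skipped_and_invariants(self, tiny_text_model):
        model, vocab = tiny_text_model
        counts = np.asarray(vocab.counts)
        thresh = int(np.median(counts))
        lists = td.build_synthetic_drm_lists(model, vocab, min_count=thresh,
                                             n_associates=8, min_length=4)
        frequent = {w for w, c in zip(vocab.words, vocab.counts) if c >= thresh}
        for drm in lists:
            assert drm.lure in frequent
            assert set(drm.studied) <= frequent
            assert drm.lure not in drm.studied
            assert len(drm.studied) >= 4

    def test_no_lists_below_floor(self, tiny_text_model):
        model, vocab = tiny_text_model
        assert td.build_synthetic_drm_lists(model, vocab,
                                            min_count=10**9) == []


class TestListIO:
    def test_round_trip(self, tmp_path):
        drm = td.DrmList(lure="sleep", studied=("bed", "rest", "awake"))
        path = tmp_path / "list.txt"
        td.write_word_list(drm, path)
        assert td.read_word_list(path) == drm

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            td.DrmList(lure="a", studied=("a", "b"))
        with pytest.raises(ValueError):
            td.DrmList(lure="c", studied=("b", "b"))
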