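"""CRF scoring/decoding vs exhaustive enumeration, BiLSTM structure, training."""

import itertools

import numpy as np
import pytest

from emrkg import autograd as ag
from emrkg import crf, labeler
from emrkg.corpus_io import TagSequence, bio_to_spans, is_bio_valid, split_dataset
from emrkg.crf import (
    LabelScheme,
    NoValidPathError,
    log_partition,
    nll_and_grads_batch,
    nll_loss,
    sequence_score,
    viterbi_decode,
)
from emrkg.encoder import EncoderConfig, build_vocab
from emrkg.labeler import LstmParams, TrainConfig, bilstm_hidden, emission_scores, init_lstm

rng = np.random.default_rng(11)


def enumerate_scores(S, T):
    n, k = S.shape
    return {
        y: sequence_score(S, T, y) for y in itertools.product(range(k), repeat=n)
    }


class TestSequenceScore:
    def test_all_zero_scores(self):
        S, T = np.zeros((4, 3)), np.zeros((3, 3))
        for y in itertools.product(range(3), repeat=4):
            assert sequence_score(S, T, y) == 0.0

    def test_hand_arithmetic(self):
        S = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert sequence_score(S, T, (0, 1, 0)) == 6.0

    def test_single_position_no_transition(self):
        S = np.array([[3.0, 7.0]])
        assert sequence_score(S, np.zeros((2, 2)), (1,)) == 7.0

    def test_invalid_label_index_rejected(self):
        with pytest.raises(IndexError):
            sequence_score(np.zeros((2, 2)), np.zeros((2, 2)), (0, 5))


class TestLogPartition:
    def test_single_position_is_logsumexp_of_row(self):
        S = np.array([[1.0, 2.0, 3.0]])
        expected = np.log(np.exp(S[0]).sum())
        assert log_partition(S, np.zeros((3, 3))) == pytest.approx(expected)

    def test_uniform_case_n_log_k(self):
        n, k = 4, 3
        assert log_partition(np.zeros((n, k)), np.zeros((k, k))) == pytest.approx(
            n * np.log(k)
        )

    def test_matches_enumeration(self):
        S = rng.integers(-3, 4, size=(3, 3)).astype(float)
        T = rng.integers(-3, 4, size=(3, 3)).astype(float)
        scores = list(enumerate_scores(S, T).values())
        brute = np.log(np.sum(np.exp(scores)))
        assert log_partition(S, T) == pytest.approx(brute, abs=1e-9)

    def test_all_paths_disallowed_raises(self):
        scheme = LabelScheme(["O", "B-x", "I-x"])
        S = np.full((2, 3), -np.inf)
        with pytest.raises(NoValidPathError):
            log_partition(S, np.zeros((3, 3)), scheme)


class TestNllLoss:
    def test_single_label_space_zero_loss(self):
        S = np.array([[2.0], [1.0]])
        assert nll_loss(S, np.zeros((1, 1)), (0, 0)) == pytest.approx(0.0)

    def test_probabilities_sum_to_one(self):
        S = rng.normal(size=(3, 2))
        T = rng.normal(size=(2, 2))
        total = sum(
            np.exp(-nll_loss(S, T, y))
            for y in itertools.product(range(2), repeat=3)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_raising_gold_emission_lowers_loss(self):
        S = rng.normal(size=(4, 3))
        T = rng.normal(size=(3, 3))
        y = (0, 2, 1, 0)
        base = nll_loss(S, T, y)
        S2 = S.copy()
        S2[1, 2] += 0.5
        assert nll_loss(S2, T, y) < base

    def test_loss_nonnegative(self):
        for _ in range(20):
            S = rng.normal(size=(3, 3))
            T = rng.normal(size=(3, 3))
            y = tuple(rng.integers(0, 3, size=3))
            assert nll_loss(S, T, y) >= -1e-12


class TestViterbi:
    def test_single_position_argmax(self):
        S = np.array([[0.3, 0.9, 0.1]])
        path, score = viterbi_decode(S, np.zeros((3, 3)))
        assert path == [1] and score == pytest.approx(0.9)

    def test_matches_exhaustive_argmax(self):
        for _ in range(100):
            S = rng.normal(size=(4, 3))
            T = rng.normal(size=(3, 3))
            scores = enumerate_scores(S, T)
            best = max(scores, key=scores.get)
            path, score = viterbi_decode(S, T)
            assert tuple(path) == best
            assert score == pytest.approx(scores[best])

    def test_tie_break_toward_lowest_index(self):
        S = np.zeros((3, 2))
        T = np.zeros((2, 2))
        path, _ = viterbi_decode(S, T)
        assert path == [0, 0, 0]

    def test_constrained_decode_is_bio_valid(self):
        scheme = LabelScheme.from_entity_types(["x", "y"])
        for _ in range(50):
            S = rng.normal(size=(6, scheme.k)) * 3
            T = rng.normal(size=(scheme.k, scheme.k))
            path, _ = viterbi_decode(S, T, scheme)
            assert is_bio_valid([scheme.labels[i] for i in path])

    def test_score_equals_sequence_score_of_path(self):
        S = rng.normal(size=(5, 4))
        T = rng.normal(size=(4, 4))
        path, score = viterbi_decode(S, T)
        assert score == pytest.approx(sequence_score(S, T, path))


class TestBatchGradients:
    def test_loss_matches_per_sequence_nll(self):
        B, n, k = 3, 4, 3
        S = rng.normal(size=(B, n, k))
        T = rng.normal(size=(k, k))
        tags = rng.integers(0, k, size=(B, n))
        loss, *_ = nll_and_grads_batch(S, T, tags)
        expected = sum(nll_loss(S[b], T, tags[b]) for b in range(B))
        assert loss == pytest.approx(expected, abs=1e-9)

    def test_gradients_match_finite_differences(self):
        B, n, k = 2, 3, 3
        S = rng.normal(size=(B, n, k))
        T = rng.normal(size=(k, k))
        start = rng.normal(size=k)
        end = rng.normal(size=k)
        tags = rng.integers(0, k, size=(B, n))
        scheme = None
        loss, dS, dT, dstart, dend = nll_and_grads_batch(S, T, tags, scheme, start, end)
        eps = 1e-6

        def f():
            return nll_and_grads_batch(S, T, tags, scheme, start, end)[0]

        for arr, grad in [(S, dS), (T, dT), (start, dstart), (end, dend)]:
            it = np.nditer(arr, flags=["multi_index"])
            while not it.finished:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                hi = f()
                arr[idx] = orig - eps
                lo = f()
                arr[idx] = orig
                assert (hi - lo) / (2 * eps) == pytest.approx(grad[idx], abs=1e-4)
                it.iternext()


class TestBiLstm:
    def test_output_width_is_twice_hidden(self):
        fwd, bwd = init_lstm(4, 3, rng), init_lstm(4, 3, rng)
        H = rng.normal(size=(5, 4))
        out = bilstm_hidden(H, fwd, bwd)
        assert out.shape == (5, 6)

    def test_reversal_symmetry_with_tied_parameters(self):
        p = init_lstm(4, 3, rng)
        H = rng.normal(size=(6, 4))
        states = bilstm_hidden(H, p, p)  # fwd half cols 0:3, bwd half 3:6
        states_rev = bilstm_hidden(H[::-1].copy(), p, p)
        # forward states of the reversed input equal backward states of the
        # original, read at mirrored positions
        assert np.allclose(states_rev[:, :3], states[::-1, 3:])
        assert np.allclose(states_rev[:, 3:], states[::-1, :3])

    def test_zero_input_bias_only_cell_arithmetic(self):
        h = 2
        p = LstmParams(
            W_x=ag.Tensor(np.zeros((3, 4 * h))),
            W_h=ag.Tensor(np.zeros((h, 4 * h))),
            b=ag.Tensor(np.array([0.5, 0.5, -1.0, -1.0, 0.2, 0.2, 0.3, 0.3])),
        )
        H = np.zeros((2, 3))
        out = bilstm_hidden(H, p, p)

        def sig(x):
            return 1 / (1 + np.exp(-x))

        # step 1: c1 = sig(b_f)*0 + sig(b_i)*tanh(b_g); h1 = sig(b_o)*tanh(c1)
        c1 = sig(0.5) * np.tanh(0.2)
        h1 = sig(0.3) * np.tanh(c1)
        # step 2 (zero weights => same gate activations): c2 = sig(b_f)*c1 + sig(b_i)*tanh(b_g)
        c2 = sig(-1.0) * c1 + sig(0.5) * np.tanh(0.2)
        h2 = sig(0.3) * np.tanh(c2)
        assert out[0, 0] == pytest.approx(h1)
        assert out[1, 0] == pytest.approx(h2)
        # backward direction mirrors: position 1 is its first step
        assert out[1, 2] == pytest.approx(h1)
        assert out[0, 2] == pytest.approx(h2)


class TestEmissionScores:
    def test_zero_weights_rows_equal_bias(self):
        h_seq = rng.normal(size=(4, 6))
        b = np.array([1.0, -2.0, 0.5])
        S = emission_scores(h_seq, np.zeros((3, 6)), b)
        assert np.allclose(S, np.tile(b, (4, 1)))

    def test_hand_product(self):
        h_seq = np.array([[1.0, 2.0]])
        W = np.array([[3.0, 4.0], [0.0, 1.0]])
        S = emission_scores(h_seq, W, np.array([0.1, 0.2]))
        assert np.allclose(S, [[3 + 8 + 0.1, 2 + 0.2]])

    def test_shapes_and_mismatch(self):
        S = emission_scores(rng.normal(size=(5, 6)), rng.normal(size=(3, 6)), np.zeros(3))
        assert S.shape == (5, 3)
        with pytest.raises(ValueError):
            emission_scores(rng.normal(size=(5, 4)), rng.normal(size=(3, 6)), np.zeros(3))


@pytest.fixture(scope="module")
def tiny_setup():
    from emrkg import synthetic

    cfg = synthetic.GeneratorConfig(n_docs=60, seed=21)
    dicts = synthetic.generate_dictionaries(cfg)
    seqs = synthetic.generate_tag_sequences(cfg, dicts)
    train, dev, _ = split_dataset(seqs, seed=2)
    vocab = build_vocab([s.tokens for s in train])
    enc_cfg = EncoderConfig(vocab=vocab, d_model=8, n_layers=1, n_heads=2,
                            d_ff=16, max_len=64, seed=1)
    return train, dev, enc_cfg


class TestTraining:
    def test_loss_decreases_after_first_epoch(self, tiny_setup):
        train, _, enc_cfg = tiny_setup
        model = labeler.fit(train, enc_cfg, train_cfg=TrainConfig(epochs=1, seed=0))
        assert model.history[1] < model.history[0]

    def test_same_seed_identical_parameters(self, tiny_setup):
        train, _, enc_cfg = tiny_setup
        a = labeler.fit(train[:40], enc_cfg, train_cfg=TrainConfig(epochs=1, seed=4))
        b = labeler.fit(train[:40], enc_cfg, train_cfg=TrainConfig(epochs=1, seed=4))
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.data, pb.data)

    def test_empty_corpus_rejected(self, tiny_setup):
        _, _, enc_cfg = tiny_setup
        with pytest.raises(ValueError):
            labeler.fit([], enc_cfg)

    def test_predictions_are_bio_valid(self, tiny_setup):
        train, dev, enc_cfg = tiny_setup
        model = labeler.fit(train, enc_cfg, train_cfg=TrainConfig(epochs=2, seed=0))
        for seq in model.predict(dev[:20]):
            assert is_bio_valid(seq.labels)

    def test_lexical_cue_recovery_small(self, tiny_setup):
        """With per-type character pools the tagger should recover most
        entities even at this small scale."""
        from emrkg import ner_eval

        train, dev, enc_cfg = tiny_setup
        model = labeler.fit(train, enc_cfg, train_cfg=TrainConfig(epochs=6, seed=0))
        counts = ner_eval.MatchCounts()
        for p, g in zip(model.predict(dev), dev):
            counts = counts + ner_eval.match_entities(
                bio_to_spans(p, strict=False), bio_to_spans(g)
            )
        _, _, f1 = ner_eval.prf(counts)
        assert f1 >= 0.8
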