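"""Linear-chain scoring, exact Viterbi decoding and perceptron training."""

import itertools

import numpy as np
import pytest

from chemtagger.tagger import (
    LABELS,
    START,
    SequenceModel,
    TrainConfig,
    load_model,
    save_model,
    sequence_score,
    train,
    viterbi,
)


def random_model(rng, feature_pool):
    emission = {
        (f, y): float(rng.normal())
        for f in feature_pool
        for y in LABELS
        if rng.random() < 0.7
    }
    transition = {
        (p, y): float(rng.normal())
        for p in (START,) + LABELS
        for y in LABELS
        if rng.random() < 0.7
    }
    return SequenceModel(emission, transition)


def random_features(rng, feature_pool, n):
    return [
        frozenset(
            str(f) for f in rng.choice(feature_pool, size=rng.integers(1, 4), replace=False)
        )
        for _ in range(n)
    ]


def enumerate_argmax(features, model):
    """Brute force: score all 3^n label sequences with independent arithmetic,
    return the best; ties resolved lexicographically in label order."""
    n = len(features)
    emit = [
        {y: sum(model.emission.get((f, y), 0.0) for f in feats) for y in LABELS}
        for feats in features
    ]
    best_score, best_seq = -float("inf"), None
    order = {y: k for k, y in enumerate(LABELS)}
    for seq in itertools.product(LABELS, repeat=n):
        s = 0.0
        prev = START
        for i, y in enumerate(seq):
            s += emit[i][y] + model.transition.get((prev, y), 0.0)
            prev = y
        key = [order[y] for y in seq]
        if s > best_score or (s == best_score and key < [order[y] for y in best_seq]):
            best_score, best_seq = s, seq
    return list(best_seq), best_score


class TestSequenceScore:
    def test_zero_model_scores_zero(self):
        model = SequenceModel()
        feats = [frozenset({"a", "b"}), frozenset({"c"})]
        assert sequence_score(feats, ["B", "I"], model) == 0.0

    def test_single_token_emission_plus_start_transition(self):
        model = SequenceModel({("f", "B"): 2.0}, {(START, "B"): 0.5})
        assert sequence_score([frozenset({"f"})], ["B"], model) == pytest.approx(2.5)

    def test_unknown_label_error(self):
        with pytest.raises(ValueError, match="unknown label"):
            sequence_score([frozenset({"f"})], ["X"], SequenceModel())

    def test_matches_direct_summation_on_random_models(self):
        rng = np.random.default_rng(0)
        pool = [f"f{i}" for i in range(6)]
        for _ in range(50):
            model = random_model(rng, pool)
            n = int(rng.integers(1, 7))
            feats = random_features(rng, pool, n)
            labels = [str(l) for l in rng.choice(LABELS, size=n)]
            direct = 0.0
            prev = START
            for fs, y in zip(feats, labels):
                direct += sum(model.emission.get((f, y), 0.0) for f in fs)
                direct += model.transition.get((prev, y), 0.0)
                prev = y
            assert sequence_score(feats, labels, model) == pytest.approx(direct)


class TestViterbi:
    def test_zero_model_decodes_all_outside(self):
        feats = [frozenset({"x"})] * 5
        assert viterbi(feats, SequenceModel()) == ["O"] * 5

    def test_handbuilt_lexicon_weights(self):
        model = SequenceModel(
            {("WL0=acid", "B"): 2.0, ("W0=x", "I"): 0.0},
            {("B", "I"): 1.5, (START, "B"): 0.0},
        )
        feats = [
            frozenset({"WL0=the"}),
            frozenset({"WL0=acid"}),
            frozenset({"WL0=works"}),
        ]
        # the B->I transition bonus pulls the following token into the entity
        expected, _ = enumerate_argmax(feats, model)
        assert viterbi(feats, model) == expected == ["O", "B", "I"]

    def test_equals_enumeration_on_random_models(self):
        rng = np.random.default_rng(42)
        pool = [f"f{i}" for i in range(5)]
        for _ in range(100):
            model = random_model(rng, pool)
            n = int(rng.integers(1, 9))
            feats = random_features(rng, pool, n)
            expected, expected_score = enumerate_argmax(feats, model)
            got = viterbi(feats, model)
            assert sequence_score(feats, got, model) == pytest.approx(expected_score)
            assert got == expected

    def test_invariant_to_feature_ordering(self):
        rng = np.random.default_rng(1)
        pool = [f"f{i}" for i in range(6)]
        model = random_model(rng, pool)
        feats = [frozenset({"f0", "f1", "f2"}), frozenset({"f3", "f4"})]
        shuffled = [frozenset(sorted(fs, reverse=True)) for fs in feats]
        assert viterbi(feats, model) == viterbi(shuffled, model)


def _toy_lexicon_task(rng, n_sequences=30):
    """Label B iff the token is in a planted lexicon; linearly separable."""
    lexicon = {"acidx", "benzol", "tholin"}
    background = ["the", "of", "result", "was", "good", "seen"]
    data = []
    for _ in range(n_sequences):
        n = int(rng.integers(3, 8))
        words = [str(w) for w in rng.choice(background, size=n)]
        if rng.random() < 0.8:
            words[int(rng.integers(0, n))] = str(rng.choice(sorted(lexicon)))
        feats = [frozenset({f"W0={w}", f"SUF2={w[-2:]}"}) for w in words]
        labels = ["B" if w in lexicon else "O" for w in words]
        data.append((feats, labels))
    return data


class TestTrain:
    def test_converges_on_separable_task(self):
        rng = np.random.default_rng(3)
        data = _toy_lexicon_task(rng)
        model = train(data, TrainConfig(epochs=10, seed=0, averaging=False))
        assert all(viterbi(f, model) == list(y) for f, y in data)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        data = _toy_lexicon_task(rng)
        m1 = train(data, TrainConfig(epochs=5, seed=11))
        m2 = train(data, TrainConfig(epochs=5, seed=11))
        assert m1.emission == m2.emission and m1.transition == m2.transition

    def test_single_update_equals_count_difference(self):
        feats = [frozenset({"f"}), frozenset({"g"})]
        gold = ["B", "I"]
        model = train(
            [(feats, gold)],
            TrainConfig(epochs=1, seed=0, shuffle=False, averaging=False),
        )
        # zero model decodes O O; update = gold counts minus predicted counts
        assert model.emission == {
            ("f", "B"): 1.0, ("g", "I"): 1.0, ("f", "O"): -1.0, ("g", "O"): -1.0,
        }
        assert model.transition == {
            (START, "B"): 1.0, ("B", "I"): 1.0, (START, "O"): -1.0, ("O", "O"): -1.0,
        }

    def test_empty_data_error(self):
        with pytest.raises(ValueError):
            train([])

    def test_loss_stays_zero_after_convergence(self):
        rng = np.random.default_rng(6)
        data = _toy_lexicon_task(rng)
        model = train(data, TrainConfig(epochs=25, seed=0, averaging=False))
        mistakes = sum(viterbi(f, model) != list(y) for f, y in data)
        assert mistakes == 0


class TestSerialization:
    def test_round_trip_preserves_decoding(self, tmp_path):
        rng = np.random.default_rng(7)
        pool = [f"f{i}" for i in range(8)]
        model = random_model(rng, pool)
        p = tmp_path / "model.txt"
        save_model(model, p)
        loaded = load_model(p)
        for _ in range(50):
            feats = random_features(rng, pool, int(rng.integers(1, 7)))
            assert viterbi(feats, model) == viterbi(feats, loaded)

    def test_empty_model_round_trip(self, tmp_path):
        p = tmp_path / "model.txt"
        save_model(SequenceModel(), p)
        loaded = load_model(p)
        assert loaded.emission == {} and loaded.transition == {}

    def test_corrupted_header_error(self, tmp_path):
        p = tmp_path / "model.txt"
        p.write_text("not a model\n")
        with pytest.raises(ValueError, match="header"):
            load_model(p)
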