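import json

import numpy as np
import pytest

from nbmature.encoding import apply_substitutions, one_hot
from nbmature.models import (
    LinearModel,
    TrainConfig,
    baseline_median_macs_distance,
    baseline_wt_distance,
    encode_for_linear,
    evaluate,
    oriented_auc,
    score,
    train_cnn,
    train_embedding_mlp,
    train_linear_l1,
    train_logistic_l1,
)

from conftest import random_mutants


def _toy_q5r_dataset(lead, n=200, seed=0):
    """Mutants of the lead, labeled by carrying the (5, R) substitution."""
    rng = np.random.default_rng(seed)
    seqs = random_mutants(lead, n, rng, max_subs=2)
    # guarantee both classes are well represented
    for i in range(0, n, 4):
        seqs[i] = apply_substitutions(lead, [(lead.sequence[4], 5, "R")])
    y = np.array([int(s[4] == "R") for s in seqs])
    return seqs, y


class TestLogistic:
    def test_separable_substitution_recovered_sparsely(self, lead20):
        seqs, y = _toy_q5r_dataset(lead20)
        enc = encode_for_linear(seqs, lead20)
        model = train_logistic_l1(enc, y, TrainConfig(seed=0))
        w = model.weights.get((5, "R"), 0.0)
        assert w > 0
        assert w == max(model.weights.values())
        # L1 keeps the solution sparse: the causal feature dominates
        others = [abs(v) for k, v in model.weights.items() if k != (5, "R")]
        assert model.n_nonzero() < 0.2 * enc.X.shape[1]
        assert all(o < w / 2 for o in others)

    def test_permuted_labels_strong_penalty_all_zero(self, lead20):
        seqs, y = _toy_q5r_dataset(lead20)
        rng = np.random.default_rng(1)
        y = rng.permutation(y)
        enc = encode_for_linear(seqs, lead20)
        cfg = TrainConfig(lambda_logistic=2.0, logistic_convention="mean")
        model = train_logistic_l1(enc, y, cfg)
        assert model.n_nonzero() == 0

    def test_duplicated_dataset_same_model_under_mean_loss(self, lead20):
        seqs, y = _toy_q5r_dataset(lead20, n=120)
        enc1 = encode_for_linear(seqs, lead20)
        enc2 = encode_for_linear(seqs + seqs, lead20)
        cfg = TrainConfig(lambda_logistic=0.01, logistic_convention="mean")
        m1 = train_logistic_l1(enc1, y, cfg)
        m2 = train_logistic_l1(enc2, np.concatenate([y, y]), cfg)
        s1 = m1.score_sequences(seqs[:20])
        s2 = m2.score_sequences(seqs[:20])
        np.testing.assert_allclose(s1, s2, atol=1e-3)

    def test_single_class_errors(self, lead20):
        seqs, _ = _toy_q5r_dataset(lead20, n=20)
        enc = encode_for_linear(seqs, lead20)
        with pytest.raises(ValueError, match="both classes"):
            train_logistic_l1(enc, np.ones(20, dtype=int), TrainConfig())


class TestLinear:
    def test_planted_effect_recovered(self, lead20):
        rng = np.random.default_rng(2)
        seqs, y = _toy_q5r_dataset(lead20, n=300, seed=2)
        e = 3.0 * y + rng.normal(0, 0.1, size=len(y))
        enc = encode_for_linear(seqs, lead20)
        model = train_linear_l1(enc, e, TrainConfig())
        assert model.weights.get((5, "R"), 0.0) == pytest.approx(3.0, abs=0.2)

    def test_constant_targets_zero_weights_mean_intercept(self, lead20):
        seqs, _ = _toy_q5r_dataset(lead20, n=50)
        enc = encode_for_linear(seqs, lead20)
        model = train_linear_l1(enc, np.full(50, 1.7), TrainConfig())
        assert model.n_nonzero() == 0
        assert model.intercept == pytest.approx(1.7)

    def test_huge_penalty_zeroes_everything(self, lead20):
        rng = np.random.default_rng(3)
        seqs, y = _toy_q5r_dataset(lead20, n=100, seed=3)
        e = 3.0 * y + rng.normal(0, 0.1, size=len(y))
        enc = encode_for_linear(seqs, lead20)
        model = train_linear_l1(enc, e, TrainConfig(lambda_linear=1e4))
        assert model.n_nonzero() == 0

    def test_monotone_sparsity_in_penalty(self, lead20):
        rng = np.random.default_rng(4)
        seqs, y = _toy_q5r_dataset(lead20, n=200, seed=4)
        e = 3.0 * y + rng.normal(0, 0.5, size=len(y))
        enc = encode_for_linear(seqs, lead20)
        nnz = [
            train_linear_l1(enc, e, TrainConfig(lambda_linear=lam)).n_nonzero()
            for lam in (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
        ]
        assert nnz == sorted(nnz, reverse=True)


class TestScore:
    def test_lead_scores_intercept(self, lead20):
        m = LinearModel({(5, "R"): 2.0}, intercept=-0.5, task="classification",
                        lam=1.0, lead=lead20)
        assert score(m, [lead20.sequence])[0] == pytest.approx(-0.5)

    def test_double_mutant_arithmetic(self, lead):
        m = LinearModel({(27, "Y"): 2.0, (30, "A"): 1.0}, intercept=-1.0,
                        task="classification", lam=1.0, lead=lead)
        double = apply_substitutions(
            lead, [(lead.sequence[26], 27, "Y"), (lead.sequence[29], 30, "A")]
        )
        assert score(m, [double])[0] == pytest.approx(2.0)

    def test_additivity_double_equals_sum_of_singles(self, lead20):
        rng = np.random.default_rng(5)
        weights = {
            (pos, aa): float(rng.normal())
            for pos in range(1, len(lead20) + 1)
            for aa in "AR" if aa != lead20.sequence[pos - 1]
        }
        m = LinearModel(weights, 0.3, "regression", 1.0, lead20)
        s1 = apply_substitutions(lead20, [("M", 1, "A")])
        s2 = apply_substitutions(lead20, [("K", 2, "R")])
        d = apply_substitutions(lead20, [("M", 1, "A"), ("K", 2, "R")])
        lead_s, a, b, ab = score(m, [lead20.sequence, s1, s2, d])
        assert ab - lead_s == pytest.approx((a - lead_s) + (b - lead_s), abs=1e-12)

    def test_serialization_bit_exact(self, lead20, tmp_path):
        seqs, y = _toy_q5r_dataset(lead20)
        enc = encode_for_linear(seqs, lead20)
        m = train_logistic_l1(enc, y, TrainConfig())
        path = tmp_path / "m.json"
        m.save(path)
        back = LinearModel.load(path)
        assert back.to_json() == m.to_json()
        np.testing.assert_array_equal(
            back.score_sequences(seqs[:10]), m.score_sequences(seqs[:10])
        )

    def test_seeded_determinism(self, lead20):
        seqs, y = _toy_q5r_dataset(lead20)
        enc = encode_for_linear(seqs, lead20)
        m1 = train_logistic_l1(enc, y, TrainConfig(seed=7))
        m2 = train_logistic_l1(enc, y, TrainConfig(seed=7))
        assert m1.to_json() == m2.to_json()


class TestBaselines:
    def test_lead_distance_zero(self, lead20):
        assert baseline_wt_distance([lead20.sequence], lead20)[0] == 0

    def test_single_mismatch(self, lead20):
        mut = apply_substitutions(lead20, [("Y", 5, "W")])
        assert baseline_wt_distance([mut], lead20)[0] == 1

    def test_macs_set_of_lead_equals_wt_baseline(self, lead20):
        rng = np.random.default_rng(6)
        seqs = random_mutants(lead20, 10, rng)
        wt = baseline_wt_distance(seqs, lead20)
        macs = baseline_median_macs_distance(seqs, [lead20.sequence], lead20)
        np.testing.assert_array_equal(wt, macs)

    def test_empty_macs_errors(self, lead20):
        with pytest.raises(ValueError):
            baseline_median_macs_distance(["A" * 20], [], lead20)


class TestEvaluate:
    def test_perfect_scores(self):
        rep = evaluate([1, 0, 1, 0], labels=[1, 0, 1, 0])
        assert rep.roc_auc == 1.0 and rep.pr_auc == 1.0

    def test_known_auc_brute_force(self):
        # brute force over the 4 positive/negative pairs: 3 wins of 4
        rep = evaluate([0.9, 0.8, 0.2, 0.1], labels=[1, 0, 1, 0])
        assert rep.roc_auc == pytest.approx(0.75)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, size=4000)
        scores = rng.normal(size=4000)
        rep = evaluate(scores, labels=labels)
        assert rep.roc_auc == pytest.approx(0.5, abs=0.05)

    def test_per_class_spearman(self):
        rng = np.random.default_rng(9)
        e = np.concatenate([rng.uniform(0.1, 2, 50), rng.uniform(-2, -0.1, 50)])
        labels = (e > 0).astype(int)
        scores = e + rng.normal(0, 0.2, size=100)
        rep = evaluate(scores, labels=labels, e_values=e)
        assert rep.spearman > 0.9
        assert -1 <= rep.spearman_enriched <= 1
        assert -1 <= rep.spearman_depleted <= 1

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            evaluate([1, 2, 3], labels=[1, 1, 1])
        with pytest.raises(ValueError):
            evaluate([1, 2, 3], e_values=[2.0, 2.0, 2.0])

    def test_oriented_auc_flips(self):
        scores = [0.1, 0.9]
        labels = [1, 0]
        auc, orient = oriented_auc(scores, labels)
        assert auc == 1.0 and orient == -1


def _additive_landscape(lead, n, seed):
    rng = np.random.default_rng(seed)
    effects = {(5, "R"): 2.0, (12, "W"): 2.0, (7, "P"): -2.0}
    seqs = random_mutants(lead, n, rng, max_subs=3)
    fitness = np.zeros(n)
    for i, s in enumerate(seqs):
        for (pos, aa), eff in effects.items():
            if s[pos - 1] == aa:
                fitness[i] += eff
    y = (fitness + rng.normal(0, 0.5, n) > 0.5).astype(int)
    return seqs, y


class TestNeuralModels:
    def test_cnn_close_to_logistic_on_additive_landscape(self, lead20):
        seqs, y = _additive_landscape(lead20, 1500, seed=10)
        tr, te = slice(0, 1000), slice(1000, 1500)
        cfg = TrainConfig(seed=0, epochs=150)
        enc = encode_for_linear(seqs[tr], lead20)
        logit = train_logistic_l1(enc, y[tr], cfg)
        cnn = train_cnn(seqs[tr], y[tr], cfg, lead20)
        auc_l = evaluate(score(logit, seqs[te]), labels=y[te]).roc_auc
        auc_c = evaluate(score(cnn, seqs[te]), labels=y[te]).roc_auc
        assert auc_c >= auc_l - 0.05

    def test_cnn_beats_logistic_on_xor_epistasis(self, lead20):
        # label = XOR of two adjacent-site substitutions: invisible to any
        # additive model, learnable by the nonlinear scorer
        rng = np.random.default_rng(11)
        n = 800
        seqs, y = [], []
        for _ in range(n):
            a, b = rng.integers(0, 2), rng.integers(0, 2)
            subs = []
            if a:
                subs.append((lead20.sequence[4], 5, "R"))
            if b:
                subs.append((lead20.sequence[5], 6, "W"))
            seqs.append(apply_substitutions(lead20, subs))
            y.append(a ^ b)
        y = np.array(y)
        tr, te = slice(0, 600), slice(600, n)
        cfg = TrainConfig(seed=0, epochs=300, patience=50)
        enc = encode_for_linear(seqs[: 600], lead20)
        logit = train_logistic_l1(enc, y[tr], cfg)
        cnn = train_cnn(seqs[: 600], y[tr], cfg, lead20)
        auc_l = evaluate(score(logit, seqs[te]), labels=y[te]).roc_auc
        auc_c = evaluate(score(cnn, seqs[te]), labels=y[te]).roc_auc
        assert auc_c > auc_l
        assert auc_c > 0.9

    def test_untrained_cnn_is_random(self, lead20):
        seqs, y = _additive_landscape(lead20, 400, seed=12)
        cnn = train_cnn(seqs, y, TrainConfig(seed=0, epochs=0), lead20)
        auc = evaluate(score(cnn, seqs), labels=y).roc_auc
        assert 0.3 < auc < 0.7

    def test_cnn_seeded_reproducibility(self, lead20):
        seqs, y = _additive_landscape(lead20, 300, seed=13)
        cfg = TrainConfig(seed=5, epochs=30)
        m1 = train_cnn(seqs, y, cfg, lead20)
        m2 = train_cnn(seqs, y, cfg, lead20)
        assert abs(m1.val_loss - m2.val_loss) < 1e-6
        np.testing.assert_allclose(
            score(m1, seqs[:10]), score(m2, seqs[:10]), atol=1e-9
        )

    def test_embedding_mlp_trains_and_scores(self, lead20):
        # clean, separable single-substitution label: the stub embedding
        # preserves the signal and the MLP separates it
        seqs, y = _toy_q5r_dataset(lead20, n=400, seed=0)
        cfg = TrainConfig(seed=0, epochs=500, patience=50)
        mlp = train_embedding_mlp(seqs, y, cfg, lead20)
        auc = evaluate(score(mlp, seqs), labels=y).roc_auc
        assert auc > 0.9
        mlp2 = train_embedding_mlp(seqs, y, cfg, lead20)
        np.testing.assert_allclose(score(mlp, seqs[:5]), score(mlp2, seqs[:5]))
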