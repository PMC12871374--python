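import numpy as np
import pytest
from scipy import stats

from nbmature.design import (
    DesignCandidate,
    GibbsConfig,
    design_batch,
    gibbs_step,
    proposal_distribution,
    run_trajectory,
    select_lr_score,
    temperature_schedule,
    write_designs,
)
from nbmature.encoding import substitutions_of
from nbmature.models import LinearModel


def _zero_model(lead):
    return LinearModel({}, 0.0, "classification", 1.0, lead)


def _positive_cdr_model(lead, rng=None, scale=1.0):
    """Additive model with positive weights on many CDR substitutions."""
    rng = rng or np.random.default_rng(0)
    weights = {}
    for pos in sorted(lead.cdr_mask):
        for aa in "ARNDE":
            if aa != lead.sequence[pos - 1]:
                weights[(pos, aa)] = float(rng.uniform(0.1, 1.0)) * scale
    return LinearModel(weights, 0.0, "classification", 1.0, lead)


class TestProposal:
    def test_probabilities_sum_to_one(self, lead):
        model = _positive_cdr_model(lead)
        state = lead.sequence
        rng = np.random.default_rng(0)
        cfg = GibbsConfig(seed=0)
        for T in (5.0, 1.0, 0.5):
            for _ in range(5):
                _, probs, _ = proposal_distribution(state, model, T, lead, cfg, 5)
                assert abs(probs.sum() - 1.0) < 1e-12
                state = gibbs_step(state, model, T, lead, cfg, 5, rng)

    def test_zero_model_uniform(self, lead):
        cfg = GibbsConfig(seed=0)
        moves, probs, _ = proposal_distribution(
            lead.sequence, _zero_model(lead), 1.0, lead, cfg, 5
        )
        np.testing.assert_allclose(probs, 1.0 / len(moves), atol=1e-15)

    def test_moves_restricted_to_cdrs(self, lead):
        cfg = GibbsConfig(seed=0)
        moves, _, _ = proposal_distribution(
            lead.sequence, _zero_model(lead), 1.0, lead, cfg, 3
        )
        assert all(m is None or m[0] in lead.cdr_mask for m in moves)

    def test_hard_mask_at_goal_distance(self, lead):
        # push the state to the goal distance, then check every proposed
        # move keeps hamming <= d_goal
        cdrs = sorted(lead.cdr_mask)[:3]
        chars = list(lead.sequence)
        for p in cdrs:
            chars[p - 1] = "A" if lead.sequence[p - 1] != "A" else "R"
        state = "".join(chars)
        cfg = GibbsConfig(seed=0)
        moves, _, _ = proposal_distribution(
            state, _zero_model(lead), 1.0, lead, cfg, 3
        )
        for m in moves:
            if m is None:
                continue
            pos, aa = m
            new = state[: pos - 1] + aa + state[pos:]
            assert sum(a != b for a, b in zip(new, lead.sequence)) <= 3

    def test_high_temperature_flattens_distribution(self, lead):
        model = _positive_cdr_model(lead)
        cfg = GibbsConfig(seed=0)
        _, p_hot, _ = proposal_distribution(
            lead.sequence, model, 1e6, lead, cfg, 5
        )
        n = len(p_hot)
        np.testing.assert_allclose(p_hot, 1.0 / n, rtol=1e-3)


class TestTrajectory:
    def test_same_seed_identical(self, lead):
        model = _positive_cdr_model(lead)
        cfg = GibbsConfig(samples_per_distance=5, seed=0)
        c1 = run_trajectory(lead, model, 5, cfg, np.random.SeedSequence([1, 5, 0]))
        c2 = run_trajectory(lead, model, 5, cfg, np.random.SeedSequence([1, 5, 0]))
        assert c1.sequence == c2.sequence
        assert c1.model_score == c2.model_score

    def test_zero_steps_returns_lead(self, lead):
        cfg = GibbsConfig(steps=0, seed=0)
        c = run_trajectory(lead, _zero_model(lead), 3, cfg, 0)
        assert c.sequence == lead.sequence and c.hamming_to_wt == 0

    def test_temperature_blocks(self):
        sched = temperature_schedule(100, (5.0, 1.0, 0.5))
        assert sched[:34] == [5.0] * 34
        assert sched[34:67] == [1.0] * 33
        assert sched[67:] == [0.5] * 33

    def test_single_strong_substitution_recovered(self, lead):
        pos = sorted(lead.cdr_mask)[0]
        aa = "Y" if lead.sequence[pos - 1] != "Y" else "W"
        model = LinearModel({(pos, aa): 5.0}, 0.0, "classification", 1.0, lead)
        cfg = GibbsConfig(seed=0, alpha=0.5)
        hits = sum(
            run_trajectory(lead, model, 1, cfg,
                           np.random.SeedSequence([0, 1, i])).sequence[pos - 1] == aa
            for i in range(200)
        )
        assert hits / 200 > 0.9

    def test_greedy_endpoint_beats_hot_endpoint(self, lead):
        model = _positive_cdr_model(lead)
        cold = GibbsConfig(temperatures=(0.01,), steps=50, seed=0)
        hot = GibbsConfig(temperatures=(5.0,), steps=50, seed=0)
        cold_scores, hot_scores = [], []
        for i in range(50):
            cold_scores.append(run_trajectory(
                lead, model, 5, cold, np.random.SeedSequence([2, 5, i])).model_score)
            hot_scores.append(run_trajectory(
                lead, model, 5, hot, np.random.SeedSequence([2, 5, i])).model_score)
        assert np.mean(cold_scores) >= np.mean(hot_scores)


class TestDesignBatch:
    def test_constraints_and_dedup(self, lead):
        model = _positive_cdr_model(lead)
        cfg = GibbsConfig(samples_per_distance=20, steps=40, seed=0)
        cands = design_batch(lead, model, cfg)
        assert len(cands) <= 30
        assert len({c.sequence for c in cands}) == len(cands)
        for c in cands:
            assert c.hamming_to_wt <= c.goal_distance
            assert all(pos in lead.cdr_mask
                       for _, pos, _ in substitutions_of(c.sequence, lead))

    def test_additive_positive_landscape_prefers_max_distance(self, lead):
        model = _positive_cdr_model(lead)
        cfg = GibbsConfig(samples_per_distance=30, steps=60, seed=1)
        cands = design_batch(lead, model, cfg)
        # with purely positive additive weights, more substitutions always
        # score higher, so the pooled top-30 concentrates at d_goal = 7
        assert np.mean([c.hamming_to_wt for c in cands]) > 5.5
        assert sum(c.goal_distance == 7 for c in cands) > 15

    def test_fewer_than_n_unique_returns_all(self, lead):
        pos = sorted(lead.cdr_mask)[0]
        aa = "Y" if lead.sequence[pos - 1] != "Y" else "W"
        model = LinearModel({(pos, aa): 10.0}, 0.0, "classification", 1.0, lead)
        cfg = GibbsConfig(samples_per_distance=3, steps=20,
                          goal_distances=(1,), seed=0, alpha=1.0)
        cands = design_batch(lead, model, cfg)
        assert 1 <= len(cands) <= 3


class TestSelectLrScore:
    def test_top_n_by_score(self, lead):
        model = _positive_cdr_model(lead)
        pos = sorted(lead.cdr_mask)[0]
        seqs = [lead.sequence]
        for aa in "ARND":
            if aa != lead.sequence[pos - 1]:
                seqs.append(lead.sequence[: pos - 1] + aa + lead.sequence[pos:])
        out = select_lr_score(seqs, model, lead, n=2)
        assert len(out) == 2
        assert out[0].model_score >= out[1].model_score

    def test_n_one_is_argmax(self, lead):
        model = _positive_cdr_model(lead)
        pos = sorted(lead.cdr_mask)[0]
        best_aa = max(
            (aa for aa in "ARNDE" if aa != lead.sequence[pos - 1]),
            key=lambda aa: model.weights.get((pos, aa), 0.0),
        )
        seqs = [lead.sequence,
                lead.sequence[: pos - 1] + best_aa + lead.sequence[pos:]]
        out = select_lr_score(seqs, model, lead, n=1)
        assert out[0].sequence == seqs[1]

    def test_empty_pool(self, lead):
        assert select_lr_score([], _zero_model(lead), lead) == []


def test_write_designs_files(tmp_path, lead):
    cands = [DesignCandidate(lead.sequence, 1.0, 0, "LR_gibbs", 3)]
    write_designs(cands, lead, tmp_path / "d.fasta", tmp_path / "d.tsv")
    fasta = (tmp_path / "d.fasta").read_text()
    assert fasta.startswith(">LR_gibbs_d3_r1\n")
    assert lead.sequence in fasta


def test_zero_model_step_chi_square_uniform(lead):
    """Sampling from a zero model is uniform over the legal option set."""
    cfg = GibbsConfig(seed=0)
    model = _zero_model(lead)
    moves, probs, _ = proposal_distribution(lead.sequence, model, 1.0, lead, cfg, 5)
    rng = np.random.default_rng(123)
    n = 10_000
    draws = rng.choice(len(moves), size=n, p=probs)
    observed = np.bincount(draws, minlength=len(moves))
    chi2, p = stats.chisquare(observed)
    assert p > 0.01
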