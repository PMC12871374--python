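"""Diversity-restricted, temperature-annealed Gibbs design of multi-mutants.

A sampling trajectory starts at the lead (WT). At each step every single-
residue change at a CDR position is scored by the landscape model; moves
that would push the Hamming distance to WT beyond the trajectory's goal
distance are masked out, the remaining regularized scores pass through a
temperature-scaled softmax, and one move is drawn. Annealing the temperature
(hot to cold) lets trajectories explore before settling into high-scoring
multi-mutants at a controlled distance from the lead. A batch samples many
trajectories at several goal distances and keeps the top scorers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import substitutions_of
from .models import LinearModel, score
from .readproc import AA_ALPHABET, LeadSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GibbsConfig:
    """Sampler schedule and constraints.

    ``steps`` moves per trajectory (default 100), annealed over
    ``temperatures`` distributed evenly across the steps (any remainder
    widens the earliest blocks). ``goal_distances`` are the target Hamming
    distances from WT; ``samples_per_distance`` trajectories are drawn per
    goal. ``alpha`` is an optional linear Hamming-distance penalty inside
    the softmax (0 = hard distance cap only). ``cdr_mask`` overrides the
    lead's CDR positions when given.
    """

    steps: int = 100
    temperatures: tuple = (5.0, 1.0, 0.5)
    goal_distances: tuple = (3, 5, 7)
    samples_per_distance: int = 100
    alpha: float = 0.0
    seed: int = 0
    cdr_mask: frozenset | None = None

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if not self.temperatures or any(t <= 0 for t in self.temperatures):
            raise ValueError("temperatures must be positive and non-empty")
        if any(d < 1 for d in self.goal_distances):
            raise ValueError("goal distances must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class DesignCandidate:
    """One designed (or selected) sequence with its provenance."""

    sequence: str
    model_score: float
    hamming_to_wt: int
    method: str  # LR_gibbs | LR_score | FACS2_count
    goal_distance: int | None = None
    trajectory_seed: tuple | None = None

    def substitutions(self, lead: LeadSpec) -> list:
        return substitutions_of(self.sequence, lead)


def _cdr_positions(lead: LeadSpec, cfg: GibbsConfig) -> list:
    mask = cfg.cdr_mask if cfg.cdr_mask is not None else lead.cdr_mask
    if not mask:
        raise ValueError("design requires a non-empty CDR mask")
    return sorted(mask)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def proposal_distribution(
    state: str, model, T: float, lead: LeadSpec, cfg: GibbsConfig, d_goal: int
):
    """All legal single-residue moves at CDR positions and their sampling
    probabilities.

    Returns (moves, probs, scores): ``moves`` are (position, new_residue)
    pairs — reversions toward the lead included — plus ``None`` for keeping
    the current state (true Gibbs resampling of a site may retain its
    residue; without it a trajectory sitting on the score optimum would be
    forced off it at every step). Moves that would leave the sequence
    farther than ``d_goal`` from WT get probability zero (they are never
    proposed); the remaining options are weighted by
    softmax((score − alpha·hamming) / T). Probabilities sum to 1.
    """
    positions = _cdr_positions(lead, cfg)
    h = _hamming(state, lead.sequence)
    moves, new_h = [None], [h]
    for pos in positions:
        cur = state[pos - 1]
        wt = lead.sequence[pos - 1]
        for aa in AA_ALPHABET:
            if aa == cur:
                continue
            nh = h - (cur != wt) + (aa != wt)
            if nh > d_goal:
                continue
            moves.append((pos, aa))
            new_h.append(nh)
    if len(moves) < 2:
        raise RuntimeError("no legal move (reversions should always be legal)")

    if isinstance(model, LinearModel):
        base = float(model.score_sequences([state])[0])
        scores = np.empty(len(moves))
        scores[0] = base
        for i, (pos, aa) in enumerate(moves[1:], start=1):
            cur, wt = state[pos - 1], lead.sequence[pos - 1]
            s = base
            if cur != wt:
                s -= model.weights.get((pos, cur), 0.0)
            if aa != wt:
                s += model.weights.get((pos, aa), 0.0)
            scores[i] = s
    else:
        seqs = [state] + [state[: p - 1] + aa + state[p:] for p, aa in moves[1:]]
        scores = np.asarray(score(model, seqs), dtype=float)

    energy = (scores - cfg.alpha * np.asarray(new_h, dtype=float)) / T
    energy -= energy.max()
    w = np.exp(energy)
    probs = w / w.sum()
    return moves, probs, scores


def gibbs_step(
    state: str, model, T: float, lead: LeadSpec, cfg: GibbsConfig,
    d_goal: int, rng: np.random.Generator,
) -> str:
    """Sample one option from the proposal distribution and apply it."""
    moves, probs, _ = proposal_distribution(state, model, T, lead, cfg, d_goal)
    idx = rng.choice(len(moves), p=probs)
    if moves[idx] is None:
        return state
    pos, aa = moves[idx]
    return state[: pos - 1] + aa + state[pos:]


def temperature_schedule(steps: int, temperatures) -> list:
    """Per-step temperatures: the series spread evenly over the steps,
    earlier blocks absorbing any remainder."""
    blocks = np.array_split(np.arange(steps), len(temperatures))
    out = [0.0] * steps
    for T, block in zip(temperatures, blocks):
        for i in block:
            out[i] = float(T)
    return out


def run_trajectory(
    lead: LeadSpec, model, d_goal: int, cfg: GibbsConfig, seed,
) -> DesignCandidate:
    """One annealed trajectory from WT; fully reproducible from the seed."""
    rng = np.random.default_rng(seed)
    state = lead.sequence
    for T in temperature_schedule(cfg.steps, cfg.temperatures):
        state = gibbs_step(state, model, T, lead, cfg, d_goal, rng)
    return DesignCandidate(
        sequence=state,
        model_score=float(score(model, [state])[0]),
        hamming_to_wt=_hamming(state, lead.sequence),
        method="LR_gibbs",
        goal_distance=d_goal,
        trajectory_seed=tuple(seed) if isinstance(seed, (list, tuple)) else (seed,),
    )


def _top_n(cands: list, n: int) -> list:
    """Deduplicate (keep first) then take the n best by
    (score desc, fewer substitutions, lexicographic)."""
    seen, unique = set(), []
    for c in cands:
        if c.sequence not in seen:
            seen.add(c.sequence)
            unique.append(c)
    unique.sort(key=lambda c: (-c.model_score, c.hamming_to_wt, c.sequence))
    return unique[:n]


def design_batch(lead: LeadSpec, model, cfg: GibbsConfig, n: int = 30) -> list:
    """Full design protocol: ``samples_per_distance`` trajectories per goal
    distance, top ``n`` per distance by model score, then the pooled top
    ``n`` as the final design set.

    Per-trajectory RNG streams derive from (master seed, goal distance,
    trajectory index), so the batch is reproducible and order-independent.
    """
    per_distance = []
    for d in cfg.goal_distances:
        trajs = [
            run_trajectory(lead, model, d, cfg, np.random.SeedSequence(
                [cfg.seed, d, i]))
            for i in range(cfg.samples_per_distance)
        ]
        per_distance.extend(_top_n(trajs, n))
    final = _top_n(per_distance, n)
    if len(final) < n:
        logger.warning("only %d unique design candidates available", len(final))
    return final


def select_lr_score(
    sequences, model, lead: LeadSpec, n: int = 30,
    scorer=None, reference_score: float | None = None, direction: str = "le",
) -> list:
    """Top-n campaign sequences by model score, after an optional
    polyreactivity-style filter against the WT reference score."""
    sequences = list(dict.fromkeys(sequences))  # dedup, keep order
    if not sequences:
        logger.warning("empty sequence pool for LR_score selection")
        return []
    scores = score(model, sequences)
    cands = [
        DesignCandidate(
            sequence=s, model_score=float(sc),
            hamming_to_wt=_hamming(s, lead.sequence) if len(s) == len(lead)
            else abs(len(s) - len(lead)) + _hamming(s, lead.sequence),
            method="LR_score",
        )
        for s, sc in zip(sequences, scores)
    ]
    if scorer is not None:
        if reference_score is None:
            reference_score = float(scorer(lead.sequence))
        from .ranking import filter_by_scorer

        cands = filter_by_scorer(cands, scorer, reference_score, direction)
    out = _top_n(cands, n)
    if len(out) < n:
        logger.warning("LR_score pool smaller than %d after filtering", n)
    return out


def write_designs(cands: list, lead: LeadSpec, fasta_path, tsv_path) -> None:
    """FASTA (ids encode method/distance/rank) + TSV with substitutions in
    WT-pos-MUT notation."""
    rows = []
    with open(fasta_path, "w") as fh:
        for rank, c in enumerate(cands, start=1):
            d = c.goal_distance if c.goal_distance is not None else "na"
            fh.write(f">{c.method}_d{d}_r{rank}\n{c.sequence}\n")
            subs = ";".join(f"{wt}{pos}{mut}"
                            for wt, pos, mut in substitutions_of(
                                c.sequence, lead))
            rows.append({
                "rank": rank, "method": c.method, "sequence": c.sequence,
                "model_score": c.model_score, "hamming": c.hamming_to_wt,
                "substitutions": subs,
            })
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
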