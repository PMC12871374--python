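"""Synthetic affinity-maturation campaign simulator with planted ground truth.

Emulates the data-generating process behind a sort-seq campaign: a lead
nanobody diversified by error-prone mutagenesis (Poisson-distributed
substitution counts, log-normal expression bias in copy numbers), a
permissive magnetic sort followed by increasingly stringent FACS gates
(each copy survives with probability sigmoid(fitness − stringency)), and
finite-depth sequencing with a per-residue error rate. True per-variant
fitness is additive over planted substitution effects (optional pairwise
epistasis terms), with the lead fixed at 0, so enrichment recovery, singles
ranking and design quality can all be scored against known truth.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .readproc import AA_ALPHABET, LeadSpec, RoundCounts

# A synthetic VHH-like lead (120 aa) with framework/CDR layout typical of a
# camelid single-domain antibody. CDR1 = 26-35, CDR2 = 50-59, CDR3 = 99-110.
DEMO_LEAD_SEQUENCE = (
    "QVQLVESGGGLVQAGGSLRLSCAASGRTFSSYAMGWFRQAPGKEREFVA"
    "AISWSGGSTYYADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYCAA"
    "DRSTVYSSDYDYWGQGTQVTVS"
)
DEMO_CDR_MASK = frozenset(range(26, 36)) | frozenset(range(50, 60)) | frozenset(
    range(99, 111)
)


def demo_lead() -> LeadSpec:
    """The synthetic demo lead used by the simulator defaults and examples."""
    return LeadSpec(DEMO_LEAD_SEQUENCE, DEMO_CDR_MASK)


# Planted landscape: six beneficial CDR substitutions and six deleterious
# (proline) substitutions; every other substitution is neutral. Effect ±4
# on the sigmoid survival scale is a strong additive landscape: at the
# first FACS gate a beneficial substitution moves WT survival from ~2% to
# ~50%.
DEFAULT_BENEFICIAL = {
    (27, "Y"): 4.0, (31, "R"): 4.0, (52, "K"): 4.0,
    (57, "W"): 4.0, (101, "F"): 4.0, (105, "H"): 4.0,
}
DEFAULT_DELETERIOUS = {
    (10, "P"): -4.0, (29, "P"): -4.0, (45, "P"): -4.0,
    (70, "P"): -4.0, (90, "P"): -4.0, (103, "P"): -4.0,
}


@dataclass
class CampaignSimConfig:
    """Mutagenesis, selection and sequencing parameters for one campaign.

    Defaults model a mid-sized yeast-display campaign under strong
    selection: a 5x10^4-variant error-prone library averaging 2
    substitutions per variant, one permissive magnetic round (stringency 0:
    WT copies survive with probability 0.5) then two FACS gates of
    increasing stringency (4 and 6 on the sigmoid survival scale: WT
    survival ~1.8% and ~0.25%, typical of gates keeping the top percent or
    two), 2x10^5 reads per round and a 10^-3 per-residue sequencing error
    rate. Under these defaults the sort-seq pathologies of real campaigns
    emerge: inter-round overlap of unique sequences below 0.3 and a
    strongly bimodal log-enrichment distribution.
    """

    lead: LeadSpec = field(default_factory=demo_lead)
    effects: dict = field(
        default_factory=lambda: {**DEFAULT_BENEFICIAL, **DEFAULT_DELETERIOUS}
    )
    epistasis: dict = field(default_factory=dict)  # ((pos,aa),(pos,aa)) -> effect
    mutation_rate: float = 2.0
    library_size: int = 50_000
    expression_sigma: float = 0.5
    copies_per_variant: int = 20
    stringencies: dict = field(
        default_factory=lambda: {"MACS": 0.0, "FACS1": 4.0, "FACS2": 6.0}
    )
    depth: int = 200_000
    error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        L = len(self.lead)
        for pos, aa in self.effects:
            if not 1 <= pos <= L:
                raise ValueError(f"planted position {pos} outside lead")
            if self.lead.sequence[pos - 1] == aa:
                raise ValueError(f"planted effect ({pos},{aa}) is the WT residue")
        if self.mutation_rate < 0 or self.error_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.depth < 1 or self.library_size < 1:
            raise ValueError("depth and library_size must be >= 1")


@dataclass
class SimTruth:
    """Planted fitness landscape; the ground truth for recovery tests."""

    lead: LeadSpec
    effects: dict
    epistasis: dict = field(default_factory=dict)

    def fitness(self, seq: str) -> float:
        """Additive planted fitness; the lead scores 0 by convention.
        Substitutions without a planted effect are neutral; gaps and
        length changes contribute nothing."""
        f = 0.0
        present = set()
        for i, (wt, aa) in enumerate(zip(self.lead.sequence, seq), start=1):
            if aa != wt:
                present.add((i, aa))
                f += self.effects.get((i, aa), 0.0)
        for (a, b), eff in self.epistasis.items():
            if a in present and b in present:
                f += eff
        return f

    @property
    def beneficial(self) -> set:
        return {k for k, v in self.effects.items() if v > 0}

    def to_json(self) -> str:
        return json.dumps(
            {
                "lead": self.lead.sequence,
                "cdr_mask": sorted(self.lead.cdr_mask),
                "effects": {f"{p}:{a}": v for (p, a), v in sorted(self.effects.items())},
                "epistasis": {
                    f"{pa}:{aa}|{pb}:{ab}": v
                    for ((pa, aa), (pb, ab)), v in sorted(self.epistasis.items())
                },
            },
            indent=2, sort_keys=True,
        )


def mutagenize(cfg: CampaignSimConfig, rng: np.random.Generator) -> dict:
    """Error-prone library: sequence -> copy number.

    Per variant, k ~ Poisson(mutation_rate) distinct positions are chosen
    uniformly and mutated to a uniform non-WT residue; copy numbers carry a
    log-normal expression bias. Identical variants are merged.
    """
    lead = cfg.lead.sequence
    L = len(lead)
    ks = rng.poisson(cfg.mutation_rate, size=cfg.library_size)
    copies = np.maximum(
        1,
        np.round(
            cfg.copies_per_variant
            * rng.lognormal(0.0, cfg.expression_sigma, size=cfg.library_size)
        ).astype(int),
    )
    library: dict = {}
    for k, cp in zip(ks, copies):
        if k == 0:
            seq = lead
        else:
            k = min(k, L)
            positions = rng.choice(L, size=k, replace=False)
            chars = list(lead)
            for p in positions:
                choices = [aa for aa in AA_ALPHABET if aa != lead[p]]
                chars[p] = choices[rng.integers(len(choices))]
            seq = "".join(chars)
        library[seq] = library.get(seq, 0) + int(cp)
    return library


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def select_round(
    pool: dict, truth: SimTruth, stringency: float, rng: np.random.Generator
) -> dict:
    """Affinity-dependent selection: each copy survives independently with
    probability sigmoid(fitness − stringency)."""
    if not pool:
        raise ValueError("empty pool")
    seqs = list(pool)
    copies = np.array([pool[s] for s in seqs])
    fit = np.array([truth.fitness(s) for s in seqs])
    surv = rng.binomial(copies, _sigmoid(fit - stringency))
    out = {s: int(c) for s, c in zip(seqs, surv) if c > 0}
    if not out:
        raise ValueError(
            f"selection at stringency {stringency} extinguished the pool; "
            "lower the stringency or increase the pool"
        )
    return out


def sequence_pool(
    pool: dict, depth: int, error_rate: float, rng: np.random.Generator,
    round_id: str = "round",
) -> RoundCounts:
    """Finite-depth sequencing: ``depth`` reads drawn multinomially by copy
    number, each read corrupted per residue with ``error_rate``."""
    if not pool:
        raise ValueError("empty pool")
    seqs = list(pool)
    copies = np.array([pool[s] for s in seqs], dtype=float)
    reads = rng.multinomial(depth, copies / copies.sum())
    counts: Counter = Counter()
    L = len(seqs[0])
    for seq, n in zip(seqs, reads):
        if n == 0:
            continue
        if error_rate > 0:
            n_err_per_read = rng.binomial(L, error_rate, size=n)
            n_clean = int((n_err_per_read == 0).sum())
        else:
            n_clean = int(n)
            n_err_per_read = np.zeros(0, dtype=int)
        if n_clean:
            counts[seq] += n_clean
        for k in n_err_per_read[n_err_per_read > 0]:
            positions = rng.choice(len(seq), size=int(k), replace=False)
            chars = list(seq)
            for p in positions:
                choices = [aa for aa in AA_ALPHABET if aa != chars[p]]
                chars[p] = choices[rng.integers(len(choices))]
            counts["".join(chars)] += 1
    return RoundCounts(round_id=round_id, counts=dict(counts))


def simulate_campaign(cfg: CampaignSimConfig) -> tuple[dict, SimTruth]:
    """Full campaign: mutagenize, then select + sequence each round in order.

    Selection rounds run sequentially on the surviving pool (MACS first,
    then the FACS gates in the order given); each round's post-selection
    pool is sequenced. Returns ({round_id: RoundCounts}, SimTruth).
    """
    truth = SimTruth(cfg.lead, dict(cfg.effects), dict(cfg.epistasis))
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(1 + 2 * len(cfg.stringencies))
    rng_mut = np.random.default_rng(children[0])
    pool = mutagenize(cfg, rng_mut)
    rounds: dict = {}
    for i, (round_id, s) in enumerate(cfg.stringencies.items()):
        rng_sel = np.random.default_rng(children[1 + 2 * i])
        rng_seq = np.random.default_rng(children[2 + 2 * i])
        pool = select_round(pool, truth, s, rng_sel)
        rounds[round_id] = sequence_pool(
            pool, cfg.depth, cfg.error_rate, rng_seq, round_id=round_id
        )
    return rounds, truth


def write_truth_json(truth: SimTruth, path) -> None:
    Path(path).write_text(truth.to_json() + "\n")
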