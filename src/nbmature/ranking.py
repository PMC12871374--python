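"""Single-substitution scoring, NDCG ranking evaluation, liability screens.

A trained landscape model induces a score change for every single
substitution of the lead; ranking those changes and comparing against a set
of experimentally validated substitutions (each weighted equally as a hit)
with NDCG measures how useful the model is for picking point mutations.
Candidate substitutions are additionally screened for sequence liabilities
(glycosylation sequons, isomerization motifs, introduced cysteines) and by a
pluggable polyreactivity scorer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import apply_substitutions, enumerate_singles
from .models import LinearModel, score
from .readproc import AA_ALPHABET, LeadSpec, RoundCounts

logger = logging.getLogger(__name__)


@dataclass
class SubstitutionScoreMatrix:
    """L x 19 table of model score changes for every single substitution."""

    delta: dict  # (position, mut_aa) -> score(single mutant) - score(lead)
    lead: LeadSpec
    provenance: str = ""

    def ranked(self) -> list:
        """Substitutions sorted by (Δscore desc, position asc, mutant
        alphabetical); each item is ((wt, pos, mut), delta)."""
        items = [
            ((self.lead.sequence[pos - 1], pos, mut), d)
            for (pos, mut), d in self.delta.items()
        ]
        items.sort(key=lambda it: (-it[1], it[0][1], it[0][2]))
        return items

    def to_heatmap_tsv(self, path) -> None:
        """Rows = lead positions (with WT residue), columns = 20 amino
        acids; the WT cell at each position is left empty."""
        rows = []
        for pos in range(1, len(self.lead) + 1):
            wt = self.lead.sequence[pos - 1]
            row = {"position": pos, "wt": wt}
            for aa in AA_ALPHABET:
                row[aa] = "" if aa == wt else self.delta.get((pos, aa), float("nan"))
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def score_all_singles(
    model, lead: LeadSpec, positions=None, provenance: str = ""
) -> SubstitutionScoreMatrix:
    """Δscore for every enumerated single substitution of the lead.

    Linear models short-circuit to their weights (the Δscore of a single
    substitution is exactly its weight); other scorers are evaluated on the
    explicit mutant sequences in one batch.
    """
    singles = enumerate_singles(lead, positions)
    if isinstance(model, LinearModel):
        delta = {(pos, mut): model.weights.get((pos, mut), 0.0)
                 for _, pos, mut in singles}
    else:
        seqs = [apply_substitutions(lead, [s]) for s in singles]
        scores = score(model, seqs)
        lead_score = float(score(model, [lead.sequence])[0])
        delta = {
            (pos, mut): float(sc) - lead_score
            for (_, pos, mut), sc in zip(singles, scores)
        }
    return SubstitutionScoreMatrix(delta=delta, lead=lead, provenance=provenance)


def ndcg(ranked_gains, k: int | None = None, discount: str = "standard") -> float:
    """Normalized discounted cumulative gain of a binary gain sequence.

    ``ranked_gains[i]`` is the gain (0/1) of the item at rank i+1 under the
    model's ordering. DCG = Σ_{rank ≤ k} gain / discount(rank) with the
    standard discount log2(rank+1); IDCG is the same sum with all hits
    ranked first; NDCG = DCG/IDCG ∈ [0, 1]. ``discount="paper"`` uses
    log2(rank) from rank 2 on with the rank-1 discount clamped to 1.
    """
    gains = [int(g) for g in ranked_gains]
    if any(g not in (0, 1) for g in gains):
        raise ValueError("gains must be binary")
    if sum(gains) == 0:
        raise ValueError("IDCG undefined: no item has gain 1")

    if discount == "standard":
        disc = lambda rank: math.log2(rank + 1)
    elif discount == "paper":
        disc = lambda rank: 1.0 if rank == 1 else math.log2(rank)
    else:
        raise ValueError(f"unknown discount {discount!r}")

    kk = len(gains) if k is None else min(k, len(gains))
    dcg = sum(g / disc(r) for r, g in enumerate(gains[:kk], start=1))
    ideal = sorted(gains, reverse=True)
    idcg = sum(g / disc(r) for r, g in enumerate(ideal[:kk], start=1))
    if idcg == 0.0:
        raise ValueError("IDCG undefined: no hit within the cutoff")
    return dcg / idcg


def ndcg_of_matrix(
    matrix: SubstitutionScoreMatrix, validated, k: int | None = None,
    discount: str = "standard",
) -> float:
    """NDCG of the matrix's ranking against a validated substitution set.

    ``validated`` contains (position, mut_aa) pairs or "N27Y"-style strings;
    each validated substitution gets gain 1, all others gain 0.
    """
    val = {parse_substitution(v) if isinstance(v, str) else tuple(v)
           for v in validated}
    gains = [1 if (pos, mut) in val else 0
             for (_, pos, mut), _ in matrix.ranked()]
    return ndcg(gains, k=k, discount=discount)


def parse_substitution(text: str) -> tuple:
    """'N27Y' -> (27, 'Y'). The WT letter is informational only."""
    return (int(text[1:-1]), text[-1])


# ---------------------------------------------------------------------------
# Liability motifs


@dataclass(frozen=True)
class LiabilityHit:
    kind: str  # glycosylation_sequon | DG_isomerization | NG_isomerization | introduced_cysteine
    position: int  # 1-based position of the motif start


@dataclass
class LiabilityReport:
    sequence: str
    hits: list = field(default_factory=list)

    def kinds(self) -> set:
        return {h.kind for h in self.hits}


def scan_liabilities(
    seq: str, lead: LeadSpec | None = None, exclude_proline: bool = True
) -> LiabilityReport:
    """Scan a protein for common developability liabilities.

    Reports every N-x-S/T glycosylation sequon (x ≠ P by default, the
    standard sequon rule), every DG and NG isomerization dipeptide, and —
    when a lead is given — every cysteine at a position where the lead has
    none (unpaired cysteines raise polyreactivity risk). Scan order is
    left-to-right, so output is deterministic.
    """
    hits = []
    for i in range(len(seq) - 2):
        if (seq[i] == "N" and seq[i + 2] in "ST"
                and not (exclude_proline and seq[i + 1] == "P")):
            hits.append(LiabilityHit("glycosylation_sequon", i + 1))
    for i in range(len(seq) - 1):
        if seq[i] == "D" and seq[i + 1] == "G":
            hits.append(LiabilityHit("DG_isomerization", i + 1))
        elif seq[i] == "N" and seq[i + 1] == "G":
            hits.append(LiabilityHit("NG_isomerization", i + 1))
    if lead is not None:
        for i, aa in enumerate(seq):
            if aa == "C" and (i >= len(lead) or lead.sequence[i] != "C"):
                hits.append(LiabilityHit("introduced_cysteine", i + 1))
    hits.sort(key=lambda h: (h.position, h.kind))
    return LiabilityReport(sequence=seq, hits=hits)


def naive_polyreactivity_scorer(lead: LeadSpec):
    """Synthetic stand-in polyreactivity scorer (higher = worse).

    Counts cysteines introduced relative to the lead plus length-3 windows
    of consecutive strongly hydrophobic residues (surface-patch proxy).
    This is a placeholder with the same call signature as a trained
    polyreactivity model; plug a real scorer into ``filter_by_scorer`` for
    production use.
    """
    hydrophobic = set("FILVWM")

    def scorer(seq: str) -> float:
        intro_cys = sum(
            1 for i, aa in enumerate(seq)
            if aa == "C" and (i >= len(lead) or lead.sequence[i] != "C")
        )
        patches = sum(
            1 for i in range(len(seq) - 2)
            if all(c in hydrophobic for c in seq[i : i + 3])
        )
        return float(intro_cys * 10 + patches)

    return scorer


def filter_by_scorer(
    candidates, scorer, reference_score: float, direction: str = "le"
):
    """Keep candidates whose scorer value passes the WT reference.

    ``direction="le"`` keeps scores ≤ reference (scorer is a liability:
    lower is better); ``"ge"`` keeps scores ≥ reference. Candidates on
    which the scorer fails are dropped with a warning. Order is preserved.
    """
    if direction not in ("le", "ge"):
        raise ValueError("direction must be 'le' or 'ge'")
    kept = []
    for cand in candidates:
        seq = cand.sequence if hasattr(cand, "sequence") else cand
        try:
            s = float(scorer(seq))
        except Exception as exc:  # scorer failure drops the candidate
            logger.warning("scorer failed on %r: %s", seq, exc)
            continue
        if (direction == "le" and s <= reference_score) or (
            direction == "ge" and s >= reference_score
        ):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Count-based candidate selection


def _hamming_padded(a: str, b: str) -> int:
    d = sum(x != y for x, y in zip(a, b))
    return d + abs(len(a) - len(b))


def top_by_count_clustered(
    facs_counts: RoundCounts, radius: int = 2, n: int = 30
) -> list:
    """Top-count cluster leaders: greedy leader clustering on Hamming
    distance.

    Sequences are visited by (count desc, sequence lexicographic); a
    sequence joins the first existing cluster whose leader is within
    ``radius``, otherwise it founds a new cluster. Returns up to ``n``
    leaders by count (all leaders if fewer clusters exist).
    """
    if not facs_counts.counts:
        raise ValueError("empty count table")
    ordered = sorted(facs_counts.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    leaders: list[str] = []
    for seq, _ in ordered:
        if not any(_hamming_padded(seq, ld) <= radius for ld in leaders):
            leaders.append(seq)
    return leaders[:n]


def write_ranking_tsv(
    matrix: SubstitutionScoreMatrix, path, lead: LeadSpec | None = None,
    validated=None,
) -> None:
    """Ranked substitution list with Δscore and liability flags."""
    lead = lead or matrix.lead
    val = {parse_substitution(v) if isinstance(v, str) else tuple(v)
           for v in (validated or [])}
    base = scan_liabilities(lead.sequence, lead).kinds()
    rows = []
    for rank, ((wt, pos, mut), d) in enumerate(matrix.ranked(), start=1):
        mutant = apply_substitutions(lead, [(wt, pos, mut)])
        rep = scan_liabilities(mutant, lead)
        new = sorted(rep.kinds() - base)
        rows.append({
            "rank": rank,
            "substitution": f"{wt}{pos}{mut}",
            "delta_score": d,
            "validated": int((pos, mut) in val),
            "new_liabilities": ";".join(new),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
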