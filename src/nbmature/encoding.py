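"""Lead-anchored alignment and one-hot encoding of nanobody variants.

Every variant is mapped onto the lead's coordinate system (positions
1..L of the starting nanobody). Because error-prone PCR libraries carry
essentially no real indels, a variant of the same length maps by identity;
length-changed variants (sequencing artefacts) are globally aligned to the
lead, insertion columns relative to the lead are discarded and unmatched
lead positions become gaps. Sequences are then one-hot encoded over a
21-letter alphabet (20 amino acids + gap). For linear models the lead's own
residue column at each site is dropped (``wt_dropped``), so every feature
represents a single substitution away from WT and the lead encodes to the
zero vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from Bio import Align

from .readproc import AA_ALPHABET, GAP, LeadSpec

ALPHABET21 = AA_ALPHABET + GAP  # gap sorts last


@dataclass
class EncodedDataset:
    """Binary feature matrix over (position, residue) columns.

    ``mode`` is ``"full21"`` (21 columns per site; rows sum to L) or
    ``"wt_dropped"`` (the lead's residue column removed at each site, 20
    columns per site; the lead encodes to all zeros).
    """

    X: sp.csr_matrix
    mode: str
    column_index: dict  # (1-based position, residue) -> column
    lead: LeadSpec
    sequences: list

    @property
    def columns(self) -> list:
        return sorted(self.column_index, key=self.column_index.get)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = 0
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def align_to_lead(seq: str, lead: LeadSpec, max_deletion: int = 10) -> str:
    """Map a variant onto lead coordinates; returns a length-L string.

    Length-L sequences map by identity. Otherwise the variant is globally
    aligned to the lead (match +1, mismatch 0, gaps −2, end gaps penalized);
    columns that are insertions relative to the lead are dropped and lead
    positions with no aligned residue become the gap symbol.
    """
    L = len(lead)
    bad = set(seq) - set(ALPHABET21)
    if bad:
        raise ValueError(f"non-canonical residues {sorted(bad)} in {seq!r}")
    if len(seq) == L:
        return seq
    aln = _aligner().align(lead.sequence, seq)[0]
    out = [GAP] * L
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for k in range(te - ts):
            out[ts + k] = seq[qs + k]
    n_gaps = out.count(GAP)
    if n_gaps > max_deletion:
        raise ValueError(
            f"alignment leaves {n_gaps} gaps (> {max_deletion}); "
            "sequence should have been filtered upstream"
        )
    return "".join(out)


def build_column_index(lead: LeadSpec, mode: str) -> dict:
    """Deterministic (position, residue) -> column map.

    Position-major; residues in fixed alphabetical order with the gap
    symbol last. In ``wt_dropped`` mode the lead's own residue at each
    position has no column.
    """
    if mode not in ("full21", "wt_dropped"):
        raise ValueError(f"unknown encoding mode {mode!r}")
    index = {}
    col = 0
    for pos in range(1, len(lead) + 1):
        wt = lead.sequence[pos - 1]
        for res in ALPHABET21:
            if mode == "wt_dropped" and res == wt:
                continue
            index[(pos, res)] = col
            col += 1
    return index


def one_hot(
    aligned: list[str], mode: str, lead: LeadSpec
) -> EncodedDataset:
    """One-hot encode aligned (length-L) sequences; sparse CSR output."""
    L = len(lead)
    index = build_column_index(lead, mode)
    indptr = [0]
    indices = []
    for i, seq in enumerate(aligned):
        if len(seq) != L:
            raise ValueError(f"sequence {i} has length {len(seq)}, expected {L}")
        for pos, res in enumerate(seq, start=1):
            key = (pos, res)
            if key not in index:
                if res not in ALPHABET21:
                    raise ValueError(
                        f"unknown symbol {res!r} at position {pos} in {seq!r}"
                    )
                continue  # wt residue in wt_dropped mode
            indices.append(index[key])
        indptr.append(len(indices))
    X = sp.csr_matrix(
        (np.ones(len(indices), dtype=np.float64), indices, indptr),
        shape=(len(aligned), len(index)),
    )
    return EncodedDataset(X=X, mode=mode, column_index=index, lead=lead,
                          sequences=list(aligned))


def decode(enc: EncodedDataset) -> list[str]:
    """Invert one_hot: recover the aligned sequences from the matrix."""
    L = len(enc.lead)
    rev = {v: k for k, v in enc.column_index.items()}
    out = []
    for i in range(enc.X.shape[0]):
        chars = list(enc.lead.sequence) if enc.mode == "wt_dropped" else [None] * L
        row = enc.X.indices[enc.X.indptr[i] : enc.X.indptr[i + 1]]
        for col in row:
            pos, res = rev[col]
            chars[pos - 1] = res
        if any(c is None for c in chars):
            raise ValueError(f"row {i} does not cover every position")
        out.append("".join(chars))
    return out


def to_tensor(aligned: list[str], lead: LeadSpec) -> np.ndarray:
    """Dense N x L x 21 one-hot tensor (full21), for the neural models."""
    L = len(lead)
    lut = {c: i for i, c in enumerate(ALPHABET21)}
    T = np.zeros((len(aligned), L, len(ALPHABET21)), dtype=np.float32)
    for n, seq in enumerate(aligned):
        if len(seq) != L:
            raise ValueError(f"sequence {n} has length {len(seq)}, expected {L}")
        for pos, res in enumerate(seq):
            T[n, pos, lut[res]] = 1.0
    return T


def enumerate_singles(lead: LeadSpec, positions=None) -> list[tuple]:
    """All single substitutions (wt_aa, position, mut_aa) of the lead.

    19 substitutions per position (gap excluded); deterministic order:
    position ascending, mutant residue alphabetical.
    """
    if positions is None:
        positions = range(1, len(lead) + 1)
    out = []
    for pos in sorted(positions):
        wt = lead.sequence[pos - 1]
        for mut in AA_ALPHABET:
            if mut != wt:
                out.append((wt, pos, mut))
    return out


def apply_substitutions(lead: LeadSpec, subs) -> str:
    """Apply (wt, pos, mut) substitutions to the lead sequence."""
    chars = list(lead.sequence)
    for wt, pos, mut in subs:
        if chars[pos - 1] != wt and lead.sequence[pos - 1] == wt:
            raise ValueError(f"conflicting substitutions at position {pos}")
        chars[pos - 1] = mut
    return "".join(chars)


def substitutions_of(seq: str, lead: LeadSpec) -> list[tuple]:
    """List (wt, pos, mut) differences of an aligned sequence vs the lead."""
    return [
        (wt, i, aa)
        for i, (wt, aa) in enumerate(zip(lead.sequence, seq), start=1)
        if aa != wt
    ]
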