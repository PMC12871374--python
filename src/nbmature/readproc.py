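"""Turn merged amplicon reads into per-round protein count tables.

The sort-seq pipeline sequences the yeast pool after every selection round.
This module translates merged nucleotide reads, keeps only reads that are
comparable to the campaign's lead nanobody (anchor match at both ends, no
major deletion), and collapses identical protein sequences to counts.
Paired-end joining and base-quality trimming are assumed done upstream.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass(frozen=True)
class LeadSpec:
    """The campaign's starting (WT) nanobody and its CDR positions.

    Parameters
    ----------
    sequence
        Amino-acid sequence of the lead; uppercase, canonical alphabet.
    cdr_mask
        1-based positions belonging to the CDR loops. Design moves and
        CDR-restricted substitution scans are limited to these positions.
    anchor_len
        Length of the prefix/suffix anchors used to recognise lead-derived
        reads (default 9 residues).
    """

    sequence: str
    cdr_mask: frozenset = frozenset()
    anchor_len: int = 9

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("lead sequence must be non-empty")
        bad = set(self.sequence) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"non-canonical residues in lead: {sorted(bad)}")
        if not isinstance(self.cdr_mask, frozenset):
            object.__setattr__(self, "cdr_mask", frozenset(self.cdr_mask))
        L = len(self.sequence)
        if any(p < 1 or p > L for p in self.cdr_mask):
            raise ValueError("cdr_mask positions must lie within the lead")
        if not 1 <= self.anchor_len <= L:
            raise ValueError("anchor_len must be within the lead length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def prefix_anchor(self) -> str:
        return self.sequence[: self.anchor_len]

    @property
    def suffix_anchor(self) -> str:
        return self.sequence[-self.anchor_len :]


@dataclass
class RoundCounts:
    """One selection round's map from protein sequence to read count."""

    round_id: str
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("all counts must be >= 1")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def translate_reads(nt_sequences: list[str], lead: LeadSpec) -> list[str]:
    """Translate merged reads in the frame that best matches the lead prefix.

    Each read is translated in the three forward frames; the frame whose
    translation has the fewest mismatches to the lead's prefix anchor is
    chosen (ties go to the lowest frame index). Reads whose chosen-frame
    translation contains an internal stop codon or an ambiguous residue
    (from an N base) are dropped. A single trailing stop is tolerated and
    stripped.
    """
    anchor = lead.prefix_anchor
    out: list[str] = []
    for nt in nt_sequences:
        nt = nt.upper()
        if len(nt) < 3:
            logger.warning("read shorter than one codon dropped: %r", nt)
            continue
        best = None
        best_mm = None
        for frame in range(3):
            sub = nt[frame : frame + 3 * ((len(nt) - frame) // 3)]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            mm = _hamming(aa[: len(anchor)], anchor) + max(0, len(anchor) - len(aa))
            if best_mm is None or mm < best_mm:
                best, best_mm = aa, mm
        if best is None:
            continue
        if best.endswith("*"):
            best = best[:-1]
        if "*" in best or "X" in best or not best:
            continue
        out.append(best)
    return out


def filter_lead_anchored(
    aa_sequences: list[str],
    lead: LeadSpec,
    max_mismatch: int = 3,
    max_deletion: int = 10,
) -> list[str]:
    """Keep sequences anchored to the lead at both ends, without major deletions.

    A sequence passes if its first and last ``lead.anchor_len`` residues each
    match the corresponding lead anchor with at most ``max_mismatch`` Hamming
    mismatches, and its length is at least ``len(lead) - max_deletion``.
    Input order is preserved.
    """
    pre, suf, k = lead.prefix_anchor, lead.suffix_anchor, lead.anchor_len
    min_len = len(lead) - max_deletion
    kept = []
    for seq in aa_sequences:
        if len(seq) < max(k, min_len):
            continue
        if _hamming(seq[:k], pre) > max_mismatch:
            continue
        if _hamming(seq[-k:], suf) > max_mismatch:
            continue
        kept.append(seq)
    return kept


def collapse_to_counts(aa_sequences: list[str], round_id: str) -> RoundCounts:
    """Merge identical protein strings into a count table."""
    return RoundCounts(round_id=round_id, counts=dict(Counter(aa_sequences)))


def filter_primers(
    nt_sequences: list[str], fwd_primer: str, rev_primer: str
) -> list[str]:
    """Optional exact-match nucleotide primer filter (and trim).

    Keeps reads that start with ``fwd_primer`` and end with ``rev_primer``,
    returning the insert between them.
    """
    fwd, rev = fwd_primer.upper(), rev_primer.upper()
    out = []
    for nt in nt_sequences:
        nt = nt.upper()
        if nt.startswith(fwd) and nt.endswith(rev):
            out.append(nt[len(fwd) : len(nt) - len(rev)])
    return out


# ---------------------------------------------------------------------------
# I/O


def read_sequences(path: str | Path) -> list[str]:
    """Read merged reads from FASTA/FASTQ, or protein strings from FASTA."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]


def read_lead_fasta(path: str | Path, cdr_mask=(), anchor_len: int = 9) -> LeadSpec:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ValueError(f"no sequence in {path}")
    return LeadSpec(str(recs[0].seq).upper(), frozenset(cdr_mask), anchor_len)


def read_counts_tsv(path: str | Path, round_id: str | None = None) -> RoundCounts:
    """Read a pre-collapsed (sequence, count) table. Header required."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"sequence", "count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'sequence' and 'count'")
    # technical replicates of the same protein are summed
    grouped = df.groupby("sequence", sort=True)["count"].sum()
    rid = round_id if round_id is not None else Path(path).stem
    return RoundCounts(round_id=rid, counts={s: int(c) for s, c in grouped.items()})


def write_counts_tsv(rc: RoundCounts, path: str | Path) -> None:
    items = sorted(rc.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(items, columns=["sequence", "count"])
    df.to_csv(path, sep="\t", index=False)


def process_reads(
    reads_path: str | Path,
    lead: LeadSpec,
    round_id: str,
    max_mismatch: int = 3,
    max_deletion: int = 10,
    is_protein: bool = False,
) -> tuple[RoundCounts, dict]:
    """Full read-processing pipeline: translate, anchor-filter, collapse.

    Returns the round's counts and a statistics dict (reads in/out at each
    filter) suitable for a JSON sidecar.
    """
    raw = read_sequences(reads_path)
    if is_protein:
        translated = [s.upper() for s in raw]
    else:
        translated = translate_reads(raw, lead)
    kept = filter_lead_anchored(translated, lead, max_mismatch, max_deletion)
    rc = collapse_to_counts(kept, round_id)
    stats = {
        "round_id": round_id,
        "reads_in": len(raw),
        "translated": len(translated),
        "anchor_filtered": len(kept),
        "unique_sequences": len(rc),
        "total_reads": rc.total_reads,
    }
    return rc, stats


def write_stats_json(stats: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
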