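"""Log-enrichment labels from FACS counts normalized by the MACS round.

Abundance after a stringent FACS sort is confounded by clone expression;
normalizing each sequence's FACS abundance by its abundance in the
permissive MACS round and taking the natural log gives the enrichment value
used as the regression target. Because round-to-round overlap of unique
sequences is low, a sequence absent (sub-threshold) from one round has its
abundance imputed to a small floor before taking the ratio, which makes the
label distribution strongly bimodal. The sign of the log ratio defines the
binary enriched/depleted label.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .readproc import RoundCounts


@dataclass(frozen=True)
class EnrichmentParams:
    """Count threshold and abundance floor for enrichment construction.

    ``count_threshold``: sequences with fewer reads in a round are treated
    as absent from that round (sequencing-noise filter; default 5).
    ``floor``: abundance imputed for a sequence absent from a round
    (default 1e-6). ``floor_mode`` selects what the floor replaces:
    ``"abundance"`` (default) floors the missing abundance before the ratio;
    ``"log_value"`` sets the log-enrichment itself to ±floor when a sequence
    is missing from one round (an alternative, literal reading of the
    imputation rule — see docs/methods.md).
    """

    count_threshold: int = 5
    floor: float = 1e-6
    floor_mode: str = "abundance"

    def __post_init__(self):
        if self.count_threshold < 1:
            raise ValueError("count_threshold must be >= 1")
        if not 0.0 < self.floor < 1.0:
            raise ValueError("floor must be in (0, 1)")
        if self.floor_mode not in ("abundance", "log_value"):
            raise ValueError("floor_mode must be 'abundance' or 'log_value'")


@dataclass
class EnrichmentDataset:
    """Per-sequence log-enrichment, binary label and round provenance."""

    df: pd.DataFrame  # columns: sequence, log_enrichment, label, in_macs, in_facs
    params: EnrichmentParams
    rounds: tuple  # (macs_id, facs_id)

    @property
    def sequences(self) -> list[str]:
        return self.df["sequence"].tolist()

    @property
    def e_values(self):
        return self.df["log_enrichment"].to_numpy()

    @property
    def labels(self):
        """Binary labels: 1 = enriched (e > 0), 0 = depleted."""
        return (self.df["label"] == "enriched").to_numpy().astype(int)

    def __len__(self) -> int:
        return len(self.df)


def apply_count_threshold(rc: RoundCounts, c: int) -> RoundCounts:
    """Remove sequences with count below ``c`` (boundary count is kept)."""
    kept = {s: n for s, n in rc.counts.items() if n >= c}
    return RoundCounts(round_id=rc.round_id, counts=kept)


def frequencies(rc: RoundCounts) -> dict:
    """Per-sequence abundance fractions over the (thresholded) round."""
    total = rc.total_reads
    if total == 0:
        raise ValueError(f"empty round after thresholding: {rc.round_id!r}")
    return {s: n / total for s, n in rc.counts.items()}


def log_enrichment(
    f_facs: float | None, f_macs: float | None, eps: float = 1e-6
) -> float:
    """Natural-log enrichment ratio with floor imputation for absent values.

    ``None`` marks a sequence absent (sub-threshold) in that round; its
    abundance is replaced by the floor ``eps``.
    """
    if f_facs is None and f_macs is None:
        raise ValueError("sequence absent from both rounds; filter upstream")
    num = eps if f_facs is None else f_facs
    den = eps if f_macs is None else f_macs
    return math.log(num / den)


def build_dataset(
    macs: RoundCounts, facs: RoundCounts, params: EnrichmentParams | None = None
) -> EnrichmentDataset:
    """Threshold both rounds, then label every surviving sequence.

    The sequence universe is the union of sequences at or above the count
    threshold in either round; sequences below threshold in both rounds are
    excluded. Records are sorted by sequence for reproducibility.
    """
    params = params or EnrichmentParams()
    m = apply_count_threshold(macs, params.count_threshold)
    f = apply_count_threshold(facs, params.count_threshold)
    universe = sorted(set(m.counts) | set(f.counts))
    if not universe:
        raise ValueError("no sequence survives the count threshold in any round")
    fm = frequencies(m) if len(m) else {}
    ff = frequencies(f) if len(f) else {}
    rows = []
    for s in universe:
        in_m, in_f = s in fm, s in ff
        if params.floor_mode == "log_value" and not (in_m and in_f):
            # literal imputation of the log value itself when a sequence is
            # missing from one round; sign follows which round is missing
            e = params.floor if not in_m else -params.floor
        else:
            e = log_enrichment(
                ff.get(s), fm.get(s), params.floor
            )
        label = "enriched" if e > 0 else "depleted"
        rows.append((s, e, label, in_m, in_f))
    df = pd.DataFrame(
        rows, columns=["sequence", "log_enrichment", "label", "in_macs", "in_facs"]
    )
    return EnrichmentDataset(df=df, params=params, rounds=(macs.round_id, facs.round_id))


def write_dataset_tsv(ds: EnrichmentDataset, path: str | Path) -> None:
    """TSV with a JSON header block echoing the parameters."""
    header = {
        "rounds": list(ds.rounds),
        "count_threshold": ds.params.count_threshold,
        "floor": ds.params.floor,
        "floor_mode": ds.params.floor_mode,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
        ds.df.to_csv(fh, sep="\t", index=False)


def read_dataset_tsv(path: str | Path) -> EnrichmentDataset:
    params = EnrichmentParams()
    rounds = ("MACS", "FACS")
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = json.loads(first[1:].strip())
            params = EnrichmentParams(
                meta["count_threshold"], meta["floor"], meta.get("floor_mode", "abundance")
            )
            rounds = tuple(meta["rounds"])
            df = pd.read_csv(fh, sep="\t")
        else:
            df = pd.read_csv(path, sep="\t")
    return EnrichmentDataset(df=df, params=params, rounds=rounds)
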