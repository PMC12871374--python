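"""Enrichment predictors and the retrospective evaluation metrics.

The workhorse models are L1-regularized logistic regression (binary
enriched/depleted label) and L1 linear regression (continuous log
enrichment), trained on WT-dropped one-hot features so each weight is the
score contribution of one substitution away from the lead. A 1-D CNN and an
embedding-MLP capture nonlinear effects; two Hamming-distance baselines
control for models merely memorizing which round a sequence came from.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from . import _nn
from .encoding import (
    ALPHABET21,
    EncodedDataset,
    align_to_lead,
    one_hot,
    to_tensor,
)
from .readproc import LeadSpec

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    The L1 strengths default to the per-model values used throughout:
    logistic 2 (scikit-learn inverse-regularization C), linear 0.0005
    (penalty weight on ‖w‖₁ added to the mean squared loss), and 1e-4 for
    both neural models (penalty weight added to the mean loss). The
    ``*_convention`` switches flip between the two parameterizations; see
    docs/methods.md for why the defaults differ per model.
    """

    lambda_logistic: float = 2.0
    lambda_linear: float = 5e-4
    lambda_cnn: float = 1e-4
    lambda_mlp: float = 1e-4
    epochs: int = 1000
    validation_fraction: float = 0.1
    patience: int = 20
    seed: int = 0
    logistic_convention: str = "inverse"  # "inverse" (sklearn C) | "mean"
    linear_convention: str = "mean"

    def __post_init__(self):
        for lam in (self.lambda_logistic, self.lambda_linear,
                    self.lambda_cnn, self.lambda_mlp):
            if lam <= 0:
                raise ValueError("all L1 strengths must be > 0")
        if not 0.0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5)")


@dataclass
class LinearModel:
    """Sparse additive sequence-function model in WT-dropped coordinates.

    ``weights[(position, residue)]`` is the score change of carrying that
    substitution; the lead scores exactly ``intercept``. Serializes to and
    reloads from JSON bit-exactly.
    """

    weights: dict  # (1-based position, residue) -> float
    intercept: float
    task: str  # "classification" | "regression"
    lam: float
    lead: LeadSpec
    mode: str = "wt_dropped"

    def score_sequences(self, sequences) -> np.ndarray:
        lead_seq = self.lead.sequence
        out = np.empty(len(sequences))
        for i, seq in enumerate(sequences):
            aligned = align_to_lead(seq, self.lead)
            s = self.intercept
            for pos, (wt, aa) in enumerate(zip(lead_seq, aligned), start=1):
                if aa != wt:
                    s += self.weights.get((pos, aa), 0.0)
            out[i] = s
        return out

    def n_nonzero(self) -> int:
        return sum(1 for w in self.weights.values() if w != 0.0)

    def to_json(self) -> str:
        payload = {
            "weights": {f"{p}:{r}": w for (p, r), w in sorted(self.weights.items())},
            "intercept": self.intercept,
            "task": self.task,
            "lambda": self.lam,
            "mode": self.mode,
            "lead": self.lead.sequence,
            "cdr_mask": sorted(self.lead.cdr_mask),
            "anchor_len": self.lead.anchor_len,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        weights = {}
        for key, w in d["weights"].items():
            pos, res = key.split(":")
            weights[(int(pos), res)] = w
        lead = LeadSpec(d["lead"], frozenset(d["cdr_mask"]), d["anchor_len"])
        return cls(weights, d["intercept"], d["task"], d["lambda"], lead, d["mode"])

    def save(self, path):
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "LinearModel":
        return cls.from_json(Path(path).read_text())


def _weights_from_coef(coef: np.ndarray, enc: EncodedDataset) -> dict:
    return {
        key: float(coef[col])
        for key, col in enc.column_index.items()
        if coef[col] != 0.0
    }


def train_logistic_l1(enc: EncodedDataset, y, cfg: TrainConfig) -> LinearModel:
    """L1 logistic regression on WT-dropped features.

    Under the default ``inverse`` convention the strength is scikit-learn's
    C (objective ‖w‖₁ + C·Σ log-loss); under ``mean`` the objective is the
    mean log-loss + λ‖w‖₁ (duplication-invariant).
    """
    if enc.mode != "wt_dropped":
        raise ValueError("linear models require wt_dropped encoding")
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present to train a classifier")
    n = enc.X.shape[0]
    if cfg.logistic_convention == "inverse":
        C = cfg.lambda_logistic
    else:
        C = 1.0 / (n * cfg.lambda_logistic)
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=1e-6, max_iter=10_000,
        random_state=0,
    )
    clf.fit(enc.X, y)
    if clf.n_iter_[0] >= 10_000:
        raise RuntimeError(
            f"logistic solver did not converge (n={n}, C={C}, tol=1e-6)"
        )
    return LinearModel(
        weights=_weights_from_coef(clf.coef_[0], enc),
        intercept=float(clf.intercept_[0]),
        task="classification",
        lam=cfg.lambda_logistic,
        lead=enc.lead,
    )


def train_linear_l1(enc: EncodedDataset, e, cfg: TrainConfig) -> LinearModel:
    """L1 (lasso) linear regression on the continuous log-enrichment value.

    Default objective: mean squared loss + λ‖w‖₁ (λ = ``lambda_linear``),
    mapped onto scikit-learn's Lasso parameterization exactly (α = λ/2).
    """
    if enc.mode != "wt_dropped":
        raise ValueError("linear models require wt_dropped encoding")
    e = np.asarray(e, dtype=float)
    n = enc.X.shape[0]
    if cfg.linear_convention == "mean":
        alpha = cfg.lambda_linear / 2.0
    else:
        alpha = 1.0 / (2.0 * n * cfg.lambda_linear)
    reg = Lasso(alpha=alpha, tol=1e-6, max_iter=100_000)
    reg.fit(enc.X, e)
    return LinearModel(
        weights=_weights_from_coef(reg.coef_, enc),
        intercept=float(reg.intercept_),
        task="regression",
        lam=cfg.lambda_linear,
        lead=enc.lead,
    )


@dataclass
class NeuralModel:
    """Opaque nonlinear scorer (CNN or MLP over embeddings)."""

    net: _nn.Network
    lead: LeadSpec
    task: str
    kind: str  # "cnn" | "mlp"
    val_loss: float = float("nan")
    embed: object = None  # embedding provider for the MLP

    def score_sequences(self, sequences) -> np.ndarray:
        aligned = [align_to_lead(s, self.lead) for s in sequences]
        if self.kind == "cnn":
            X = to_tensor(aligned, self.lead).astype(np.float64)
        else:
            X = self.embed(aligned)
        return np.asarray(self.net.forward(X), dtype=float)


def train_cnn(
    aligned_sequences, target, cfg: TrainConfig, lead: LeadSpec,
    task: str = "classification",
) -> NeuralModel:
    """Train the 1-D CNN scorer (kernel 5, 32 channels, dense 64).

    Early stopping on a seeded held-out split; same seed reproduces the
    same validation loss. ``epochs=0`` returns the untrained (random-init)
    scorer.
    """
    X = to_tensor(aligned_sequences, lead).astype(np.float64)
    rng = np.random.default_rng(cfg.seed)
    net = _nn.make_cnn(len(lead), len(ALPHABET21), rng, l1=cfg.lambda_cnn)
    val = _nn.train(
        net, X, np.asarray(target, dtype=float), task,
        epochs=cfg.epochs, seed=cfg.seed,
        val_fraction=cfg.validation_fraction, patience=cfg.patience,
    )
    return NeuralModel(net=net, lead=lead, task=task, kind="cnn", val_loss=val)


class RandomProjectionEmbedding:
    """Seeded random projection of one-hot features: a synthetic stand-in
    embedding provider with the same call signature as a pretrained
    protein-language-model encoder. Any callable ``sequences -> (N, D)``
    array can replace it."""

    def __init__(self, lead: LeadSpec, dim: int = 64, seed: int = 0):
        self.lead = lead
        rng = np.random.default_rng(seed)
        self.P = rng.normal(0, 1, size=(len(lead) * len(ALPHABET21), dim))
        self.P /= np.sqrt(dim)

    def __call__(self, sequences) -> np.ndarray:
        X = to_tensor(list(sequences), self.lead).astype(np.float64)
        return X.reshape(len(sequences), -1) @ self.P


def train_embedding_mlp(
    aligned_sequences, target, cfg: TrainConfig, lead: LeadSpec,
    task: str = "classification", provider=None,
) -> NeuralModel:
    """MLP over a pluggable embedding provider (default: seeded random
    projection stand-in)."""
    provider = provider or RandomProjectionEmbedding(lead, seed=cfg.seed)
    X = provider(list(aligned_sequences))
    rng = np.random.default_rng(cfg.seed)
    net = _nn.make_mlp(X.shape[1], rng, l1=cfg.lambda_mlp)
    val = _nn.train(
        net, X, np.asarray(target, dtype=float), task,
        epochs=cfg.epochs, seed=cfg.seed,
        val_fraction=cfg.validation_fraction, patience=cfg.patience,
    )
    return NeuralModel(net=net, lead=lead, task=task, kind="mlp",
                       val_loss=val, embed=provider)


def score(model, sequences) -> np.ndarray:
    """Model scores for raw protein sequences (decision function, not
    probability); deterministic."""
    return model.score_sequences(list(sequences))


# ---------------------------------------------------------------------------
# Distance baselines


def _as_matrix(aligned) -> np.ndarray:
    return np.frombuffer("".join(aligned).encode(), dtype=np.uint8).reshape(
        len(aligned), -1
    )


def baseline_wt_distance(sequences, lead: LeadSpec) -> np.ndarray:
    """Hamming distance to the lead (gaps count as mismatches)."""
    aligned = [align_to_lead(s, lead) for s in sequences]
    M = _as_matrix(aligned)
    ref = np.frombuffer(lead.sequence.encode(), dtype=np.uint8)
    return (M != ref).sum(axis=1).astype(float)


def baseline_median_macs_distance(
    sequences, macs_sequences, lead: LeadSpec,
    max_macs: int = 2000, seed: int = 0,
) -> np.ndarray:
    """Median Hamming distance to the MACS-round sequences.

    For large MACS rounds a seeded subsample of ``max_macs`` sequences is
    used; the median is robust to this.
    """
    macs_sequences = list(macs_sequences)
    if not macs_sequences:
        raise ValueError("empty MACS sequence set")
    if len(macs_sequences) > max_macs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(macs_sequences), size=max_macs, replace=False)
        macs_sequences = [macs_sequences[i] for i in sorted(idx)]
    A = _as_matrix([align_to_lead(s, lead) for s in sequences])
    B = _as_matrix([align_to_lead(s, lead) for s in macs_sequences])
    out = np.empty(len(A))
    chunk = max(1, 10_000_000 // max(1, B.size))
    for start in range(0, len(A), chunk):
        block = A[start : start + chunk]
        d = (block[:, None, :] != B[None, :, :]).sum(axis=2)
        out[start : start + chunk] = np.median(d, axis=1)
    return out.astype(float)


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvalReport:
    """Classification and/or regression metrics for one model on one test set."""

    roc_auc: float = float("nan")
    pr_auc: float = float("nan")
    spearman: float = float("nan")
    spearman_enriched: float = float("nan")
    spearman_depleted: float = float("nan")
    n: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "spearman": self.spearman,
            "spearman_enriched": self.spearman_enriched,
            "spearman_depleted": self.spearman_depleted,
            "n": self.n,
        }
        d.update(self.extra)
        return d


def evaluate(scores, labels=None, e_values=None) -> EvalReport:
    """ROC-AUC / PR-AUC against binary labels; Spearman (overall and
    per-class) against continuous log-enrichment values. Ties are handled
    by rank averaging in all three statistics."""
    scores = np.asarray(scores, dtype=float)
    rep = EvalReport(n=len(scores))
    if labels is None and e_values is None:
        raise ValueError("provide labels and/or e_values")
    if labels is not None:
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            raise ValueError("need both classes to compute ROC/PR AUC")
        rep.roc_auc = float(roc_auc_score(labels, scores))
        rep.pr_auc = float(average_precision_score(labels, scores))
    if e_values is not None:
        e_values = np.asarray(e_values, dtype=float)
        if len(np.unique(e_values)) < 2:
            raise ValueError("need >= 2 distinct target values for Spearman")
        rep.spearman = float(stats.spearmanr(scores, e_values).statistic)
        if labels is not None:
            for cls, attr in ((1, "spearman_enriched"), (0, "spearman_depleted")):
                mask = labels == cls
                if (mask.sum() >= 2 and len(np.unique(e_values[mask])) >= 2
                        and len(np.unique(scores[mask])) >= 2):
                    setattr(
                        rep, attr,
                        float(stats.spearmanr(scores[mask], e_values[mask]).statistic),
                    )
    return rep


def oriented_auc(scores, labels) -> tuple[float, int]:
    """ROC-AUC under the better of the two score orientations.

    Distance baselines have no intrinsic sign convention; returns
    (max AUC, orientation) with orientation +1 for scores-as-given and −1
    for flipped. Both orientations are reported by the retrospective
    workflow."""
    auc = float(roc_auc_score(np.asarray(labels), np.asarray(scores, dtype=float)))
    return (auc, 1) if auc >= 0.5 else (1.0 - auc, -1)


def encode_for_linear(sequences, lead: LeadSpec) -> EncodedDataset:
    """Convenience: align then one-hot in wt_dropped mode."""
    aligned = [align_to_lead(s, lead) for s in sequences]
    return one_hot(aligned, "wt_dropped", lead)
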