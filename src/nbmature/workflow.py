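"""End-to-end orchestration: retrospective evaluation and design runs.

``run_retrospective`` trains the configured models on the FACS1/MACS
enrichment dataset and evaluates them on FACS2/MACS (the early-round to
late-round generalization protocol), alongside the two Hamming-distance
baselines. ``run_design`` assembles the three candidate sets: model-ranked
campaign sequences (LR_score), Gibbs-designed novel multi-mutants
(LR_gibbs), and redundancy-reduced top FACS2 counts (FACS2_count). A single
master seed fans out to per-stage seeds so any stage can be rerun
independently and full runs are byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .design import GibbsConfig, design_batch, select_lr_score, write_designs
from .enrichment import (
    EnrichmentParams,
    apply_count_threshold,
    build_dataset,
    write_dataset_tsv,
)
from .models import (
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
from .ranking import naive_polyreactivity_scorer, score_all_singles, write_ranking_tsv
from .readproc import LeadSpec, read_counts_tsv, write_counts_tsv
from .simulate import CampaignSimConfig, simulate_campaign, write_truth_json

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One campaign analysis: inputs, parameters, seed.

    Either ``round_paths`` (round_id -> counts TSV) or ``sim`` (a simulated
    campaign) supplies the data. ``rounds`` names the (MACS, FACS1, FACS2)
    round ids used by the retrospective protocol.
    """

    lead: LeadSpec
    round_paths: dict | None = None
    sim: CampaignSimConfig | None = None
    rounds: tuple = ("MACS", "FACS1", "FACS2")
    enrich: EnrichmentParams = field(default_factory=EnrichmentParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)
    models: tuple = ("logistic", "linear")
    nn_max_train: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        lead = LeadSpec(
            raw["lead"]["sequence"],
            frozenset(raw["lead"].get("cdr_mask", [])),
            raw["lead"].get("anchor_len", 9),
        )
        kwargs = dict(lead=lead, seed=raw.get("seed", 0))
        if "round_paths" in raw:
            kwargs["round_paths"] = dict(raw["round_paths"])
        if "rounds" in raw:
            kwargs["rounds"] = tuple(raw["rounds"])
        if "models" in raw:
            kwargs["models"] = tuple(raw["models"])
        if "enrich" in raw:
            kwargs["enrich"] = EnrichmentParams(**raw["enrich"])
        if "train" in raw:
            kwargs["train"] = TrainConfig(**raw["train"])
        if "gibbs" in raw:
            g = dict(raw["gibbs"])
            for key in ("temperatures", "goal_distances"):
                if key in g:
                    g[key] = tuple(g[key])
            kwargs["gibbs"] = GibbsConfig(**g)
        return cls(**kwargs)


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return int(
        np.random.SeedSequence([master, sum(ord(c) for c in stage)])
        .generate_state(1)[0] % (2**31)
    )


def load_rounds(cfg: RunConfig) -> tuple[dict, object]:
    """Round count tables from files or from the simulator; truth when
    simulated, else None."""
    if cfg.sim is not None:
        return simulate_campaign(cfg.sim)
    if not cfg.round_paths:
        raise ValueError("RunConfig needs round_paths or a sim config")
    rounds = {
        rid: read_counts_tsv(path, round_id=rid)
        for rid, path in cfg.round_paths.items()
    }
    return rounds, None


def _train_models(cfg: RunConfig, ds_train):
    lead = cfg.lead
    trained = {}
    if {"logistic", "linear"} & set(cfg.models):
        enc = encode_for_linear(ds_train.sequences, lead)
        if "logistic" in cfg.models:
            trained["logistic"] = train_logistic_l1(enc, ds_train.labels, cfg.train)
        if "linear" in cfg.models:
            trained["linear"] = train_linear_l1(enc, ds_train.e_values, cfg.train)
    if {"cnn", "mlp"} & set(cfg.models):
        seqs = ds_train.sequences
        labels = ds_train.labels
        if len(seqs) > cfg.nn_max_train:
            rng = np.random.default_rng(_stage_seed(cfg.seed, "nn_subsample"))
            idx = rng.choice(len(seqs), size=cfg.nn_max_train, replace=False)
            seqs = [seqs[i] for i in sorted(idx)]
            labels = labels[sorted(idx)]
        if "cnn" in cfg.models:
            trained["cnn"] = train_cnn(seqs, labels, cfg.train, lead)
        if "mlp" in cfg.models:
            trained["mlp"] = train_embedding_mlp(seqs, labels, cfg.train, lead)
    return trained


def run_retrospective(cfg: RunConfig, out_dir=None) -> dict:
    """Train on FACS1/MACS enrichment, test on FACS2/MACS.

    Returns {"models": trained models, "reports": metrics, "datasets": ...}.
    Metrics are reported on all test sequences and with train-overlapping
    sequences removed; baseline AUCs are reported in both orientations
    with the better one flagged.
    """
    rounds, truth = load_rounds(cfg)
    macs_id, facs1_id, facs2_id = cfg.rounds
    for rid in cfg.rounds:
        if rid not in rounds:
            raise ValueError(f"round {rid!r} missing from inputs")
    ds_train = build_dataset(rounds[macs_id], rounds[facs1_id], cfg.enrich)
    ds_test = build_dataset(rounds[macs_id], rounds[facs2_id], cfg.enrich)
    trained = _train_models(cfg, ds_train)

    train_seqs = set(ds_train.sequences)
    mask_new = np.array([s not in train_seqs for s in ds_test.sequences])
    reports: dict = {}
    for name, model in trained.items():
        s = score(model, ds_test.sequences)
        rep = evaluate(s, labels=ds_test.labels, e_values=ds_test.e_values)
        entry = {"all": rep.to_dict()}
        if mask_new.sum() >= 2 and len(np.unique(ds_test.labels[mask_new])) == 2:
            entry["train_overlap_removed"] = evaluate(
                s[mask_new], labels=ds_test.labels[mask_new],
                e_values=ds_test.e_values[mask_new],
            ).to_dict()
        reports[name] = entry

    macs_thresh = apply_count_threshold(
        rounds[macs_id], cfg.enrich.count_threshold
    )
    b_wt = baseline_wt_distance(ds_test.sequences, cfg.lead)
    b_macs = baseline_median_macs_distance(
        ds_test.sequences, list(macs_thresh.counts), cfg.lead,
        seed=_stage_seed(cfg.seed, "macs_baseline"),
    )
    for name, b in (("WT_dist", b_wt), ("median_MACS_dist", b_macs)):
        auc_best, orient = oriented_auc(b, ds_test.labels)
        reports[name] = {
            "all": {
                "roc_auc": auc_best,
                "orientation": orient,
                "roc_auc_as_given": evaluate(b, labels=ds_test.labels).roc_auc,
                "n": len(b),
            }
        }

    result = {
        "reports": reports, "models": trained,
        "datasets": {"train": ds_train, "test": ds_test},
        "rounds": rounds, "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rid, rc in rounds.items():
            write_counts_tsv(rc, out / f"counts_{rid}.tsv")
        write_dataset_tsv(ds_train, out / f"enrich_{facs1_id}.tsv")
        write_dataset_tsv(ds_test, out / f"enrich_{facs2_id}.tsv")
        for name, model in trained.items():
            if hasattr(model, "save"):
                model.save(out / f"model_{name}.json")
        (out / "report.json").write_text(
            json.dumps(reports, indent=2, sort_keys=True) + "\n"
        )
        if truth is not None:
            write_truth_json(truth, out / "truth.json")
    return result


def run_design(cfg: RunConfig, retro: dict, out_dir=None, n: int = 30) -> dict:
    """Assemble the LR_gibbs, LR_score and FACS2_count candidate sets."""
    lead = cfg.lead
    model = retro["models"].get("logistic") or next(iter(retro["models"].values()))
    gibbs_cfg = GibbsConfig(
        steps=cfg.gibbs.steps, temperatures=cfg.gibbs.temperatures,
        goal_distances=cfg.gibbs.goal_distances,
        samples_per_distance=cfg.gibbs.samples_per_distance,
        alpha=cfg.gibbs.alpha, seed=_stage_seed(cfg.seed, "gibbs"),
        cdr_mask=cfg.gibbs.cdr_mask,
    )
    lr_gibbs = design_batch(lead, model, gibbs_cfg, n=n)

    pool = sorted(
        set(retro["datasets"]["train"].sequences)
        | set(retro["datasets"]["test"].sequences)
    )
    poly = naive_polyreactivity_scorer(lead)
    lr_score = select_lr_score(pool, model, lead, n=n, scorer=poly)

    macs_id, facs1_id, facs2_id = cfg.rounds
    from .ranking import top_by_count_clustered

    facs2 = apply_count_threshold(
        retro["rounds"][facs2_id], cfg.enrich.count_threshold
    )
    if facs2.counts:
        leaders = top_by_count_clustered(facs2, radius=2, n=n)
        facs2_scores = score(model, leaders)
        from .design import DesignCandidate, _hamming

        facs2_set = [
            DesignCandidate(
                sequence=s, model_score=float(sc),
                hamming_to_wt=_hamming(s, lead.sequence)
                if len(s) == len(lead.sequence) else -1,
                method="FACS2_count",
            )
            for s, sc in zip(leaders, facs2_scores)
        ]
    else:
        logger.warning("FACS2 round empty after thresholding; FACS2_count set empty")
        facs2_set = []

    sets = {"LR_gibbs": lr_gibbs, "LR_score": lr_score, "FACS2_count": facs2_set}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, cands in sets.items():
            write_designs(
                cands, lead,
                out / f"designs_{name}.fasta", out / f"designs_{name}.tsv",
            )
        matrix = score_all_singles(model, lead, provenance="logistic")
        matrix.to_heatmap_tsv(out / "singles_heatmap.tsv")
        write_ranking_tsv(matrix, out / "singles_ranked.tsv", lead)
    return sets


def run(cfg: RunConfig, out_dir) -> dict:
    """Full retrospective + design run; all outputs under ``out_dir`` are
    regenerated byte-identically from (config, seed)."""
    out = Path(out_dir)
    retro = run_retrospective(cfg, out_dir=out / "retrospective")
    sets = run_design(cfg, retro, out_dir=out / "designs")
    return {"retrospective": retro, "designs": sets}
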