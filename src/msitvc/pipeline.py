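"""End-to-end workflow: simulate -> select/fuse -> train -> stack -> evaluate.

The two feature blocks (mean reflectance; pixel-intensity sd) are processed
in parallel branches: each gets its own ranking/fusion and its own
neuro-fuzzy base model.  Base-model generalization is measured by k-fold
out-of-fold (OOF) prediction; the stacking combiners are evaluated on
meta-level OOF predictions so no stage ever scores its own training fits.
Every stage derives its RNG seed from the single pipeline seed by stable
hashing of the stage name, so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .cagfinn import CAGFINNRegressor
from .dataset import SpectralDataset, write_dataset, write_ranking_table
from .ensemble import (MetaPLSRegressor, StackedPredictions, average_combine,
                       oof_predictions)
from .metrics import compute_metrics
from .selection import fuse_rankings, rank_all
from .simulate import GrowthParams, SpectralResponseParams, generate_dataset
from .wavebands import feature_columns

log = logging.getLogger("msitvc.pipeline")

DEFAULT_FS_METHODS = ("boruta", "rfe", "ga", "stepwise", "lasso", "relimp", "plsr")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific seed (< 2^31) by stable hashing."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str = "runs/default"
    seed: int = 1
    blocks: tuple[str, ...] = ("mean", "sd")
    n_per_temp: int = 17
    temps: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0)
    fs_methods: tuple[str, ...] = DEFAULT_FS_METHODS
    threshold: str | int = "majority"
    radius_frac: float = 0.4
    lvq_rate: float = 0.05
    learning_rate: float = 0.01
    max_epochs: int = 200
    rls_forgetting: float = 1.0
    tol: float = 1e-6
    n_splits: int = 5
    ensemble_kinds: tuple[str, ...] = ("average", "pls_linear", "poly4_nipals")

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _make_base(cfg: PipelineConfig, seed: int) -> CAGFINNRegressor:
    return CAGFINNRegressor(
        radius_frac=cfg.radius_frac, lvq_rate=cfg.lvq_rate,
        learning_rate=cfg.learning_rate, max_epochs=cfg.max_epochs,
        rls_forgetting=cfg.rls_forgetting, tol=cfg.tol, seed=seed,
    )


def run_pipeline(cfg: PipelineConfig, dataset: SpectralDataset | None = None) -> dict:
    """Execute the full workflow; returns a results dict with artifact paths.

    ``dataset`` overrides the simulation stage (e.g. to run on measured data).
    Artifacts: ``data.csv``, per-block ``ranks_<block>.csv`` /
    ``fusion_<block>.json`` / ``model_<block>.json`` /
    ``report_base_<block>.json``, per-combiner ``ensemble_<kind>.json``,
    ``oof_predictions.csv`` and ``manifest.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    results: dict = {"config": cfg.to_dict()}

    stage = "simulate"
    log.info("stage %s", stage)
    if dataset is None:
        dataset = generate_dataset(
            n_per_temp=cfg.n_per_temp, temps=cfg.temps,
            gp=GrowthParams(), sp=SpectralResponseParams(),
            seed=stage_seed(cfg.seed, stage),
        )
    artifacts["data"] = write_dataset(dataset, out / "data.csv")

    y = dataset.tvc
    oof: dict[str, np.ndarray] = {}
    base_rmse: dict[str, float] = {}
    results["blocks"] = {}
    for block in cfg.blocks:
        log.info("stage select/%s", block)
        ranks = rank_all(dataset, methods=cfg.fs_methods, statistic=block,
                         seed=stage_seed(cfg.seed, f"select/{block}"))
        artifacts[f"ranks_{block}"] = write_ranking_table(
            ranks, out / f"ranks_{block}.csv")
        fusion = fuse_rankings(ranks, threshold=cfg.threshold)
        fusion_path = out / f"fusion_{block}.json"
        fusion_path.write_text(json.dumps(fusion.to_dict(), indent=2))
        artifacts[f"fusion_{block}"] = fusion_path

        cols = [feature_columns(block)[b - 1] for b in sorted(fusion.selected)]
        X = dataset.frame[cols].to_numpy(dtype=float)

        log.info("stage train/%s (%d bands)", block, len(cols))
        tseed = stage_seed(cfg.seed, f"train/{block}")
        oof[block] = oof_predictions(X, y, _make_base(cfg, tseed),
                                     n_splits=cfg.n_splits, seed=tseed)
        report = compute_metrics(y, oof[block])
        report.to_json(out / f"report_base_{block}.json")
        artifacts[f"report_base_{block}"] = out / f"report_base_{block}.json"
        base_rmse[block] = report.rmse

        final = _make_base(cfg, tseed).fit(X, y)
        final.to_json(out / f"model_{block}.json")
        artifacts[f"model_{block}"] = out / f"model_{block}.json"
        results["blocks"][block] = {
            "selected_bands": fusion.selected,
            "n_rules": final.n_rules_,
            "oof_rmse": report.rmse,
            "report": report.to_dict(),
        }

    results["base_rmse"] = base_rmse
    if set(cfg.blocks) >= {"mean", "sd"}:
        log.info("stage ensemble")
        eseed = stage_seed(cfg.seed, "ensemble")
        xm, xs = oof["mean"], oof["sd"]
        np.savetxt(out / "oof_predictions.csv",
                   np.column_stack([xm, xs, y]), delimiter=",",
                   header="x_mean,x_sd,tvc", comments="")
        artifacts["oof_predictions"] = out / "oof_predictions.csv"
        results["ensemble"] = {}
        for kind in cfg.ensemble_kinds:
            if kind == "average":
                preds = average_combine(xm, xs)
            else:
                preds = _meta_oof(xm, xs, y, kind, cfg.n_splits, eseed)
            report = compute_metrics(y, preds)
            path = out / f"ensemble_{kind}.json"
            report.to_json(path)
            artifacts[f"ensemble_{kind}"] = path
            results["ensemble"][kind] = report.to_dict()
    else:
        log.info("stage ensemble skipped: needs both feature blocks, have %s",
                 list(cfg.blocks))
        results["ensemble_skipped"] = (
            f"requires both feature blocks, configured: {list(cfg.blocks)}"
        )

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s)
                        for s in ["simulate", "ensemble"]
                        + [f"select/{b}" for b in cfg.blocks]
                        + [f"train/{b}" for b in cfg.blocks]},
        "config": cfg.to_dict(),
        "artifacts": {k: {"path": str(p), "sha256": _sha256(p)}
                      for k, p in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    results["out_dir"] = str(out)
    return results


def _meta_oof(xm, xs, y, kind: str, n_splits: int, seed: int) -> np.ndarray:
    """Meta-level out-of-fold predictions of one stacking combiner."""
    from sklearn.model_selection import KFold

    X2 = np.column_stack([xm, xs])
    preds = np.full(len(y), np.nan)
    for tr, te in KFold(n_splits, shuffle=True, random_state=seed).split(X2):
        meta = MetaPLSRegressor(kind=kind, seed=seed).fit(X2[tr], y[tr])
        preds[te] = meta.predict(X2[te])
    return preds
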