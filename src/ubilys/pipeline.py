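"""End-to-end pipeline: simulate → reduce → featurize → train → cross-validate.

A :class:`RunConfig` (usually read from YAML) names every input/output and
hyper-parameter; each stage writes its artifact plus a stamp file holding a
hash of the stage inputs and config, so an unchanged stage is skipped on
re-run.  Every results file embeds the seed and config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from . import evaluation, rbfn
from .features import EncoderConfig, build_feature_matrix, feature_names
from .redundancy import reduce_fragments
from .seqio import SiteAnnotation, extract_fragment
from .simulate import Dataset, SimulationParams, load_dataset, simulate, write_dataset

logger = logging.getLogger("ubilys")


@dataclass
class RunConfig:
    out_dir: str = "run"
    data_dir: Optional[str] = None  # existing dataset; None → simulate
    seed: int = 0
    window_n: int = 20
    blocks: Tuple[str, ...] = ("AAC", "PSSM400")
    sigma: float = 5.0
    ridge: float = 1e-8
    k: int = 5
    identity_threshold: float = 0.30
    reduce: bool = True
    grouping: Optional[str] = None  # None | "protein"
    simulation: SimulationParams = field(default_factory=SimulationParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("simulation", {}) or {}).items()
        })
        if "blocks" in raw:
            raw["blocks"] = tuple(raw["blocks"])
        return cls(simulation=sim, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stamp_path(out_dir: Path, stage: str) -> Path:
    return out_dir / f".{stage}.stamp.json"


def _stage_fresh(out_dir: Path, stage: str, key: str, outputs: list[Path]) -> bool:
    stamp = _stamp_path(out_dir, stage)
    if not stamp.exists() or not all(p.exists() for p in outputs):
        return False
    try:
        return json.loads(stamp.read_text()).get("key") == key
    except ValueError:
        return False


def _write_stamp(out_dir: Path, stage: str, key: str) -> None:
    _stamp_path(out_dir, stage).write_text(json.dumps({"key": key}))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, skipping those whose inputs are unchanged.

    Returns a summary dict with the pooled CV metrics; artifacts are
    written under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    # stage: data --------------------------------------------------------
    try:
        if config.data_dir is not None:
            dataset = load_dataset(config.data_dir)
        else:
            data_dir = out_dir / "data"
            key = f"{chash}:{config.seed}"
            if _stage_fresh(out_dir, "simulate", key, [data_dir / "proteins.fasta"]):
                logger.info("simulate: up to date, skipped")
                dataset = load_dataset(data_dir)
            else:
                logger.info("simulate: generating synthetic proteome")
                dataset = simulate(config.simulation, seed=config.seed)
                write_dataset(dataset, data_dir)
                _write_stamp(out_dir, "simulate", key)
    except Exception as exc:
        raise RuntimeError(f"stage 'data' failed: {exc}") from exc

    # stage: redundancy reduction ---------------------------------------
    try:
        sites = dataset.sites
        if config.reduce:
            frags = [
                extract_fragment(
                    next(p for p in dataset.proteins if p.id == s.protein_id),
                    s.position,
                    config.window_n,
                    s.label,
                )
                for s in sites
            ]
            kept = reduce_fragments(frags, dataset.proteins, config.identity_threshold)
            kept_keys = {(f.protein_id, f.center) for f in kept}
            sites = [s for s in sites if (s.protein_id, s.position) in kept_keys]
            logger.info("reduce: kept %d of %d sites", len(sites), len(dataset.sites))
    except Exception as exc:
        raise RuntimeError(f"stage 'reduce' failed: {exc}") from exc

    # stage: featurize ---------------------------------------------------
    try:
        enc = EncoderConfig(n=config.window_n, blocks=tuple(config.blocks))
        X, labels, names, prov = build_feature_matrix(
            dataset.proteins, sites, dataset.profiles, enc
        )
        logger.info("featurize: %d sites × %d features", *X.shape)
    except Exception as exc:
        raise RuntimeError(f"stage 'featurize' failed: {exc}") from exc

    # stage: cross-validate ---------------------------------------------
    try:
        groups = [p.split(":")[0] for p in prov] if config.grouping == "protein" else None
        cv = evaluation.kfold(
            X,
            labels,
            k=config.k,
            seed=config.seed,
            groups=groups,
            sigma=config.sigma,
            ridge=config.ridge,
        )
        m = cv.pooled_metrics
    except Exception as exc:
        raise RuntimeError(f"stage 'crossval' failed: {exc}") from exc

    # stage: final model on all data -------------------------------------
    try:
        model = rbfn.train(X, labels, sigma=config.sigma, ridge=config.ridge)
        rbfn.save(model, out_dir / "model.ubs")
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc

    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "n_sites": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "folds": [
            {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn} for c in cv.fold_counts
        ],
        "pooled": {
            "precision": m.precision,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "accuracy": m.accuracy,
        },
    }
    with open(out_dir / "cv.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
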