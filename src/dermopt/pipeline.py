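"""Composed pipeline: enhance → (features in) → fuse → select → classify.

The deep-feature extraction stage of a real deployment is a pluggable
boundary: the pipeline consumes feature CSVs from any source, or generates
labelled synthetic matrices when asked to run self-contained.  A run is
described by a validated configuration mapping and produces a JSON-ready
report with per-stage artifacts, the seed, and package version.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np

from dermopt import __version__
from dermopt.bat import BatConfig
from dermopt.bees import BeeConfig
from dermopt.enhancer import enhance_image
from dermopt.fusion import FeatureMatrix, reduction_percentage, serial_concat
from dermopt.image_core import load_image, save_image
from dermopt.selection import WhaleConfig, select_features
from dermopt.simulate import gen_feature_matrix
from dermopt.stats import train_eval_classifier

__all__ = ["DEFAULT_CONFIG", "PipelineError", "run_pipeline", "validate_config"]

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "output_dir": "dermopt_run",
    "enhancer": {
        "image": None,        # path to an RGB image, or null to skip the stage
        "iters": 100,         # total budget, split evenly bat/colony per round
        "pop": 50,
        "window": 3,
        "rounds": 1,
    },
    "features": {
        "sources": [],        # CSV paths; empty -> synthetic
        "synthetic": {
            "n_samples": 200,
            "n_informative": 5,
            "n_redundant": 5,
            "n_noise": 40,
            "separation": 3.0,
        },
    },
    "selector": {
        "agents": 30,
        "iters": 100,
        "sparsity_weight": 0.5,
        "threshold": 0.5,
        "fitness_mode": "info_gain",
    },
    "classifier": {
        "families": ["quadratic-svm"],
        "test_size": 0.2,
        "k_folds": None,
        "averaging": "micro",
    },
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def validate_config(cfg: dict) -> dict:
    """Merge ``cfg`` over the defaults, rejecting unknown keys."""

    def _merge(defaults: dict, given: dict, path: str) -> dict:
        out = copy.deepcopy(defaults)
        for key, value in given.items():
            if key not in defaults:
                raise ValueError(f"unknown config key {path}{key}")
            if isinstance(defaults[key], dict) and defaults[key]:
                if not isinstance(value, dict):
                    raise ValueError(f"config key {path}{key!r} must be a mapping")
                out[key] = _merge(defaults[key], value, f"{path}{key}.")
            else:
                out[key] = value
        return out

    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return _merge(DEFAULT_CONFIG, cfg, "")


def _load_blocks(paths: list[str]) -> list[FeatureMatrix]:
    blocks = []
    for p in paths:
        if not Path(p).exists():
            raise PipelineError(f"fusion stage: feature source not found: {p}")
        blocks.append(FeatureMatrix.from_csv(p))
    return blocks


def run_pipeline(cfg: dict) -> dict:
    """Execute the configured stages and return the run report.

    Artifacts (enhanced image, selected features, report JSON) are written
    under ``output_dir``; on failure the files written so far are removed.
    """
    cfg = validate_config(cfg)
    seed = int(cfg["seed"])
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {"seed": seed, "version": __version__, "stages": {}}

    try:
        enh = cfg["enhancer"]
        if enh["image"] is not None:
            if not Path(enh["image"]).exists():
                raise PipelineError(
                    f"enhance stage: image not found: {enh['image']}"
                )
            pixels = load_image(enh["image"])
            share = max(int(enh["iters"]) // (2 * int(enh["rounds"])), 1)
            res = enhance_image(
                pixels,
                bat_cfg=BatConfig(pop_size=int(enh["pop"]), max_iter=share,
                                  seed=seed),
                bee_cfg=BeeConfig(max_iter=share, seed=seed),
                rounds=int(enh["rounds"]),
                seed=seed,
                window=int(enh["window"]),
            )
            out_img = out_dir / "enhanced.png"
            save_image(out_img, res.enhanced)
            written.append(out_img)
            report["stages"]["enhance"] = {
                "input": str(enh["image"]),
                "output": str(out_img),
                **res.to_report(),
            }

        feats = cfg["features"]
        if feats["sources"]:
            blocks = _load_blocks(list(feats["sources"]))
        else:
            syn = feats["synthetic"]
            fixture = gen_feature_matrix(
                n_samples=int(syn["n_samples"]),
                n_informative=int(syn["n_informative"]),
                n_redundant=int(syn["n_redundant"]),
                n_noise=int(syn["n_noise"]),
                separation=float(syn["separation"]),
                seed=seed,
            )
            blocks = [fixture.matrix]
        fused = serial_concat(blocks)
        report["stages"]["fuse"] = {
            "blocks": [b.n_features for b in blocks],
            "fused_width": fused.n_features,
            "n_samples": fused.n_samples,
        }

        sel_cfg = cfg["selector"]
        sel = select_features(
            fused,
            WhaleConfig(
                agents=int(sel_cfg["agents"]),
                max_iter=int(sel_cfg["iters"]),
                sparsity_weight=float(sel_cfg["sparsity_weight"]),
                threshold=float(sel_cfg["threshold"]),
                fitness_mode=str(sel_cfg["fitness_mode"]),
                seed=seed,
            ),
        )
        sel_path = out_dir / "selected.csv"
        sel.selected.to_csv(sel_path)
        written.append(sel_path)
        report["stages"]["select"] = {
            "selected_width": sel.selected.n_features,
            "reduction_pct": sel.reduction_pct,
            "fitness": sel.fitness,
            "output": str(sel_path),
        }
        assert sel.reduction_pct == reduction_percentage(
            fused.n_features, sel.selected.n_features
        )

        if sel.selected.labels is None:
            raise PipelineError(
                "classify stage: selected features carry no labels"
            )
        clf_cfg = cfg["classifier"]
        metrics = {}
        for family in clf_cfg["families"]:
            rep = train_eval_classifier(
                sel.selected.values,
                sel.selected.labels,
                family,
                test_size=float(clf_cfg["test_size"]),
                k_folds=clf_cfg["k_folds"],
                averaging=str(clf_cfg["averaging"]),
                seed=seed,
            )
            metrics[family] = {
                k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in rep.to_dict().items()
            }
        report["stages"]["classify"] = metrics

        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=2))
        written.append(report_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return report
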