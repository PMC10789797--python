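"""End-to-end orchestration: stability -> restrict -> fit -> bootstrap -> OGT -> tree.

A :class:`RunConfig` names the inputs and the handful of statistical
constants (bootstrap size, confidence level, width-transition rate ``w``,
lifestyle thresholds, root seed). :func:`run_pipeline` executes the stages
per protein with full isolation — one pathological profile is reported in
the manifest without sinking the batch — and writes every table, the
annotated tree, and a JSON manifest recording the configuration hash and
every seed used, into a fresh output directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import bootstrap_peak_ci
from .ogt import OgtEstimate, infer_ogt, pearson_r, read_calibration_table
from .profiles import FluorescenceProfile, read_profiles
from .thermostability import restrict_to_stable, stable_range
from .trees import annotate_nodes, annotations_table, read_newick_file, trajectory_table, write_newick_file


@dataclass
class RunConfig:
    """Inputs and constants for one pipeline run."""

    binding_path: Optional[str] = None
    stability_path: Optional[str] = None
    tree_path: Optional[str] = None
    calibration_path: Optional[str] = None
    out_dir: str = "run_out"
    n_boot: int = 1000
    level: float = 0.90
    w: float = 5.0
    mesophile_max: float = 45.0
    moderate_max: float = 80.0
    seed: int = 0
    restrict_to_stable_range: bool = True

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _protein_seed(root_seed: int, protein_id: str) -> int:
    """Deterministic per-protein seed independent of batch order (< 2^31)."""
    h = hashlib.sha256(f"{root_seed}:{protein_id}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full inference and return the manifest (also written to disk)."""
    if config.binding_path is None:
        raise FileNotFoundError("configuration error: binding_path is required")
    for attr in ("binding_path", "stability_path", "tree_path", "calibration_path"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configuration error: {attr} {p!r} does not exist")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    binding = {p.protein_id: p for p in read_profiles(config.binding_path, "binding")}
    stability: Dict[str, FluorescenceProfile] = {}
    if config.stability_path:
        stability = {p.protein_id: p for p in read_profiles(config.stability_path, "stability")}

    manifest: dict = {
        "version": __version__,
        "config": dict(config.__dict__),
        "config_hash": config.config_hash(),
        "root_seed": config.seed,
        "proteins": {},
        "errors": {},
    }

    stab_rows, fit_rows = [], []
    estimates: Dict[str, OgtEstimate] = {}
    for pid, prof in binding.items():
        seed = _protein_seed(config.seed, pid)
        record: dict = {"seed": seed}
        try:
            fit_range = None
            if config.restrict_to_stable_range and pid in stability:
                sr = stable_range(stability[pid])
                record["stable_range"] = [sr.stable_min, sr.stable_max]
                stab_rows.append(
                    {
                        "protein_id": pid,
                        "t_transition": sr.t_transition,
                        "stable_min": sr.stable_min,
                        "stable_max": sr.stable_max,
                    }
                )
                prof = restrict_to_stable(prof, sr)
                fit_range = sr.fit_range
            boot = bootstrap_peak_ci(
                prof,
                n_boot=config.n_boot,
                level=config.level,
                seed=seed,
                fit_range=fit_range,
                w=config.w,
            )
            est = infer_ogt(
                pid, boot, mesophile_max=config.mesophile_max, moderate_max=config.moderate_max
            )
            estimates[pid] = est
            record.update(
                t_star=boot.point_estimate,
                ci_lower=boot.ci_lower,
                ci_upper=boot.ci_upper,
                n_failed=boot.n_failed,
                lifestyle=est.lifestyle,
            )
            fit_rows.append(
                {
                    "protein_id": pid,
                    "t_star": boot.point_estimate,
                    "ci_lower": boot.ci_lower,
                    "ci_upper": boot.ci_upper,
                    "n_boot": boot.n_boot,
                    "n_failed": boot.n_failed,
                    "seed": seed,
                    "ogt": est.ogt,
                    "lifestyle": est.lifestyle,
                }
            )
        except Exception as exc:  # per-protein isolation
            manifest["errors"][pid] = f"{type(exc).__name__}: {exc}"
            continue
        manifest["proteins"][pid] = record

    if stab_rows:
        pd.DataFrame(stab_rows).to_csv(out / "stability.tsv", sep="\t", index=False)
        manifest["stability_table"] = "stability.tsv"
    if fit_rows:
        pd.DataFrame(fit_rows).to_csv(out / "ogt_estimates.tsv", sep="\t", index=False)
        manifest["ogt_table"] = "ogt_estimates.tsv"

    if config.calibration_path:
        points = read_calibration_table(config.calibration_path)
        cal = pearson_r(points)
        pd.DataFrame(
            [{"r": cal.r, "n": cal.n}]
        ).to_csv(out / "calibration.tsv", sep="\t", index=False)
        manifest["calibration"] = {"r": cal.r, "n": cal.n}

    if config.tree_path:
        tree = read_newick_file(config.tree_path)
        known = set(tree.labels())
        attachable = [e for lab, e in estimates.items() if lab in known]
        tree = annotate_nodes(tree, attachable)
        write_newick_file(tree, out / "annotated_tree.nwk", annotations=True)
        annotations_table(tree).to_csv(out / "tree_annotations.tsv", sep="\t", index=False)
        if tree.estimates:
            trajectory_table(tree).to_csv(out / "trajectory.tsv", sep="\t", index=False)
            manifest["trajectory_table"] = "trajectory.tsv"
        manifest["tree"] = "annotated_tree.nwk"
        manifest["n_annotated_nodes"] = len(tree.estimates)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
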