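"""End-to-end orchestration: simulate -> classify -> quantify -> compare -> profile.

``run_pipeline`` executes every stage appropriate to its inputs (a synthetic
experiment, or user-supplied assay/array files), writes each stage's tables
through :mod:`embryomir.qpcr_io`, and records a reproducibility manifest
(config hash, seed, version, per-stage row counts).  Rerunning with an
identical configuration reproduces identical outputs.

Logging goes to stderr; stdout stays reserved for machine-readable summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .detection import ClassificationSummary, DetectionThresholds, classify_array
from .errors import ConfigurationError
from .panels import (
    PANEL_A,
    StageThresholds,
    classify_stage,
    droplet_balance_scores,
    uc_retention,
)
from .qpcr_io import (
    PANEL_B,
    VolumeModel,
    parse_array_export,
    parse_assay_table,
    write_results,
)
from .quantify import (
    EfficiencyModel,
    ExpressionProfile,
    build_expression_profiles,
    estimate_fractions,
    fractions_to_frame,
)
from .simulate import SimConfig, simulate_array_screen, simulate_experiment
from .stats import DEFAULT_CONTRASTS, Contrast, run_contrasts

log = logging.getLogger("embryomir")


@dataclass
class RunConfig:
    """One pipeline run: either a simulation or a set of input files."""

    sim: SimConfig | None = None
    assay_path: str | None = None
    meta_path: str | None = None
    array_conditioned_path: str | None = None
    array_blank_path: str | None = None
    thresholds: DetectionThresholds = field(default_factory=DetectionThresholds)
    efficiency: EfficiencyModel = field(default_factory=EfficiencyModel)
    volumes: VolumeModel = field(default_factory=VolumeModel)
    stage_thresholds: StageThresholds = field(default_factory=StageThresholds)
    contrasts: Sequence[Contrast] = DEFAULT_CONTRASTS
    reference_id: str = "miR-191-5p"
    seed: int = 0
    out_dir: str = "embryomir_out"
    simulate_array: bool = True  # also emit/classify a synthetic screen in sim runs

    def validate(self) -> None:
        has_files = bool(self.assay_path or self.array_conditioned_path)
        if self.sim is not None and has_files:
            raise ConfigurationError("provide either a SimConfig or input paths, not both")
        if self.sim is None and not has_files:
            raise ConfigurationError("provide a SimConfig or input paths")
        for p in (
            self.assay_path,
            self.meta_path,
            self.array_conditioned_path,
            self.array_blank_path,
        ):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"input file does not exist: {p}")
        if (self.array_conditioned_path is None) != (self.array_blank_path is None):
            raise ConfigurationError(
                "array classification needs both conditioned and blank exports"
            )

    def config_hash(self) -> str:
        payload = {
            "sim": self.sim.to_dict() if self.sim else None,
            "assay_path": self.assay_path,
            "meta_path": self.meta_path,
            "array_conditioned_path": self.array_conditioned_path,
            "array_blank_path": self.array_blank_path,
            "thresholds": dataclasses.asdict(self.thresholds),
            "efficiency": dataclasses.asdict(self.efficiency),
            "volumes": dataclasses.asdict(self.volumes),
            "stage_thresholds": dataclasses.asdict(self.stage_thresholds),
            "contrasts": [dataclasses.asdict(c) for c in self.contrasts],
            "reference_id": self.reference_id,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all applicable stages; return (and write) the run manifest."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    tables: dict[str, pd.DataFrame] = {}
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }

    measurements, metas = [], []
    summary: ClassificationSummary | None = None

    if cfg.sim is not None:
        cfg.sim.seed = cfg.seed
        log.info("stage simulate: seed=%d", cfg.seed)
        dataset = simulate_experiment(cfg.sim)
        dataset.to_files(out_dir / "simulated")
        measurements, metas = dataset.measurements, dataset.metas
        tables["ground_truth"] = dataset.truth
        manifest["stages"]["simulate"] = {"rows": len(measurements)}
        if cfg.simulate_array:
            screen = simulate_array_screen(cfg.sim)
            screen.to_files(out_dir / "simulated")
            summary = classify_array(
                screen.array_conditioned, screen.array_blank, cfg.thresholds
            )
    else:
        if cfg.array_conditioned_path:
            log.info("stage classify: %s", cfg.array_conditioned_path)
            cond = parse_array_export(cfg.array_conditioned_path, sample_id="conditioned")
            blank = parse_array_export(cfg.array_blank_path, sample_id="blank")
            summary = classify_array(cond, blank, cfg.thresholds)
        if cfg.assay_path:
            measurements, metas = parse_assay_table(cfg.assay_path, cfg.meta_path)

    if summary is not None:
        tables["classification_counts"] = summary.to_frame()
        tables["classification_calls"] = summary.calls_frame()
        tables["short_list"] = pd.DataFrame({"mirna_id": list(summary.short_list)})
        manifest["stages"]["classify"] = {
            "rows": summary.n_screened,
            "n_detected_conditioned": summary.n_detected_conditioned,
            "n_detected_blank": summary.n_detected_blank,
            "short_list": len(summary.short_list),
        }

    profile: ExpressionProfile | None = None
    if measurements and metas:
        log.info("stage quantify: %d measurements", len(measurements))
        profile = build_expression_profiles(
            measurements, metas, reference_id=cfg.reference_id, eff=cfg.efficiency
        )
        tables["expression_profiles"] = profile.data
        estimates, undefined = estimate_fractions(profile, cfg.volumes)
        tables["fraction_estimates"] = fractions_to_frame(estimates)
        manifest["stages"]["quantify"] = {
            "rows": len(profile.data),
            "fractions": len(estimates),
            "undefined_fractions": undefined,
        }

        present = set(profile.data["group"].unique())
        usable = [
            c for c in cfg.contrasts if {c.group_a, c.group_b} <= present
        ]
        if usable:
            log.info("stage compare: %d contrasts", len(usable))
            comparisons = run_contrasts(profile, usable)
            tables["comparisons"] = comparisons
            manifest["stages"]["compare"] = {"rows": len(comparisons)}

        stage_groups = [g for g in ("zygote", "four_cell", "blastocyst") if g in present]
        if stage_groups:
            log.info("stage profile-stage: %s", stage_groups)
            frames = []
            for g in stage_groups:
                scores = droplet_balance_scores(profile, PANEL_A, PANEL_B, g)
                scores["stage_call"] = [
                    classify_stage(s, cfg.stage_thresholds).stage_estimate
                    for s in scores["balance_score"]
                ]
                frames.append(scores)
            stage_table = pd.concat(frames, ignore_index=True)
            tables["stage_calls"] = stage_table
            manifest["stages"]["profile_stage"] = {"rows": len(stage_table)}

        if {"pre_uc", "post_uc"} <= present:
            log.info("stage uc-retention")
            pre, post = uc_frames_from_profile(profile)
            result = uc_retention(pre, post)
            tables["uc_retention"] = result.per_sequence
            manifest["stages"]["uc_retention"] = {
                "rows": len(result.per_sequence),
                "panel_mean_retention": result.panel_mean_retention,
                "pooled_retention": result.pooled_retention,
            }

    paths = write_results(tables, out_dir, metadata=manifest)
    manifest["outputs"] = {k: str(v) for k, v in paths.items()}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest


def uc_frames_from_profile(
    profile: ExpressionProfile,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract paired pre-/post-spin quantity frames for uc_retention."""
    out = []
    for group in ("pre_uc", "post_uc"):
        d = profile.data
        sub = d[(d["group"] == group) & (d["compartment"] == "extracellular")]
        out.append(
            sub.rename(columns={"rq": "quantity"})[
                ["mirna_id", "replicate", "quantity"]
            ].reset_index(drop=True)
        )
    return out[0], out[1]
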