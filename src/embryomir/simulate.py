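"""Measurement-level emulator of embryo-cohort qPCR experiments.

The generator produces complete synthetic experiments — panel assay tables
across developmental stages, treatment arms and ultracentrifugation arms, and
a 641-target array screen — with known ground truth, so every pipeline stage
is testable without external data.

Generative model (per sample, per target):

* a true linear quantity ``q`` is assembled on the RQ scale of the cohort
  lysate's reference (miR-191 lysate = 1):

  - cohort lysate data point: ``stage_profile / s_lysate``
  - conditioned-media data point:
    ``stage_profile * release_fraction / s_media + blank_contamination``
  - blank-media data point: ``blank_contamination``
  - post-spin media: pre-spin embryo-derived quantity times
    ``(1 - vesicle_fraction * spin_efficiency)``

* ``Ct = ct_anchor - log2(q) / log2(base) + Normal(0, ct_noise_sd)``,
  censored at ``max_cycles``; ``q = 0`` is always censored.

The volume scales ``s_media`` (16) and ``s_lysate`` (1.1) mirror the volume
bookkeeping of the assay workflow, so the pipeline's extracellular-fraction
estimator recovers the planted release fraction exactly at zero noise.

The Ct anchor (Ct of unit RQ) defaults to 22 cycles, emulating the assay
workflow's pre-amplification; it must sit low enough that cleavage-stage
media quantities (release fractions of a few 0.1%) stay inside the 40-cycle
window.  All pipeline outputs are delta-Ct based, so the anchor cancels from
every relative quantity (scale-invariance property).

The array screen plants targets inside their category's region of
(Ct, dRn) space with a configurable margin from every decision boundary and
*truncates* Ct noise at 3 standard deviations, which guarantees exact
category recovery whenever the margin is at least ``3 * ct_noise_sd``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .detection import CATEGORIES, DetectionThresholds
from .errors import ConfigurationError
from .qpcr_io import (
    PANEL_A,
    PANEL_B,
    PANEL_B_UC,
    ArrayDialect,
    AssayMeasurement,
    SampleMeta,
    VolumeModel,
    write_array_export,
    write_assay_table,
    write_sample_meta,
)
from .quantify import EfficiencyModel

# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

PANEL_MIRNAS = tuple(dict.fromkeys(PANEL_A.members + PANEL_B.members + PANEL_B_UC.members))


def default_stage_profile() -> dict[str, dict[str, float]]:
    """Intracellular RQ (vs miR-191) per miRNA per group.

    Shapes follow the developmental series: the conserved panel A carries a
    maternal load that decays after the zygote stage and plateaus; the
    miR-290-cluster panel B starts from a faint maternal presence, switches
    on at the 4-cell stage and surges at the blastocyst stage.  Treatment
    groups (vehicle / rhein / degenerate) share the blastocyst-stage profile;
    the degenerate cohort halves miR-294 (down-regulated in degenerate
    lysates).
    """
    base = {
        #                 zygote  four_cell  blastocyst
        "miR-20a-5p":   (1.5, 0.8, 0.7),
        "miR-30c-5p":   (2.5, 0.5, 1.5),
        "miR-142-3p":   (0.3, 0.2, 0.6),
        "miR-191-5p":   (1.0, 1.0, 1.0),
        "miR-320a-3p":  (3.0, 1.0, 0.8),
        "miR-291-3p":   (0.40, 1.2, 6.0),
        "miR-292-3p":   (0.30, 0.9, 5.0),
        "miR-293-3p":   (0.35, 1.0, 6.0),
        "miR-294-3p":   (0.50, 1.5, 8.0),
        "miR-295-3p":   (0.45, 1.3, 7.0),
        "miR-290-3p":   (0.20, 0.8, 4.0),
        "miR-290-5p":   (0.10, 0.4, 2.0),
    }
    profile: dict[str, dict[str, float]] = {}
    for m, (z, c, b) in base.items():
        profile[m] = {
            "zygote": z,
            "four_cell": c,
            "blastocyst": b,
            "vehicle": b,
            "rhein": b,
            "degenerate": b * (0.5 if m == "miR-294-3p" else 1.0),
        }
    return profile


def default_release_fractions() -> dict[str, dict[str, float]]:
    """Fraction of the intracellular quantity present in the droplet media.

    Stage defaults follow the measured extracellular percentages of the
    three-stage comparison (panel B absent at the zygote stage, ~0.1-0.4% at
    the 4-cell stage, ~3% at the blastocyst stage); treatment-group defaults
    follow the degeneracy comparison (vehicle ~5-12%, rhein and degenerate
    cohorts several-fold higher).
    """
    table = {
        #                zygote  four_cell blastocyst vehicle  rhein  degenerate
        "miR-20a-5p":   (0.0351, 0.0002, 0.0325, 0.0943, 0.1806, 0.2503),
        "miR-30c-5p":   (0.0170, 0.0389, 0.0303, 0.0836, 0.1582, 0.3489),
        "miR-142-3p":   (0.0000, 0.0123, 0.0175, 0.1183, 0.5359, 0.6495),
        "miR-191-5p":   (0.0649, 0.0024, 0.0552, 0.0726, 0.1409, 0.3610),
        "miR-320a-3p":  (0.1568, 0.1027, 0.0629, 0.0457, 0.1472, 0.7823),
        "miR-291-3p":   (0.0000, 0.0040, 0.0317, 0.1005, 0.1817, 0.3434),
        "miR-292-3p":   (0.0000, 0.0014, 0.0293, 0.0497, 0.1049, 0.1904),
        "miR-293-3p":   (0.0000, 0.0021, 0.0322, 0.0583, 0.1596, 0.5101),
        "miR-294-3p":   (0.0000, 0.0026, 0.0301, 0.0519, 0.1010, 0.2582),
        "miR-295-3p":   (0.0000, 0.0029, 0.0257, 0.0498, 0.1407, 0.6291),
        "miR-290-3p":   (0.0000, 0.0030, 0.0300, 0.0500, 0.1000, 0.3000),
        "miR-290-5p":   (0.0000, 0.0030, 0.0300, 0.0500, 0.1000, 0.3000),
    }
    groups = ("zygote", "four_cell", "blastocyst", "vehicle", "rhein", "degenerate")
    return {m: dict(zip(groups, vals)) for m, vals in table.items()}


def default_blank_contamination() -> dict[str, float]:
    """Trace linear quantities (per data point) amplifying in blank media."""
    return {
        "miR-20a-5p": 2e-4,
        "miR-30c-5p": 1e-4,
        "miR-142-3p": 3e-4,
        "miR-191-5p": 1e-4,
    }


def default_vesicle_fraction() -> dict[str, float]:
    """Fraction of each sequence encapsulated in spin-sensitive vesicles."""
    return {m: 0.5 for m in PANEL_MIRNAS}


@dataclass
class SimConfig:
    """Generative parameters; a fixed seed gives byte-identical output."""

    stages: tuple[str, ...] = ("zygote", "four_cell", "blastocyst")
    treatments: tuple[str, ...] = ()
    include_uc: bool = False
    stage_profile: dict[str, dict[str, float]] = field(default_factory=default_stage_profile)
    release_fraction: dict[str, dict[str, float]] = field(default_factory=default_release_fractions)
    blank_contamination: dict[str, float] = field(default_factory=default_blank_contamination)
    water_contamination: dict[str, float] = field(default_factory=lambda: {"miR-191-5p": 5e-5})
    vesicle_fraction: dict[str, float] = field(default_factory=default_vesicle_fraction)
    spin_efficiency: float = 0.8
    ct_noise_sd: float = 0.25
    max_cycles: float = 40.0
    ct_anchor: float = 22.0
    efficiency_base: float = 2.0
    n_replicates: int = 3
    seed: int = 0
    volumes: VolumeModel = field(default_factory=VolumeModel)
    #: heavy-tailed release multiplier applied to one replicate of each
    #: degeneracy arm, emulating occasional debris capture during collection
    debris_outlier: bool = False
    debris_multiplier: float = 10.0

    def mirnas(self) -> tuple[str, ...]:
        return tuple(self.stage_profile)

    def validate(self) -> None:
        errors: list[str] = []
        if self.ct_noise_sd < 0:
            errors.append("ct_noise_sd must be >= 0")
        if self.n_replicates < 1:
            errors.append("n_replicates must be >= 1")
        if not (0.0 <= self.spin_efficiency <= 1.0):
            errors.append("spin_efficiency must be in [0, 1]")
        for m in self.mirnas():
            rel = self.release_fraction.get(m)
            if rel is None:
                errors.append(f"release_fraction missing for {m}")
                continue
            for group, frac in rel.items():
                if not (0.0 <= frac <= 1.0):
                    errors.append(f"release_fraction[{m}][{group}]={frac} outside [0, 1]")
            vf = self.vesicle_fraction.get(m)
            if vf is None:
                errors.append(f"vesicle_fraction missing for {m}")
            elif not (0.0 <= vf <= 1.0):
                errors.append(f"vesicle_fraction[{m}]={vf} outside [0, 1]")
        if errors:
            raise ConfigurationError("; ".join(errors))

    def efficiency(self) -> EfficiencyModel:
        return EfficiencyModel(self.efficiency_base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["volumes"] = dataclasses.asdict(self.volumes)
        return d


@dataclass
class SyntheticDataset:
    """Emitted measurement tables with their ground truth."""

    measurements: list[AssayMeasurement]
    metas: list[SampleMeta]
    truth: pd.DataFrame
    config: SimConfig
    array_conditioned: list[AssayMeasurement] = field(default_factory=list)
    array_blank: list[AssayMeasurement] = field(default_factory=list)

    def to_files(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        if self.measurements:
            paths["assays"] = write_assay_table(self.measurements, out_dir / "assays.tsv")
            paths["sample_meta"] = write_sample_meta(self.metas, out_dir / "sample_meta.tsv")
        if self.array_conditioned:
            paths["array_conditioned"] = write_array_export(
                self.array_conditioned, out_dir / "array_conditioned.csv"
            )
            paths["array_blank"] = write_array_export(
                self.array_blank, out_dir / "array_blank.csv"
            )
        truth_path = out_dir / "ground_truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["ground_truth"] = truth_path
        cfg_path = out_dir / "sim_config.yaml"
        cfg_path.write_text(yaml.safe_dump(self.config.to_dict(), sort_keys=True))
        paths["sim_config"] = cfg_path
        return paths


# --------------------------------------------------------------------------
# assay-table experiments
# --------------------------------------------------------------------------


def _measure_ct(
    q: float, cfg: SimConfig, rng: np.random.Generator
) -> float | None:
    """True quantity -> noisy censored Ct."""
    if q <= 0.0:
        return None
    ct = cfg.ct_anchor - math.log2(q) / math.log2(cfg.efficiency_base)
    if cfg.ct_noise_sd > 0:
        ct += rng.normal(0.0, cfg.ct_noise_sd)
    if ct >= cfg.max_cycles:
        return None
    return float(max(ct, 1e-6))


def _stage_of_group(group: str) -> str | None:
    return {
        "zygote": "zygote",
        "four_cell": "four_to_eight_cell",
        "blastocyst": "blastocyst",
        "vehicle": "blastocyst",
        "rhein": "blastocyst",
        "degenerate": "blastocyst",
        "pre_uc": "blastocyst",
        "post_uc": "blastocyst",
    }.get(group)


def simulate_experiment(cfg: SimConfig | None = None) -> SyntheticDataset:
    """Generate tidy assay tables for the configured stage/treatment/UC arms.

    Every (group, replicate) run emits a cohort-lysate, conditioned-media and
    blank-media sample (UC arms: paired pre-/post-spin media only, over the
    UC panel variant), with ground truth recording the planted quantities and
    release fractions.  Deterministic under a fixed seed.
    """
    if cfg is None:
        cfg = SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    vm = cfg.volumes
    measurements: list[AssayMeasurement] = []
    metas: list[SampleMeta] = []
    truth_rows: list[dict] = []

    groups = list(cfg.stages) + list(cfg.treatments)
    for group in groups:
        stage = _stage_of_group(group)
        treatment = group if group in ("vehicle", "rhein", "degenerate") else "none"
        outlier_rep = (
            int(rng.integers(1, cfg.n_replicates + 1))
            if (cfg.debris_outlier and group in ("rhein", "degenerate"))
            else None
        )
        for rep in range(1, cfg.n_replicates + 1):
            lys_id = f"{group}_lysate_r{rep}"
            med_id = f"{group}_media_r{rep}"
            blank_id = f"{group}_blank_r{rep}"
            metas.append(SampleMeta(lys_id, "cohort_lysate", stage, treatment, rep))
            metas.append(SampleMeta(med_id, "conditioned_media", stage, treatment, rep))
            metas.append(SampleMeta(blank_id, "blank_media", stage, treatment, rep))
            debris = cfg.debris_multiplier if rep == outlier_rep else 1.0
            for m in cfg.mirnas():
                intra = cfg.stage_profile[m].get(group, 0.0)
                release = min(1.0, cfg.release_fraction[m].get(group, 0.0) * debris)
                contam = cfg.blank_contamination.get(m, 0.0)
                q_lys = intra / vm.scale_lysate
                q_med = intra * release / vm.scale_media + contam
                q_blank = contam
                measurements.append(
                    AssayMeasurement(m, lys_id, _measure_ct(q_lys, cfg, rng))
                )
                measurements.append(
                    AssayMeasurement(m, med_id, _measure_ct(q_med, cfg, rng))
                )
                measurements.append(
                    AssayMeasurement(m, blank_id, _measure_ct(q_blank, cfg, rng))
                )
                truth_rows.append(
                    {
                        "mirna_id": m,
                        "group": group,
                        "replicate": rep,
                        "true_intracellular_rq": intra,
                        "true_release_fraction": release,
                        "true_media_point_q": q_med,
                        "blank_contamination": contam,
                        "expected_percent": 100.0 * release,
                    }
                )
        if cfg.water_contamination:
            water_id = f"{group}_water_r1"
            metas.append(SampleMeta(water_id, "water", None, "none", 1))
            for m, q in cfg.water_contamination.items():
                measurements.append(
                    AssayMeasurement(m, water_id, _measure_ct(q, cfg, rng))
                )

    if cfg.include_uc:
        uc_members = PANEL_B_UC.members
        for rep in range(1, cfg.n_replicates + 1):
            pre_id = f"pre_uc_media_r{rep}"
            post_id = f"post_uc_media_r{rep}"
            metas.append(
                SampleMeta(pre_id, "conditioned_media", "blastocyst", "pre_uc", rep)
            )
            metas.append(
                SampleMeta(post_id, "conditioned_media", "blastocyst", "post_uc", rep)
            )
            for m in uc_members:
                intra = cfg.stage_profile[m]["blastocyst"]
                release = cfg.release_fraction[m]["blastocyst"]
                q_pre = intra * release / vm.scale_media
                surviving = 1.0 - cfg.vesicle_fraction[m] * cfg.spin_efficiency
                q_post = q_pre * surviving
                measurements.append(
                    AssayMeasurement(m, pre_id, _measure_ct(q_pre, cfg, rng))
                )
                measurements.append(
                    AssayMeasurement(m, post_id, _measure_ct(q_post, cfg, rng))
                )
                truth_rows.append(
                    {
                        "mirna_id": m,
                        "group": "uc",
                        "replicate": rep,
                        "true_intracellular_rq": intra,
                        "true_release_fraction": release,
                        "true_media_point_q": q_pre,
                        "blank_contamination": 0.0,
                        "expected_percent": 100.0 * surviving,  # expected retention %
                    }
                )

    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(measurements, metas, truth, cfg)


# --------------------------------------------------------------------------
# array screen with planted categories
# --------------------------------------------------------------------------

DEFAULT_PLANTED_COUNTS: dict[str, int] = {
    "conditioned_exclusive_strict": 39,
    "conditioned_exclusive": 42,
    "both_elevated": 57,
    "both_lower": 3,
    "blank_exclusive": 2,
    "undetected": 498,
}


def _truncnorm(rng: np.random.Generator, sd: float) -> float:
    """Gaussian noise truncated (clipped) at +/- 3 sd; keeps planted margins."""
    if sd <= 0:
        return 0.0
    return float(np.clip(rng.normal(0.0, sd), -3.0 * sd, 3.0 * sd))


def simulate_array_screen(
    cfg: SimConfig | None = None,
    n_targets: int = 641,
    planted_counts: Mapping[str, int] | None = None,
    margin: float | None = None,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> SyntheticDataset:
    """Plant targets inside category regions of (Ct, dRn) space, with margin.

    ``margin`` (cycles; default ``3 * ct_noise_sd``) is the guaranteed
    distance of every planted base Ct from every Ct decision boundary; Ct
    noise is truncated at 3 sd, so recovery of the planted categories is
    exact whenever ``margin >= 3 * ct_noise_sd``.  dRn values are drawn
    inside bands separated from both dRn thresholds.  ``both_other`` (the
    exact-tie category) cannot be planted with a positive margin.
    """
    if cfg is None:
        cfg = SimConfig()
    counts = dict(planted_counts or DEFAULT_PLANTED_COUNTS)
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ConfigurationError(f"unknown planted categories: {sorted(unknown)}")
    if counts.get("both_other"):
        raise ConfigurationError(
            "both_other is an exact-tie category and cannot be planted with a margin"
        )
    if sum(counts.values()) != n_targets:
        raise ConfigurationError(
            f"planted counts sum to {sum(counts.values())}, expected n_targets={n_targets}"
        )
    if margin is None:
        margin = 3.0 * cfg.ct_noise_sd if cfg.ct_noise_sd > 0 else 0.5
    if margin <= 0:
        raise ConfigurationError("margin must be > 0 (degenerate at-threshold plants)")
    if 3.0 * cfg.ct_noise_sd > margin:
        raise ConfigurationError(
            f"margin {margin} smaller than 3 * ct_noise_sd = {3 * cfg.ct_noise_sd}; "
            "category recovery would not be guaranteed"
        )
    th = thresholds
    if th.ct_max - margin <= 20.0 + margin:
        raise ConfigurationError("margin too large for the detectable Ct range")

    rng = np.random.default_rng(cfg.seed)
    sd = cfg.ct_noise_sd

    def detected_ct() -> float:
        return float(rng.uniform(20.0, th.ct_max - margin))

    def high_drn() -> float:
        return float(rng.uniform(th.drn_min + 0.4, th.drn_min + 0.9))

    def mid_drn() -> float:  # above trace, below detection
        lo = th.drn_trace + 0.25 * (th.drn_min - th.drn_trace)
        hi = th.drn_min - 0.25 * (th.drn_min - th.drn_trace)
        return float(rng.uniform(lo, hi))

    def trace_drn() -> float:
        return float(rng.uniform(0.0, 0.5 * th.drn_trace))

    plants: list[tuple[str, float | None, float, float | None, float]] = []
    for category, n in counts.items():
        for _ in range(n):
            if category == "conditioned_exclusive_strict":
                plants.append((category, detected_ct(), high_drn(), None, trace_drn()))
            elif category == "conditioned_exclusive":
                plants.append((category, detected_ct(), high_drn(), None, mid_drn()))
            elif category == "blank_exclusive":
                plants.append((category, None, trace_drn(), detected_ct(), high_drn()))
            elif category == "both_elevated":
                ct_b = float(rng.uniform(24.0, min(29.0, th.ct_max - margin - 5.0)))
                dct = float(rng.uniform(-3.0, th.delta_ct_margin - 2.0 * margin))
                plants.append((category, ct_b + dct, high_drn(), ct_b, high_drn()))
            elif category == "both_lower":
                lo = th.delta_ct_margin + 2.0 * margin
                ct_b = float(rng.uniform(21.0, th.ct_max - margin - lo - 2.0))
                dct = float(rng.uniform(lo, lo + 2.0))
                plants.append((category, ct_b + dct, high_drn(), ct_b, high_drn()))
            elif category == "undetected":
                if rng.random() < 0.5:
                    plants.append((category, None, trace_drn(), None, trace_drn()))
                else:  # observed but past the detection cutoff
                    hi_ct = float(rng.uniform(th.ct_max + margin, cfg.max_cycles - margin))
                    plants.append((category, hi_ct, mid_drn(), None, trace_drn()))
            else:
                raise ConfigurationError(f"cannot plant category {category!r}")

    order = rng.permutation(len(plants))
    cond: list[AssayMeasurement] = []
    blank: list[AssayMeasurement] = []
    truth_rows = []
    for i, idx in enumerate(order):
        category, ct_c, drn_c, ct_b, drn_b = plants[idx]
        name = f"syn-miR-{i + 1:04d}"
        ct_c_obs = None if ct_c is None else ct_c + _truncnorm(rng, sd)
        ct_b_obs = None if ct_b is None else ct_b + _truncnorm(rng, sd)
        cond.append(AssayMeasurement(name, "array_conditioned", ct_c_obs, drn_c))
        blank.append(AssayMeasurement(name, "array_blank", ct_b_obs, drn_b))
        truth_rows.append({"mirna_id": name, "true_category": category})

    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(
        measurements=[],
        metas=[],
        truth=truth,
        config=cfg,
        array_conditioned=cond,
        array_blank=blank,
    )
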