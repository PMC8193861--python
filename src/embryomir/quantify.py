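"""Reference-normalized relative quantification of censored Ct data.

The delta-Ct method: a target's relative quantity against an endogenous
reference is ``RQ = base^(Ct_ref - Ct_target)`` with ``base`` the per-cycle
amplification efficiency (2.0 = perfect doubling).  Media samples are
normalized to the *intracellular* reference of the paired cohort lysate
(default miR-191-5p), which also sidesteps the reference assay's reported
trace amplification in blank media.  Censored targets carry RQ = 0 with the
detection flag down — non-amplification is treated as absence, never as a
numeric Ct.

Blank-media background is subtracted in linear quantity space, after volume
matching and before normalization: subtraction of contaminating template is
physically linear, so ``q_adjusted = max(0, q_conditioned - q_blank)``.

The extracellular fraction of a sequence scales the media and lysate data
points back to whole-droplet and whole-lysate quantities:

    percent = 100 * (RQ_media * s_media) / (RQ_lysate * s_lysate)

with ``s_media = droplet_volume / media_equivalent_per_datapoint`` (16 by
default) and ``s_lysate = lysate_total / rt_aliquot`` (1.1 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AnalysisError,
    ConfigurationError,
    UndefinedFractionError,
    UsageError,
)
from .qpcr_io import (
    AssayMeasurement,
    SampleMeta,
    VolumeModel,
    canonical_mirna_id,
    index_measurements,
)

DEFAULT_REFERENCE = "miR-191-5p"


@dataclass(frozen=True)
class EfficiencyModel:
    """Per-cycle amplification efficiency; one source for every exponentiation."""

    base: float = 2.0

    def __post_init__(self):
        if not (1.0 < self.base <= 2.0):
            raise ConfigurationError("efficiency base must be in (1, 2]")

    def fold(self, delta_ct: float) -> float:
        return self.base ** delta_ct


def linear_quantity(ct: float | None, eff: EfficiencyModel = EfficiencyModel()) -> float:
    """Linear template quantity ``base^(-Ct)``; censored Ct maps to 0."""
    if ct is None:
        return 0.0
    return eff.base ** (-ct)


def relative_quantity(
    ct_target: float | None,
    ct_ref: float | None,
    eff: EfficiencyModel = EfficiencyModel(),
) -> float:
    """Delta-Ct relative quantity ``base^(Ct_ref - Ct_target)``.

    A censored target yields RQ = 0 (undetected).  A censored reference is an
    analysis error: the endogenous reference must amplify.
    """
    if ct_ref is None:
        raise AnalysisError("reference assay is censored; reference must amplify")
    if ct_target is None:
        return 0.0
    return eff.fold(ct_ref - ct_target)


def background_correct(q_cond: float, q_blank: float) -> float:
    """Subtract blank-media background in linear quantity space, clamped at 0."""
    if q_cond < 0 or q_blank < 0:
        raise UsageError("linear quantities must be nonnegative")
    return max(0.0, q_cond - q_blank)


def extracellular_fraction(
    media_rq: float,
    lysate_rq: float,
    vm: VolumeModel = VolumeModel(),
) -> float:
    """Single-replicate extracellular percent of the cohort-lysate quantity.

    Both RQs must be computed against the same reference sample.  An
    intracellularly undetected target (lysate RQ = 0) has no defined fraction.
    A media-undetected target contributes 0 percent.
    """
    if media_rq < 0 or lysate_rq < 0:
        raise UsageError("relative quantities must be nonnegative")
    if lysate_rq == 0:
        raise UndefinedFractionError(
            "target undetected in cohort lysate; extracellular fraction undefined"
        )
    if media_rq == 0:
        return 0.0
    return 100.0 * (media_rq * vm.scale_media) / (lysate_rq * vm.scale_lysate)


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sample SD / sqrt n) over >= 2 replicate values."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise UsageError("SEM requires at least 2 replicate values")
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(vals.size))


# --------------------------------------------------------------------------
# profile assembly over a whole experiment
# --------------------------------------------------------------------------


@dataclass
class ExpressionProfile:
    """Tidy per-(miRNA, group, replicate, compartment) relative quantities.

    ``data`` columns: mirna_id, group, replicate, compartment
    ("intracellular" or "extracellular"), rq, detected.
    """

    data: pd.DataFrame
    reference_id: str = DEFAULT_REFERENCE
    efficiency: EfficiencyModel = field(default_factory=EfficiencyModel)

    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["group"].unique()))

    def replicate_values(
        self, mirna_id: str, group: str, compartment: str
    ) -> pd.DataFrame:
        d = self.data
        sel = d[
            (d["mirna_id"] == mirna_id)
            & (d["group"] == group)
            & (d["compartment"] == compartment)
        ]
        return sel.sort_values("replicate")


@dataclass(frozen=True)
class FractionEstimate:
    """Extracellular abundance as percent of the cohort lysate, with SEM."""

    mirna_id: str
    group: str
    percent: float
    sem: float

    def __post_init__(self):
        if self.percent < 0 or self.sem < 0:
            raise UsageError("percent and sem must be nonnegative")


def build_expression_profiles(
    measurements: Iterable[AssayMeasurement],
    metas: Iterable[SampleMeta],
    reference_id: str = DEFAULT_REFERENCE,
    eff: EfficiencyModel = EfficiencyModel(),
    background: bool = True,
) -> ExpressionProfile:
    """Assemble intracellular and extracellular RQ profiles for an experiment.

    For every (group, replicate) with a cohort lysate, the lysate's reference
    Ct anchors both compartments.  Media quantities are blank-corrected in
    linear space (when a paired blank-media sample exists and ``background``
    is true) before normalization.  Groups without a lysate (e.g. the
    ultracentrifugation arms) are emitted with raw linear quantities as their
    extracellular values; ratios between such groups are reference-free.
    """
    reference_id = canonical_mirna_id(reference_id)
    by_key = index_measurements(measurements)
    metas = list(metas)
    targets = sorted({m.mirna_id for m in by_key.values()})

    samples: dict[tuple[str, int, str], SampleMeta] = {}
    for sm in metas:
        samples[(sm.group, sm.replicate, sm.sample_type)] = sm

    group_reps = sorted(
        {(sm.group, sm.replicate) for sm in metas if sm.sample_type != "water"}
    )

    rows: list[dict] = []
    for group, rep in group_reps:
        lys = samples.get((group, rep, "cohort_lysate"))
        med = samples.get((group, rep, "conditioned_media"))
        blank = samples.get((group, rep, "blank_media"))

        q_ref = None
        if lys is not None:
            ref_m = by_key.get((lys.sample_id, reference_id))
            if ref_m is None or ref_m.ct is None:
                raise AnalysisError(
                    f"reference {reference_id} missing or censored in lysate "
                    f"{lys.sample_id}"
                )
            q_ref = linear_quantity(ref_m.ct, eff)

        for t in targets:
            if lys is not None:
                m = by_key.get((lys.sample_id, t))
                if m is not None:
                    q = linear_quantity(m.ct, eff)
                    rows.append(
                        {
                            "mirna_id": t,
                            "group": group,
                            "replicate": rep,
                            "compartment": "intracellular",
                            "rq": q / q_ref,
                            "detected": m.ct is not None,
                        }
                    )
            if med is not None:
                m = by_key.get((med.sample_id, t))
                if m is not None:
                    q = linear_quantity(m.ct, eff)
                    if background and blank is not None:
                        bm = by_key.get((blank.sample_id, t))
                        qb = linear_quantity(bm.ct, eff) if bm is not None else 0.0
                        q = background_correct(q, qb)
                    rq = q / q_ref if q_ref is not None else q
                    rows.append(
                        {
                            "mirna_id": t,
                            "group": group,
                            "replicate": rep,
                            "compartment": "extracellular",
                            "rq": rq,
                            "detected": m.ct is not None,
                        }
                    )
    data = pd.DataFrame(
        rows,
        columns=["mirna_id", "group", "replicate", "compartment", "rq", "detected"],
    )
    return ExpressionProfile(data=data, reference_id=reference_id, efficiency=eff)


def estimate_fractions(
    profile: ExpressionProfile,
    vm: VolumeModel = VolumeModel(),
    groups: Sequence[str] | None = None,
) -> tuple[list[FractionEstimate], list[str]]:
    """Per-(miRNA, group) extracellular fraction estimates with SEM.

    Replicate fractions are computed pairwise (media vs lysate of the same
    replicate) and aggregated as mean +/- SEM.  Targets undetected
    intracellularly in any replicate have no defined fraction; they are
    skipped and reported in the second return value.
    """
    d = profile.data
    estimates: list[FractionEstimate] = []
    undefined: list[str] = []
    use_groups = groups or sorted(d["group"].unique())
    for group in use_groups:
        gd = d[d["group"] == group]
        intra = gd[gd["compartment"] == "intracellular"]
        extra = gd[gd["compartment"] == "extracellular"]
        if intra.empty or extra.empty:
            continue
        for t in sorted(extra["mirna_id"].unique()):
            lys = intra[intra["mirna_id"] == t].set_index("replicate")["rq"]
            med = extra[extra["mirna_id"] == t].set_index("replicate")["rq"]
            reps = sorted(set(lys.index) & set(med.index))
            if len(reps) < 2:
                continue
            try:
                percents = [
                    extracellular_fraction(float(med[r]), float(lys[r]), vm)
                    for r in reps
                ]
            except UndefinedFractionError:
                undefined.append(f"{t}:{group}")
                continue
            mean, sem = aggregate_replicates(percents)
            estimates.append(FractionEstimate(t, group, mean, sem))
    return estimates, undefined


def fractions_to_frame(estimates: Sequence[FractionEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [e.mirna_id for e in estimates],
            "group": [e.group for e in estimates],
            "percent": [e.percent for e in estimates],
            "sem": [e.sem for e in estimates],
        }
    )
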