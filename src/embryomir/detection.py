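"""Presence/absence and exclusivity calling for a paired conditioned/blank array.

A target is *detected* in a sample when its Ct is observed below ``ct_max``
(strictly) and its dRn exceeds ``drn_min`` (strictly) — the screen's guard
against false positives.  Each screened target then receives exactly one
category:

========================== =====================================================
conditioned_exclusive       detected only in the conditioned droplet
conditioned_exclusive_strict as above, and the blank shows minimal-or-no signal
                            (Ct censored or > ct_max, dRn < drn_trace) — the
                            stringent short list
blank_exclusive             detected only in the blank droplet
both_elevated               detected in both, Ct_cond - Ct_blank < margin
both_lower                  detected in both, Ct_cond - Ct_blank > margin
both_other                  detected in both, difference exactly at the margin
undetected                  detected in neither
========================== =====================================================

``mode="canonical"`` (default) uses the single coherent "detected" predicate
above; ``mode="literal"`` reproduces the screen's printed set expressions
verbatim for auditing (exclusivity of the conditioned sample via
``Ct_blank > ct_max OR dRn_blank < drn_min``; of the blank via
``Ct_cond > ct_max AND dRn_cond < drn_min``).  The two readings coincide except
on pathological boundary rows; in literal mode a one-sided detection whose
printed expression fails falls into ``both_other`` so the category partition
is preserved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, IntegrityError, UsageError
from .qpcr_io import AssayMeasurement

CATEGORIES = (
    "conditioned_exclusive",
    "conditioned_exclusive_strict",
    "blank_exclusive",
    "both_elevated",
    "both_lower",
    "both_other",
    "undetected",
)

#: categories implying detection in the conditioned sample
_DETECTED_COND = frozenset(
    {"conditioned_exclusive", "conditioned_exclusive_strict", "both_elevated",
     "both_lower", "both_other"}
)
_DETECTED_BLANK = frozenset(
    {"blank_exclusive", "both_elevated", "both_lower", "both_other"}
)


@dataclass(frozen=True)
class DetectionThresholds:
    """Detection and exclusivity thresholds of the array screen."""

    ct_max: float = 35.0        # cycles; detected requires Ct strictly below
    drn_min: float = 0.5        # normalized-reporter floor for detection
    delta_ct_margin: float = 5.0  # cycles separating "elevated" from "lower"
    drn_trace: float = 0.1      # dRn ceiling for the stringent short list
    max_cycles: float = 40.0    # run cycle limit (censoring point)

    def __post_init__(self):
        if not (0 < self.ct_max <= self.max_cycles):
            raise ConfigurationError("require 0 < ct_max <= max_cycles")
        if not (0 <= self.drn_trace < self.drn_min):
            raise ConfigurationError("require 0 <= drn_trace < drn_min")
        if self.delta_ct_margin <= 0:
            raise ConfigurationError("delta_ct_margin must be > 0")


@dataclass(frozen=True)
class DetectionCall:
    """Category assignment for one target of a conditioned/blank pair."""

    mirna_id: str
    category: str
    detected_conditioned: bool
    detected_blank: bool


@dataclass(frozen=True)
class ClassificationSummary:
    """Category partition, totals, and the stringent short list for one screen."""

    counts: dict[str, int]
    short_list: tuple[str, ...]
    excluded_despite_elevation: tuple[str, ...]
    n_screened: int
    n_detected_conditioned: int
    n_detected_blank: int
    calls: tuple[DetectionCall, ...] = field(repr=False, default=())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": list(CATEGORIES),
             "count": [self.counts[c] for c in CATEGORIES]}
        )

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mirna_id": [c.mirna_id for c in self.calls],
                "category": [c.category for c in self.calls],
                "detected_conditioned": [c.detected_conditioned for c in self.calls],
                "detected_blank": [c.detected_blank for c in self.calls],
            }
        )


def is_detected(m: AssayMeasurement, th: DetectionThresholds) -> bool:
    """Detected: Ct observed strictly below ct_max and dRn strictly above drn_min."""
    if m.delta_rn is None:
        raise UsageError(f"{m.mirna_id}: array detection requires a dRn value")
    return m.ct is not None and m.ct < th.ct_max and m.delta_rn > th.drn_min


def _ct_above(m: AssayMeasurement, limit: float) -> bool:
    """Censored-or-greater comparison: censored Ct counts as above any limit."""
    return m.ct is None or m.ct > limit


def call_detection(
    cond: AssayMeasurement,
    blank: AssayMeasurement,
    th: DetectionThresholds = DetectionThresholds(),
    mode: str = "canonical",
) -> DetectionCall:
    """Classify one target from its paired conditioned and blank measurements."""
    if cond.mirna_id != blank.mirna_id:
        raise UsageError(
            f"mismatched targets: {cond.mirna_id!r} vs {blank.mirna_id!r}"
        )
    if mode not in ("canonical", "literal"):
        raise UsageError("mode must be 'canonical' or 'literal'")
    det_c = is_detected(cond, th)
    det_b = is_detected(blank, th)

    if det_c and det_b:
        # both Cts are observed here by the detection predicate
        dct = cond.ct - blank.ct  # type: ignore[operator]
        if dct < th.delta_ct_margin:
            category = "both_elevated"
        elif dct > th.delta_ct_margin:
            category = "both_lower"
        else:
            category = "both_other"
    elif det_c:
        if mode == "literal" and not (
            _ct_above(blank, th.ct_max) or blank.delta_rn < th.drn_min
        ):
            category = "both_other"  # printed union fails on this boundary row
        elif _ct_above(blank, th.ct_max) and blank.delta_rn < th.drn_trace:
            category = "conditioned_exclusive_strict"
        else:
            category = "conditioned_exclusive"
    elif det_b:
        if mode == "literal" and not (
            _ct_above(cond, th.ct_max) and cond.delta_rn < th.drn_min
        ):
            category = "both_other"  # printed intersection fails here
        else:
            category = "blank_exclusive"
    else:
        category = "undetected"
    return DetectionCall(cond.mirna_id, category, det_c, det_b)


def classify_array(
    cond: Sequence[AssayMeasurement],
    blank: Sequence[AssayMeasurement],
    th: DetectionThresholds = DetectionThresholds(),
    mode: str = "canonical",
    join: str = "censor_missing",
) -> ClassificationSummary:
    """Aggregate per-target calls over a conditioned/blank array pair.

    ``join="censor_missing"`` treats a target absent from one list as censored
    with dRn 0 there; ``join="strict"`` requires identical target sets.
    The summary also reports the *excluded despite elevation* set: targets
    detected in both samples at elevated conditioned levels, excluded from the
    exclusive list because of their blank-media presence.
    """
    if join not in ("censor_missing", "strict"):
        raise UsageError("join must be 'censor_missing' or 'strict'")
    cond_by_id = _index_by_target(cond, "conditioned")
    blank_by_id = _index_by_target(blank, "blank")
    if join == "strict" and set(cond_by_id) != set(blank_by_id):
        only = set(cond_by_id) ^ set(blank_by_id)
        raise IntegrityError(
            f"target sets differ between samples (strict join): {sorted(only)[:5]}..."
        )
    targets = list(cond_by_id)
    targets += [t for t in blank_by_id if t not in cond_by_id]

    calls = []
    for t in targets:
        c = cond_by_id.get(t) or AssayMeasurement(t, "conditioned", None, 0.0)
        b = blank_by_id.get(t) or AssayMeasurement(t, "blank", None, 0.0)
        calls.append(call_detection(c, b, th, mode=mode))

    counts = Counter(c.category for c in calls)
    full_counts = {cat: counts.get(cat, 0) for cat in CATEGORIES}
    short_list = tuple(
        sorted(c.mirna_id for c in calls if c.category == "conditioned_exclusive_strict")
    )
    excluded = tuple(sorted(c.mirna_id for c in calls if c.category == "both_elevated"))
    return ClassificationSummary(
        counts=full_counts,
        short_list=short_list,
        excluded_despite_elevation=excluded,
        n_screened=len(calls),
        n_detected_conditioned=sum(c.detected_conditioned for c in calls),
        n_detected_blank=sum(c.detected_blank for c in calls),
        calls=tuple(calls),
    )


def _index_by_target(
    measurements: Iterable[AssayMeasurement], label: str
) -> dict[str, AssayMeasurement]:
    out: dict[str, AssayMeasurement] = {}
    for m in measurements:
        if m.mirna_id in out:
            raise IntegrityError(f"duplicate target {m.mirna_id!r} in {label} sample")
        out[m.mirna_id] = m
    return out
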