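"""Panel-level summaries: stage gauge and ultracentrifugation retention.

The *balance score* formalizes "tracking the shift of the media miRNA
composition toward the miR-290 cluster" as a single number:

    score = log2((mean RQ over panel B + pseudocount) /
                 (mean RQ over panel A + pseudocount))

Panel B (miR-290 cluster) is silent in media conditioned by zygotes, faint at
the cleavage stages and dominant by the blastocyst stage, so the score climbs
monotonically with development; two thresholds map it to a stage call.  The
score and the two-threshold classifier are this package's formalization of
the stage gauge (an extension over per-sequence testing); the default
thresholds are midpoints of noise-free simulator scores for the three stages.

*Retention* after ultracentrifugation is the pure quantity ratio
post-spin / pre-spin per sequence; depletion suggests a vesicle-encapsulated
fraction.  Because pre and post come from the same droplet and dilution, any
common normalization reference or dilution factor cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import math

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError, UsageError
from .qpcr_io import PANEL_A, PANEL_B, PANEL_B_UC, PanelDefinition, canonical_mirna_id
from .quantify import ExpressionProfile, aggregate_replicates
from .stats import TTestResult, t_test_paired

PSEUDOCOUNT_DEFAULT = 1e-6  # RQ units; floor for all-zero panels


@dataclass(frozen=True)
class PanelProfile:
    """Mean and SEM of each panel member's RQ in one compartment and group."""

    panel: PanelDefinition
    compartment: str
    group: str
    means: dict[str, float]
    sems: dict[str, float]
    replicates: pd.DataFrame = field(repr=False, default=None)  # mirna_id, replicate, rq

    @property
    def panel_mean(self) -> float:
        return float(np.mean([self.means[m] for m in self.panel.members]))


def build_panel_profile(
    profile: ExpressionProfile,
    panel: PanelDefinition,
    compartment: str,
    group: str,
) -> PanelProfile:
    """Summarize an expression profile over one panel; members must all be present."""
    if compartment not in ("intracellular", "extracellular"):
        raise UsageError("compartment must be 'intracellular' or 'extracellular'")
    means: dict[str, float] = {}
    sems: dict[str, float] = {}
    frames = []
    for member in panel.members:
        sel = profile.replicate_values(member, group, compartment)
        if sel.empty:
            raise ConfigurationError(
                f"panel {panel.name}: member {member} missing from profile "
                f"({group}, {compartment})"
            )
        mean, sem = aggregate_replicates(sel["rq"].to_list())
        means[member] = mean
        sems[member] = sem
        frames.append(sel[["mirna_id", "replicate", "rq"]])
    return PanelProfile(
        panel=panel,
        compartment=compartment,
        group=group,
        means=means,
        sems=sems,
        replicates=pd.concat(frames, ignore_index=True),
    )


def panel_balance_score(
    profile_a: PanelProfile,
    profile_b: PanelProfile,
    pseudocount: float = PSEUDOCOUNT_DEFAULT,
) -> float:
    """log2 ratio of panel-B to panel-A mean RQ, stabilized by a pseudocount."""
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    return balance_score_from_means(profile_a.panel_mean, profile_b.panel_mean, pseudocount)


def balance_score_from_means(
    mean_a: float, mean_b: float, pseudocount: float = PSEUDOCOUNT_DEFAULT
) -> float:
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    if mean_a < 0 or mean_b < 0:
        raise UsageError("panel means must be nonnegative")
    return math.log2((mean_b + pseudocount) / (mean_a + pseudocount))


@dataclass(frozen=True)
class StageThresholds:
    """Two ordered cut points on the balance score separating the three calls.

    Defaults are midpoints of the noise-free default-generator scores
    (zygote ~ -13.1, cleavage ~ -3.0, blastocyst ~ +2.4 on media RQ profiles).
    """

    low: float = -8.0
    high: float = -0.3

    def __post_init__(self):
        if not self.low < self.high:
            raise ConfigurationError("stage thresholds must be strictly ordered")


@dataclass(frozen=True)
class StageCall:
    """Stage estimate from a media balance score."""

    balance_score: float
    stage_estimate: str
    thresholds: StageThresholds


def classify_stage(
    score: float, thresholds: StageThresholds = StageThresholds()
) -> StageCall:
    """Map a balance score to {zygote, cleavage, blastocyst}.

    A score exactly at a threshold is assigned to the higher stage.
    """
    if score >= thresholds.high:
        stage = "blastocyst"
    elif score >= thresholds.low:
        stage = "cleavage"
    else:
        stage = "zygote"
    return StageCall(score, stage, thresholds)


def droplet_balance_scores(
    profile: ExpressionProfile,
    panel_a: PanelDefinition,
    panel_b: PanelDefinition,
    group: str,
    pseudocount: float = PSEUDOCOUNT_DEFAULT,
) -> pd.DataFrame:
    """Per-droplet (per-replicate) balance scores for one group's media profile."""
    d = profile.data
    sub = d[(d["group"] == group) & (d["compartment"] == "extracellular")]
    if sub.empty:
        raise ConfigurationError(f"no extracellular data for group {group!r}")
    rows = []
    for rep, rd in sub.groupby("replicate"):
        by_id = rd.set_index("mirna_id")["rq"]
        try:
            mean_a = float(np.mean([by_id[m] for m in panel_a.members]))
            mean_b = float(np.mean([by_id[m] for m in panel_b.members]))
        except KeyError as e:
            raise ConfigurationError(f"panel member missing in replicate {rep}: {e}")
        rows.append(
            {
                "group": group,
                "replicate": int(rep),
                "balance_score": balance_score_from_means(mean_a, mean_b, pseudocount),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ultracentrifugation retention
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RetentionResult:
    """Per-sequence and panel-level retention after a high-g spin.

    ``per_sequence`` columns: mirna_id, retention, n, t, df, p, significant.
    ``panel_mean_retention`` averages the per-sequence ratios;
    ``pooled_retention`` is total post / total pre quantity (near-unbiased
    under multiplicative measurement noise); both are reported because the
    averaging scheme is a convention.
    """

    per_sequence: pd.DataFrame
    panel_mean_retention: float
    pooled_retention: float
    excluded: tuple[str, ...]


def uc_retention(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    alpha: float = 0.05,
) -> RetentionResult:
    """Retention = post-spin / pre-spin quantity, with paired one-tailed tests.

    ``pre`` and ``post`` are tidy frames with columns (mirna_id, replicate,
    quantity) on a common linear (or common-reference RQ) scale; pairing is by
    replicate index.  Sequences with zero pre-spin quantity have undefined
    retention: they are excluded and reported.
    """
    for name, df in (("pre", pre), ("post", post)):
        missing = {"mirna_id", "replicate", "quantity"} - set(df.columns)
        if missing:
            raise UsageError(f"{name} frame lacks columns {sorted(missing)}")
    pre = pre.assign(mirna_id=pre["mirna_id"].map(canonical_mirna_id))
    post = post.assign(mirna_id=post["mirna_id"].map(canonical_mirna_id))
    pre_ids = set(pre["mirna_id"])
    if pre_ids != set(post["mirna_id"]):
        raise UsageError("pre and post must cover the same sequence set")

    rows = []
    excluded: list[str] = []
    total_pre = 0.0
    total_post = 0.0
    for t in sorted(pre_ids):
        p_vals = pre[pre["mirna_id"] == t].sort_values("replicate")
        q_vals = post[post["mirna_id"] == t].sort_values("replicate")
        if not (p_vals["replicate"].to_list() == q_vals["replicate"].to_list()):
            raise UsageError(f"{t}: pre/post replicates are not paired")
        xs = p_vals["quantity"].to_numpy(dtype=float)
        ys = q_vals["quantity"].to_numpy(dtype=float)
        if (xs < 0).any() or (ys < 0).any():
            raise UsageError("quantities must be nonnegative")
        total_pre += xs.sum()
        total_post += ys.sum()
        if xs.sum() == 0:
            excluded.append(t)
            continue
        retention = float(ys.sum() / xs.sum())
        res: TTestResult = t_test_paired(xs, ys, tails=1, alternative="less", alpha=alpha)
        rows.append(
            {
                "mirna_id": t,
                "retention": retention,
                "n": int(xs.size),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "significant": res.significant,
            }
        )
    per_sequence = pd.DataFrame(
        rows, columns=["mirna_id", "retention", "n", "t", "df", "p", "significant"]
    )
    if per_sequence.empty:
        raise AnalysisError("no sequence had nonzero pre-spin quantity")
    panel_mean = float(per_sequence["retention"].mean())
    pooled = float(total_post / total_pre) if total_pre > 0 else float("nan")
    return RetentionResult(per_sequence, panel_mean, pooled, tuple(excluded))
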