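"""Replicate-level hypothesis testing as applied by the panel analyses.

Adjacent-stage and treatment contrasts use independent two-tailed Student t
tests on the replicate means (pooled variance by default, matching a
spreadsheet Analysis-ToolPak workflow; Welch available by flag).  The
ultracentrifugation comparison uses a paired one-tailed t test with the
depletion alternative (post-spin below pre-spin).  All tests are evaluated at
alpha = 0.05 and no multiplicity adjustment is applied by default; an optional
Benjamini-Hochberg switch is provided as an extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, UsageError
from .quantify import ExpressionProfile

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TTestResult:
    """A t statistic with its p value and the decision at level alpha."""

    t: float
    df: float
    p: float
    tails: int
    paired: bool
    alpha: float = ALPHA_DEFAULT

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise UsageError("p value out of [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def _p_from_t(t: float, df: float, tails: int, alternative: str) -> float:
    if tails == 2:
        return float(2.0 * sps.t.sf(abs(t), df))
    if alternative == "less":
        return float(sps.t.cdf(t, df))
    return float(sps.t.sf(t, df))


def t_test_independent(
    xs: Sequence[float],
    ys: Sequence[float],
    tails: int = 2,
    pooled: bool = True,
    alternative: str = "two-sided",
    alpha: float = ALPHA_DEFAULT,
) -> TTestResult:
    """Independent-samples Student t test (pooled variance; Welch by flag).

    Degenerate zero-variance inputs are resolved deterministically: equal
    means give t = 0 (p = 1 two-tailed); unequal means with no variance give
    an infinite t and p of 0 or 1 according to the alternative.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size < 2 or y.size < 2:
        raise UsageError("each sample needs at least 2 values")
    if tails not in (1, 2):
        raise UsageError("tails must be 1 or 2")
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()

    if pooled:
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:  # Welch–Satterthwaite
        se = math.sqrt(v1 / n1 + v2 / n2)
        if se > 0:
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            df = float(n1 + n2 - 2)

    if se == 0.0:
        if diff == 0.0:
            t = 0.0
            p = 1.0 if tails == 2 else 0.5
        else:
            t = math.inf if diff > 0 else -math.inf
            if tails == 2:
                p = 0.0
            else:
                p = 0.0 if (t < 0) == (alternative == "less") else 1.0
        return TTestResult(t, df, p, tails, paired=False, alpha=alpha)

    t = diff / se
    p = _p_from_t(t, df, tails, alternative)
    return TTestResult(float(t), float(df), p, tails, paired=False, alpha=alpha)


def t_test_paired(
    xs: Sequence[float],
    ys: Sequence[float],
    tails: int = 1,
    alternative: str = "less",
    alpha: float = ALPHA_DEFAULT,
) -> TTestResult:
    """Paired t test on within-pair differences ``ys - xs``.

    The default one-tailed alternative "less" tests whether ``ys`` (e.g. the
    post-spin quantities) are lower than ``xs`` (pre-spin), pairing by
    replicate index.  All-zero differences give t = 0 and one-tailed p = 0.5.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size != y.size:
        raise UsageError("paired samples must have equal lengths")
    if x.size < 2:
        raise UsageError("paired test needs at least 2 pairs")
    if tails not in (1, 2):
        raise UsageError("tails must be 1 or 2")
    d = y - x
    n = d.size
    df = float(n - 1)
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            t = 0.0
            p = 1.0 if tails == 2 else 0.5
        else:
            t = math.inf if mean > 0 else -math.inf
            if tails == 2:
                p = 0.0
            else:
                p = 0.0 if (t < 0) == (alternative == "less") else 1.0
        return TTestResult(t, df, p, tails, paired=True, alpha=alpha)
    t = mean / (sd / math.sqrt(n))
    p = _p_from_t(t, df, tails, alternative)
    return TTestResult(float(t), df, p, tails, paired=True, alpha=alpha)


# --------------------------------------------------------------------------
# contrast tables over expression profiles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Contrast:
    """A labeled two-group comparison, e.g. ("zygote_vs_four_cell", ...)."""

    label: str
    group_a: str
    group_b: str


DEFAULT_CONTRASTS = (
    Contrast("zygote_vs_four_cell", "zygote", "four_cell"),
    Contrast("four_cell_vs_blastocyst", "four_cell", "blastocyst"),
)


def run_contrasts(
    profile: ExpressionProfile,
    contrasts: Sequence[Contrast] = DEFAULT_CONTRASTS,
    test: str = "pooled",
    tails: int = 2,
    alpha: float = ALPHA_DEFAULT,
    adjust: str | None = None,
) -> pd.DataFrame:
    """One t test per (miRNA, contrast, compartment) over replicate RQ values.

    No multiplicity adjustment by default; ``adjust="bh"`` adds a
    Benjamini-Hochberg q-value column as a labeled extension.
    """
    if test not in ("pooled", "welch"):
        raise ConfigurationError("test must be 'pooled' or 'welch'")
    d = profile.data
    present = set(d["group"].unique())
    for c in contrasts:
        missing = {c.group_a, c.group_b} - present
        if missing:
            raise ConfigurationError(
                f"contrast {c.label!r} references missing group(s): {sorted(missing)}"
            )
    rows = []
    for c in contrasts:
        for compartment in ("intracellular", "extracellular"):
            sub = d[d["compartment"] == compartment]
            if sub.empty:
                continue
            for t_id in sorted(sub["mirna_id"].unique()):
                xs = sub[(sub["mirna_id"] == t_id) & (sub["group"] == c.group_a)]["rq"]
                ys = sub[(sub["mirna_id"] == t_id) & (sub["group"] == c.group_b)]["rq"]
                if len(xs) < 2 or len(ys) < 2:
                    raise ConfigurationError(
                        f"{t_id} {c.label} {compartment}: needs >= 2 replicates per group"
                    )
                res = t_test_independent(
                    list(xs), list(ys), tails=tails, pooled=(test == "pooled"),
                    alpha=alpha,
                )
                rows.append(
                    {
                        "mirna_id": t_id,
                        "contrast": c.label,
                        "compartment": compartment,
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                        "significant": res.significant,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=["mirna_id", "contrast", "compartment", "t", "df", "p", "significant"],
    )
    if adjust == "bh" and not table.empty:
        table["q_bh"] = benjamini_hochberg(table["p"].to_numpy())
    return table


def benjamini_hochberg(pvals: Iterable[float]) -> np.ndarray:
    """BH step-up q-values (extension; the default workflow applies none)."""
    p = np.asarray(list(pvals), dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0, 1)
    return out
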