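# Methods

## The measurement model

Everything in `embryomir` rests on one view of an RT-qPCR data point: a
target with linear template quantity `q` in the reaction crosses the
fluorescence threshold at

    Ct = anchor − log_E(q),      E = per-cycle amplification efficiency,

so quantities are recovered as `q = E^(−Ct)` and ratios as
`RQ = E^(Ct_ref − Ct_target)` (the ΔCt method). A reaction that never
crosses the threshold within the run's cycle limit (40 cycles) is
*censored*: it is stored as "no Ct", carries `RQ = 0` with a detection flag,
and is excluded from all arithmetic — no operation ever substitutes a
numeric Ct for a censored one except the detection rules, which explicitly
treat "censored" as "Ct above any limit". This mirrors how the assay
workflow treats non-amplification as absence, and it is the single most
consequential convention in the package: means, SEMs, t tests and fractions
all operate on the zero-imputed RQ scale, not on censored Ct values.

`E` defaults to 2.0 (perfect doubling). It lives in one place
(`EfficiencyModel`) so that a calibrated efficiency can be threaded through
every exponentiation consistently; values are restricted to (1, 2].

## Detection and exclusivity calling

The array screen guards against false positives by requiring both
`Ct < 35` and `ΔRn > 0.5` (both strict, as printed in instrument exports)
for a target to count as detected. The category partition
(conditioned-exclusive, strict short list, blank-exclusive,
both-elevated/lower/other, undetected) is defined once from that predicate,
which makes the partition property (every target in exactly one category;
counts sum to the screen size) hold by construction.

The source screen's criteria mix intersection and union forms for the two
exclusivity directions; the canonical mode here derives both from the single
detection predicate, and a `literal` mode evaluates the printed expressions
verbatim for auditing. The two disagree only on boundary rows (e.g. a
one-sided detection whose partner sits exactly at `Ct = 35` or
`ΔRn = 0.5`); in literal mode such rows fall into `both_other` so the
partition survives. Ties at the 5-cycle elevated/lower margin also land in
`both_other` — strict inequalities as printed.

## Background correction and normalization

Blank-media contamination (observed for miR-20a, miR-30c, miR-142-3p and as
trace amplification of the miR-191 assay) is subtracted in *linear quantity
space*, after volume matching and before normalization:
`q_adj = max(0, q_cond − q_blank)`. Subtraction of contaminating template is
physically linear; subtracting Ct values would multiply instead. The clamp
at zero means heavily contaminated, weakly released targets can be driven to
zero — which is the honest answer at this sensitivity.

Media samples are normalized to the *intracellular* miR-191-5p of the paired
cohort lysate rather than to media miR-191, both because the media reference
assay itself shows background amplification and because a lysate anchor puts
both compartments on one scale.

## Volume bookkeeping and the extracellular fraction

One media data point represents
`15/(15+15) × 2.5 = 1.25 µL` of a 20 µL droplet (`s_media = 16`); one lysate
data point represents `2.5 µL of lysate_total_ul`. The extracellular
fraction is

    percent = 100 · (RQ_media · s_media) / (RQ_lysate · s_lysate).

**Warning:** `lysate_total_ul` defaults to 2.75 µL (2 µL lysis solution plus
kit additions). The true prepared-lysate volume depends on the lysis
protocol and is not generally knowable from an export; absolute percentages
are only meaningful once this value is set from the actual protocol.
Within-study comparisons (stages, treatments, retention) are unaffected
because the factor is common.

Replicate fractions are aggregated as arithmetic mean ± SEM (sample SD/√n),
the reporting convention of the source workflow. Targets undetected in the
lysate have no defined fraction and are reported as such, never as 0 or ∞;
targets undetected in media contribute 0 %.

## Hypothesis testing

Stage and treatment contrasts: independent two-tailed Student t tests on the
replicate RQ values, pooled variance by default — matching the
spreadsheet-ToolPak workflow the analyses emulate — with Welch's correction
available by flag. Ultracentrifugation: paired one-tailed t tests with the
depletion alternative (post-spin < pre-spin), pairing by replicate. α = 0.05
throughout; no multiple-testing correction by default (none is applied in
the emulated workflow), with a Benjamini–Hochberg q-value column available
as a labeled extension.

Degenerate inputs are resolved deterministically rather than erroring or
returning NaN: zero variance with equal means gives `t = 0, p = 1`
(one-tailed 0.5); zero variance with distinct means gives an infinite t and
a p of 0 or 1 by direction. p values come from `scipy.stats.t`.

## The balance score and stage classifier

Per-sequence t tests show stage separability but do not by themselves
provide a decision rule. The balance score

    score = log2((mean RQ over panel B + ε) / (mean RQ over panel A + ε))

is this package's formalization (an extension over the source analyses): the
miR-290-family panel B is silent in zygote-conditioned media, faint at
cleavage and dominant at the blastocyst stage, while the conserved panel A
is comparatively flat, so the score increases monotonically with
development. The pseudocount ε (default 1e-6 RQ units) floors the score when
panel B is entirely censored, which by the invariant forces a zygote call.

The two default thresholds (−8.0 and −0.3) are midpoints of the noise-free
default-generator scores for the three stages (≈ −13.1 / −3.0 / +2.4 on
media RQ profiles); a score exactly at a threshold goes to the higher stage.
They are calibrated for profiles normalized per this pipeline — scores
computed on other scales need recalibration, which is why the thresholds are
explicit configuration rather than constants.

## Ultracentrifugation retention

Retention is the pure quantity ratio post-spin/pre-spin per sequence
(ratio of replicate sums), with a paired one-tailed test per sequence.
Because pre and post derive from the same droplet and dilution, any common
reference or the 3× PBS dilution before the spin cancels; the
`VolumeModel.uc_dilution_factor` is carried for bookkeeping only. Sequences
with zero pre-spin quantity are excluded and reported. The panel-level
number is reported two ways — the mean of per-sequence ratios and the pooled
total-post/total-pre ratio — because the averaging scheme is a convention;
the pooled form is near-unbiased under multiplicative measurement noise and
is the one quoted by the acceptance studies.

## The synthetic-data generator

The generator is a *measurement-level statistical emulator*, not an embryo
model: no cell counts, kinetics or apoptosis mechanics. For each sample it
assembles a true linear quantity on the lysate-reference RQ scale —

* lysate point: `stage_profile / s_lysate`
* media point: `stage_profile × release_fraction / s_media + contamination`
* blank point: `contamination`
* post-spin point: pre-spin × `(1 − vesicle_fraction × spin_efficiency)`

— then draws `Ct = anchor − log2(q)/log2(E) + N(0, σ)`, censoring at 40
cycles. Defaults encode the study conditions: intracellular stage profiles
shaped like the developmental series (panel A maternal decay then plateau;
panel B onset at the 4-cell stage, blastocyst surge), release fractions
equal to the measured stage and degeneracy-arm extracellular percentages,
blank contamination on the four affected assays, vesicle fraction 0.5 with
spin efficiency 0.8, σ(Ct) = 0.25 cycles (the real Ct repeatability is not
reported; 0.25 is a documented assumption typical of replicate TaqMan
assays), and n = 3 replicates.

Two numerical choices matter:

* **Ct anchor 22.** The anchor (Ct of unit RQ) cancels from every ΔCt-based
  output, but it does interact with censoring: it must sit low enough that
  cleavage-stage media quantities (release fractions of a few 0.1 %) stay
  inside the 40-cycle window, as they do in the emulated assays thanks to
  pre-amplification. 22 cycles achieves that; the scale-invariance property
  test confirms the outputs are otherwise anchor-free.
* **Truncated noise in the array screen.** Planted screens guarantee exact
  category recovery by placing base (Ct, ΔRn) values at least `margin` from
  every decision boundary and clipping Ct noise at ±3σ; with the default
  `margin = 3σ` the planted category is recovered exactly (boundary contact
  has probability zero). The assay-table generator uses untruncated Gaussian
  noise. A margin of 0 — plants exactly at thresholds — is rejected.

An optional degeneracy mode multiplies one replicate's release fractions by
a heavy "debris capture" factor (default 10×), emulating the outlier
replicate behavior of degenerate-cohort collections; it is off by default.

What passing tests on this generator do **not** show: real media exhibit
assay-specific efficiencies, inter-plate effects, carrier-dependent
recovery, and contamination that varies by media lot — none of which are
modeled. The generator validates the *analysis logic* (censoring handling,
correction arithmetic, estimator calibration), not assay chemistry.

## Estimator calibration in the recovery studies

Gaussian Ct noise is multiplicative on quantities, so a per-replicate
fraction estimate is lognormal around truth. The arithmetic mean of such
ratios is biased upward by ≈ e^((ln2·σ)²) per independent noise pair
(≈ +3 % at σ = 0.25) — an estimator artifact, not a pipeline error — and at
200 replicates that bias is comparable to two standard errors. The
Monte-Carlo recovery studies therefore compare in log space (geometric
mean), the natural scale of qPCR noise, while the user-facing tables keep
the conventional arithmetic mean ± SEM. The residual caveat is the
background-subtraction clamp: for sequences whose blank contamination is a
large share of the media signal (miR-142-3p at default settings, blank ≈
45 % of signal) the corrected quantities are noisier and carry a small
negative log-scale bias, visible as occasional 2-SE excursions in recovery
coverage.

## Known limitations

* Absolute extracellular percentages depend on the unverifiable
  `lysate_total_ul` convention (above).
* One conditioned/blank pair per screen: no inter-card calibration or
  multi-array normalization.
* No absolute (standard-curve) quantification; all quantities are relative.
* The stage classifier is calibrated on the default generator; shifted
  release kinetics (e.g. altered conditioning time) move the score scale.
* Raw amplification curves are out of scope; the package consumes exported
  Ct/ΔRn values.
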