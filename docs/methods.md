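# Methods

`binbat` implements a bin-based analysis pipeline for the basophil
activation test (BAT): from event-level flow-cytometry data through
automated basophil gating and square-bin (PRI-style) visual statistics
to per-sample CD63 activation metrics and cohort-level diagnostic
accuracy against serum sIgE markers. Because no event-level BAT data
are publicly available for this assay, the package ships a first-class
synthetic-cytometry generator that plants the statistical structure the
analysis assumes; every quantitative claim the test suite makes is a
recovery of a planted parameter or an agreement with an independent
oracle.

## The assay and its conventions

The BAT quantifies allergen-induced degranulation of basophils in
whole blood. Basophils are identified as SSC-low / FceRIa-high events;
degranulation surfaces CD63, and the readout is the percentage of
CD63-positive basophils. Three printed conventions anchor the
analysis and are defaults throughout:

* **1% anchoring** — each patient's CD63 positivity cutoff is placed on
  their own unstimulated negative control so that the control reads
  (at most) 1% CD63+ basophils. We use the nearest-rank-above order
  statistic: with n control values and anchor a, the cutoff is the
  k-th largest value, k = floor(n·a/100); ties at the cutoff push it
  strictly above the tied value (reading low rather than high).
* **5% positivity** — a stimulated sample is called positive when its
  anchored %CD63+ is at least 5 (inclusive at the boundary; the
  convention's behaviour at exactly 5% is not published, so the
  inclusive reading is a documented package choice).
* **70% CD32 baseline** — CD32 (FcgRIIB) time courses around oral food
  challenges (OFC) are normalized multiplicatively so the baseline
  sample reads exactly 70%, making patients comparable. The CD32
  cutoff is derived once from the baseline sample (density-valley
  method) and reused across timepoints so changes reflect biology, not
  gate drift.

The standard stimulation panel is: negative control (PBS), gluten 400,
gliadin 300, wheat extract 50, timothy grass pollen 1 µg/mL, anti-IgE
(IgE-receptor crosslinking positive control) and fMLP
(IgE-independent positive control).

## Automated gating

The published analysis is automated, but no gating algorithm is
published for it; the strategies here are replacements, not
reconstructions, and every threshold is reported for reproducibility.

The default **valley** strategy works on a floored-log10 display scale
(floor 1, so zeros map to 0). For each axis a 256-bin histogram is
smoothed with a Gaussian kernel (Silverman-rule bandwidth); peaks are
detected on log1p(counts) so the rare basophil mode (~0.5% of events)
is not drowned out by the leukocyte bulk. The FceRIa threshold is the
density minimum between the rightmost (basophil) mode and the highest
mode to its left; the SSC threshold is the minimum between the
dominant high-SSC (granulocyte) mode and the mode below it. A
candidate valley must dip below half the smaller flanking peak;
otherwise the channel is treated as unimodal and the deterministic
**quantile** strategy is the documented fallback. Masks are inclusive
on the basophil side (SSC ≤ threshold, FceRIa ≥ threshold); optional
CD32-high refinement intersects a third mask. QC requires ≥ 300
gated basophils by default (common BAT practice; configurable).

## PRI square-bin statistics

The plane of two display-scale markers is partitioned into half-open
square bins `[origin + k·w, origin + (k+1)·w)` with a common width
(default w = 0.2 decades; the original method's numeric parameters are
not published, so both w and the display threshold min_cells = 5 are
configuration with documented defaults). Per bin we report the event
count n_b, the mean signal intensity MSI_b of a target marker over all
events, MSI+_b over target-positive events only, and the positive
fraction. MSI+ of a bin without positive events is *undefined*
(rendered neutral), never zero — fabricating low intensities would
bias the visual impression. Quadrant statistics use the same
inclusive-side convention as gating: black percentages are fractions
of all events per quadrant, red percentages the positive fractions
within each quadrant. The grid origin defaults to the data minimum
floored to a bin-width multiple, making grids deterministic for fixed
data.

## Cohort-level diagnostics

An **IgE non-responder** is a clinically allergic patient whose
basophils do not respond to anti-IgE in vitro (< 5% anchored CD63+);
such patients are uninterpretable by this assay and excluded before
diagnostic evaluation (tolerant patients are never excluded by this
rule). Group comparisons use the unpaired one-sided Wilcoxon rank-sum
test: exact when the combined sample size is ≤ 12 without ties,
otherwise the normal approximation with tie and continuity
corrections; the method used is recorded. AUC is the Mann–Whitney
probability (ties count half). Operating cutoffs maximize Youden's
J = sensitivity + specificity − 1 over midpoints between consecutive
unique scores plus ±∞ sentinels, with ties broken toward higher
specificity (fewer false positives in a confirmatory test).
Sensitivity, specificity, PPV and NPV carry two-sided 95% Wilson score
intervals; the published table's interval method is not identifiable
from its printed bounds, so interval values are reported but not
treated as reference quantities. Serum sIgE values are clamped to the
reportable range before analysis (< 0.1 → 0.05, > 100 → 101 kU/L).
Orientation is fixed to "higher marker ⇒ allergic"; anti-discriminating
markers warn rather than silently reversing. Reactivity classes
(negative ↓ / intermediate → / high ↑) use explicit boundaries —
defaults 5/35 %CD63+ for BAT, 0.35/17.5 kU/L for sIgE — because the
published figure prints arrows without numeric limits; the boundaries
used are echoed in every output.

`matrix_from_rates` reconstructs the unique integer confusion matrix
behind a printed sensitivity/specificity pair at known group sizes and
refuses ambiguous cases; it is how the package reproduces published
predictive values without patient-level data.

## The synthetic generator

`binbat.synthetic` emulates erythrolyzed whole blood as a three-part
mixture (log10-scale Gaussians, then exponentiated):

| population      | fraction | SSC (loc, sd) | FceRIa | CD63 | CD32 |
|-----------------|---------:|--------------|--------|------|------|
| basophil        | 0.005    | 1.88, 0.08   | 2.50, 0.12 | 1.00, 0.15 | 2.30, 0.15 |
| other leukocyte | 0.695    | 2.50, 0.15   | 1.00, 0.15 | 0.90, 0.20 | 1.60, 0.25 |
| debris          | 0.300    | 1.70, 0.18   | 0.85, 0.22 | 0.80, 0.25 | 1.00, 0.30 |

The basophil SSC mode sits ~0.24× the leukocyte mode so that the
density valley between the debris and leukocyte SSC modes (~log10 2.1)
clears the basophil population by > 2.5 SD — placing it much closer to
the valley would make automated gating of a 0.5% population
intrinsically unstable, which is a property of the geometry, not the
gating code. All locations, scales and fractions are configurable.

Basophil CD63 is a two-component mixture: activated cells are shifted
by +1.2 decades, and the activated weight follows a Hill curve
w(d) = f_base + (f_max − f_base)·d^h/(EC50^h + d^h) with defaults
f_base = 0.01, f_max = 0.6, EC50 = 40 µg/mL, h = 1 (the assay shows
dose dependence saturating near 400 µg/mL gluten but publishes no
functional form; the Hill form is the generator's choice). Allergic
responders respond to the wheat-derived allergens and anti-IgE;
tolerant patients respond to anti-IgE and fMLP but show only baseline
allergen activation; non-responders respond to fMLP only (the
published definition mentions only the absent CD63 response; routing
non-responders through the IgE-independent pathway follows standard
BAT practice and is configurable). Cohort presets mirror the study
design: 14/11 children and 18/9 adults, one planted non-responder
each. Per-patient heterogeneity draws f_max uniformly from
(0.25, 0.75) and EC50 log-normally (σ = 0.3 decades). Serum sIgE is
log-normal per marker and status; by default ω-5 gliadin (Tri a 19) is
planted as a near-perfect separator (emulating its standout published
accuracy) while the extract markers overlap, and tolerant patients can
carry elevated extract sIgE (sensitized-but-tolerant). CD32 kinetics
plant a stable positive fraction (default 0.7) for uneventful
challenges and a multiplicative post-reaction drop (default factor
0.6) for allergic reactions.

Seeds propagate hierarchically (cohort → patient → sample) and every
per-sample seed is recorded in the manifest, so any single sample is
reproducible in isolation; identical seeds give bit-identical events.

**What the generator does not emulate:** instrument artifacts
(doublets, time drift, fluorescence spillover/compensation),
correlated marker biology beyond an optional common pairwise
correlation, mechanistic child/adult differences (only effect sizes
are configurable), and the long right tails of real cytometry data.
Passing recovery tests therefore demonstrates that the analysis is
correct *given* its distributional assumptions, not that those
assumptions hold on any particular instrument.

## Numerical choices and degenerate inputs

* Anchoring with f_base equal to the anchor fraction puts the
  control's top-1% rank statistic at the edge of the activated
  component; the resulting cutoff is only stable with ≥ ~500 gated
  basophils. The pipeline default of 100 000 events/sample (~500
  basophils at the 0.5% fraction) respects this; metric-level
  simulations use the direct basophil samplers at n ≥ 2000.
* Empty event tables yield empty grids (no error); empty quadrants and
  positive-free bins report undefined (NaN) statistics rather than 0.
* An all-tied negative control places the cutoff strictly above the
  tied value and warns.
* Valley thresholds are the midpoint of the minimal density plateau
  between the chosen peaks, so wide empty gaps resolve
  deterministically.
* Exact vs approximate Wilcoxon switches at combined n = 12; the
  asymptotic branch always applies tie and continuity corrections.
* CSV interchange keeps 7 significant digits by default (bit-exact
  round trips available on request); FCS support is read-only and
  strict — linear list-mode only, anything else is rejected loudly.

## Problem sizes used by the checks

The acceptance script and test suite run at desk scale: 20 seeded
samples of 100 000 events for gating recovery, 20 synthetic cohorts of
13/11 patients for AUC recovery, 2000 null replicates for the
Wilcoxon size check, 2000 basophils/sample for exclusion counting, and
50 000 basophils/timepoint for the CD32 pipeline. Cohort-level
published quantities that depend on unpublished patient-level raw data
(the exact AUCs, p-values and Youden cutoffs of the study tables) are
covered by these recovery and oracle checks instead of direct
reproduction; the published predictive values are reproduced exactly
via contingency reconstruction from the printed rates.

## Known limitations

* The valley gating strategy assumes a detectable FceRIa-high mode;
  samples without one (basopenia, failed staining) fail QC rather than
  being rescued.
* Wilson intervals differ from the (unidentifiable) interval method of
  the published table; values agree, intervals may not.
* The paired structure of CD32 time courses is analyzed with the
  stated rank-sum test for group contrasts; a signed-rank alternative
  may be more appropriate for paired hypotheses and is available via
  scipy directly.
* No compensation/spillover handling: channel values are taken as
  given.
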