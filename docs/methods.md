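# Methods

## Design model

The analysis targets a balanced two-factor randomized-complete-block
screen: *h* hybrids crossed with two water treatments (drought T₁,
irrigated control T₂), replicated in *r* blocks (replicate column sets in
the SPAR facility), with every trait measured once per experimental unit at
a single harvest. The packaged reference trial has h = 6, r = 4 (48 units)
and 22 traits. Replicate id is modelled as the block factor; the published
description conflates replication and blocking, and treating the four
replicate sets as complete blocks is the reading that yields a proper RCBD
with 33 error degrees of freedom (47 total − 3 block − 1 treatment −
5 hybrid − 5 interaction).

## Trait panel

The default panel holds 22 traits in three categories (developmental, root,
physiological). Twenty-one are members of the cumulative index; ETR is
measured but excluded from the sum, matching the index's published term
list. Three synonym pairs are normalized on input (RL→TRL, ARD→RD, RS→RSR):
the results narration and the index formula use the former names while the
data tables use the latter, and they denote the same quantities. Stem dry
weight without leaves (STDW) is defined in the reference protocol but never
tabulated; it is not in the default panel, though custom panels may add it.
All panel traits are constrained nonnegative.

## Indices and classification

IDSRI is the drought/control ratio of cell means; CDSRI the unweighted sum
of IDSRI over the member traits. Two deliberate choices:

- **No direction normalization.** Traits that increase under drought
  contribute ratios above 1 exactly as the formula states. The consequence —
  higher CDSRI = more tolerant — matches the published group ordering.
- **Cell means first.** With replicate-level input, cells are collapsed to
  means before taking ratios (a mean of per-replicate ratios is a different,
  biased estimator and is not what treatment-level indices describe).

A missing member trait is a hard error rather than a silent renormalization,
because CDSRI magnitudes are only comparable at fixed trait count; an
explicit trait subset can be passed to score reduced panels, and the result
records `n_traits`.

Classification cuts the observed score range [min, max] into three
equal-width bins (sensitive < moderate < tolerant with increasing score);
the lower two bins are half-open, the top bin closed, so a score on an
interior edge joins the upper class. This rule is a reconstruction: the
published class intervals have equal width but are internally inconsistent
(their lower edge excludes the lowest published score, and their span
overshoots the observed maximum), whereas equal-width thirds of the observed
range reproduce the published memberships from the published scores.
Classification needs ≥ 3 hybrids and a non-degenerate range.

### Known discrepancy in the reference trial

Applying the index formula to the reference trial's published trait means
yields CDSRI ≈ 15.1–18.0, not the published 25.21–28.32; no published data
reproduces the published magnitudes (they were presumably computed from
unpublished replicate-level or rescaled data). The package therefore follows
the formula, carries the published scores verbatim only as classification
inputs, and ships `cdsri_discrepancy_report` so the mismatch is explicit in
every reproduction run rather than papered over.

## Summary statistics

Percent responses are computed on unrounded means and rounded to two
decimals only for display; decline = 100·(C−D)/C and increase is its exact
negative. Overall responses are ratios of unweighted across-hybrid means
(equal hybrid counts make this identical to using grand cell means). Cell
SE is sd/√n with the sample (n−1) standard deviation; single-replicate
cells carry an undefined (NaN) SE. A handful of published narrated averages
differ from recomputation in the last printed digit (e.g. a total-root-length
decline printed 27.98 vs recomputed 27.99); these are truncation/rounding
artifacts and the package always reports the recomputed value.

## Inference layer

ANOVA sums of squares use the explicit balanced-design partition (correction
factor and marginal-total squares); F ratios test block, treatment, hybrid
and interaction mean squares against the error mean square, with upper-tail
F p-values from scipy and strict star tiers (*** p<0.001, ** p<0.01,
* p<0.05, NS). Unbalanced data is rejected. A zero error mean square
(noise-free input) reports F = ∞, p = 0. Tiny negative round-off in the
subtraction-derived interaction and error SS is clamped to 0.

Fisher's LSD is *protected*: it runs only when the omnibus F for the factor
is significant at α (default 0.05 — the protocol's printed "p = 0.5" is an
evident typo for 0.05). LSD = t(1−α/2, df_error)·√(2·MS_error/n) with n the
per-level replication; the compact letter display assigns shared letters to
maximal runs of the descending means whose extremes differ by at most the
LSD, which for this one-dimensional rule makes "share a letter" equivalent
to "differ by at most the LSD".

Pearson correlations are computed within a treatment on replicate-level
values paired by (hybrid, replicate) — n = 24 in the reference design, the
only reading consistent with the published significance calls — with
two-sided p from t = r√(n−2)/√(1−r²). The correlation tables use the
legend of the published trait-correlation matrix (* = p<0.01,
** = p<0.001), which differs from the ANOVA star tiers; each emitting
operation honors its own table's legend. A zero-variance trait yields an
undefined marker (NaN/"NA"), never r = 0. The combined report places
drought correlations above the diagonal and control correlations below.
The published correlation matrix itself contains asymmetric anomalies
(entries marked NS despite |r| > 0.8), so the package reports computed
values only and does not attempt to reproduce its cells.

## Synthetic trial generator

The generator emulates the reference design: for every hybrid × treatment ×
replicate × trait it draws Normal(mean, cv·|mean|) (or a fixed sd), with
the cell means defaulting to the packaged reference table, n = 4
replicates, and cv = 0.10 — the trial publishes no within-cell variance, so
0.10 is a modeling default typical of controlled-environment phenotyping,
chosen once. Nonnegative traits are truncated at zero by rejection
(re-draw) rather than clamping, keeping the distribution continuous. A
single RNG stream and fixed row order (hybrids, treatments, replicates,
panel-order traits) make output fully reproducible from one seed.

What the generator deliberately omits: block effects, trait–trait
covariance, genotype-specific variance heterogeneity, and any time-course
or soil-moisture dynamics. Passing tests on synthetic data therefore
demonstrate correctness of the arithmetic and calibration of the
inferential machinery under independent normal noise — not robustness to
correlated or non-normal field data.

A layout helper assigns hybrids to numbered chamber positions: positions are
split into contiguous per-treatment blocks (drought and control columns are
physically separate), and hybrid × replicate slots are permuted within each.

## Problem sizes used in the checks

The packaged trait-mean table is desk-scale (264 cells), so the percent
responses, treatment means and index arithmetic are recomputed exactly in
milliseconds. Statistical guarantees use simulation: cell-mean recovery
over 10 seeds at cv = 0.05 (≥ 99% of 2 640 recovered means within three
standard errors), noise monotonicity over three cv levels × 10 seeds, and
drought-effect detection for the strongly affected traits over 200 seeds at
cv = 0.10 (expected ≥ 95% of trials starred ***; the true effects are many
error-SDs wide, so detection is essentially certain).

## Pipeline determinism

`run_pipeline` is pure given (inputs, seed): the manifest records content
hashes of inputs and emitted tables, and rerunning an identical config
yields a byte-identical bundle. For that reason timestamps appear only in
the stderr log, never in the manifest. Mean-only input (the common published
form) downgrades capability explicitly: ANOVA, LSD and correlations are
skipped with a logged reason instead of being silently approximated from
means.
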