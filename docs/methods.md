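# Methods

This note documents the models and procedures implemented in `riverpress`,
the parameters that matter, the numerical choices, and what the synthetic
data can and cannot show.

## Pressure schema and harmonisation

Fifteen ordinal pressure variables describe a sampling site, in four
groups: hydrology (H_imp, H_hydrop, H_waterabstr, H_resflush, H_hydromod),
morphology (M_channel, M_crosssec, M_instrhab, M_embankm, M_floodpr),
water quality (W_acid, W_eutroph, W_opoll) and segment-scale connectivity
(C_B_s_up, C_B_s_do).  Every variable is harmonised onto a 1–5 gradient
(1 nearly undisturbed … 5 strongly impacted), but the allowed levels differ
by variable: binary pressures map presence to 3 (e.g. reservoir flushing),
embankment has an extra "slight" level 2, eutrophication spans 1/3/4/5, and
the downstream-barrier variable codes any barrier as 4 while the upstream
one codes it as 3.  This asymmetry is preserved verbatim from the source
coding scheme rather than rationalised; likewise "partial" and "yes"
modalities of hydropeaking and barriers collapse onto a single level, as
printed in the source classification.  The three instream-morphology
variables are aggregated into `M_morph_instr` by their plain arithmetic
mean over the values that are present.

Missing raw values propagate as missing and are excluded from downstream
means — absence of evidence of a pressure is not evidence of its absence.
`M_morph_instr` is missing only when all three components are; a pressure
group with every member missing yields a missing index that contributes
nothing to the GPI, and sites with fewer than four scored groups carry a
`complete = False` flag so summaries can filter on completeness.

Catchment size assigns the segment length over which barriers are recorded:
1 km below 100 km², 5 km for 100–1000 km² (bracket read as closed at both
ends; the verbal rule does not fix the endpoints) and 10 km above.  The
catchment-level connectivity flag (`disconnected_from_sea`) is stored but
deliberately enters no computation.

## Indices, GPI and classes

The group index is the *threshold-conditional mean*: the mean of exactly
the values ≥ 3 when any value reaches 3, otherwise the mean of all values.
This makes the index non-compensatory — adding nearly-undisturbed variables
to an impacted group cannot lower it — at the price of non-monotonicity at
the threshold: raising a variable from 1 to 3 in a group whose impacted
mean exceeds 3 *dilutes* the index (values (1, 1, 5) score 5; (1, 3, 5)
score 4).  This dilution is inherent to the published construction and is
deliberately not "fixed"; the property tests document both the
non-compensation that holds and the monotonicity that does not.

The GPI sums the group indices that reach the threshold, giving values in
{0} ∪ [3, 20]; the brute-force enumeration of all 1 492 992 valid
configurations (exposed as both a streaming scorer and a vectorised
group-decomposition oracle) confirms that no value in (0, 3) is attainable,
that the minimum positive GPI is exactly 3, and that the attainable maximum
is 19 = 5 + 5 + 5 + 4 (one variable per group at its top level; the
all-variables-at-maximum site scores only 15.97 because the 3-capped
variables dilute the means).  Classes are half-open bins 0: < 3,
1: [3, 6), 2: [6, 9), 3: [9, 12), 4: [12, 20], so fractional index values
are always classifiable; the verbal integer phrasing of the class bounds
leaves interior fractions undefined and half-open bins are the minimal
completion.  Because the bin edges are themselves attainable exact values
(3 per impacted group), the GPI is snapped to 9 decimals before binning —
scalar and vectorised summation orders otherwise disagree by one ulp at
e.g. GPI = 12 and would flip sites across the class-3/4 edge.  Index
comparisons use ≥ 3.0 exactly, with no rounding; display rounding (one
decimal) is applied only in `SummaryTable.display`.

Affected groups count the indices ≥ 3 and may be 0 (the class-0 case).
The combination split is W / HMC / W+HMC / NoP according to whether the
water-quality index and/or any of the hydrology, morphology, connectivity
indices are impacted.

## Typology and summaries

The 15 European Fish Types collapse onto six river types (1–4 → A
Headwater, 5–6 → B Downstream, 7 & 9 → C Greyling, 8, 11, 12 → D Salmon,
10 & 13 → E Mediterranean, 14–15 → F Lowland).  The fish-type prediction
model itself is out of scope; `eft_code` is an input, and sites without it
are excluded from river-type summaries.

Summary tables compute fractions of impacted sites per index (with both
the assessable-sites and the all-sites denominator, since the choice is
not determined by the reported figures), combination proportions (rows sum
to 1 within 1e-9), GPI distribution statistics (min/max/mean/median;
median of an even count is the mean of the central pair; the
`impacted_only` filter keeps GPI ≥ 3, which is why reported minima are
always 3.0), the GPI class histogram, a row-normalised ecoregion ×
river-type cross-tab, and population-density quartiles per combination
category.  All summaries are permutation-invariant and exclude
missing-value sites per table with logged counts.

## Synthetic-site generator

The generator emulates the structure of a multi-country survey that is not
publicly distributable.  Sites are stratified into (ecoregion × river
type) cells; each cell has a weight (defaults follow the published site
distribution over 10 Illies ecoregions and 6 river types) and a *severity
shift* δ.  Each site draws one latent severity Z ~ N(δ, 1); each pressure
variable v is an ordinal discretisation of its own latent
X_v = √ρ·Z + √(1−ρ)·ε_v — a one-factor Gaussian copula.  Thresholds are
set from per-variable class probabilities, so at δ = 0 marginals are exact
by construction; ρ ∈ [0, 1] couples variables within and across groups
through shared severity (ρ = 0 independence, ρ = 1 comonotone).  The
dependence of real pressure data is unknown beyond co-occurrence rates, so
ρ is a free knob, not an estimate.

Default calibration: per-group above-threshold masses and ρ are solved
(1-D quadrature over the latent mixture plus Brent root-finding) so that
the European-level group-impact prevalences are 0.59 / 0.41 / 0.39 / 0.35
(water quality / hydrology / morphology / connectivity) and 21% of sites
are unimpacted; the solution (ρ ≈ 0.225) is stored in
`src/riverpress/data/default_generator.yaml` as an editable config, and
`calibrate_marginals` re-derives it.  Above-threshold mass is split across
severity levels with fixed ratios (0.7/0.3 for 1-3-5 variables,
0.55/0.30/0.15 for eutrophication; 15% of embankment's sub-threshold mass
on the "slight" level) — a pragmatic choice, as only the group-level
prevalences are anchored by published numbers.  Environmental covariates
are drawn per ecoregion from two-piece uniform distributions (log-space
for slope, catchment and distance) anchored at the published medians and
ranges; catchment lower bounds are clipped to 0.5 km² to respect
positivity.  Population density is log-normal with location
3.912 + 0.6·Z, so degraded sites sit in denser areas; sites are flagged
disconnected-from-sea with probability 0.85.

Because the model is fully specified, the population values of every
recovered statistic are computed *exactly* (to quadrature precision, a
301-point trapezoid rule over the latent mixture): per-group impact
prevalences, combination probabilities, the affected-groups distribution
(Poisson-binomial over groups), per-variable mixture marginals and the
full GPI-class distribution via the exact conditional law of each group's
GPI contribution.  Recovery experiments compare pipeline output against
these values with binomial standard errors.

What the generator does *not* emulate: spatial autocorrelation along river
networks, country-level coding idiosyncrasies, missing data (generated
tables are complete; missingness handling is tested separately),
non-Gaussian dependence (e.g. tail dependence between pollution and
barriers), and any real relationship between the environmental covariates
and the pressures (covariates are independent of severity given the cell).
Passing recovery tests therefore demonstrates correctness of the pipeline
arithmetic and calibration machinery, not fidelity to any real survey.

## Problem sizes and determinism

The test suite and the acceptance script use n = 300–10 000 synthetic
sites, 2–3 replicate generations, and the full 1 492 992-configuration
enumeration (vectorised: milliseconds; streamed scalar scoring: ~20 s) —
sizes chosen so the whole suite runs in well under a minute of compute per
heavy test.  All randomness flows through a single `numpy` Generator
seeded explicitly; identical config and seed reproduce output CSVs
byte-for-byte.

## Known limitations

* The GPI inherits the dilution non-monotonicity of the threshold-
  conditional mean (above); rank comparisons of sites differing by single
  sub-threshold-to-3 transitions can be counterintuitive.
* Harmonisation trusts the source-modality tables; it cannot detect
  semantically wrong but syntactically valid codings.
* The class-probability splits and severity shifts of the default
  generator are plausibility choices, anchored only at group level.
* Summaries expose both Fig-2-style denominators but offer no inference
  (no confidence intervals on prevalences); none are defined by the
  assessment procedure.
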