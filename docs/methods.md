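# Methods

## Plate stress-test derivation (`xf_mst`)

Raw per-cycle OCR (pmol O₂/min) is reduced to four raw states per well:
last basal cycle, minimum post-oligomycin cycle, maximum post-FCCP cycle,
minimum post-antimycin/rotenone cycle.  This is the instrument vendor's
report convention; `state_selection="mean"` switches every state to the
phase mean.  With noisy cycles the min/max selection is biased low/high by
roughly 0.85·σ_cycle for three-cycle phases; the bias is identical across
groups, so group *differences* are unaffected — a reason the default suite
anchors acceptance to differences, never to absolute state levels.

Non-mitochondrial respiration is subtracted from basal, leak and max in raw
pmol/min; the result is divided by (seeding count / 10⁶).  Subtraction and
scaling commute, so the order is a numerical no-op; both identities
`basal = ATP + leak` and `CE% = 100·ATP/basal` hold to machine precision by
construction and are asserted in tests.  Negative corrected states are kept
(flagged `NEGATIVE_CORRECTED_STATE`), never clipped, so that downstream
means and tests see unbiased values.

Reserve capacity as a percentage is printed in two conventions in the
literature; both are emitted: `rescap_pct = 100·max/basal` (ratio reading,
100% = no reserve is false — 100% means max equals basal) and
`rescap_pct_diff = 100·(max−basal)/basal`.

QC defaults (all configurable):

| check | default | rationale |
|---|---|---|
| O₂ floor | 10 mmHg | reported exhaustion traces approach 0 mmHg; 10 leaves margin above the noise floor |
| recovery fraction | 0.5 | a J-shaped post-FCCP O₂ trace fails to re-oxygenate during mixing; half the pre-measure level is a conservative cut |
| basal CV | 0.15 | "stable baseline" principle; 15% CV tolerates ordinary cycle noise at typical basal rates |

An oligomycin artifact (post-oligomycin minimum not below the last basal
cycle, or a non-finite post-oligomycin cycle) invalidates only the
oligomycin-dependent parameters (ATP, leak, CE%); basal, max and non-mito
survive, and duplicate aggregation averages each parameter over the wells
where it is defined.

## Chamber SUIT derivation (`o2k_suit`)

Each respiratory state is the mean flux over the last 40 ticks (80 s at the
2-s acquisition interval) of its titration window; windows start
`equilibration_delay_s` (default 60 s) after the titration mark to exclude
mixing transients.  Shorter windows are averaged over what exists and
flagged `SHORT_WINDOW`.

The correction chain, all in pmol/s/mL before normalization:

1. fiber background = mean flux over the pre-substrate window − instrumental
   background;
2. Rox = (post-antimycin/rotenone flux − instrumental) − fiber background
   (background-corrected only);
3. every state = (measured − instrumental) − fiber background − Rox.

Subtracting both fiber background and Rox risks double-counting
non-mitochondrial O₂ use if the bare bundle's O₂ consumption is itself
partly non-mitochondrial; it is implemented as stated because that is the
declared convention of the analysis being reproduced, and
`rox_only_correction=True` exists for sensitivity analysis.  Normalization
to mass multiplies by the chamber volume (default 2 mL) and divides by the
bundle wet weight (mean of the two weighings).

Saturating ADP (the 15 mM step) defines CI OXPHOS; per-step ADP fluxes are
also emitted.  The cytochrome-c response uses the pre-CytC CI OXPHOS state
as denominator (`(CI+CytC − CI)/CI`), while flux control efficiencies use
the post-step flux as reference (`FCE = gain / post-step flux`, hence
FCE ≤ 1 whenever the gain is non-negative) — the reference-flux convention.
Post-FCCP electron-transport capacity is parsed when an FCCP mark exists
but reported only on request (`emit_e=True`), because FCCP does not reach
maximal respiration in murine permeabilized muscle (E ≤ P); a titration
order with FCCP before oligomycin is flagged `FCCP_PROTOCOL_ERROR` and
nulls L, ATP-linked, CE% and RCR.

Exclusion rules: `NEG_BACKGROUND` when fiber background is negative after
instrumental correction; `ADP_NONRESPONSIVE` when the saturating-ADP flux
does not exceed the pre-ADP flux by at least `adp_min_gain` (default 10%);
`CYTC_EXCEEDS_CUTOFF` when the cytochrome-c response exceeds 20%
(strictly) — applied per group policy: the cutoff screens preparation
damage in controls, but an elevated response in a severe disease model is
phenotype, so the disease group is flagged (`CYTC_RESPONSE_HIGH`) and
retained.  Duplicate chambers are averaged per parameter when both survive,
the survivor is used verbatim when one is excluded, and the animal is
dropped (logged) when both fail.  States measured while chamber O₂ is
outside 180–400 µM are flagged `O2_REGIME`.

## Cohort statistics (`cohort_stats`)

Fixed, logged exclusion order: upstream QC flags → ROUT per parameter per
group → Shapiro–Wilk gate → tests/correlations.  The cleaning step is
idempotent.

ROUT is implemented on a constant-location model (the regression procedure's
special case for a column of scalars): the location minimizes the Lorentzian
merit Σ log(1 + (residual/s)²) with the scale iterated as the 68.27th
percentile of absolute residuals; RSDR applies the small-sample adjustment
n/(n−1) (one fitted parameter); each point gets a two-tailed p from the
t distribution with n−1 df of residual/RSDR; Benjamini–Hochberg step-up at
rate Q (default 0.01) declares outliers from most to least extreme.  With
more than 68% of values identical the scale is zero and any point off that
value is treated as infinitely extreme; with all values identical nothing
is removed.

The normality gate defaults to pooled within-group-centered residuals per
parameter (so a genuine group shift cannot masquerade as non-normality);
`mode="per_group"` tests groups separately and any non-normal group gates
the parameter non-normal.  The gate decides both the comparison test
(Welch t vs Mann–Whitney with Hodges–Lehmann median difference; exact
Mann–Whitney null for ≤8 per group without ties, tie-corrected normal
approximation otherwise) and the correlation method (Pearson vs Spearman).

Pearson CIs use Fisher z with SE 1/√(n−3); Spearman CIs use Fisher z with
the adjusted SE 1.03/√(n−3).  A permutation p-value (full enumeration for
n ≤ 8, i.e. all n! pairings) is available as `p_method="permutation"`.
No multiple-testing correction is applied across the correlation matrix by
default (per-pair p-values are reported, matching reporting practice for
exploratory cross-tissue matrices); Benjamini–Hochberg can be layered on by
the caller.  Significance annotation: * p<0.05, ** p<0.01.

## Exact correlation power (`power_corr`)

Under bivariate normality the sample correlation r of n pairs has the exact
density given in the README; it is evaluated in log space with scipy's
hyp2f1, falling back to 50-digit mpmath arithmetic for any point where the
fast path loses finiteness.  Power integrates this density outside the
t-based critical value by adaptive quadrature (absolute tolerance 1e-10,
well inside the 1e-6 budget); a quadrature that cannot certify its error
raises rather than silently degrading.  The Fisher-z approximation and a
vectorized Monte-Carlo estimator are exposed as cross-checks; the exact and
Fisher-z curves agree to <0.002 by n ≈ 500 at small ρ.

Sample-size solving treats power as a smooth function of real n (the
density is defined for any n > 3 via the gamma functions) and locates the
crossing of the target power by Brent's method between the bracketing
integers.  The default rounding convention returns the *nearest* whole
subject to the crossing — the behavior of mainstream power software, which
can therefore quote an n whose achieved power sits a fraction of a point
below the nominal target (e.g. ρ = 0.5, α = 0.05 two-tailed, target 0.80:
crossing 28.05 → n = 28, achieved 0.7992).  `rounding="ceiling"` gives the
strict smallest n with power ≥ target (29 in that example), and the strict
bracketing invariants are tested in that mode.  The null hypothesis is
fixed at ρ₀ = 0; testing against nonzero ρ₀ is out of scope.

## Synthetic cohorts (`synth_data`)

Defaults encode the study conditions the pipeline is meant to analyze:
23 control and 12 diseased animals (the analyzed platelet cohort), platelet
seeding 20×10⁶ per well with duplicate wells when the simulated platelet
yield (blood volume × yield per mL, blood volume = 72 mL/kg × body mass)
allows, and duplicate chambers per animal at 2-s acquisition.

Effect-size defaults are the reported disease-minus-control mean differences
for the *independent* states: platelet ATP +7.923, leak +1.136, max +14.12
(pmol/min/10⁶); muscle P −7.722, L −5.955, Rox −0.9542 (pmol/s/mg),
cytochrome-c gain +5.337, plus a small non-significant CI shift (−1.5).
Composite shifts are derived, not set: platelet basal = ATP + leak shifts
(9.059 — the independently printed 9.066 reflects per-parameter exclusions
and cannot hold jointly with the component values under the identity), the
succinate gain = P − CI − CytC shifts (−11.56, matching the reported
negative direction), and CE%, RCR and the FCE ratios emerge with the
reported signs (CE% ≈ +11, FCE_cytc ≈ +0.21, FCE_succ ≈ −0.38 at the
default baselines).  Control-group baselines (platelet basal 30
pmol/min/10⁶, muscle P 33.5 pmol/s/mg, etc.) are arbitrary documented
choices — only differences are anchored — and fully configurable.

Cross-tissue structure: one latent factor per animal with loading
√|r|·σ_basal on platelet respiration (split between ATP and leak) and
−√|r|·σ_P on muscle CI, sized so the population correlation between
platelet basal and muscle P equals `cross_tissue_r` (default −0.5) exactly.
This also fixes the platelet-leak × muscle-CI correlation negative
(≈ −0.8, an assumption where no direction is reported) and leaves the
platelet-CE% × muscle-CI correlation weakly positive (≈ +0.03): under a
single shared factor a ratio whose numerator and denominator both load on
the factor retains little of it, so the positive sign is present but
faint — a structural limitation of the one-factor model, documented rather
than tuned away.

Noise: iid Gaussian at the animal level (SDs chosen so the reported
standard errors of the anchored differences are plausible at n = 23/12:
platelet basal SD 8, muscle P SD 6.5, etc.), iid Gaussian measurement noise
at the cycle (SD 3 pmol/min raw) and tick (SD 0.35 pmol/s/mL) level, and a
3% CV on duplicate wet weighings.  Physiological floors (leak ≥ 0.2,
L ≥ 0.8, Rox ≥ 0.05) clip rare negative draws; cytochrome-c and succinate
gains may go slightly negative, which is measurement-realistic.  Truths
satisfy basal = ATP + leak and P = ATP-linked + L exactly, so the pipeline
identities are testable end to end, and a noiseless render (all SDs zero)
is inverted exactly by the derivation modules: the flux approach transient
(τ = 10 s) is forced to its target 40 s after each titration, before the
steady-state window opens, and the renderer computes chamber flux from the
*recorded* wet weights so mass normalization cancels exactly.

What the simulator does not emulate: instrument drift, temperature
transients, chamber leaks, platelet activation during handling, fiber
bundle heterogeneity, or any pharmacokinetics of the effectors (steps are
instantaneous first-order approaches).  Passing tests therefore certify the
*analysis* — derivation arithmetic, QC logic, exclusion policy, statistical
calibration — not the biology of real traces.

O₂ bookkeeping: plate O₂ declines within each measure period in proportion
to OCR and re-oxygenates during mixing (the exhaustion scenario uses
25×10⁶-equivalent seeding, a deeper depletion coefficient and 30% recovery,
producing the J-shape the detector must catch); chamber O₂ integrates
−flux/1000 µM per tick with re-oxygenation to 395 µM whenever it falls to
185 µM, so the flux–concentration conservation is exact by construction
and asserted in tests.

## Problem sizes used by the test suite

Simulation-based checks run at: 200 replicates of the full
simulate→render→derive→test pipeline at n = 23/12 for effect-direction
recovery; 1000 zero-effect cohorts through the statistics stage for null
calibration (the rendering stage is deterministic arithmetic already
verified by the oracles and the noiseless round-trip, so calibration
replicates operate on cohort tables); 1000 clean normal samples (n = 30)
for ROUT false-discovery control; 100 labeled plates per QC detector; 10⁵
bivariate samples for the Monte-Carlo power cross-check.

## Known limitations

- The exact-power module covers the test of zero correlation only.
- ROUT on a constant model is an interpretation of a procedure published
  for regression; its operating characteristics are verified by simulation
  (≥97% of clean normal n = 30 samples lose nothing at Q = 1%).
- Between-instrument duplicate-chamber matching is not modeled; duplicates
  share one background draw structure and differ only by noise.
- The single-latent-factor cross-tissue model cannot produce strong
  correlations for ratio parameters (see above); multi-factor structure
  would be needed to reproduce a strong CE%↔CI coupling.
- Binary instrument exports are out of scope; ingestion expects the
  documented delimited-text dialects.
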