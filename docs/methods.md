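# Methods

## Problem and analysis unit

The package evaluates bedside rules that predict whether a blood culture
drawn at emergency-department presentation will grow a clinically relevant
pathogen. The analysis unit is the blood-culture *event*; a patient sampled
twice contributes two events treated as independent, which slightly
understates between-event correlation — a documented limitation inherited
from the study design the pipeline mirrors. Cultures growing skin flora
judged not clinically relevant ("contaminants") are grouped with negatives
in every accuracy computation, and carry their own outcome label so the
grouping is reversible.

Canonical units are fixed internally (creatinine µmol/L, counts and
platelets ×10⁹/L, temperature °C). The only supported on-read conversion is
creatinine mg/dL → µmol/L (×88.4), because the Shapiro threshold is
conventionally quoted as 2 mg/dL = 176.8 µmol/L.

## Scores

**Modified Shapiro score.** Nine criteria (the band-cell criterion of the
original score is deliberately unimplemented: band percentages are not
routinely measured in many laboratories, and the "modified" score is
defined by its absence). A missing component contributes 0 points and
clears a completeness flag; the score is the total over evaluable
components, matching pragmatic scoring on available data. Two conventions
the published rule table leaves open are fixed here:

- the temperature band (39.3, 39.4] °C sits between the minor range
  (38.3–39.3) and the major threshold (> 39.4); it scores as minor
  (1 point), on the argument of continuity of risk;
- temperature contributes at most one of the major/minor entries.

The original decision rule ("one major or two or more minor criteria
advise culture") is exposed as `mss_rule_advises_culture`; the accuracy
analysis uses point totals at cut-offs ≥ 2 and ≥ 3, with strict "> 10" /
"> 12" for NLCR, since those are the operating points quoted in the
literature. Vital signs are treated as single "at presentation" values; the
schema does not distinguish first from worst readings.

**SIRS** uses the standard Sepsis-2 thresholds (temperature > 38 or
< 36 °C, HR > 90, RR > 20, WBC > 12 or < 4 ×10⁹/L). **qSOFA** uses
RR ≥ 22, SBP ≤ 100 (both boundaries inclusive), altered mentation.
**Sepsis-3** is an acute SOFA rise ≥ 2 over baseline; SOFA totals are
inputs, never recomputed from organ components.

## Accuracy statistics

Confusion matrices are complete-case per rule: records whose predictor is
missing are excluded and counted explicitly, so evaluated + excluded always
equals the stratum size. Interval methods (all switchable via `CiConfig`):

- sensitivity/specificity: Clopper–Pearson exact (Beta quantiles);
- PPV/NPV: standard logit intervals (Mercaldo), SE = √(1/a + 1/b), 0.5
  correction on an empty cell;
- LR±: log-method (Simel), with a 0.5 continuity correction applied to all
  four cells *for the interval only* when any cell is zero. spec = 1 yields
  LR+ = ∞ with a one-sided interval.

These are the documented defaults of the commercial package most clinical
papers in this area use, which is why they are the defaults here.
`metrics_from_rates` exposes the Bayes identities directly so published
(sens, spec, prevalence) triples can be converted to predictive values and
likelihood ratios; it agrees exactly with the count-based path when fed
rates derived from the same counts (a tested invariant).

## ROC analysis

AUC is the normalized Mann–Whitney statistic (ties ½), computed through
midrank placement values; the same placements give the DeLong variance,
the 2×2 covariance of two AUCs measured on the same patients, and the
paired z-test. Curve points are reported at every distinct observed score
under declared threshold semantics — "> t" for continuous markers, "≥ t"
for the integer MSS — with an optional midpoint style (thresholds halfway
between adjacent observed values, the convention behind quoted cut-offs
like 19.25). Youden's J is maximized with ties broken toward higher
sensitivity, then the lower threshold. Marker comparisons are paired
complete-case on NLCR (MSS is computable for every record); the combined
marker is the linear predictor of an IRLS logistic fit on (MSS, ln NLCR).

## Statistics engine

Implemented from first principles, with scipy supplying only distribution
functions; scipy/statsmodels serve as independent cross-checks in the test
suite, never as the implementation.

- **Fisher exact**: point-probability two-sided rule (sum of hypergeometric
  probabilities ≤ the observed table's, with a 1+1e−7 relative guard
  against float ties); "twice the smaller tail" available via flag.
- **Pearson χ²**: definitional statistic, Yates correction optional and off
  by default (published baseline-table p-values are assumed uncorrected).
- **McNemar**: exact doubled-tail binomial below 25 discordant pairs
  (for the symmetric Binomial(n, ½) this equals the point-probability
  rule), χ² (b−c)²/(b+c) above.
- **Mann–Whitney**: exact enumeration of all group assignments for
  n + m ≤ 12 (valid under ties); otherwise tie-corrected,
  continuity-corrected normal approximation. Near the null the corrected
  normal p saturates at 1 while the discrete exact p stays just below it.
- **t-test**: pooled (default) or Welch, from raw data or published
  summary statistics (mean, SD, n).
- **Logistic regression**: Newton–Raphson/IRLS, convergence when the score
  vector's max component < 1e−8 within 25 iterations. Separation is
  detected both as non-convergence and as numerically saturated fitted
  probabilities (max |η| > 20); the last iterate is returned flagged.

The Gram-agreement analysis partitions culture-positive patients by which
rule flagged them (complete-case on both scores) and cross-tabulates the
Gram stain of *isolates* in the two single-rule cells — isolate counts can
exceed patient counts because a culture may grow more than one organism.

## Synthetic cohort generator

The generator emulates a prospective suspected-BSI ED cohort: 484 events,
prevalence 84/484 of relevant positives, contaminants at 15/400 of the
non-relevant remainder, Sepsis-3 rates 32/84 (positives) and 123/400
(negatives), Gram-negative fraction 51/90 among isolates with a species
table matching a typical mix (E. coli and S. aureus dominant), and
per-variable missingness at published rates (e.g. lactate 53/484, NLCR
inputs 16/484, with neutrophil missingness nested inside lymphocyte
missingness at 12/16).

Continuous variables are group-conditional: log-normal for strictly
positive laboratory values with (µ, σ) from the published median/IQR via
µ = ln median, σ = (ln q3 − ln q1)/(2·0.67449); normal for age (published
mean/SD) and for temperature and vital signs (median/IQR treated as
mean/quartiles — these are not materially skewed). A warning fires when a
quantile triple is markedly asymmetric in log space, since a log-normal
then reproduces the median and log-IQR but shifts the individual quartiles
(about 2% for the positives' NLCR triple).

NLCR is generated *directly* from its group log-normal — its distribution
is the published calibration target — with lymphocytes drawn from their own
log-normal and neutrophils back-solved as NLCR × lymphocytes. WBC is drawn
separately, so the accounting identity WBC ≈ neutrophils + lymphocytes is
not enforced; scores never use that identity.

Variables feeding a Shapiro threshold are drawn indicator-first: the
criterion indicator is Bernoulli at a configured rate, then the value is
drawn from the group distribution truncated to the matching band
(inverse-CDF). When the rate equals the distribution-implied rate — the
default for every criterion pinned by a published summary — the marginal is
exactly the configured distribution. The four free binary components
(chills, suspected endocarditis, vascular catheter, and an override rate
for platelets < 150, none of which have published distributions) are set by
`calibrate_mss_components`, which evaluates P(MSS ≥ k) exactly by
convolving the independent component point masses and minimizes the squared
deviation from target rule-level operating points (MSS ≥ 2: sens 0.857 /
spec 0.382; MSS ≥ 3: sens 0.69 / spec 0.64) under a weighted ridge that
keeps rare components near clinically plausible priors. The shipped
defaults are that calibration's output; a 50,000-event simulation
reproduces the targets within ±5 percentage points in the tests.
Boundary targets (sens = spec = 1) are infeasible under independent
components and produce a best-effort fit with warnings.

Sepsis-3 flags are drawn at the group rates and the SOFA totals are then
constructed to be consistent with the flag (baseline from {0, 1, 2} with
probabilities 0.6/0.3/0.1; admission = baseline + 2 + Poisson(0.6) when
flagged, + {0, 1} otherwise), so recomputing the flag from the totals
reproduces the draw exactly.

An optional Gaussian-copula coupling (config `coupling` ∈ [0, 1], default
0) correlates the temperature-band and high-WBC indicators with the NLCR
latent; the default keeps the model minimal.

**What the generator does not emulate.** MSS components are independent
within group (the calibration compensates only at the rule level); the
joint distribution of MSS and NLCR is unknown, so rule-agreement patterns
(Venn overlap) and any MSS–NLCR dependence are not calibrated; Gram labels
are independent of the scores, so differential Gram prediction by rule does
not appear in simulated cohorts; qSOFA and SIRS marginals are emergent from
the vitals rather than calibrated. Passing tests therefore demonstrate the
correctness of the scoring and statistics machinery and the fidelity of the
calibrated marginals — not that real MSS/NLCR joint behavior is reproduced.

## Numerical choices and problem sizes

Determinism: one `numpy` Generator seeded per simulation; identical
(config, seed) pairs give byte-identical CSVs and identical report JSON.
Default problem sizes used by the tests and the acceptance script: 100,000
draws per group for distribution-level operating points; 50,000 events for
rule-level calibration validation; 20,000 bootstrap replicates for the
DeLong cross-check at n = 30; 2,000 simulated tables for CI coverage at
the cohort's own class sizes (84/400), where exact Clopper–Pearson
coverage is 96.4%/95.3%. Float CSV cells use `repr` so round-tripping is
exact; Youden ties use a 1e−12 tolerance.

## Known limitations

Repeated-patient correlation ignored; per-rule complete-case denominators
may differ by a few counts from analyses that impute or use per-marker
denominators; the point-probability Fisher rule and the exact/asymptotic
McNemar switch at 25 discordant pairs are conventions — other software
defaults differ; the logit PPV/NPV intervals assume the study prevalence
applies (they are not transportable intervals).
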