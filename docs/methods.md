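# Methods

This note documents the models, algorithms and numerical choices behind
`hrvfda`, and what its synthetic-data experiments do and do not establish.

## The scientific problem

Heart rate variability (HRV) — beat-to-beat variation in RR intervals —
indexes autonomic modulation of the heart; its high-frequency band
(0.15–0.40 Hz, HF-HRV, in ms²) specifically reflects cardiac vagal control.
Multi-day ambulatory ECG yields an HF-HRV value every five minutes over
many days, and the scientific question is *time-specific*: at which times
of day do groups (e.g. adults with mild cognitive impairment, MCI, versus
cognitively normal, CN) differ? `hrvfda` implements the full chain from
RR-interval series to a function-on-scalar regression answering that
question, together with a calibrated generator that produces synthetic
cohorts with known ground truth.

## Pipeline stages

### RR cleaning (`hrvfda.rr`)

Input is a beat-indexed tachogram per subject-day (R-wave time in seconds
since local midnight, interval in ms). A beat is flagged artifactual when
its interval deviates by more than 20% (configurable) from the median of
its `window` (default 5) nearest neighbours **on each side, excluding the
beat itself**. Using 2×`window` neighbours keeps the reference robust to
runs of up to `window` consecutive corrupted beats; a window containing
the beat itself could never flag such runs. Flagged runs of ≤3 beats are
replaced by the reference median ("corrected by interpolation"); longer
runs are excluded outright — long corrupted stretches have no reliable
local reference. Beat times are then rebuilt cumulatively from intervals
inside each contiguous segment; a new segment starts where the recorded
gap exceeds the interval by >1.5 s, so wear gaps and excised runs are
preserved rather than closed up, and segment anchors are clamped so times
never step backwards. Cleaning is idempotent on realistic recordings.

Limitations: beats corrupted in runs longer than `window` can evade
detection (negligible under Bernoulli artifact rates of a few percent);
interpolation happens in the beat domain, not the time domain.

### Epoch segmentation and validity

Beats are assigned to half-open clock-aligned 5-minute bins anchored at
local midnight (bin = ⌊t/300⌋; a beat at exactly a boundary belongs to the
later bin), giving 288 bins per day. Clock alignment (not sliding windows)
is required for the later time-of-day analysis. An epoch is invalid when
*more than* 20% of its beats required interpolation (equality retained),
when it has fewer than 32 beats (an implementation guard — too few beats
cannot support a stable spectrum), or when its HF power falls below a
10⁻⁶ ms² floor (avoiding −∞ under the log).

### Interval spectrum (`hrvfda.spectra`)

HF power is computed by the interval method: the epoch's beat-indexed
interval sequence is detrended (linear by default; mean-removal optional),
discrete-Fourier-transformed, and the cycles-per-beat frequency axis is
mapped to Hz via the mean interval, f_j = j/(N·r̄). Power is one-sided and
*summed* (ms², not a density), normalised so the total over non-zero
frequencies equals the variance of the detrended sequence (Parseval).
HF power is the sum over 0.15 ≤ f < 0.40 Hz, then natural-log-transformed.

Numerical choices: linear detrending suppresses low-frequency leakage into
the HF band; tapering is off by default so a sinusoidal modulation of
amplitude A carries exactly A²/2 of band power (the identity used to
calibrate the generator and verified to <2% end to end; a Hann option is
provided with mean-square-taper power rescaling). With r̄ ≤ 1.2 s the
implied Nyquist frequency stays above the 0.40 Hz band edge.

### Profiles (`hrvfda.profiles`)

A day is valid when it has at least 100 valid epochs (strictly "fewer
than 100" excludes; 200 is the sensitivity setting). Each subject's valid
days are averaged per bin into one 288-bin Ln(HF-HRV) profile Y_i(t);
bins observed on no valid day remain missing and simply contribute no
observation to the model — no imputation, no pre-smoothing. Days are
calendar-clock days; partial first/last days pass through the same
epoch-count rule as any other day.

### Actuarial MCI classification (`hrvfda.cognition`)

Jak/Bondi criteria on ten age/sex/education-normed z-scores (two per
domain: memory, executive, attention, language, visuospatial) plus the
Lawton–Brody instrumental-activities count. "Impaired" is strictly more
than `cutoff_sd` (default 1) SD below the norm; z = −1.0 exactly is
unimpaired. MCI ⇔ both measures impaired in ≥1 domain, or ≥1 impaired
measure in ≥3 of 5 domains, or a Lawton–Brody score of 4. Rule 1 is
applied over all five domains by default; `rule1_domains` restricts it to
a subset (the narrower memory/language/executive reading is a documented
option, since published formulations differ on this point). The
classifier is verified against an independent count-based oracle on the
full 3¹⁰ grid of score patterns.

## The functional additive mixed model (`hrvfda.fosr`)

The response is the 24-h profile; the covariates are scalars:

    Y_i(t) = β₀(t) + β₁(t)·MCI_i + β₂(t)·Age_i + β₃(t)·Female_i
             + β₄(t)·Black_i + β₅(t)·OtherEthnicity_i + β₆(t)·Educ_i
             + b_i + ε_i(t),

with age and education centered at the sample mean, ethnicity dummies
against non-Hispanic White, b_i ~ N(0, σ_b²) a scalar subject random
intercept and ε white Gaussian noise. The secondary model adds
depression, diabetes and hypertension; domain-specific runs replace the
MCI indicator with a domain impairment flag.

Each β_k(t) is expanded in a **cyclic** cubic B-spline basis (default 24
uniform basis functions — one knot per hour — giving effective df that
can span flat to wiggly) with a second-order difference penalty on the
coefficients; cyclicity enforces continuity across the midnight wrap, and
a non-cyclic mode is available for sensitivity. The penalty null space is
the constants, so a heavily penalized curve degenerates to a scalar
effect rather than to zero.

Estimation uses the mixed-model representation of penalties. With
C = [X | Z] the stacked spline and subject-indicator design,
S(λ) = blockdiag(λ₀P, …, λ_KP, λ_b·I) and A = C′C + S(λ), the profiled
restricted likelihood

    −2ℓ_R = D_p/φ + (n − M_p)·log(2πφ) + log|A| − log|S(λ)|₊,
    D_p = y′y − y′C A⁻¹C′y,   φ̂ = D_p/(n − M_p),

is minimised over the log smoothing parameters (one per curve plus the
subject-ridge ratio λ_b = σ_ε²/σ_b²) with L-BFGS-B (finite-difference
gradients, step 10⁻⁶; box −15 ≤ log λ ≤ 25; iteration cap 200, non-
convergence raises an error carrying the last iterate). M_p counts the
penalty null-space dimensions (one constant per curve). Variance
components follow as σ̂_ε² = φ̂ and σ̂_b² = φ̂/λ̂_b. A relative ~10⁻¹⁰ ridge
keeps A positive definite in degenerate corners of the search. The fit
is deterministic given the design; rank-deficient covariates are rejected
up front with the offending columns named.

Pointwise standard errors use the posterior covariance of the penalized
fit, φ̂·A⁻¹ (bias-uncorrected "shading"-style bands): 95% intervals are
β̂_k(t) ± 1.96·SE_k(t), with no simultaneous-band adjustment and no
multiple-testing correction, matching pointwise functional inference.
Significance windows are maximal runs of bins whose CI excludes zero,
merged across the midnight wrap and reported as clock intervals. Effect
sizes standardise a curve difference by the sample SD of person-level
mean Ln(HF-HRV) (Cohen's d).

Verified reductions: with the minimum basis and λ → ∞ every curve
collapses, to within 10⁻⁴, onto an independent generalized-least-squares
oracle (for balanced data, OLS of subject means on the covariates);
free REML on flat-truth data stays within 0.05 of the same oracle;
pointwise 95% bands cover a true nocturnal-dip curve at ≈92–95% of
(replicate, bin) pairs — the mild shortfall from nominal is the usual
smoothing-bias effect of penalized bands near curvature; under a null
effect curve the bands exclude zero at far below the 7% benchmark
(penalization makes the null test conservative).

## The synthetic cohort (`hrvfda.synth`)

Defaults define the emulated study conditions:

| parameter | default | rationale |
|---|---|---|
| n_subjects / prop_mci | 81, 20/81 | cohort size and MCI fraction |
| mean profile β₀(t) | cosinor, mesor 4.5 ln ms², amplitude 0.5, acrophase 03:00 | person-level mean ≈4.5; vagal tone peaks nocturnally |
| MCI curve β₁(t) | raised-cosine dip, depth 0.6 ln ms², centred 00:00, span 12 h | nocturnal deficit largest at midnight, vanishing mid-day |
| other effects | 0 | no time-varying effects reported for the adjustment covariates |
| σ_b | 0.79 ln ms² | calibrates person-level SD to ≈0.8 (the dominant between-subject variance source); exposed in config |
| σ_ε | 1.0 ln ms² | epoch-to-epoch noise; not separately identified by the cohort margins, placeholder exposed in config |
| rr_base_ms / rsa_freq_hz | 800 ms, 0.25 Hz | typical older-adult resting rate; mid-band respiratory frequency avoids edge leakage |
| n_days | 8 | protocol length |
| wear model | day dropout 0.175, flat epoch retention 0.9 | mean valid days 8×0.825 ≈ 6.6; worn days almost surely exceed the 100-epoch rule |
| artifact_rate | 0.02 | a few percent corrupted beats, symmetric long/short factors ≥40% off the local median |

The dip is centred at midnight (rather than at the centre of a
19:00–07:00 window, i.e. 01:00) so the curve's maximum magnitude falls
exactly at the midnight grid point; its span is 12 h (support
18:00–06:00). Covariates are drawn marginally (age truncated-normal
N(78.3, 5.2²) on [70, ∞) — truncation raises the realised mean slightly —
education N(14.9, 3.3²) rounded, 81.5% female, ethnicity 38.3/43.2/18.5%,
diabetes 18.5%, hypertension 67.9%, depression 15%); joint dependence
between covariates is deliberately omitted. Each subject also receives
instrument z-scores constructed to fire (for MCI, one of the three rules,
weighted 0.6/0.3/0.1) or fail (for CN) the actuarial criteria, so the
classification stage is exercised with known labels.

Randomness is split into four deterministic child streams (cohort, epoch
noise, RR synthesis, wear/artifacts) of the config seed; identical config
gives bit-identical output.

What the generator does **not** emulate: sleep stages, physical activity,
posture or any within-day nonstationarity beyond the cosinor; serially
correlated epoch noise; joint covariate structure; artifact clustering
(ectopy bursts); R-wave detection from voltage. Passing tests therefore
show that the pipeline recovers the assumed data-generating structure,
not that real recordings satisfy those assumptions.

## Validation experiments and problem sizes

All experiment sizes are package choices made to resolve the quantities
of interest at useful Monte-Carlo precision:

* **Recovery** (`run_recovery_experiment`): 50 replicates of 81 subjects
  (20 MCI), σ_b = 0.3, σ_ε = 1.0, 8 full-wear days through the direct
  epoch-level path. The mean fitted |β₁| at the midnight bin recovers the
  true 0.6 within 0.05 (observed ≈0.596, MC SE ≈0.011), and ≥80% of
  replicates flag significantly negative windows both before 07:00 and
  after 19:00.
* **Calibration** (`run_calibration_experiment`): 10 seeds of the default
  generator through the full RR-path pipeline (≈56 million beats per
  cohort). Person-level mean Ln(HF-HRV) lands within 0.15 of 4.5, its SD
  within 0.15 of 0.8, and mean valid days within 0.4 of 6.6.
* The direct path backs the model experiments and the RR path the
  signal-processing experiments, so failures localise to the stage that
  caused them.

`scripts/acceptance.py` re-runs both experiments from scratch with seeds
derived from `--seed` and writes the two headline numbers as JSON.

## Known limitations

* The REML search uses finite-difference gradients; with ~10 smoothing
  parameters this is robust but not the fastest possible scheme.
* Pointwise bands are bias-uncorrected; coverage dips slightly below
  nominal where the true curve bends sharply.
* Fisher's exact test is applied only to 2×2 tables (larger sparse tables
  fall back to chi-squared with a note).
* σ_ε and σ_b are not separately identifiable from the published cohort
  margins the generator targets; only their person-level combination is
  calibrated.
* Epoch-level HF estimates inherit a small negative bias (~frac
  interpolated) on epochs whose beats were corrected, since interpolation
  flattens the respiratory modulation in those beats.
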