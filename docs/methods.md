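# Methods

This note documents the models and procedures implemented in `alsquant`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generators do and do not establish.

## 1. Synthetic DAB histology (`alsquant.histology`)

The generator emulates a brightfield image of a coronal lumbar spinal-cord
section after DAB immunohistochemistry: brown motor-neuron somata and
lighter diffuse brown neuropil staining on a bluish counterstained tissue
region, surrounded by white slide background.

**Geometry.** The tissue region is a parametric ellipse or a bilateral
"butterfly" of two overlapping lobes. Somata are ellipses with equivalent
diameters drawn uniformly from a configured range (default 15–40 µm, the
scale of motor-neuron cell bodies at the default 0.65 µm/px), placed by
rejection sampling fully inside the tissue with ≥ 2 px clearance between
cells — except for requested *touching pairs*, circular cells placed at a
center distance of r₁ + r₂ − 1 px so they abut over a 1–3 px contact.
Touching pairs are the watershed stress test; the contact is kept narrow
so the split is testable rather than adversarial. Infeasible requests
(too many/large cells) raise an explicit placement error after a bounded
number of attempts.

**Stain fraction.** `diffuse_fraction` targets the *total* DAB-positive
fraction of tissue area — somata plus diffuse blobs. Blobs of shrinking
radius are added at random tissue locations until the realized fraction is
within ±0.01 of the target; scenes whose somata alone exceed the target
(or that cannot converge) are flagged (`diffuse_shortfall`) rather than
silently accepted. The stored positive mask therefore includes cell
pixels; this is the only self-consistent reading when percent-area
recovery is checked on images that also contain cells.

**Rendering.** Somata are painted dark brown (130, 80, 40), diffuse stain
a lighter brown (150, 110, 80) — mirroring the higher chromogen density of
cell bodies in real material, and what makes soma detection by color
thresholds well-posed — tissue bluish-gray (190, 190, 210), background
white. Optional Gaussian blur (µm) and additive Gaussian noise follow; all
randomness derives from the scene seed, and identical (config, seed) pairs
are bit-identical. The palette and scale are fixtures chosen once to
exercise RGB-threshold logic; they are not claims about any instrument.

## 2. IHC quantification (`alsquant.ihc`)

All tunables live in `QuantConfig`; the constants below were tuned once
against the synthetic palette and are instrument-specific.

* **Tissue mask** — per-channel RGB interval rule (anything darker than
  near-white), morphological closing + opening (2 µm), hole filling, and
  removal of debris < 500 µm².
* **Edge erosion** — binary erosion by a disk of the configured margin
  (default 5 µm) to avoid section-edge artifacts; anti-extensive by
  construction.
* **Motor-neuron detection** — three stages: (a) a global dark-brown color
  gate restricted to tissue, then opening (2 µm); (b) closing-by-
  reconstruction followed by opening-by-reconstruction (3 µm), which
  regularizes blobs without displacing their boundaries; (c) watershed on
  a marker landscape, dilation by 1 µm, and inclusive size filtering to
  [100, 1800] µm².
* **Watershed markers** — regional minima of the negated, Gaussian-smoothed
  (1.3 µm) Euclidean distance transform of the candidate mask, extracted
  with an h-extrema prominence threshold (0.65 µm). Prominence-based
  suppression was chosen over minimum-distance peak suppression because
  closing can bridge nearly-adjacent somata into clusters whose lobe
  maxima shift toward the bridges; a distance criterion then discards
  genuine markers, while a depth criterion does not. A smoothed-intensity
  landscape is available (`marker_source="intensity"`), but on flat
  synthetic somata the intensity is constant within a blob and cannot
  separate touching cells, so distance is the default.
* **Brown detection** — a pixel inside tissue is positive iff its
  normalized blue ratio B/(R+G+B) is below 0.28 and its mean intensity
  below 220 (excluding white background; zero-sum pixels are non-brown).
  Neighboring positives are filtered and merged by opening–closing. Both
  operators are monotone, so the positive count is monotone in the ratio
  threshold.
* **Cluster cutoff** — connected components (8-connectivity, as
  everywhere) smaller than `min_cluster_area_um2` (default 180 µm²) are
  removed whole; this is the sensitivity mechanism for enlarged microglia
  and clusters.
* **Percent area** — 100 × |positive ∩ tissue| / |tissue| in µm²; an empty
  tissue mask is an explicit error for this ratio (but a valid, area-0
  masking result upstream).
* **Count calibration** — OLS of automated on manual counts plus the mean
  fractional undercount; automated soma counting characteristically
  undercounts by a roughly constant factor, and the calibration quantifies
  it rather than correcting counts silently.

Anatomical restriction (e.g. to the ventral horn) is exposed as an
optional region mask with no default prior, since the analysis region of
the original workflow is not recoverable.

## 3. Cohort simulator (`alsquant.cohort`)

One mouse is a set of latent variables plus an observation timeline on the
study calendar (2 evenly spaced sessions/week for ages 42–63 d, 3/week
thereafter; exact weekdays are not modelled).

| process | model | defaults (`sod1_like_v1`) |
|---|---|---|
| disease death | Weibull(k, λ·ratio^treated) | k = 8, λ = 160 d, ratio = 1.0 |
| latent onset | Normal(µ + shift·treated, σ) | µ = 65 d, σ = 8 d, shift = +6 d |
| symptom flags | Bernoulli, p ramps after onset | 0.08/day ramp, baseline 0 |
| weight | logistic growth to an individual peak age, then proportional linear decline | asymptote 25 ± 2 g, midpoint 35 d, τ = 12 d, peak 100 ± 8 d, 0.5%/day decline, noise SD 0.3 g |
| wire hang | 60 s ceiling until an individual decline age, then linear fall with per-trial noise, clamped to [0, 60] | decline 95 ± 8 d at 1.5 s/day, noise SD 3 s |
| righting | prompt (1 s) until the final week of disease, then rising past 15 s | — |
| non-disease death | constant daily hazard after a threshold age | 0.006/day after 110 d |

The weight trend has a unique global maximum by construction (strictly
rising logistic, strictly falling decline), so running-peak tracking is
unambiguous; observation noise sits on top of the trend. Non-disease
deaths start at 110 d, echoing late injection-related losses, and are
recorded as censored in the survival frame. Arms are balanced exactly;
everything is deterministic given the seed.

The balance-beam session (3 trials × beams of 24/19/11 mm at ~17 weeks,
mice alive at test age only) draws latency from a linear mixed model and
slips from a Poisson log-linear mixed model, both with fixed intercept +
difficulty (mm below the largest beam) + treatment and per-animal random
intercepts and difficulty slopes.

These are the *simplest* generative forms reproducing the qualitative
trajectory shapes of a high-copy SOD1-G93A study. They deliberately omit:
litter/sex structure beyond a label, missed sessions, florid individual
heterogeneity, correlated symptom processes, and any pharmacokinetics. A
green end-to-end test therefore establishes that the derivation and
statistics recover known latent structure — not that the simulator is a
faithful model of real cohorts.

## 4. Endpoint rules (`alsquant.endpoints`)

* **Early symptom onset** — a session is positive iff tremor OR lost
  hindlimb extension; onset is the earliest pair of consecutive positive
  sessions. Dating defaults to the *first* of the pair ("appearance",
  confirmed by the second); `dating="second"` is available since the
  original convention is not recoverable. No pair → right-censored at the
  last observation.
* **Weight-loss onset** — first observation at or below (1 − d) × running
  peak (d defaults to 0.05) whose contemporaneous peak is never re-attained
  afterwards; transient dips followed by renewed growth are ignored. The
  operational definition is not fixed by convention anywhere, so d and the
  sustainedness rule are explicit and configurable.
* **Last full hang** — greatest age whose best-of-3 (cap 60 s) equals 60;
  still at 60 at the last session → censored there; never 60 → flagged
  degenerate event at the first hang session rather than silent exclusion.
  An empty session is a missing marker, never 0 s.
* **Humane endpoint** — righting strictly > 15 s ("within 15 seconds"
  passes at exactly 15) or weight ≤ 0.80 × peak (the 20% boundary
  included). Missing righting passes that criterion.
* **Censoring taxonomy** — of the seven death modes, found-dead-without-
  approaching-criteria, injury euthanasia, and weight-only-without-other-
  signs are censored; righting failure, weight criterion, both, and
  found-dead-near-criteria are events.
* **Dosing** — exact volume (µl) = weight(g) × dose(mg/kg) / conc(mg/ml),
  bracketed to the nearest 20 µl with ties rounding up (deterministic),
  and the delivered dose recomputed from the bracketed volume. Powder
  weight for formulation: W = conc / 0.915 × V (salt correction to free
  base).
* **NMJ innervation** — per-side percentages averaged (not pooled counts);
  a single scored side is used alone and flagged asymmetric.

## 5. Censored statistics (`alsquant.stats`)

**Risk table conventions.** One row per distinct event time; censored
subjects leave the risk set after their censor time; the hypergeometric
variance is 0 when a single subject remains.

**Combined test.** M = max(|Z_LR|, |Z_W|) with the Gehan–Breslow weighting
(w_j = n_j) as the default censored Wilcoxon; Peto–Prentice
(w_j = pooled modified KM survival) is available by flag, since which
variant the classical implementations used is a convention, not a fact
recoverable here. Significance by label permutation with group sizes
fixed: exhaustive enumeration when C(n, n₁) ≤ 20 000 (p is the exact
fraction of arrangements with M_b ≥ M_obs — the observed arrangement is
one of them), otherwise Monte Carlo with p = (1 + #{M_b ≥ M_obs})/(B + 1),
which never returns 0. Ties count toward rejection (conservative, exact
under exchangeability). Degenerate permutations (zero variance) contribute
M_b = 0 with a logged warning. Two-sided |Z|s are used throughout, since
reported p-values for such designs are conventionally two-sided. The
permutation core evaluates all arrangements as one matrix product against
precomputed at-risk/event indicator matrices, which is what makes the
calibration simulations (1000 replicates × B = 500) affordable.

**Kaplan–Meier.** Product-limit estimator; median = first event time with
S ≤ 0.5 (possibly not reached); the "mean" under censoring is reported as
the restricted mean survival time to the largest observed time — the only
well-defined nonparametric mean.

**Weibull LRT.** Censored ML in the extreme-value/log-time
parameterization (log-shape, log-scale intercept, treatment log time
ratio), Nelder–Mead from moment-based starts; the reduced model drops the
treatment term; Λ = 2Δℓ (clipped at 0) against χ²₁. Medians are
λ_g (ln 2)^{1/k}. Non-convergence raises an explicit `FitError`. The
treatment coefficient is relative to the alphabetically first group
label.

**Mixed models.** Latency: statsmodels `MixedLM` (correlated random
intercept + slope), fit by ML so the treatment LRT is valid; variance
components at/near zero or non-convergence set a boundary flag instead of
crashing. Slips: a Laplace-approximation Poisson GLMM (independent random
intercept and slope, the `(1 + x || g)` structure) authored here — the
conditional modes are found by damped Newton per animal, the marginal
likelihood approximated as h(b̂) − ½log det D − ½log det(Z'WZ + D⁻¹), and
the outer problem solved by Nelder–Mead; this is the same approximation
lme4's `glmer` defaults to, against which the implementation is
cross-checked in the test suite. All-zero counts return a flagged
degenerate result. Wald SEs are not reported for the GLMM (the LRT is the
inferential contract).

**qPCR.** ΔCt = Ct_target − Ct_reference per sample; ΔΔCt is the
difference of group means; fold change = 2^(−ΔΔCt); a two-sided t test on
ΔCt values accompanies it. Samples missing a Ct are excluded with a
warning.

**Multiplicity.** The endpoint table reports unadjusted p-values (the
conventional presentation for this study type) with a clearly labeled
Holm-adjusted column alongside.

## 6. Numerical and testing choices

* Coordinates are row-major, origin top-left, 0-based; areas are compared
  in µm² after scale conversion; size filters are inclusive on both
  bounds.
* Every stochastic component takes an explicit seed; generators use
  fresh `numpy` `default_rng` instances so outputs are bit-reproducible.
* The acceptance-style checks validate properties, not the original
  animal numbers: the study's per-animal data and images were never
  deposited, so equality with the original instrument-specific thresholds
  is not claimable and is not claimed.
* Calibration simulations in the test suite use the stated replicate
  counts (e.g. 1000 replicates at B = 500 for the type-I check); the
  null-uniformity check for the Weibull LRT uses n = 50/arm per replicate,
  a size choice made for runtime that does not affect the uniformity
  property being tested.

## 7. Known limitations

* The synthetic palette is far cleaner than real DAB material: no uneven
  illumination, stain gradients, tears, folds or out-of-focus regions.
  Exact count recovery on clean fixtures bounds algorithmic correctness,
  not real-world accuracy.
* The brown rule is a two-parameter color heuristic, not stain-vector
  deconvolution; heavily counterstained material would need retuning.
* The Laplace approximation can be biased for very small counts per
  animal; the beam simulator's defaults produce means where it is
  accurate (cross-checked against `glmer`).
* Endpoint rules assume complete sessions; no imputation of missed
  observations is attempted.
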