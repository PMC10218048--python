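# Methods

## The problem

Forensic body-fluid identification asks: given a stain of unknown origin,
which biological fluid (venous blood, menstrual secretions, feces, urine,
saliva, semen, vaginal secretions) produced it? MicroRNA expression measured
by RT-qPCR discriminates these fluids: a small panel of target miRNAs
(miR-200b, -320c, -10b, -891a, -141, -412, -205) shows fluid-specific
expression, and two endogenous references (let-7g, let-7i) are stable across
fluids and so normalize for input quantity.

`mirfluid` implements the statistical pipeline around such a panel:
normalization, missing-marker imputation, open-set quadratic discriminant
classification, and cross-validated evaluation, together with a synthetic
generator that emulates a casework-scale population study so every stage is
testable without access to restricted human data.

## Preprocessing

Each marker is amplified in duplicate technical replicates; the replicates
are averaged. A replicate pair further apart than the concordance limit
(default 1.0 cycle) is flagged `discordant_replicates` but retained — the
assay convention states duplicates, not a rejection rule. If any replicate
is a non-detect (never crossed the fluorescence threshold within the
40-cycle protocol), the marker is a non-detect for that sample.

The classifier feature is

    ΔCq = Cq(target) − mean(Cq(let-7g), Cq(let-7i))     [cycles]

Lower ΔCq = higher expression relative to the references. ΔCq is invariant
to adding a constant to all Cq values of a sample, which is what makes it
robust to input quantity.

Two handling rules matter:

* **Non-detect targets become missing values**, later imputed. Assigning a
  ceiling Cq (e.g. 40) instead would place a point mass at an arbitrary
  boundary and distort every Gaussian fit downstream.
* **Samples missing either reference marker are excluded** (with a written
  reason): ΔCq is undefined without the normalizer, and imputing the
  normalizer itself would manufacture the very quantity being controlled
  for.

## Imputation: conditional multivariate mean

Missing target markers are filled by single imputation under a pooled
multivariate normal fitted to all fully observed profiles (all fluids
together — at prediction time the fluid is unknown, so a class-specific
imputation model would be circular). For a profile with observed block *o*
and missing block *m*,

    x̂_m = μ_m + Σ_mo Σ_oo⁻¹ (x_o − μ_o),

the conditional mean given everything observed for that subject. Multiple
imputation is deliberately not used: the goal is a single reproducible
classification per sample, and a multiply-imputed sample has no single
validated call.

The pooled fit uses complete cases only (no EM): at the emulated study's
missingness (~71% complete of 355) that leaves ~250 rows for a 7-dimensional
fit, ample for a stable covariance.

## The Other class: open-set rejection

QDA alone must assign every point to some fluid, however extreme — an
extrapolation artifact. To prevent it, a synthetic "Other" training class is
built by fitting a pooled Gaussian to the whole dataset and drawing samples
outside its 3.5-standard-deviation ellipsoid, i.e. the Mahalanobis level set

    { x : sqrt((x−μ)ᵀ Σ⁻¹ (x−μ)) = 3.5 }.

Implementation: rejection sampling. Proposals come from N(μ, inflation²·Σ)
with inflation 2.0; proposals with Mahalanobis distance ≤ 3.5 are discarded.
Inflation 2 gives an acceptance probability of P(χ²_d > (3.5/2)²) ≈ 0.88 in
d = 7, while still concentrating Other mass near the boundary where the
open-set decision is made. A budget of 10⁶ proposals bounds the worst case;
exhausting it raises an error advising a larger inflation. The number of
Other rows defaults to the mean fluid-class size, keeping the augmented
design roughly balanced.

For reference, a draw from the fitted Gaussian itself lands outside the 3.5
ellipsoid with probability P(χ²₇ > 12.25) ≈ 0.093 — the ellipsoid is a
boundary of the *pooled, multi-fluid* cloud, not a per-fluid outlier test.

## Classifier

Quadratic discriminant analysis: each class k ∈ {7 fluids, Other} gets its
own Gaussian N(μ_k, Σ_k) (unbiased sample covariance per class), and

    p(k | x) ∝ π_k · N(x; μ_k, Σ_k).

Priors default to uniform over all classes including Other: forensic
casework has no defensible prevalence for body fluids, and empirical priors
would merely encode the study's collection convenience. (`priors_mode=
"empirical"` is available.)

All density arithmetic is in log space: log-determinants from a Cholesky
factorization, max-subtraction before exponentiation, so posteriors stay
finite and normalized even thousands of SDs from every class. Every
covariance carries a relative ridge, ridge × (trace/d) on the diagonal
(default ridge 1e−6), and any factorization failure is reported with advice
to raise it — never silently pseudo-inverted.

**Confidence gate.** A call is reported only if the top posterior reaches
the threshold (default 50%); otherwise the sample is "inconclusive". Exact
ties resolve to the earlier class in panel order. The published three-column
rate-table layout (correct / another body fluid / Other) has no
inconclusive column, so the gate can be disabled (`gate=False`,
`--no-gate`) to force an argmax call for every sample; both behaviors are
first-class because the source analysis does not state which was used when
no posterior reached 50%.

## Cross-validation

Stratified k-fold (default k = 10): within each class, samples are shuffled
and dealt round-robin to folds, the dealing counter carrying across classes,
so per-class fold counts differ by at most one. Stratification is a design
choice — with ~50 samples per class, unstratified 10% folds risk losing a
class from a training fold entirely.

Per fold, everything downstream of the raw profiles is recomputed from the
training fold only: pooled imputation Gaussian, imputed training rows, Other
draws (per-fold seed), per-class QDA fit. Held-out rows are imputed with the
*training* fold's pooled Gaussian and then classified. This is the
leakage-free ordering; whether the original analysis imputed before or after
splitting is unstated, so the leaky variant (`impute_before_split=True`) is
kept for comparison but is not the default. The per-fold parameters are
retained in `CVResult.folds` so leakage-freedom can be audited by
recomputation — the test suite does exactly that.

Results aggregate into a `RateTable`: per true fluid, the fractions called
correctly, called as another body fluid, rejected into Other, or gated
inconclusive (rows sum to 1); overall accuracy is the n-weighted mean of
per-class correct rates. CSV output prints fractions to 4 decimals.

## Synthetic data generator

The generator emulates the statistical shape of a casework-scale population
study:

* **Class sizes** (51, 53, 50, 46, 53, 52, 50) — 355 samples.
* **Per-fluid ΔCq distributions**: multivariate normal, d = 7. The default
  mean vectors are invented fixtures following qualitative literature
  patterns — semen extreme (low) in miR-891a, feces low in miR-141, saliva
  low in miR-205/miR-412, blood low in miR-320c/miR-10b, urine low in
  miR-200b, menstrual intermediate between blood and vaginal — with
  marginal SDs 1.2–1.5 cycles and exchangeable within-fluid correlation
  0.3. Menstrual and vaginal secretions deliberately overlap, since that is
  the canonical hard pair. With these defaults the full pipeline
  cross-validates in the high-80s/low-90s percent overall — a moderate,
  non-saturated regime whose confusion structure (menstrual↔vaginal
  dominant) mirrors real panels without reproducing any real dataset's
  numbers.
* **Missingness**: MCAR, uniform per-marker rate r solving (1−r)⁷ = 252/355
  (r ≈ 0.0477), so the expected complete-case fraction is ≈ 71%.
* **Replicate-level simulation** (`level="cq"`): per sample, reference Cq ~
  N(20, 1.5²) per reference marker; each target's true Cq is the reference
  average plus the latent ΔCq; duplicate replicates add N(0, 0.25²) noise;
  Cq above 40 becomes a non-detect; masked markers are simply not measured.
  In the zero-noise, zero-missingness limit this construction is exactly
  inverted by preprocessing (to ~1e−15), which the tests assert at 1e−12.
* **Treatments**: named additive per-marker ΔCq offsets (degradation delays
  amplification, raising ΔCq). Defaults: "heat" hits miR-891a/-412/-205
  (+2–3 cycles), "chem_uv" hits miR-200b/-10b/-205. These model the
  *direction* of degradation effects — classification of shifted fluids
  degrades when the model was trained untreated — not any measured
  magnitude.

What passing tests on this generator do **not** show: robustness to
non-Gaussian ΔCq distributions, informative (non-MCAR) missingness,
between-run batch effects, inhibited reactions, or mixed-source stains.
Mixture deconvolution is explicitly out of scope.

## Numerical choices

* Ridge: relative, ridge × (trace/d), so it is invariant to rescaling all
  markers jointly; default 1e−6.
* All solves via Cholesky; PSD validation tolerates eigenvalues ≥ −1e−8 ×
  scale to absorb round-off, and serialization uses shortest round-trip
  float `repr` so write→read is bit-identical for CSV profiles, Cq tables
  and model JSON.
* Determinism: every stochastic step takes an explicit seed; the CV driver
  derives its fold-split seed and per-fold Other seeds from one master seed
  (default 7), so rate tables and per-sample prediction CSVs are
  byte-identical across reruns.
* Degenerate inputs: fully missing profiles are an error at imputation
  (nothing to condition on); classes with fewer than d+1 rows are a training
  error naming the class; a training fold that loses a class is a fold
  error.

## Known limitations

* The Other augmentation is a ring of samples just outside the pooled
  ellipsoid; its fitted Gaussian is broad and can absorb a small fraction
  (typically ≲ 2%) of legitimate fluid samples near their cluster fringes,
  visible even on cleanly separated synthetic data. Raising the Other count
  or the inflation trades this against open-set sensitivity.
* Complete-case estimation of the pooled Gaussian is slightly inefficient
  versus EM under MCAR and biased under informative missingness.
* The confidence gate applies to the argmax posterior only; a calibrated
  confidence (e.g. conformal) is not attempted.
* Rate tables condition on the true fluid; no ROC/AUC or mixture analysis.
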