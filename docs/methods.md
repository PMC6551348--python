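# Methods

This note documents the statistical model the package implements, the
synthetic cohort it is validated on, the numerical choices that matter, and
what the validation studies do and do not establish.

## Normative model

At each vertex the measurement (cortical thickness, mm) is modeled as a
zero-mean Gaussian process over the covariates after centering the targets:

K(x, x′) = v_s · exp(−½ Σ_j (x_j − x′_j)²/ℓ_j²) + v_lin ⟨x, x′⟩ + v_b,
observations y = f(x) + ε with ε ~ N(0, σ²_n).

The composite kernel is a deliberate design choice: the linear + bias
components capture the dominant near-linear age decline of cortical
thickness cheaply and extrapolate sensibly, while the ARD squared
exponential accommodates curvature (inverted-U trajectories) where the data
demand it; far from the training ages the stationary component reverts to
the prior, so predictive intervals widen — inference becomes more
conservative where data are scarce. Continuous covariates are z-scored with
the training statistics (stored with the model); 0/1 dummies pass through.

Hyperparameters (log v_s, log ℓ_j, log v_lin, log v_b, log σ²_n) are set
per vertex by empirical Bayes: L-BFGS-B on the negative log marginal
likelihood with analytic gradients, one heuristic start (half the target
variance in signal and noise, unit length scales) plus 5 random restarts
(unit log-normal perturbations), convergence tolerance 1e-6 on the NLML,
box bounds on the log scale to prevent overflow. A relative jitter of
1e-6 × mean diagonal is added before Cholesky factorization and escalated
×10 up to three times on failure; a vertex whose restarts all fail is
flagged, excluded downstream, and removed from every subject's
multiple-testing family.

**Cross-validation discipline.** Reference (TD) subjects are scored
strictly out-of-fold under seeded 10-fold CV (unstratified by default;
sex stratification available); clinical subjects are scored by the model
refit on the full reference cohort. Provenance is recorded per subject
and enforced: fit evaluation refuses predictions that are not
out-of-fold. Within the CV loop each fold's optimization warm-starts from
the full-cohort optimum but re-maximizes its own marginal likelihood on
the fold's training subjects only; the warm start affects only which
local optimum the fold converges to, not what data inform it, and the
calibration study below verifies out-of-fold behavior empirically.

**Deviations.** Z = (y − ŷ)/√(σ²_* + σ²_n); two-sided normal p-values;
Benjamini–Hochberg step-up within each subject across its valid vertices
at q = 0.05, signs kept after rejection. Two-sided p-values were chosen
because deviations of both signs are of interest; BH (not BY) matches
common vertexwise practice. The extreme score is the mean of the
⌈0.01·m⌉ largest |Z| (⌈·⌉ with a floor of one vertex, so small parcels
reduce to the parcel maximum). The cross-subject law of these scores is
modeled as Gumbel — the natural domain of attraction for maxima of
near-Gaussian deviations — fit by maximum likelihood via the 1-D profile
equation for the scale (bracketed Brent solve seeded at the moment
estimate) and the closed-form location; a GEV alternative sits behind a
flag. The top-k membership test defaults to the hypergeometric null
(sampling k subjects without replacement from the realized cohort sizes);
binomial-cohort and coin-flip (0.5) nulls are also implemented, because
the choice materially changes the tail probability (at 527 subjects,
321 cases, k = 15: ≈5.2e-4, ≈5.9e-4 and ≈3.05e-5 respectively) and which
null a reported bound refers to is often ambiguous.

**Associations.** Spearman ρ via mid-ranks; p by the t approximation for
n ≥ 10 and exhaustive permutation below that. FDR families are
(symptom × stratum) across parcels — male and female maps corrected
separately, a documented choice where either convention is defensible —
while the global score is tested at nominal α in its own right. Missing
symptom scores are dropped pairwise per instrument, with the n used
recorded in every cell. Confound checks (IQ, image-quality surrogate) are
reported descriptively, flagged post hoc, without FDR.

**Case-control GLM.** Ordinary least squares per vertex on diagnosis,
centered age polynomial terms (centering limits collinearity among
powers), and optionally sex; t-test on the diagnosis (or
diagnosis-by-age) coefficient; BH across vertices. Sex-stratified models
drop the sex column. Rank-deficient designs raise an error naming the
collinear columns.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with the emulated study's exact design: 206 TD (127 male) and 321 ASD
(232 male) subjects in four recruitment schedules (A adults 125/84,
B adolescents 112/70, C children 64/52, D adolescents/adults with
IQ < 70, 20/0 — ASD/TD), ages uniform within each schedule's window
(the within-schedule age distribution is a stand-in; the real one is not
published), IQ truncated-normal above 70 except schedule D.

Vertices (default 1,000 in 34 contiguous parcels, a single-hemisphere
Desikan–Killiany-scale stand-in) get trajectory coefficients drawn once
per seed: intercepts 2.6–3.6 mm, linear slopes −0.035 to −0.005 mm/yr,
with 20% of vertices given an inverted-U (peak age 8–14, curvature
−0.004 to −0.001 mm/yr²); sex offsets up to ±0.06 mm; independent
Gaussian noise with per-vertex SD 0.10–0.25 mm. These ranges are chosen
to be realistic for cortical thickness development; no spatial
autocorrelation of the noise is simulated (a documented non-goal), so
the generator is *harder* than real data for spatial methods and
*exactly* matched to the per-vertex independence the analysis assumes.

Deviations are planted in an exact-count subset of ASD subjects
(round(prevalence · n), default prevalence 0.4) rather than by Bernoulli
sampling, so truth-based tests are non-flaky. Each affected subject gets
2 whole parcels (individualized: parcels drawn independently per subject,
so cross-subject overlap is minimal by construction), with magnitudes
|N(4, 0.5²)| in units of the vertex noise SD and a sign determined by
schedule: negative for children (C), positive for adolescents/adults
(A, B, D). With prevalence 0 the ASD and TD laws are identical — the
null embedding under which all detection stages must run at nominal
error rates.

Symptom scores (ADI-R social/communication/repetitive, ADOS-2
total/social/repetitive) are generated for ASD subjects only through a
Gaussian copula on the mid-ranks of the per-subject planted magnitude:
the latent Pearson correlation is 2·sin(πρ_S/6), the bivariate-normal
inversion of the target Spearman ρ_S, then rescaled to the instrument's
target moments (e.g. ADI-R repetitive 4.32 ± 2.69). Scores are left
continuous and unclipped so the configured moments and rank link are
exact in expectation. The default link is −0.21 for ADOS-2 repetitive
behavior and −0.10 elsewhere. Missingness is listwise per instrument at
exact counts (ADI-R observed for 308/321, ADOS-2 for 258/321). All
stages draw from named SeedSequence substreams of one seed;
identical configuration is bit-identical output.

## Validation studies and problem sizes

`normdev.evaluation` (exercised by `tests/test_acceptance.py` and
`scripts/acceptance.py`) recomputes:

* **Enrichment bound** — top-15 all-cases tail probability under all
  three nulls at the 527/321 cohort sizes (closed forms).
* **Oracle equivalence** — GP mean/variance/NLML against dense
  explicit-inverse algebra at n ≤ 50; BH against the literal step-up scan
  on 1,000 random p-vectors; trimmed-top scores against a full sort;
  Spearman against rank-then-Pearson.
* **Calibration** — 206 reference subjects × 200 vertices, 10-fold CV:
  pooled out-of-fold mean Z and the |Z| > 1.96 exceedance fraction.
  200 vertices keeps the study a few CPU-minutes while pooling ~41k
  Z values, plenty to resolve the 5% ± 1.5% band.
* **FDR control** — 500 null subjects × 1,000 vertices, average realized
  per-subject false-discovery proportion at q = 0.05.
* **Recovery** — GP signal/noise log-variances (mean error over 20
  replicates at n = 200, generating RBF length scale e^−0.7 ≈ 0.5 so the
  signal variance is identified rather than degenerate with the linear
  component); Gumbel location/scale at n = 5,000 (20 replicates);
  symptom-link ρ at the generator's ADOS-2 sample size (50 replicates).
* **Headline contrast** — the full 527-subject default cohort at 250
  vertices (34 parcels preserved, so per-subject deviation extent in
  vertices scales down with the parcels): GLM-significant vertex
  fraction, proportion of cases with ≥1 significant deviation, summed
  case/reference overlap ratio, extreme-score rank-sum shift. The vertex
  count is the package's own runtime choice for this replication-style
  study; the contrast is parcel-level and does not depend on it. The
  shift is additionally replicated over 20 seeds at a further reduced
  scale (80 TD + 120 ASD, 60 vertices).

## Known limitations

* Empirical Bayes is plug-in: hyperparameter uncertainty is not
  propagated into predictive variances. At the study's reference size
  (~185 training subjects per fold) out-of-fold Z calibration holds to
  within the tested bands, but with much smaller reference cohorts
  (a few dozen subjects) the extreme tails of Z become mildly
  anti-conservative, visible as an elevated per-subject any-rejection
  rate in the README's miniature example.
* Gaussian likelihood only; no warped or heteroscedastic variants, no
  sparse approximations for very large vertex counts.
* The generator omits spatial noise autocorrelation, site effects on the
  measurements, and longitudinal structure; passing tests therefore
  certify the statistical machinery under the stated generative law, not
  robustness to those real-data features.
* Exact GP inference is O(n³) per vertex per fit; the default pipeline is
  sized for cohorts of hundreds of subjects and ~10³ vertices.
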