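# normdev

Normative modeling of heterogeneous cortical anatomy.

Case-control comparisons describe the *average* patient, but conditions such
as autism spectrum disorder are strikingly heterogeneous: different
individuals can depart from typical brain development in different places and
in different directions, so group means wash the effects out. `normdev`
implements the complementary, individual-centric analysis: a **normative
model** — the neuroimaging analogue of a pediatric growth chart — is fit to a
typically developing (TD) reference cohort, and every clinical (ASD) subject
is then scored against the typical range at every cortical location.

## The model

At each surface vertex *v*, cortical thickness *y* is modeled as a Gaussian
process over covariates **x** = (age, sex):

    y(x) ~ GP(m, k(x, x')) + ε,   ε ~ N(0, σ²_n)

with a composite covariance (ARD squared-exponential + linear + bias) whose
hyperparameters are set per vertex by empirical Bayes (type-II maximum
likelihood). The reference cohort is scored under 10-fold cross-validation
(every TD prediction is out-of-fold); the model is then refit on all TD
subjects to score the clinical cohort. For subject *i* the deviation is

    Z_iv = (y_iv − ŷ_iv) / sqrt(σ²_*iv + σ²_n,v)

i.e. the residual standardized by the *total* predictive uncertainty (latent
function variance plus noise). Downstream stages:

* **Normative probability maps** — two-sided normal p-values per vertex,
  thresholded by Benjamini–Hochberg FDR *within each subject* (q = 0.05),
  keeping the deviation's sign.
* **Overlap maps & GLM** — per-vertex counts of significantly deviating
  subjects (by cohort, schedule and sign) next to the classical
  mass-univariate case-control GLM, exposing the contrast between sparse
  individual deviations and absent group effects.
* **Extreme scores** — each subject's atypicality summarized by the trimmed
  mean of the top 1% absolute Z (globally and per parcel), modeled across
  subjects with a maximum-likelihood Gumbel fit, plus a top-k
  cohort-membership (enrichment) test.
* **Associations** — Spearman correlations of extreme scores with symptom
  instruments (ADI-R / ADOS-2 domains), overall and by sex, FDR-corrected
  per (symptom × stratum) family across parcels, plus post hoc confound
  checks (IQ, image-quality surrogate).

Because no subject-level imaging data ship with the package, a first-class
**synthetic cohort generator** emulates the study's statistical structure
(declining, partly inverted-U thickness trajectories; sex offsets; sparse
subject-specific, schedule-signed deviations; copula-linked symptom scores)
with exact-count determinism, so every stage is testable end-to-end.

## Worked example

```python
from normdev import RunConfig, scaled_simulation_config, run

config = RunConfig(
    simulation=scaled_simulation_config(
        n_td=60, n_asd=60, n_vertices=80, n_regions=16, seed=0),
    folds=10, seed=42)
results = run(config, out_dir="example_out")

print("GLM-significant vertices:", int(results["glm"]["significant"].sum()))
asd = (results["cohort"]["group"] == "ASD").to_numpy()
print("ASD subjects with >=1 significant deviation:",
      int((results["mask"][asd] != 0).any(axis=1).sum()), "/", asd.sum())
tk = results["topk"]
print(f"top-{tk.k} membership: {tk.n_cases_in_top} cases, "
      f"p = {tk.p_value:.4f} ({tk.null})")
```

prints

```
GLM-significant vertices: 0
ASD subjects with >=1 significant deviation: 32 / 60
top-15 membership: 14 cases, p = 0.0002 (hypergeometric)
```

— the package's central result in miniature: the case-control GLM finds
nothing, yet the individual deviation maps flag every one of the 24 ASD
subjects carrying planted deviations (plus a handful of tail false
positives at this deliberately small reference size; see
`docs/methods.md`), and 14 of the 15 most atypical subjects are cases.
The run
directory contains the cohort table, Z/p/mask matrices, overlap and GLM
tables, extreme scores, association tables and a `manifest.json` with
seeds, parameters and per-stage summaries; re-running with the same
config is bit-identical (stage timings go to the log, keeping the
manifest deterministic).

The same stages are available from the shell:

```bash
normdev run --out out --seed 42            # everything, default design
normdev simulate --out data --seed 1       # or stage by stage:
normdev fit --in data --out data --folds 10 --seed 1
normdev npm --in data --out data --q 0.05
normdev overlap --in data --out data
normdev glm --in data --out data --age-powers 1,2,3
normdev extremes --in data --out data --topk 15 --null hypergeometric
normdev associate --in data --out data
```

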