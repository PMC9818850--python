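# gmsubtype

Cross-species glycolysis-metabolic (GM) subtyping of liver tumors.

Hepatocellular carcinoma cells often run glycolysis far above normal
hepatocytes, and how strongly a tumor commits to that metabolic program
carries prognostic information. `gmsubtype` implements the comparative
pipeline that quantifies this: a controlled mouse feeding experiment
(fructose or glucose vs tap water) defines a hepatic glycolytic gene
expression signature, and that signature — transferred to human tumors
through 1:1 orthologs — scores each tumor's glycolytic activity and
stratifies patients into high / middle / low metabolic subtypes whose
overall survival separates. The package is aimed at computational biologists
who want to derive such diet-induced signatures, apply them across species,
and validate the resulting subtypes against clinical outcomes, without
depending on any particular array platform or download.

## Method

1. **Signature derivation.** For each sugar-vs-control contrast, a per-gene
   two-sample Student's *t*-test selects genes at *p* < 0.01; the
   direction-consistent intersection of the two contrasts is the GM
   signature, with per-gene weights *t<sub>i</sub>* (training
   *t*-statistics).
2. **Cross-species transfer.** Mouse and human matrices are restricted to
   shared 1:1 orthologs and each gene is independently converted to
   z-scores, *z* = (*x* − mean)/SD, within its own dataset.
3. **Bayesian compound covariate prediction (BCCP).** Each sample is scored
   by the compound covariate *c* = Σ<sub>i</sub> *t<sub>i</sub>
   z<sub>i</sub>*. Class-conditional Gaussians N(μ<sub>k</sub>,
   σ<sub>k</sub>²) are fitted to the training samples' scores (sugar-fed vs
   control) and a tumor's posterior probability of high glycolytic activity
   follows from Bayes' rule with equal priors. Training robustness is
   estimated by leave-one-out cross-validation with full in-loop gene
   re-selection.
4. **Trichotomization & validation.** Posteriors > 0.8 call a tumor
   *high*, < 0.2 *low*, anything else *middle*. Subtypes are validated with
   Kaplan–Meier curves, *k*-group log-rank tests, univariate/multivariate
   Cox proportional-hazards regression, and association tests against
   mutation and per-sample score tables (Fisher exact, Welch *t*, Pearson).

A fully seeded synthetic-data module generates the mouse experiment
(3 groups × 6 animals, partially overlapping induced gene sets) and a human
cohort in which a latent metabolic score loads on the signature orthologs
and multiplies the survival hazard — so the entire pipeline runs and is
tested end-to-end with no downloads.

## Worked example

```python
import pandas as pd
from gmsubtype import (MouseSimConfig, HumanSimConfig, OrthologMap, BCCP,
                       simulate_mouse, simulate_cohort, derive_signature,
                       zscore_genes, loocv, predict_cohort, logrank_test,
                       km_estimate)

# mouse feeding experiment and signature
expr, labels, truth = simulate_mouse(MouseSimConfig(seed=1))
sig, venn = derive_signature(expr, labels)
print(f"contrast X: {venn['n_x']} genes, contrast Y: {venn['n_y']} genes, "
      f"overlap signature: {venn['n_overlap']}")

# train the predictor and cross-validate
res = BCCP(zscore_genes(expr), labels, sig).fit()
print(res.summary())
cv = loocv(expr, labels)
print(f"LOOCV sensitivity={cv.sensitivity:.2f}, specificity={cv.specificity:.2f}")

# score a human cohort through the ortholog bridge
omap = OrthologMap(pd.DataFrame({"a": expr.gene_ids,
                                 "b": ["H" + g.upper() for g in expr.gene_ids]}))
human_sig = sorted("H" + g.upper() for g in truth.overlap)
cohort, clinical, _ = simulate_cohort(HumanSimConfig(seed=2), human_sig)
calls = predict_cohort(res, cohort, ortholog_map=omap, train_expr=expr)
print(calls.counts().to_dict())

lr = logrank_test(clinical, calls)
print(f"log-rank chi2={lr.chi_square:.2f} (df={lr.df}), p={lr.p_value:.2g}")
```

Output:

```
contrast X: 366 genes, contrast Y: 363 genes, overlap signature: 57
Bayesian Compound Covariate Predictor
=============================================
Signature genes (usable)   57
Class priors (high, ctrl)  0.5, 0.5
mu_high, sigma_high        155.2, 20.26
mu_control, sigma_control  -310.4, 23.12
Class separation (d)       15.15
Training resubstitution acc 1.000
LOOCV sensitivity=1.00, specificity=1.00
{'high': 176, 'middle': 0, 'low': 124}
log-rank chi2=12.73 (df=1), p=0.00036
```

Of 5000 simulated genes, 366 respond to fructose and 363 to glucose at
*p* < 0.01; their direction-consistent overlap (57 genes) is the signature.
The two training classes separate completely (LOOCV 1.0/1.0). In a 300-tumor
cohort the predictor calls 176 high and 124 low, and the high-metabolic
subtype's survival is markedly worse (log-rank *p* ≈ 4 × 10⁻⁴; median 17.4
vs 36.9 months).

The same workflow is available from the shell:

```sh
gmsubtype run --out-dir demo_run --seed 1     # full demo pipeline
gmsubtype report --run-dir demo_run           # markdown summary
```

and stage-by-stage via `simulate`, `derive-signature`, `train`, `predict`,
`survival` and `assoc` subcommands operating on plain TSV/JSON files.

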