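# Methods

## The model

`gmsubtype` treats "glycolytic activity" of a tumor as a one-dimensional
score learned from a controlled cross-species contrast. The training data
are mouse livers under three diets (control tap water, 20% fructose, 20%
glucose; n = 6 each). Genes responding to either sugar at p < 0.01
(two-sided Student's t-test, pooled variance) whose response direction
agrees across the two sugars form the glycolysis-metabolic (GM) signature;
each signature gene carries its training t-statistic t_i as a weight.

Transfer to human tumors assumes only that ortholog expression ranks
comparably after within-dataset standardization: both matrices are
restricted to 1:1 orthologs and each gene row is z-scored (sample SD,
divisor n−1) inside its own dataset. No cross-dataset normalization is
attempted — the z-score is the entire bridge.

The classifier is a Bayesian compound covariate predictor. A sample with
standardized signature expression z_i gets the score

    c = Σ_i t_i · z_i

Gaussians are fitted to the training scores of each class (sugar-fed,
control) by moment matching, and the posterior of the high-metabolic class
is Bayes' rule over those two densities with equal priors:

    P(high | c) = π_h φ(c; μ_h, σ_h) / [π_h φ(c; μ_h, σ_h) + π_c φ(c; μ_c, σ_c)]

Tumors are trichotomized at the posterior: > 0.8 high, < 0.2 low, otherwise
middle (both boundaries fall in the middle class). Subtype validity is then
a survival question: Kaplan–Meier curves per subtype, the k-group log-rank
test, and Cox proportional-hazards regression with the subtype encoded as
the binary "high vs middle/low" indicator alongside clinical covariates.

### Assumptions

- The diet contrast in mouse liver is a usable proxy for tumor glycolytic
  activity; the package tests transferability mechanics, not that biology.
- Two classes suffice; the middle subtype is deliberate abstention, not a
  third fitted class.
- Class-conditional score distributions are adequately Gaussian. With many
  summed genes this is mild (CLT on c).
- Proportional hazards between subtypes for the Cox stage.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `p_cutoff` | 0.01 | per-gene selection level, strict `<`; raw p by design — the classifier, not the gene list, carries the inference, and FDR correction is intentionally not applied at this stage |
| selection mode | two_sided + same direction | keeps coherently down-regulated genes; `up_only` available |
| `weight_mode` | refit | weights re-estimated as pooled sugar-vs-control t-statistics on the training z-matrix; `signature` uses the stored mean-of-contrasts weights |
| priors | 0.5 / 0.5 | training arms are 12 sugar-fed vs 6 control; equal priors keep the unbalanced design from biasing the posterior |
| trichotomy cutoffs | 0.2 / 0.8 | posterior abstention band; boundaries map to middle |
| `min_coverage` | 0.7 | minimum fraction of signature genes a cohort must cover; partial scores are renormalized by total/present absolute weight |
| variance mode | pooled | classical Student's t; Welch by flag |

Training contrast: the predictor is trained on pooled sugar-fed (n = 12)
vs control (n = 6); per-diet training is available through the contrast
arguments.

## The synthetic-data generators

`simulate_mouse` emulates the feeding experiment: per-gene baselines
N(8, 1) log-units, i.i.d. N(0, noise_sd²) noise, and additive shifts of
`effect_size`·noise_sd (default 2.0) applied to the induced genes of each
diet group. Defaults — 5000 genes, 490 fructose-induced, 505
glucose-induced, 21% of the smaller set shared (~103 genes) — mirror the
proportions of a real diet experiment at about a quarter of whole-array
scale, keeping every test desk-sized. At these conditions the exact
noncentral-t power of a single p < 0.01 gene test is 0.62, so roughly 60%
of induced genes are recovered per contrast and ~40% of the true overlap
survives both contrasts; the class separation of the resulting compound
covariate is nonetheless extreme (standardized distance > 10), which is why
leave-one-out classification is perfect while gene-level recovery is not.

`simulate_cohort` generates a human cohort in which a standard-normal
latent metabolic score g per patient loads (coefficient `loading`, default
2.0) on every signature ortholog, with pure-noise genes elsewhere. True
classes are the tertiles of g. Survival is exponential under proportional
hazards: baseline 0.02 events/month, multiplied by exp(log 3) for the true
high tertile; censoring mixes a 60-month administrative horizon with
uniform random early censoring for 20% of patients (~30–40% censoring
overall). Binary clinical covariates (AFP > 300 ng/mL, tumor size > 6 cm,
BCLC B/C/D, cirrhosis, sex, age > 60) are independent Bernoulli draws with
liver-cancer-plausible prevalences; they are deliberately independent of g
so covariate-adjusted analyses have a known null.

All randomness flows through one `numpy.random.Generator` seeded from the
config; identical config + seed reproduces byte-identical files.

**What the simulators do not emulate:** probe-level microarray artifacts,
batch and platform effects, correlated gene modules, non-1:1 ortholog
structure, informative censoring, covariates correlated with metabolic
state, and mutation landscapes (mutations are i.i.d. Bernoulli, used only
to test the association machinery). Passing tests therefore demonstrate
that the pipeline's mathematics and plumbing are correct and calibrated
under its own assumptions — not that the biological signature transfers on
any particular real cohort.

## Numerical choices

- **Degenerate t-tests.** Zero variance on both sides with equal means →
  t = 0, p = 1; with unequal means → p = 0; both flagged `degenerate` and
  excluded from signatures by default. Genes with < 2 usable samples per
  side are dropped with a log entry; missing values are handled
  pairwise-complete per gene.
- **Posterior evaluation** uses log-densities and `logsumexp`; when both
  class densities underflow far in the tails, the tie is broken by distance
  to the class means. Agreement with the plain density-ratio formula is
  verified to 1e-12.
- **z-scores** use the n−1 sample SD; zero-SD rows are dropped with a
  warning; z-scoring requires ≥ 3 samples, so single-sample prediction is
  unsupported by design (practical minimum cohort ≈ 10).
- **LOOCV** re-selects the signature inside every fold (honest CV: t-tests,
  selection, intersection, refit), standardizes the held-out sample with the
  fold's training means/SDs, and classifies at posterior 0.5. A
  `fixed_signature` mode skips re-selection; it is optimistically biased and
  intended for exploration. In the minimal n = 2-per-class setting a fold
  leaves a singleton class; the fold then borrows the other class's SD for
  the singleton Gaussian and uses the fixed signature weights — outside
  folds, classes with < 2 samples are an error.
- **Cox regression** delegates to lifelines (Newton–Raphson tightened to
  1e-12 step precision), which implements Efron tie handling; with the
  generators' continuous times there are no ties, where Efron and Breslow
  coincide. Wald 95% CIs, two-sided p. The multivariate model includes
  exactly the covariates with univariate Wald p < 0.05 (the conventional
  two-stage screen).
- **Fisher association tests** are subtype-vs-rest 2×2 exact tests;
  Benjamini–Hochberg FDR is reported across genes alongside raw p. Exact
  p-values are discrete and conservative (super-uniform under the null), so
  calibration checks bound the rejection rate rather than testing
  uniformity.
- **Duplicate probes** collapse to the maximum-variance row (deterministic,
  favors informative probes); a mean rule is available. Gene ids match
  case-insensitively (mouse Title-case vs human upper-case), original
  spellings preserved.

## Open design choices made here

- Per-gene signature weights are not uniquely determined by membership in
  two contrasts; the package defaults to refitting them on the pooled
  sugar-vs-control training contrast, with the symmetric
  mean-of-contrast-t's stored in the signature as the fallback.
- Human cohorts are z-scored per cohort before prediction ("independently
  converted"); a pooled multi-cohort mode can be assembled by concatenating
  matrices before prediction, but per-cohort is the supported default.
- Selection is two-sided with direction consistency required, which covers
  both an "induced genes" and a "differentially expressed genes" reading of
  the derivation; `up_only` mode implements the strictly-induced variant.

## Problem sizes used by the test suite

Unit and acceptance tests run at the generators' default conditions (5000
genes × 18 mice; cohorts of 300). Replicated checks use 20 cohorts for
posterior/latent-score recovery, 50 replicates of n = 500 for Cox hazard
recovery, 100 replicates for log-rank power, 200 replicates of n = 60 for
null log-rank calibration, and 1000 random small instances per brute-force
oracle. Full-pipeline determinism and CLI tests use a 1200-gene / 120-
patient configuration, chosen as the smallest scale at which every stage
(coverage checks included) is still exercised.

## Known limitations

- Per-gene selection at n = 6 per arm has 0.62 power at the default effect
  size; derived signatures are reliable but incomplete subsets of the true
  induced sets.
- With strongly separated training classes the posterior saturates near 0/1
  on cohort samples, so the middle subtype can be empty on clean synthetic
  cohorts; middle calls arise from noisier, weaker-loading data.
- The Gaussian score model is unweighted by gene-gene correlation; strongly
  co-expressed signatures overstate the effective number of independent
  genes.
- No platform/batch correction: cross-dataset comparability rests entirely
  on within-dataset z-scoring.
- The Cox stage assumes proportional hazards and provides no diagnostics
  (out of scope); time-varying effects, competing risks and stratification
  are not supported.
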