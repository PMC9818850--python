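"""Cross-species harmonization and the Bayesian compound covariate predictor.

The predictor scores a sample by the compound covariate

    c = sum_i t_i * z_i

over signature genes, where z_i is the per-gene z-score (computed within
each dataset independently, sample SD with n-1) and t_i the per-gene
training t-statistic. Class-conditional Gaussians N(mu_k, sigma_k^2) are
fitted to the training samples' compound covariates for the two classes
(sugar-fed vs control), and a new sample's posterior probability of the
high-metabolic class follows from Bayes' rule with configurable priors
(equal by default, so unequal training arms do not bias the posterior):

    P(high | c) = pi_h phi(c; mu_h, s_h) / [pi_h phi(c; mu_h, s_h) + pi_c phi(c; mu_c, s_c)]

Posteriors are trichotomized into high (> 0.8), low (< 0.2) and middle
(boundaries inclusive) subtype calls.

Organised statsmodels-style: :class:`BCCP` is the model specification built
from data, its :meth:`BCCP.fit` returns a :class:`BCCPResults` carrying the
fitted parameters, training diagnostics, prediction methods and a
``summary()`` table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .data import (
    DataError,
    ExpressionMatrix,
    GeneSignature,
    OrthologMap,
    SampleLabels,
    SubtypeCalls,
)
from .signature import derive_signature, per_gene_ttest

logger = logging.getLogger(__name__)

WeightMode = Literal["refit", "signature"]


# ---------------------------------------------------------------------------
# z-scoring and cross-species harmonization
# ---------------------------------------------------------------------------

def zscore_genes(expr: ExpressionMatrix, drop_zero_sd: bool = True) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sample SD 1 (ddof=1) within the dataset.

    Rows with zero SD carry no information and are dropped with a warning.
    """
    if expr.shape[1] < 3:
        raise DataError("z-scoring needs >=3 samples")
    x = expr.values
    mean = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, ddof=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    if not keep.all():
        if drop_zero_sd:
            logger.warning("zscore_genes: dropping %d zero-SD gene rows", int((~keep).sum()))
        else:
            raise DataError(f"{int((~keep).sum())} gene rows have zero SD")
    z = (x - mean) / sd
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(z[keep], genes, expr.sample_ids)


@dataclass
class HarmonizedPair:
    """Two matrices restricted to shared 1:1 orthologs, z-scored independently.

    Rows of ``b`` are renamed into ``a``'s gene namespace so the row sets
    are identical; ``mapping`` records the retained pairs.
    """

    a: ExpressionMatrix
    b: ExpressionMatrix
    mapping: pd.DataFrame  # columns: a, b

    def __post_init__(self):
        if [g.upper() for g in self.a.gene_ids] != [g.upper() for g in self.b.gene_ids]:
            raise DataError("harmonized matrices must share the same gene rows")


def harmonize(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    ortholog_map: OrthologMap,
    signature: GeneSignature | None = None,
    min_coverage: float = 0.7,
) -> HarmonizedPair:
    """Restrict both matrices to shared 1:1 orthologs and z-score each.

    ``b``'s rows are renamed to their ``a`` orthologs. When a signature is
    given, the retained orthologs must cover at least ``min_coverage`` of
    its genes.
    """
    if len(ortholog_map) == 0:
        raise DataError("empty ortholog map")
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise DataError("harmonize needs >=3 samples in each matrix")
    pairs = ortholog_map.one_to_one().pairs
    a_idx = a.gene_index_ci()
    b_idx = b.gene_index_ci()
    keep = pairs[
        pairs["a"].str.upper().isin(a_idx) & pairs["b"].str.upper().isin(b_idx)
    ].reset_index(drop=True)
    if keep.empty:
        raise DataError("no shared orthologs between the two matrices")

    a_sub = a.subset_genes(list(keep["a"]))
    b_sub = b.subset_genes(list(keep["b"]))
    # rename b's rows into a's namespace before z-scoring
    b_named = ExpressionMatrix(b_sub.values, a_sub.gene_ids, b_sub.sample_ids)

    a_z = zscore_genes(a_sub)
    b_z = zscore_genes(b_named)
    shared = [g for g in a_z.gene_ids if g in set(b_z.gene_ids)]
    a_z = a_z.subset_genes(shared)
    b_z = b_z.subset_genes(shared)

    if signature is not None:
        covered = set(g.upper() for g in shared) & set(g.upper() for g in signature.gene_ids)
        cov = len(covered) / len(signature)
        if cov < min_coverage:
            raise DataError(
                f"ortholog coverage of signature is {cov:.0%} < {min_coverage:.0%}"
            )
    keep = keep[keep["a"].isin(shared)].reset_index(drop=True)
    return HarmonizedPair(a=a_z, b=b_z, mapping=keep)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class BCCP:
    """Bayesian compound covariate predictor of the high-metabolic class.

    Parameters
    ----------
    train_z : ExpressionMatrix
        Training expression, already z-scored per gene (rows ~ mean 0, SD 1).
    labels : SampleLabels
        Binary class labels; ``positive_class`` marks the high-metabolic arm.
    signature : GeneSignature
        Genes (and fallback weights) defining the compound covariate.
    weight_mode : 'refit' (default) or 'signature'
        ``refit`` recomputes per-gene t-statistics of positive-vs-negative
        on the training data; ``signature`` uses the stored weights as-is.
    priors : (pi_positive, pi_negative)
        Class priors; equal by default.

    Examples
    --------
    >>> model = BCCP(train_z, labels, signature)
    >>> res = model.fit()
    >>> res.posterior_high(cohort_z)
    """

    def __init__(
        self,
        train_z: ExpressionMatrix,
        labels: SampleLabels,
        signature: GeneSignature,
        weight_mode: WeightMode = "refit",
        positive_class: str = "treated",
        priors: tuple[float, float] = (0.5, 0.5),
        allow_singleton_class: bool = False,
    ):
        labels.validate_against(train_z)
        if len(signature) == 0:
            raise DataError("cannot fit a BCCP on an empty signature")
        classes = labels.classes()
        if positive_class not in classes or len(classes) != 2:
            raise DataError(
                f"need exactly 2 classes including {positive_class!r}; got {classes}"
            )
        if not np.isclose(sum(priors), 1.0) or min(priors) <= 0 or max(priors) >= 1:
            raise DataError("priors must lie in (0,1) and sum to 1")
        self.train_z = train_z
        self.labels = labels
        self.signature = signature
        self.weight_mode = weight_mode
        self.positive_class = positive_class
        self.negative_class = [c for c in classes if c != positive_class][0]
        self.priors = tuple(float(p) for p in priors)
        self.allow_singleton_class = allow_singleton_class

    def fit(self) -> "BCCPResults":
        lut = self.train_z.gene_index_ci()
        present = [g for g in self.signature.gene_ids if g.upper() in lut]
        if not present:
            raise DataError("no signature genes present in training matrix")
        if len(present) < len(self.signature):
            logger.info("fit: %d/%d signature genes present in training data",
                        len(present), len(self.signature))
        sub = self.train_z.subset_genes(present)

        if self.weight_mode == "refit":
            de = per_gene_ttest(
                sub, self.labels, (self.positive_class, self.negative_class),
                by_group=False,
            )
            weights = de["t"].reindex([lut[g.upper()] for g in present])
            weights.index = present
            ok = np.isfinite(weights) & (weights != 0)
            weights = weights[ok]
            sub = sub.subset_genes(list(weights.index))
        elif self.weight_mode == "signature":
            weights = self.signature.weights.reindex(present)
        else:
            raise DataError(f"unknown weight mode: {self.weight_mode}")
        if weights.empty:
            raise DataError("no usable signature genes after weighting")

        c = weights.to_numpy() @ sub.values  # compound covariate per training sample
        c = pd.Series(c, index=sub.sample_ids)

        pos = self.labels.labels.index[self.labels.labels == self.positive_class]
        neg = self.labels.labels.index[self.labels.labels == self.negative_class]
        c_pos, c_neg = c[pos], c[neg]
        if len(c_pos) < 2 or len(c_neg) < 2:
            if not self.allow_singleton_class or min(len(c_pos), len(c_neg)) < 1 \
                    or max(len(c_pos), len(c_neg)) < 2:
                raise DataError("each class needs >=2 training samples")
        mu_h, sd_h = float(c_pos.mean()), float(c_pos.std(ddof=1))
        mu_c, sd_c = float(c_neg.mean()), float(c_neg.std(ddof=1))
        # singleton-class fallback (cross-validation folds only): borrow the
        # other class's spread so the Gaussian is defined
        if len(c_pos) == 1:
            sd_h = sd_c
        elif len(c_neg) == 1:
            sd_c = sd_h
        if sd_h == 0 or sd_c == 0:
            raise DataError(
                "zero within-class SD of the compound covariate (degenerate "
                "separation); add samples or reduce the signature"
            )
        if mu_h <= mu_c:
            logger.warning(
                "direction sanity check: mean compound covariate of the positive "
                "class (%.3g) does not exceed the negative class (%.3g) — check "
                "weight signs", mu_h, mu_c,
            )
        return BCCPResults(
            model=self,
            weights=weights,
            mu_high=mu_h, sigma_high=sd_h,
            mu_control=mu_c, sigma_control=sd_c,
            priors=self.priors,
            train_scores=c,
        )


class BCCPResults:
    """Fitted BCCP: per-gene weights, class Gaussians, priors, diagnostics."""

    def __init__(self, model: BCCP | None, weights: pd.Series, mu_high: float,
                 sigma_high: float, mu_control: float, sigma_control: float,
                 priors: tuple[float, float], train_scores: pd.Series | None = None):
        self.model = model
        self.weights = weights
        self.mu_high = mu_high
        self.sigma_high = sigma_high
        self.mu_control = mu_control
        self.sigma_control = sigma_control
        self.priors = tuple(priors)
        self.train_scores = train_scores

    # -- scoring -----------------------------------------------------------
    def compound_covariate(self, z: ExpressionMatrix, min_coverage: float = 0.7
                           ) -> pd.Series:
        """c_j = sum_i t_i z_ij over the signature genes present in ``z``.

        Missing signature genes are tolerated up to ``1 - min_coverage``;
        the partial sum is renormalized by total/present absolute weight so
        its scale matches the training compound covariate.
        """
        lut = z.gene_index_ci()
        present = [g for g in self.weights.index if g.upper() in lut]
        if not present:
            raise DataError("no signature genes present in prediction data")
        cov = len(present) / len(self.weights)
        if cov < min_coverage:
            raise DataError(f"signature coverage {cov:.0%} < {min_coverage:.0%}")
        w = self.weights.reindex(present)
        scale = float(np.abs(self.weights).sum() / np.abs(w).sum())
        if cov < 1.0:
            logger.info("compound_covariate: %d/%d signature genes present "
                        "(renormalizing by %.3f)", len(present), len(self.weights), scale)
        sub = z.subset_genes(present)
        c = scale * (w.to_numpy() @ sub.values)
        return pd.Series(c, index=z.sample_ids)

    def posterior_from_score(self, c) -> np.ndarray:
        """Bayes posterior of the high class given compound covariate(s)."""
        c = np.atleast_1d(np.asarray(c, dtype=float))
        log_h = np.log(self.priors[0]) + stats.norm.logpdf(c, self.mu_high, self.sigma_high)
        log_c = np.log(self.priors[1]) + stats.norm.logpdf(c, self.mu_control, self.sigma_control)
        denom = logsumexp(np.stack([log_h, log_c]), axis=0)
        with np.errstate(invalid="ignore"):
            p = np.exp(log_h - denom)
        # both densities can underflow to -inf far in the tails; break the tie
        # by distance to the class means
        both_zero = ~np.isfinite(denom)
        if both_zero.any():
            closer_high = np.abs(c - self.mu_high) < np.abs(c - self.mu_control)
            p = np.where(both_zero, closer_high.astype(float), p)
        return p

    def posterior_high(self, z: ExpressionMatrix, min_coverage: float = 0.7) -> pd.Series:
        """Per-sample posterior probability of the high-metabolic class."""
        c = self.compound_covariate(z, min_coverage=min_coverage)
        return pd.Series(self.posterior_from_score(c.to_numpy()), index=c.index)

    def predict(self, cohort: ExpressionMatrix, lo: float = 0.2, hi: float = 0.8,
                already_zscored: bool = False, min_coverage: float = 0.7) -> SubtypeCalls:
        """z-score a cohort (within itself), score it and trichotomize."""
        z = cohort if already_zscored else zscore_genes(cohort)
        post = self.posterior_high(z, min_coverage=min_coverage)
        return trichotomize(post, lo=lo, hi=hi)

    # -- reporting / serialization ----------------------------------------
    def summary(self) -> str:
        n = len(self.weights)
        lines = [
            "Bayesian Compound Covariate Predictor",
            "=" * 45,
            f"Signature genes (usable)   {n}",
            f"Class priors (high, ctrl)  {self.priors[0]:.3g}, {self.priors[1]:.3g}",
            f"mu_high, sigma_high        {self.mu_high:.4g}, {self.sigma_high:.4g}",
            f"mu_control, sigma_control  {self.mu_control:.4g}, {self.sigma_control:.4g}",
            f"Class separation (d)       "
            f"{(self.mu_high - self.mu_control) / np.hypot(self.sigma_high, self.sigma_control):.4g}",
        ]
        if self.train_scores is not None and self.model is not None:
            post = self.posterior_from_score(self.train_scores.to_numpy())
            lab = self.model.labels.labels.reindex(self.train_scores.index)
            correct = ((post > 0.5) == (lab == self.model.positive_class)).mean()
            lines.append(f"Training resubstitution acc {correct:.3f}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "gene_ids": list(self.weights.index),
            "weights": [float(w) for w in self.weights],
            "mu_high": self.mu_high, "sigma_high": self.sigma_high,
            "mu_control": self.mu_control, "sigma_control": self.sigma_control,
            "priors": list(self.priors),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BCCPResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            model=None,
            weights=pd.Series(d["weights"], index=d["gene_ids"], dtype=float),
            mu_high=d["mu_high"], sigma_high=d["sigma_high"],
            mu_control=d["mu_control"], sigma_control=d["sigma_control"],
            priors=tuple(d["priors"]),
        )


# ---------------------------------------------------------------------------
# trichotomization, LOOCV, end-to-end prediction
# ---------------------------------------------------------------------------

def trichotomize(posteriors: pd.Series, lo: float = 0.2, hi: float = 0.8) -> SubtypeCalls:
    """Map posteriors to subtype labels: > hi -> high, < lo -> low, else middle.

    The boundaries themselves fall in the middle class.
    """
    if not 0 < lo < hi < 1:
        raise DataError("cutoffs must satisfy 0 < lo < hi < 1")
    p = pd.Series(posteriors, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DataError("posteriors must lie in [0, 1]")
    label = np.where(p.to_numpy() > hi, "high", np.where(p.to_numpy() < lo, "low", "middle"))
    return SubtypeCalls(
        pd.DataFrame({"posterior_high": p.to_numpy(), "subtype": label}, index=p.index),
        cutoffs=(lo, hi),
    )


@dataclass
class LOOCVResult:
    sensitivity: float
    specificity: float
    posteriors: pd.Series  # held-out posterior of the positive class
    misclassified: list[str]


def loocv(
    train: ExpressionMatrix,
    labels: SampleLabels,
    contrast_x: tuple[str, str] = ("fructose", "control"),
    contrast_y: tuple[str, str] = ("glucose", "control"),
    p_cutoff: float = 0.01,
    positive_class: str = "treated",
    fixed_signature: GeneSignature | None = None,
) -> LOOCVResult:
    """Leave-one-out cross-validation with full in-loop feature re-selection.

    Each fold drops one sample, re-derives the signature on the remainder
    (both diet contrasts, p < ``p_cutoff``, direction-consistent overlap),
    z-scores the remainder, refits the BCCP and classifies the held-out
    sample — standardized with the fold's training means/SDs — at a 0.5
    posterior cutoff. Passing ``fixed_signature`` skips the re-selection
    (faster, optimistically biased; for exploration only).

    Sensitivity is the recalled fraction of the positive (sugar-fed) class,
    specificity of the control class.
    """
    labels.validate_against(train)
    lab = labels.labels
    classes = sorted(lab.unique())
    if len(classes) != 2:
        raise DataError("LOOCV needs exactly 2 classes")
    negative_class = [c for c in classes if c != positive_class][0]

    post = {}
    for held in train.sample_ids:
        rest = [s for s in train.sample_ids if s != held]
        rest_lab = SampleLabels(
            labels=lab.reindex(rest),
            groups=None if labels.groups is None else labels.groups.reindex(rest),
            min_per_class=1,
        )
        if rest_lab.labels.nunique() < 2:
            raise DataError(f"fold holding out {held} leaves a single class")
        singleton_fold = rest_lab.labels.value_counts().min() < 2
        sub = train.subset_samples(rest)
        if fixed_signature is None:
            sig, _ = derive_signature(
                sub, rest_lab, contrast_x=contrast_x, contrast_y=contrast_y,
                p_cutoff=p_cutoff,
            )
            if len(sig) == 0:
                post[held] = 0.5  # uninformative fold
                continue
        else:
            sig = fixed_signature

        # fold-internal standardization; held-out sample uses training stats
        x = sub.values
        mean = np.nanmean(x, axis=1)
        sd = np.nanstd(x, axis=1, ddof=1)
        keep = sd > 0
        genes = [g for g, k in zip(sub.gene_ids, keep) if k]
        z_train = ExpressionMatrix(
            (x[keep] - mean[keep, None]) / sd[keep, None], genes, rest
        )
        res = BCCP(
            z_train, rest_lab, sig, positive_class=positive_class,
            weight_mode="signature" if singleton_fold else "refit",
            allow_singleton_class=singleton_fold,
        ).fit()

        held_x = train.subset_samples([held]).values[:, 0]
        held_z = (held_x[keep] - mean[keep]) / sd[keep]
        z_held = ExpressionMatrix(held_z[:, None], genes, [held])
        post[held] = float(res.posterior_high(z_held).iloc[0])

    post = pd.Series(post).reindex(train.sample_ids)
    called_pos = post > 0.5
    is_pos = lab.reindex(post.index) == positive_class
    sens = float(called_pos[is_pos].mean())
    spec = float((~called_pos[~is_pos]).mean())
    miss = list(post.index[called_pos != is_pos])
    return LOOCVResult(sensitivity=sens, specificity=spec, posteriors=post,
                       misclassified=miss)


def predict_cohort(
    results: BCCPResults,
    cohort: ExpressionMatrix,
    ortholog_map: OrthologMap | None = None,
    train_expr: ExpressionMatrix | None = None,
    lo: float = 0.2,
    hi: float = 0.8,
    min_coverage: float = 0.7,
) -> SubtypeCalls:
    """Score a human cohort with a mouse-trained model.

    With an ortholog map and the (unstandardized) training matrix, the
    cohort is harmonized first (1:1 orthologs, independent z-scores, rows
    renamed into the training namespace); otherwise the cohort's gene ids
    are assumed to already live in the model's namespace and the cohort is
    z-scored within itself.
    """
    if ortholog_map is not None:
        if train_expr is None:
            raise DataError("ortholog mapping needs the training matrix")
        pair = harmonize(train_expr, cohort, ortholog_map,
                         signature=None, min_coverage=min_coverage)
        z = pair.b
    else:
        z = zscore_genes(cohort)
    post = results.posterior_high(z, min_coverage=min_coverage)
    return trichotomize(post, lo=lo, hi=hi)
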