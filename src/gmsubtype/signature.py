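"""Derivation of the diet-induced glycolytic gene signature.

Per-gene two-sample t-tests for each treatment-vs-control contrast at a raw
p < 0.01 cutoff, then a direction-consistent intersection of the two
contrasts' gene lists. The intersected genes, weighted by the mean of the
two contrast t-statistics, form the transferable signature. No multiple-
testing correction is applied at this stage by design: the selection level
is a raw per-gene threshold and the downstream classifier is what carries
the inference.

The t-test is vectorised over genes and handles missing values
pairwise-complete per gene: each gene uses whatever samples it has on each
side (at least two), so a sparse gene is tested on fewer degrees of freedom
rather than dropped wholesale.
"""

from __future__ import annotations

import logging
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError, ExpressionMatrix, GeneSignature, SampleLabels

logger = logging.getLogger(__name__)

VarianceMode = Literal["pooled", "welch"]
SelectionMode = Literal["two_sided", "up_only"]


def _group_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row count, mean and (n-1)-variance ignoring NaN."""
    n = np.sum(~np.isnan(x), axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(x, axis=1)
        # nanvar with ddof=1 warns on rows with a single value; mask instead
        var = np.full(x.shape[0], np.nan)
        ok = n >= 2
        if ok.any():
            var[ok] = np.nanvar(x[ok], axis=1, ddof=1)
    return n, mean, var


def per_gene_ttest(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    contrast: tuple[str, str],
    variance_mode: VarianceMode = "pooled",
    by_group: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per gene for a (treated, control) contrast.

    Parameters
    ----------
    contrast : (treated, control)
        Group tags (``by_group=True``, default) or class labels to compare.
    variance_mode : 'pooled' or 'welch'
        Classical Student's t with pooled variance, or Welch's unequal-
        variance form.

    Returns
    -------
    DataFrame indexed by gene id with columns ``t``, ``p``, ``direction``
    (sign of treated-minus-control mean difference), ``n_treated``,
    ``n_control`` and ``degenerate``. Genes with fewer than two usable
    samples on either side are dropped (logged). Zero-variance genes are
    flagged degenerate: p = 1 when the means agree, p = 0 otherwise.
    """
    treated, control = contrast
    labels.validate_against(expr)
    src = labels.groups if by_group and labels.groups is not None else labels.labels
    t_samples = list(src.index[src == treated])
    c_samples = list(src.index[src == control])
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise DataError(f"contrast {contrast} needs >=2 samples per side")

    xt = expr.subset_samples(t_samples).values
    xc = expr.subset_samples(c_samples).values
    n1, m1, v1 = _group_moments(xt)
    n0, m0, v0 = _group_moments(xc)

    usable = (n1 >= 2) & (n0 >= 2)
    if not usable.all():
        logger.info("per_gene_ttest: skipped %d genes with <2 usable samples per side",
                    int((~usable).sum()))

    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        if variance_mode == "pooled":
            sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
            se = np.sqrt(sp2 * (1 / n1 + 1 / n0))
            df = n1 + n0 - 2
        elif variance_mode == "welch":
            a, b = v1 / n1, v0 / n0
            se = np.sqrt(a + b)
            df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n0 - 1))
        else:
            raise DataError(f"unknown variance mode: {variance_mode}")
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = usable & (se == 0)
    zero_equal = degenerate & (diff == 0)
    zero_diff = degenerate & (diff != 0)
    t = np.where(zero_equal, 0.0, t)
    p = np.where(zero_equal, 1.0, p)
    p = np.where(zero_diff, 0.0, p)

    out = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "direction": np.sign(diff).astype(int),
            "n_treated": n1.astype(int),
            "n_control": n0.astype(int),
            "degenerate": degenerate,
        },
        index=expr.gene_ids,
    )
    return out[usable]


def select_genes(
    de: pd.DataFrame,
    p_cutoff: float = 0.01,
    mode: SelectionMode = "two_sided",
    include_degenerate: bool = False,
) -> list[str]:
    """Genes with p strictly below ``p_cutoff`` (and direction +1 if up_only).

    Degenerate zero-variance genes (p forced to 0) are excluded by default.
    """
    if de.empty:
        raise DataError("empty differential-expression result")
    keep = de["p"] < p_cutoff
    if mode == "up_only":
        keep &= de["direction"] == 1
    elif mode != "two_sided":
        raise DataError(f"unknown selection mode: {mode}")
    if not include_degenerate:
        keep &= ~de["degenerate"]
    genes = list(de.index[keep])
    if not genes:
        logger.warning("select_genes: no genes pass p<%g", p_cutoff)
    return genes


def intersect_contrasts(
    de_x: pd.DataFrame,
    de_y: pd.DataFrame,
    genes_x: Sequence[str],
    genes_y: Sequence[str],
    require_same_direction: bool = True,
    metadata: dict | None = None,
) -> GeneSignature:
    """Intersect two contrasts' selected genes into a weighted signature.

    The signature weight of a retained gene is the arithmetic mean of its
    two contrast t-statistics; with ``require_same_direction`` the gene must
    move the same way in both contrasts. An empty intersection yields an
    empty signature (warning, not an error).
    """
    common = [g for g in genes_x if g in set(genes_y)]
    rows = []
    for g in common:
        dx, dy = de_x.loc[g, "direction"], de_y.loc[g, "direction"]
        if require_same_direction and dx != dy:
            continue
        w = 0.5 * (de_x.loc[g, "t"] + de_y.loc[g, "t"])
        if w == 0:
            continue
        rows.append((g, w))
    meta = dict(metadata or {})
    meta.setdefault("weight", "mean of contrast t-statistics")
    meta["require_same_direction"] = require_same_direction
    if not rows:
        logger.warning("intersect_contrasts: empty intersection")
        return GeneSignature(pd.DataFrame(columns=["gene_id", "weight"]), metadata=meta)
    df = pd.DataFrame(rows, columns=["gene_id", "weight"])
    return GeneSignature(df, metadata=meta)


def derive_signature(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    contrast_x: tuple[str, str] = ("fructose", "control"),
    contrast_y: tuple[str, str] = ("glucose", "control"),
    p_cutoff: float = 0.01,
    mode: SelectionMode = "two_sided",
    variance_mode: VarianceMode = "pooled",
    require_same_direction: bool = True,
) -> tuple[GeneSignature, dict]:
    """Full derivation: two contrasts, selection, intersection.

    Returns the signature and a Venn summary dict with counts of genes
    exclusive to each contrast and shared.
    """
    de_x = per_gene_ttest(expr, labels, contrast_x, variance_mode=variance_mode)
    de_y = per_gene_ttest(expr, labels, contrast_y, variance_mode=variance_mode)
    gx = select_genes(de_x, p_cutoff=p_cutoff, mode=mode)
    gy = select_genes(de_y, p_cutoff=p_cutoff, mode=mode)
    sig = intersect_contrasts(
        de_x, de_y, gx, gy, require_same_direction=require_same_direction,
        metadata={
            "p_cutoff": p_cutoff, "mode": mode, "variance_mode": variance_mode,
            "contrast_x": list(contrast_x), "contrast_y": list(contrast_y),
        },
    )
    venn = {
        "n_x": len(gx),
        "n_y": len(gy),
        "n_overlap": len(sig),
        "x_only": len(set(gx) - set(sig.gene_ids)),
        "y_only": len(set(gy) - set(sig.gene_ids)),
    }
    logger.info("signature derivation: %(n_x)d vs %(n_y)d genes, %(n_overlap)d shared", venn)
    return sig, venn
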