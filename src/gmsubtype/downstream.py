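"""Subtype-vs-feature association statistics.

Group comparisons of arbitrary per-sample numeric tables (mutation burden,
fraction of genome altered, marker expression, immune-cell fractions...),
per-gene Fisher tests of mutation status against subtype, and Pearson
correlation of per-sample scores. These consume plain numeric/binary tables;
how those tables were produced (variant calling, deconvolution, copy-number
segmentation) is outside this package.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import DataError, SubtypeCalls

logger = logging.getLogger(__name__)

SUBTYPE_ORDER = ("high", "middle", "low")


def compare_groups(
    values: pd.Series,
    calls: SubtypeCalls,
    pairs: list[tuple[str, str]] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sample t-test of a per-sample numeric feature between subtype pairs.

    Welch's unequal-variance form by default (subtype arms are rarely the
    same size); ``equal_var=True`` gives the pooled classical test. Pairs
    with an empty or singleton group are skipped with a warning.

    Returns a DataFrame with one row per tested pair: group means, sizes,
    ``t`` and two-sided ``p``.
    """
    values = pd.Series(values, dtype=float)
    pairs = pairs or list(combinations(SUBTYPE_ORDER, 2))
    rows = []
    for g1, g2 in pairs:
        x1 = values.reindex(calls.samples_of(g1)).dropna()
        x2 = values.reindex(calls.samples_of(g2)).dropna()
        if len(x1) < 2 or len(x2) < 2:
            logger.warning("compare_groups: skipping %s vs %s (<2 samples)", g1, g2)
            continue
        t, p = stats.ttest_ind(x1, x2, equal_var=equal_var)
        rows.append(
            {
                "group_a": g1, "group_b": g2,
                "mean_a": x1.mean(), "mean_b": x2.mean(),
                "n_a": len(x1), "n_b": len(x2),
                "t": float(t), "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def mutation_subtype_association(
    mutations: pd.DataFrame, calls: SubtypeCalls,
    subtypes: tuple[str, ...] = SUBTYPE_ORDER,
) -> pd.DataFrame:
    """Per-gene Fisher's exact test of mutation status vs subtype.

    ``mutations`` is a binary genes x samples matrix. Each subtype is tested
    against the rest as a 2x2 table (mutated x in-subtype); the two-sided
    exact p comes from the hypergeometric distribution of the table given
    its margins. Benjamini-Hochberg FDR is reported across genes within
    each subtype contrast alongside the raw p.
    """
    shared = [s for s in mutations.columns if s in calls.table.index]
    if not shared:
        raise DataError("no shared samples between mutations and calls")
    mut = mutations[shared]
    if not mut.isin([0, 1]).all().all():
        raise DataError("mutation matrix must be binary 0/1")
    subtype = calls.table.loc[shared, "subtype"]

    rows = []
    for st in subtypes:
        in_st = (subtype == st).to_numpy()
        if in_st.sum() == 0:
            logger.warning("mutation association: no samples in subtype %r", st)
            continue
        for gene, vec in mut.iterrows():
            v = vec.to_numpy()
            a = int(((v == 1) & in_st).sum())
            b = int(((v == 1) & ~in_st).sum())
            c = int(((v == 0) & in_st).sum())
            d = int(((v == 0) & ~in_st).sum())
            if (a + b) == 0 or (c + d) == 0:  # all-or-none mutated: no association testable
                odds, p = np.nan, 1.0
            else:
                odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {"gene": gene, "subtype": st, "n_mut_in": a, "n_mut_out": b,
                 "n_wt_in": c, "n_wt_out": d, "odds_ratio": odds, "p": float(p)}
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = np.nan
        for st in out["subtype"].unique():
            m = out["subtype"] == st
            out.loc[m, "fdr"] = multipletests(out.loc[m, "p"], method="fdr_bh")[1]
    return out


def score_correlation(a: pd.Series, b: pd.Series) -> dict:
    """Pearson correlation of two per-sample scores (t-based two-sided p)."""
    a, b = pd.Series(a, dtype=float), pd.Series(b, dtype=float)
    shared = a.index.intersection(b.index)
    x = a.reindex(shared)
    y = b.reindex(shared)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise DataError("correlation needs >=3 paired samples")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise DataError("zero variance in a score vector")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(x))}
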