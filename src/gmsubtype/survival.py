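"""Survival validation of subtype calls: Kaplan-Meier curves, k-group
log-rank tests and Cox proportional-hazards regression.

Estimation is delegated to lifelines; this module adapts the package's
containers (ClinicalTable, SubtypeCalls) to it, applies the conventions
used throughout the analysis (Efron tie handling, Wald 95% intervals,
two-sided p-values, the "high vs middle/low" binary encoding of the
metabolic subtype) and implements the two-stage Cox screen in which only
covariates significant univariately enter the multivariate model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .data import ClinicalTable, DataError, SubtypeCalls

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    group: str
    timeline: np.ndarray  # observed times (events and censorings)
    survival: np.ndarray  # S(t) at each timeline point
    at_risk: np.ndarray  # subjects at risk just before each time
    censor_times: np.ndarray
    n: int
    events: int

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (S(0) = 1)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median_survival(self) -> float:
        below = self.survival <= 0.5
        return float(self.timeline[below][0]) if below.any() else float("inf")


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def _align(clinical: ClinicalTable, groups: pd.Series) -> pd.DataFrame:
    groups = pd.Series(groups, dtype=object)
    shared = clinical.table.index.intersection(groups.index)
    if len(shared) == 0:
        raise DataError("no shared ids between clinical table and groups")
    df = clinical.table.loc[shared, ["time", "event"]].copy()
    df["group"] = groups.reindex(shared)
    return df[df["group"].notna()]


def _group_series(groups) -> pd.Series:
    if isinstance(groups, SubtypeCalls):
        return groups.table["subtype"]
    return pd.Series(groups, dtype=object)


def km_estimate(clinical: ClinicalTable, groups) -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit estimate per group.

    ``groups`` is a SubtypeCalls object or a per-sample Series of labels.
    Ties at identical event times are handled jointly. Empty groups are
    dropped with a warning.
    """
    df = _align(clinical, _group_series(groups))
    out: dict[str, KMCurve] = {}
    for g, sub in df.groupby("group", sort=True):
        if len(sub) == 0:  # pragma: no cover - groupby never yields empties
            logger.warning("km_estimate: dropping empty group %r", g)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        # lifelines timeline includes t=0; report observed times only
        timeline = kmf.timeline[kmf.timeline > 0]
        surv = kmf.survival_function_["KM_estimate"].reindex(timeline).to_numpy()
        at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy()
        out[str(g)] = KMCurve(
            group=str(g),
            timeline=np.asarray(timeline, dtype=float),
            survival=surv,
            at_risk=at_risk.astype(float),
            censor_times=np.sort(sub.loc[sub["event"] == 0, "time"].to_numpy()),
            n=len(sub),
            events=int(sub["event"].sum()),
        )
    return out


def logrank_test(clinical: ClinicalTable, groups) -> LogRankResult:
    """k-group log-rank test (chi-square with k-1 df, two-sided p)."""
    df = _align(clinical, _group_series(groups))
    k = df["group"].nunique()
    if k < 2:
        raise DataError("log-rank test needs >=2 groups")
    if df["event"].sum() == 0:
        raise DataError("log-rank statistic undefined with no events")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=int(k - 1),
        p_value=float(res.p_value),
    )


class CoxResults:
    """Hazard ratios with Wald 95% CIs and p-values, per covariate."""

    def __init__(self, table: pd.DataFrame, mode: str, n: int, events: int,
                 selected: list[str] | None = None):
        self.table = table  # index covariate; columns hr, ci_low, ci_high, p
        self.mode = mode
        self.n = n
        self.events = events
        self.selected = selected or []

    def summary(self) -> str:
        lines = [
            f"Cox proportional hazards ({self.mode}): n={self.n}, events={self.events}",
            f"{'covariate':<20}{'HR':>8}{'95% CI':>18}{'p':>12}",
        ]
        for cov, row in self.table.iterrows():
            ci = f"({row.ci_low:.2f}-{row.ci_high:.2f})"
            lines.append(f"{cov:<20}{row.hr:>8.2f}{ci:>18}{row.p:>12.3g}")
        return "\n".join(lines)


def gm_high_indicator(calls: SubtypeCalls) -> pd.Series:
    """Binary 'high vs middle/low' encoding of the metabolic subtype."""
    return (calls.table["subtype"] == "high").astype(int).rename("gm_high")


def cox_fit(
    clinical: ClinicalTable,
    covariates: list[str] | None = None,
    mode: str = "univariate",
    extra: pd.DataFrame | None = None,
    screen_alpha: float = 0.05,
) -> CoxResults:
    """Cox PH regression over the requested design columns.

    ``mode='univariate'`` fits each covariate alone; ``mode='multivariate'``
    jointly fits the covariates whose univariate Wald p < ``screen_alpha``
    (the conventional two-stage screen). ``extra`` supplies design columns
    not already in the clinical table (e.g. the subtype indicator).
    """
    df = clinical.table.copy()
    if extra is not None:
        extra = pd.DataFrame(extra)
        df = df.join(extra.reindex(df.index))
        if df[list(extra.columns)].isna().any().any():
            df = df.dropna(subset=list(extra.columns))
    covariates = covariates or [c for c in df.columns if c not in ("time", "event")]
    for cov in covariates:
        if df[cov].nunique() <= 1:
            raise DataError(f"constant covariate: {cov}")
    if df["event"].sum() < len(covariates) + 1:
        raise DataError("too few events for the number of covariates")

    def _fit(cols: list[str]) -> pd.DataFrame:
        cph = CoxPHFitter()
        try:
            cph.fit(
                df[["time", "event", *cols]], duration_col="time", event_col="event",
                fit_options={"precision": 1e-12},
            )
        except Exception as exc:
            raise DataError(f"Cox fit failed for {cols}: {exc}") from exc
        s = cph.summary
        out = pd.DataFrame(
            {
                "hr": np.exp(s["coef"]),
                "ci_low": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
                "ci_high": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
                "p": 2 * stats.norm.sf(np.abs(s["coef"] / s["se(coef)"])),
            },
            index=s.index,
        )
        return out

    n, events = len(df), int(df["event"].sum())
    uni = pd.concat([_fit([c]) for c in covariates])
    if mode == "univariate":
        return CoxResults(uni, "univariate", n, events)
    if mode != "multivariate":
        raise DataError(f"unknown Cox mode: {mode}")
    selected = list(uni.index[uni["p"] < screen_alpha])
    if not selected:
        raise DataError(f"no covariate passes univariate p<{screen_alpha}")
    multi = _fit(selected)
    return CoxResults(multi, "multivariate", n, events, selected=selected)


def plot_km(curves: dict[str, KMCurve], path=None, title: str = "Overall survival"):
    """Step plot of the KM curves (one line per group); optionally saved."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, c in sorted(curves.items()):
        t = np.concatenate([[0.0], c.timeline])
        s = np.concatenate([[1.0], c.survival])
        ax.step(t, s, where="post", label=f"{g} (n={c.n})")
    ax.set_xlabel("Time (months)")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
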