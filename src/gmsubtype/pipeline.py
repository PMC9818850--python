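"""End-to-end pipeline runner: configuration, stages, manifest.

A run reproduces the full workflow in one directory: derive the
diet-induced signature from the mouse experiment, train the Bayesian
compound covariate predictor, score a human cohort through the ortholog
bridge, trichotomize, and validate the subtypes against survival (and,
optionally, mutation/feature tables). Every stage consumes and produces
plain-text files readable by :mod:`gmsubtype.data`, so stages can also be
run and tested in isolation. A manifest records the configuration, seed,
input hashes and per-stage gene/sample counts; identical config + seed
reproduces byte-identical artifacts.

In demo mode (no input paths) the bundled simulators generate the mouse
experiment and a linked human cohort, including an ortholog table mapping
the mouse genes onto synthetic human symbols.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import data as dio
from .bccp import BCCP, loocv, predict_cohort, zscore_genes
from .data import DataError
from .downstream import compare_groups, mutation_subtype_association
from .signature import derive_signature
from .simulate import HumanSimConfig, MouseSimConfig, simulate_cohort, simulate_mouse
from .survival import cox_fit, gm_high_indicator, km_estimate, logrank_test, plot_km

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run; load from YAML with :meth:`from_yaml`."""

    out_dir: str = "gm_run"
    seed: int = 0
    # input paths; None -> simulate (demo mode)
    mouse_expr: str | None = None
    mouse_labels: str | None = None
    cohort_expr: str | None = None
    clinical: str | None = None
    ortholog_map: str | None = None
    mutations: str | None = None
    # analysis parameters
    p_cutoff: float = 0.01
    lo: float = 0.2
    hi: float = 0.8
    selection_mode: str = "two_sided"
    variance_mode: str = "pooled"
    weight_mode: str = "refit"
    priors: tuple[float, float] = (0.5, 0.5)
    min_coverage: float = 0.7
    run_loocv: bool = True
    make_plots: bool = False
    # demo-mode simulator settings
    sim_mouse: dict = field(default_factory=dict)
    sim_cohort: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.lo < self.hi < 1:
            raise DataError("trichotomy cutoffs must satisfy 0 < lo < hi < 1")
        if not 0 < self.p_cutoff < 1:
            raise DataError("p_cutoff must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise DataError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if isinstance(cfg.priors, list):
            cfg.priors = tuple(cfg.priors)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["priors"] = list(self.priors)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _demo_inputs(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    """Simulate mouse + cohort inputs and write them as pipeline input files."""
    mcfg = MouseSimConfig(seed=cfg.seed, **cfg.sim_mouse)
    expr, labels, truth = simulate_mouse(mcfg)

    # synthetic human symbols: upper-cased mouse ids with an H prefix
    human_of = {g: "H" + g.upper() for g in expr.gene_ids}
    omap = dio.OrthologMap(pd.DataFrame({"a": list(human_of), "b": list(human_of.values())}))

    sig_genes_human = sorted(human_of[g] for g in truth.overlap)
    hcfg = HumanSimConfig(seed=cfg.seed + 1, **cfg.sim_cohort)
    cexpr, clin, ctruth = simulate_cohort(hcfg, sig_genes_human)

    paths = {
        "mouse_expr": out / "inputs" / "mouse_expression.tsv",
        "mouse_labels": out / "inputs" / "mouse_labels.tsv",
        "cohort_expr": out / "inputs" / "cohort_expression.tsv",
        "clinical": out / "inputs" / "clinical.tsv",
        "ortholog_map": out / "inputs" / "ortholog_map.tsv",
        "truth": out / "inputs" / "cohort_truth.tsv",
    }
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    dio.write_expression(expr, paths["mouse_expr"])
    dio.write_labels(labels, paths["mouse_labels"])
    dio.write_expression(cexpr, paths["cohort_expr"])
    dio.write_clinical(clin, paths["clinical"])
    dio.write_ortholog_map(omap, paths["ortholog_map"])
    pd.DataFrame({"g": ctruth.g, "true_class": ctruth.true_class}).rename_axis(
        "sample_id"
    ).to_csv(paths["truth"], sep="\t", float_format="%.10g")
    return paths


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> Path:
    """Execute every stage; returns the run directory.

    Stages: inputs -> signature -> train (+LOOCV) -> predict -> survival
    [-> associations]. Any stage failure aborts with the stage name; the
    manifest marks the run invalid in that case.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise DataError(f"run directory {out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"config": cfg.to_dict(), "stages": {}, "valid": False}
    stage = "inputs"
    try:
        if cfg.mouse_expr is None:
            paths = _demo_inputs(cfg, out)
        else:
            need = ["mouse_expr", "mouse_labels", "cohort_expr", "clinical", "ortholog_map"]
            paths = {k: Path(getattr(cfg, k)) for k in need if getattr(cfg, k)}
        if cfg.mutations:
            paths["mutations"] = Path(cfg.mutations)
        manifest["inputs"] = {k: {"path": str(p), "sha256": _sha256(p)}
                              for k, p in paths.items()}
        manifest["stages"][stage] = "ok"

        stage = "signature"
        expr = dio.read_expression(paths["mouse_expr"])
        labels = dio.read_labels(paths["mouse_labels"])
        sig, venn = derive_signature(
            expr, labels, p_cutoff=cfg.p_cutoff, mode=cfg.selection_mode,
            variance_mode=cfg.variance_mode,
        )
        dio.write_signature(sig, out / "signature.tsv")
        (out / "venn.json").write_text(json.dumps(venn, indent=1))
        manifest["stages"][stage] = {"n_signature": len(sig), **venn}

        stage = "train"
        train_z = zscore_genes(expr)
        res = BCCP(
            train_z, labels, sig, weight_mode=cfg.weight_mode, priors=cfg.priors
        ).fit()
        res.to_json(out / "model.json")
        (out / "model_summary.txt").write_text(res.summary() + "\n")
        train_info = {"n_genes_used": len(res.weights)}
        if cfg.run_loocv:
            cv = loocv(expr, labels, p_cutoff=cfg.p_cutoff)
            train_info["loocv_sensitivity"] = cv.sensitivity
            train_info["loocv_specificity"] = cv.specificity
        manifest["stages"][stage] = train_info

        stage = "predict"
        cohort = dio.read_expression(paths["cohort_expr"])
        omap = dio.read_ortholog_map(paths["ortholog_map"])
        calls = predict_cohort(
            res, cohort, ortholog_map=omap, train_expr=expr,
            lo=cfg.lo, hi=cfg.hi, min_coverage=cfg.min_coverage,
        )
        dio.write_predictions(calls, out / "predictions.tsv")
        manifest["stages"][stage] = {
            "n_samples": len(calls),
            "counts": {k: int(v) for k, v in calls.counts().items()},
        }

        stage = "survival"
        clin = dio.read_clinical(paths["clinical"])
        curves = km_estimate(clin, calls)
        km_rows = [
            {"group": g, "time": t, "survival": s, "at_risk": r}
            for g, c in curves.items()
            for t, s, r in zip(c.timeline, c.survival, c.at_risk)
        ]
        pd.DataFrame(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False,
                                     float_format="%.10g")
        lr = logrank_test(clin, calls)
        surv_out = {
            "logrank": {"chi_square": lr.chi_square, "df": lr.df, "p": lr.p_value},
            "median_survival": {g: c.median_survival() for g, c in curves.items()},
        }
        gm = gm_high_indicator(calls)
        try:
            uni = cox_fit(clin, mode="univariate", extra=gm.to_frame())
            surv_out["cox_univariate"] = uni.table.round(6).to_dict("index")
            multi = cox_fit(clin, mode="multivariate", extra=gm.to_frame())
            surv_out["cox_multivariate"] = multi.table.round(6).to_dict("index")
            surv_out["cox_selected"] = multi.selected
        except DataError as exc:
            surv_out["cox_note"] = str(exc)
        (out / "survival.json").write_text(json.dumps(surv_out, indent=1, default=float))
        if cfg.make_plots:
            plot_km(curves, out / "km_plot.png")
        manifest["stages"][stage] = {"logrank_p": lr.p_value}

        if "mutations" in paths:
            stage = "associations"
            mut = pd.read_csv(paths["mutations"], sep="\t", index_col=0)
            assoc = mutation_subtype_association(mut, calls)
            assoc.to_csv(out / "mutation_association.tsv", sep="\t", index=False,
                         float_format="%.10g")
            burden = mut.sum(axis=0).astype(float)
            cg = compare_groups(burden, calls)
            cg.to_csv(out / "burden_comparison.tsv", sep="\t", index=False,
                      float_format="%.10g")
            manifest["stages"][stage] = {"n_genes": int(mut.shape[0])}

        manifest["valid"] = True
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
        raise DataError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    return out


def write_report(run_dir, path=None) -> str:
    """Render a short markdown report from a completed run directory."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    if not manifest.get("valid"):
        raise DataError("run directory is marked invalid")
    surv = json.loads((run_dir / "survival.json").read_text())
    venn = json.loads((run_dir / "venn.json").read_text())
    counts = manifest["stages"]["predict"]["counts"]

    lines = [
        "# Glycolysis-metabolic subtyping report",
        "",
        f"- Signature: {manifest['stages']['signature']['n_signature']} genes "
        f"(contrast X: {venn['n_x']}, contrast Y: {venn['n_y']}, overlap: {venn['n_overlap']})",
        f"- Cohort calls: high={counts.get('high', 0)}, middle={counts.get('middle', 0)}, "
        f"low={counts.get('low', 0)}",
        f"- Log-rank across subtypes: chi2={surv['logrank']['chi_square']:.3g} "
        f"(df={surv['logrank']['df']}), p={surv['logrank']['p']:.3g}",
        "- Median survival (months): "
        + ", ".join(f"{g}={m:.1f}" for g, m in surv["median_survival"].items()),
    ]
    train = manifest["stages"]["train"]
    if "loocv_sensitivity" in train:
        lines.append(
            f"- LOOCV (mouse training): sensitivity={train['loocv_sensitivity']:.2f}, "
            f"specificity={train['loocv_specificity']:.2f}"
        )
    if "cox_univariate" in surv and "gm_high" in surv["cox_univariate"]:
        u = surv["cox_univariate"]["gm_high"]
        lines.append(
            f"- Cox (univariate, high vs mid/low): HR={u['hr']:.2f} "
            f"({u['ci_low']:.2f}-{u['ci_high']:.2f}), p={u['p']:.3g}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
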