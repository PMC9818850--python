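"""Synthetic datasets with the statistical structure the pipeline assumes.

Two generators: a three-group mouse feeding experiment (control / fructose /
glucose, n = 6 per group) in which two partially overlapping gene sets are
induced by the sugar diets, and a human tumor cohort in which a latent
metabolic score loads on the ortholog signature genes and multiplies the
survival hazard of the truly-high tertile. A trivial Bernoulli mutation
generator supports the association tests.

All randomness flows through one explicitly passed, seeded
``numpy.random.Generator``; identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ClinicalTable, DataError, ExpressionMatrix, SampleLabels

# Default induced-set sizes mirror the real experiment's proportions at a
# 5000-gene desk scale (about a quarter of a whole-array universe):
# ~490 fructose-induced, ~505 glucose-induced, ~21% shared.
MOUSE_DEFAULT_N_GENES = 5000
MOUSE_DEFAULT_N_FRUCTOSE = 490
MOUSE_DEFAULT_N_GLUCOSE = 505
MOUSE_DEFAULT_OVERLAP = 0.21


@dataclass
class MouseSimConfig:
    """Design of the simulated mouse feeding experiment.

    ``effect_size`` is the mean log-expression shift of an induced gene in
    its diet group, in units of ``noise_sd``. ``overlap_fraction`` is the
    proportion of the smaller induced set shared between the two diets.
    """

    n_per_group: int = 6
    n_genes: int = MOUSE_DEFAULT_N_GENES
    n_fructose_up: int = MOUSE_DEFAULT_N_FRUCTOSE
    n_glucose_up: int = MOUSE_DEFAULT_N_GLUCOSE
    overlap_fraction: float = MOUSE_DEFAULT_OVERLAP
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0  # per-gene baseline, log units
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise DataError("n_per_group must be >= 2")
        if min(self.n_genes, self.n_fructose_up, self.n_glucose_up) <= 0:
            raise DataError("gene counts must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise DataError("overlap_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if self.n_fructose_up + self.n_glucose_up > self.n_genes:
            raise DataError("induced sets exceed the gene universe")


@dataclass
class MouseTruth:
    fructose_induced: set[str]
    glucose_induced: set[str]

    @property
    def overlap(self) -> set[str]:
        return self.fructose_induced & self.glucose_induced


def simulate_mouse(config: MouseSimConfig) -> tuple[ExpressionMatrix, SampleLabels, MouseTruth]:
    """Simulate the three-group mouse liver experiment.

    Returns the expression matrix (genes x 3*n samples), sample labels
    (``treated`` for both sugar groups, ``control`` otherwise, with per-diet
    group tags) and the ground-truth induced gene sets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    genes = [f"Gene{i:05d}" for i in range(config.n_genes)]
    samples = (
        [f"ctrl_{i+1}" for i in range(n)]
        + [f"fruc_{i+1}" for i in range(n)]
        + [f"gluc_{i+1}" for i in range(n)]
    )
    group = ["control"] * n + ["fructose"] * n + ["glucose"] * n

    n_overlap = int(round(config.overlap_fraction * min(config.n_fructose_up, config.n_glucose_up)))
    perm = rng.permutation(config.n_genes)
    shared = perm[:n_overlap]
    fr_only = perm[n_overlap : n_overlap + config.n_fructose_up - n_overlap]
    gl_stop = config.n_fructose_up + config.n_glucose_up - n_overlap
    gl_only = perm[config.n_fructose_up : gl_stop]
    fr_idx = np.concatenate([shared, fr_only])
    gl_idx = np.concatenate([shared, gl_only])

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, 3 * n))

    shift = config.effect_size * config.noise_sd
    fr_cols = np.arange(n, 2 * n)
    gl_cols = np.arange(2 * n, 3 * n)
    values[np.ix_(fr_idx, fr_cols)] += shift
    values[np.ix_(gl_idx, gl_cols)] += shift

    expr = ExpressionMatrix(values, genes, samples)
    labels = SampleLabels(
        labels=pd.Series(
            ["control"] * n + ["treated"] * (2 * n), index=samples, dtype=object
        ),
        groups=pd.Series(group, index=samples, dtype=object),
    )
    truth = MouseTruth(
        fructose_induced={genes[i] for i in fr_idx},
        glucose_induced={genes[i] for i in gl_idx},
    )
    return expr, labels, truth


@dataclass
class HumanSimConfig:
    """Human cohort generator: latent metabolic score, expression loadings,
    proportional-hazards survival.

    A standard-normal latent score ``g`` per patient loads (coefficient
    ``loading``) on every ortholog signature gene; non-signature genes are
    pure noise. True classes are the tertiles of ``g``; the top tertile's
    death hazard is multiplied by ``exp(log_hazard_high)``. Censoring mixes
    an administrative horizon with uniform random early censoring.
    """

    n_patients: int = 300
    n_noise_genes: int = 1000
    loading: float = 2.0
    noise_sd: float = 1.0
    log_hazard_high: float = float(np.log(3.0))
    baseline_hazard: float = 0.02  # events per month
    admin_censor_time: float = 60.0  # months
    random_censor_frac: float = 0.2
    covariate_prevalence: dict = field(
        default_factory=lambda: {
            "afp_high": 0.35, "size_large": 0.25, "bclc_advanced": 0.30,
            "cirrhosis": 0.70, "male": 0.85, "age_over_60": 0.30,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 10:
            raise DataError("n_patients must be >= 10 for survival stages to be meaningful")
        if self.baseline_hazard <= 0 or self.admin_censor_time <= 0:
            raise DataError("hazard and censoring parameters must be positive")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if not 0.0 <= self.random_censor_frac <= 1.0:
            raise DataError("random_censor_frac must lie in [0, 1]")


@dataclass
class CohortTruth:
    g: pd.Series  # latent metabolic score per patient
    true_class: pd.Series  # high / middle / low by tertile of g


def simulate_cohort(
    config: HumanSimConfig, signature_genes: Sequence[str]
) -> tuple[ExpressionMatrix, ClinicalTable, CohortTruth]:
    """Simulate a human tumor cohort tied to a signature gene list."""
    config.validate()
    if len(signature_genes) == 0:
        raise DataError("signature_genes must be nonempty")
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patients = [f"PT{i+1:04d}" for i in range(n)]

    g = rng.standard_normal(n)
    tertiles = np.quantile(g, [1 / 3, 2 / 3])
    true_class = np.where(g > tertiles[1], "high", np.where(g <= tertiles[0], "low", "middle"))

    sig = [str(x) for x in signature_genes]
    noise_genes = [f"NOISE{i:05d}" for i in range(config.n_noise_genes)]
    genes = sig + noise_genes
    values = rng.normal(0.0, config.noise_sd, size=(len(genes), n))
    values[: len(sig), :] += config.loading * g[None, :]

    expr = ExpressionMatrix(values, genes, patients)

    # exponential survival under proportional hazards for the true-high class
    hazard = config.baseline_hazard * np.exp(
        config.log_hazard_high * (true_class == "high").astype(float)
    )
    death = rng.exponential(1.0 / hazard)
    censor = np.full(n, config.admin_censor_time)
    random_mask = rng.random(n) < config.random_censor_frac
    censor[random_mask] = rng.uniform(0.0, config.admin_censor_time, size=random_mask.sum())
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    time = np.maximum(time, 1e-6)  # ClinicalTable requires strictly positive times

    cols = {"time": time, "event": event}
    for name, prev in config.covariate_prevalence.items():
        cols[name] = (rng.random(n) < prev).astype(int)
    clinical = ClinicalTable(
        pd.DataFrame(cols, index=patients),
        metadata={
            "afp_high": "AFP > 300 ng/mL",
            "size_large": "tumor size > 6 cm",
            "bclc_advanced": "BCLC stage B/C/D vs 0/A",
            "age_over_60": "age > 60 years",
            "time_unit": "months",
        },
    )
    truth = CohortTruth(
        g=pd.Series(g, index=patients),
        true_class=pd.Series(true_class, index=patients, dtype=object),
    )
    return expr, clinical, truth


def simulate_mutations(
    sample_ids: Sequence[str], n_genes: int = 50, rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli gene x sample binary mutation matrix (for association tests)."""
    rng = np.random.default_rng(seed)
    genes = [f"MUT{i:03d}" for i in range(n_genes)]
    m = (rng.random((n_genes, len(sample_ids))) < rate).astype(int)
    return pd.DataFrame(m, index=genes, columns=list(sample_ids))
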