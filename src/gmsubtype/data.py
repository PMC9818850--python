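"""Core data containers and plain-text readers/writers.

All tabular formats are tab-separated text. Expression matrices are stored
genes x samples on a log scale; missing values use the ``NA`` token. Gene
identifiers are matched case-insensitively throughout (mouse symbols are
Title-case, human symbols upper-case), with the original spelling preserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"


class DataError(ValueError):
    """Raised when an input file or container violates its contract."""


def _check_unique_ci(ids: Sequence[str], what: str) -> None:
    keys = pd.Index([str(i).upper() for i in ids])
    if keys.has_duplicates:
        dup = keys[keys.duplicated()].unique().tolist()[:5]
        raise DataError(f"duplicate {what} (case-insensitive): {dup}")


class ExpressionMatrix:
    """A genes x samples log-expression matrix.

    Parameters
    ----------
    values : array-like, shape (n_genes, n_samples)
        Log-scale expression; NaN marks missing values.
    gene_ids, sample_ids : sequences of str
        Unique identifiers (genes unique after case-normalization).
    """

    def __init__(self, values, gene_ids: Sequence[str], sample_ids: Sequence[str]):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        if arr.shape != (len(gene_ids), len(sample_ids)):
            raise DataError(
                f"shape {arr.shape} does not match {len(gene_ids)} genes "
                f"x {len(sample_ids)} samples"
            )
        _check_unique_ci(gene_ids, "gene ids")
        if pd.Index(sample_ids).has_duplicates:
            raise DataError("duplicate sample ids")
        with np.errstate(invalid="ignore"):
            if np.isinf(arr).any():
                raise DataError("expression values must be finite or NA")
        self._df = pd.DataFrame(arr, index=list(gene_ids), columns=list(sample_ids))

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    # -- subsetting --------------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = set(sample_ids) - set(self._df.columns)
        if missing:
            raise DataError(f"unknown sample ids: {sorted(missing)[:5]}")
        return ExpressionMatrix.from_dataframe(self._df[list(sample_ids)])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Subset rows by gene id, case-insensitively; order follows the request."""
        lut = {g.upper(): g for g in self._df.index}
        rows = []
        for g in gene_ids:
            key = str(g).upper()
            if key not in lut:
                raise DataError(f"gene {g!r} not in matrix")
            rows.append(lut[key])
        return ExpressionMatrix.from_dataframe(self._df.loc[rows])

    def gene_index_ci(self) -> dict[str, str]:
        """Upper-cased gene id -> stored spelling."""
        return {g.upper(): g for g in self._df.index}

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


@dataclass
class SampleLabels:
    """Per-sample class label (binary for training) and optional group tag."""

    labels: pd.Series  # sample_id -> class label
    groups: pd.Series | None = None  # sample_id -> group tag (e.g. fructose)
    min_per_class: int = 2  # relaxed internally by cross-validation folds

    def __post_init__(self):
        self.labels = pd.Series(self.labels, dtype=object)
        if self.labels.index.has_duplicates:
            raise DataError("duplicate sample ids in labels")
        counts = self.labels.value_counts()
        if (counts < self.min_per_class).any():
            small = counts[counts < self.min_per_class].index.tolist()
            raise DataError(f"classes with <{self.min_per_class} samples: {small}")
        if self.groups is not None:
            self.groups = pd.Series(self.groups, dtype=object)

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = set(self.labels.index) - set(expr.sample_ids)
        if missing:
            raise DataError(f"labeled samples absent from matrix: {sorted(missing)[:5]}")

    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    def samples_of(self, label: str, by_group: bool = False) -> list[str]:
        src = self.groups if by_group else self.labels
        if src is None:
            raise DataError("no group tags present")
        return list(src.index[src == label])


@dataclass
class OrthologMap:
    """Pairs of (species-A gene id, species-B gene id), e.g. mouse <-> human."""

    pairs: pd.DataFrame  # columns: a, b

    def __post_init__(self):
        df = pd.DataFrame(self.pairs)
        if df.shape[1] != 2:
            raise DataError("ortholog map needs exactly two columns")
        df.columns = ["a", "b"]
        self.pairs = df.astype(str)

    def one_to_one(self) -> "OrthologMap":
        """Retain only pairs that are 1:1 in both directions (case-insensitive)."""
        df = self.pairs.copy()
        df["_a"] = df["a"].str.upper()
        df["_b"] = df["b"].str.upper()
        df = df.drop_duplicates(["_a", "_b"])
        ok_a = df["_a"].map(df["_a"].value_counts()) == 1
        ok_b = df["_b"].map(df["_b"].value_counts()) == 1
        kept = df.loc[ok_a & ok_b, ["a", "b"]].reset_index(drop=True)
        n_drop = len(df) - len(kept)
        if n_drop:
            logger.info("ortholog map: dropped %d non-1:1 pairs", n_drop)
        return OrthologMap(kept)

    def __len__(self) -> int:
        return len(self.pairs)


class GeneSignature:
    """An ordered gene list with per-gene t-statistic weights.

    Weights are the training t-statistics; direction is their sign. Metadata
    records how the signature was derived (p cutoff, contrasts, mode).
    """

    def __init__(self, entries: pd.DataFrame, metadata: Mapping | None = None):
        df = pd.DataFrame(entries)
        if not {"gene_id", "weight"}.issubset(df.columns):
            raise DataError("signature needs columns gene_id, weight")
        df = df[["gene_id", "weight"]].copy()
        df["gene_id"] = df["gene_id"].astype(str)
        df["weight"] = df["weight"].astype(float)
        if not np.isfinite(df["weight"]).all():
            raise DataError("signature weights must be finite")
        if (df["weight"] == 0).any():
            raise DataError("signature weights must be nonzero")
        _check_unique_ci(df["gene_id"], "signature gene ids")
        df["direction"] = np.sign(df["weight"]).astype(int)
        self.entries = df.reset_index(drop=True)
        self.metadata = dict(metadata or {})

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries["gene_id"])

    @property
    def weights(self) -> pd.Series:
        return pd.Series(self.entries["weight"].values, index=self.entries["gene_id"].values)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneSignature)
            and self.entries[["gene_id", "weight"]].equals(other.entries[["gene_id", "weight"]])
        )


@dataclass
class ClinicalTable:
    """Per-patient survival time (months), event indicator and covariates.

    Covariate dichotomizations (e.g. AFP > 300 ng/mL, tumor size > 6 cm,
    age > 60 years, BCLC B/C/D vs 0/A) are data, recorded in ``metadata``.
    """

    table: pd.DataFrame  # index: patient id; columns: time, event, covariates...
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        df = pd.DataFrame(self.table)
        if not {"time", "event"}.issubset(df.columns):
            raise DataError("clinical table needs columns time, event")
        if df.index.has_duplicates:
            raise DataError("duplicate patient ids")
        if (df["time"] <= 0).any() or not np.isfinite(df["time"]).all():
            raise DataError("survival time must be finite and > 0")
        if not df["event"].isin([0, 1]).all():
            raise DataError("event must be 0 or 1")
        self.table = df

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("time", "event")]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SubtypeCalls:
    """Per-sample posterior of the high-metabolic class and trichotomized label."""

    table: pd.DataFrame  # index: sample id; columns: posterior_high, subtype
    cutoffs: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self):
        df = pd.DataFrame(self.table)
        if not {"posterior_high", "subtype"}.issubset(df.columns):
            raise DataError("subtype calls need columns posterior_high, subtype")
        p = df["posterior_high"].astype(float)
        if ((p < 0) | (p > 1)).any():
            raise DataError("posterior probabilities must lie in [0, 1]")
        lo, hi = self.cutoffs
        expect = np.where(p.to_numpy() > hi, "high", np.where(p.to_numpy() < lo, "low", "middle"))
        if (df["subtype"].to_numpy() != expect).any():
            raise DataError("subtype labels inconsistent with posterior cutoffs")
        self.table = df

    def samples_of(self, subtype: str) -> list[str]:
        return list(self.table.index[self.table["subtype"] == subtype])

    def counts(self) -> pd.Series:
        return self.table["subtype"].value_counts().reindex(
            ["high", "middle", "low"], fill_value=0
        )

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    path,
    missing_token: str = MISSING_TOKEN,
    duplicate_rule: str = "max_variance",
    max_missing: float = 0.5,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Duplicate gene rows (multiple probes per symbol, case-insensitive) are
    collapsed per ``duplicate_rule``: ``max_variance`` keeps the most variable
    row, ``mean`` averages. Rows with more than ``max_missing`` missing values
    are rejected.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise DataError(f"empty or missing expression file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(samples) != len(set(samples)):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise DataError(f"duplicate sample ids in {path}: {dup[:5]}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[missing_token],
                         keep_default_na=False)
    except Exception as exc:  # malformed file
        raise DataError(f"cannot parse expression file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise DataError(f"no sample columns in {path}")
    if pd.Index(df.columns).has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample ids in {path}: {dup[:5]}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nonnum = df[col].notna() & bad.isna()
        if nonnum.any():
            raise DataError(
                f"non-numeric cell in {path} at gene {df.index[nonnum.to_numpy().argmax()]!r}, "
                f"sample {col!r}"
            )
        df[col] = bad
    df.index = df.index.astype(str)

    # collapse duplicate gene rows
    key = df.index.str.upper()
    if key.has_duplicates:
        if duplicate_rule == "max_variance":
            var = df.var(axis=1, ddof=1).fillna(-np.inf)
            order = np.argsort(-var.to_numpy(), kind="stable")
            df = df.iloc[order]
            df = df[~df.index.str.upper().duplicated(keep="first")]
            # restore a deterministic order: original first-appearance order
            first = pd.Index(key).drop_duplicates()
            df = df.loc[sorted(df.index, key=lambda g: first.get_loc(g.upper()))]
        elif duplicate_rule == "mean":
            spelling = {k: g for g, k in zip(df.index[::-1], key[::-1])}
            df = df.groupby(key, sort=False).mean()
            df.index = [spelling[k] for k in df.index]
        else:
            raise DataError(f"unknown duplicate rule: {duplicate_rule}")
        logger.info("collapsed duplicate gene rows by %s", duplicate_rule)

    frac_missing = df.isna().mean(axis=1)
    bad_rows = frac_missing > max_missing
    if bad_rows.any():
        raise DataError(
            f"{int(bad_rows.sum())} gene rows exceed {max_missing:.0%} missing "
            f"values (first: {df.index[bad_rows][0]!r})"
        )
    return ExpressionMatrix.from_dataframe(df)


def write_expression(expr: ExpressionMatrix, path, missing_token: str = MISSING_TOKEN) -> None:
    df = expr.to_dataframe()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep=missing_token, float_format="%.10g")


def read_labels(path) -> SampleLabels:
    """Read sample labels: TSV with columns sample_id, label[, group]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "label"}
    if not need.issubset(df.columns):
        raise DataError(f"label file needs columns {sorted(need)}")
    labels = pd.Series(df["label"].values, index=df["sample_id"].values)
    groups = None
    if "group" in df.columns:
        groups = pd.Series(df["group"].values, index=df["sample_id"].values)
    return SampleLabels(labels=labels, groups=groups)


def write_labels(labels: SampleLabels, path) -> None:
    df = pd.DataFrame({"sample_id": labels.labels.index, "label": labels.labels.values})
    if labels.groups is not None:
        df["group"] = labels.groups.reindex(df["sample_id"]).values
    df.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path) -> OrthologMap:
    """Two-column TSV of (species-A gene, species-B gene); header optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise DataError("ortholog map must have exactly two columns")
    return OrthologMap(df)


def write_ortholog_map(omap: OrthologMap, path) -> None:
    df = omap.pairs.copy()
    df.columns = ["gene_a", "gene_b"]
    df.to_csv(path, sep="\t", index=False)


def write_signature(sig: GeneSignature, path) -> None:
    """Write a signature as TSV; metadata goes into a leading '#' JSON comment."""
    with open(path, "w") as fh:
        if sig.metadata:
            fh.write("# " + json.dumps(sig.metadata, sort_keys=True, default=str) + "\n")
        fh.write("gene_id\tweight\n")
        for g, w in zip(sig.entries["gene_id"], sig.entries["weight"]):
            fh.write(f"{g}\t{w!r}\n")


def read_signature(path) -> GeneSignature:
    path = Path(path)
    metadata: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            metadata = json.loads(first.lstrip("# "))
            body = fh.read()
        else:
            body = first + fh.read()
    from io import StringIO

    try:
        df = pd.read_csv(StringIO(body), sep="\t", dtype={"gene_id": str, "weight": float})
    except Exception as exc:
        raise DataError(f"cannot parse signature {path}: {exc}") from exc
    if not {"gene_id", "weight"}.issubset(df.columns):
        raise DataError(f"signature {path} needs columns gene_id, weight")
    return GeneSignature(df, metadata=metadata)


def write_signature_gmt(sig: GeneSignature, path, name: str = "GM_signature",
                        description: str = "") -> None:
    """GMT export: name, description, then the gene list on one line."""
    with open(path, "w") as fh:
        fh.write("\t".join([name, description, *sig.gene_ids]) + "\n")


def read_clinical(path, column_roles: Mapping[str, str] | None = None,
                  metadata: Mapping | None = None) -> ClinicalTable:
    """Read a per-patient clinical TSV.

    ``column_roles`` maps file column names onto the canonical roles
    ``patient_id``, ``time``, ``event``; unlisted columns pass through as
    covariates. Defaults assume the canonical names are used directly.
    """
    df = pd.read_csv(path, sep="\t")
    roles = dict(column_roles or {})
    rename = {src: dst for src, dst in roles.items() if src in df.columns}
    df = df.rename(columns=rename)
    idcol = "patient_id" if "patient_id" in df.columns else df.columns[0]
    df = df.set_index(idcol)
    df.index = df.index.astype(str)
    return ClinicalTable(df, metadata=dict(metadata or {}))


def write_clinical(clin: ClinicalTable, path) -> None:
    df = clin.table.copy()
    df.index.name = "patient_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_predictions(calls: SubtypeCalls, path) -> None:
    df = calls.table.copy()
    df.index.name = "sample_id"
    out = df[["posterior_high", "subtype"]].copy()
    out["posterior_high"] = [f"{p!r}" for p in out["posterior_high"]]
    out.to_csv(path, sep="\t")


def read_predictions(path, cutoffs: tuple[float, float] = (0.2, 0.8)) -> SubtypeCalls:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return SubtypeCalls(df, cutoffs=cutoffs)
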