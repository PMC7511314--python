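"""Expression-matrix container, file I/O, normalization, filtering and the
cohort-comparison utility.

The central object is :class:`ExpressionMatrix`, a genes x samples numeric
matrix with identifiers and a scale flag distinguishing raw counts from
log2-CPM values.  TSV (header row of sample IDs, first column gene IDs) and
MatrixMarket coordinate format (with ``.rows``/``.cols`` label sidecars) are
supported on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import scipy.stats


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


Scale = Literal["raw_counts", "log2_cpm"]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix.

    Parameters
    ----------
    values
        2-D float array, rows are genes, columns are samples.
    gene_ids, sample_ids
        Unique identifiers for rows / columns.
    scale
        ``"raw_counts"`` for nonnegative integer counts, ``"log2_cpm"`` for
        log2(CPM + 1) normalized values.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scale: Scale = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        ng, ns = self.values.shape
        if ng != len(self.gene_ids) or ns != len(self.sample_ids):
            raise FormatError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene and {len(self.sample_ids)} sample ids"
            )
        if len(set(self.gene_ids)) != ng:
            raise FormatError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != ns:
            raise FormatError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite entries in expression matrix")
        if self.scale == "raw_counts" and np.any(self.values < 0):
            raise FormatError("negative entries in a raw count matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        rows = [idx[g] for g in genes]
        return replace(self, values=self.values[rows], gene_ids=list(genes))


@dataclass
class ComparisonRecord:
    variable: str
    test: str
    statistic: float
    p: float


@dataclass
class CohortComparison:
    """Per-variable two-group comparison (demographics-table style)."""

    records: list[ComparisonRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.variable, r.test, r.statistic, r.p) for r in self.records],
            columns=["variable", "test", "statistic", "p"],
        )

    def __getitem__(self, variable: str) -> ComparisonRecord:
        for r in self.records:
            if r.variable == variable:
                return r
        raise KeyError(variable)


# ---------------------------------------------------------------------------
# I/O


def read_counts(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a raw count matrix from TSV or MatrixMarket.

    TSV layout: header row of sample IDs, first column gene IDs.  MatrixMarket
    files need sidecar label files ``<path>.rows`` and ``<path>.cols`` with one
    identifier per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs in {path}: {dups[:5]}")
        if df.columns.has_duplicates:
            raise FormatError(f"duplicate sample IDs in {path}")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric entries in {path}: {exc}") from exc
        if not np.all(np.isfinite(values)):
            raise FormatError(f"missing or non-finite entries in {path}")
        if np.any(values < 0):
            raise FormatError(f"negative counts in {path}")
        return ExpressionMatrix(values, list(df.index), list(df.columns))
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = Path(str(path) + ".rows").read_text().split()
        samples = Path(str(path) + ".cols").read_text().split()
        if np.any(np.asarray(mat) < 0):
            raise FormatError(f"negative counts in {path}")
        if len(set(genes)) != len(genes):
            raise FormatError(f"duplicate gene IDs in {path}.rows")
        return ExpressionMatrix(np.asarray(mat, dtype=float), genes, samples)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")


def write_counts(x: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write an expression matrix in TSV or MatrixMarket coordinate format."""
    path = Path(path)
    if format == "tsv":
        x.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(x.values))
        Path(str(path) + ".rows").write_text("\n".join(x.gene_ids) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(x.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Normalization and filtering


def _cpm(values: np.ndarray, sample_ids: Sequence[str]) -> np.ndarray:
    libsize = values.sum(axis=0)
    zero = np.flatnonzero(libsize <= 0)
    if zero.size:
        raise ValueError(f"zero library size for sample(s): {[sample_ids[i] for i in zero]}")
    return values / libsize * 1e6


def filter_low_abundance(
    x: ExpressionMatrix, min_cpm: float = 1.0, min_fraction: float = 0.5
) -> ExpressionMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_fraction`` of samples.

    Gene order is preserved.  An empty result triggers a warning, not an error.
    """
    if x.scale != "raw_counts":
        raise ValueError("low-abundance filtering operates on raw counts")
    cpm = _cpm(x.values, x.sample_ids)
    keep = (cpm >= min_cpm).mean(axis=1) >= min_fraction
    if not keep.any():
        warnings.warn("no genes pass the low-abundance filter", stacklevel=2)
    return replace(
        x,
        values=x.values[keep],
        gene_ids=[g for g, k in zip(x.gene_ids, keep) if k],
    )


def cpm_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Return log2(CPM + 1) normalized expression."""
    if x.scale != "raw_counts":
        raise ValueError("cpm_normalize expects raw counts")
    return replace(x, values=np.log2(_cpm(x.values, x.sample_ids) + 1.0), scale="log2_cpm")


# ---------------------------------------------------------------------------
# Cohort comparison (demographics table)


def yates_chi2(table: np.ndarray) -> tuple[float, float]:
    """Yates continuity-corrected Pearson chi-square for a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables")
    stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=True)
    return float(stat), float(p)


def compare_groups(
    pheno: pd.DataFrame,
    group_var: str,
    continuous_vars: Sequence[str] = (),
    categorical_vars: Sequence[str] = (),
    equal_var: bool = True,
) -> CohortComparison:
    """Two-group comparison of demographic / technical variables.

    Continuous variables get a two-sample t-test (pooled variance by default,
    Welch with ``equal_var=False``); binary categoricals get a Yates
    continuity-corrected Pearson chi-square on the 2x2 table.
    """
    groups = pd.unique(pheno[group_var].dropna())
    if len(groups) != 2:
        raise ValueError(f"group variable {group_var!r} must be binary, got {list(groups)}")
    g0 = pheno[pheno[group_var] == groups[0]]
    g1 = pheno[pheno[group_var] == groups[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs at least 2 samples")
    comp = CohortComparison()
    for var in continuous_vars:
        t, p = scipy.stats.ttest_ind(g0[var], g1[var], equal_var=equal_var)
        comp.records.append(ComparisonRecord(var, "t", float(t), float(p)))
    for var in categorical_vars:
        tab = pd.crosstab(pheno[group_var], pheno[var])
        if tab.shape != (2, 2):
            raise ValueError(f"categorical variable {var!r} is not binary")
        stat, p = yates_chi2(tab.to_numpy())
        comp.records.append(ComparisonRecord(var, "chi2_yates", stat, p))
    return comp
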