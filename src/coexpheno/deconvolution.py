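"""Leukocyte deconvolution of bulk expression against a fixed signature matrix.

Per sample, expression on the shared genes is regressed on the signature
columns by ordinary least squares; negative coefficients are eliminated
iteratively (drop the most negative cell type, refit) and the surviving
coefficients are normalized to proportions.  Mixing is linear in cell
abundance, so deconvolution runs on linear-scale expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .expression import CohortComparison, ComparisonRecord, ExpressionMatrix


@dataclass
class CellProportionMatrix:
    """Samples x cell-types nonnegative proportions, rows summing to 1."""

    values: np.ndarray
    sample_ids: list[str]
    celltypes: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.celltypes)


def _check_signature_rank(S: np.ndarray, celltypes: list[str]) -> None:
    rank = np.linalg.matrix_rank(S)
    if rank < S.shape[1]:
        # name the offending columns: those whose removal restores full rank
        collinear = []
        for j in range(S.shape[1]):
            rest = np.delete(S, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                collinear.append(celltypes[j])
        raise ValueError(
            f"signature matrix is rank-deficient; collinear columns: {collinear}"
        )


def _nnls_by_elimination(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS with iterative elimination of negative coefficients.

    While any coefficient is negative, the most negative one (ties broken by
    lower column index) is dropped and the remaining columns are refit.
    Terminates in at most ``S.shape[1]`` refits.
    """
    k = S.shape[1]
    active = list(range(k))
    coef = np.zeros(k)
    while active:
        b, *_ = np.linalg.lstsq(S[:, active], y, rcond=None)
        if np.all(b >= 0) or len(active) == 1:
            coef[:] = 0.0
            coef[active] = np.clip(b, 0.0, None)
            return coef
        worst = int(np.argmin(b))  # argmin takes the first (lowest index) on ties
        active.pop(worst)
    return coef


def estimate_proportions(
    x: ExpressionMatrix, signature: ExpressionMatrix
) -> CellProportionMatrix:
    """Estimate cell-type proportions for every sample of ``x``.

    ``signature`` is a genes x cell-types matrix (cell types in the sample
    slot).  At least two genes must be shared with ``x`` and the signature
    columns must be linearly independent on the shared genes.
    """
    shared = [g for g in signature.gene_ids if g in set(x.gene_ids)]
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} genes shared between expression and signature; need >= 2"
        )
    S = signature.subset_genes(shared).values
    X = x.subset_genes(shared).values
    celltypes = list(signature.sample_ids)
    _check_signature_rank(S, celltypes)

    props = np.zeros((x.n_samples, len(celltypes)))
    for i in range(x.n_samples):
        coef = _nnls_by_elimination(S, X[:, i])
        total = coef.sum()
        props[i] = coef / total if total > 0 else np.full(len(celltypes), np.nan)
    return CellProportionMatrix(props, list(x.sample_ids), celltypes)


def test_proportion_differences(
    props: CellProportionMatrix, pheno: pd.DataFrame, var: str
) -> CohortComparison:
    """Two-sample t-test per cell type for a binary grouping variable.

    Degenerate (constant) proportions yield NaN statistics, flagged by the
    NaN itself rather than an error.
    """
    groups = pd.unique(pheno[var].dropna())
    if len(groups) != 2:
        raise ValueError(f"grouping variable {var!r} must be binary")
    mask0 = (pheno[var] == groups[0]).to_numpy()
    mask1 = (pheno[var] == groups[1]).to_numpy()
    if mask0.sum() < 2 or mask1.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    comp = CohortComparison()
    for j, ct in enumerate(props.celltypes):
        a, b = props.values[mask0, j], props.values[mask1, j]
        if np.allclose(np.concatenate([a, b]).std(), 0.0):
            comp.records.append(ComparisonRecord(ct, "t", float("nan"), float("nan")))
            continue
        t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
        comp.records.append(ComparisonRecord(ct, "t", float(t), float(p)))
    return comp


# the name follows the per-cell-type testing operation, not a pytest test
test_proportion_differences.__test__ = False  # type: ignore[attr-defined]
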