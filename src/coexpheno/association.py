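"""Negative-binomial association of syndrome-scale t-scores with module
eigengenes and with individual genes, plus the supporting statistics
(Benjamini-Hochberg FDR, Nagelkerke pseudo-R^2).

The t-scores are bounded below at 50 by construction and right-skewed, so
they are modeled directly as NB2 counts on the log link (an optional
``shift_floor`` subtracts the floor first, for sensitivity analysis).  Each
test compares a full model (predictor + covariates + surrogate variables)
against the nested null without the predictor: the predictor's Wald Z and
two-sided normal p-value are reported together with the Nagelkerke R^2
increment, and BH-FDR is applied across the whole family of tests.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .nbglm import GLMFit, RankDeficientDesign, fit_nb_glm
from .network import ModuleEigengenes, ModulePartition
from .sva import PROTECTED_COVARIATES, SurrogateVariables
from .synthetic import SYNDROME_SCALES

ASSOCIATION_COLUMNS = ["scale", "unit", "beta", "se", "z", "p", "fdrp", "r2_nagelkerke"]


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nagelkerke_r2(fit: GLMFit, null_fit: GLMFit) -> float:
    """Nagelkerke pseudo-R^2 of ``fit`` against the nested ``null_fit``.

    R^2_CS = 1 - exp((2/n)(ll0 - ll1)); Nagelkerke divides by its maximum
    1 - exp((2/n) ll0), giving a value in [0, 1].
    """
    if fit.n != null_fit.n:
        raise ValueError("fits compare different numbers of observations")
    ll1, ll0, n = fit.loglik, null_fit.loglik, fit.n
    if ll1 < ll0 - 1e-6:
        raise ValueError(
            f"full-model log-likelihood ({ll1:.6g}) below null ({ll0:.6g}); "
            "models are not nested or the fit failed"
        )
    r2_cs = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    denom = 1.0 - np.exp((2.0 / n) * ll0)
    if denom <= 0:
        return 0.0
    return float(np.clip(r2_cs / denom, 0.0, 1.0))


def _design_matrix(
    pheno: pd.DataFrame,
    covariates: Sequence[str],
    svs: SurrogateVariables | None,
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for c in covariates:
        cols.append(pheno[c].to_numpy(dtype=float))
        names.append(c)
    if svs is not None:
        if list(svs.sample_ids) != list(pheno.index):
            raise ValueError("surrogate variables and phenotypes have misaligned samples")
        for j in range(svs.k):
            cols.append(svs.values[:, j])
            names.append(f"SV{j + 1}")
    return np.column_stack(cols), names


def _scale_counts(pheno: pd.DataFrame, scale: str, shift_floor: bool, t_floor: int) -> np.ndarray:
    y = pheno[scale].to_numpy(dtype=float)
    if shift_floor:
        y = y - t_floor
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError(f"scale {scale!r} does not contain nonnegative integer t-scores")
    return y


def _associate(
    predictors: dict[str, np.ndarray],
    pheno: pd.DataFrame,
    scales: Sequence[str],
    covariates: Sequence[str],
    svs: SurrogateVariables | None,
    shift_floor: bool,
    t_floor: int,
    pairs: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Shared driver: NB fit per (scale, predictor) vs the nested null."""
    base, base_names = _design_matrix(pheno, covariates, svs)
    records = []
    for scale in scales:
        units = pairs[scale] if pairs is not None else list(predictors)
        if not units:
            continue
        y = _scale_counts(pheno, scale, shift_floor, t_floor)
        null_fit = fit_nb_glm(y, base, names=base_names)
        for unit in units:
            X = np.column_stack([base[:, :1], predictors[unit], base[:, 1:]])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise RankDeficientDesign(
                    f"design for ({scale}, {unit}) is rank deficient "
                    "(predictor collinear with covariates?)"
                )
            fit = fit_nb_glm(y, X, names=["intercept", unit] + base_names[1:])
            beta, se, z, p = fit.coef_named(unit)
            r2 = nagelkerke_r2(fit, null_fit) if fit.loglik >= null_fit.loglik - 1e-6 else 0.0
            records.append((scale, unit, beta, se, z, p, np.nan, r2))
    table = pd.DataFrame(records, columns=ASSOCIATION_COLUMNS)
    if len(table):
        table["fdrp"] = bh_fdr(table["p"].to_numpy())
    return table


def associate_modules(
    me: ModuleEigengenes,
    pheno: pd.DataFrame,
    covariates: Sequence[str] = PROTECTED_COVARIATES,
    svs: SurrogateVariables | None = None,
    scales: Sequence[str] = SYNDROME_SCALES,
    shift_floor: bool = False,
    t_floor: int = 50,
) -> pd.DataFrame:
    """NB association of every (scale, module eigengene) pair.

    BH-FDR is applied jointly across the full scales x modules family.
    Returns a table with columns scale, unit, beta, se, z, p, fdrp and the
    Nagelkerke R^2 increment of the eigengene over the covariate-only null.
    """
    if list(me.sample_ids) != list(pheno.index):
        raise ValueError("eigengenes and phenotypes have misaligned samples")
    predictors = {name: me.values[:, j] for j, name in enumerate(me.names)}
    return _associate(predictors, pheno, scales, covariates, svs, shift_floor, t_floor)


def significant_pairs(table: pd.DataFrame, alpha: float = 0.05) -> list[tuple[str, str]]:
    """(scale, unit) pairs significant after FDR correction."""
    hits = table[table.fdrp < alpha]
    return list(zip(hits.scale, hits.unit))


def associate_genes(
    x: ExpressionMatrix,
    pheno: pd.DataFrame,
    partition: ModulePartition,
    sig_pairs: Sequence[tuple[str, str]],
    covariates: Sequence[str] = PROTECTED_COVARIATES,
    svs: SurrogateVariables | None = None,
    shift_floor: bool = False,
    t_floor: int = 50,
) -> pd.DataFrame:
    """Gene-level NB association, restricted to the follow-up family.

    For each scale with at least one FDR-significant module, every gene of
    that scale's significant modules is tested (standardized normalized
    expression as the predictor); BH-FDR is applied across exactly these
    tests.  An empty ``sig_pairs`` yields an empty table.
    """
    if list(x.sample_ids) != list(pheno.index):
        raise ValueError("expression and phenotypes have misaligned samples")
    if not sig_pairs:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)

    scale_modules: dict[str, list[int]] = {}
    for scale, unit in sig_pairs:
        label = int(str(unit).removeprefix("ME"))
        scale_modules.setdefault(scale, []).append(label)

    gene_rows = {g: i for i, g in enumerate(x.gene_ids)}
    z = x.values - x.values.mean(axis=1, keepdims=True)
    sd = x.values.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = z / sd[:, None]

    predictors: dict[str, np.ndarray] = {}
    pairs: dict[str, list[str]] = {}
    for scale, labels in scale_modules.items():
        genes: list[str] = []
        for label in sorted(set(labels)):
            genes.extend(partition.module_genes(label))
        pairs[scale] = genes
        for g in genes:
            predictors.setdefault(g, z[gene_rows[g]])

    return _associate(
        predictors, pheno, list(pairs), covariates, svs, shift_floor, t_floor, pairs=pairs
    )
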