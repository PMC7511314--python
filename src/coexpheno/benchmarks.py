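"""Recovery and calibration experiments on the synthetic generator.

Each function runs one planted-truth experiment end to end (generate ->
analyze -> score against truth) and returns plain numbers.  They are used by
the acceptance test suite and by ``scripts/acceptance.py``; problem sizes are
chosen to finish in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .association import associate_modules, nagelkerke_r2
from .deconvolution import estimate_proportions
from .expression import ExpressionMatrix, cpm_normalize
from .nbglm import fit_nb_glm
from .network import (
    ModuleEigengenes,
    ModulePartition,
    NetworkParams,
    adjacency,
    detect_modules,
    module_eigengenes,
    tom_dissimilarity,
)
from .ptrs import crossvalidate_ptrs
from .sva import estimate_num_sv, estimate_svs, residualize_expression
from .synthetic import SimulationConfig, generate_cohort, generate_mixture

COVARIATES = ["age", "sex", "race", "rin"]


def make_signature(seed: int = 7, n_genes: int = 40, n_types: int = 5) -> ExpressionMatrix:
    """Synthetic leukocyte signature: blocks of over-expressed marker genes
    per cell type on a shared lognormal baseline."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=3.0, sigma=0.4, size=(n_genes, 1))
    values = np.tile(base, (1, n_types))
    block = n_genes // n_types
    names = ["neutrophil", "lymphocyte", "monocyte", "eosinophil", "basophil"][:n_types]
    for t in range(n_types):
        markers = slice(t * block, (t + 1) * block)
        values[markers, t] *= rng.uniform(5.0, 10.0, size=block)
    return ExpressionMatrix(
        values, [f"sig{i:02d}" for i in range(n_genes)], names, scale="raw_counts"
    )


# ---------------------------------------------------------------------------
# module recovery


def module_recovery(n_seeds: int = 20, seed0: int = 0) -> list[float]:
    """ARI of detected vs planted modules on the reference generator
    (100 samples, 3000 genes, 10 modules, loading SD 1).

    Expression is adjusted for the known covariates and the planted batch
    before network construction, isolating module detection from
    hidden-factor estimation (which has its own recovery experiment).
    """
    aris = []
    for s in range(n_seeds):
        cfg = SimulationConfig(seed=seed0 + s)
        coh = generate_cohort(cfg)
        x = cpm_normalize(coh.counts)
        design = np.column_stack(
            [coh.phenotypes[COVARIATES].to_numpy(float), coh.truth_batch]
        )
        x_adj = residualize_expression(x, design)
        params = NetworkParams()
        dissim = tom_dissimilarity(adjacency(x_adj, params))
        part = detect_modules(dissim, params, expression=x_adj)
        aris.append(float(adjusted_rand_score(coh.truth_modules, part.labels)))
    return aris


# ---------------------------------------------------------------------------
# surrogate variables


def _batch_only_cohort(seed: int) -> tuple:
    cfg = SimulationConfig(
        seed=seed,
        n_samples=100,
        n_genes=1000,
        factor_loading_sd=0.0,
        n_modules=2,
        module_sizes=[20, 20],
        batch_effect_sd=0.5,
    )
    coh = generate_cohort(cfg)
    x = cpm_normalize(coh.counts)
    cov = coh.phenotypes[COVARIATES].to_numpy(float)
    return coh, x, cov


def sva_null_rate(n_seeds: int = 20, seed0: int = 40_000) -> float:
    """Fraction of pure-noise datasets (100 x 1000 Gaussian) where the
    permutation criterion selects zero surrogate variables."""
    zeros = 0
    for s in range(n_seeds):
        vals = np.random.default_rng(seed0 + s).standard_normal((1000, 100))
        x = ExpressionMatrix(
            vals, [f"g{i}" for i in range(1000)], [f"s{i}" for i in range(100)],
            scale="log2_cpm",
        )
        zeros += estimate_num_sv(x, None, n_permutations=50, seed=s) == 0
    return zeros / n_seeds


def sva_power_rate(n_seeds: int = 20, seed0: int = 0) -> float:
    """Fraction of batch-only cohorts (batch SD 0.5 on 30% of genes) where at
    least one surrogate variable is detected."""
    hits = 0
    for s in range(n_seeds):
        coh, x, cov = _batch_only_cohort(seed0 + s)
        hits += estimate_num_sv(x, cov, n_permutations=50, seed=s) >= 1
    return hits / n_seeds


def sva_batch_correlation(n_seeds: int = 5, seed0: int = 100) -> list[float]:
    """|cor(SV1, planted batch)| on batch-only cohorts."""
    cors = []
    for s in range(n_seeds):
        coh, x, cov = _batch_only_cohort(seed0 + s)
        svs = estimate_svs(x, cov, k=1)
        cors.append(float(abs(np.corrcoef(svs.values[:, 0], coh.truth_batch)[0, 1])))
    return cors


# ---------------------------------------------------------------------------
# deconvolution


def deconvolution_errors(seed: int = 0, n_mixtures: int = 30) -> tuple[float, float]:
    """(max abs error on noiseless mixtures, RMSE at noise SD = 10% of the
    mean signal)."""
    signature = make_signature()
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(np.full(signature.n_samples, 2.0), size=n_mixtures)
    clean = generate_mixture(signature, props, noise_sd=0.0, seed=seed)
    est = estimate_proportions(clean, signature)
    max_err = float(np.max(np.abs(est.values - props)))
    noisy = generate_mixture(
        signature, props, noise_sd=0.1 * float(signature.values.mean()), seed=seed + 1
    )
    est_noisy = estimate_proportions(noisy, signature)
    rmse = float(np.sqrt(np.mean((est_noisy.values - props) ** 2)))
    return max_err, rmse


# ---------------------------------------------------------------------------
# association calibration


def _calibration_cohort(seed: int):
    cfg = SimulationConfig(
        seed=seed,
        n_samples=95,
        n_genes=200,
        n_modules=2,
        module_sizes=[30, 20],
        phenotype_effects={"attention_problems": [(0, 1.2)]},
    )
    return generate_cohort(cfg)


def association_type1_rate(n_sims: int = 500, alpha: float = 0.05, seed0: int = 50_000) -> float:
    """Type-I error of the module-association NB Wald test on a null
    scale-module pair (no planted effect) at n = 95."""
    rejections = 0
    for s in range(n_sims):
        coh = _calibration_cohort(seed0 + s)
        x = cpm_normalize(coh.counts)
        part = ModulePartition(coh.truth_modules, x.gene_ids)
        me_all = module_eigengenes(x, part)
        # module 2 has no effect on somatic complaints (a null scale)
        j = me_all.module_labels.index(2)
        me = ModuleEigengenes(
            me_all.values[:, [j]], me_all.sample_ids, [2], [me_all.var_explained[j]]
        )
        table = associate_modules(me, coh.phenotypes, scales=["somatic_complaints"])
        rejections += int(table.p.iloc[0] < alpha)
    return rejections / n_sims


# ---------------------------------------------------------------------------
# polytranscript risk scores


def _ptrs_cohort(seed: int):
    cfg = SimulationConfig(
        seed=seed,
        n_samples=95,
        n_genes=300,
        n_modules=3,
        module_sizes=[40, 30, 30],
        phenotype_effects={"attention_problems": [(0, 1.2)]},
    )
    return generate_cohort(cfg)


def ptrs_null(n_seeds: int = 50, seed0: int = 0, perm_seed0: int = 10_000) -> tuple[float, float]:
    """(mean max R^2, FDR-significant fraction) of cross-validated scores
    against permuted phenotypes."""
    maxr2, sig, total = [], 0, 0
    for s in range(n_seeds):
        coh = _ptrs_cohort(seed0 + s)
        x = cpm_normalize(coh.counts)
        rng = np.random.default_rng(perm_seed0 + s)
        pheno = coh.phenotypes.copy()
        pheno[["attention_problems"]] = pheno[["attention_problems"]].to_numpy()[
            rng.permutation(len(pheno))
        ]
        res = crossvalidate_ptrs(x, pheno, scales=["attention_problems"], k=5, seed=seed0 + s)
        maxr2.append(float(res.summary.max_r2.iloc[0]))
        sig += int((res.table.fdrp < 0.05).sum())
        total += len(res.table)
    return float(np.mean(maxr2)), sig / total


def ptrs_recovery(n_seeds: int = 20, seed0: int = 0) -> tuple[float, float]:
    """(mean cross-validated max R^2, mean oracle in-sample R^2) for the
    planted attention-problems signal calibrated to oracle R^2 ~ 0.15."""
    cvs, oracles = [], []
    for s in range(n_seeds):
        coh = _ptrs_cohort(seed0 + s)
        x = cpm_normalize(coh.counts)
        y = coh.phenotypes["attention_problems"].to_numpy(float)
        f = coh.truth_factors[:, 0]
        cov = coh.phenotypes[COVARIATES].to_numpy(float)
        base = np.column_stack([np.ones_like(f), cov])
        full = np.column_stack([np.ones_like(f), f, cov])
        oracles.append(nagelkerke_r2(fit_nb_glm(y, full), fit_nb_glm(y, base)))
        res = crossvalidate_ptrs(x, coh.phenotypes, scales=["attention_problems"], k=5, seed=seed0 + s)
        cvs.append(float(res.summary.max_r2.iloc[0]))
    return float(np.mean(cvs)), float(np.mean(oracles))
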