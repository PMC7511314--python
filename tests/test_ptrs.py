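"""Polytranscript risk scoring: weight training, scoring arithmetic,
cross-validation hygiene (no leakage, determinism) and external-weights mode."""

import numpy as np
import pandas as pd
import pytest

from coexpheno.expression import ExpressionMatrix, cpm_normalize
from coexpheno.ptrs import (
    DEFAULT_THRESHOLDS,
    TranscriptWeightTable,
    crossvalidate_ptrs,
    external_ptrs,
    score_samples,
    train_weights,
)


@pytest.fixture(scope="module")
def cohort_x(small_cohort_module):
    return cpm_normalize(small_cohort_module.counts)


@pytest.fixture(scope="module")
def small_cohort_module():
    from coexpheno.synthetic import SimulationConfig, generate_cohort

    cfg = SimulationConfig(
        n_samples=80,
        n_genes=200,
        n_modules=2,
        module_sizes=[40, 30],
        seed=21,
        phenotype_effects={"attention_problems": [(0, 1.2)]},
    )
    return generate_cohort(cfg)


def _weights(genes, betas, ps, **kw):
    return TranscriptWeightTable(
        pd.DataFrame({"gene_id": genes, "beta": betas, "p": ps}), **kw
    )


class TestTrainWeights:
    def test_constant_gene_flagged(self, small_cohort_module, cohort_x):
        vals = cohort_x.values.copy()
        vals[0] = 3.0  # constant gene
        x = ExpressionMatrix(vals, cohort_x.gene_ids, cohort_x.sample_ids, scale="log2_cpm")
        wt = train_weights(x, small_cohort_module.phenotypes, "attention_problems")
        assert wt.table.beta.iloc[0] == 0.0
        assert wt.table.p.iloc[0] == 1.0

    def test_causal_genes_rank_first(self, small_cohort_module, cohort_x):
        wt = train_weights(cohort_x, small_cohort_module.phenotypes, "attention_problems")
        top = wt.table.nsmallest(10, "p").gene_id
        causal = set(np.array(cohort_x.gene_ids)[small_cohort_module.truth_modules == 1])
        assert sum(g in causal for g in top) >= 5

    def test_null_p_roughly_uniform(self, small_cohort_module, cohort_x):
        # somatic complaints carries no planted module effect
        from scipy.stats import kstest

        wt = train_weights(cohort_x, small_cohort_module.phenotypes, "somatic_complaints")
        background = wt.table.p[small_cohort_module.truth_modules == 0]
        assert kstest(background, "uniform").pvalue > 0.01

    def test_small_subset_raises(self, small_cohort_module, cohort_x):
        with pytest.raises(ValueError, match=">= 20"):
            train_weights(
                cohort_x,
                small_cohort_module.phenotypes,
                "attention_problems",
                sample_subset=cohort_x.sample_ids[:10],
            )


class TestScoreSamples:
    def test_single_gene_arithmetic(self):
        # beta = 2 and standardized expression z = (-1, 0, 1) -> scores (-2, 0, 2)
        x = ExpressionMatrix(
            np.array([[1.0, 2.0, 3.0]]), ["g"], ["a", "b", "c"], scale="log2_cpm"
        )
        wt = _weights(["g"], [2.0], [0.001])
        stats = (pd.Series([2.0], index=["g"]), pd.Series([1.0], index=["g"]))
        out = score_samples(x, wt, p_threshold=0.05, standardization_stats=stats)
        np.testing.assert_allclose(out.scores, [-2.0, 0.0, 2.0], atol=1e-12)

    def test_threshold_one_includes_all(self, cohort_x):
        n = cohort_x.n_genes
        wt = _weights(cohort_x.gene_ids, np.ones(n), np.linspace(0, 1, n))
        out = score_samples(cohort_x, wt, p_threshold=1.0)
        assert out.n_genes == n

    def test_empty_selection_flagged(self, cohort_x):
        wt = _weights(cohort_x.gene_ids[:5], np.ones(5), np.full(5, 0.9))
        out = score_samples(cohort_x, wt, p_threshold=0.001)
        assert out.empty and np.all(out.scores == 0)

    def test_gene_order_invariance(self, cohort_x, rng):
        n = cohort_x.n_genes
        betas = rng.standard_normal(n)
        ps = rng.uniform(size=n)
        wt = _weights(cohort_x.gene_ids, betas, ps)
        perm = rng.permutation(n)
        wt_perm = _weights(
            [cohort_x.gene_ids[i] for i in perm], betas[perm], ps[perm]
        )
        a = score_samples(cohort_x, wt, p_threshold=0.5)
        b = score_samples(cohort_x, wt_perm, p_threshold=0.5)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-10)

    def test_missing_genes_raise(self, cohort_x):
        wt = _weights(["nope1", "nope2"], [1.0, 1.0], [0.0, 0.0])
        with pytest.raises(KeyError, match="nope"):
            score_samples(cohort_x, wt, p_threshold=1.0)


class TestCrossvalidate:
    def test_deterministic_given_seed(self, small_cohort_module, cohort_x):
        a = crossvalidate_ptrs(
            cohort_x, small_cohort_module.phenotypes, scales=["attention_problems"], seed=4
        )
        b = crossvalidate_ptrs(
            cohort_x, small_cohort_module.phenotypes, scales=["attention_problems"], seed=4
        )
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_no_information_leak(self, small_cohort_module, cohort_x):
        """Duplicating a withheld sample into the training data changes its
        score: training and scoring are otherwise disjoint."""
        pheno = small_cohort_module.phenotypes
        train_ids = cohort_x.sample_ids[:60]
        held = cohort_x.sample_ids[60:]
        wt_clean = train_weights(
            cohort_x, pheno, "attention_problems", sample_subset=train_ids
        )
        # contaminate: replace one training sample by a withheld one
        leak_ids = train_ids[:-1] + [held[0]]
        wt_leaky = train_weights(
            cohort_x, pheno, "attention_problems", sample_subset=leak_ids
        )
        test = ExpressionMatrix(
            cohort_x.values[:, 60:], cohort_x.gene_ids, held, scale="log2_cpm"
        )
        s_clean = score_samples(test, wt_clean, p_threshold=1.0).scores
        s_leaky = score_samples(test, wt_leaky, p_threshold=1.0).scores
        assert not np.allclose(s_clean[0], s_leaky[0])

    def test_r2_bounds_and_fdr(self, small_cohort_module, cohort_x):
        res = crossvalidate_ptrs(
            cohort_x, small_cohort_module.phenotypes, scales=["attention_problems"], seed=0
        )
        assert ((res.table.r2_nagelkerke >= 0) & (res.table.r2_nagelkerke <= 1)).all()
        assert (res.table.fdrp >= res.table.p - 1e-12).all()
        assert len(res.table) == len(DEFAULT_THRESHOLDS)

    def test_wrong_grid_length_raises(self, small_cohort_module, cohort_x):
        with pytest.raises(ValueError, match="threshold grid"):
            crossvalidate_ptrs(
                cohort_x,
                small_cohort_module.phenotypes,
                thresholds=(0.05, 1.0),
            )


class TestExternal:
    def test_matches_whole_sample_weights(self, small_cohort_module, cohort_x):
        """External mode with de-novo whole-sample weights equals a direct
        (no-CV) evaluation of those same scores."""
        pheno = small_cohort_module.phenotypes
        wt = train_weights(cohort_x, pheno, "attention_problems")
        wt.source = "denovo"
        res = external_ptrs(cohort_x, pheno, [wt], scales=["attention_problems"])
        # independent direct computation at one threshold
        from coexpheno.ptrs import _evaluate_scores

        sv = score_samples(cohort_x, wt, p_threshold=0.05)
        r2, p = _evaluate_scores(
            sv.scores, pheno, "attention_problems", ("age", "sex", "race", "rin")
        )
        row = res.table[(res.table.threshold == 0.05)].iloc[0]
        assert row.r2_nagelkerke == pytest.approx(r2, abs=1e-10)
        assert row.p == pytest.approx(p, abs=1e-10)

    def test_48_test_contract(self, small_cohort_module, cohort_x):
        pheno = small_cohort_module.phenotypes
        wt = train_weights(cohort_x, pheno, "attention_problems")
        wt.source = "disorderX"
        res = external_ptrs(cohort_x, pheno, [wt])
        assert len(res.table) == 48  # 8 scales x 6 thresholds

    def test_signal_transfers_only_with_shared_causal_module(self):
        from coexpheno.synthetic import SimulationConfig, generate_cohort

        def make(seed, effects):
            cfg = SimulationConfig(
                n_samples=80,
                n_genes=200,
                n_modules=2,
                module_sizes=[40, 30],
                seed=seed,
                phenotype_effects=effects,
            )
            return generate_cohort(cfg)

        src = make(31, {"attention_problems": [(0, 1.2)]})
        tgt_shared = make(32, {"attention_problems": [(0, 1.2)]})
        tgt_disjoint = make(33, {"attention_problems": [(1, 1.2)]})
        xs = cpm_normalize(src.counts)
        wt = train_weights(xs, src.phenotypes, "attention_problems")
        wt.source = "source_cohort"
        # same gene universe by construction (same generator layout)
        r_shared = external_ptrs(
            cpm_normalize(tgt_shared.counts),
            tgt_shared.phenotypes,
            [wt],
            scales=["attention_problems"],
        )
        r_disjoint = external_ptrs(
            cpm_normalize(tgt_disjoint.counts),
            tgt_disjoint.phenotypes,
            [wt],
            scales=["attention_problems"],
        )
        assert r_shared.summary.max_r2.iloc[0] > r_disjoint.summary.max_r2.iloc[0]
        assert r_shared.summary.min_p.iloc[0] < 0.05

    def test_empty_intersection_raises(self, small_cohort_module, cohort_x):
        wt = _weights(["zz1", "zz2", "zz3"], np.ones(3), np.zeros(3))
        wt.source = "alien"
        with pytest.raises(ValueError, match="shared"):
            external_ptrs(cohort_x, small_cohort_module.phenotypes, [wt])
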