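"""Surrogate variable analysis: estimate hidden confounders in expression
data while protecting known covariates.

Two stages, mirroring the classical recipe:

* ``estimate_num_sv`` — how many hidden factors?  The expression matrix is
  residualized on the protected covariates and the residual singular-value
  spectrum is compared against a permutation null (per-gene permutation of
  residuals, re-residualized), counting leading components whose
  variance-explained exceeds the null's upper quantile.  This is a
  distribution-free parallel-analysis criterion.

* ``estimate_svs`` — iteratively re-weighted estimation: SVD of the
  covariate-residualized matrix proposes candidate surrogate variables; each
  gene is weighted by the evidence that it is affected by the candidate SVs
  but not by the covariates (from nested-model F-tests); the SVD is recomputed
  on the weighted matrix until the SV subspace stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.stats

from .expression import ExpressionMatrix

#: Covariates protected by default in this pipeline: age, sex, race and RNA
#: quality (RIN).
PROTECTED_COVARIATES = ("age", "sex", "race", "rin")


@dataclass
class SurrogateVariables:
    """Samples x k surrogate-variable scores, unit variance, orthogonal."""

    values: np.ndarray
    sample_ids: list[str]
    converged: bool = True

    @property
    def k(self) -> int:
        return self.values.shape[1]


def _with_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if covariates is None or covariates.size == 0:
        return ones
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    return np.hstack([ones, covariates])


def _residualize(E: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of each column of E (samples x genes) on the design."""
    beta, *_ = np.linalg.lstsq(design, E, rcond=None)
    return E - design @ beta


def estimate_num_sv(
    x: ExpressionMatrix,
    covariates: np.ndarray | None = None,
    n_permutations: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
) -> int:
    """Permutation (parallel-analysis) estimate of the number of hidden factors.

    Counts leading residual singular values whose variance-explained share
    exceeds the (1 - alpha) quantile of the permutation null, stopping at the
    first failure.
    """
    E = x.values.T  # samples x genes
    n, g = E.shape
    design = _with_intercept(covariates, n)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("protected covariates are not full rank")
    if n <= design.shape[1] + 2:
        raise ValueError(
            f"too few samples (n={n}) for {design.shape[1]} protected covariates"
        )
    R = _residualize(E, design)
    if np.allclose(R, 0.0):
        return 0
    sv = np.linalg.svd(R, compute_uv=False)
    obs = sv**2 / np.sum(sv**2)

    rng = np.random.default_rng(seed)
    n_comp = min(n, g)
    null = np.empty((n_permutations, n_comp))
    for b in range(n_permutations):
        P = R.copy()
        # permute residuals within each gene, breaking sample structure
        idx = np.argsort(rng.random((n, g)), axis=0)
        P = np.take_along_axis(P, idx, axis=0)
        P = _residualize(P, design)
        psv = np.linalg.svd(P, compute_uv=False)
        null[b] = psv**2 / np.sum(psv**2)

    # exact permutation p-value per component: (1 + #{null >= obs}) / (B + 1)
    k = 0
    for i in range(len(obs)):
        p = (1.0 + np.sum(null[:, i] >= obs[i])) / (n_permutations + 1.0)
        if p <= alpha:
            k += 1
        else:
            break
    return k


def residualize_expression(
    x: ExpressionMatrix,
    covariates: np.ndarray | None = None,
    svs: SurrogateVariables | None = None,
) -> ExpressionMatrix:
    """Expression adjusted for covariates and surrogate variables.

    Gene means are added back so the result stays on the original scale.
    Used before network construction so hidden factors do not masquerade as
    co-expression modules.
    """
    from dataclasses import replace

    E = x.values.T
    design = _with_intercept(covariates, E.shape[0])
    if svs is not None:
        if list(svs.sample_ids) != list(x.sample_ids):
            raise ValueError("surrogate variables and expression have misaligned samples")
        design = np.hstack([design, svs.values])
    R = _residualize(E, design)
    return replace(x, values=R.T + x.values.mean(axis=1, keepdims=True))


def _f_pvalues(E: np.ndarray, full: np.ndarray, reduced: np.ndarray) -> np.ndarray:
    """Per-gene p-values from nested-model F-tests (columns of E are genes)."""
    n = E.shape[0]
    df_full = n - full.shape[1]
    df_extra = full.shape[1] - reduced.shape[1]
    if df_full <= 0 or df_extra <= 0:
        raise ValueError("degenerate nested design")
    rss_full = np.sum(_residualize(E, full) ** 2, axis=0)
    rss_red = np.sum(_residualize(E, reduced) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / df_extra) / (rss_full / df_full)
    f = np.where(np.isfinite(f), np.clip(f, 0, None), 0.0)
    return scipy.stats.f.sf(f, df_extra, df_full)


def estimate_svs(
    x: ExpressionMatrix,
    covariates: np.ndarray | None = None,
    k: int = 1,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> SurrogateVariables:
    """Iteratively re-weighted estimation of ``k`` surrogate variables.

    Gene weights are (1 - p_sv) * p_cov: large when the gene tracks the
    candidate SVs (small nested-F p-value ``p_sv``) and does not track the
    protected covariates (large ``p_cov``).  Convergence is declared when the
    largest principal angle between successive SV subspaces falls below
    ``tol``; otherwise the last iterate is returned flagged unconverged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    E = x.values.T
    n = E.shape[0]
    design = _with_intercept(covariates, n)
    R = _residualize(E, design)
    rank = np.linalg.matrix_rank(R)
    if k > rank:
        raise ValueError(f"requested k={k} exceeds residual rank {rank}")

    u, s, vt = np.linalg.svd(R, full_matrices=False)
    svs = u[:, :k]
    converged = False
    intercept = design[:, :1]
    for _ in range(max_iter):
        full_sv = np.hstack([design, svs])
        p_sv = _f_pvalues(E, full_sv, design)
        if design.shape[1] > 1:
            p_cov = _f_pvalues(E, design, intercept)
        else:
            p_cov = np.ones(E.shape[1])
        w = (1.0 - p_sv) * p_cov
        u, s, vt = np.linalg.svd(R * w[None, :], full_matrices=False)
        new = u[:, :k]
        angle = scipy.linalg.subspace_angles(svs, new).max()
        svs = new
        if angle < tol:
            converged = True
            break

    # unit variance, sign fixed so each SV correlates positively with its
    # top-weighted gene residual
    out = np.empty_like(svs)
    for j in range(k):
        v = svs[:, j]
        lead = int(np.argmax(np.abs(R.T @ v)))
        if float(R[:, lead] @ v) < 0:
            v = -v
        sd = v.std(ddof=0)
        out[:, j] = v / sd if sd > 0 else v
    return SurrogateVariables(out, list(x.sample_ids), converged=converged)
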