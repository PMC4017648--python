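"""Expression preprocessing: variance-stabilising transform, latent-factor
removal, quantile normalisation and polygenic (GRAMMAR-style) residuals.

The canonical order is transform -> factor removal -> quantile normalisation,
with GRAMMAR residuals as a final stage before variance-QTL scanning. Each
stage tags its output and refuses out-of-order input.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .dataio import ExpressionTable, TwinCohort
from .lmm import TwinStructure, fit_lmm

__all__ = [
    "transform_expression",
    "remove_latent_factors",
    "quantile_normalize",
    "grammar_residuals",
    "normal_scores",
]

# stage -> stages allowed as its input
_ALLOWED_INPUT = {
    "transformed": {"raw"},
    "factor-removed": {"transformed", "raw"},
    "normalized": {"factor-removed", "transformed", "raw"},
    "grammar-residual": {"normalized"},
}


def _check_stage(e: ExpressionTable, target: str) -> None:
    if e.stage not in _ALLOWED_INPUT[target]:
        raise ValueError(
            f"stage {e.stage!r} is not valid input for {target!r} "
            f"(expected one of {sorted(_ALLOWED_INPUT[target])})"
        )


def transform_expression(e: ExpressionTable, kind: str = "sqrt") -> ExpressionTable:
    """Elementwise variance-stabilising transform.

    'sqrt' is the default for read-count-derived abundances (RPKM): counts are
    Poisson-sampled, and the square root breaks the mean-variance link
    (delta method: Var(sqrt(X)) ~ 1/4 for X ~ Poisson). 'log' applies
    log(1 + x), a common alternative for heteroskedasticity checks.
    """
    _check_stage(e, "transformed")
    v = e.values
    if kind == "sqrt":
        if (v < 0).any():
            i, j = np.argwhere(v < 0)[0]
            raise ValueError(
                f"negative value for gene {e.genes['gene_id'].iloc[i]!r}, "
                f"sample {e.samples[j]!r} under sqrt transform"
            )
        out = np.sqrt(v)
    elif kind == "log":
        out = np.log1p(v)
    elif kind == "none":
        out = v.copy()
    else:
        raise ValueError(f"unknown transform {kind!r}")
    return e.with_values(out, "transformed")


def remove_latent_factors(
    e: ExpressionTable, n_factors: int, protect: np.ndarray | None = None
) -> ExpressionTable:
    """Residualise each gene on the top sample-space principal components.

    Broad technical confounders (batch, cell growth, sequencing depth) load on
    many genes and dominate the leading PCs of the expression matrix; removing
    them is the PCA analogue of latent-factor correction. `protect` is an
    optional (n_samples, k) covariate matrix whose signal should be retained:
    it is regressed out of the factors before residualisation so variation
    aligned with the protected covariates survives.
    """
    _check_stage(e, "factor-removed")
    M = e.values - e.values.mean(axis=1, keepdims=True)
    n_genes, n_samples = M.shape
    if n_factors >= min(n_genes, n_samples):
        raise ValueError("n_factors must be below the matrix rank")
    if n_factors == 0:
        return e.with_values(M, "factor-removed")
    # right singular vectors = sample-space principal components
    _, s, Vt = np.linalg.svd(M, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum())
    if n_factors > rank:
        raise ValueError(f"n_factors={n_factors} exceeds matrix rank {rank}")
    F = Vt[:n_factors].T  # (n_samples, n_factors)
    if protect is not None:
        C = np.column_stack([np.ones(n_samples), np.asarray(protect, dtype=float)])
        F = F - C @ np.linalg.lstsq(C, F, rcond=None)[0]
        keep = np.linalg.norm(F, axis=0) > 1e-10
        F = F[:, keep]
        if F.shape[1] == 0:
            return e.with_values(M, "factor-removed")
    Q, _ = np.linalg.qr(F)
    out = M - (M @ Q) @ Q.T
    return e.with_values(out, "factor-removed")


def normal_scores(n: int) -> np.ndarray:
    """The fixed vector of normal scores Phi^{-1}((rank - 0.5)/n), rank=1..n."""
    return stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)


def quantile_normalize(e: ExpressionTable) -> ExpressionTable:
    """Map each gene's values to normal scores Phi^{-1}((rank - 0.5)/n).

    Ties receive the average rank (and thus share a quantile). The output is
    invariant to any strictly monotone transform of the input. Constant genes
    are set to all zeros with a warning.
    """
    _check_stage(e, "normalized")
    v = e.values
    if np.isnan(v).any():
        raise ValueError("missing values not supported in quantile normalisation")
    n = v.shape[1]
    ranks = stats.rankdata(v, axis=1, method="average")
    out = stats.norm.ppf((ranks - 0.5) / n)
    const = np.ptp(v, axis=1) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant gene(s) set to zero in quantile "
            "normalisation",
            stacklevel=2,
        )
        out[const] = 0.0
    return e.with_values(out, "normalized")


def grammar_residuals(e: ExpressionTable, cohort: TwinCohort) -> ExpressionTable:
    """Remove twin-structure correlation gene by gene (two-stage strategy).

    For each gene the null mixed model (intercept + family and MZ random
    intercepts) is fitted by ML and the conditional (BLUP-subtracted)
    residuals are returned: with V = s2_fam*Z_fam + s2_mz*Z_mz + s2*I and
    r = y - mu_hat, the residual is s2 * V^{-1} r, which equals the raw
    centred values when the cohort has no twin structure. Downstream variance
    tests can then ignore relatedness.
    """
    _check_stage(e, "grammar-residual")
    ts = TwinStructure.from_cohort(cohort, e.samples)
    out = np.empty_like(e.values)
    X = np.ones((len(e.samples), 1))
    for i in range(e.n_genes):
        y = e.values[i]
        try:
            fit = fit_lmm(y, X, ts, columns=["intercept"])
        except Exception:
            warnings.warn(
                f"mixed-model fit failed for gene "
                f"{e.genes['gene_id'].iloc[i]!r}; falling back to family-mean "
                "centering",
                stacklevel=2,
            )
            out[i] = _family_center(y, cohort, e.samples)
            continue
        out[i] = _conditional_residuals(y, fit, ts)
    return e.with_values(out, "grammar-residual")


def _conditional_residuals(y: np.ndarray, fit, ts: TwinStructure) -> np.ndarray:
    r = y - fit.mu
    s2, vf, vm = fit.var_res, fit.var_fam, fit.var_mz
    d = vf + vm + s2
    out = np.empty_like(r)
    if len(ts.singles):
        out[ts.singles] = s2 * r[ts.singles] / d
    for i1, i2, o in ((ts.mz1, ts.mz2, vf + vm), (ts.dz1, ts.dz2, vf)):
        if len(i1) == 0:
            continue
        det = d * d - o * o
        r1, r2 = r[i1], r[i2]
        out[i1] = s2 * (d * r1 - o * r2) / det
        out[i2] = s2 * (d * r2 - o * r1) / det
    return out


def _family_center(y: np.ndarray, cohort: TwinCohort, samples: list[str]) -> np.ndarray:
    fam = cohort.align(list(samples)).table["family_id"].to_numpy()
    out = y.astype(float).copy()
    for f in np.unique(fam):
        idx = fam == f
        out[idx] -= y[idx].mean()
    return out
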