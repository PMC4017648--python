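"""Variance-eQTL scan: squared-residual Spearman statistic with a shared
permutation FDR.

For every SNP in a gene's cis window, mean (eQTL) effects are removed by
regressing the phenotype on the genotype-probability columns P(het) and
P(alt-hom); the squared residuals measure each individual's distance from its
genotype-class mean; a Spearman rank correlation between this distance and
genotype dosage tests for a variance effect. A single set of permutations of
the distance residuals, shared across all genes and variants so that LD
structure is preserved, yields the null distribution of per-gene peak
p-values and a plug-in FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionTable, GenotypeTable, cis_window_variants

__all__ = [
    "VeqtlResult",
    "distance_residuals",
    "variance_test",
    "scan_gene",
    "scan_cohort",
    "permutation_fdr",
    "make_permutations",
    "N_PERMUTATIONS",
]

N_PERMUTATIONS = 5


class UntestableVariant(ValueError):
    """Raised when a variant's genotype design is rank deficient."""


@dataclass
class VeqtlResult:
    gene_id: str
    variant_id: str
    rho: float
    p: float
    is_peak: bool
    direction: int
    fdr: float | None = None
    perm_peak_p: np.ndarray | None = None  # peak only: permuted peak p-values


def distance_residuals(y: np.ndarray, gp: np.ndarray) -> np.ndarray:
    """Squared residuals of the regression of y on [1, P(het), P(alt-hom)].

    With hard genotype calls the regression saturates the three genotype
    classes, so the result is the squared deviation from the genotype-class
    mean. Raises UntestableVariant when the design is rank deficient
    (monomorphic variant).
    """
    y = np.asarray(y, dtype=float)
    gp = np.asarray(gp, dtype=float)
    X = np.column_stack([np.ones(len(y)), gp[:, 1], gp[:, 2]])
    if np.linalg.matrix_rank(X) < 3:
        raise UntestableVariant("genotype-probability design is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return r * r


def variance_test(
    d: np.ndarray,
    dosage: np.ndarray,
    method: str = "t",
    n_resamples: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Tie-corrected Spearman correlation between distance and dosage.

    The default p-value comes from the two-sided t approximation on n-2 df;
    ``method='permutation'`` replaces it with a permutation p-value (seeded,
    ``n_resamples`` label shuffles), preferable for small samples (n < 30)
    where the t approximation is rough. Constant distance returns (0.0, 1.0)
    (undefined correlation, flagged by the caller); constant dosage is an
    error.
    """
    d = np.asarray(d, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if len(d) < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(dosage) == 0:
        raise ValueError("dosage is constant")
    if np.ptp(d) == 0:
        return 0.0, 1.0
    rho, p = stats.spearmanr(d, dosage)
    if method == "permutation":
        rank_g = stats.rankdata(dosage)
        rank_d = stats.rankdata(d)
        rng = np.random.default_rng(seed)
        a = rank_d - rank_d.mean()
        b = rank_g - rank_g.mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        obs = (a * b).sum() / denom
        count = 0
        for _ in range(n_resamples):
            count += abs((a[rng.permutation(len(a))] * b).sum() / denom) >= abs(obs) - 1e-12
        p = (count + 1) / (n_resamples + 1)
    elif method != "t":
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


def make_permutations(n: int, n_perm: int, seed: int) -> np.ndarray:
    """One global set of permutation index vectors, drawn once per run and
    reused for every gene-variant test (the LD-preservation contract)."""
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def _spearman_matrix(rank_d: np.ndarray, rank_g: np.ndarray) -> np.ndarray:
    """Rowwise Pearson correlation of two equally-shaped rank matrices."""
    a = rank_d - rank_d.mean(axis=1, keepdims=True)
    b = rank_g - rank_g.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    return np.clip(rho, -1.0, 1.0)


def _t_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.clip(rho, -0.9999999999, 0.9999999999)
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * stats.t.sf(np.abs(t), n - 2)


def scan_gene(
    y: np.ndarray,
    gene_id: str,
    variant_ids: list[str],
    dosage: np.ndarray,
    gp: np.ndarray,
    positions: np.ndarray,
    permutations: np.ndarray,
) -> list[VeqtlResult]:
    """Scan one gene's window; returns per-variant results with the peak
    (minimum p, ties broken by genomic position) carrying the permuted peak
    p-values needed for the FDR."""
    n = len(y)
    testable, dists = [], []
    for j in range(len(variant_ids)):
        try:
            dists.append(distance_residuals(y, gp[j]))
            testable.append(j)
        except UntestableVariant:
            continue
    if not testable:
        warnings.warn(f"gene {gene_id!r}: no testable variants", stacklevel=2)
        return []
    testable = np.array(testable)
    D = np.asarray(dists)  # (m, n)
    G = dosage[testable]
    rank_d = stats.rankdata(D, axis=1)
    rank_g = stats.rankdata(G, axis=1)

    rho = _spearman_matrix(rank_d, rank_g)
    p = _t_pvalue(rho, n)
    perm_peaks = np.empty(len(permutations))
    for k, perm in enumerate(permutations):
        rho_k = _spearman_matrix(rank_d[:, perm], rank_g)
        perm_peaks[k] = _t_pvalue(rho_k, n).min()

    pos = positions[testable]
    peak_local = int(np.lexsort((pos, p))[0])
    out = []
    for loc, j in enumerate(testable):
        is_peak = loc == peak_local
        out.append(
            VeqtlResult(
                gene_id=gene_id,
                variant_id=variant_ids[j],
                rho=float(rho[loc]),
                p=float(p[loc]),
                is_peak=is_peak,
                direction=int(np.sign(rho[loc])),
                perm_peak_p=perm_peaks if is_peak else None,
            )
        )
    return out


def permutation_fdr(
    observed_peak_p: np.ndarray,
    permuted_peak_p: np.ndarray,
    n_perm: int = N_PERMUTATIONS,
    zero_protect: bool = True,
) -> np.ndarray:
    """Plug-in FDR at each observed per-gene peak p-value.

    FDR(t) = [#{permuted peaks <= t} / n_perm] / #{observed peaks <= t},
    made monotone nondecreasing in t and capped at 1. With zero_protect
    (default) the permutation count is floored at 1 so that an observed peak
    falling below every permuted statistic reports the resolution limit
    (1/n_perm)/#observed rather than an FDR of exactly zero — with a handful
    of permutations a zero count is sampling noise, not evidence of a zero
    false-discovery rate. Set zero_protect=False for the raw proportion.
    """
    obs = np.asarray(observed_peak_p, dtype=float)
    perm = np.sort(np.asarray(permuted_peak_p, dtype=float).ravel())
    order = np.argsort(obs, kind="stable")
    raw = np.empty(len(obs))
    for rank, i in enumerate(order, start=1):
        count = np.searchsorted(perm, obs[i], side="right")
        if zero_protect:
            count = max(count, 1)
        raw[i] = (count / n_perm) / rank
    # monotone: running minimum from the largest observed p downwards
    fdr = np.empty_like(raw)
    running = np.inf
    for i in order[::-1]:
        running = min(running, raw[i])
        fdr[i] = running
    return np.minimum(fdr, 1.0)


def scan_cohort(
    expr: ExpressionTable,
    geno: GenotypeTable,
    seed: int,
    half_width: int = 1_000_000,
    n_perm: int = N_PERMUTATIONS,
    zero_protect: bool = True,
) -> pd.DataFrame:
    """v-eQTL scan over all genes: per-gene peak results with permutation FDR.

    Expression must be at the grammar-residual stage (relatedness removed), or
    'normalized' for unrelated cohorts. Returns a DataFrame of peak rows
    (gene_id, variant_id, rho, p, fdr, n_variants) plus all per-variant
    results in the attribute ``.attrs['all_results']``.
    """
    if expr.stage not in ("grammar-residual", "normalized"):
        raise ValueError(
            f"expression stage {expr.stage!r}: run preprocessing first"
        )
    perms = make_permutations(len(expr.samples), n_perm, seed)
    peaks, all_rows = [], []
    for i in range(expr.n_genes):
        gene = expr.genes.iloc[i]
        window = cis_window_variants(geno, gene, half_width)
        if not window:
            continue
        idx = [geno.index_of(v) for v in window]
        results = scan_gene(
            expr.values[i],
            gene["gene_id"],
            window,
            geno.dosage[idx],
            geno.gp[idx],
            geno.variants["pos"].to_numpy()[idx],
            perms,
        )
        for r in results:
            all_rows.append((r.gene_id, r.variant_id, r.rho, r.p, r.is_peak))
        peak = next((r for r in results if r.is_peak), None)
        if peak is not None:
            peaks.append(peak)
    if not peaks:
        out = pd.DataFrame(
            columns=["gene_id", "variant_id", "rho", "p", "fdr", "n_variants"]
        )
        out.attrs["all_results"] = pd.DataFrame(
            all_rows, columns=["gene_id", "variant_id", "rho", "p", "is_peak"]
        )
        return out
    obs_p = np.array([r.p for r in peaks])
    perm_p = np.concatenate([r.perm_peak_p for r in peaks])
    fdr = permutation_fdr(obs_p, perm_p, n_perm, zero_protect=zero_protect)
    out = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in peaks],
            "variant_id": [r.variant_id for r in peaks],
            "rho": [r.rho for r in peaks],
            "p": obs_p,
            "fdr": fdr,
        }
    )
    out.attrs["all_results"] = pd.DataFrame(
        all_rows, columns=["gene_id", "variant_id", "rho", "p", "is_peak"]
    )
    return out
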