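"""Gene-by-environment detection through monozygotic-twin discordance.

MZ twins share their entire genome, so epistasis or haplotype effects cannot
create genotype-dependent differences in expression *within* MZ pairs. A
variant whose genotype predicts within-pair discordance (a d-eQTL) therefore
points to interaction with the environment. The default test asks whether the
variance of the within-pair expression difference depends on the pair's
shared genotype; the classical max-on-min regression (larger value on smaller
value plus genotype) is available as an alternative mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import TwinCohort

__all__ = ["DeqtlResult", "deqtl_test", "gxe_fraction"]


@dataclass
class DeqtlResult:
    gene_id: str
    variant_id: str
    p_discordance: float
    group_discordance: dict[int, float]  # rounded genotype -> mean |within-pair diff|
    n_pairs: dict[int, int]
    small_groups: list[int]  # genotype groups with fewer than 3 pairs


def _mz_pair_arrays(
    expr_row: np.ndarray,
    samples: list[str],
    cohort: TwinCohort,
    dosage: np.ndarray,
    tol: float = 1e-6,
):
    pos = {s: i for i, s in enumerate(samples)}
    pairs = cohort.pairs("MZ")
    if len(pairs) < 10:
        raise ValueError("need at least 10 MZ pairs")
    y1 = np.array([expr_row[pos[a]] for a, _ in pairs])
    y2 = np.array([expr_row[pos[b]] for _, b in pairs])
    g1 = np.array([dosage[pos[a]] for a, _ in pairs])
    g2 = np.array([dosage[pos[b]] for _, b in pairs])
    if np.abs(g1 - g2).max() > tol:
        bad = int(np.argmax(np.abs(g1 - g2)))
        raise ValueError(
            f"MZ pair {pairs[bad]} has differing dosages "
            f"({g1[bad]:.6g} vs {g2[bad]:.6g}): data integrity error"
        )
    return y1, y2, (g1 + g2) / 2.0


def deqtl_test(
    expr_row: np.ndarray,
    samples: list[str],
    cohort: TwinCohort,
    dosage: np.ndarray,
    gene_id: str = "",
    variant_id: str = "",
    test: str = "variance-lrt",
) -> DeqtlResult:
    """Test for genotype-dependent MZ-twin discordance at one variant.

    The default ``'variance-lrt'`` mode models the within-pair difference
    d = y1 - y2 as N(0, exp(alpha + beta*g)) and tests beta = 0 by a
    chi-square(1) likelihood ratio. Because d cancels every pair-shared
    contribution exactly — additive effects, epistasis and haplotype effects
    all act identically on both MZ twins — this statistic is null-calibrated
    for any purely genetic architecture and responds only to
    genotype-dependent environmental sensitivity.

    Modes ``'joint'`` and ``'interaction'`` implement the max-on-min
    construction instead: the larger expression value of each pair is
    regressed on the smaller, the pair's shared genotype dosage and their
    product (max ~ mu + lambda*min + delta*g + eta*(min*g)), with an F-test
    of delta = eta = 0 (joint) or eta = 0 alone. Note that because the
    estimated slope lambda is attenuated below 1, a pure mean (eQTL) effect
    leaks into delta, so the joint mode is anti-conservative for variants
    that also shift mean expression.

    Group discordance summaries use the rounded dosage. Every mode is
    invariant to which twin of a pair is listed first.
    """
    y1, y2, g = _mz_pair_arrays(expr_row, samples, cohort, dosage)
    n = len(y1)
    if test == "variance-lrt":
        p = _variance_lrt(y1 - y2, g)
    elif test in ("joint", "interaction"):
        mx, mn = np.maximum(y1, y2), np.minimum(y1, y2)
        X_full = np.column_stack([np.ones(n), mn, g, mn * g])
        if test == "joint":
            X_null = np.column_stack([np.ones(n), mn])
            df_num = 2
        else:
            X_null = np.column_stack([np.ones(n), mn, g])
            df_num = 1
        if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
            p = 1.0
        else:
            rss_full = _rss(X_full, mx)
            rss_null = _rss(X_null, mx)
            df_den = n - X_full.shape[1]
            F = ((rss_null - rss_full) / df_num) / (rss_full / df_den)
            p = float(stats.f.sf(max(F, 0.0), df_num, df_den))
    else:
        raise ValueError(f"unknown test {test!r}")

    diff = np.abs(y1 - y2)
    groups = np.rint(g).astype(int)
    group_disc = {int(k): float(diff[groups == k].mean()) for k in np.unique(groups)}
    n_pairs = {int(k): int((groups == k).sum()) for k in np.unique(groups)}
    small = [k for k, v in n_pairs.items() if v < 3]
    return DeqtlResult(
        gene_id=gene_id,
        variant_id=variant_id,
        p_discordance=p,
        group_discordance=group_disc,
        n_pairs=n_pairs,
        small_groups=small,
    )


def _variance_lrt(d: np.ndarray, g: np.ndarray) -> float:
    """LRT p-value for log-linear dependence of Var(d) on genotype g,
    d ~ N(0, exp(alpha + beta*g)), H0: beta = 0."""
    from scipy import optimize

    d2 = d * d + 1e-300
    ll0 = -0.5 * float(np.sum(np.log(d2.mean()) + d2 / d2.mean()))

    def nll(par):
        lv = par[0] + par[1] * g
        return 0.5 * float(np.sum(lv + d2 * np.exp(-np.clip(lv, -700, 700))))

    res = optimize.minimize(
        nll, [np.log(d2.mean()), 0.0], method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10},
    )
    stat = max(0.0, 2.0 * (-res.fun - ll0))
    return float(stats.chi2.sf(stat, 1))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def gxe_fraction(p_values: np.ndarray, fdr_level: float = 0.05):
    """Summarise the GxE contribution among a set of v-eQTL.

    Delegates to the Storey q-value machinery: returns (Pi1Summary,
    n_significant) where pi1 estimates the fraction of v-eQTL that show
    genotype-dependent MZ discordance and n_significant counts those passing
    q < fdr_level.
    """
    from .replication import storey_qvalues

    q, summary = storey_qvalues(np.asarray(p_values, dtype=float))
    return summary, int((q < fdr_level).sum())
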