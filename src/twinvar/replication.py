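"""Replication of interactions in an unrelated cohort, haplotype-effect
exclusion, and replication summaries (Storey q-values, pi1, concordance).

The replication cohort has no family structure, so models are ordinary least
squares with indicator covariates for study population. An interaction that
replicates must additionally survive a conditional eQTL analysis: a forward
stepwise scan lists every cis eQTL (down to rare variants), and the
interaction is retested conditioning on each eQTL in turn — if its weakest
(largest) conditional p-value no longer meets the FDR cut, the apparent
interaction is attributable to a haplotype effect (a single causal eQTL
tagged by the pair) and is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReplicationRecord",
    "Pi1Summary",
    "replicate_interaction",
    "eqtl_forward_scan",
    "haplotype_exclusion_filter",
    "apply_haplotype_filter",
    "storey_qvalues",
    "concordance_summary",
    "population_design",
    "P_ENTER_EQTL",
]

P_ENTER_EQTL = 1e-5


@dataclass
class Pi1Summary:
    pi0_hat: float
    lambda_grid: np.ndarray
    method: str = "smoother"

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0_hat


@dataclass
class ReplicationRecord:
    gene_id: str
    veqtl_id: str
    partner_id: str
    interaction_p: float
    signed_variance_share_replication: float
    q_value: float | None = None
    eqtl_conditional_max_p: float | None = None
    survives_haplotype_filter: bool | None = None
    sign_concordant: bool | None = None
    conditional_p: dict[str, float] = field(default_factory=dict)


def population_design(population: pd.Series | np.ndarray | None, n: int) -> np.ndarray:
    """Population indicator columns (reference level dropped); levels with
    fewer than 3 samples are merged into the largest level with a warning."""
    if population is None:
        return np.empty((n, 0))
    pop = pd.Series(np.asarray(population, dtype=object))
    counts = pop.value_counts()
    small = counts[counts < 3].index.tolist()
    if small:
        warnings.warn(
            f"population level(s) {small} have <3 samples; merged into "
            f"{counts.idxmax()!r}",
            stacklevel=2,
        )
        pop = pop.replace({s: counts.idxmax() for s in small})
    dummies = pd.get_dummies(pop, drop_first=True).to_numpy(dtype=float)
    return dummies


def _ols(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    n, p = X.shape
    s2 = float(r @ r) / (n - p)
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(XtX_inv) * s2)
    return beta, se, s2, n - p


def replicate_interaction(
    y: np.ndarray,
    veqtl_dosage: np.ndarray,
    partner_dosage: np.ndarray,
    population: pd.Series | np.ndarray | None = None,
    extra: np.ndarray | None = None,
) -> tuple[float, float]:
    """Interaction t-test in an unrelated cohort.

    Fits y ~ mu + a*S_v + b*S_K + c*S_v*S_K + population indicators (+ extra
    conditioning columns) by least squares; returns the two-sided t-test p for
    c and the signed variance share of the interaction (centred-product
    numerator over predictor variance plus residual variance).
    """
    y = np.asarray(y, dtype=float)
    sv = np.asarray(veqtl_dosage, dtype=float)
    sk = np.asarray(partner_dosage, dtype=float)
    n = len(y)
    cols = [np.ones(n), sv, sk, sv * sk]
    c_idx = 3
    pop = population_design(population, n)
    if pop.shape[1]:
        cols.append(pop)
    if extra is not None:
        extra = np.atleast_2d(np.asarray(extra, dtype=float))
        if extra.shape[0] != n:
            extra = extra.T
        cols.append(extra)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("replication design is rank deficient")
    beta, se, s2, df = _ols(X, y)
    t = beta[c_idx] / se[c_idx]
    p = 2.0 * float(stats.t.sf(abs(t), df))
    fitted = X @ beta
    total = float(np.var(fitted)) + s2
    prod_c = (sv - sv.mean()) * (sk - sk.mean())
    share = float(np.var(beta[c_idx] * prod_c)) / total
    signed = float(np.sign(beta[c_idx])) * share if beta[c_idx] != 0 else 0.0
    return p, signed


def eqtl_forward_scan(
    y: np.ndarray,
    dosages: dict[str, np.ndarray],
    population: pd.Series | np.ndarray | None = None,
    p_enter: float = P_ENTER_EQTL,
    max_steps: int = 20,
) -> list[str]:
    """Forward stepwise additive cis eQTL scan.

    Repeatedly adds the variant with the smallest conditional t-test p-value
    (conditioning on previously selected variants and population) while that
    p-value is below p_enter. An empty list is a valid result.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    pop = population_design(population, n)
    selected: list[str] = []
    sel_cols: list[np.ndarray] = []
    remaining = {k: np.asarray(v, dtype=float) for k, v in dosages.items()}
    for _ in range(max_steps):
        best = None
        base = [np.ones(n)] + sel_cols + ([pop] if pop.shape[1] else [])
        for vid, dose in remaining.items():
            X = np.column_stack(base + [dose])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            beta, se, _, df = _ols(X, y)
            t = beta[-1] / se[-1] if se[-1] > 0 else 0.0
            p = 2.0 * float(stats.t.sf(abs(t), df))
            if best is None or (p, vid) < best[:2]:
                best = (p, vid, dose)
        if best is None or best[0] >= p_enter:
            break
        _, vid, dose = best
        selected.append(vid)
        sel_cols.append(dose)
        del remaining[vid]
    return selected


def haplotype_exclusion_filter(
    record: ReplicationRecord,
    y: np.ndarray,
    veqtl_dosage: np.ndarray,
    partner_dosage: np.ndarray,
    eqtl_dosages: dict[str, np.ndarray],
    population: pd.Series | np.ndarray | None = None,
) -> ReplicationRecord:
    """Record the weakest conditional interaction p over all candidate eQTL.

    For each eQTL the interaction model is refitted with that eQTL's dosage as
    a covariate and the interaction retested; the maximum conditional p across
    eQTL is stored in ``eqtl_conditional_max_p``. A collinear eQTL is skipped
    (conservative: it cannot weaken the interaction evidence). With no eQTL,
    the unconditional p stands. The survives flag is set jointly across
    records by :func:`apply_haplotype_filter` using the FDR cut.
    """
    if not eqtl_dosages:
        record.eqtl_conditional_max_p = record.interaction_p
        return record
    max_p = record.interaction_p
    for vid, dose in eqtl_dosages.items():
        try:
            p, _ = replicate_interaction(
                y, veqtl_dosage, partner_dosage, population, extra=dose
            )
        except np.linalg.LinAlgError:
            record.conditional_p[vid] = np.nan
            continue
        record.conditional_p[vid] = p
        max_p = max(max_p, p)
    record.eqtl_conditional_max_p = max_p
    return record


def apply_haplotype_filter(
    records: list[ReplicationRecord], fdr_cut: float = 0.05
) -> list[ReplicationRecord]:
    """Set the survives flag: the weakest conditional p of each record must
    itself pass the Storey q < fdr_cut rule computed over all tested records."""
    ps = np.array([r.eqtl_conditional_max_p for r in records], dtype=float)
    if len(ps) == 0:
        return records
    q, _ = storey_qvalues(ps)
    for r, qi in zip(records, q):
        r.survives_haplotype_filter = bool(qi < fdr_cut)
    return records


def storey_qvalues(
    p: np.ndarray, lambda_step: float = 0.05, min_tests: int = 20
) -> tuple[np.ndarray, Pi1Summary]:
    """Storey q-values with the lambda grid restricted to the range of the
    p-values.

    pi0 is estimated by the smoother method: pi0(lambda) = #{p > lambda} /
    (n(1-lambda)) on a grid 0.05, 0.10, ..., truncated to [min(p), max(p)] to
    prevent overly lenient correction when the p-value set is bounded away
    from 1; a cubic polynomial fit of pi0(lambda) is evaluated at the largest
    admissible lambda and clipped to (0, 1]. With fewer than ``min_tests``
    p-values (or fewer than 4 usable grid points) pi0 is fixed at 1, which
    reduces q-values to Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = len(p)
    grid_full = np.arange(lambda_step, 0.95 + 1e-9, lambda_step)
    grid = grid_full[(grid_full >= p.min()) & (grid_full <= p.max())]
    if n < min_tests or len(grid) < 4:
        if n < min_tests:
            warnings.warn(
                f"only {n} p-values: pi0 fixed at 1 (BH fallback)", stacklevel=2
            )
        pi0 = 1.0
        grid = grid if len(grid) else np.array([lambda_step])
        method = "bh-fallback"
    else:
        pi0_lambda = np.array([(p > lam).sum() / (n * (1.0 - lam)) for lam in grid])
        coeffs = np.polyfit(grid, pi0_lambda, deg=3)
        pi0 = float(np.polyval(coeffs, grid.max()))
        pi0 = float(np.clip(pi0, 1.0 / n, 1.0))
        method = "smoother"
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * n * p[order] / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, Pi1Summary(pi0_hat=pi0, lambda_grid=grid, method=method)


def concordance_summary(
    discovery_shares: np.ndarray, replication_shares: np.ndarray
) -> tuple[float, int, float]:
    """Cross-cohort effect-size agreement for signed interaction shares.

    Returns (Pearson r, number of same-sign pairs, exact two-sided binomial
    sign-test p against 0.5).
    """
    a = np.asarray(discovery_shares, dtype=float)
    b = np.asarray(replication_shares, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired vectors required")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite effect sizes")
    r = float(stats.pearsonr(a, b)[0])
    same = int((np.sign(a) == np.sign(b)).sum())
    p_sign = float(stats.binomtest(same, len(a), 0.5).pvalue)
    return r, same, p_sign
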