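"""Twin-cohort linear mixed models and the forward-stepwise epistasis scan.

The phenotype of individual i is modelled as

    y_i = mu + a*S_iv + sum_k (b_k*S_ik + c_k*S_iv*S_ik) + beta_i + gamma_i + e_i

with beta_i ~ N(0, s2_fam) shared by both members of a twin pair (MZ or DZ),
gamma_i ~ N(0, s2_mz) shared only within MZ pairs, and e_i ~ N(0, s2) iid.
The marginal covariance is block diagonal over families: every diagonal entry
is s2_fam + s2_mz + s2, the within-pair covariance is s2_fam for DZ pairs and
s2_fam + s2_mz for MZ pairs. All fits are maximum likelihood (not REML).

Fitting profiles both the fixed effects (GLS) and the residual variance out of
the likelihood, leaving a 2-dimensional optimization over the variance ratios
tau_fam = s2_fam/s2 and tau_mz = s2_mz/s2 on the log scale. Because every MZ
block shares one 2x2 covariance and every DZ block another, the weighted cross
products entering the profiled likelihood are linear combinations of a handful
of precomputed p x p matrices, so each likelihood evaluation is O(p^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .dataio import TwinCohort

__all__ = [
    "TwinStructure",
    "LmmFit",
    "EpistasisHit",
    "fit_lmm",
    "likelihood_ratio_test",
    "forward_stepwise_epistasis",
    "dominance_conditional_filter",
    "interaction_variance_share",
    "ALPHA_BONFERRONI",
]

ALPHA_BONFERRONI = 1.98e-8  # 0.05 / (number of interaction tests in a full scan)

_LOG_TAU_FLOOR = -27.6  # exp(-27.6) ~ 1e-12: effective zero for a variance ratio
_STARTS = ((0.5, 0.5), (0.05, 0.05), (2.0, 2.0))  # three fixed (tau_fam, tau_mz) starts


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class TwinStructure:
    """Index arrays locating singletons, MZ pairs and DZ pairs in a sample list."""

    singles: np.ndarray
    mz1: np.ndarray
    mz2: np.ndarray
    dz1: np.ndarray
    dz2: np.ndarray
    n: int

    @classmethod
    def from_cohort(cls, cohort: TwinCohort, samples: list[str] | None = None) -> "TwinStructure":
        if samples is None:
            samples = cohort.samples
        pos = {s: i for i, s in enumerate(samples)}
        cohort = cohort.align(list(samples))
        singles = [pos[s] for s in cohort.table.loc[
            cohort.table["zygosity"] == "singleton", "sample_id"]]
        mz = cohort.pairs("MZ")
        dz = cohort.pairs("DZ")
        return cls(
            singles=np.array(singles, dtype=int),
            mz1=np.array([pos[a] for a, _ in mz], dtype=int),
            mz2=np.array([pos[b] for _, b in mz], dtype=int),
            dz1=np.array([pos[a] for a, _ in dz], dtype=int),
            dz2=np.array([pos[b] for _, b in dz], dtype=int),
            n=len(samples),
        )

    @property
    def n_mz(self) -> int:
        return len(self.mz1)

    @property
    def n_dz(self) -> int:
        return len(self.dz1)


@dataclass
class LmmFit:
    """Maximum-likelihood fit of the twin mixed model."""

    beta: np.ndarray
    columns: list[str]
    var_fam: float
    var_mz: float
    var_res: float
    loglik: float
    converged: bool
    n_obs: int
    se: np.ndarray | None = None
    fitted_fixed: np.ndarray | None = None

    def coef(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])

    @property
    def mu(self) -> float:
        return self.coef("intercept")

    @property
    def total_variance(self) -> float:
        fv = 0.0 if self.fitted_fixed is None else float(np.var(self.fitted_fixed))
        return fv + self.var_fam + self.var_mz + self.var_res


class _ProfiledLikelihood:
    """Precomputed cross products for fast profiled loglik evaluations."""

    def __init__(self, y: np.ndarray, X: np.ndarray, ts: TwinStructure):
        self.n = len(y)
        self.p = X.shape[1]
        self.ts = ts
        s, (m1, m2), (d1, d2) = ts.singles, (ts.mz1, ts.mz2), (ts.dz1, ts.dz2)
        Z = np.column_stack([X, y])  # fold y in: cross products computed once
        Zs = Z[s]
        self.S = Zs.T @ Zs
        Z1, Z2 = Z[m1], Z[m2]
        self.A_mz = Z1.T @ Z1 + Z2.T @ Z2
        self.B_mz = Z1.T @ Z2 + Z2.T @ Z1
        Z1, Z2 = Z[d1], Z[d2]
        self.A_dz = Z1.T @ Z1 + Z2.T @ Z2
        self.B_dz = Z1.T @ Z2 + Z2.T @ Z1

    def _weighted(self, tau_fam: float, tau_mz: float) -> tuple[np.ndarray, float]:
        d = 1.0 + tau_fam + tau_mz
        o_mz = tau_fam + tau_mz
        o_dz = tau_fam
        det_mz = d * d - o_mz * o_mz
        det_dz = d * d - o_dz * o_dz
        M = (
            self.S / d
            + (d * self.A_mz - o_mz * self.B_mz) / det_mz
            + (d * self.A_dz - o_dz * self.B_dz) / det_dz
        )
        logdet = (
            len(self.ts.singles) * np.log(d)
            + self.ts.n_mz * np.log(det_mz)
            + self.ts.n_dz * np.log(det_dz)
        )
        return M, logdet

    def profile(self, tau_fam: float, tau_mz: float):
        """Return (loglik, beta, s2, XtWiX) at the profiled optimum."""
        M, logdet = self._weighted(tau_fam, tau_mz)
        p = self.p
        XtWiX = M[:p, :p]
        XtWiy = M[:p, p]
        ytWiy = M[p, p]
        try:
            beta = np.linalg.solve(XtWiX, XtWiy)
        except np.linalg.LinAlgError:
            return -np.inf, None, None, None
        rss_w = ytWiy - beta @ XtWiy
        if rss_w <= 0:
            rss_w = max(rss_w, 1e-300)
        s2 = rss_w / self.n
        ll = -0.5 * (self.n * (np.log(2 * np.pi) + 1.0 + np.log(s2)) + logdet)
        return ll, beta, s2, XtWiX

    def neg_loglik(self, log_tau: np.ndarray, active: tuple[bool, bool]) -> float:
        tf, tm = _expand_tau(log_tau, active)
        return -self.profile(tf, tm)[0]


def _expand_tau(log_tau: np.ndarray, active: tuple[bool, bool]) -> tuple[float, float]:
    vals, i = [0.0, 0.0], 0
    for j in range(2):
        if active[j]:
            vals[j] = float(np.exp(log_tau[i]))
            i += 1
    return vals[0], vals[1]


def _check_design(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal set of collinear columns for the error message
        _, R = np.linalg.qr(X)
        bad = [columns[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8 * abs(R).max()]
        raise np.linalg.LinAlgError(f"design is rank deficient; collinear columns: {bad}")


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    cohort: TwinCohort | TwinStructure,
    columns: list[str] | None = None,
    n_starts: int = 3,
) -> LmmFit:
    """Fit the twin mixed model by maximum likelihood.

    Parameters
    ----------
    y : (n,) phenotype vector.
    X : (n, p) fixed-effect design, full column rank (include the intercept).
    cohort : TwinCohort aligned with y, or a prebuilt TwinStructure.
    columns : names for the design columns (defaults x0..x{p-1}, first forced
        to "intercept" if it is constant).
    n_starts : number of fixed optimizer starting points (<= 3).

    Variance components are optimized on the log-ratio scale; components whose
    sharing structure is absent from the cohort (no pairs / no MZ pairs) are
    pinned to zero so the model stays identified.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if columns is None:
        columns = [f"x{j}" for j in range(p)]
        if np.ptp(X[:, 0]) == 0:
            columns[0] = "intercept"
    _check_design(X, columns)
    ts = cohort if isinstance(cohort, TwinStructure) else TwinStructure.from_cohort(cohort)
    if ts.n != n:
        raise ValueError("cohort does not match phenotype length")

    has_pairs = ts.n_mz + ts.n_dz > 0
    has_mz = ts.n_mz > 0
    active = (has_pairs, has_mz)
    pl = _ProfiledLikelihood(y, X, ts)

    n_active = sum(active)
    if n_active == 0:
        ll, beta, s2, XtWiX = pl.profile(0.0, 0.0)
        best_tau, best_ll, success = (0.0, 0.0), ll, True
    else:
        best_ll, best_tau, success = -np.inf, (0.0, 0.0), False
        for start in _STARTS[:max(1, n_starts)]:
            x0 = np.log([start[j] for j in range(2) if active[j]])
            res = optimize.minimize(
                pl.neg_loglik,
                x0,
                args=(active,),
                method="L-BFGS-B",
                bounds=[(_LOG_TAU_FLOOR, 15.0)] * n_active,
            )
            if np.isfinite(res.fun) and -res.fun > best_ll + 1e-12:
                best_ll, best_tau = -res.fun, _expand_tau(res.x, active)
                success = success or res.success
            elif np.isfinite(res.fun):
                success = success or res.success
        ll, beta, s2, XtWiX = pl.profile(*best_tau)

    if beta is None or not np.isfinite(ll):
        raise ConvergenceError("twin LMM failed to produce a finite likelihood")

    tf, tm = best_tau
    # snap ratios at the floor to exact zero for reporting
    if tf <= 2e-12:
        tf = 0.0
    if tm <= 2e-12:
        tm = 0.0
    se = np.sqrt(np.diag(np.linalg.inv(XtWiX)) * s2)
    return LmmFit(
        beta=np.asarray(beta),
        columns=list(columns),
        var_fam=tf * s2,
        var_mz=tm * s2,
        var_res=s2,
        loglik=float(ll),
        converged=bool(success),
        n_obs=n,
        se=se,
        fitted_fixed=X @ beta,
    )


def likelihood_ratio_test(full: LmmFit, null: LmmFit, df: int = 1) -> float:
    """Chi-square LRT p-value for nested ML fits (negative statistic clamped to 0)."""
    if not (full.converged and null.converged):
        raise ConvergenceError("refusing LRT on non-converged fits")
    if len(full.columns) - len(null.columns) != df:
        raise ValueError("designs do not differ by the stated degrees of freedom")
    if not set(null.columns) <= set(full.columns):
        raise ValueError("null design is not nested in the full design")
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    return float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# epistasis scan
# ---------------------------------------------------------------------------


@dataclass
class EpistasisHit:
    gene_id: str
    veqtl_id: str
    partner_id: str
    c_k: float
    lrt_p: float
    step: int
    signed_variance_share: float
    passed_dominance: bool | None = None
    dominance_p: float | None = None
    untestable_dominance: bool = False
    fit: LmmFit | None = field(default=None, repr=False)


def interaction_variance_share(
    fit: LmmFit, term: str, sv: np.ndarray, sk: np.ndarray
) -> float:
    """Signed share of phenotypic variance attributed to one interaction term.

    The numerator is Var_i(c_hat * (S_iv - mean)(S_ik - mean)) — the variance
    the interaction explains *beyond* what additive recoding of the two SNPs
    can absorb (the "additional variance explained" scale); the denominator is
    Var_i(fixed predictor) + s2_fam + s2_mz + s2 (marginal-R^2 construction).
    The sign is sign(c_hat) with both dosages coded as alternate-allele counts:
    positive means the joint alternate-allele effect raises expression beyond
    the additive prediction, negative that it lowers it.
    """
    total = fit.total_variance
    if total <= 0:
        raise ValueError("zero total variance")
    c = fit.coef(term)
    prod = (np.asarray(sv) - np.mean(sv)) * (np.asarray(sk) - np.mean(sk))
    share = float(np.var(c * prod)) / total
    return float(np.sign(c)) * share if c != 0 else 0.0


def _scan_design(
    sv: np.ndarray,
    partners: list[np.ndarray],
    candidate: np.ndarray | None,
    with_interaction: bool,
    dominance: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Assemble the fixed-effect design for one step of the stepwise scan.

    Model: intercept + v-eQTL main effect (additive, or het/hom probabilities
    under dominance coding) + (b_k, c_k) for previously selected partners +
    b_K for the candidate, plus c_K when with_interaction.
    """
    n = len(sv)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if dominance is None:
        cols.append(sv)
        names.append("a")
    else:
        het, hom = dominance
        cols += [het, hom]
        names += ["a_het", "a_hom"]
    for k, sk in enumerate(partners):
        cols += [sk, sv * sk]
        names += [f"b{k + 1}", f"c{k + 1}"]
    if candidate is not None:
        cols.append(candidate)
        names.append("bK")
        if with_interaction:
            cols.append(sv * candidate)
            names.append("cK")
    return np.column_stack(cols), names


def forward_stepwise_epistasis(
    y: np.ndarray,
    veqtl_dosage: np.ndarray,
    candidates: dict[str, np.ndarray],
    cohort: TwinCohort | TwinStructure,
    gene_id: str = "",
    veqtl_id: str = "",
    alpha_bonf: float = ALPHA_BONFERRONI,
    max_steps: int = 10,
    positions: dict[str, int] | None = None,
) -> list[EpistasisHit]:
    """Forward stepwise scan for cis partners in epistasis with the v-eQTL.

    At step K every remaining candidate SNP is tested by an LRT of the model
    with its interaction term c_K free against the nested model with only its
    additive term b_K, both conditioned on all previously selected pairs. The
    minimum-p candidate is added while p < alpha_bonf (ties broken by genomic
    position, then id). Collinear candidates are skipped, not fatal.
    """
    ts = cohort if isinstance(cohort, TwinStructure) else TwinStructure.from_cohort(cohort)
    sv = np.asarray(veqtl_dosage, dtype=float)
    selected: list[EpistasisHit] = []
    sel_dosages: list[np.ndarray] = []
    remaining = dict(candidates)
    for step in range(1, max_steps + 1):
        best = None  # (p, pos, vid, fit_full, fit_null)
        for vid, sk in remaining.items():
            sk = np.asarray(sk, dtype=float)
            X_full, names_full = _scan_design(sv, sel_dosages, sk, True)
            X_null, names_null = _scan_design(sv, sel_dosages, sk, False)
            try:
                fit_null = fit_lmm(y, X_null, ts, columns=names_null)
                fit_full = fit_lmm(y, X_full, ts, columns=names_full)
                p = likelihood_ratio_test(fit_full, fit_null)
            except (np.linalg.LinAlgError, ConvergenceError):
                continue  # collinear or degenerate candidate: skip
            pos = positions.get(vid, 0) if positions else 0
            key = (p, pos, vid)
            if best is None or key < best[0]:
                best = (key, vid, fit_full)
        if best is None:
            break
        (p, _, _), vid, fit_full = best
        if p >= alpha_bonf:
            break
        sk = np.asarray(remaining.pop(vid), dtype=float)
        share = interaction_variance_share(fit_full, "cK", sv, sk)
        selected.append(
            EpistasisHit(
                gene_id=gene_id,
                veqtl_id=veqtl_id,
                partner_id=vid,
                c_k=fit_full.coef("cK"),
                lrt_p=p,
                step=step,
                signed_variance_share=share,
                fit=fit_full,
            )
        )
        sel_dosages.append(sk)
    return selected


def dominance_conditional_filter(
    hits: list[EpistasisHit],
    y: np.ndarray,
    veqtl_dosage: np.ndarray,
    veqtl_gp: np.ndarray,
    candidates: dict[str, np.ndarray],
    cohort: TwinCohort | TwinStructure,
    alpha_bonf: float = ALPHA_BONFERRONI,
) -> list[EpistasisHit]:
    """Retest each hit with a free non-additive (dominance) v-eQTL effect.

    The additive term a*S_iv is replaced by a_het*P(het) + a_hom*P(alt-hom)
    (previously selected pairs keep their additive coding) and the interaction
    c_K is retested by LRT. Hits with p >= alpha_bonf are dropped: their
    apparent interaction is explainable as a non-additive effect of the v-eQTL
    tagged by a partner in LD. Degenerate genotype probabilities (no
    heterozygote information) leave the hit retained but flagged untestable.
    """
    ts = cohort if isinstance(cohort, TwinStructure) else TwinStructure.from_cohort(cohort)
    sv = np.asarray(veqtl_dosage, dtype=float)
    gp = np.asarray(veqtl_gp, dtype=float)
    het, hom = gp[:, 1], gp[:, 2]
    kept: list[EpistasisHit] = []
    prior: list[np.ndarray] = []
    for hit in sorted(hits, key=lambda h: h.step):
        sk = np.asarray(candidates[hit.partner_id], dtype=float)
        X_full, names_full = _scan_design(sv, prior, sk, True, dominance=(het, hom))
        X_null, names_null = _scan_design(sv, prior, sk, False, dominance=(het, hom))
        try:
            fit_null = fit_lmm(y, X_null, ts, columns=names_null)
            fit_full = fit_lmm(y, X_full, ts, columns=names_full)
            p = likelihood_ratio_test(fit_full, fit_null)
        except (np.linalg.LinAlgError, ConvergenceError):
            hit.untestable_dominance = True
            hit.passed_dominance = True
            kept.append(hit)
            prior.append(sk)
            continue
        hit.dominance_p = p
        hit.passed_dominance = p < alpha_bonf
        if hit.passed_dominance:
            kept.append(hit)
        prior.append(sk)
    return kept
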