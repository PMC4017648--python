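"""Cis/trans/cis-x-trans variance decomposition from twin IBD sharing.

Assuming no recombination within the cis window, DZ twins share 0, 50 or 100%
of the cis region identically by descent, which supports a linkage-style
variance-components model. The trait covariance is

    Omega = Pi_cis*s2_cis + Pi_trans*s2_trans + Pi_ct*s2_ct + I*s2_e

where Pi_cis and Pi_trans hold pairwise IBD sharing proportions (unit
diagonal; MZ entries 1) and Pi_ct is their Hadamard (elementwise) product —
the relatedness structure of a cis-x-trans epistatic component. Parameters
are estimated by maximum likelihood over nonnegative components, and the
epistatic fraction is s2_ct / (s2_cis + s2_trans + s2_ct + s2_e). The
competing explanation — a shared twin-pair environment — is assessed by
fitting Omega = Pi_cis*s2_cis + Pi_trans*s2_trans + C*s2_c + I*s2_e with C the
within-pair indicator, and comparing maximised likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .cohortsim import IbdSharing
from .dataio import TwinCohort
from .lmm import TwinStructure

__all__ = [
    "RelatednessMatrices",
    "VcFit",
    "build_relatedness",
    "fit_vc",
    "vc_loglik",
    "compare_common_environment",
]

_LOG_FLOOR = -27.6
_VC_STARTS = (
    (0.25, 0.25, 0.25, 0.25),
    (0.05, 0.05, 0.05, 0.85),
    (0.4, 0.4, 0.1, 0.1),
)


@dataclass
class RelatednessMatrices:
    """Pairwise IBD sharing with unit diagonal; pi_cistrans is the Hadamard
    product of pi_cis and pi_trans. Also carries the pair-level arrays the
    fitter uses (one entry per twin pair, aligned with the structure)."""

    pi_cis: np.ndarray
    pi_trans: np.ndarray
    pi_cistrans: np.ndarray
    structure: TwinStructure
    pair_pi_cis: np.ndarray  # per pair (MZ pairs first, then DZ)
    pair_pi_trans: np.ndarray

    @property
    def n(self) -> int:
        return self.pi_cis.shape[0]


@dataclass
class VcFit:
    var_cis: float
    var_trans: float
    var_cistrans: float
    var_env: float
    loglik: float
    converged: bool
    mu: float
    var_common: float = 0.0  # only in the common-environment alternative

    @property
    def total(self) -> float:
        return (
            self.var_cis + self.var_trans + self.var_cistrans + self.var_env
            + self.var_common
        )

    @property
    def share_cistrans(self) -> float:
        return self.var_cistrans / self.total

    @property
    def shares(self) -> dict[str, float]:
        t = self.total
        return {
            "cis": self.var_cis / t,
            "trans": self.var_trans / t,
            "cistrans": self.var_cistrans / t,
            "env": (self.var_env + self.var_common) / t,
        }


def build_relatedness(
    cohort: TwinCohort, ibd: IbdSharing, default_pi_trans: float = 0.5
) -> RelatednessMatrices:
    """Assemble the Pi matrices from the cohort and its IBD sharing table.

    MZ pair entries are 1 for all components; DZ pairs use their pi values
    (pi_trans falling back to the genome-wide expectation 0.5 when absent);
    unrelated entries are 0 and the diagonal is 1. DZ families with no IBD
    entry at all are excluded with a warning.
    """
    samples = cohort.samples
    ibd_df = ibd.table.set_index("family_id")
    keep = []
    tab = cohort.table
    for fam, grp in tab.groupby("family_id", sort=False):
        if grp["zygosity"].iloc[0] == "DZ" and fam not in ibd_df.index:
            warnings.warn(f"DZ family {fam} has no IBD entry; excluded", stacklevel=2)
            continue
        keep.extend(grp["sample_id"].tolist())
    keep = [s for s in samples if s in set(keep)]
    cohort = TwinCohort(tab[tab["sample_id"].isin(keep)].reset_index(drop=True))
    ts = TwinStructure.from_cohort(cohort, keep)

    n = len(keep)
    pi_c = np.eye(n)
    pi_t = np.eye(n)
    pair_c, pair_t = [], []
    for i1, i2 in zip(ts.mz1, ts.mz2):
        pi_c[i1, i2] = pi_c[i2, i1] = 1.0
        pi_t[i1, i2] = pi_t[i2, i1] = 1.0
        pair_c.append(1.0)
        pair_t.append(1.0)
    pos = {s: i for i, s in enumerate(keep)}
    fam_of = dict(zip(tab["sample_id"], tab["family_id"]))
    for i1, i2 in zip(ts.dz1, ts.dz2):
        fam = fam_of[keep[i1]]
        pic = float(ibd_df.loc[fam, "pi_cis"])
        pit = (
            float(ibd_df.loc[fam, "pi_trans"])
            if "pi_trans" in ibd_df.columns and not np.isnan(ibd_df.loc[fam, "pi_trans"])
            else default_pi_trans
        )
        pi_c[i1, i2] = pi_c[i2, i1] = pic
        pi_t[i1, i2] = pi_t[i2, i1] = pit
        pair_c.append(pic)
        pair_t.append(pit)
    return RelatednessMatrices(
        pi_cis=pi_c,
        pi_trans=pi_t,
        pi_cistrans=pi_c * pi_t,
        structure=ts,
        pair_pi_cis=np.array(pair_c),
        pair_pi_trans=np.array(pair_t),
    )


class _PairwiseVcLikelihood:
    """ML likelihood for block-diagonal (pair/singleton) covariance models.

    Blocks are 2x2 with diagonal d = sum of all components and off-diagonal
    o_j = sum over components of (pair coefficient * component); singletons
    contribute d alone. Vectorised over pairs.
    """

    def __init__(self, y: np.ndarray, R: RelatednessMatrices, common_env: bool):
        ts = R.structure
        self.n = len(y)
        self.y = np.asarray(y, dtype=float)
        self.common_env = common_env
        idx1 = np.concatenate([ts.mz1, ts.dz1])
        idx2 = np.concatenate([ts.mz2, ts.dz2])
        self.y1, self.y2 = self.y[idx1], self.y[idx2]
        self.ys = self.y[ts.singles]
        # per-pair coefficients of each variance component in the off-diagonal
        if common_env:
            self.coefs = np.stack(
                [R.pair_pi_cis, R.pair_pi_trans, np.ones(len(idx1))]
            )  # cis, trans, common-env
        else:
            self.coefs = np.stack(
                [R.pair_pi_cis, R.pair_pi_trans, R.pair_pi_cis * R.pair_pi_trans]
            )  # cis, trans, cis-x-trans

    def loglik(self, comps: np.ndarray) -> tuple[float, float]:
        """Profiled over the intercept; comps = (c1, c2, c3, env)."""
        c123, env = comps[:3], comps[3]
        d = float(c123.sum() + env)
        o = c123 @ self.coefs  # per-pair off-diagonal
        det = d * d - o * o
        if d <= 0 or (det <= 0).any():
            return -np.inf, 0.0
        # GLS intercept: for a 2x2 block, 1'Vb^{-1}1 = 2(d-o)/det and
        # 1'Vb^{-1}y = (d-o)(y1+y2)/det
        a = (d - o) / det
        denom = (2.0 * a).sum() + len(self.ys) / d
        num = (a * (self.y1 + self.y2)).sum() + self.ys.sum() / d
        mu = num / denom
        r1, r2, rs = self.y1 - mu, self.y2 - mu, self.ys - mu
        quad = ((d * (r1 * r1 + r2 * r2) - 2.0 * o * r1 * r2) / det).sum()
        quad += (rs * rs).sum() / d
        logdet = np.log(det).sum() + len(self.ys) * np.log(d)
        ll = -0.5 * (self.n * np.log(2.0 * np.pi) + logdet + quad)
        return float(ll), float(mu)

    def neg_loglik_log(self, log_comps: np.ndarray) -> float:
        return -self.loglik(np.exp(log_comps))[0]


def _fit_components(y: np.ndarray, R: RelatednessMatrices, common_env: bool) -> VcFit:
    if R.structure.n_mz + R.structure.n_dz < 100:
        warnings.warn(
            "fewer than 100 twin pairs: variance-component estimates will be "
            "unstable",
            stacklevel=3,
        )
    pl = _PairwiseVcLikelihood(y, R, common_env)
    vy = float(np.var(y))
    best_ll, best_x, success = -np.inf, None, False
    for start in _VC_STARTS:
        x0 = np.log(np.maximum(np.array(start) * vy, 1e-10))
        res = optimize.minimize(
            pl.neg_loglik_log,
            x0,
            method="L-BFGS-B",
            bounds=[(np.log(vy) + _LOG_FLOOR, np.log(vy) + 5.0)] * 4,
        )
        if np.isfinite(res.fun) and -res.fun > best_ll + 1e-12:
            best_ll, best_x = -res.fun, res.x
        if np.isfinite(res.fun):
            success = success or res.success
    if best_x is None:
        raise RuntimeError("variance-component optimisation failed from all starts")
    comps = np.exp(best_x)
    comps[comps < vy * 2e-12] = 0.0
    ll, mu = pl.loglik(np.maximum(comps, 1e-300))
    if comps[3] == 0.0:  # keep env strictly positive for reporting
        comps[3] = max(comps[3], vy * 1e-12)
    c1, c2, c3, env = comps
    if common_env:
        return VcFit(
            var_cis=c1, var_trans=c2, var_cistrans=0.0, var_env=env,
            loglik=float(ll), converged=success, mu=mu, var_common=c3,
        )
    return VcFit(
        var_cis=c1, var_trans=c2, var_cistrans=c3, var_env=env,
        loglik=float(ll), converged=success, mu=mu,
    )


def vc_loglik(
    y: np.ndarray, R: RelatednessMatrices, comps: np.ndarray, common_env: bool = False
) -> float:
    """Profiled (over the intercept) log-likelihood at fixed components
    (c_cis, c_trans, c_ct_or_common, c_env)."""
    pl = _PairwiseVcLikelihood(y, R, common_env)
    return pl.loglik(np.asarray(comps, dtype=float))[0]


def fit_vc(y: np.ndarray, R: RelatednessMatrices) -> VcFit:
    """Maximum-likelihood fit of the cis/trans/cis-x-trans model.

    Components are optimised on the log scale (effective zero at 1e-12 of the
    phenotypic variance) from three fixed starting points. The epistatic
    share is s2_ct over the sum of all four components.
    """
    return _fit_components(y, R, common_env=False)


def compare_common_environment(
    y: np.ndarray, R: RelatednessMatrices
) -> tuple[VcFit, VcFit, float]:
    """Fit the cis-x-trans model and the common-environment alternative.

    Returns (cistrans fit, common-environment fit, delta loglik); a positive
    delta favours the epistatic model. The models are non-nested (both have
    four components) so only the likelihood difference is reported, no
    p-value.
    """
    fit_ct = _fit_components(y, R, common_env=False)
    fit_ce = _fit_components(y, R, common_env=True)
    return fit_ct, fit_ce, fit_ct.loglik - fit_ce.loglik
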