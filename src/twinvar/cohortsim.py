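"""Synthetic twin cohorts with known ground truth.

The generator emulates the statistical structure that the downstream analyses
assume: MZ/DZ twin pairs plus singletons; cis variants in LD with optional
dosage uncertainty; expression built from additive eQTL, pairwise epistasis,
genotype-dependent environmental variance (GxE), family and MZ-pair variance
components; and rare-eQTL haplotype confounders (high D', low R^2 with a pair
of common tag SNPs).

Simulation is haplotype-level: every genome carries two 0/1 haplotypes over
the region, so identity-by-descent sharing, D' and R^2 are exact constructs
and genotype = haplotype sum. DZ pairs share 0, 1 or 2 whole-region haplotypes
according to their cis IBD state (no recombination within the window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataio import ExpressionTable, GenotypeTable, TwinCohort

__all__ = [
    "IbdSharing",
    "SimTruth",
    "GeneSpec",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_haplotype_confounder",
    "simulate_expression",
    "simulate_vc_phenotype",
    "simulate_unrelated_cohort",
    "ld_stats",
    "DEFAULT_N_MZ",
    "DEFAULT_N_DZ",
    "DEFAULT_N_SINGLE",
]

# Cohort composition mirrors the discovery study: 134 MZ pairs, 192 DZ pairs,
# 113 singletons -> 765 samples.
DEFAULT_N_MZ = 134
DEFAULT_N_DZ = 192
DEFAULT_N_SINGLE = 113

_IBD_STATES = np.array([0.0, 0.5, 1.0])
_IBD_PROBS = np.array([0.25, 0.5, 0.25])  # autosomal expectation for DZ pairs


@dataclass
class IbdSharing:
    """Per-family IBD sharing proportions for the cis and trans regions.

    MZ families are 1/1 by construction; DZ families take values in
    {0, 0.5, 1}; singletons have no entry.
    """

    table: pd.DataFrame  # family_id, pi_cis, pi_trans

    def of(self, family_id: str) -> tuple[float, float]:
        row = self.table.set_index("family_id").loc[family_id]
        return float(row["pi_cis"]), float(row["pi_trans"])


@dataclass
class GeneSpec:
    """Planted effects for one simulated gene. Shares are fractions of the
    total phenotypic variance (target 1.0); the interaction share is signed."""

    gene_id: str
    additive: list[tuple[str, float]] = field(default_factory=list)  # (variant, share)
    epistasis: list[tuple[str, str, float]] = field(default_factory=list)  # (v, k, signed share)
    gxe: tuple[str, float] | None = None  # (variant, share of variance from GxE)
    var_fam: float = 0.0
    var_mz: float = 0.0
    mu: float = 0.0
    chrom: str = "1"
    tss: int = 1_000_000


@dataclass
class SimTruth:
    """Realized ground truth of a simulated cohort."""

    seed: int
    genes: dict[str, dict] = field(default_factory=dict)
    confounders: list[dict] = field(default_factory=list)


def simulate_cohort(
    n_mz: int, n_dz: int, n_single: int, seed: int
) -> tuple[TwinCohort, IbdSharing]:
    """Generate a twin cohort and its IBD sharing.

    DZ cis and trans IBD are drawn independently from {0, 0.5, 1} with
    probabilities (0.25, 0.5, 0.25); MZ sharing is 1 for both regions.
    """
    if n_mz < 0 or n_dz < 0 or n_single < 0:
        raise ValueError("counts must be nonnegative")
    if n_mz + n_dz + n_single == 0:
        raise ValueError("empty cohort requested")
    rng = np.random.default_rng(seed)
    rows, ibd_rows = [], []
    for i in range(n_mz):
        fam = f"FMZ{i + 1:04d}"
        rows += [(f"MZ{i + 1:04d}a", fam, "MZ"), (f"MZ{i + 1:04d}b", fam, "MZ")]
        ibd_rows.append((fam, 1.0, 1.0))
    for i in range(n_dz):
        fam = f"FDZ{i + 1:04d}"
        rows += [(f"DZ{i + 1:04d}a", fam, "DZ"), (f"DZ{i + 1:04d}b", fam, "DZ")]
        pic = float(rng.choice(_IBD_STATES, p=_IBD_PROBS))
        pit = float(rng.choice(_IBD_STATES, p=_IBD_PROBS))
        ibd_rows.append((fam, pic, pit))
    for i in range(n_single):
        rows.append((f"S{i + 1:04d}", f"FS{i + 1:04d}", "singleton"))
    cohort = TwinCohort(pd.DataFrame(rows, columns=["sample_id", "family_id", "zygosity"]))
    ibd = IbdSharing(pd.DataFrame(ibd_rows, columns=["family_id", "pi_cis", "pi_trans"]))
    return cohort, ibd


def _family_haplotype_plan(
    cohort: TwinCohort, ibd: IbdSharing, region: str, rng: np.random.Generator
) -> tuple[int, np.ndarray]:
    """Assign founder haplotype indices to each sample's two haplotype slots.

    Returns (n_founder_haplotypes, assignment) where assignment has shape
    (n_samples, 2). MZ twins reuse both haplotypes; DZ twins share 2/1/0
    haplotypes for pi = 1/0.5/0.
    """
    ibd_col = "pi_cis" if region == "cis" else "pi_trans"
    ibd_map = ibd.table.set_index("family_id")[ibd_col].to_dict()
    assign = np.empty((len(cohort.samples), 2), dtype=int)
    pos = {s: i for i, s in enumerate(cohort.samples)}
    counter = 0

    def fresh() -> int:
        nonlocal counter
        counter += 1
        return counter - 1

    for fam, grp in cohort.table.groupby("family_id", sort=True):
        members = grp["sample_id"].tolist()
        z = grp["zygosity"].iloc[0]
        if z == "singleton":
            assign[pos[members[0]]] = [fresh(), fresh()]
            continue
        a, b = members
        if z == "MZ":
            h = [fresh(), fresh()]
            assign[pos[a]] = h
            assign[pos[b]] = h
            continue
        pi = ibd_map.get(fam)
        if pi is None:
            raise ValueError(f"missing IBD entry for DZ family {fam}")
        if pi == 1.0:
            h = [fresh(), fresh()]
            assign[pos[a]] = h
            assign[pos[b]] = h
        elif pi == 0.5:
            shared = fresh()
            assign[pos[a]] = [shared, fresh()]
            assign[pos[b]] = [shared, fresh()]
        else:
            assign[pos[a]] = [fresh(), fresh()]
            assign[pos[b]] = [fresh(), fresh()]
    return counter, assign


def simulate_genotypes(
    cohort: TwinCohort,
    ibd: IbdSharing,
    n_variants: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.8,
    region: tuple[str, int] = ("1", 500_000),
    spacing: int = 5_000,
    gp_noise: float = 0.0,
    which: str = "cis",
    id_prefix: str = "rsS",
) -> GenotypeTable:
    """Simulate a genotype panel over one region of a twin cohort.

    Haplotypes follow a first-order allele-copy process: the allele at variant
    j copies variant j-1's allele with probability ld_rho and is otherwise a
    fresh Bernoulli draw at that variant's frequency, so adjacent-variant
    genotype correlation is approximately ld_rho (exact when neighbouring
    frequencies match) and correlation decays geometrically with distance.
    IBD sharing is applied at the whole-region level (no recombination within
    the window).
    gp_noise in [0, 1) mixes the exact genotype-probability triplet with a
    symmetric Dirichlet draw to emulate imputation uncertainty; dosage is
    recomputed from the blurred triplet.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_hap, assign = _family_haplotype_plan(cohort, ibd, which, rng)

    freqs = rng.uniform(lo, hi, size=n_variants)
    founder = np.empty((n_variants, n_hap), dtype=np.int8)
    founder[0] = rng.random(n_hap) < freqs[0]
    for j in range(1, n_variants):
        copy = rng.random(n_hap) < ld_rho
        fresh = (rng.random(n_hap) < freqs[j]).astype(np.int8)
        founder[j] = np.where(copy, founder[j - 1], fresh)

    n_samples = len(cohort.samples)
    hap = np.empty((n_variants, 2 * n_samples), dtype=np.int8)
    hap[:, 0::2] = founder[:, assign[:, 0]]
    hap[:, 1::2] = founder[:, assign[:, 1]]
    geno = hap[:, 0::2] + hap[:, 1::2]

    gp = np.zeros((n_variants, n_samples, 3))
    np.put_along_axis(gp, geno[..., None].astype(int), 1.0, axis=2)
    if gp_noise > 0.0:
        blur = rng.dirichlet(np.ones(3), size=(n_variants, n_samples))
        gp = (1.0 - gp_noise) * gp + gp_noise * blur
    dosage = gp[..., 1] + 2.0 * gp[..., 2]

    chrom, start = region
    positions = start + spacing * np.arange(n_variants)
    variants = pd.DataFrame(
        {
            "variant_id": [f"{id_prefix}{j + 1:05d}" for j in range(n_variants)],
            "chrom": str(chrom),
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(dosage.mean(axis=1) / 2, 1 - dosage.mean(axis=1) / 2),
            "info": 1.0,
        }
    )
    return GenotypeTable(
        variants=variants,
        dosage=dosage,
        gp=gp,
        samples=cohort.samples,
        haplotypes=hap,
    )


def ld_stats(hap_a: np.ndarray, hap_b: np.ndarray) -> tuple[float, float]:
    """(D', R^2) between two variants from phased 0/1 haplotype vectors."""
    pa, pb = hap_a.mean(), hap_b.mean()
    pab = (hap_a * hap_b).mean()
    D = pab - pa * pb
    if D >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = 0.0 if dmax == 0 else abs(D) / dmax
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = 0.0 if denom == 0 else D * D / denom
    return float(dprime), float(r2)


def simulate_haplotype_confounder(
    g: GenotypeTable,
    tag1_id: str,
    tag2_id: str,
    rare_maf: float,
    seed: int,
    variant_id: str = "rsRARE",
    pos: int | None = None,
) -> tuple[GenotypeTable, dict]:
    """Plant a rare variant nested on a specific two-SNP haplotype background.

    The rare minor allele is placed only on haplotypes carrying the alternate
    allele of *both* tag variants, so realized D' with each tag is 1 while R^2
    stays low when rare_maf << tag MAF. Only the rare variant should receive an
    expression effect downstream; an apparent interaction between the tags is
    then a pure haplotype artifact.
    """
    if g.haplotypes is None:
        raise ValueError("haplotype-level genotypes required")
    i1, i2 = g.index_of(tag1_id), g.index_of(tag2_id)
    for i in (i1, i2):
        if rare_maf >= g.variants["maf"].iloc[i]:
            raise ValueError("rare_maf must be below the tag MAFs")
    rng = np.random.default_rng(seed)
    background = np.flatnonzero((g.haplotypes[i1] == 1) & (g.haplotypes[i2] == 1))
    n_hap = g.haplotypes.shape[1]
    n_rare = int(round(rare_maf * n_hap))
    if n_rare == 0 or len(background) < n_rare:
        raise ValueError(
            f"insufficient target haplotype background ({len(background)} haplotypes "
            f"for {n_rare} rare alleles)"
        )
    carriers = rng.choice(background, size=n_rare, replace=False)
    rare_hap = np.zeros(n_hap, dtype=np.int8)
    rare_hap[carriers] = 1
    rare_geno = (rare_hap[0::2] + rare_hap[1::2]).astype(float)
    gp = np.zeros((1, g.n_samples, 3))
    np.put_along_axis(gp, rare_geno[None, :, None].astype(int), 1.0, axis=2)

    d1, r1 = ld_stats(rare_hap, g.haplotypes[i1])
    d2, r2 = ld_stats(rare_hap, g.haplotypes[i2])
    if pos is None:
        pos = int(g.variants["pos"].iloc[[i1, i2]].mean())
    row = pd.DataFrame(
        {
            "variant_id": [variant_id],
            "chrom": [g.variants["chrom"].iloc[i1]],
            "pos": [pos],
            "ref": ["A"],
            "alt": ["G"],
            "maf": [rare_geno.mean() / 2],
            "info": [1.0],
        }
    )
    out = GenotypeTable(
        variants=pd.concat([g.variants, row], ignore_index=True),
        dosage=np.vstack([g.dosage, rare_geno[None, :]]),
        gp=np.concatenate([g.gp, gp], axis=0),
        samples=list(g.samples),
        gp_degenerate=g.gp_degenerate,
        haplotypes=np.vstack([g.haplotypes, rare_hap[None, :]]),
    )
    truth = {
        "variant_id": variant_id,
        "tags": [tag1_id, tag2_id],
        "dprime": [d1, d2],
        "r2": [r1, r2],
        "rare_maf_realized": float(rare_geno.mean() / 2),
    }
    return out, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _solve_interaction_coef(
    rest: np.ndarray, product: np.ndarray, noise_var: float, share: float
) -> float:
    """Coefficient c with Var(c*product) / [Var(rest + c*product) + noise_var]
    = |share| and sign(c) = sign(share).

    `rest` is the deterministic part of the phenotype built so far (additive
    terms); `noise_var` is the variance of the independent terms still to be
    added (family + MZ + residual), deterministic in expectation.
    """
    if share == 0.0:
        return 0.0
    if abs(share) > 0.5:
        raise ValueError("requested interaction variance fraction above 0.5 is unrealistic")
    vp = np.var(product)
    if vp <= 0:
        raise ValueError("interaction product has zero variance")
    target = abs(share)
    sign = np.sign(share)

    def f(c: float) -> float:
        cs = sign * c
        return cs * cs * vp / (np.var(rest + cs * product) + noise_var) - target

    hi = np.sqrt((np.var(rest) + noise_var) / vp * target / (1.0 - target)) * 10.0 + 1.0
    return float(sign * optimize.brentq(f, 0.0, hi, xtol=1e-14))


def _solve_gxe_eta(g_dose: np.ndarray, share: float) -> float:
    """eta with Var(eta * g * E) = eta^2 * mean(g^2) = share (E ~ N(0,1))."""
    if share <= 0:
        return 0.0
    m2 = float(np.mean(g_dose**2))
    if m2 <= 0:
        raise ValueError("GxE variant has no alternate alleles")
    return float(np.sqrt(share / m2))


def simulate_expression(
    g: GenotypeTable,
    cohort: TwinCohort,
    specs: list[GeneSpec],
    seed: int,
    truth: SimTruth | None = None,
) -> tuple[ExpressionTable, SimTruth]:
    """Simulate expression for a list of gene specifications.

    y_i = mu + sum_j a_j*S_ij + sum (c*S_iv*S_ik) [+ eta*g_i*E_i]
          + beta_i + gamma_i + eps_i,

    with beta shared within twin pairs, gamma within MZ pairs, and for GxE
    genes an unobserved exposure E_i ~ N(0,1) drawn independently per
    individual (so also within MZ pairs) interacting with the genotype g_i:
    conditional on genotype the phenotype variance is sigma^2 + eta^2*g_i^2,
    and within-MZ-pair discordance grows with genotype while purely genetic
    terms cancel in the pair difference.

    Effect sizes are calibrated on the realized genotype matrix so each
    planted term's variance fraction matches its target share; realized
    fractions (marginal and incremental) are recorded in the returned truth.
    """
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = SimTruth(seed=seed)
    n = g.n_samples
    tab = cohort.table.set_index("sample_id").loc[g.samples]
    fam_codes, fam_idx = np.unique(tab["family_id"].to_numpy(), return_inverse=True)
    is_mz = tab["zygosity"].to_numpy() == "MZ"

    rows, gene_meta = [], []
    for spec in specs:
        planted_share = (
            sum(s for _, s in spec.additive)
            + sum(abs(s) for *_, s in spec.epistasis)
            + (spec.gxe[1] if spec.gxe else 0.0)
            + spec.var_fam
            + spec.var_mz
        )
        sigma2 = 1.0 - planted_share
        if sigma2 <= 0.05:
            raise ValueError(f"{spec.gene_id}: planted shares leave no residual variance")

        terms: list[tuple[str, np.ndarray]] = []
        y = np.full(n, spec.mu)
        record: dict = {"mu": spec.mu, "additive": [], "epistasis": [], "gxe": None}
        noise_var = sigma2 + spec.var_fam + spec.var_mz
        if spec.gxe is not None:
            noise_var += spec.gxe[1]

        for vid, share in spec.additive:
            dose = g.dosage_of(vid)
            a = np.sqrt(share / np.var(dose)) if share > 0 else 0.0
            term = a * dose
            y = y + term
            terms.append((f"additive:{vid}", term))
            record["additive"].append({"variant": vid, "beta": float(a), "share_target": share})

        for vid, kid, share in spec.epistasis:
            sv, sk = g.dosage_of(vid), g.dosage_of(kid)
            # the interaction enters on mean-centred dosages so its planted
            # variance is the share *beyond* what additive recoding absorbs
            prod = (sv - sv.mean()) * (sk - sk.mean())
            c = _solve_interaction_coef(y - y.mean(), prod, noise_var, share)
            term = c * prod
            y = y + term
            terms.append((f"epistasis:{vid}x{kid}", term))
            record["epistasis"].append(
                {"veqtl": vid, "partner": kid, "c": float(c), "share_target": share}
            )

        beta_fam = np.sqrt(spec.var_fam) * rng.standard_normal(len(fam_codes))[fam_idx]
        gamma_raw = rng.standard_normal(len(fam_codes))[fam_idx]
        gamma_mz = np.sqrt(spec.var_mz) * np.where(is_mz, gamma_raw, rng.standard_normal(n))
        y = y + beta_fam + gamma_mz
        terms.append(("fam", beta_fam))
        terms.append(("mz", gamma_mz))

        if spec.gxe is not None:
            vid, gshare = spec.gxe
            dose = g.dosage_of(vid)
            eta = _solve_gxe_eta(dose, gshare)
            exposure = rng.standard_normal(n)  # independent within MZ pairs
            gxe_term = eta * dose * exposure
            y = y + gxe_term
            terms.append(("gxe", gxe_term))
            record["gxe"] = {"variant": vid, "eta": float(eta), "share_target": gshare}
        eps = np.sqrt(sigma2) * rng.standard_normal(n)
        y = y + eps
        terms.append(("residual", eps))

        vy = np.var(y)
        marginal = {name: float(np.var(t) / vy) for name, t in terms}
        running, incremental, acc = np.full(n, spec.mu), {}, 0.0
        for name, t in terms:
            running = running + t
            v_new = np.var(running) / vy
            incremental[name] = float(v_new - acc)
            acc = v_new
        record["share_marginal"] = marginal
        record["share_incremental"] = incremental
        record["var_fam"], record["var_mz"], record["sigma2"] = (
            spec.var_fam,
            spec.var_mz,
            sigma2,
        )
        truth.genes[spec.gene_id] = record
        rows.append(y)
        gene_meta.append((spec.gene_id, spec.chrom, spec.tss, "+"))

    genes = pd.DataFrame(gene_meta, columns=["gene_id", "chrom", "tss", "strand"])
    expr = ExpressionTable(genes, np.asarray(rows), list(g.samples), stage="raw")
    return expr, truth


def simulate_vc_phenotype(
    cohort: TwinCohort,
    ibd: IbdSharing,
    var_cis: float,
    var_trans: float,
    var_cistrans: float,
    var_env: float,
    seed: int,
    common_env: float = 0.0,
) -> np.ndarray:
    """Draw a phenotype with IBD-structured cis/trans/cis-x-trans variance
    components (plus an optional shared-pair environment term).

    Within a twin pair each genetic component is bivariate normal with
    correlation equal to the pair's IBD sharing (pi_cis, pi_trans, or their
    product for the interaction component); MZ pairs have correlation 1.
    """
    rng = np.random.default_rng(seed)
    samples = cohort.samples
    n = len(samples)
    y = np.zeros(n)
    pos = {s: i for i, s in enumerate(samples)}
    ibd_map = ibd.table.set_index("family_id")[["pi_cis", "pi_trans"]]

    def pair_draw(var: float, corr: float) -> np.ndarray:
        a = rng.standard_normal()
        b = corr * a + np.sqrt(max(0.0, 1.0 - corr * corr)) * rng.standard_normal()
        return np.sqrt(var) * np.array([a, b])

    for fam, grp in cohort.table.groupby("family_id", sort=True):
        members = grp["sample_id"].tolist()
        z = grp["zygosity"].iloc[0]
        if z == "singleton":
            i = pos[members[0]]
            y[i] += np.sqrt(var_cis + var_trans + var_cistrans) * rng.standard_normal()
            continue
        if z == "MZ":
            pic = pit = 1.0
        else:
            pic, pit = float(ibd_map.loc[fam, "pi_cis"]), float(ibd_map.loc[fam, "pi_trans"])
        idx = [pos[m] for m in members]
        y[idx] += pair_draw(var_cis, pic)
        y[idx] += pair_draw(var_trans, pit)
        y[idx] += pair_draw(var_cistrans, pic * pit)
        if common_env > 0:
            y[idx] += np.sqrt(common_env) * rng.standard_normal()
    y += np.sqrt(var_env) * rng.standard_normal(n)
    return y


def simulate_unrelated_cohort(
    n: int,
    seed: int,
    populations: tuple[str, ...] = ("CEU", "YRI", "TSI", "GBR", "FIN"),
) -> tuple[TwinCohort, IbdSharing, pd.Series]:
    """An all-singleton cohort with categorical population labels (for the
    replication analyses; labels shift expression means only)."""
    cohort, ibd = simulate_cohort(0, 0, n, seed)
    rng = np.random.default_rng(seed + 1)
    labels = pd.Series(
        rng.choice(populations, size=n), index=cohort.samples, name="population"
    )
    return cohort, ibd, labels
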