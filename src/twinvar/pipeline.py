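"""End-to-end orchestration: preprocess -> v-eQTL scan -> epistasis scan ->
GxE (d-eQTL) -> cis/trans variance components, with reproducible seeds and a
self-describing run directory.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cohortsim import IbdSharing
from .dataio import (
    ExpressionTable,
    GenotypeTable,
    TwinCohort,
    apply_qc_filters,
    cis_window_variants,
)
from .gxe import deqtl_test, gxe_fraction
from .lmm import (
    ALPHA_BONFERRONI,
    TwinStructure,
    dominance_conditional_filter,
    forward_stepwise_epistasis,
)
from .preprocess import (
    grammar_residuals,
    quantile_normalize,
    remove_latent_factors,
    transform_expression,
)
from .veqtl import N_PERMUTATIONS, scan_cohort
from .cistrans import build_relatedness, compare_common_environment

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Thresholds and toggles for a full analysis run (defaults mirror the
    discovery analysis: sqrt transform, 50 latent factors, MAF>=0.01,
    info>=0.8, +/-1 Mbp cis window, 5 permutations, Bonferroni 1.98e-8)."""

    seed: int = 0
    transform: str = "sqrt"
    n_factors: int = 50
    maf_min: float = 0.01
    info_min: float = 0.8
    zero_frac_max: float = 0.10
    cis_half_width: int = 1_000_000
    trans_min_distance: int = 5_000_000
    n_permutations: int = N_PERMUTATIONS
    alpha_bonf: float = ALPHA_BONFERRONI
    fdr_level: float = 0.05
    p_enter: float = 1e-5
    run_veqtl: bool = True
    run_epistasis: bool = True
    run_gxe: bool = True
    run_vc: bool = False


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: RunConfig,
    geno: GenotypeTable,
    expr: ExpressionTable,
    cohort: TwinCohort,
    out_dir: str | Path,
    ibd: IbdSharing | None = None,
) -> dict:
    """Run the enabled stages and write stage outputs plus a summary JSON.

    Returns the summary dict. Stage outputs: qc_report.tsv, veqtl_peaks.tsv,
    epistasis_hits.tsv, deqtl.tsv, vc.tsv, manifest.json, summary.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config), "version": __version__}
    manifest = {"version": __version__, "seed": config.seed, "config": asdict(config)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    stage = "qc"
    try:
        geno_q, expr_q, report = apply_qc_filters(
            geno, expr, config.maf_min, config.info_min, config.zero_frac_max
        )
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        summary["qc"] = {
            "variants_kept": geno_q.n_variants,
            "genes_kept": expr_q.n_genes,
            "removed": len(report),
        }

        stage = "preprocess"
        e = transform_expression(expr_q, config.transform)
        n_factors = min(config.n_factors, min(e.n_genes, len(e.samples)) - 1)
        e = remove_latent_factors(e, max(0, n_factors))
        e = quantile_normalize(e)
        e_norm = e
        e_resid = grammar_residuals(e, cohort)
        summary["preprocess"] = {"stage": e_resid.stage, "n_factors": n_factors}

        peaks = None
        if config.run_veqtl:
            stage = "veqtl"
            peaks = scan_cohort(
                e_resid, geno_q, seed=config.seed,
                half_width=config.cis_half_width, n_perm=config.n_permutations,
            )
            peaks.to_csv(out / "veqtl_peaks.tsv", sep="\t", index=False)
            all_res = peaks.attrs.get("all_results")
            if all_res is not None:
                all_res.to_csv(out / "veqtl_all.tsv", sep="\t", index=False)
            sig = peaks[peaks["fdr"] < config.fdr_level]
            summary["veqtl"] = {
                "genes_tested": len(peaks),
                "significant": int(len(sig)),
            }

        if config.run_epistasis and peaks is not None:
            stage = "epistasis"
            ts = TwinStructure.from_cohort(cohort, e_norm.samples)
            hit_rows = []
            sig = peaks[peaks["fdr"] < config.fdr_level]
            for _, row in sig.iterrows():
                gene = e_norm.genes[e_norm.genes["gene_id"] == row["gene_id"]].iloc[0]
                y = e_norm.row(row["gene_id"])
                window = cis_window_variants(geno_q, gene, config.cis_half_width)
                vi = geno_q.index_of(row["variant_id"])
                sv = geno_q.dosage[vi]
                cands = {
                    v: geno_q.dosage_of(v) for v in window if v != row["variant_id"]
                }
                positions = dict(
                    zip(geno_q.variants["variant_id"], geno_q.variants["pos"])
                )
                hits = forward_stepwise_epistasis(
                    y, sv, cands, ts,
                    gene_id=row["gene_id"], veqtl_id=row["variant_id"],
                    alpha_bonf=config.alpha_bonf, positions=positions,
                )
                hits = dominance_conditional_filter(
                    hits, y, sv, geno_q.gp[vi], cands, ts,
                    alpha_bonf=config.alpha_bonf,
                )
                for h in hits:
                    hit_rows.append(
                        (h.gene_id, h.veqtl_id, h.partner_id, h.c_k, h.lrt_p,
                         h.step, h.signed_variance_share, h.passed_dominance)
                    )
            hits_df = pd.DataFrame(
                hit_rows,
                columns=["gene_id", "veqtl_id", "partner_id", "c_k", "lrt_p",
                         "step", "signed_variance_share", "passed_dominance"],
            )
            hits_df.to_csv(out / "epistasis_hits.tsv", sep="\t", index=False)
            summary["epistasis"] = {
                "hits": int(len(hits_df)),
                "genes": int(hits_df["gene_id"].nunique()) if len(hits_df) else 0,
            }

        if config.run_gxe and peaks is not None and len(peaks):
            stage = "gxe"
            rows = []
            # only the discovered v-eQTL are candidates for the GxE reading;
            # testing every in-sample peak would inherit selection bias
            gxe_set = peaks[peaks["fdr"] < config.fdr_level]
            for _, row in gxe_set.iterrows():
                try:
                    r = deqtl_test(
                        e_norm.row(row["gene_id"]), e_norm.samples, cohort,
                        geno_q.dosage_of(row["variant_id"]),
                        gene_id=row["gene_id"], variant_id=row["variant_id"],
                    )
                except ValueError:
                    continue
                rows.append((r.gene_id, r.variant_id, r.p_discordance))
            deqtl_df = pd.DataFrame(
                rows, columns=["gene_id", "variant_id", "p_discordance"]
            )
            deqtl_df.to_csv(out / "deqtl.tsv", sep="\t", index=False)
            if len(deqtl_df) >= 1:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pi1, n_sig = gxe_fraction(
                        deqtl_df["p_discordance"].to_numpy(), config.fdr_level
                    )
                summary["gxe"] = {
                    "tested": int(len(deqtl_df)),
                    "pi1": float(pi1.pi1),
                    "significant": n_sig,
                }

        if config.run_vc and ibd is not None:
            stage = "vc"
            R = build_relatedness(cohort, ibd)
            keep = [s for s in e_norm.samples]
            rows = []
            for i in range(e_norm.n_genes):
                y = e_norm.values[i][[e_norm.samples.index(s) for s in keep]]
                fit_ct, fit_ce, dll = compare_common_environment(y, R)
                rows.append(
                    (e_norm.genes["gene_id"].iloc[i], fit_ct.var_cis,
                     fit_ct.var_trans, fit_ct.var_cistrans, fit_ct.var_env,
                     fit_ct.share_cistrans, dll)
                )
            vc_df = pd.DataFrame(
                rows, columns=["gene_id", "var_cis", "var_trans", "var_cistrans",
                               "var_env", "share_cistrans", "delta_loglik"],
            )
            vc_df.to_csv(out / "vc.tsv", sep="\t", index=False)
            summary["vc"] = {
                "genes": int(len(vc_df)),
                "mean_share_cistrans": float(vc_df["share_cistrans"].mean()),
            }
    except Exception as exc:  # halt with a stage-named error, keep partials
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str)
        )
        raise StageError(stage, exc) from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str)
    )
    return summary
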