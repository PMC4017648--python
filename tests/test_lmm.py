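import numpy as np
import pytest
from scipy import stats

from twinvar import cohortsim as cs
from twinvar.lmm import (
    ConvergenceError,
    TwinStructure,
    dominance_conditional_filter,
    fit_lmm,
    forward_stepwise_epistasis,
    interaction_variance_share,
    likelihood_ratio_test,
    _scan_design,
)

from _oracles import dense_twin_loglik


def _sim_gene(seed, n_mz=134, n_dz=199, n_single=134, n_variants=40, **spec_kwargs):
    cohort, ibd = cs.simulate_cohort(n_mz, n_dz, n_single, seed)
    g = cs.simulate_genotypes(
        cohort, ibd, n_variants, seed=seed + 1, maf_range=(0.2, 0.5), ld_rho=0.8
    )
    spec = cs.GeneSpec("g0", **spec_kwargs)
    expr, truth = cs.simulate_expression(g, cohort, [spec], seed=seed + 2)
    return cohort, g, expr.values[0], truth


class TestFitLmm:
    def test_matches_dense_oracle_on_random_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(12):
            cohort, ibd = cs.simulate_cohort(
                int(rng.integers(2, 6)), int(rng.integers(2, 6)),
                int(rng.integers(1, 8)), int(rng.integers(1e6)),
            )
            n = len(cohort.samples)
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            tab = cohort.table.set_index("sample_id").loc[cohort.samples]
            _, fi = np.unique(tab["family_id"], return_inverse=True)
            y = (
                0.5 * X[:, 1]
                + 0.8 * rng.standard_normal(fi.max() + 1)[fi]
                + 0.6 * rng.standard_normal(n)
            )
            fit = fit_lmm(y, X, cohort)
            oll, obeta = dense_twin_loglik(y, X, cohort)
            assert fit.loglik == pytest.approx(oll, abs=1e-4)
            np.testing.assert_allclose(fit.beta, obeta, atol=1e-3)

    def test_collapses_to_ols_without_variance_components(self):
        cohort, g, y, _ = _sim_gene(100, var_fam=0.0, var_mz=0.0)
        sv = g.dosage[0]
        X = np.column_stack([np.ones(len(y)), sv])
        fit = fit_lmm(y, X, cohort, columns=["intercept", "a"])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-3)
        total = fit.var_fam + fit.var_mz + fit.var_res
        assert fit.var_fam < 0.05 * total and fit.var_mz < 0.05 * total

    def test_identical_mz_values_drive_residual_to_zero(self):
        cohort, _ = cs.simulate_cohort(30, 0, 0, seed=3)
        rng = np.random.default_rng(4)
        pair_vals = rng.standard_normal(30)
        y = np.repeat(pair_vals, 2)
        fit = fit_lmm(y, np.ones((60, 1)), cohort, columns=["intercept"])
        assert fit.var_res < 1e-4 * np.var(y)

    def test_rank_deficient_design_names_columns(self, small_cohort):
        cohort, _ = small_cohort
        n = len(cohort.samples)
        x = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_lmm(np.ones(n), X, cohort, columns=["intercept", "x", "x2"])


class TestLikelihoodRatioTest:
    def test_chi_square_reference_values(self, small_cohort):
        from twinvar.lmm import LmmFit

        def mkfit(ll, cols):
            return LmmFit(
                beta=np.zeros(len(cols)), columns=cols, var_fam=0, var_mz=0,
                var_res=1, loglik=ll, converged=True, n_obs=10,
            )

        # 2*dll = 10.83 -> p ~ 1.0e-3 (chi2(1) survival function)
        p = likelihood_ratio_test(mkfit(-100.0 + 10.83 / 2, ["a", "b"]), mkfit(-100.0, ["a"]))
        assert p == pytest.approx(stats.chi2.sf(10.83, 1), rel=1e-12)
        assert p == pytest.approx(1.0e-3, rel=0.01)
        # dll = 0 -> p = 1; negative statistic clamps to 0
        assert likelihood_ratio_test(mkfit(-100.0, ["a", "b"]), mkfit(-100.0, ["a"])) == 1.0
        assert likelihood_ratio_test(mkfit(-101.0, ["a", "b"]), mkfit(-100.0, ["a"])) == 1.0
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(mkfit(-1, ["a", "c"]), mkfit(-2, ["b"]))
        bad = mkfit(-1, ["a", "b"])
        bad.converged = False
        with pytest.raises(ConvergenceError):
            likelihood_ratio_test(bad, mkfit(-2, ["a"]))

    def test_null_lrt_close_to_uniform(self):
        # 400-simulation smoke check; the full 5000-run calibration lives in
        # the acceptance suite
        cohort, ibd = cs.simulate_cohort(40, 60, 20, seed=5)
        g = cs.simulate_genotypes(cohort, ibd, 2, seed=6, ld_rho=0.0)
        ts = TwinStructure.from_cohort(cohort)
        sv, sk = g.dosage[0], g.dosage[1]
        Xf, nf = _scan_design(sv, [], sk, True)
        Xn, nn = _scan_design(sv, [], sk, False)
        tab = cohort.table.set_index("sample_id").loc[cohort.samples]
        _, fi = np.unique(tab["family_id"], return_inverse=True)
        rng = np.random.default_rng(7)
        n = len(sv)
        ps = []
        for _ in range(400):
            y = (
                0.3 * sv
                + np.sqrt(0.15) * rng.standard_normal(fi.max() + 1)[fi]
                + np.sqrt(0.85) * rng.standard_normal(n)
            )
            ps.append(
                likelihood_ratio_test(
                    fit_lmm(y, Xf, ts, columns=nf), fit_lmm(y, Xn, ts, columns=nn)
                )
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.001
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.03


class TestStepwise:
    def test_null_gene_yields_no_hits(self):
        hits_total = 0
        for rep in range(5):
            cohort, g, y, _ = _sim_gene(
                200 + rep, n_variants=30, additive=[], var_fam=0.1, var_mz=0.1
            )
            sv = g.dosage[5]
            cands = {
                v: g.dosage_of(v)
                for v in g.variants["variant_id"]
                if v != g.variants["variant_id"].iloc[5]
            }
            ts = TwinStructure.from_cohort(cohort)
            hits_total += len(forward_stepwise_epistasis(y, sv, cands, ts))
        assert hits_total == 0  # Bonferroni 1.98e-8 admits essentially nothing

    def test_recovers_planted_partner_and_share(self):
        cohort, ibd = cs.simulate_cohort(134, 199, 134, 300)
        g = cs.simulate_genotypes(
            cohort, ibd, 40, seed=301, maf_range=(0.2, 0.5), ld_rho=0.8
        )
        vids = g.variants["variant_id"].tolist()
        v, k = vids[10], vids[30]
        spec = cs.GeneSpec(
            "g0", additive=[(v, 0.2), (k, 0.05)], epistasis=[(v, k, 0.05)],
            var_fam=0.1, var_mz=0.1,
        )
        expr, truth = cs.simulate_expression(g, cohort, [spec], seed=302)
        ts = TwinStructure.from_cohort(cohort)
        cands = {vv: g.dosage_of(vv) for vv in vids if vv != v}
        pos = dict(zip(g.variants["variant_id"], g.variants["pos"]))
        hits = forward_stepwise_epistasis(
            expr.values[0], g.dosage_of(v), cands, ts, positions=pos
        )
        assert len(hits) >= 1
        h = hits[0]
        r = np.corrcoef(g.dosage_of(h.partner_id), g.dosage_of(k))[0, 1]
        assert h.partner_id == k or abs(r) > 0.9
        assert h.signed_variance_share == pytest.approx(0.05, abs=0.03)
        assert h.signed_variance_share > 0

    def test_order_invariance_of_selection(self):
        cohort, ibd = cs.simulate_cohort(50, 80, 30, 310)
        g = cs.simulate_genotypes(
            cohort, ibd, 15, seed=311, maf_range=(0.2, 0.5), ld_rho=0.5
        )
        vids = g.variants["variant_id"].tolist()
        v, k = vids[2], vids[10]
        spec = cs.GeneSpec("g0", additive=[(v, 0.2)], epistasis=[(v, k, 0.15)])
        expr, _ = cs.simulate_expression(g, cohort, [spec], seed=312)
        ts = TwinStructure.from_cohort(cohort)
        pos = dict(zip(g.variants["variant_id"], g.variants["pos"]))
        cands = {vv: g.dosage_of(vv) for vv in vids if vv != v}
        rev = dict(reversed(list(cands.items())))
        h1 = forward_stepwise_epistasis(expr.values[0], g.dosage_of(v), cands, ts, positions=pos)
        h2 = forward_stepwise_epistasis(expr.values[0], g.dosage_of(v), rev, ts, positions=pos)
        assert [h.partner_id for h in h1] == [h.partner_id for h in h2]

    def test_adding_interaction_never_decreases_loglik(self, small_cohort):
        cohort, _ = small_cohort
        rng = np.random.default_rng(8)
        n = len(cohort.samples)
        sv = rng.integers(0, 3, n).astype(float)
        sk = rng.integers(0, 3, n).astype(float)
        y = rng.standard_normal(n)
        ts = TwinStructure.from_cohort(cohort)
        Xf, nf = _scan_design(sv, [], sk, True)
        Xn, nn = _scan_design(sv, [], sk, False)
        full = fit_lmm(y, Xf, ts, columns=nf)
        null = fit_lmm(y, Xn, ts, columns=nn)
        assert full.loglik >= null.loglik - 1e-8


class TestDominanceFilter:
    def _dominance_gene(self, seed):
        """A purely dominant v-eQTL (het effect only) with an LD partner."""
        cohort, ibd = cs.simulate_cohort(100, 150, 100, seed)
        g = cs.simulate_genotypes(
            cohort, ibd, 10, seed=seed + 1, maf_range=(0.3, 0.5), ld_rho=0.9
        )
        sv = g.dosage[4]
        het = g.gp[4][:, 1]
        rng = np.random.default_rng(seed + 2)
        y = 1.0 * het + np.sqrt(0.7) * rng.standard_normal(len(sv))
        return cohort, g, y, sv

    def test_dominance_artifacts_removed(self):
        removed, found = 0, 0
        for rep in range(8):
            cohort, g, y, sv = self._dominance_gene(400 + 10 * rep)
            ts = TwinStructure.from_cohort(cohort)
            vids = g.variants["variant_id"].tolist()
            cands = {vv: g.dosage_of(vv) for vv in vids if vv != vids[4]}
            hits = forward_stepwise_epistasis(
                y, sv, cands, ts, alpha_bonf=1e-4  # permissive to surface artifacts
            )
            if not hits:
                continue
            found += len(hits)
            kept = dominance_conditional_filter(
                hits, y, sv, g.gp[4], cands, ts, alpha_bonf=1e-4
            )
            removed += len(hits) - len(kept)
        assert found > 0
        assert removed / found >= 0.9

    def test_genuine_interaction_survives(self):
        cohort, ibd = cs.simulate_cohort(134, 199, 134, 500)
        g = cs.simulate_genotypes(
            cohort, ibd, 40, seed=501, maf_range=(0.2, 0.5), ld_rho=0.8
        )
        vids = g.variants["variant_id"].tolist()
        v, k = vids[10], vids[30]
        spec = cs.GeneSpec(
            "g0", additive=[(v, 0.2)], epistasis=[(v, k, 0.08)],
            var_fam=0.1, var_mz=0.1,
        )
        expr, _ = cs.simulate_expression(g, cohort, [spec], seed=502)
        ts = TwinStructure.from_cohort(cohort)
        cands = {vv: g.dosage_of(vv) for vv in vids if vv != v}
        vi = 10
        hits = forward_stepwise_epistasis(expr.values[0], g.dosage_of(v), cands, ts)
        assert hits
        kept = dominance_conditional_filter(
            hits, expr.values[0], g.dosage_of(v), g.gp[vi], cands, ts
        )
        assert [h.partner_id for h in kept] == [h.partner_id for h in hits]

    def test_degenerate_gp_flags_untestable(self, small_cohort):
        from twinvar.lmm import EpistasisHit

        cohort, _ = small_cohort
        rng = np.random.default_rng(9)
        n = len(cohort.samples)
        sv = rng.integers(0, 3, n).astype(float)
        sk = rng.integers(0, 3, n).astype(float)
        y = rng.standard_normal(n)
        gp = np.zeros((n, 3))
        gp[:, 0] = 1.0  # no heterozygote information at all
        hit = EpistasisHit("g", "v", "k", 0.1, 1e-9, 1, 0.01)
        kept = dominance_conditional_filter(
            [hit], y, sv, gp, {"k": sk}, TwinStructure.from_cohort(cohort)
        )
        assert kept and kept[0].untestable_dominance


class TestVarianceShare:
    def test_zero_coefficient_gives_zero_share(self, small_cohort):
        cohort, _ = small_cohort
        n = len(cohort.samples)
        rng = np.random.default_rng(10)
        y = rng.standard_normal(n)
        fit = fit_lmm(y, np.ones((n, 1)), cohort, columns=["cK"])
        fit.beta[0] = 0.0
        assert interaction_variance_share(fit, "cK", rng.random(n), rng.random(n)) == 0.0

    def test_sign_follows_coefficient(self):
        cohort, ibd = cs.simulate_cohort(60, 90, 50, 600)
        g = cs.simulate_genotypes(cohort, ibd, 10, seed=601, maf_range=(0.3, 0.5))
        v, k = g.variants["variant_id"].iloc[2], g.variants["variant_id"].iloc[8]
        spec = cs.GeneSpec("g0", additive=[(v, 0.1)], epistasis=[(v, k, -0.1)])
        expr, truth = cs.simulate_expression(g, cohort, [spec], seed=602)
        ts = TwinStructure.from_cohort(cohort)
        sv, sk = g.dosage_of(v), g.dosage_of(k)
        X, names = _scan_design(sv, [], sk, True)
        fit = fit_lmm(expr.values[0], X, ts, columns=names)
        share = interaction_variance_share(fit, "cK", sv, sk)
        assert truth.genes["g0"]["epistasis"][0]["c"] < 0
        assert share < 0
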