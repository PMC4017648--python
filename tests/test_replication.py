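import numpy as np
import pytest
from scipy import stats

from twinvar import cohortsim as cs
from twinvar.dataio import cis_window_variants
from twinvar.replication import (
    ReplicationRecord,
    apply_haplotype_filter,
    concordance_summary,
    eqtl_forward_scan,
    haplotype_exclusion_filter,
    replicate_interaction,
    storey_qvalues,
)

POP_SHIFT = {"CEU": 0.0, "YRI": 0.5, "TSI": -0.3, "GBR": 0.2, "FIN": -0.1}


def _unrelated(seed, n=462, n_variants=30, ld_rho=0.5):
    cohort, ibd, popl = cs.simulate_unrelated_cohort(n, seed)
    g = cs.simulate_genotypes(
        cohort, ibd, n_variants, seed=seed + 1, maf_range=(0.25, 0.4), ld_rho=ld_rho
    )
    return cohort, g, popl


class TestReplicateInteraction:
    def test_null_rejection_rate_calibrated(self):
        cohort, g, popl = _unrelated(10)
        sv, sk = g.dosage[5], g.dosage[20]
        shift = popl.map(POP_SHIFT).to_numpy()
        rng = np.random.default_rng(11)
        rej = 0
        n_sim = 600
        for _ in range(n_sim):
            y = 0.3 * sv + 0.2 * sk + shift + rng.standard_normal(len(sv))
            p, _ = replicate_interaction(y, sv, sk, popl)
            rej += p < 0.05
        assert abs(rej / n_sim - 0.05) < 0.025

    def test_power_at_replication_cohort_size(self):
        hits = 0
        for rep in range(25):
            cohort, g, popl = _unrelated(100 + rep)
            v, k = g.variants["variant_id"].iloc[5], g.variants["variant_id"].iloc[20]
            spec = cs.GeneSpec(
                "g0", additive=[(v, 0.15), (k, 0.05)], epistasis=[(v, k, 0.05)]
            )
            expr, _ = cs.simulate_expression(g, cohort, [spec], seed=200 + rep)
            y = expr.values[0] + popl.map(POP_SHIFT).to_numpy()
            p, share = replicate_interaction(y, g.dosage_of(v), g.dosage_of(k), popl)
            hits += p < 0.05
        assert hits >= 20  # >= 80% power at n=462, share 0.05

    def test_population_covariates_protect_calibration(self):
        # strong population mean structure plus population-correlated dosage
        rng = np.random.default_rng(12)
        n = 400
        popl = np.repeat(["A", "B"], n // 2)
        sv = np.concatenate(
            [rng.binomial(2, 0.15, n // 2), rng.binomial(2, 0.45, n // 2)]
        ).astype(float)
        sk = rng.binomial(2, 0.3, n).astype(float)
        shift = np.where(popl == "A", 0.0, 1.5)
        rej_with, rej_without = 0, 0
        for _ in range(300):
            y = shift + rng.standard_normal(n)
            p_with, _ = replicate_interaction(y, sv, sk, popl)
            p_without, _ = replicate_interaction(y, sv, sk, None)
            rej_with += p_with < 0.05
            rej_without += p_without < 0.05
        assert abs(rej_with / 300 - 0.05) < 0.035

    def test_small_population_level_merged_with_warning(self):
        rng = np.random.default_rng(13)
        n = 50
        popl = np.array(["A"] * 48 + ["B", "B"])
        sv = rng.binomial(2, 0.3, n).astype(float)
        sk = rng.binomial(2, 0.3, n).astype(float)
        y = rng.standard_normal(n)
        with pytest.warns(UserWarning, match="merged"):
            p, _ = replicate_interaction(y, sv, sk, popl)
        assert 0 <= p <= 1


class TestEqtlForwardScan:
    def test_null_gene_selects_nothing(self):
        empty = 0
        for rep in range(10):
            cohort, g, popl = _unrelated(300 + rep)
            rng = np.random.default_rng(400 + rep)
            y = popl.map(POP_SHIFT).to_numpy() + rng.standard_normal(g.n_samples)
            sel = eqtl_forward_scan(
                y, {v: g.dosage_of(v) for v in g.variants["variant_id"]}, popl
            )
            empty += not sel
        assert empty >= 9

    def test_planted_eqtl_recovered_first(self):
        cohort, g, popl = _unrelated(500)
        v = g.variants["variant_id"].iloc[12]
        spec = cs.GeneSpec("g0", additive=[(v, 0.25)])
        expr, _ = cs.simulate_expression(g, cohort, [spec], seed=501)
        y = expr.values[0] + popl.map(POP_SHIFT).to_numpy()
        sel = eqtl_forward_scan(
            y, {vv: g.dosage_of(vv) for vv in g.variants["variant_id"]}, popl
        )
        assert sel
        r = np.corrcoef(g.dosage_of(sel[0]), g.dosage_of(v))[0, 1]
        assert sel[0] == v or abs(r) > 0.9

    def test_two_independent_eqtl_both_selected(self):
        cohort, g, popl = _unrelated(600, ld_rho=0.3)
        v1 = g.variants["variant_id"].iloc[3]
        v2 = g.variants["variant_id"].iloc[25]
        spec = cs.GeneSpec("g0", additive=[(v1, 0.2), (v2, 0.2)])
        expr, _ = cs.simulate_expression(g, cohort, [spec], seed=601)
        y = expr.values[0] + popl.map(POP_SHIFT).to_numpy()
        sel = eqtl_forward_scan(
            y, {vv: g.dosage_of(vv) for vv in g.variants["variant_id"]}, popl
        )
        found = 0
        for target in (v1, v2):
            for s in sel:
                if abs(np.corrcoef(g.dosage_of(s), g.dosage_of(target))[0, 1]) > 0.9:
                    found += 1
                    break
        assert found == 2


class TestHaplotypeFilter:
    def test_empty_eqtl_list_keeps_unconditional_p(self):
        rec = ReplicationRecord("g", "v", "k", 1e-6, 0.05)
        rng = np.random.default_rng(14)
        out = haplotype_exclusion_filter(
            rec, rng.standard_normal(50), rng.random(50), rng.random(50), {}
        )
        assert out.eqtl_conditional_max_p == 1e-6

    def test_spurious_interaction_removed_genuine_kept(self):
        records, truths = [], []
        for rep in range(12):
            spurious = rep % 2 == 0
            cohort, g, popl = _unrelated(700 + rep)
            shift = popl.map(POP_SHIFT).to_numpy()
            if spurious:
                t1 = g.variants["variant_id"].iloc[5]
                t2 = g.variants["variant_id"].iloc[8]
                g2, _ = cs.simulate_haplotype_confounder(
                    g, t1, t2, 0.03, seed=800 + rep
                )
                rng = np.random.default_rng(900 + rep)
                y = 1.2 * g2.dosage_of("rsRARE") + shift + rng.standard_normal(
                    g2.n_samples
                )
                sv, sk = g2.dosage_of(t1), g2.dosage_of(t2)
                gsrc = g2
            else:
                v = g.variants["variant_id"].iloc[5]
                k = g.variants["variant_id"].iloc[20]
                spec = cs.GeneSpec(
                    "g0", additive=[(v, 0.15), (k, 0.05)], epistasis=[(v, k, 0.08)]
                )
                expr, _ = cs.simulate_expression(g, cohort, [spec], seed=950 + rep)
                y = expr.values[0] + shift
                sv, sk = g.dosage_of(v), g.dosage_of(k)
                gsrc = g
            p, share = replicate_interaction(y, sv, sk, popl)
            gene = {"chrom": "1", "tss": int(gsrc.variants["pos"].iloc[15])}
            window = cis_window_variants(gsrc, gene)
            eqtls = eqtl_forward_scan(
                y, {vv: gsrc.dosage_of(vv) for vv in window}, popl
            )
            rec = ReplicationRecord("g", "v", "k", p, share)
            haplotype_exclusion_filter(
                rec, y, sv, sk, {vv: gsrc.dosage_of(vv) for vv in eqtls}, popl
            )
            records.append(rec)
            truths.append(not spurious)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            apply_haplotype_filter(records, fdr_cut=0.05)
        survived = np.array([r.survives_haplotype_filter for r in records])
        truths = np.array(truths)
        assert survived[truths].mean() >= 0.8  # genuine kept
        assert survived[~truths].mean() <= 0.2  # spurious removed

    def test_monotone_screening_property(self):
        # conditioning on more eQTL can only weaken the interaction evidence
        cohort, g, popl = _unrelated(1100)
        v = g.variants["variant_id"].iloc[5]
        k = g.variants["variant_id"].iloc[20]
        spec = cs.GeneSpec("g0", additive=[(v, 0.15)], epistasis=[(v, k, 0.05)])
        expr, _ = cs.simulate_expression(g, cohort, [spec], seed=1101)
        y = expr.values[0] + popl.map(POP_SHIFT).to_numpy()
        p, share = replicate_interaction(y, g.dosage_of(v), g.dosage_of(k), popl)
        others = [vv for vv in g.variants["variant_id"] if vv not in (v, k)]
        small = {vv: g.dosage_of(vv) for vv in others[:2]}
        big = {vv: g.dosage_of(vv) for vv in others[:6]}
        rec_small = haplotype_exclusion_filter(
            ReplicationRecord("g", "v", "k", p, share), y, g.dosage_of(v),
            g.dosage_of(k), small, popl,
        )
        rec_big = haplotype_exclusion_filter(
            ReplicationRecord("g", "v", "k", p, share), y, g.dosage_of(v),
            g.dosage_of(k), big, popl,
        )
        assert rec_big.eqtl_conditional_max_p >= rec_small.eqtl_conditional_max_p


class TestStoreyQvalues:
    def test_uniform_null_pi1_near_zero(self):
        rng = np.random.default_rng(15)
        q, summary = storey_qvalues(rng.uniform(size=5000))
        assert summary.pi1 <= 0.1

    def test_mixture_pi1_recovered(self):
        ests = []
        for rep in range(10):
            rng = np.random.default_rng(1600 + rep)
            p = np.concatenate(
                [rng.beta(0.05, 1, size=3500), rng.uniform(size=1500)]
            )
            _, summary = storey_qvalues(np.clip(p, 1e-300, 1))
            ests.append(summary.pi1)
        assert abs(np.mean(ests) - 0.7) < 0.1

    def test_all_ones_gives_unit_qvalues(self):
        with pytest.warns(UserWarning):
            q, summary = storey_qvalues(np.ones(10))
        np.testing.assert_array_equal(q, 1.0)
        assert summary.method == "bh-fallback"

    def test_qvalues_monotone_bounded_and_above_bh_floor(self):
        rng = np.random.default_rng(17)
        p = np.clip(rng.beta(0.3, 1, size=300), 1e-300, 1)
        q, summary = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert q.max() <= 1.0
        # Storey q-values are BH q-values scaled by pi0_hat
        bh = np.empty_like(p)
        sp = p[order]
        qs = np.minimum.accumulate((len(p) * sp / np.arange(1, len(p) + 1))[::-1])[::-1]
        bh[order] = np.minimum(qs, 1)
        np.testing.assert_allclose(q, np.minimum(summary.pi0_hat * bh, 1), atol=1e-10)

    def test_rejects_out_of_range_p(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.0, 0.5]))


class TestConcordance:
    def test_identical_vectors(self):
        a = np.array([0.1, -0.2, 0.3, 0.05])
        r, same, p = concordance_summary(a, a)
        assert r == pytest.approx(1.0)
        assert same == 4

    def test_independent_signs_not_significant(self):
        ok = 0
        for rep in range(20):
            rng = np.random.default_rng(1800 + rep)
            a = rng.standard_normal(246)
            b = rng.standard_normal(246)
            _, _, p = concordance_summary(a, b)
            ok += p > 0.01
        assert ok >= 18

    def test_correlated_shares_estimate_r(self):
        rng = np.random.default_rng(19)
        ests = []
        for _ in range(10):
            z = rng.standard_normal(246)
            a = 0.6**0.5 * z + (1 - 0.6) ** 0.5 * rng.standard_normal(246)
            b = 0.6**0.5 * z + (1 - 0.6) ** 0.5 * rng.standard_normal(246)
            ests.append(concordance_summary(a, b)[0])
        assert abs(np.mean(ests) - 0.6) < 0.15

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_summary(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
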