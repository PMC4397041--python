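import numpy as np
import pandas as pd
import pytest

import contactzone as cz
from contactzone.pst import PstFstReport


def balanced_groups(means, sd, n, seed=0):
    rng = np.random.default_rng(seed)
    vals = np.concatenate([rng.normal(m, sd, n) for m in means])
    labels = np.repeat([f"g{k}" for k in range(len(means))], n)
    return vals, labels


class TestVarianceComponents:
    def test_no_between_signal_hits_boundary(self):
        vals, labels = balanced_groups([0.0, 0.0, 0.0], 1.0, 200, seed=1)
        vc = cz.variance_components(vals, labels)
        assert vc.sigma2_gb == 0.0
        assert vc.boundary
        assert vc.sigma2_gw == pytest.approx(1.0, rel=0.15)

    def test_balanced_equals_hand_anova(self):
        """Alternating +/-1 around means 0 and 10: closed-form ANOVA."""
        v0 = np.tile([-1.0, 1.0], 25)
        v1 = 10.0 + np.tile([-1.0, 1.0], 25)
        vals = np.concatenate([v0, v1])
        labels = np.repeat(["a", "b"], 50)
        vc = cz.variance_components(vals, labels)
        n, k = 50, 2
        msw = (np.sum(v0**2) + np.sum((v1 - 10) ** 2)) / (2 * n - k)
        msb = n * ((0 - 5) ** 2 + (10 - 5) ** 2) / (k - 1)
        assert vc.sigma2_gw == pytest.approx(msw, abs=1e-10)
        assert vc.sigma2_gb == pytest.approx((msb - msw) / n, abs=1e-10)

    def test_unbalanced_matches_mixedlm_reml(self):
        """1-D profiled REML equals the statsmodels MixedLM fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        sizes = [12, 25, 40, 8]
        effects = rng.normal(0, 2.0, len(sizes))
        vals = np.concatenate(
            [rng.normal(5 + e, 1.0, n) for e, n in zip(effects, sizes)]
        )
        labels = np.repeat([f"g{k}" for k in range(len(sizes))], sizes)
        vc = cz.variance_components(vals, labels)
        md = sm.MixedLM(vals, np.ones((len(vals), 1)), groups=labels)
        fit = md.fit(reml=True)
        assert vc.sigma2_gb == pytest.approx(float(np.asarray(fit.cov_re)[0, 0]), rel=1e-3)
        assert vc.sigma2_gw == pytest.approx(float(fit.scale), rel=1e-3)

    def test_recovery_of_configured_components(self):
        """sigma2_GB = 4, sigma2_GW = 1, 3 x 200: within 25% in >=90% of 100."""
        ok = 0
        ss = np.random.SeedSequence(7)
        for child in ss.spawn(100):
            rng = np.random.default_rng(child)
            vals = np.concatenate([rng.normal(m, 1.0, 200) for m in (-2.0, 0.0, 2.0)])
            labels = np.repeat(list("abc"), 200)
            vc = cz.variance_components(vals, labels)
            ok += (abs(vc.sigma2_gb - 4.0) / 4.0 <= 0.25
                   and abs(vc.sigma2_gw - 1.0) <= 0.25)
        assert ok >= 90

    def test_small_group_excluded_then_error(self):
        with pytest.warns(UserWarning, match="excluded"):
            with pytest.raises(ValueError, match="two groups"):
                cz.variance_components([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestPstArithmetic:
    @pytest.mark.parametrize("gb, gw, expected", [
        (0.0, 1.0, 0.0),
        (5.0, 0.0, 1.0),
        (2.0, 1.0, 0.5),
    ])
    def test_point_values(self, gb, gw, expected):
        vc = cz.VarianceComponents(gb, gw, 2, 100)
        assert cz.pst(vc) == expected

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            cz.pst(cz.VarianceComponents(0.0, 0.0, 2, 10))

    def test_scale_invariance(self):
        vals, labels = balanced_groups([0.0, 3.0], 1.0, 40, seed=2)
        p1 = cz.pst(cz.variance_components(vals, labels))
        p2 = cz.pst(cz.variance_components(vals * 7.3, labels))
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_monotone_in_between_component(self):
        vals = [cz.pst(cz.VarianceComponents(gb, 1.0, 2, 10))
                for gb in (0.1, 0.5, 1.0, 5.0, 50.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestPairwisePst:
    def test_null_case_near_zero(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"mean_plates": rng.normal(15, 1, 100)},
                          index=[f"i{k}" for k in range(100)])
        grouping = {f"i{k}": ("a" if k < 50 else "b") for k in range(100)}
        est = cz.pairwise_pst(cz.PhenotypeTable(df), grouping,
                              n_boot=200, seed=1)[("a", "b")]
        assert est.point < 0.2
        assert est.ci_low <= 0.05

    def test_strong_divergence(self):
        """Group means 5 vs 31 at sigma = 1: P_ST above 0.95."""
        vals, labels = balanced_groups([5.0, 31.0], 1.0, 50, seed=3)
        df = pd.DataFrame({"mean_plates": vals},
                          index=[f"i{k}" for k in range(100)])
        grouping = dict(zip(df.index, labels))
        est = cz.pairwise_pst(cz.PhenotypeTable(df), grouping,
                              n_boot=200, seed=2)[("g0", "g1")]
        assert est.point > 0.95

    def test_ci_determinism(self):
        vals, labels = balanced_groups([0.0, 1.0, 2.0], 1.0, 30, seed=5)
        df = pd.DataFrame({"mean_plates": vals + 16},
                          index=[f"i{k}" for k in range(90)])
        grouping = dict(zip(df.index, labels))
        m1 = cz.pairwise_pst(cz.PhenotypeTable(df), grouping, n_boot=300, seed=11)
        m2 = cz.pairwise_pst(cz.PhenotypeTable(df), grouping, n_boot=300, seed=11)
        for key in m1:
            assert (m1[key].ci_low, m1[key].ci_high) == (m2[key].ci_low, m2[key].ci_high)

    def test_bootstrap_covers_analytic_pst(self):
        """Configured fixed group means: CI covers the analytic value."""
        truth = 4.0 / (4.0 + 2.0)   # ddof=1 variance of (-2, 0, 2) is 4
        cover = 0
        ss = np.random.SeedSequence(999)
        for child in ss.spawn(30):
            rng = np.random.default_rng(child)
            vals = np.concatenate([rng.normal(m, 1.0, 50) for m in (-2.0, 0.0, 2.0)])
            labels = np.repeat(list("abc"), 50)
            sub = int(child.generate_state(1, np.uint32)[0] % 2**31)
            est = cz.pst_with_ci(vals, labels, n_boot=500, seed=sub)
            cover += est.ci_low <= truth <= est.ci_high
        assert cover >= 24  # 80% of a 30-seed spot check


class TestPstFstComparison:
    def test_t_from_r_closed_forms(self):
        assert cz.t_from_r(0.5, 4) == pytest.approx(0.5 * 2 / np.sqrt(0.75), abs=1e-12)
        assert cz.t_from_r(0.0, 4) == 0.0
        with pytest.raises(ValueError):
            cz.t_from_r(1.0, 4)

    def test_zero_correlation_gives_p_one(self):
        pairs = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
        comp = cz.pst_fst_correlation(dict(zip(pairs, x)), dict(zip(pairs, y)))
        assert comp.t == pytest.approx(0.0, abs=1e-12)
        assert comp.p == pytest.approx(1.0, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        with pytest.raises(ValueError, match="4"):
            cz.pst_fst_correlation(dict(zip(pairs, [1, 2, 3])),
                                   dict(zip(pairs, [1, 2, 3])))

    def test_identical_vectors_flagged(self):
        pairs = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
        v = dict(zip(pairs, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
        with pytest.raises(ValueError, match="diverges"):
            cz.pst_fst_correlation(v, dict(v))

    def test_constant_vector_rejected(self):
        pairs = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
        with pytest.raises(ValueError, match="constant"):
            cz.pst_fst_correlation(dict(zip(pairs, [1.0] * 6)),
                                   dict(zip(pairs, [1, 2, 3, 4, 5, 6])))


class TestReport:
    def _mats(self):
        pairs = [("a", "b"), ("a", "c"), ("a", "d"),
                 ("b", "c"), ("b", "d"), ("c", "d")]
        pst_mat = {p: cz.PstEstimate(0.6 + 0.05 * k, 0.5, 0.7, 100,
                                     "mean_plates", p)
                   for k, p in enumerate(pairs)}
        fst_mats = {}
        for panel, base in (("all", 0.1), ("neutral", 0.05), ("qtl", 0.2)):
            fst_mats[panel] = {
                p: cz.DiffEstimate("theta_WC", panel, p,
                                   pd.Series(dtype=float), base + 0.02 * k,
                                   ci_low=base, ci_high=base + 0.1)
                for k, p in enumerate(pairs)
            }
        return pst_mat, fst_mats

    def test_shape_and_panels(self):
        pst_mat, fst_mats = self._mats()
        rep = cz.pst_fst_report(pst_mat, fst_mats)
        assert isinstance(rep, PstFstReport)
        assert len(rep.rows) == 6 * 4          # P_ST + three panels
        assert set(rep.comparisons.panel) == {"all", "neutral", "qtl"}

    def test_pst_exceeds_theta_under_strong_trait_divergence(self):
        pst_mat, fst_mats = self._mats()
        rep = cz.pst_fst_report(pst_mat, fst_mats)
        wide = rep.rows.pivot_table(index=["group_a", "group_b"],
                                    columns="statistic", values="point",
                                    aggfunc="first")
        assert (wide["P_ST"] >= wide["theta_WC"]).all()

    def test_missing_panel_simply_absent(self):
        pst_mat, fst_mats = self._mats()
        del fst_mats["qtl"]
        rep = cz.pst_fst_report(pst_mat, fst_mats)
        assert "qtl" not in set(rep.rows.panel)
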