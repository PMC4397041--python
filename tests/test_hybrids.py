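import numpy as np
import pandas as pd
import pytest

import contactzone as cz
from contactzone.crosses import ANCESTRY_FREQS, CLASS_ORDER
from contactzone.hybrids import smooth_frequencies
from conftest import make_table
from reference import admixture_q_grid, class_genotype_prob_enum


def diag_freqs(n_loci):
    fa = {f"L{j}": {1: 1.0} for j in range(n_loci)}
    fb = {f"L{j}": {2: 1.0} for j in range(n_loci)}
    return fa, fb


def diag_model(n_loci, n=50):
    fa, fb = diag_freqs(n_loci)
    return cz.ClassifierModel(fa, fb, nA=n, nB=n)


def cohort_from_calls(calls, n_loci, label="x"):
    ids = [f"i{k}" for k in range(len(calls))]
    markers = [cz.MarkerDef(f"L{j}") for j in range(n_loci)]
    return cz.GenotypeTable(ids, markers, np.array(calls), {i: label for i in ids})


class TestClassLikelihood:
    def test_heterozygous_individual_prefers_f1(self):
        model = diag_model(6)
        cohort = cohort_from_calls([[(1, 2)] * 6], 6)
        ll = model.loglik_matrix(cohort).iloc[0]
        assert ll.idxmax() == "F1"
        assert ll["F1"] > ll.drop("F1").max()

    def test_homozygous_a_prefers_pa(self):
        model = diag_model(6)
        cohort = cohort_from_calls([[(1, 1)] * 6], 6)
        ll = model.loglik_matrix(cohort).iloc[0]
        assert ll.idxmax() == "PA"

    def test_matches_enumeration_oracle(self):
        """One-locus likelihoods equal brute-force ancestry enumeration."""
        fa = {"L0": {1: 0.7, 2: 0.3}}
        fb = {"L0": {1: 0.2, 2: 0.8}}
        model = cz.ClassifierModel(fa, fb, nA=10, nB=10)
        for genotype in [(1, 1), (1, 2), (2, 2)]:
            cohort = cohort_from_calls([[genotype]], 1)
            ll = model.loglik_matrix(cohort).iloc[0]
            for cls in CLASS_ORDER:
                expected = class_genotype_prob_enum(
                    genotype, model.pA["L0"], model.pB["L0"],
                    ANCESTRY_FREQS[cls])
                assert ll[cls] == pytest.approx(np.log(expected), abs=1e-10)

    def test_impossible_class_strongly_excluded(self):
        """Post-smoothing, an F1 pattern leaves parental classes behind by a
        likelihood ratio above 1e6 at six or more diagnostic loci."""
        model = diag_model(6)
        cohort = cohort_from_calls([[(1, 2)] * 6], 6)
        ll = model.loglik_matrix(cohort).iloc[0]
        assert ll["F1"] - ll["PA"] > np.log(1e6)

    def test_missing_loci_skipped(self):
        model = diag_model(3)
        full = cohort_from_calls([[(1, 2), (1, 2), (1, 2)]], 3)
        partial = cohort_from_calls([[(1, 2), (-1, -1), (1, 2)]], 3)
        ll_full = model.loglik_matrix(full).iloc[0]["F1"]
        ll_part = model.loglik_matrix(partial).iloc[0]["F1"]
        assert ll_part == pytest.approx(ll_full * 2 / 3, rel=1e-9)

    def test_all_missing_rejected(self):
        model = diag_model(2)
        cohort = cohort_from_calls([[(-1, -1), (-1, -1)]], 2)
        with pytest.raises(ValueError, match="zero non-missing"):
            model.loglik_matrix(cohort)

    def test_locus_permutation_invariance(self):
        rng = np.random.default_rng(2)
        fa = {f"L{j}": {1: 0.8, 2: 0.2} for j in range(4)}
        fb = {f"L{j}": {1: 0.1, 2: 0.9} for j in range(4)}
        model = cz.ClassifierModel(fa, fb, nA=20, nB=20)
        calls = [[tuple(sorted(rng.integers(1, 3, 2))) for _ in range(4)]]
        c1 = cohort_from_calls(calls, 4)
        perm = [3, 0, 2, 1]
        c2 = cohort_from_calls([[calls[0][j] for j in perm]], 4)
        assert np.allclose(model.loglik_matrix(c1).to_numpy(),
                           model.loglik_matrix(c2).to_numpy())


class TestClassify:
    def test_posteriors_normalised(self):
        rng = np.random.default_rng(3)
        a, b = cz.make_power_baselines(F=0.3, seed=3)
        model = cz.ClassifierModel.from_tables(a, b)
        post = model.classify(a).table
        sums = post[[f"post_{c}" for c in CLASS_ORDER]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_f1_cohort_all_assigned_f1(self):
        fa, fb = diag_freqs(6)
        cohort = cz.simulate_class("F1", fa, fb, 50, np.random.default_rng(4))
        model = cz.ClassifierModel(fa, fb, nA=50, nB=50)
        assert (model.classify(cohort).assigned == "F1").all()

    def test_baseline_individuals_self_assign(self):
        """At 14 strongly divergent loci, >=99% of PA fish classify as PA."""
        a, b = cz.make_power_baselines(F=0.5, seed=0)
        model = cz.ClassifierModel.from_tables(a, b)
        assert (model.classify(a).assigned == "PA").mean() >= 0.99


class TestAdmixtureQ:
    def test_pure_a_boundary(self):
        model = diag_model(5)
        cohort = cohort_from_calls([[(1, 1)] * 5], 5)
        est = model.admixture_q(cohort)[0]
        assert est.q == 1.0
        assert est.pure_flag

    def test_all_heterozygous_gives_half(self):
        model = diag_model(5)
        cohort = cohort_from_calls([[(1, 2)] * 5], 5)
        est = model.admixture_q(cohort)[0]
        assert est.q == pytest.approx(0.5, abs=1e-9)
        assert not est.pure_flag

    def test_matches_grid_search_oracle(self):
        fa = {"L0": {1: 0.7, 2: 0.3}}
        fb = {"L0": {1: 0.2, 2: 0.8}}
        model = cz.ClassifierModel(fa, fb, nA=25, nB=25)
        for genotype in [(1, 1), (1, 2), (2, 2)]:
            cohort = cohort_from_calls([[genotype]], 1)
            q_impl = model.admixture_q(cohort)[0].q
            q_grid = admixture_q_grid([genotype], [model.pA["L0"]],
                                      [model.pB["L0"]])
            assert q_impl == pytest.approx(q_grid, abs=1e-3)

    def test_antisymmetry_under_baseline_swap(self):
        rng = np.random.default_rng(7)
        fa = {f"L{j}": {1: 0.85, 2: 0.15} for j in range(6)}
        fb = {f"L{j}": {1: 0.1, 2: 0.9} for j in range(6)}
        m1 = cz.ClassifierModel(fa, fb, nA=30, nB=30)
        m2 = cz.ClassifierModel(fb, fa, nA=30, nB=30)
        calls = [[tuple(sorted(rng.integers(1, 3, 2))) for _ in range(6)]
                 for _ in range(20)]
        cohort = cohort_from_calls(calls, 6)
        q1 = np.array([e.q for e in m1.admixture_q(cohort)])
        q2 = np.array([e.q for e in m2.admixture_q(cohort)])
        assert np.allclose(q1 + q2, 1.0, atol=1e-9)


class TestPurityFilter:
    def test_pure_cohorts_fully_retained(self):
        a, b = cz.make_power_baselines(F=0.5, seed=0)
        merged = a.concat(b)
        res = cz.purity_filter(merged, "A", "B", threshold=0.9)
        assert res.excluded == []
        assert res.cohort_a.n_individuals == a.n_individuals

    def test_salted_f1s_excluded(self):
        a, b = cz.make_power_baselines(F=0.5, seed=0)
        afa, afb = cz.allele_frequencies(a), cz.allele_frequencies(b)
        fa = afa.marker_freqs(afa.groups[0])
        fb = afb.marker_freqs(afb.groups[0])
        f1 = cz.simulate_class("F1", fa, fb, 5, np.random.default_rng(3),
                               markers=a.markers, id_prefix="s_")
        f1 = f1.with_groups({i: "A" for i in f1.individuals})
        merged = a.concat(f1).concat(b)
        res = cz.purity_filter(merged, "A", "B", threshold=0.9)
        assert sorted(res.excluded) == sorted(f1.individuals)

    def test_zero_threshold_is_identity(self):
        a, b = cz.make_power_baselines(F=0.1, seed=2)
        merged = a.concat(b)
        res = cz.purity_filter(merged, "A", "B", threshold=0.0)
        assert res.excluded == []

    def test_depleted_baseline_raises(self):
        # identical baseline frequencies: the q profile is flat, nobody
        # clears the own-side threshold and the filter must refuse
        a, _ = cz.make_power_baselines(F=0.1, n_per_pop=10, seed=5)
        dup = cz.GenotypeTable([f"B_{k}" for k in range(a.n_individuals)],
                               a.markers, a.calls,
                               {f"B_{k}": "B" for k in range(a.n_individuals)})
        with pytest.raises(ValueError, match="relax"):
            cz.purity_filter(a.concat(dup), "A", "B", threshold=0.9)


class TestPowerAnalysis:
    def test_monotone_in_diagnostic_loci(self):
        """Per-class accuracy is non-decreasing on the ladder L = 2, 6, 14."""
        accs = {}
        for L in (2, 6, 14):
            fa, fb = diag_freqs(L)
            cohorts = cz.simulate_cross(cz.CrossSpec(seed=11), fa, fb)
            model = cz.ClassifierModel(fa, fb, nA=50, nB=50)
            per_class = {}
            for c in cohorts:
                post = model.classify(c.table)
                truth = pd.Series(c.truth)
                for cls in CLASS_ORDER:
                    mask = truth == cls
                    per_class.setdefault(cls, []).append(
                        float((post.assigned[mask.index[mask]] == cls).mean()))
            accs[L] = {cls: np.mean(v) for cls, v in per_class.items()}
        for cls in CLASS_ORDER:
            assert accs[2][cls] <= accs[6][cls] + 1e-9
            assert accs[6][cls] <= accs[14][cls] + 1e-9

    def test_report_structure_and_determinism(self):
        a, b = cz.make_power_baselines(F=0.5, seed=1)
        spec = cz.CrossSpec(n_per_class=10, n_reps=2, seed=4)
        r1 = cz.power_analysis(a, b, spec)
        r2 = cz.power_analysis(a, b, spec)
        pd.testing.assert_frame_equal(r1.per_class, r2.per_class)
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)
        # confusion rows count n_per_class x n_reps per simulated class
        assert (r1.confusion.sum(axis=1)[list(CLASS_ORDER)] == 10 * 2).all()

    def test_panel_subsetting(self):
        a, b = cz.make_power_baselines(F=0.5, seed=6)
        qtl = [m.name for m in a.markers[:4]]
        a2 = cz.GenotypeTable(a.individuals,
                              [cz.MarkerDef(m.name, "qtl" if m.name in qtl else "neutral")
                               for m in a.markers], a.calls, a.groups)
        b2 = cz.GenotypeTable(b.individuals, a2.markers, b.calls, b.groups)
        rep = cz.power_analysis(a2, b2, cz.CrossSpec(n_per_class=5, n_reps=1, seed=1),
                                panel="qtl")
        assert rep.panel == "qtl"


def test_smoothing_adds_pseudocounts():
    fr = {"L0": {1: 1.0}}
    sm = smooth_frequencies(fr, {"L0": 10}, {"L0": {1, 2}}, pseudo=0.5)
    assert sm["L0"][1] == pytest.approx(20.5 / 21)
    assert sm["L0"][2] == pytest.approx(0.5 / 21)
    assert sum(sm["L0"].values()) == pytest.approx(1.0)
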