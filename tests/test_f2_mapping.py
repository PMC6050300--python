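"""F2 fine-mapping: markers, haplotype tracks, adjustment, association,
segregation, SV genotyping, ddCt."""

import numpy as np
import pandas as pd
import pytest

from ducksweep import (
    DiagnosticMarker,
    adjust_phenotypes,
    classify_haplotypes,
    genotype_association,
    genotype_sv,
    genotype_sv_table,
    relative_expression_ddct,
    segregation_chi2,
    select_diagnostic_markers,
)
from conftest import make_gm, make_pm


class TestSelectDiagnosticMarkers:
    def test_daf_threshold_strict(self):
        # p_wild and p_elite realised exactly with 10 founders each
        def dosages(freq, n=10):
            alt = int(round(freq * 2 * n))
            full, rem = divmod(alt, 2)
            return [2] * full + [1] * rem + [0] * (n - full - rem)

        freqs = [(0.1, 0.9), (0.3, 0.85), (0.0, 1.0), (0.25, 0.75), (0.5, 0.5)]
        rows = [dosages(w) + dosages(e) for w, e in freqs]
        gm = make_gm(rows)
        pm = make_pm(gm, {"wild": 10, "elite": 10})
        markers = select_diagnostic_markers(gm, pm, "wild", "elite", 0.6)
        assert [m.pos for m in markers] == [100, 300]  # dAF 0.8 and 1.0 pass
        assert all(m.elite_allele == "alt" for m in markers)
        # dAF = 0.55 rejected; boundary equality rejected under strict >
        # (0.25/0.75 are exact in binary, so the 0.5 boundary is exact)
        boundary = select_diagnostic_markers(gm, pm, "wild", "elite", 0.5)
        assert 400 not in [m.pos for m in boundary]
        assert 200 in [m.pos for m in boundary]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, (20, 16)).astype(np.int8)
        # make half the panel strongly divergent so both outcomes occur
        g[::2, :8] = rng.binomial(2, 0.05, (10, 8))
        g[::2, 8:] = rng.binomial(2, 0.95, (10, 8))
        gm = make_gm(g)
        pm = make_pm(gm, {"wild": 8, "elite": 8})
        markers = select_diagnostic_markers(gm, pm, "wild", "elite", 0.6)
        expect = []
        for i in range(20):
            pw = g[i, :8].sum() / 16
            pe = g[i, 8:].sum() / 16
            if abs(pe - pw) > 0.6:
                expect.append(int(gm.pos[i]))
        assert expect  # the comparison is non-vacuous
        assert [m.pos for m in markers] == expect

    def test_none_passing_warns(self):
        gm = make_gm([[1, 1, 1, 1]])
        pm = make_pm(gm, {"wild": 2, "elite": 2})
        with pytest.warns(UserWarning, match="no markers"):
            assert select_diagnostic_markers(gm, pm, "wild", "elite") == []


def _markers_for(gm):
    return [DiagnosticMarker("1", int(p), 1.0, "alt") for p in gm.pos]


def _calls_for_codes(codes, **kw):
    """Run classification for a single individual with given elite-dosage."""
    gm = make_gm(np.asarray(codes, dtype=np.int8).reshape(-1, 1),
                 samples=["ind"])
    return classify_haplotypes(gm, _markers_for(gm), **kw)[0]


class TestClassifyHaplotypes:
    def test_single_breakpoint_track(self):
        c = _calls_for_codes([2, 2, 2, 2, 0, 0, 0, 0], smooth_k=3,
                             min_segment=2)
        assert c.signature == "P|M"
        assert c.breakpoints == [3]  # between markers 4 and 5 (1-based)

    def test_isolated_error_absorbed_by_smoothing(self):
        c = _calls_for_codes([2, 2, 0, 2, 2, 2, 0, 0, 0], smooth_k=3,
                             min_segment=2)
        assert c.signature == "P|M"
        assert c.breakpoints == [5]  # between markers 6 and 7 (1-based)

    def test_heterozygous_segment(self):
        c = _calls_for_codes([1] * 6 + [2] * 6, smooth_k=3, min_segment=2)
        assert c.signature == "H|P"

    def test_majority_missing_unclassified(self):
        codes = [2, -1, -1, -1, -1, -1, 0, -1]
        with pytest.warns(UserWarning, match="unclassified"):
            c = _calls_for_codes(codes, smooth_k=3, min_segment=1)
        assert not c.classified and c.haplotype_class is None

    def test_classes_partition_identical_tracks(self):
        g = np.array([
            [2, 2, 2, 2, 0, 0, 0, 0],
            [2, 2, 2, 2, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 0, 0],
            [2, 2, 2, 0, 0, 0, 0, 0],  # breakpoint one marker earlier
        ]).T.astype(np.int8)
        gm = make_gm(g, samples=["a", "b", "c", "d"])
        calls = classify_haplotypes(gm, _markers_for(gm), smooth_k=3,
                                    min_segment=2, breakpoint_bin_tol=2)
        by = {c.individual: c for c in calls}
        assert by["a"].haplotype_class == by["b"].haplotype_class
        assert by["c"].haplotype_class != by["a"].haplotype_class
        # d's breakpoint falls in the same shared bin -> same class as a/b
        assert by["d"].haplotype_class == by["a"].haplotype_class

    def test_smoothing_is_deterministic(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, (40, 6)).astype(np.int8)
        gm = make_gm(g)
        c1 = classify_haplotypes(gm, _markers_for(gm))
        c2 = classify_haplotypes(gm, _markers_for(gm))
        assert [c.breakpoints for c in c1] == [c.breakpoints for c in c2]

    def test_breakpoint_count_nonincreasing_with_wider_smoothing(self):
        rng = np.random.default_rng(1)
        base = np.repeat([2, 1, 0], [20, 20, 20])
        noisy = base.copy()
        flip = rng.random(60) < 0.1
        noisy[flip] = rng.integers(0, 3, flip.sum())
        for k_small, k_big in [(3, 7), (5, 9)]:
            c_small = _calls_for_codes(noisy, smooth_k=k_small, min_segment=3)
            c_big = _calls_for_codes(noisy, smooth_k=k_big, min_segment=3)
            assert len(c_big.breakpoints) <= len(c_small.breakpoints)


class TestAdjustPhenotypes:
    def test_balanced_two_site_means(self):
        pt = pd.DataFrame({
            "site": ["a"] * 4 + ["b"] * 4,
            "sex": ["F", "M"] * 4,
            "w": [100.0] * 4 + [200.0] * 4,
        })
        adj = adjust_phenotypes(pt, ["w"], ["site"])
        np.testing.assert_allclose(adj["w"], 150.0)

    def test_residuals_match_normal_equations(self):
        rng = np.random.default_rng(4)
        n = 60
        site = rng.choice(["a", "b", "c"], n)
        y = 50.0 + np.where(site == "b", 10, 0) + np.where(site == "c", -5, 0) \
            + rng.normal(0, 2, n)
        pt = pd.DataFrame({"site": site, "w": y})
        adj = adjust_phenotypes(pt, ["w"], ["site"])
        # independent oracle: solve the normal equations directly
        X = np.column_stack([np.ones(n), site == "b", site == "c"]).astype(float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        np.testing.assert_allclose(adj["w"], y.mean() + resid, atol=1e-9)
        # least-squares property: residuals sum to 0 within each level
        for lev in "abc":
            assert abs((adj["w"] - y.mean())[site == lev].sum()) < 1e-8

    def test_single_level_factor_is_identity(self):
        pt = pd.DataFrame({"site": ["a"] * 5, "w": [1.0, 2, 3, 4, 5]})
        with pytest.warns(UserWarning, match="< 2 levels"):
            adj = adjust_phenotypes(pt, ["w"], ["site"])
        np.testing.assert_allclose(adj["w"], pt["w"])

    def test_missing_values_propagate(self):
        pt = pd.DataFrame({
            "site": ["a", "a", "b", "b"],
            "w": [1.0, np.nan, 3.0, 5.0],
        })
        adj = adjust_phenotypes(pt, ["w"], ["site"])
        assert np.isnan(adj["w"].iloc[1])
        assert adj["w"].notna().sum() == 3


class TestGenotypeAssociation:
    def test_effect_percentage_arithmetic(self):
        pt = pd.DataFrame({"w": [2000.0] * 10 + [2150.0] * 20 + [2300.0] * 10})
        geno = [0] * 10 + [1] * 20 + [2] * 10
        res = genotype_association(geno, pt, "w")
        assert res.effect_pct == pytest.approx(15.0)
        assert res.group_means["M"] == pytest.approx(2000.0)

    def test_identical_means_zero_variance_explained(self):
        pt = pd.DataFrame({"w": [10.0, 12, 10, 12, 10, 12]})
        res = genotype_association([0, 0, 1, 1, 2, 2], pt, "w")
        assert res.variance_explained == pytest.approx(0.0, abs=1e-12)
        assert res.effect_pct == pytest.approx(0.0, abs=1e-9)

    def test_programmed_r2_recovered_at_scale(self):
        rng = np.random.default_rng(6)
        n, r2 = 1000, 0.15
        sigma = 1.0
        beta = np.sqrt(r2 / (1 - r2) * sigma**2 / 0.5)
        dose = rng.binomial(2, 0.5, n)
        y = 5.0 + beta * (dose - 1) + rng.normal(0, sigma, n)
        res = genotype_association(dose, pd.DataFrame({"w": y}), "w")
        assert abs(res.variance_explained - r2) < 0.03

    def test_small_groups_excluded(self):
        pt = pd.DataFrame({"w": [1.0, 2, 3, 4, 10.0]})
        res = genotype_association([0, 0, 1, 1, 2], pt, "w")  # P group n=1
        assert res.group_sizes["P"] == 1
        assert np.isfinite(res.variance_explained)


class TestSegregationChi2:
    @pytest.mark.parametrize("obs,ratio,chi2,yates", [
        ((750, 250), (3, 1), 0.0, 0.0),
        ((776, 250), (3, 1), 0.21963, 0.18714),
        ((0, 100), (3, 1), 300.0, 296.0133),  # Yates: 74.5^2 (1/75 + 1/25)
    ])
    def test_pearson_and_yates_values(self, obs, ratio, chi2, yates):
        res = segregation_chi2(obs, ratio)
        assert res["chi2"] == pytest.approx(chi2, abs=1e-4)
        assert res["chi2_yates"] == pytest.approx(yates, abs=1e-4)
        assert res["df"] == 1

    def test_zero_total_fatal(self):
        with pytest.raises(ValueError):
            segregation_chi2((0, 0))


class TestGenotypeSV:
    @pytest.mark.parametrize("ref,ins,expect", [
        (10, 0, "NN"),
        (0, 12, "II"),
        (6, 5, "IN"),
        (3, 0, "missing"),   # too shallow for a confident NN
        (1, 1, "missing"),
        (12, 1, "NN"),
        (1, 12, "II"),
    ])
    def test_rule_with_defaults(self, ref, ins, expect):
        assert genotype_sv(ref, ins) == expect

    def test_allele_balance_guard(self):
        # two stray reads out of 25 conflict with a confident heterozygote
        assert genotype_sv(23, 2) == "missing"
        assert genotype_sv(23, 2, min_minor_frac=0.0) == "IN"

    def test_table_version_matches_scalar(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "individual": [f"i{k}" for k in range(50)],
            "ref_support": rng.integers(0, 30, 50),
            "ins_support": rng.integers(0, 30, 50),
        })
        out = genotype_sv_table(df)
        for _, r in out.iterrows():
            assert r.genotype == genotype_sv(r.ref_support, r.ins_support)


class TestRelativeExpression:
    @pytest.mark.parametrize("cts,expect", [
        ((25, 20, 24, 20), 0.5),
        ((24, 20, 24, 20), 1.0),
        ((20, 20, 23, 20), 8.0),
    ])
    def test_worked_examples(self, cts, expect):
        assert relative_expression_ddct(*cts) == pytest.approx(expect)
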