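import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import orthohrv as oh
from orthohrv.cohort_stats import (NON_NORMAL, NORMAL, bonferroni,
                                   signed_rank, significance_code)


def exact_signed_rank_p(d):
    """Two-sided signed-rank p by enumeration of all 2^n sign patterns."""
    d = np.asarray(d, float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array([ranks[np.array(signs)].sum() if any(signs) else 0.0
                   for signs in itertools.product([False, True], repeat=n)])
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def kw_h_and_exact_p(values, labels):
    """Tie-corrected Kruskal-Wallis H plus the exact permutation p over all
    label assignments (independent of scipy)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    n = len(values)
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_corr = 1 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)

    def h_for(lab):
        h = 0.0
        for g in np.unique(lab):
            r = ranks[lab == g]
            h += r.sum() ** 2 / len(r)
        return (12.0 / (n * (n + 1)) * h - 3 * (n + 1)) / tie_corr

    h_obs = h_for(labels)
    hs = [h_for(np.array(perm)) for perm in
          set(itertools.permutations(labels))]
    hs = np.asarray(hs)
    return h_obs, float(np.mean(hs >= h_obs - 1e-12))


class TestNormalityGate:
    def test_large_gaussian_normal(self):
        rng = np.random.default_rng(0)
        groups = {"a": rng.normal(size=80), "b": rng.normal(size=80)}
        assert oh.normality_gate(groups) == NORMAL

    def test_lognormal_detected(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.lognormal(sigma=1.2, size=60),
                  "b": rng.lognormal(sigma=1.2, size=60)}
        assert oh.normality_gate(groups) == NON_NORMAL

    def test_tiny_group_warns_non_normal(self):
        with pytest.warns(UserWarning, match="n=2"):
            gate = oh.normality_gate({"a": [1.0, 2.0], "b": [1, 2, 3, 4]})
        assert gate == NON_NORMAL

    def test_nominal_level(self):
        # Gaussian cohorts should pass the gate in roughly 1 - alpha' of
        # seeds (two groups, so alpha' is just under 2 * 0.05)
        rng = np.random.default_rng(42)
        hits = sum(
            oh.normality_gate({"a": rng.normal(size=40),
                               "b": rng.normal(size=40)}) == NORMAL
            for _ in range(300))
        assert 0.82 < hits / 300 < 0.97


class TestOmnibus:
    def test_kw_hand_example(self):
        res = oh.omnibus_test({"g1": [1, 2, 3], "g2": [4, 5, 6]},
                              gate=NON_NORMAL)
        assert res.test_name == "Kruskal-Wallis"
        assert res.statistic == pytest.approx(3.857, abs=0.001)
        assert res.p_raw == pytest.approx(0.0495, abs=0.0005)

    def test_identical_groups_null(self):
        res = oh.omnibus_test({"g1": [5, 5, 5, 5], "g2": [5, 5, 5, 5]},
                              gate=NON_NORMAL)
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_anova_path_selected_for_gaussian(self):
        rng = np.random.default_rng(3)
        res = oh.omnibus_test({"a": rng.normal(0, 1, 50),
                               "b": rng.normal(1, 1, 50)})
        assert res.test_name == "one-way ANOVA"

    def test_zero_variance_fallback(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = oh.omnibus_test({"a": [2.0, 2.0, 2.0, 2.0],
                                   "b": [1.0, 2.0, 3.0, 2.5]}, gate=NORMAL)
        assert res.test_name == "Kruskal-Wallis"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            oh.omnibus_test({"a": [1, 2, 3]})

    def test_gate_is_deterministic(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=60)
        lab = np.repeat(["a", "b", "c"], 20)
        r1 = oh.omnibus_test(v, lab)
        r2 = oh.omnibus_test(v, lab)
        assert r1.test_name == r2.test_name and r1.p_raw == r2.p_raw

    def test_type_one_error_calibrated(self):
        """Global null: omnibus rejection rate ~ 5% over 500 replicates."""
        rng = np.random.default_rng(2024)
        rej = 0
        n_rep = 500
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_rep):
                v = rng.normal(size=45)
                lab = np.repeat(["a", "b", "c"], 15)
                if oh.omnibus_test(v, lab).p_raw < 0.05:
                    rej += 1
        # 95% binomial band around 0.05 at n=500: ~[0.031, 0.069]
        assert 0.03 <= rej / n_rep <= 0.07


class TestPairwise:
    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(4)
        data = {g: rng.normal(i, 1, 20) for i, g in enumerate("abc")}
        res = oh.pairwise_tests(data)
        assert len(res) == 3
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw))
            assert r.p_adjusted >= r.p_raw

    def test_paired_identical_is_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = oh.pairwise_tests({"s": x, "t": x.copy()}, paired=True,
                                gate=NON_NORMAL)
        assert res[0].p_raw == 1.0
        assert "zero" in res[0].note

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError, match="unequal"):
            oh.pairwise_tests({"s": [1, 2, 3], "t": [1, 2]}, paired=True,
                              gate=NON_NORMAL)

    @pytest.mark.parametrize("seed", range(6))
    def test_signed_rank_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        d = rng.normal(0.3, 1.0, n)
        _, p, _ = signed_rank(d, np.zeros(n))
        assert p == pytest.approx(exact_signed_rank_p(d), rel=1e-12)

    def test_contrast_letters_for_standard_groups(self):
        rng = np.random.default_rng(5)
        data = {g: rng.normal(size=10) for g in ["Vata", "Pitta", "Kapha"]}
        res = oh.pairwise_tests(data, gate=NON_NORMAL)
        letters = {r.contrast: r.contrast_letter for r in res}
        assert letters["Vata-vs-Kapha"] == "a"
        assert letters["Vata-vs-Pitta"] == "c"

    def test_significance_codes(self):
        assert significance_code(0.04) == "*"
        assert significance_code(0.004) == "**"
        assert significance_code(0.0004) == "***"
        assert significance_code(0.00004) == "****"
        assert significance_code(0.2) == ""

    def test_bonferroni_capped_at_one(self):
        assert bonferroni(0.7, 3) == 1.0


class TestKWExactOrdering:
    def test_chi_square_and_enumeration_comonotone(self):
        """Across all assignments of one pooled dataset, the chi-square p
        and the exact permutation p induce the same rejection ordering."""
        rng = np.random.default_rng(6)
        values = rng.uniform(size=7)
        base = np.array(["a"] * 3 + ["b"] * 4)
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for perm in sorted(set(itertools.permutations(base))):
                lab = np.array(perm)
                res = oh.omnibus_test(values, lab, gate=NON_NORMAL)
                h, p_exact = kw_h_and_exact_p(values, lab)
                assert res.statistic == pytest.approx(h, rel=1e-9)
                rows.append((res.p_raw, p_exact))
        for (pc1, pe1), (pc2, pe2) in itertools.combinations(rows, 2):
            if pc1 < pc2 - 1e-12:
                assert pe1 <= pe2 + 1e-12


class TestSummaries:
    def test_interpolation_quantiles(self):
        df = pd.DataFrame({"g": ["x"] * 5, "v": [1, 2, 3, 4, 5]})
        cell = oh.summarize(df, ["v"], by=["g"]).iloc[0]
        assert (cell["median"], cell["q1"], cell["q3"]) == (3, 2, 4)
        assert cell["q1"] <= cell["median"] <= cell["q3"]

    def test_single_value(self):
        df = pd.DataFrame({"g": ["x"], "v": [7.0]})
        cell = oh.summarize(df, ["v"], by=["g"]).iloc[0]
        assert cell["median"] == cell["q1"] == cell["q3"] == 7.0

    def test_empty_stratum_flagged(self):
        df = pd.DataFrame({"g": ["x", "y"], "v": [1.0, np.nan]})
        out = oh.summarize(df, ["v"], by=["g"]).set_index("g")
        assert out.loc["y", "n"] == 0

    def test_cohort_hr_rises_on_tilt(self, small_bundle):
        s = oh.summarize(small_bundle.panels, ["hr_bpm"], by=["phase_name"])
        s = s.set_index("phase_name")
        assert s.loc["tilt", "median"] > s.loc["supine", "median"]


class TestAgeBands:
    def test_disjoint_bands_required(self):
        df = pd.DataFrame({"subject_id": ["A"], "v": [1.0]})
        meta = pd.DataFrame({"subject_id": ["A"], "group_label": ["x"], "age": [25]})
        with pytest.raises(ValueError, match="disjoint"):
            oh.age_band_compare(df, meta, ["v"], bands=((18, 30), (25, 40)))

    def test_empty_bands_yield_nothing(self):
        df = pd.DataFrame({"subject_id": list("ABCD"), "v": [1.0, 2, 3, 4]})
        meta = pd.DataFrame({"subject_id": list("ABCD"),
                             "group_label": ["x"] * 4,
                             "age": [25, 26, 27, 28]})
        assert oh.age_band_compare(df, meta, ["v"]) == []

    def test_programmed_hf_decline_detected(self):
        """Baseline HF power declines with age in the generator; the upper
        age band should show lower supine HF than the lower band."""
        cfg = oh.GeneratorConfig(seed=31)
        rows, meta_rows = [], []
        for i in range(40):
            age = 18.0 if i < 20 else 40.0
            s = oh.gen_subject_rr(cfg, "Mixed", 1000 + i, age=age,
                                  subject_id=f"S{i:02d}")
            seg = oh.segment_phases(s, cfg.protocol)[0]
            p = oh.compute_panel(seg, metrics=["hf_ms2"])
            rows.append({"subject_id": p.subject_id, "hf_ms2": p.hf_ms2})
            meta_rows.append({"subject_id": p.subject_id,
                              "group_label": "Mixed", "age": age})
        res = oh.age_band_compare(pd.DataFrame(rows), pd.DataFrame(meta_rows),
                                  ["hf_ms2"], by_group=False)
        assert len(res) == 1
        lower = [v for v in res[0].n_per_group][0]
        # direction: lower band's median HF exceeds the upper band's
        hf = pd.DataFrame(rows).set_index("subject_id")["hf_ms2"]
        ages = pd.DataFrame(meta_rows).set_index("subject_id")["age"]
        assert hf[ages == 18].median() > hf[ages == 40].median()
        assert res[0].p_raw < 0.05
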