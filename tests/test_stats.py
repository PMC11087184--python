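"""BSA, ANOVA, Holm adjustment, chi-square, coverage and group tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lvmotion.stats import (anova_oneway, bsa_mosteller, build_group_tables,
                            chi_square_counts, format_group_table,
                            holm_adjust, normal_fraction_below,
                            normalize_by_bsa, one_sigma_interval)


class TestBSA:
    @pytest.mark.parametrize("h,w,expected", [
        (170.0, 79.3, 1.9),   # control group means
        (172.1, 86.6, 2.0),   # HFrEF group means
        (60.0, 60.0, 1.0),
    ])
    def test_mosteller_examples(self, h, w, expected):
        assert round(bsa_mosteller(h, w), 1) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bsa_mosteller(0.0, 70.0)

    def test_normalize(self):
        assert normalize_by_bsa(10.0, 2.0) == 5.0
        assert normalize_by_bsa(0.0, 1.7) == 0.0
        with pytest.raises(ValueError):
            normalize_by_bsa(5.0, 0.0)

    def test_equal_bsa_preserves_ordering(self, rng):
        vals = np.sort(rng.uniform(1, 15, size=10))
        normed = [normalize_by_bsa(v, 1.9) for v in vals]
        assert all(a < b for a, b in zip(normed, normed[1:]))


class TestAnova:
    def test_zero_between_group_variance(self):
        f, p = anova_oneway([[1, 2, 3]] * 4)
        assert f == 0.0 and p == 1.0

    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(size=12), rng.normal(1.0, 1.0, size=15)
        f, p = anova_oneway([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t.statistic**2, rel=1e-10)
        assert p == pytest.approx(t.pvalue, rel=1e-10)

    def test_hand_expanded_sums_of_squares(self):
        groups = [np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0]),
                  np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0]),
                  np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0])]
        # direct SS decomposition oracle
        all_vals = np.concatenate(groups)
        grand = all_vals.mean()
        ssb = sum(len(g) * (g.mean() - grand)**2 for g in groups)
        ssw = sum(((g - g.mean())**2).sum() for g in groups)
        f_oracle = (ssb / 2) / (ssw / 15)
        f, p = anova_oneway(groups)
        assert f == pytest.approx(f_oracle, abs=1e-10)
        # independent library cross-check
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])


class TestHolm:
    def test_single_hypothesis_unchanged(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.06, 0.06])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=10))
    def test_dominates_bonferroni_and_exceeds_raw(self, pvals):
        p = np.array(pvals)
        adj = holm_adjust(p)
        bonf = np.minimum(p * len(p), 1.0)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= bonf + 1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=8)
        _, ref, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestChiSquare:
    def test_proportional_table_is_zero(self):
        stat, p = chi_square_counts([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_homogeneous_2x2(self):
        stat, _ = chi_square_counts([[10, 10], [10, 10]])
        assert stat == 0.0

    def test_formula_oracle_random_table(self, rng):
        obs = rng.integers(5, 40, size=(2, 4)).astype(float)
        stat, _ = chi_square_counts(obs)
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        assert stat == pytest.approx(((obs - exp)**2 / exp).sum(), abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_counts([[0, 0], [3, 4]])


class TestCoverage:
    def test_fraction_below_5mm(self):
        assert round(100 * normal_fraction_below(3.4, 1.6, 5.0)) == 84

    def test_threshold_at_mean(self):
        assert normal_fraction_below(2.0, 0.5, 2.0) == pytest.approx(0.5)

    def test_monte_carlo_oracle(self):
        draws = np.random.default_rng(7).normal(3.4, 1.6, size=1_000_000)
        assert normal_fraction_below(3.4, 1.6, 5.0) \
            == pytest.approx(np.mean(draws < 5.0), abs=0.002)

    def test_one_sigma_interval(self):
        lo, hi = one_sigma_interval(6.1, 3.6)
        assert (round(lo, 1), round(hi, 1)) == (2.5, 9.7)
        assert one_sigma_interval(4.0, 0.0) == (4.0, 4.0)
        lo, hi = one_sigma_interval(1.0, 0.7)
        assert hi - lo == pytest.approx(2 * 0.7)


def _cohort_frame(rng, n=20, hfref_scale=1.0):
    rows, subs = [], []
    for g, scale in (("control", 1.0), ("HFpEF", 1.0), ("HFmrEF", 1.0),
                     ("HFrEF", hfref_scale)):
        for k in range(n):
            sid = f"{g}{k}"
            subs.append({"subject_id": sid, "group": g})
            for seg in (1, 2):
                base = 8.0 * scale
                rows.append({
                    "subject_id": sid, "plane": "long_axis", "border": "epi",
                    "segment": seg,
                    "overall": base * rng.lognormal(0, 0.15),
                    "tangential": 0.7 * base * rng.lognormal(0, 0.15),
                    "normal": 0.6 * base * rng.lognormal(0, 0.15),
                    "n_points": 50})
    return pd.DataFrame(rows), pd.DataFrame(subs)


class TestGroupTables:
    def test_constructed_effect_detected(self, rng):
        per_patient, subjects = _cohort_frame(rng, n=25, hfref_scale=0.6)
        tab = build_group_tables(per_patient, subjects)
        cell = tab[(tab.segment == 1) & (tab.component == "overall")].iloc[0]
        assert cell["HFrEF_mean"] < cell["control_mean"]
        assert cell["anova_p"] < 0.05
        assert "a" in cell["HFrEF_marks"]

    def test_permutation_invariance(self, rng):
        per_patient, subjects = _cohort_frame(rng, n=8)
        t1 = build_group_tables(per_patient, subjects)
        shuffled = per_patient.sample(frac=1.0, random_state=5)
        t2 = build_group_tables(shuffled, subjects)
        pd.testing.assert_frame_equal(
            t1.reset_index(drop=True), t2.reset_index(drop=True))

    def test_small_group_flagged_not_fatal(self, rng):
        per_patient, subjects = _cohort_frame(rng, n=3)
        drop = subjects[subjects.group == "HFrEF"]["subject_id"][1:]
        per_patient = per_patient[~per_patient.subject_id.isin(drop)]
        tab = build_group_tables(per_patient, subjects)
        assert tab["insufficient"].all()
        assert tab["anova_p"].isna().all()

    def test_adjusted_at_least_raw_and_formatting(self, rng):
        per_patient, subjects = _cohort_frame(rng, n=10, hfref_scale=0.7)
        tab = build_group_tables(per_patient, subjects)
        pair_cols = [c for c in tab.columns if c.startswith("p_")]
        assert ((tab[pair_cols] <= 1.0) & (tab[pair_cols] >= 0.0)).all().all()
        formatted = format_group_table(tab, "long_axis", "epi", "overall")
        assert list(formatted.columns) == ["segment", "control", "HFpEF",
                                           "HFmrEF", "HFrEF", "p"]
        assert formatted["control"].str.contains("±").all()
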