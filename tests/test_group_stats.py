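import numpy as np
import pandas as pd
import pytest
from scipy import stats

from audpath.group_stats import (
    StatsError,
    chi_square_2x2,
    mann_whitney_u,
    mixed_ancova,
    moods_median_test,
    paired_t_percent_diff,
    pearson_r,
    skew_kurtosis_screen,
)


def make_cohort(
    rng,
    n_low=8,
    n_high=8,
    regions=("CN", "IC"),
    group_shift=0.0,
    age_slope=0.0,
    subject_sd=0.5,
    noise_sd=0.3,
):
    rows = []
    for g, n in (("low", n_low), ("high", n_high)):
        for i in range(n):
            age = rng.uniform(25, 40)
            subj = rng.normal(0, subject_sd)
            row = {
                "participant_id": f"{g}{i}",
                "group": g,
                "age_years": age,
                "sex": "F" if rng.random() < 0.5 else "M",
            }
            for r_i, region in enumerate(regions):
                for hemi in ("left", "right"):
                    mu = (
                        1.0
                        + 0.5 * r_i
                        + (group_shift if g == "high" else 0.0)
                        + age_slope * (age - 32.0)
                        + subj
                    )
                    row[f"onset_{region}_{hemi}"] = mu + rng.normal(
                        0, noise_sd
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def splitplot_oracle(y, groups):
    """Textbook balanced split-plot ANOVA via cell means.

    ``y`` is [n_subjects, n_regions]; ``groups`` a label per subject.
    Returns F statistics for group, region and region x group.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    n_subj, r = y.shape
    g = len(levels)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[groups == lv].mean() for lv in levels])
    region_means = y.mean(axis=0)
    cell_means = np.vstack([y[groups == lv].mean(axis=0) for lv in levels])
    n_per = np.array([(groups == lv).sum() for lv in levels])

    ss_group = r * np.sum(n_per * (group_means - grand) ** 2)
    ss_subj = r * sum(
        np.sum((subj_means[groups == lv] - group_means[i]) ** 2)
        for i, lv in enumerate(levels)
    )
    ss_region = n_subj * np.sum((region_means - grand) ** 2)
    ss_rg = np.sum(
        n_per[:, None]
        * (cell_means - group_means[:, None] - region_means[None, :] + grand)
        ** 2
    )
    ss_err = 0.0
    for i, lv in enumerate(levels):
        block = y[groups == lv]
        expected = (
            cell_means[i][None, :]
            + subj_means[groups == lv][:, None]
            - group_means[i]
        )
        ss_err += np.sum((block - expected) ** 2)

    f_group = (ss_group / (g - 1)) / (ss_subj / (n_subj - g))
    df_w = (n_subj - g) * (r - 1)
    f_region = (ss_region / (r - 1)) / (ss_err / df_w)
    f_rg = (ss_rg / ((g - 1) * (r - 1))) / (ss_err / df_w)
    return {"group": f_group, "region": f_region, "region:group": f_rg}


class TestMixedAncova:
    def test_matches_splitplot_oracle_on_balanced_toy(self, rng):
        regions = ("CN", "IC")
        table = make_cohort(rng, n_low=6, n_high=6, regions=regions)
        # collapse hemispheres so the toy is a pure 2x2 split plot
        y = np.column_stack(
            [
                table[[f"onset_{r}_left", f"onset_{r}_right"]].mean(axis=1)
                for r in regions
            ]
        )
        for i, r in enumerate(regions):
            table[f"resp_{r}"] = y[:, i]
        result = mixed_ancova(
            table,
            response="resp",
            within={"region": regions},
            covariate=None,
        )
        oracle = splitplot_oracle(y, table["group"])
        assert result.F("group") == pytest.approx(oracle["group"], rel=1e-8)
        assert result.F("region") == pytest.approx(oracle["region"], rel=1e-8)
        assert result.F("region:group") == pytest.approx(
            oracle["region:group"], rel=1e-8
        )

    def test_study_layout_degrees_of_freedom(self, rng):
        table = make_cohort(
            rng, n_low=30, n_high=32, regions=("CN", "IC", "MGB", "AC")
        )
        result = mixed_ancova(
            table,
            response="onset",
            within={
                "region": ("CN", "IC", "MGB", "AC"),
                "hemisphere": ("left", "right"),
            },
        )
        group = result.effect("group")
        assert (group["df1"], group["df2"]) == (1, 59)
        region = result.effect("region")
        assert (region["df1"], region["df2"]) == (3, 177)
        hemi = result.effect("hemisphere")
        assert (hemi["df1"], hemi["df2"]) == (1, 59)

    def test_location_invariance(self, rng):
        table = make_cohort(rng)
        shifted = table.copy()
        for c in table.columns:
            if c.startswith("onset_"):
                shifted[c] = table[c] + 100.0
        r1 = mixed_ancova(table, response="onset",
                          within={"region": ("CN", "IC"),
                                  "hemisphere": ("left", "right")})
        r2 = mixed_ancova(shifted, response="onset",
                          within={"region": ("CN", "IC"),
                                  "hemisphere": ("left", "right")})
        for eff in ("group", "region", "region:group", "hemisphere"):
            assert r1.F(eff) == pytest.approx(r2.F(eff), rel=1e-9)

    def test_detects_group_effect(self, rng):
        table = make_cohort(rng, n_low=20, n_high=20, group_shift=1.0,
                            subject_sd=0.3)
        result = mixed_ancova(
            table, response="onset",
            within={"region": ("CN", "IC"),
                    "hemisphere": ("left", "right")},
        )
        assert result.p("group") < 0.01

    def test_missing_cell_raises(self, rng):
        table = make_cohort(rng).drop(columns=["onset_IC_left"])
        with pytest.raises(StatsError, match="onset_IC_left"):
            mixed_ancova(table, response="onset",
                         within={"region": ("CN", "IC"),
                                 "hemisphere": ("left", "right")})

    def test_null_calibration_small(self, rng):
        # reduced version of the acceptance-scale calibration
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            table = make_cohort(rng, n_low=10, n_high=10)
            result = mixed_ancova(
                table, response="onset",
                within={"region": ("CN", "IC"),
                        "hemisphere": ("left", "right")},
            )
            hits += result.p("group") < 0.05
        assert 0.02 <= hits / n_sims <= 0.09

    def test_sex_as_additional_between_factor(self, rng):
        table = make_cohort(rng, n_low=12, n_high=12)
        result = mixed_ancova(
            table, response="onset", between=("group", "sex"),
            within={"region": ("CN", "IC"),
                    "hemisphere": ("left", "right")},
        )
        assert {"group", "sex"} <= set(result.table["effect"])
        sex = result.effect("sex")
        assert sex["df2"] == len(table) - 4


class TestSkewKurtosisScreen:
    def test_normal_calibration(self, rng):
        normal = 0
        n_draws = 400
        for _ in range(n_draws):
            out = skew_kurtosis_screen(rng.standard_normal(62))
            normal += out["classification"] == "normal"
        assert normal / n_draws >= 0.95

    def test_exponential_power(self, rng):
        flagged = 0
        n_draws = 300
        for _ in range(n_draws):
            out = skew_kurtosis_screen(rng.exponential(size=62))
            flagged += out["classification"] == "non-normal"
        assert flagged / n_draws >= 0.90

    def test_symmetric_two_point_zero_skew(self):
        x = np.array([-1.0, 1.0] * 6)
        out = skew_kurtosis_screen(x)
        assert out["z_skew"] == pytest.approx(0.0, abs=1e-12)

    def test_validation(self):
        with pytest.raises(StatsError):
            skew_kurtosis_screen([1.0] * 20)
        with pytest.raises(StatsError):
            skew_kurtosis_screen([1.0, 2.0])


class TestMoodsMedian:
    def test_separated_groups(self):
        out = moods_median_test([1, 2, 3, 4], [5, 6, 7, 8])
        # all of group 1 at/below the grand median, all of group 2 above
        tbl = np.asarray(out["table"], dtype=float)
        assert tbl[0].tolist() == [0.0, 4.0] or tbl[1].tolist() == [0.0, 4.0]
        # hand-computed Pearson chi-square on [[0, 4], [4, 0]]
        assert out["chi2"] == pytest.approx(8.0)

    def test_identical_groups(self):
        out = moods_median_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 25)
        assert moods_median_test(a, b)["chi2"] == pytest.approx(
            moods_median_test(b, a)["chi2"]
        )

    def test_constant_input_raises(self):
        with pytest.raises(StatsError):
            moods_median_test([2, 2], [2, 2])


class TestChiSquare2x2:
    def test_tinnitus_counts(self):
        # 2x2 of tinnitus presence by exposure group
        out = chi_square_2x2([[6, 24], [13, 19]])
        assert out["chi2"] == pytest.approx(3.099, abs=5e-4)

    def test_identical_rows_zero(self):
        out = chi_square_2x2([[7, 3], [7, 3]])
        assert out["chi2"] == pytest.approx(0.0)

    def test_transpose_invariance(self):
        a = chi_square_2x2([[6, 24], [13, 19]])["chi2"]
        b = chi_square_2x2([[6, 13], [24, 19]])["chi2"]
        assert a == pytest.approx(b)

    def test_continuity_correction_switch(self):
        plain = chi_square_2x2([[6, 24], [13, 19]])["chi2"]
        corrected = chi_square_2x2([[6, 24], [13, 19]], correction=True)[
            "chi2"
        ]
        assert corrected < plain

    def test_zero_marginal_raises(self):
        with pytest.raises(StatsError):
            chi_square_2x2([[0, 0], [3, 4]])


class TestMannWhitney:
    def test_complete_separation(self):
        assert mann_whitney_u([1, 2], [3, 4])["U"] == 0.0

    def test_identical_groups(self):
        out = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert out["U"] == pytest.approx(4.5)  # n^2 / 2

    def test_ties_match_pair_enumeration(self):
        a = [1.0, 2.0, 2.0, 5.0, 7.0]
        b = [2.0, 3.0, 5.0, 5.0, 8.0]
        brute = sum(
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x in a
            for y in b
        )
        assert mann_whitney_u(a, b)["U"] == pytest.approx(brute)

    def test_empty_group_raises(self):
        with pytest.raises(StatsError):
            mann_whitney_u([], [1.0])


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)["r"] == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        assert pearson_r(x, -2 * x + 3)["r"] == pytest.approx(-1.0)

    def test_calibration_against_population_value(self, rng):
        rs = []
        for _ in range(800):
            cov = np.array([[1.0, 0.14], [0.14, 1.0]])
            xy = rng.multivariate_normal([0, 0], cov, size=62)
            rs.append(pearson_r(xy[:, 0], xy[:, 1])["r"])
        assert np.mean(rs) == pytest.approx(0.14, abs=0.02)

    def test_zero_variance_raises(self):
        with pytest.raises(StatsError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestPairedTPercentDiff:
    def test_no_change(self):
        a = np.array([1.0, 1.2, 0.8])
        out = paired_t_percent_diff(a, a)
        assert out["percent_mean"] == 0.0
        assert out["t"] == 0.0

    def test_exact_ten_percent_is_degenerate(self):
        a = np.array([1.0, 2.0, 4.0])
        with np.errstate(all="ignore"):
            out = paired_t_percent_diff(a, 1.1 * a)
        assert out["percent_mean"] == pytest.approx(10.0)
        assert out["degenerate"] or not np.isfinite(out["t"]) or out["p"] < 1e-6

    def test_zero_reference_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero reference"):
            out = paired_t_percent_diff([0.0, 1.0, 2.0], [0.1, 1.1, 2.2])
        assert out["n_excluded"] == 1
        assert out["n"] == 2

    def test_power_matches_noncentral_t_oracle(self, rng):
        n = 25
        n_sims = 400
        rejections = 0
        for _ in range(n_sims):
            a = rng.normal(1.0, 0.1, n)
            b = a + rng.normal(0.05, 0.05, n)
            rejections += paired_t_percent_diff(a, b)["p"] < 0.05
        # analytic power for a paired t with effect size 0.05/0.05 = 1
        ncp = 1.0 * np.sqrt(n)
        crit = stats.t.ppf(0.975, n - 1)
        power = stats.nct.sf(crit, n - 1, ncp) + stats.nct.cdf(
            -crit, n - 1, ncp
        )
        assert abs(rejections / n_sims - power) < 0.05


class TestOrderInvariance:
    def test_tests_invariant_to_observation_order(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.3, 1, 18)
        perm_a = rng.permutation(a)
        perm_b = rng.permutation(b)
        assert mann_whitney_u(a, b)["U"] == mann_whitney_u(perm_a, perm_b)["U"]
        assert moods_median_test(a, b)["chi2"] == pytest.approx(
            moods_median_test(perm_a, perm_b)["chi2"]
        )
        pr1 = pearson_r(a, b[:15])
        idx = rng.permutation(15)
        pr2 = pearson_r(a[idx], b[:15][idx])
        assert pr1["r"] == pytest.approx(pr2["r"])
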