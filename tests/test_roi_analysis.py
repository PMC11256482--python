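"""ROI means, two-way ANOVA with Fisher LSD, and correlation matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from morphorad.cohort import make_parameter_table
from morphorad.roi_analysis import (
    anchored_matrix,
    extract_roi_means,
    fisher_z_pvalue,
    pearson_matrix,
    two_way_anova_lsd,
)

from conftest import make_volume


class TestROIMeans:
    def test_constant_map(self):
        vol = make_volume(np.full((4, 4, 4), 3.5))
        roi = np.zeros((4, 4, 4), bool)
        roi[1:3, 1:3, 1:3] = True
        assert extract_roi_means(vol, roi) == 3.5

    def test_toy_values(self):
        vol = make_volume(np.zeros((4, 1, 1)))
        vol.data[:, 0, 0] = [1, 2, 3, 4]
        assert extract_roi_means(vol, np.ones((4, 1, 1), bool)) == 2.5

    def test_matches_brute_force(self, rng):
        data = rng.random((6, 6, 6))
        roi = rng.random((6, 6, 6)) < 0.4
        got = extract_roi_means(make_volume(data), roi)
        total, count = 0.0, 0
        for idx in np.ndindex(6, 6, 6):
            if roi[idx]:
                total += data[idx]
                count += 1
        assert got == pytest.approx(total / count)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            extract_roi_means(make_volume(np.ones((3, 3, 3))), np.zeros((3, 3, 3), bool))

    def test_nan_excluded_with_warning(self):
        data = np.ones((3, 3, 3))
        data[0, 0, 0] = np.nan
        with pytest.warns(UserWarning, match="NaN"):
            got = extract_roi_means(make_volume(data), np.ones((3, 3, 3), bool))
        assert got == 1.0


def balanced_toy_table():
    """2 groups x 3 times x 3 replicates with distinct cell means."""
    rows = []
    vals = {
        ("control", "1M"): [10.0, 11.0, 12.0],
        ("control", "3M"): [12.0, 13.0, 14.0],
        ("control", "6M"): [14.0, 15.0, 16.0],
        ("irradiated", "1M"): [8.0, 9.0, 10.0],
        ("irradiated", "3M"): [12.0, 12.5, 13.5],
        ("irradiated", "6M"): [15.0, 16.5, 18.0],
    }
    for (g, t), ys in vals.items():
        for i, y in enumerate(ys):
            rows.append({"group": g, "timepoint": t, "y": y, "subject_id": f"{g}{i}"})
    return pd.DataFrame(rows)


def anova_ss_oracle(df):
    """Hand-computed sums of squares for the balanced two-way layout."""
    grand = df["y"].mean()
    n_cell = 3
    groups = sorted(df["group"].unique())
    times = sorted(df["timepoint"].unique())
    cell = {(g, t): df[(df.group == g) & (df.timepoint == t)]["y"].mean()
            for g in groups for t in times}
    gmean = {g: df[df.group == g]["y"].mean() for g in groups}
    tmean = {t: df[df.timepoint == t]["y"].mean() for t in times}
    ss_a = n_cell * len(times) * sum((gmean[g] - grand) ** 2 for g in groups)
    ss_b = n_cell * len(groups) * sum((tmean[t] - grand) ** 2 for t in times)
    ss_ab = n_cell * sum(
        (cell[(g, t)] - gmean[g] - tmean[t] + grand) ** 2 for g in groups for t in times
    )
    ss_err = sum(
        (row.y - cell[(row.group, row.timepoint)]) ** 2 for row in df.itertuples()
    )
    df_a, df_b = len(groups) - 1, len(times) - 1
    df_ab = df_a * df_b
    df_err = len(df) - len(groups) * len(times)
    mse = ss_err / df_err
    return {
        "group": (ss_a, df_a, ss_a / df_a / mse),
        "timepoint": (ss_b, df_b, ss_b / df_b / mse),
        "interaction": (ss_ab, df_ab, ss_ab / df_ab / mse),
        "residual": (ss_err, df_err, None),
    }


class TestANOVA:
    def test_matches_hand_computed_ss(self):
        df = balanced_toy_table()
        res = two_way_anova_lsd(df, "y")
        oracle = anova_ss_oracle(df)
        got = {r.effect: (r.sum_sq, r.df, r.F) for r in res.table.itertuples()}
        for effect in ("group", "timepoint", "interaction"):
            ss, dfree, F = oracle[effect]
            assert got[effect][0] == pytest.approx(ss, abs=1e-10)
            assert got[effect][1] == pytest.approx(dfree)
            assert got[effect][2] == pytest.approx(F, abs=1e-10)
        assert res.mse == pytest.approx(oracle["residual"][0] / oracle["residual"][1], abs=1e-12)

    def test_lsd_uses_pooled_mse(self):
        df = balanced_toy_table()
        res = two_way_anova_lsd(df, "y")
        oracle = anova_ss_oracle(df)
        mse = oracle["residual"][0] / oracle["residual"][1]
        row = res.lsd[res.lsd["timepoint"] == "1M"].iloc[0]
        diff = 11.0 - 9.0  # control mean - irradiated mean at 1M
        t_exp = diff / np.sqrt(mse * (1 / 3 + 1 / 3))
        assert row["difference"] == pytest.approx(diff)
        assert row["t"] == pytest.approx(t_exp, abs=1e-10)
        p_exp = 2 * sstats.t.sf(abs(t_exp), oracle["residual"][1])
        assert row["p"] == pytest.approx(p_exp, abs=1e-12)

    def test_constant_response_flagged(self):
        df = balanced_toy_table()
        df["y"] = 7.0
        res = two_way_anova_lsd(df, "y")
        assert res.table["F"].isna().all()

    def test_time_effect_invariant_to_group_relabeling_within_cells(self):
        df = balanced_toy_table()
        res1 = two_way_anova_lsd(df, "y")
        # swap the group labels of entire cells (exchange cell assignments)
        swapped = df.copy()
        swapped["group"] = swapped["group"].map(
            {"control": "irradiated", "irradiated": "control"}
        )
        res2 = two_way_anova_lsd(swapped, "y")
        t1 = res1.table[res1.table.effect == "timepoint"].iloc[0]
        t2 = res2.table[res2.table.effect == "timepoint"].iloc[0]
        assert t1.F == pytest.approx(t2.F, abs=1e-10)

    def test_empty_cell_named_in_error(self):
        df = balanced_toy_table()
        df = df[~((df.group == "irradiated") & (df.timepoint == "3M"))]
        with pytest.raises(ValueError, match="irradiated"):
            two_way_anova_lsd(df, "y")


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"JD": x, "MD": 2 * x})
        cm = pearson_matrix(df, parameters=("JD", "MD"))
        assert cm.r.loc["JD", "MD"] == pytest.approx(1.0)
        assert cm.p.loc["JD", "MD"] == 0.0

    def test_orthogonal_zero_correlation(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0] * 2)
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0] * 2)  # orthogonal to x, mean centred
        df = pd.DataFrame({"JD": x, "MD": y})
        cm = pearson_matrix(df, parameters=("JD", "MD"))
        assert cm.r.loc["JD", "MD"] == pytest.approx(0.0, abs=1e-12)
        assert cm.p.loc["JD", "MD"] == pytest.approx(1.0, abs=1e-12)

    def test_fisher_z_against_normal_cdf(self):
        """r=0.6, n=10: p = 2 * (1 - Phi(atanh(0.6) * sqrt(7))) to 1e-12."""
        z = np.arctanh(0.6) * np.sqrt(7)
        expected = 2 * (1 - sstats.norm.cdf(z))
        assert fisher_z_pvalue(0.6, 10) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_unit_diagonal_and_bounds(self, rng):
        df = pd.DataFrame(rng.standard_normal((20, 5)),
                          columns=["JD", "CBV", "MD", "AD", "RD"])
        cm = pearson_matrix(df)
        assert np.allclose(cm.r.values, cm.r.values.T)
        assert np.allclose(np.diag(cm.r.values), 1.0)
        assert (np.abs(cm.r.values) <= 1.0 + 1e-12).all()

    def test_affine_rescaling_invariance(self, rng):
        df = pd.DataFrame(rng.standard_normal((15, 3)), columns=["JD", "CBV", "MD"])
        cm1 = pearson_matrix(df, parameters=("JD", "CBV", "MD"))
        df2 = df.copy()
        df2["CBV"] = -4.0 * df2["CBV"] + 100.0
        cm2 = pearson_matrix(df2, parameters=("JD", "CBV", "MD"))
        assert abs(cm1.r.loc["JD", "CBV"]) == pytest.approx(abs(cm2.r.loc["JD", "CBV"]), abs=1e-12)
        assert cm1.p.loc["JD", "CBV"] == pytest.approx(cm2.p.loc["JD", "CBV"], abs=1e-12)

    def test_small_n_p_undefined(self):
        df = pd.DataFrame({"JD": [1.0, 2.0, 3.0], "MD": [2.0, 2.5, 4.0]})
        with pytest.warns(UserWarning, match="n="):
            cm = pearson_matrix(df, parameters=("JD", "MD"))
        assert np.isfinite(cm.r.loc["JD", "MD"])
        assert np.isnan(cm.p.loc["JD", "MD"])


class TestHeatmap:
    def test_heatmap_written(self, tmp_path, rng):
        from morphorad.roi_analysis import plot_correlation_heatmap

        df = pd.DataFrame(rng.standard_normal((12, 3)), columns=["JD", "CBV", "MD"])
        cm = pearson_matrix(df, parameters=("JD", "CBV", "MD"))
        path = plot_correlation_heatmap(cm, tmp_path / "heat.png")
        assert path.exists() and path.stat().st_size > 0


class TestFisherZProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(r=st.floats(-0.999, 0.999), n=st.integers(5, 500))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_p_symmetric_and_monotone_in_magnitude(self, r, n):
        """p(r) = p(-r), p is within [0, 1], and a stronger |r| at fixed n never
        raises the p-value."""
        p = fisher_z_pvalue(r, n)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(fisher_z_pvalue(-r, n), abs=1e-15)
        stronger = fisher_z_pvalue(min(0.9995, abs(r) * 1.2 + 1e-4), n)
        assert stronger <= p + 1e-12


class TestPlantedCoupling:
    def test_anchored_matrix_recovers_planted_jd_md_correlation(self):
        """The planted severity coupling yields a significant JD~MD correlation
        at the anchored timepoint, with the planted (positive) sign, in >= 80%
        of simulations."""
        hits = 0
        n_sim = 25
        for seed in range(n_sim):
            table = make_parameter_table(n_control=6, n_irradiated=6, seed=seed)
            cm = anchored_matrix(table, anchor_param="JD", anchor_time="1M",
                                 parameters=("MD",))
            r = cm.r.loc["JD@1M", "MD@1M"]
            p = cm.p.loc["JD@1M", "MD@1M"]
            hits += (p < 0.05) and (r > 0)
        assert hits >= 0.8 * n_sim

    def test_null_table_no_systematic_group_difference(self):
        """With couplings disabled the two groups are exchangeable draws."""
        table = make_parameter_table(seed=11, couple_md=False)
        table = table[table.timepoint == "3M"]  # no effects planted at 3M
        a = table[table.group == "control"]["MD"]
        b = table[table.group == "irradiated"]["MD"]
        assert sstats.ttest_ind(a, b).pvalue > 0.01
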