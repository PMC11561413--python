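import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from sparscreen import (
    AnovaTable,
    DesignSpec,
    ObservationTable,
    SyntheticConfig,
    combined_matrix_report,
    fisher_lsd,
    generate,
    pearson_matrix,
    rcbd_anova,
    star_code,
)
from sparscreen.inference import corr_star_code
from sparscreen.trait_model import TraitMeanTable, ValidationError


def _obs_from_array(y, hybrids, treatments, trait="PH"):
    """y shaped (hybrid, treatment, replicate)."""
    rows = []
    for i, h in enumerate(hybrids):
        for j, t in enumerate(treatments):
            for k in range(y.shape[2]):
                rows.append(dict(hybrid=h, treatment=t, replicate=k + 1, trait=trait,
                                 value=float(y[i, j, k])))
    return ObservationTable(pd.DataFrame(rows))


def _brute_force_ss(y):
    """Definitional sums of squared deviations of group means, as an
    independent oracle for the balanced RCBD partition."""
    h, t, r = y.shape
    grand = y.mean()
    ss_block = h * t * ((y.mean(axis=(0, 1)) - grand) ** 2).sum()
    ss_treat = h * r * ((y.mean(axis=(0, 2)) - grand) ** 2).sum()
    ss_hyb = t * r * ((y.mean(axis=(1, 2)) - grand) ** 2).sum()
    cell = y.mean(axis=2)
    ss_int = r * (
        (cell - y.mean(axis=(1, 2))[:, None] - y.mean(axis=(0, 2))[None, :] + grand) ** 2
    ).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_block - ss_treat - ss_hyb - ss_int
    return dict(block=ss_block, treatment=ss_treat, hybrid=ss_hyb,
                interaction=ss_int, error=ss_err, total=ss_total)


class TestRcbdAnova:
    def test_degrees_of_freedom_for_full_design(self, synthetic_obs, design):
        at = rcbd_anova(synthetic_obs, "Phot", design)
        assert list(at.table["df"]) == [3, 1, 5, 5, 33, 47]

    def test_noise_free_data_has_zero_error_ss(self, noiseless_obs, design):
        at = rcbd_anova(noiseless_obs, "Phot", design)
        assert at.row("error")["SS"] == pytest.approx(0.0, abs=1e-6)
        assert np.isinf(at.row("treatment")["F"])
        assert at.p("treatment") == 0.0

    def test_toy_dataset_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.normal(10, 2, size=(2, 2, 2))
        obs = _obs_from_array(y, ["H1", "H2"], ["T1", "T2"])
        d = DesignSpec(hybrids=("H1", "H2"), treatments=("T1", "T2"), n_replicates=2)
        at = rcbd_anova(obs, "PH", d)
        oracle = _brute_force_ss(y)
        assert at.row("treatment")["SS"] == pytest.approx(oracle["treatment"], rel=1e-10)
        assert at.row("hybrid")["SS"] == pytest.approx(oracle["hybrid"], rel=1e-10)
        assert at.row("block")["SS"] == pytest.approx(oracle["block"], rel=1e-10)
        assert at.row("treatment:hybrid")["SS"] == pytest.approx(oracle["interaction"], rel=1e-10)
        assert at.row("error")["SS"] == pytest.approx(oracle["error"], rel=1e-8, abs=1e-10)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_ss_partition_sums_to_total(self, seed):
        rng = np.random.default_rng(seed)
        h, t, r = rng.integers(2, 5), 2, rng.integers(2, 5)
        y = rng.normal(50, 10, size=(h, t, r))
        obs = _obs_from_array(y, [f"H{i}" for i in range(h)], ["T1", "T2"])
        d = DesignSpec(
            hybrids=tuple(f"H{i}" for i in range(h)), treatments=("T1", "T2"),
            n_replicates=int(r),
        )
        at = rcbd_anova(obs, "PH", d)
        parts = at.table.loc[["block", "treatment", "hybrid", "treatment:hybrid", "error"], "SS"]
        assert parts.sum() == pytest.approx(at.row("total")["SS"], rel=1e-8)
        assert at.table.loc[["block", "treatment", "hybrid", "treatment:hybrid", "error"], "df"].sum() \
            == at.row("total")["df"]

    def test_statsmodels_cross_check(self, synthetic_obs, design):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols

        frame = synthetic_obs.subset(trait="Phot").rename(columns={"replicate": "block"})
        model = ols("value ~ C(block) + C(treatment) * C(hybrid)", data=frame).fit()
        expected = sm.stats.anova_lm(model, typ=1)
        at = rcbd_anova(synthetic_obs, "Phot", design)
        assert at.row("treatment")["SS"] == pytest.approx(expected.loc["C(treatment)", "sum_sq"])
        assert at.row("hybrid")["SS"] == pytest.approx(expected.loc["C(hybrid)", "sum_sq"])
        assert at.row("treatment:hybrid")["SS"] == pytest.approx(
            expected.loc["C(treatment):C(hybrid)", "sum_sq"]
        )
        assert at.row("error")["SS"] == pytest.approx(expected.loc["Residual", "sum_sq"])
        assert at.p("treatment") == pytest.approx(expected.loc["C(treatment)", "PR(>F)"])

    def test_treatment_f_equals_squared_paired_t_in_one_hybrid_limit(self):
        """With one hybrid and two treatments the treatment F test collapses
        to the paired (block-wise) two-level t-test: F = t^2."""
        rng = np.random.default_rng(8)
        y = rng.normal(20, 3, size=(1, 2, 6))
        obs = _obs_from_array(y, ["H1"], ["T1", "T2"])
        d = DesignSpec(hybrids=("H1",), treatments=("T1", "T2"), n_replicates=6)
        at = rcbd_anova(obs, "PH", d)
        t_stat = stats.ttest_rel(y[0, 0], y[0, 1]).statistic
        assert at.row("treatment")["F"] == pytest.approx(t_stat**2, rel=1e-10)

    def test_unbalanced_data_rejected(self, synthetic_obs, design):
        frame = synthetic_obs.frame
        dropped = ObservationTable(frame.drop(frame.index[0]))
        with pytest.raises(ValidationError, match="unbalanced"):
            rcbd_anova(dropped, frame.iloc[0]["trait"], design)


class TestStarCodes:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.05, "NS"), (0.2, "NS"),
         (0.001, "**"), (0.01, "*")],
    )
    def test_three_tier_codes(self, p, expected):
        assert star_code(p) == expected

    @pytest.mark.parametrize(
        "p,expected", [(0.0005, "**"), (0.005, "*"), (0.03, "NS"), (0.01, "NS")]
    )
    def test_correlation_legend_codes(self, p, expected):
        assert corr_star_code(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            star_code(1.5)


def _manual_anova(trait, ms_error, df_error, p_factor):
    table = pd.DataFrame(
        {
            "SS": [0, 0, 0, 0, ms_error * df_error, 0],
            "df": [3, 1, 5, 5, df_error, 47],
            "MS": [np.nan, np.nan, np.nan, np.nan, ms_error, np.nan],
            "F": np.nan,
            "p": [0.5, p_factor, p_factor, 0.5, np.nan, np.nan],
            "stars": "",
        },
        index=pd.Index(["block", "treatment", "hybrid", "treatment:hybrid", "error", "total"],
                       name="source"),
    )
    return AnovaTable(trait_code=trait, table=table)


class TestFisherLsd:
    def test_lsd_value_from_t_quantile(self, synthetic_obs, design):
        # MS_error = 4 with 8 units per level makes sqrt(2 MS/n) = 1, so the
        # LSD is exactly the two-sided t quantile at 33 error df.
        anova = _manual_anova("Phot", ms_error=4.0, df_error=33, p_factor=0.001)
        res = fisher_lsd(anova, synthetic_obs, "Phot", "hybrid", design)
        assert not res.protected_skip
        assert res.lsd_value == pytest.approx(stats.t.ppf(0.975, 33), abs=1e-9)
        assert res.lsd_value == pytest.approx(2.0345, abs=5e-4)

    def test_non_significant_factor_is_protected_skip(self, synthetic_obs, design):
        anova = _manual_anova("Phot", ms_error=4.0, df_error=33, p_factor=0.8)
        res = fisher_lsd(anova, synthetic_obs, "Phot", "hybrid", design)
        assert res.protected_skip and res.grouping is None

    def test_equal_means_share_one_letter(self, noiseless_obs, design):
        # same LSD construction; noiseless LN means differ by at most 0.5
        anova = _manual_anova("LN", ms_error=4.0, df_error=33, p_factor=0.001)
        res = fisher_lsd(anova, noiseless_obs, "LN", "hybrid", design)
        letters = set(res.grouping.values())
        assert letters == {"a"}

    def test_letters_separate_beyond_lsd(self, synthetic_obs, design):
        at = rcbd_anova(synthetic_obs, "Phot", design)
        res = fisher_lsd(at, synthetic_obs, "Phot", "treatment", design)
        assert not res.protected_skip
        # drought vs control photosynthesis differ hugely: disjoint letters
        letters = list(res.grouping.values())
        assert set(letters[0]).isdisjoint(letters[1])

    def test_grouping_shares_letter_iff_within_lsd(self, synthetic_obs, design):
        at = rcbd_anova(synthetic_obs, "Phot", design)
        res = fisher_lsd(at, synthetic_obs, "Phot", "hybrid", design)
        if res.protected_skip:
            pytest.skip("hybrid factor not significant for this seed")
        means = res.means
        for a in means.index:
            for b in means.index:
                shares = bool(set(res.grouping[a]) & set(res.grouping[b]))
                assert shares == (abs(means[a] - means[b]) <= res.lsd_value + 1e-9)


class TestPearson:
    def _obs(self, columns):
        rows = []
        for trait, values in columns.items():
            for i, v in enumerate(values):
                rows.append(dict(hybrid="H1", treatment="T1", replicate=i + 1,
                                 trait=trait, value=float(v)))
        return ObservationTable(pd.DataFrame(rows))

    def test_exact_linear_relation(self):
        x = [1, 2, 3, 4, 5]
        cm = pearson_matrix(self._obs({"PH": x, "LA": [2 * v + 1 for v in x]}), "T1")
        assert cm.r.loc["PH", "LA"] == pytest.approx(1.0)
        assert cm.p.loc["PH", "LA"] < 1e-8

    def test_hand_computed_r_and_p(self):
        cm = pearson_matrix(self._obs({"PH": [1, 2, 3, 4], "LA": [1, 3, 2, 4]}), "T1")
        assert cm.r.loc["PH", "LA"] == pytest.approx(0.8)
        assert cm.p.loc["PH", "LA"] == pytest.approx(0.2)

    def test_constant_trait_is_undefined_not_zero(self):
        cm = pearson_matrix(self._obs({"PH": [1, 2, 3, 4], "LA": [5, 5, 5, 5]}), "T1")
        assert np.isnan(cm.r.loc["PH", "LA"])
        assert cm.stars.loc["PH", "LA"] == "NA"

    def test_matches_covariance_ratio_oracle(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=30), rng.normal(size=30)
        cm = pearson_matrix(self._obs({"PH": x, "LA": y}), "T1")
        expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert cm.r.loc["PH", "LA"] == pytest.approx(expected, abs=1e-12)

    def test_full_trial_matrix_shape_and_symmetry(self, synthetic_obs):
        cm = pearson_matrix(synthetic_obs, "D")
        assert cm.r.shape == (22, 22) and cm.n == 24
        np.testing.assert_allclose(cm.r.to_numpy(), cm.r.to_numpy().T)
        assert (np.diag(cm.r.to_numpy()) == 1.0).all()
        assert (cm.r.abs().to_numpy() <= 1 + 1e-12).all()


class TestCombinedReport:
    def test_swapped_inputs_transpose_off_diagonal(self, synthetic_obs):
        cm_d = pearson_matrix(synthetic_obs, "D")
        cm_c = pearson_matrix(synthetic_obs, "C")
        a = combined_matrix_report(cm_d, cm_c)
        b = combined_matrix_report(cm_c, cm_d)
        assert a.shape == (22, 22)
        assert (np.diag(a.to_numpy()) == "1.000").all()
        assert a.loc["PH", "LA"] == b.loc["LA", "PH"]
        assert a.loc["LA", "PH"] == b.loc["PH", "LA"]
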