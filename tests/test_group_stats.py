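import subprocess
import shutil

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from langlat import group_stats as gs


def simulate_measures(
    rng,
    n_subjects=20,
    effect=1.0,
    subject_sd=0.3,
    froi_sd=0.15,
    resid_sd=0.4,
    groups=("adult",),
):
    """Two-condition measure table with crossed subject/fROI random intercepts."""
    frois = ["IFG", "IFGorb", "MFG", "AntTemp", "PostTemp"]
    bf = {f: rng.normal(0, froi_sd) for f in frois}
    rows = []
    sid = 0
    for group in groups:
        for _ in range(n_subjects):
            bs = rng.normal(0, subject_sd)
            age = rng.uniform(*{"early": (4, 7), "middle": (7, 11), "late": (12, 15), "adult": (19, 45)}[group])
            for f in frois:
                for cond, mu in (("Control", 0.0), ("Language", effect)):
                    rows.append(
                        {
                            "subject": f"s{sid}",
                            "group": group,
                            "age": age,
                            "froi": f,
                            "condition": cond,
                            "psc": mu + bs + bf[f] + rng.normal(0, resid_sd),
                        }
                    )
            sid += 1
    return pd.DataFrame(rows)


class TestSidak:
    def test_closed_form(self):
        assert np.isclose(gs.sidak_adjust([0.05], m=3)[0], 0.142625, atol=1e-6)
        assert gs.sidak_adjust([0.0], m=5)[0] == 0.0
        assert gs.sidak_adjust([1.0], m=2)[0] == 1.0

    def test_never_decreases_p(self):
        p = np.linspace(0, 1, 21)
        adj = gs.sidak_adjust(p, m=3)
        assert np.all(adj >= p)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_clipped(self, ps):
        adj = gs.sidak_adjust(ps)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            gs.sidak_adjust([1.2])


class TestConditionModel:
    def test_recovers_planted_effect(self):
        df = simulate_measures(np.random.default_rng(0), effect=1.0)
        eff = gs.fit_condition_model(df)
        assert abs(eff.b - 1.0) < 3 * eff.se
        assert eff.p < 1e-6
        assert eff.structure == "subject+froi"

    def test_single_condition_rejected(self):
        df = simulate_measures(np.random.default_rng(0))
        with pytest.raises(ValueError):
            gs.fit_condition_model(df[df["condition"] == "Language"])

    def test_component_subsets_fit_separately(self):
        df = simulate_measures(np.random.default_rng(1), effect=0.8)
        full = gs.fit_condition_model(df)
        frontal = gs.fit_condition_model(df, subset="frontal")
        temporal = gs.fit_condition_model(df, subset="temporal")
        for eff in (frontal, temporal):
            assert abs(eff.b - 0.8) < 4 * eff.se
        assert frontal.b != full.b

    def test_matches_lme4_reml(self, tmp_path):
        # independent oracle: lme4/lmerTest via Rscript on the same table
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = simulate_measures(np.random.default_rng(3), effect=0.6)
        csv = tmp_path / "mm.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "mm.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- lmer(psc ~ condition + (1|subject) + (1|froi), data=d, REML=TRUE)\n"
            "s <- summary(m)$coefficients\n"
            "cat(sprintf('%.8f %.8f', s[2,1], s[2,2]))\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, check=True)
        b_r, se_r = map(float, out.stdout.split())
        eff = gs.fit_condition_model(df)
        assert abs(eff.b - b_r) < 1e-4
        assert abs(eff.se - se_r) < 1e-4


class TestHemisphereModels:
    def _hemi_df(self, rng, lh_mu, rh_mu, n=20):
        rows = []
        for s in range(n):
            bs = rng.normal(0, 0.2)
            rows.append({"subject": f"s{s}", "hemisphere": "LH", "value": lh_mu + bs + rng.normal(0, 0.2)})
            rows.append({"subject": f"s{s}", "hemisphere": "RH", "value": rh_mu + bs + rng.normal(0, 0.2)})
        return pd.DataFrame(rows)

    def test_symmetric_data_gives_null_effect(self):
        rng = np.random.default_rng(0)
        df = self._hemi_df(rng, 0.8, 0.8)
        effs = gs.fit_hemisphere_models(df, df.copy())
        assert abs(effs["magnitude"].stat) < 3

    def test_lateralized_data_detected(self):
        rng = np.random.default_rng(1)
        df = self._hemi_df(rng, 1.0, 0.5)
        effs = gs.fit_hemisphere_models(df, df.copy())
        assert effs["magnitude"].b > 0 and effs["magnitude"].p < 0.05

    def test_hemisphere_swap_flips_sign(self):
        rng = np.random.default_rng(2)
        df = self._hemi_df(rng, 1.0, 0.4)
        swapped = df.assign(hemisphere=df["hemisphere"].map({"LH": "RH", "RH": "LH"}))
        b_fwd = gs.fit_hemisphere_models(df, df.copy())["magnitude"].b
        b_rev = gs.fit_hemisphere_models(swapped, swapped.copy())["magnitude"].b
        assert np.isclose(b_fwd, -b_rev, atol=1e-8)

    def test_missing_hemisphere_rejected(self):
        df = self._hemi_df(np.random.default_rng(0), 1.0, 0.5)
        with pytest.raises(ValueError):
            gs.fit_hemisphere_models(df[df["hemisphere"] == "LH"], df)


class TestGroupComparisons:
    def _li_df(self, rng, means, n=20):
        rows = []
        for g, mu in means.items():
            for i in range(n):
                rows.append({"subject": f"{g}{i}", "group": g, "li": mu + rng.normal(0, 0.15)})
        return pd.DataFrame(rows)

    def test_planted_group_differences_detected(self):
        rng = np.random.default_rng(0)
        df = self._li_df(rng, {"early": 0.0, "middle": 0.2, "late": 0.4, "adult": 0.5})
        comps = gs.compare_li_across_groups(df)
        labels = {c.label for c in comps}
        assert labels == {"Early vs Adult", "Middle vs Adult", "Late vs Adult"}
        early = next(c for c in comps if c.label == "Early vs Adult")
        assert early.b < 0 and early.p_adjusted < 0.001

    def test_adjusted_p_never_below_raw(self):
        df = self._li_df(np.random.default_rng(1), {"early": 0.1, "adult": 0.12})
        for c in gs.compare_li_across_groups(df):
            assert c.p_adjusted >= c.p

    def test_missing_adult_rejected(self):
        df = self._li_df(np.random.default_rng(0), {"early": 0.1, "late": 0.2})
        with pytest.raises(ValueError):
            gs.compare_li_across_groups(df)

    def test_single_group_rejected(self):
        df = self._li_df(np.random.default_rng(0), {"adult": 0.2})
        with pytest.raises(ValueError):
            gs.compare_li_across_groups(df)


class TestInteractionModel:
    def _mag_df(self, rng, bias_by_group, n=15, contrast=0.8):
        rows = []
        sid = 0
        for g, bias in bias_by_group.items():
            for _ in range(n):
                bs = rng.normal(0, 0.15)
                slope = rng.normal(0, 0.1)
                for f in ["IFG", "MFG", "AntTemp"]:
                    for hemi, mu in (("LH", contrast), ("RH", bias * contrast)):
                        rows.append(
                            {
                                "subject": f"s{sid}",
                                "group": g,
                                "hemisphere": hemi,
                                "froi": f,
                                "value": mu + bs + (slope if hemi == "LH" else 0) + rng.normal(0, 0.2),
                            }
                        )
                sid += 1
        return pd.DataFrame(rows)

    def test_equal_bias_gives_null_interaction(self):
        df = self._mag_df(np.random.default_rng(0), {"early": 0.7, "adult": 0.7})
        comps, _ = gs.fit_interaction_model(df)
        assert all(abs(c.stat) < 3 for c in comps)

    def test_differing_bias_detected_with_correct_sign(self):
        df = self._mag_df(np.random.default_rng(1), {"early": 1.0, "adult": 0.4}, n=25)
        comps, _ = gs.fit_interaction_model(df)
        early = next(c for c in comps if c.label.startswith("Early"))
        assert early.b < 0 and early.p_adjusted < 0.05  # children less lateralized than planted adults

    def test_hemisphere_swap_flips_interaction_sign(self):
        rng = np.random.default_rng(2)
        df = self._mag_df(rng, {"early": 1.0, "adult": 0.4}, n=10)
        swapped = df.assign(hemisphere=df["hemisphere"].map({"LH": "RH", "RH": "LH"}))
        b_fwd = gs.fit_interaction_model(df)[0][0].b
        b_rev = gs.fit_interaction_model(swapped)[0][0].b
        assert np.sign(b_fwd) == -np.sign(b_rev)


class TestContinuousAge:
    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(0)
        df = simulate_measures(rng, n_subjects=15, effect=0.0, groups=("early", "middle", "late"))
        df["psc"] = df["psc"] + 0.05 * df["age"]
        eff = gs.fit_continuous_age_model(df)
        assert abs(eff.b - 0.05) < 3 * eff.se
        assert eff.p < 0.05

    def test_null_slope_not_flagged(self):
        df = simulate_measures(np.random.default_rng(1), n_subjects=15, effect=0.0, groups=("early", "late"))
        eff = gs.fit_continuous_age_model(df)
        assert abs(eff.b) < 4 * eff.se

    def test_adult_rows_rejected(self):
        df = simulate_measures(np.random.default_rng(0), groups=("early", "adult"))
        with pytest.raises(ValueError, match="children-only"):
            gs.fit_continuous_age_model(df)

    def test_constant_age_rejected(self):
        df = simulate_measures(np.random.default_rng(0), groups=("early",))
        df["age"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            gs.fit_continuous_age_model(df)


class TestModelSpecAndMotion:
    def test_motion_covariate_appended_exactly_once(self):
        spec = gs.ModelSpec(response="li", fixed_effects=["C(group)"])
        out = gs.add_motion_covariate(spec, {"s1": 3, "s2": 7})
        out = gs.add_motion_covariate(out, {"s1": 3, "s2": 7})
        assert out.covariates.count("motion_outliers") == 1
        assert "motion_outliers" in out.formula()

    def test_zero_variance_covariate_dropped_with_warning(self):
        spec = gs.ModelSpec(response="li", fixed_effects=["C(group)"])
        with pytest.warns(UserWarning, match="zero variance"):
            out = gs.add_motion_covariate(spec, {"s1": 2, "s2": 2})
        assert "motion_outliers" not in out.covariates

    def test_orthogonal_covariate_leaves_estimates_unchanged(self):
        # balanced design: group indicator and covariate exactly orthogonal
        import statsmodels.formula.api as smf

        n = 40
        group = np.repeat([0.0, 1.0], n // 2)
        motion = np.tile([-1.0, 1.0], n // 2)  # orthogonal to group by construction
        rng = np.random.default_rng(0)
        y = 0.5 * group + 0.3 * motion + rng.normal(0, 0.2, n)
        df = pd.DataFrame({"y": y, "group": group, "motion_outliers": motion})
        b_without = smf.ols("y ~ group", data=df).fit().params["group"]
        b_with = smf.ols("y ~ group + motion_outliers", data=df).fit().params["group"]
        assert abs(b_with - b_without) < 1e-6
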