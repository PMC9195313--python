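"""Trial tables, mixed-model fitting, Holm step-down and responsiveness."""
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from facegamma import group_stats as gs


def simulate_trials(rng, beta_group=5.0, sd_patient=2.0, sd_resid=8.0,
                    n_patients=6, n_trials=200, beta_face=0.0):
    """Trials from the generating model of the mixed analysis: a group offset
    for group O, a patient-level random intercept and i.i.d. residuals."""
    rows = []
    for i in range(n_patients):
        group = "O" if i < n_patients // 2 else "M"
        intercept = rng.normal(0.0, sd_patient)
        cats = rng.choice(["caucasian", "famous", "mosaic"], size=n_trials)
        eff = (beta_group if group == "O" else 0.0) + intercept
        vals = eff + beta_face * (cats != "mosaic") + \
            rng.normal(0.0, sd_resid, n_trials)
        for c, v in zip(cats, vals):
            rows.append(dict(patient=f"P{i:02d}", group=group,
                             hemisphere="L" if i % 2 else "R",
                             region="amygdala", channel=f"C{i}", category=c,
                             amplitude_uv=v))
    return pd.DataFrame(rows)


class TestBuildTrialTable:
    def test_row_counts_and_picture_column(self, rng):
        df = simulate_trials(rng, n_trials=50)
        t1 = gs.build_trial_table(df, "amplitude_uv", model=1)
        assert len(t1) == len(df)
        assert set(t1["picture"]) == {"face", "mosaic"}
        assert t1.groupby("group").size().eq(
            df.groupby("group").size()).all()

    def test_model2_drops_mosaics(self, rng):
        df = simulate_trials(rng, n_trials=50)
        t2 = gs.build_trial_table(df, "amplitude_uv", model=2)
        assert "mosaic" not in set(t2["category"])

    def test_missing_metadata_rejected(self, rng):
        df = simulate_trials(rng, n_trials=5)
        df.loc[3, "region"] = np.nan
        with pytest.raises(ValueError, match="metadata"):
            gs.build_trial_table(df, "amplitude_uv")


class TestHolm:
    def test_worked_example(self):
        np.testing.assert_allclose(gs.holm_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.06, 0.06])

    def test_trivial_cases(self):
        assert gs.holm_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(gs.holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gs.holm_adjust([0.5, 1.2])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_matches_stepdown_decision_oracle(self, ps):
        """Adjusted p-values reproduce the raw step-down decisions
        (reject while p_(i) <= alpha/(m-i+1)) at every alpha."""
        adj = gs.holm_adjust(ps)
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        for alpha in (0.01, 0.05, 0.1, 0.5):
            expected = np.zeros(m, dtype=bool)
            for rank, idx in enumerate(order):
                if ps[idx] <= alpha / (m - rank):
                    expected[idx] = True
                else:
                    break
            np.testing.assert_array_equal(adj <= alpha, expected)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=10)
        ours = gs.holm_adjust(p)
        theirs = multipletests(p, method="holm")[1]
        np.testing.assert_allclose(ours, theirs)


class TestFitLme:
    def test_group_effect_recovered_within_ci(self, rng):
        df = simulate_trials(rng)
        table = gs.build_trial_table(df, "amplitude_uv", model=1)
        spec = gs.ModelSpec("amplitude_uv", "picture", include_peaks=False)
        fit = gs.fit_lme(table, spec)
        row = fit.terms.set_index("term").loc["C(group)"]
        assert row["ci_low"] <= 5.0 <= row["ci_high"]

    def test_row_order_invariance(self, rng):
        df = simulate_trials(rng, n_trials=60)
        table = gs.build_trial_table(df, "amplitude_uv", model=1)
        spec = gs.ModelSpec("amplitude_uv", "picture", include_peaks=False)
        a = gs.fit_lme(table, spec).terms
        b = gs.fit_lme(table.sample(frac=1.0, random_state=1), spec).terms
        np.testing.assert_allclose(a["beta"].astype(float),
                                   b["beta"].astype(float), rtol=1e-6)

    def test_degenerate_random_effect_matches_ols(self, rng):
        import statsmodels.formula.api as smf
        df = simulate_trials(rng, sd_patient=0.0, n_trials=150)
        table = gs.build_trial_table(df, "amplitude_uv", model=1)
        spec = gs.ModelSpec("amplitude_uv", "picture", include_peaks=False)
        fit = gs.fit_lme(table, spec)
        ols = smf.ols(spec.formula, table).fit()
        ours = fit.terms.set_index("term")["beta"]
        assert ours["C(picture)"] == pytest.approx(
            ols.params["C(picture)[T.mosaic]"], abs=0.1)

    def test_matches_r_lmertest_oracle(self, rng, tmp_path):
        """Independent cross-check of the REML fit against lme4/lmerTest."""
        df = simulate_trials(rng, n_trials=100)
        table = gs.build_trial_table(df, "amplitude_uv", model=1)
        spec = gs.ModelSpec("amplitude_uv", "picture", include_peaks=False)
        fit = gs.fit_lme(table, spec)
        csv = tmp_path / "trials.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages({{library(lme4); library(lmerTest)}})
d <- read.csv("{csv}")
m <- lmer(value ~ group + picture + hemisphere + group:picture + (1|patient),
          data=d, REML=TRUE)
co <- coef(summary(m))
write.csv(data.frame(term=rownames(co), est=co[,"Estimate"],
                     se=co[,"Std. Error"], p=co[,"Pr(>|t|)"]),
          "{tmp_path / 'ref.csv'}", row.names=FALSE)
""")
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "ref.csv").set_index("term")
        ours = fit.terms.set_index("term")
        pairs = {"C(group)": "groupO", "C(picture)": "picturemosaic",
                 "C(hemisphere)": "hemisphereR"}
        for term, rterm in pairs.items():
            assert ours.loc[term, "beta"] == pytest.approx(
                ref.loc[rterm, "est"], rel=0.02, abs=0.02)
        # within-patient term: df agree, so p-values do too
        assert ours.loc["C(picture)", "p_raw"] == pytest.approx(
            ref.loc["picturemosaic", "p"], rel=0.05, abs=0.005)

    def test_interaction_triggers_tukey_posthoc(self, rng):
        df = simulate_trials(rng, beta_group=0.0, sd_patient=0.5,
                             sd_resid=4.0, n_trials=150)
        # build a strong group x picture interaction by hand
        face = df["category"] != "mosaic"
        df.loc[face & (df["group"] == "O"), "amplitude_uv"] += 6.0
        table = gs.build_trial_table(df, "amplitude_uv", model=1)
        spec = gs.ModelSpec("amplitude_uv", "picture", include_peaks=False)
        fit = gs.fit_lme(table, spec)
        inter_p = fit.terms.set_index("term").loc["C(group):C(picture)",
                                                  "p_raw"]
        assert inter_p < 0.05
        assert len(fit.contrasts) == 2  # one contrast per group
        o_row = fit.contrasts[fit.contrasts["group"] == "O"].iloc[0]
        assert abs(o_row["beta"]) > abs(
            fit.contrasts[fit.contrasts["group"] == "M"].iloc[0]["beta"])
        assert o_row["p_tukey"] < 0.05

    def test_empty_cells_rejected(self, rng):
        df = simulate_trials(rng, n_trials=30)
        df = df[~((df["group"] == "M") & (df["category"] == "mosaic"))]
        table = gs.build_trial_table(df, "amplitude_uv", model=1)
        spec = gs.ModelSpec("amplitude_uv", "picture", include_peaks=False)
        with pytest.raises(ValueError, match="cells"):
            gs.fit_lme(table, spec)


class TestClassifyResponsive:
    def contact_rows(self, rng, erp_amp=0.0, n=80):
        rows = []
        for peak in ("N110", "N240", "N360"):
            amp = erp_amp if peak == "N240" else 0.0
            for v in amp + rng.normal(0, 1.0, n):
                rows.append(dict(peak=peak, amplitude_uv=v))
        return pd.DataFrame(rows)

    def test_erp_only_contact(self, rng):
        flags = gs.classify_responsive(self.contact_rows(rng, erp_amp=2.0),
                                       rng.normal(0.0, 1.0, 80))
        assert flags == {"erp_responsive": True, "gamma_responsive": False}

    def test_gamma_only_contact(self, rng):
        flags = gs.classify_responsive(self.contact_rows(rng, erp_amp=0.0),
                                       rng.normal(2.0, 1.0, 80))
        assert flags == {"erp_responsive": False, "gamma_responsive": True}

    def test_noise_contact_rarely_flagged(self, rng):
        hits_erp = hits_gamma = 0
        for _ in range(40):
            flags = gs.classify_responsive(self.contact_rows(rng),
                                           rng.normal(0.0, 1.0, 80))
            hits_erp += flags["erp_responsive"]
            hits_gamma += flags["gamma_responsive"]
        assert hits_erp <= 8 and hits_gamma <= 8

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            gs.classify_responsive(pd.DataFrame(columns=["peak",
                                                         "amplitude_uv"]),
                                   np.array([]))
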