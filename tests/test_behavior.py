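"""Choice models, effect sizes, PSE, power and safety arithmetic."""

import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from fnmes_eeg.behavior import (LOGISTIC_SD, cohens_d_from_logit,
                                compute_pse, fit_choice_model,
                                posthoc_contrasts, power_simulation,
                                rms_current_density, term_name,
                                _quick_neutral_design)
from fnmes_eeg.simulate import EffectParams, simulate_choices


class TestEffectSizeConversion:
    @pytest.mark.parametrize("b, expected", [
        (5.50, 3.03),    # happy-face coefficient
        (0.133, 0.07),   # late-stimulation coefficient
        (0.14, 0.08),    # stimulation main effect in the N170 model
        (-4.23, -2.33),  # sad-face coefficient
        (0.0, 0.0),
    ])
    def test_printed_pairs_reproduce_at_2dp(self, b, expected):
        assert round(cohens_d_from_logit(b), 2) == expected

    def test_rounded_vs_unrounded_early_coefficient(self):
        # the reported early-stimulation d of 0.10 corresponds to the
        # unrounded coefficient z x SE = 3.84 x 0.046 ~ 0.177; the rounded
        # coefficient 0.17 converts to 0.09
        assert round(cohens_d_from_logit(0.17), 2) == 0.09
        assert round(cohens_d_from_logit(3.84 * 0.046), 2) == 0.10

    @settings(max_examples=30, deadline=None)
    @given(a=st.floats(-10, 10), b=st.floats(-10, 10))
    def test_linear_and_sign_preserving(self, a, b):
        assert cohens_d_from_logit(a + b) == pytest.approx(
            cohens_d_from_logit(a) + cohens_d_from_logit(b), abs=1e-12)
        if a != 0:
            assert np.sign(cohens_d_from_logit(a)) == np.sign(a)

    def test_scale_is_logistic_sd(self):
        assert LOGISTIC_SD == pytest.approx(np.pi / np.sqrt(3.0))


class TestChoiceModel:
    @pytest.fixture(scope="class")
    def fitted(self):
        params = EffectParams(choice_b_early=0.4, choice_b_late=0.2,
                              choice_b_happy=0.0, choice_b_sad=0.0,
                              subject_sd=1.0)
        ch = simulate_choices(_quick_neutral_design(30, 96), params, seed=11)
        return ch, fit_choice_model(ch, "choice ~ fnmes")

    def test_laplace_fit_recovers_generator(self, fitted):
        _, fit = fitted
        assert fit.method == "laplace" and fit.converged
        b = fit[term_name("fnmes", "early")]
        assert abs(b.b - 0.4) < 3 * b.se
        assert 0.5 < fit.sigma_u < 2.0

    def test_agrees_with_lme4_glmer(self, fitted, tmp_path):
        """Independent oracle: R lme4 on the identical data."""
        ch, fit = fitted
        assert shutil.which("Rscript"), "R toolchain expected on PATH"
        csv = tmp_path / "choices.csv"
        ch.to_csv(csv, index=False)
        script = f'''
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$fnmes <- relevel(factor(d$fnmes), ref="off")
        d$y <- as.integer(d$choice == "happy")
        m <- glmer(y ~ fnmes + (1|subject), data=d, family=binomial)
        co <- summary(m)$coefficients
        cat(co["fnmesearly", 1], co["fnmesearly", 2],
            sqrt(unlist(VarCorr(m))), sep=",")
        '''
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        b_r, se_r, sd_r = map(float, out.stdout.strip().split(","))
        mine = fit[term_name("fnmes", "early")]
        assert mine.b == pytest.approx(b_r, abs=0.01)
        assert mine.se == pytest.approx(se_r, rel=0.05)
        assert fit.sigma_u == pytest.approx(sd_r, rel=0.05)

    def test_zero_effect_gives_zero_d(self):
        params = EffectParams(choice_b_early=0.0, choice_b_late=0.0,
                              choice_b_happy=0.0, choice_b_sad=0.0,
                              subject_sd=0.8)
        ch = simulate_choices(_quick_neutral_design(25, 80), params, seed=3)
        fit = fit_choice_model(ch, "choice ~ fnmes")
        t = fit[term_name("fnmes", "early")]
        assert abs(t.d) < 3 * t.se / LOGISTIC_SD

    def test_random_slope_request_is_simplified_with_note(self, fitted):
        ch, _ = fitted
        fit = fit_choice_model(ch, "choice ~ fnmes",
                               re_formula="~fnmes")
        assert any("simplified" in n for n in fit.notes)

    def test_separation_is_flagged_not_silent(self):
        df = pd.DataFrame({
            "subject": np.repeat([1, 2, 3, 4], 20),
            "fnmes": np.tile(["off", "early"], 40),
            "emotion": "neutral"})
        df["choice"] = np.where(df["fnmes"] == "early", "happy", "sad")
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_choice_model(df, "choice ~ fnmes")
        assert fit.method == "penalised"

    def test_single_subject_rejected(self):
        df = pd.DataFrame({"subject": 1, "fnmes": ["off", "early"] * 10,
                           "choice": ["happy", "sad"] * 10})
        with pytest.raises(ValueError):
            fit_choice_model(df, "choice ~ fnmes")


class TestPosthocs:
    @pytest.fixture(scope="class")
    def fit(self):
        params = EffectParams(choice_b_early=0.5, choice_b_late=0.1,
                              choice_b_happy=0.0, choice_b_sad=0.0,
                              subject_sd=0.7)
        ch = simulate_choices(_quick_neutral_design(20, 60), params, seed=21)
        return fit_choice_model(ch, "choice ~ fnmes")

    def test_adjusted_p_is_bonferroni_of_raw(self, fit):
        tab = posthoc_contrasts(fit, "fnmes", ["off", "early", "late"])
        m = len(tab)
        for _, row in tab.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, m * row["p_raw"]))

    def test_single_comparison_is_unadjusted(self, fit):
        tab = posthoc_contrasts(fit, "fnmes", ["off", "early"])
        assert len(tab) == 1
        assert tab["p_adj"].iloc[0] == pytest.approx(tab["p_raw"].iloc[0])

    def test_contrast_recovers_coefficient_difference(self, fit):
        tab = posthoc_contrasts(fit, "fnmes", ["off", "early", "late"])
        row = tab[tab["contrast"] == "early - late"].iloc[0]
        expect = (fit[term_name("fnmes", "early")].b
                  - fit[term_name("fnmes", "late")].b)
        assert row["estimate"] == pytest.approx(expect)


class TestPSE:
    def _choices_from_curve(self, intercept, slope, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.choice([-1.0, 0.0, 1.0], size=n)
        p = expit(intercept + slope * x)
        return pd.DataFrame({
            "subject": 1, "fnmes": "off",
            "emotion": np.select([x < 0, x > 0], ["sad", "happy"],
                                 "neutral"),
            "choice": np.where(rng.random(n) < p, "happy", "sad")})

    def test_zero_intercept_gives_zero_pse(self):
        pse = compute_pse(self._choices_from_curve(0.0, 2.0))
        assert abs(pse["pse"].iloc[0]) < 0.1

    def test_closed_form_root(self):
        # logit P = 1 + 2x  =>  P = 0.5 at x = -0.5
        pse = compute_pse(self._choices_from_curve(1.0, 2.0, seed=1))
        assert pse["pse"].iloc[0] == pytest.approx(-0.5, abs=0.1)

    def test_intercept_shift_moves_pse_by_delta_over_slope(self):
        a = compute_pse(self._choices_from_curve(0.0, 2.0, seed=2))
        b = compute_pse(self._choices_from_curve(1.0, 2.0, seed=2))
        shift = b["pse"].iloc[0] - a["pse"].iloc[0]
        assert shift == pytest.approx(-0.5, abs=0.1)

    def test_degenerate_cell_flagged_missing(self):
        df = pd.DataFrame({"subject": 1, "fnmes": "off",
                           "emotion": ["neutral"] * 20,
                           "choice": ["happy"] * 20})
        pse = compute_pse(df)
        assert not pse["valid"].iloc[0]
        assert np.isnan(pse["pse"].iloc[0])


class TestPowerSimulation:
    def test_large_effect_saturates(self):
        est = power_simulation([12], b_early=1.5, subject_sd=0.3,
                               n_sims=12, seed=5, trials_per_cond=40)[0]
        assert est.power == 1.0
        assert est.ci_low <= est.power <= est.ci_high

    def test_null_effect_power_near_alpha(self):
        est = power_simulation([8], b_early=0.0, b_late=0.0,
                               subject_sd=0.5, n_sims=40, seed=6,
                               trials_per_cond=30)[0]
        # binomial(40, 0.05): 3 MC-SE margin
        assert est.power <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 40)

    def test_power_grows_with_sample_size(self):
        ests = power_simulation([6, 24], b_early=0.6, subject_sd=0.5,
                                n_sims=25, seed=7, trials_per_cond=48)
        assert ests[1].power >= ests[0].power


class TestAU12Stats:
    def test_null_generator_gives_tiny_eta(self, face_design):
        from fnmes_eeg.behavior import au12_stats
        from fnmes_eeg.simulate import simulate_au_timeseries

        sub = face_design[face_design["subject"] == 1]
        au = simulate_au_timeseries(sub, gain={"off": 0, "early": 0,
                                               "late": 0}, seed=8)
        st_ = au12_stats(au)
        eta = st_["anova"].loc["C(fnmes, Sum)", "eta_p2"]
        assert eta < 0.1

    def test_condition_contrast_recovered(self, face_design):
        from fnmes_eeg.behavior import au12_stats
        from fnmes_eeg.simulate import simulate_au_timeseries

        au = simulate_au_timeseries(
            face_design, gain={"off": 0.0, "early": 0.137, "late": 0.156},
            seed=9)
        st_ = au12_stats(au)
        fit = st_["model"]
        est = fit.params["fnmes[T.early]"]
        se = fit.bse["fnmes[T.early]"]
        assert abs(est - 0.137) < 2 * se

    def test_eta_matches_brute_force_ss_ratio(self, face_design):
        from fnmes_eeg.behavior import au12_stats
        from fnmes_eeg.simulate import simulate_au_timeseries

        sub = face_design[face_design["subject"] == 1]
        au = simulate_au_timeseries(sub, seed=10)
        st_ = au12_stats(au)
        aov = st_["anova"]
        ss_res = aov.loc["Residual", "sum_sq"]
        for row in ("C(fnmes, Sum)", "C(emotion, Sum)"):
            brute = aov.loc[row, "sum_sq"] / (aov.loc[row, "sum_sq"]
                                              + ss_res)
            assert aov.loc[row, "eta_p2"] == pytest.approx(brute)


class TestCurrentDensity:
    def test_printed_stimulation_parameters(self):
        cd = rms_current_density(22.60, 100.0, 70.0, (16.0, 19.0))
        assert round(cd.density_rms_ma_cm2, 2) == 0.62
        assert cd.within_safety

    def test_matches_numerical_waveform_rms(self):
        # integrate one period of an explicitly sampled pulse train
        current, width_us, rate = 22.60, 100.0, 70.0
        period = 1.0 / rate
        t = np.linspace(0, period, 2_000_001, endpoint=False)
        wave = np.where(t < width_us * 1e-6, current, 0.0)
        rms_num = np.sqrt(np.mean(wave ** 2))
        cd = rms_current_density(current, width_us, rate)
        assert cd.rms_current_ma == pytest.approx(rms_num, rel=1e-3)

    def test_zero_current(self):
        assert rms_current_density(0.0).density_rms_ma_cm2 == 0.0

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError):
            rms_current_density(10.0, pulse_width_us=20_000.0, rate_hz=70.0)


class TestChoiceByN170:
    def test_opposite_slopes_yield_positive_interaction(self):
        """Generator with a negative N170-choice slope without stimulation
        and a positive slope under early stimulation: the interaction
        coefficient must come out positive."""
        from fnmes_eeg.erp import choice_by_n170_model

        rng = np.random.default_rng(30)
        rows = []
        for s in range(1, 25):
            b0 = 0.5 * rng.standard_normal()
            for fn in ("off", "early"):
                slope = -0.3 if fn == "off" else 0.3
                n170 = -5 + 2 * rng.standard_normal(80)
                p = expit(b0 + slope * n170)
                for v, pi in zip(n170, p):
                    rows.append({"subject": s, "fnmes": fn,
                                 "emotion": "neutral", "n170_uv": v,
                                 "choice": "happy" if rng.random() < pi
                                 else "sad"})
        fit = choice_by_n170_model(pd.DataFrame(rows))
        inter = fit["fnmes[T.early]:n170_uv"]
        assert inter.b > 0 and inter.p < 0.05

    def test_uncorrelated_n170_gives_null_interaction(self):
        from fnmes_eeg.erp import choice_by_n170_model

        rng = np.random.default_rng(31)
        rows = []
        for s in range(1, 16):
            for fn in ("off", "early"):
                for _ in range(60):
                    rows.append({"subject": s, "fnmes": fn,
                                 "emotion": "neutral",
                                 "n170_uv": -5 + 2 * rng.standard_normal(),
                                 "choice": "happy" if rng.random() < 0.5
                                 else "sad"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = choice_by_n170_model(pd.DataFrame(rows))
        inter = fit["fnmes[T.early]:n170_uv"]
        assert abs(inter.z) < 2.5
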