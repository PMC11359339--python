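"""Stage-1 budbreak curve fitting, AIC selection, and 5% inversion."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from phenocast import budbreak, synthetic
from phenocast.budbreak import FamilyFit
from phenocast.config import SyntheticConfig
from phenocast.errors import DegenerateFitError, ExtrapolationError


def logistic_survey(rng, total=40, intercept=-10.0, slope=0.02, n_obs=15):
    """Cumulative counts from shared logistic bud thresholds."""
    gdd = np.linspace(100, 600, n_obs)
    req = rng.logistic(loc=-intercept / slope, scale=1.0 / slope, size=total)
    broken = (req[None, :] <= gdd[:, None]).sum(axis=1)
    return pd.DataFrame({"vine_id": "v", "gdd_cum": gdd,
                         "broken_buds": broken, "total_buds": total})


class TestFamilies:
    def test_logistic_counts_prefer_binomial(self):
        rng = np.random.default_rng(3)
        wins = 0
        for _ in range(20):
            fits = budbreak.fit_budbreak_curves(logistic_survey(rng))
            if budbreak.select_best_family(fits).family == "binomial":
                wins += 1
        assert wins >= 18

    def test_perfectly_linear_counts_polynomial_r2_one(self):
        survey = pd.DataFrame({"gdd_cum": [100.0, 150, 200, 250, 300],
                               "broken_buds": [2, 6, 10, 14, 18], "total_buds": 40})
        fits = budbreak.fit_budbreak_curves(survey)
        assert fits["polynomial"].r_squared == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_counts_rejected(self):
        zero = pd.DataFrame({"gdd_cum": [100.0, 150, 200, 250],
                             "broken_buds": [0, 0, 0, 0], "total_buds": 40})
        with pytest.raises(DegenerateFitError):
            budbreak.fit_budbreak_curves(zero)
        saturated = zero.assign(broken_buds=40)
        with pytest.raises(DegenerateFitError):
            budbreak.fit_budbreak_curves(saturated)


class TestSelection:
    @staticmethod
    def _fit(family, aic):
        return FamilyFit(family, np.zeros(2 if family != "polynomial" else 3),
                         aic, 0.9, 40)

    def test_argmin_aic(self):
        fits = {"binomial": self._fit("binomial", 6.4),
                "poisson": self._fit("poisson", 30.0),
                "polynomial": self._fit("polynomial", 25.0)}
        assert budbreak.select_best_family(fits).family == "binomial"

    def test_tie_goes_to_binomial(self):
        fits = {"binomial": self._fit("binomial", 10.0),
                "polynomial": self._fit("polynomial", 10.0)}
        assert budbreak.select_best_family(fits).family == "binomial"

    def test_tie_prefers_fewer_parameters(self):
        fits = {"poisson": self._fit("poisson", 10.0),
                "polynomial": self._fit("polynomial", 10.0)}
        assert budbreak.select_best_family(fits).family == "poisson"

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        fits = budbreak.fit_budbreak_curves(logistic_survey(rng))
        forward = budbreak.select_best_family(fits)
        backward = budbreak.select_best_family(dict(reversed(list(fits.items()))))
        assert forward.family == backward.family


class TestInversion:
    def test_closed_form_logit_inversion(self):
        """Fitted logistic with intercept -10, slope 0.02 crosses 5% at ~352.8."""
        fit = FamilyFit("binomial", np.array([-10.0, 0.02]), 0.0, 1.0, 40)
        survey = pd.DataFrame({"gdd_cum": [100.0, 300, 500, 700],
                               "broken_buds": [0, 5, 35, 40], "total_buds": 40})
        gdd5, extrapolated = budbreak.invert_at_5pct(fit, survey)
        expected = (logit(0.05) + 10.0) / 0.02
        assert gdd5 == pytest.approx(expected, abs=0.1)
        assert expected == pytest.approx(352.8, abs=0.1)
        assert not extrapolated

    def test_consistency_at_the_root(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            survey = logistic_survey(rng)
            fit = budbreak.fit_budbreak_curves(survey)["binomial"]
            gdd5, _ = budbreak.invert_at_5pct(fit, survey)
            final = survey["broken_buds"].iloc[-1] / survey["total_buds"].iloc[-1]
            assert fit.predict_proportion(gdd5) == pytest.approx(0.05 * final, abs=1e-3)

    def test_bisection_matches_dense_grid(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            survey = logistic_survey(rng)
            fit = budbreak.fit_budbreak_curves(survey)["binomial"]
            gdd5, _ = budbreak.invert_at_5pct(fit, survey)
            final = survey["broken_buds"].iloc[-1] / survey["total_buds"].iloc[-1]
            grid = np.arange(0.0, 1.5 * survey["gdd_cum"].max(), 0.01)
            above = grid[fit.predict_proportion(grid) >= 0.05 * final]
            assert gdd5 == pytest.approx(above[0], abs=0.02)

    def test_unreachable_level_flagged(self):
        # a curve pinned near zero never reaches 5% of the final proportion
        fit = FamilyFit("binomial", np.array([-30.0, 0.001]), 0.0, 1.0, 40)
        survey = pd.DataFrame({"gdd_cum": [100.0, 200, 300, 400],
                               "broken_buds": [1, 2, 3, 4], "total_buds": 40})
        with pytest.raises(ExtrapolationError):
            budbreak.invert_at_5pct(fit, survey)

    def test_alternative_level_of_total_buds(self):
        rng = np.random.default_rng(7)
        survey = logistic_survey(rng)
        fit = budbreak.fit_budbreak_curves(survey)["binomial"]
        gdd_own, _ = budbreak.invert_at_5pct(fit, survey, of_total_buds=False)
        gdd_total, _ = budbreak.invert_at_5pct(fit, survey, of_total_buds=True)
        final = survey["broken_buds"].iloc[-1] / survey["total_buds"].iloc[-1]
        if final < 1.0:
            assert gdd_total > gdd_own  # 5% of all buds is the higher bar


class TestRecovery:
    def test_more_buds_tighter_bb_estimates(self):
        """Median |estimated - true BB| shrinks from 10 to 80 buds per vine."""
        errors = {}
        for buds in (10, 80):
            cfg = SyntheticConfig(seed=13, n_years=2, start_year=2020,
                                  n_orchards_per_region=1, n_vines_per_orchard=10,
                                  buds_per_vine=buds)
            ds = synthetic.simulate_dataset(cfg)
            fits = budbreak.fit_panel(ds.surveys)
            m = fits.merge(ds.flowering[["vine_id", "true_bb"]], on="vine_id")
            errors[buds] = float((m["gdd_at_5pct"] - m["true_bb"]).abs().median())
        assert errors[80] < errors[10]

    def test_panel_output_schema(self, small_dataset):
        fits = budbreak.fit_panel(small_dataset.surveys)
        assert {"vine_id", "family", "aic", "r2", "gdd_at_5pct", "flag"} <= set(fits.columns)
        assert len(fits) == small_dataset.flowering.shape[0]
        assert fits["gdd_at_5pct"].between(0, 1500).all()
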