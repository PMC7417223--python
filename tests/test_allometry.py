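"""Mixed-model fitting: grouping, structure selection, LRT, parameter extraction."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mothmass import (
    MothMassRegressor,
    SyntheticConfig,
    extract_parameters,
    filter_records,
    fit_mixed_allometry,
    group_families,
    lrt_family_interaction,
    marginal_r2,
    select_structure,
    simulate_community,
)
from mothmass.allometry import STRUCTURES


def _species_frame(layout: dict[str, int]) -> pd.DataFrame:
    rows = [
        {"species": f"{fam}_{i}", "family": fam, "forewing_length_mm": 10.0,
         "dry_mass_mg": 5.0}
        for fam, k in layout.items()
        for i in range(k)
    ]
    return pd.DataFrame(rows)


class TestGroupFamilies:
    def test_speciose_families_keep_their_label(self):
        layout = {"Noctuidae": 36, "Crambidae": 11, "Erebidae": 10, "Geometridae": 22}
        layout.update({f"Small{i}": c for i, c in enumerate([3, 3, 2, 2, 2, 2, 1])})
        grouping = group_families(_species_frame(layout), threshold=5)
        assert set(grouping.groups) == {
            "Crambidae", "Erebidae", "Geometridae", "Noctuidae", "other",
        }
        assert grouping.group_of("Small3") == "other"

    def test_threshold_boundary_is_inclusive(self):
        grouping = group_families(_species_frame({"Erebidae": 5}), threshold=5)
        assert grouping.group_of("Erebidae") == "Erebidae"

    def test_all_small_families_pool_into_one_group(self):
        grouping = group_families(_species_frame({"A": 2, "B": 2}), threshold=5)
        assert grouping.group_of("A") == grouping.group_of("B") == "other"
        assert grouping.groups == ["other"]

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="empty|no records"):
            group_families(_species_frame({}))


class TestFitting:
    def test_noiseless_fit_recovers_generating_coefficients(self):
        cfg = SyntheticConfig(
            species_intercept_sd=1e-6, residual_sd=1e-6, quantize=False
        )
        records, _, truth = simulate_community(cfg, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = MothMassRegressor().fit(records)
        assert abs(est.params_.reference_slope - 3.056) / 3.056 < 1e-3
        assert abs(est.params_.reference_intercept - (-5.016)) / 5.016 < 1e-3
        for fam, (ds, di) in truth.params.family_adjustments.items():
            got_s, got_i = est.params_.family_adjustments[fam]
            assert abs(got_s - ds) < 5e-3
            assert abs(got_i - di) < 5e-3

    def test_slope_estimate_within_sampling_error(self, fitted):
        est, se = fitted.fit_.fixed_effects["ln_length"]
        assert abs(est - 3.056) < 3 * se

    def test_bic_definition_and_unit_invariance(self, community):
        """Dividing masses by 1000 (mg -> g) shifts ln(mass) by a constant:
        the ln-scale likelihood, slope and BIC are exactly unchanged, while the
        implied mass-scale BIC shifts by n*ln(c^2) through the log Jacobian."""
        records, _, _ = community
        rescaled = records.assign(dry_mass_mg=records["dry_mass_mg"] / 1000.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_mg = fit_mixed_allometry(records)
            fit_g = fit_mixed_allometry(rescaled)
        assert fit_g.bic == pytest.approx(fit_mg.bic, abs=1e-4)
        assert fit_g.fixed_effects["ln_length"][0] == pytest.approx(
            fit_mg.fixed_effects["ln_length"][0], abs=1e-6
        )
        assert fit_g.fixed_effects["intercept"][0] == pytest.approx(
            fit_mg.fixed_effects["intercept"][0] - np.log(1000.0), abs=1e-5
        )
        # BIC expressed on the mass scale gains the Jacobian 2*sum(ln m)
        n = fit_mg.n_obs
        jac_mg = 2.0 * np.log(records["dry_mass_mg"]).sum()
        jac_g = 2.0 * np.log(rescaled["dry_mass_mg"]).sum()
        assert (fit_g.bic + jac_g) - (fit_mg.bic + jac_mg) == pytest.approx(
            -n * np.log(1000.0**2), rel=1e-10
        )
        k = len(fit_mg.fixed_effects) + 2
        assert fit_mg.bic == pytest.approx(
            -2 * fit_mg.log_likelihood + k * np.log(n), rel=1e-12
        )

    def test_reference_level_changes_coefficients_not_predictions(self, community):
        records, _, _ = community
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_other = fit_mixed_allometry(records)
            fit_noct = fit_mixed_allometry(records, reference="Noctuidae")
        assert fit_other.fixed_effects != fit_noct.fixed_effects
        pred_a = fit_other.fixed_prediction(records)
        pred_b = fit_noct.fixed_prediction(records)
        # agreement is limited by the variance-parameter optimizer tolerance
        assert np.max(np.abs(pred_a - pred_b)) < 2e-5

    def test_singular_species_variance_warns_not_errors(self):
        cfg = SyntheticConfig(
            families=("Noctuidae",), species_per_family=(10,),
            true_family_adjustments={}, n_individuals=100,
            species_intercept_sd=0.0, residual_sd=0.3,
        )
        records, _, _ = simulate_community(cfg, seed=1)
        with pytest.warns(UserWarning, match="singular"):
            fit = fit_mixed_allometry(records)
        assert fit.random_intercept_variance < 1e-10

    def test_rejects_nonpositive_measurements(self, small_community):
        records, _, _ = small_community
        bad = records.copy()
        bad.loc[bad.index[0], "dry_mass_mg"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            MothMassRegressor().fit(bad)


class TestStructureSelection:
    def test_loglog_wins_on_data_generated_under_loglog(self, community):
        records, _, _ = community
        grouping = group_families(records)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = [
                fit_mixed_allometry(records, structure=s, grouping=grouping)
                for s in STRUCTURES
            ]
        assert select_structure(fits).structure == "loglog"

    def test_loglog_wins_across_seeds(self):
        wins = 0
        for seed in range(5):
            records, _, _ = simulate_community(SyntheticConfig(), seed=100 + seed)
            records, _ = filter_records(records)
            grouping = group_families(records)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits = [
                    fit_mixed_allometry(records, structure=s, grouping=grouping)
                    for s in ("linear", "loglog")
                ]
            wins += select_structure(fits).structure == "loglog"
        assert wins == 5

    def test_single_candidate_is_returned_unchanged(self, fitted):
        assert select_structure([fitted.fit_]) is fitted.fit_

    def test_differing_record_sets_are_rejected(self, fitted, small_community):
        records, _, _ = small_community
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            other = fit_mixed_allometry(records)
        with pytest.raises(ValueError, match="differing"):
            select_structure([fitted.fit_, other])


class TestLRT:
    def test_single_group_is_degenerate(self):
        cfg = SyntheticConfig(
            families=("Noctuidae",), species_per_family=(12,),
            true_family_adjustments={}, n_individuals=120,
        )
        records, _, _ = simulate_community(cfg, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lrt_family_interaction(records)
        assert res.chi_square == 0.0
        assert res.p_value == 1.0

    def test_interaction_detected_with_df_equal_to_extra_groups(self, community):
        records, _, _ = community
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lrt_family_interaction(records)
        assert res.df == 4  # five groups, four interaction coefficients
        assert res.chi_square > 0.0
        assert res.p_value < 0.001


class TestMarginalR2:
    def test_noiseless_fit_explains_everything(self):
        cfg = SyntheticConfig(
            species_intercept_sd=1e-6, residual_sd=1e-6, quantize=False
        )
        records, _, _ = simulate_community(cfg, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mixed_allometry(records)
        assert marginal_r2(fit, records) > 0.999

    def test_no_fixed_effect_variance_means_zero(self):
        cfg = SyntheticConfig(
            true_reference_slope=0.0, true_family_adjustments={},
            species_intercept_sd=0.3, residual_sd=0.3, quantize=False,
        )
        records, _, _ = simulate_community(cfg, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mixed_allometry(records)
        # the fitted slopes are pure noise, so the fixed-effect variance is
        # a small finite-sample artefact, not structure
        assert marginal_r2(fit, records) < 0.10

    def test_strong_allometry_gives_high_marginal_r2(self, fitted, community):
        records, _, _ = community
        r2 = marginal_r2(fitted.fit_, records)
        assert 0.75 < r2 < 1.0


class TestExtractParameters:
    def test_round_trip_matches_fixed_predictions(self, fitted, community):
        records, _, _ = community
        params = extract_parameters(fitted.fit_)
        via_params = params.linear_predictor(
            np.log(records["forewing_length_mm"].to_numpy(float)),
            records["family"].to_numpy(object),
        )
        direct = fitted.fit_.fixed_prediction(records)
        assert np.max(np.abs(via_params - direct)) < 1e-10

    def test_round_trip_holds_for_any_reference_level(self, community):
        records, _, _ = community
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mixed_allometry(records, reference="Geometridae")
        params = extract_parameters(fit)
        via_params = params.linear_predictor(
            np.log(records["forewing_length_mm"].to_numpy(float)),
            records["family"].to_numpy(object),
        )
        assert np.max(np.abs(via_params - fit.fixed_prediction(records))) < 1e-10

    def test_single_group_has_no_adjustments(self):
        cfg = SyntheticConfig(
            families=("Noctuidae",), species_per_family=(12,),
            true_family_adjustments={}, n_individuals=120,
        )
        records, _, _ = simulate_community(cfg, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mixed_allometry(records)
        assert extract_parameters(fit).family_adjustments == {}

    def test_non_loglog_structures_are_rejected(self, community):
        records, _, _ = community
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mixed_allometry(records, structure="linear")
        with pytest.raises(ValueError, match="loglog"):
            extract_parameters(fit)
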