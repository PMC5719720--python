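import numpy as np
import pandas as pd
import pytest

from nirscal import synthgen
from nirscal.datasets import InputError, SpectraDataset
from nirscal.modelstats import (
    calibration_stats,
    cross_validate,
    evaluate_recipe,
    external_validate,
    grid_search,
    rpd,
    split_calibration_validation,
)
from nirscal.mpls import fit_mpls
from nirscal.preprocess import ModelRecipe, apply_recipe


class TestCalibrationStats:
    def test_hand_arithmetic(self):
        sec, r2 = calibration_stats([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8], n_factors=1)
        np.testing.assert_allclose(sec, np.sqrt(0.10 / 2), atol=1e-10)
        np.testing.assert_allclose(r2, 1 - 0.10 / 5, atol=1e-10)

    def test_perfect_fit(self):
        sec, r2 = calibration_stats([1.0, 2.0, 3.0, 5.0], [1.0, 2.0, 3.0, 5.0], 1)
        assert sec == 0 and r2 == 1

    def test_null_model_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        _, r2 = calibration_stats(y, np.full(4, y.mean()), 1)
        np.testing.assert_allclose(r2, 0, atol=1e-12)

    def test_constant_reference_errors(self):
        with pytest.raises(InputError):
            calibration_stats([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 2.0], 1)


class TestRPD:
    @pytest.mark.parametrize(
        "sd,secv,expected", [(7.95, 1.35, 5.89), (10.11, 2.20, 4.60), (3.0, 3.0, 1.0)]
    )
    def test_printed_ratios(self, sd, secv, expected):
        assert round(rpd(sd, secv), 2) == expected

    def test_nonpositive_secv_errors(self):
        with pytest.raises(InputError):
            rpd(1.0, 0.0)


class TestCrossValidate:
    def test_deterministic_given_seed(self, small_population):
        a = cross_validate(small_population, ModelRecipe(), "hex_pre", seed=9)
        b = cross_validate(small_population, ModelRecipe(), "hex_pre", seed=9)
        np.testing.assert_array_equal(a.folds, b.folds)
        assert a.secv == b.secv and a.terms == b.terms

    def test_noiseless_linear_data_tiny_secv(self, rng):
        # y exactly linear in 3 spectral factors, no noise anywhere
        grid = np.arange(408.0, 808.0, 8.0)
        T = rng.normal(size=(40, 3))
        X = T @ rng.normal(size=(3, grid.size))
        y = T @ np.array([2.0, -1.0, 0.5]) + 30
        traits = pd.DataFrame({"y": y}, index=[f"s{i}" for i in range(40)])
        ds = SpectraDataset(grid, X, list(traits.index), traits=traits)
        cv = cross_validate(ds, ModelRecipe(), "y", max_factors=5, seed=1)
        assert cv.secv_by_factor[2] <= 1e-6

    def test_n_fold_equals_loo_oracle(self, rng):
        """CV with n groups = n matches a brute-force leave-one-out oracle."""
        grid = np.arange(408.0, 568.0, 8.0)
        X = rng.normal(size=(12, grid.size))
        y = rng.normal(size=12)
        traits = pd.DataFrame({"y": y}, index=[f"s{i}" for i in range(12)])
        ds = SpectraDataset(grid, X, list(traits.index), traits=traits)
        cv = cross_validate(ds, ModelRecipe(), "y", max_factors=3, n_groups=12, seed=0)
        # oracle: refit without each sample, predict it
        preds = np.empty((12, 3))
        for i in range(12):
            mask = np.arange(12) != i
            m = fit_mpls(X[mask], y[mask], n_factors=3)
            preds[i] = m.predict_per_factor(X[i][None, :])
        secv_oracle = np.sqrt(((preds - y[:, None]) ** 2).sum(axis=0) / 12)
        np.testing.assert_allclose(cv.secv_by_factor, secv_oracle, atol=1e-10)

    def test_too_few_groups(self, small_population):
        with pytest.raises(InputError):
            cross_validate(small_population, ModelRecipe(), "hex_pre", n_groups=1)


class TestSplit:
    def test_sizes_and_partition(self, clean_population):
        cal, val, summary = split_calibration_validation(clean_population, 93, seed=2)
        assert (cal.n_samples, val.n_samples) == (154, 93)
        assert set(cal.ids) | set(val.ids) == set(clean_population.ids)
        assert set(cal.ids) & set(val.ids) == set()
        assert set(summary["set"]) == {"calibration", "validation"}
        assert set(summary.columns) == {"set", "trait", "n", "mean", "min", "max", "sd"}

    def test_deterministic(self, clean_population):
        a = split_calibration_validation(clean_population, 93, seed=2)[1]
        b = split_calibration_validation(clean_population, 93, seed=2)[1]
        assert a.ids == b.ids

    def test_bad_sizes(self, clean_population):
        with pytest.raises(InputError):
            split_calibration_validation(clean_population, 247, seed=0)


class TestExternalValidate:
    def test_perfect_model_on_same_set(self, rng):
        # y exactly linear in the spectra: the fitted model is perfect, and
        # self-validation (overlap guard disabled deliberately) gives R2ev ~ 1
        grid = np.arange(408.0, 808.0, 8.0)
        T = rng.normal(size=(30, 3))
        X = T @ rng.normal(size=(3, grid.size))
        y = T @ np.array([1.0, 2.0, -1.0]) + 10
        traits = pd.DataFrame({"y": y}, index=[f"s{i}" for i in range(30)])
        ds = SpectraDataset(grid, X, list(traits.index), traits=traits)
        recipe = ModelRecipe()
        pre, state = apply_recipe(ds, recipe)
        model = fit_mpls(pre.X, y, n_factors=3)
        r2ev, sep, rpd_ev = external_validate(
            model, ds, "y", recipe, state=state,
            calibration_ids=set(ds.ids), allow_overlap=True,
        )
        assert r2ev > 0.999999

    def test_overlap_guard(self, small_population):
        recipe = ModelRecipe()
        pre, state = apply_recipe(small_population, recipe)
        y = small_population.traits["hex_pre"].to_numpy(float)
        model = fit_mpls(pre.X, y, n_factors=3)
        with pytest.raises(InputError, match="overlap"):
            external_validate(model, small_population, "hex_pre", recipe,
                              state=state, calibration_ids=set(small_population.ids))

    def test_shuffled_labels_destroy_association(self, coarse_library, rng):
        traits = synthgen.generate_trait_table(140, seed=21)
        ds = synthgen.generate_spectra(traits, lib=coarse_library, seed=22)
        cal, val, _ = split_calibration_validation(ds, 50, seed=3)
        recipe = ModelRecipe((1, 4, 4, 1), "SNV", (780.0, 2492.0))
        stats, model, state = evaluate_recipe(cal, recipe, "hex_pre", seed=4)
        shuffled = val.traits.copy()
        shuffled["hex_pre"] = rng.permutation(shuffled["hex_pre"].to_numpy())
        val_shuffled = SpectraDataset(val.wavelengths, val.X, val.ids, traits=shuffled)
        r2ev, _, _ = external_validate(model, val_shuffled, "hex_pre", recipe,
                                       state=state, calibration_ids=set(cal.ids))
        assert r2ev <= 0.1

    def test_shift_invariance_of_errors(self, rng):
        """SEP (and SECV) depend only on residuals: adding a constant to both
        y and predictions leaves them unchanged."""
        y = rng.normal(size=30)
        yhat = y + rng.normal(0, 0.3, size=30)
        sep = np.sqrt(((y - yhat) ** 2).mean())
        sep_shifted = np.sqrt((((y + 5) - (yhat + 5)) ** 2).mean())
        np.testing.assert_allclose(sep, sep_shifted, atol=1e-12)


class TestGridSearch:
    @pytest.fixture(scope="class")
    def tiny_grid_table(self, small_population):
        return grid_search(
            small_population, "hex_pre",
            derivative_codes=[(0, 0, 1, 1), (1, 4, 4, 1)],
            scatter_methods=("NONE", "SNV", "MSC"),
            ranges=[(408.0, 2492.0), (1108.0, 2492.0)],
            max_factors=8, seed=6,
        )

    def test_enumerates_full_grid(self, tiny_grid_table):
        assert len(tiny_grid_table) == 2 * 3 * 2
        assert (tiny_grid_table.status == "ok").all()

    def test_ranked_by_secv(self, tiny_grid_table):
        ok = tiny_grid_table[tiny_grid_table.status == "ok"]
        assert ok["SECV"].is_monotonic_increasing

    def test_rpd_identity_on_every_row(self, tiny_grid_table):
        ok = tiny_grid_table[tiny_grid_table.status == "ok"]
        np.testing.assert_allclose(ok["RPD"], ok["SD"] / ok["SECV"], atol=0.005)

    def test_deterministic(self, small_population):
        kwargs = dict(
            derivative_codes=[(1, 4, 4, 1)], scatter_methods=("SNV",),
            ranges=[(780.0, 2492.0)], max_factors=6, seed=6,
        )
        a = grid_search(small_population, "hex_pre", **kwargs)
        b = grid_search(small_population, "hex_pre", **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_scatter_correction_beats_none_on_multiplicative_artifact(self, coarse_library):
        traits = synthgen.generate_trait_table(80, seed=31)
        scatter = synthgen.ScatterConfig(
            multiplicative_sd=0.25, offset_sd=0.0, slope_sd=0.0, noise_sd=1e-4
        )
        ds = synthgen.generate_spectra(traits, lib=coarse_library,
                                       scatter=scatter, seed=32)
        table = grid_search(
            ds, "cellulose",
            derivative_codes=[(0, 0, 1, 1)],
            scatter_methods=("NONE", "SNV", "MSC"),
            ranges=[(408.0, 2492.0)],
            max_factors=8, seed=7,
        )
        best = table[table.status == "ok"].iloc[0]
        assert best["SCM"] in ("SNV", "MSC")

    def test_failed_combination_recorded_not_fatal(self, small_population):
        # a huge gap on a narrow range trims below 2 points -> recorded as failed
        table = grid_search(
            small_population, "hex_pre",
            derivative_codes=[(0, 0, 1, 1), (2, 10, 10, 2)],
            scatter_methods=("NONE",),
            ranges=[(2400.0, 2492.0)],
            max_factors=4, seed=0,
        )
        assert (table.status != "ok").any() and (table.status == "ok").any()

    def test_empty_grid_errors(self, small_population):
        with pytest.raises(InputError):
            grid_search(small_population, "hex_pre", derivative_codes=[])


def test_r2cv_increases_with_snr(coarse_library):
    """Cross-validated R² rises monotonically over a 3-point noise ladder."""
    traits = synthgen.generate_trait_table(90, seed=41)
    r2s = []
    for noise in (0.05, 0.01, 0.0005):
        scatter = synthgen.ScatterConfig(multiplicative_sd=0.02, offset_sd=0.01,
                                         slope_sd=0.0, noise_sd=noise)
        ds = synthgen.generate_spectra(traits, lib=coarse_library,
                                       scatter=scatter, seed=42)
        cv = cross_validate(ds, ModelRecipe((1, 4, 4, 1), "SNV", (780.0, 2492.0)),
                            "hex_pre", max_factors=10, seed=8)
        r2s.append(cv.r2cv)
    assert r2s[0] < r2s[1] < r2s[2]
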