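import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirscal.datasets import InputError
from nirscal.preprocess import (
    ModelRecipe,
    apply_recipe,
    detrend,
    gap_segment_derivative,
    msc,
    snv,
    wmsc,
)


class TestSNV:
    def test_worked_examples(self):
        out = snv(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]], atol=1e-12)
        out = snv(np.array([[2.0, 4.0, 4.0, 4.0, 6.0]]))
        r2 = np.sqrt(2)
        np.testing.assert_allclose(out, [[-r2, 0, 0, 0, r2]], atol=1e-8)

    def test_row_mean_zero_sd_one(self, rng):
        out = snv(rng.normal(size=(20, 37)))
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_idempotent(self, rng):
        X = rng.normal(size=(5, 30))
        np.testing.assert_allclose(snv(snv(X)), snv(X), atol=1e-10)

    def test_zero_variance_row_names_sample(self):
        X = np.vstack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(InputError, match="straw42"):
            snv(X, ids=["ok", "straw42"])


class TestDetrend:
    def test_quadratic_row_vanishes(self):
        x = np.linspace(0, 1, 40)
        X = (3 + 2 * x - 5 * x**2)[None, :]
        np.testing.assert_allclose(detrend(X, x, order=2), 0, atol=1e-10)

    def test_linear_fit_closed_form(self):
        # OLS line through (0,1),(1,2),(2,4) leaves residuals (1/6, -1/3, 1/6)
        out = detrend(np.array([[1.0, 2.0, 4.0]]), np.array([0.0, 1.0, 2.0]), order=1)
        np.testing.assert_allclose(out, [[1 / 6, -1 / 3, 1 / 6]], atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        grid = np.linspace(408, 2492, 50)
        out = detrend(rng.normal(size=(8, 50)), grid, order=2)
        for col in (np.ones(50), grid, grid**2):
            assert np.abs(out @ (col / np.linalg.norm(col))).max() < 1e-8

    def test_idempotent(self, rng):
        grid = np.linspace(0, 1, 30)
        X = rng.normal(size=(4, 30))
        once = detrend(X, grid)
        np.testing.assert_allclose(detrend(once, grid), once, atol=1e-10)

    def test_order_too_high(self):
        with pytest.raises(InputError):
            detrend(np.ones((1, 3)), order=3)


class TestMSC:
    def test_self_reference_identity(self, rng):
        x = rng.normal(size=10)
        np.testing.assert_allclose(msc(x[None, :], reference=x), x[None, :], atol=1e-10)

    def test_affine_inversion(self, rng):
        ref = rng.normal(size=25)
        x = 0.5 + 2.0 * ref
        np.testing.assert_allclose(msc(x[None, :], reference=ref), ref[None, :], atol=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        ref = rng.normal(size=6)
        x = rng.normal(size=6)
        # brute-force 2-parameter OLS: solve [[n, sum r],[sum r, sum r^2]]
        A = np.array([[6.0, ref.sum()], [ref.sum(), (ref**2).sum()]])
        a, b = np.linalg.solve(A, np.array([x.sum(), (x * ref).sum()]))
        np.testing.assert_allclose(msc(x[None, :], reference=ref), ((x - a) / b)[None, :],
                                   atol=1e-10)

    def test_uncorrelated_spectrum_errors(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        flat = np.full(4, 7.0)
        with pytest.raises(InputError, match="uncorrelated"):
            msc(flat[None, :], reference=ref)


class TestWMSC:
    def test_equal_weights_reduce_to_msc(self, rng):
        X = rng.normal(size=(7, 40))
        ref = X.mean(axis=0)
        np.testing.assert_allclose(
            wmsc(X, reference=ref, weights=np.full(40, 3.0)),
            msc(X, reference=ref), atol=1e-12,
        )

    def test_exact_affine_model_any_weights(self, rng):
        ref = rng.normal(size=30)
        w = rng.uniform(0.1, 5.0, size=30)
        x = -1.2 + 0.7 * ref
        np.testing.assert_allclose(wmsc(x[None, :], reference=ref, weights=w),
                                   ref[None, :], atol=1e-10)

    def test_matches_weighted_normal_equation_oracle(self, rng):
        ref = rng.normal(size=9)
        x = rng.normal(size=9)
        w = rng.uniform(0.5, 2.0, size=9)
        A = np.array([[w.sum(), (w * ref).sum()],
                      [(w * ref).sum(), (w * ref**2).sum()]])
        a, b = np.linalg.solve(A, np.array([(w * x).sum(), (w * x * ref).sum()]))
        np.testing.assert_allclose(wmsc(x[None, :], reference=ref, weights=w),
                                   ((x - a) / b)[None, :], atol=1e-10)


class TestGapSegmentDerivative:
    def test_null_code_is_identity(self, rng):
        X = rng.normal(size=(3, 20))
        grid = np.linspace(408, 446, 20)
        Xd, gd = gap_segment_derivative(X, grid, (0, 0, 1, 1))
        np.testing.assert_array_equal(Xd, X)
        np.testing.assert_array_equal(gd, grid)

    def test_linear_row_gap_difference(self):
        # x_i = 3*i: smoothing preserves linearity, gap-4 difference = slope*4 = 12
        x = 3.0 * np.arange(30.0)
        Xd, _ = gap_segment_derivative(x[None, :], np.arange(30.0), (1, 4, 4, 1))
        np.testing.assert_allclose(Xd, 12.0, atol=1e-10)

    @pytest.mark.parametrize("code", [(1, 4, 4, 1), (2, 5, 5, 2), (2, 10, 10, 2)])
    def test_constant_row_maps_to_zero(self, code):
        x = np.full(60, 3.7)
        Xd, _ = gap_segment_derivative(x[None, :], np.arange(60.0), code)
        np.testing.assert_allclose(Xd, 0, atol=1e-12)

    @pytest.mark.parametrize("code", [(1, 3, 2, 1), (2, 4, 4, 2), (1, 5, 1, 3)])
    def test_operator_is_linear(self, rng, code):
        grid = np.arange(50.0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        lhs, _ = gap_segment_derivative((2.5 * x - 1.5 * y)[None, :], grid, code)
        tx, _ = gap_segment_derivative(x[None, :], grid, code)
        ty, _ = gap_segment_derivative(y[None, :], grid, code)
        np.testing.assert_allclose(lhs, 2.5 * tx - 1.5 * ty, atol=1e-10)

    def test_odd_gap_offsets(self):
        # gap 3 uses +2/-1 offsets: difference of a linear row = slope * 3
        x = 2.0 * np.arange(12.0)
        Xd, gd = gap_segment_derivative(x[None, :], np.arange(12.0), (1, 3, 1, 1))
        np.testing.assert_allclose(Xd, 6.0, atol=1e-12)
        # trimmed grid sits at the midpoint of the differenced positions
        np.testing.assert_allclose(gd[0], (0 + 3) / 2)

    def test_too_narrow_errors(self):
        with pytest.raises(InputError):
            gap_segment_derivative(np.ones((1, 4)), np.arange(4.0), (2, 4, 1, 1))


class TestRecipe:
    def test_token_round_trip(self):
        r = ModelRecipe((2, 5, 5, 2), "SNVD", (1108.0, 2492.0))
        assert r.token() == "2,5,5,2 | SNVD | 1108-2492"
        assert ModelRecipe.from_token(r.token()) == r

    @pytest.mark.parametrize(
        "kwargs", [
            {"derivative": (3, 1, 1, 1)},
            {"derivative": (1, 0, 1, 1)},
            {"derivative": (0, 0, 0, 1)},
            {"scatter": "OSC"},
            {"wl_range": (2492.0, 408.0)},
        ],
    )
    def test_invalid_recipes_rejected(self, kwargs):
        with pytest.raises(InputError):
            ModelRecipe(**kwargs)

    def test_identity_recipe(self, small_population):
        out, _ = apply_recipe(small_population, ModelRecipe())
        np.testing.assert_array_equal(out.X, small_population.X)
        assert out.provenance[-1] == "0,0,1,1 | NONE | 408-2492"

    def test_full_recipe_trims_grid(self, population):
        recipe = ModelRecipe((1, 4, 4, 1), "SNV", (408.0, 2492.0))
        out, _ = apply_recipe(population, recipe)
        assert 2 <= out.n_wavelengths < population.n_wavelengths
        assert out.n_samples == population.n_samples

    def test_snv_removes_affine_distortion_before_derivative(self, rng):
        from nirscal.datasets import SpectraDataset
        grid = np.linspace(408, 2492, 200)
        x = rng.normal(size=(4, 200))
        recipe = ModelRecipe((1, 4, 4, 1), "SNV", (408.0, 2492.0))
        a = apply_recipe(SpectraDataset(grid, x, [f"a{i}" for i in range(4)]), recipe)[0]
        b = apply_recipe(SpectraDataset(grid, 2 * x + 5, [f"a{i}" for i in range(4)]), recipe)[0]
        np.testing.assert_allclose(a.X, b.X, atol=1e-10)

    def test_row_permutation_equivariance(self, small_population):
        recipe = ModelRecipe((1, 4, 4, 1), "SNVD", (780.0, 2492.0))
        from nirscal.datasets import SpectraDataset
        base, _ = apply_recipe(small_population, recipe)
        rev = SpectraDataset(
            small_population.wavelengths,
            small_population.X[::-1],
            list(reversed(small_population.ids)),
        )
        out, _ = apply_recipe(rev, recipe)
        np.testing.assert_allclose(out.X[::-1], base.X, atol=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_msc_idempotent_against_own_mean(seed):
    """MSC with the corrected matrix's own mean as reference is idempotent."""
    rng = np.random.default_rng(seed)
    base = np.abs(rng.normal(1.0, 0.2, size=12))
    # pure multiplicative/offset distortion: the scatter model is exact
    X = rng.uniform(0.7, 1.3, (6, 1)) * base + rng.normal(0, 0.05, size=(6, 1))
    once = msc(X)
    np.testing.assert_allclose(msc(once, reference=once.mean(axis=0)), once, atol=1e-8)
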