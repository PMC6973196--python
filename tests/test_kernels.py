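"""Scalar kernels, the hybrid LGP kernel, Gram matrices and PSD validation."""

import math

import numpy as np
import pytest

from lgpsvm.kernels import (
    INDEFINITE_LGP_EXAMPLE,
    INDEFINITE_LGP_POINTS,
    KernelParams,
    check_psd,
    gaussian_kernel,
    gram_matrix,
    lgp_exponent_magnitude,
    lgp_kernel,
    lgp_series_oracle,
    lgp_series_oracle_scaled,
    linear_kernel,
    polynomial_kernel,
    series_terms_needed,
)

LGP_EXAMPLE = KernelParams(
    kind="lgp", beta=(0.5, 0.3, 0.2), eta=1.0, delta=0.0, degree=2, sigma=1.0
)


def draw_table_params(rng) -> KernelParams:
    """One LGP parameter set sampled over the full search ranges (log2 scale
    for gamma and eta, as the optimizer samples them)."""
    b = rng.uniform(0.0, 1.0, size=3)
    b = b / b.sum()
    return KernelParams.from_gamma(
        "lgp",
        2.0 ** rng.uniform(-15, 3),
        beta=tuple(b),
        eta=float(2.0 ** rng.uniform(-15, 3)),
        delta=float(rng.uniform(0, 5)),
        degree=int(rng.integers(2, 6)),
    )


def draw_unit_pair(rng, p=5):
    x = rng.normal(size=p)
    y = rng.normal(size=p)
    return x / max(1.0, np.linalg.norm(x)), y / max(1.0, np.linalg.norm(y))


class TestScalarKernels:
    def test_linear_examples(self):
        assert linear_kernel([1, 2], [3, 4]) == 11.0
        assert linear_kernel([0, 0], [0, 0]) == 0.0
        x = np.array([2.0, -1.5, 0.5])
        assert linear_kernel(x, x) == pytest.approx(np.sum(x**2))

    def test_polynomial_examples(self):
        assert polynomial_kernel([1, 2], [3, 4], eta=1, delta=1, degree=2) == 144.0
        assert polynomial_kernel([1, 0], [0, 1], eta=2, delta=0, degree=3) == 0.0
        # degree 1 degenerates to an affine linear kernel
        assert polynomial_kernel([1, 2], [3, 4], eta=0.5, delta=2, degree=1) == (
            pytest.approx(0.5 * 11 + 2)
        )

    def test_gaussian_examples(self):
        x = np.array([0.3, -0.7])
        assert gaussian_kernel(x, x, sigma=2.0) == 1.0
        assert gaussian_kernel([1, 0], [0, 1], sigma=1.0) == pytest.approx(
            math.exp(-1.0)
        )

    def test_gaussian_monotone_in_distance(self):
        x = np.zeros(3)
        values = [gaussian_kernel(x, np.full(3, t), sigma=1.5) for t in (0.1, 0.5, 1, 2)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="mismatch"):
            linear_kernel([1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="degree"):
            polynomial_kernel([1], [1], eta=1, delta=0, degree=0)
        with pytest.raises(ValueError, match="sigma"):
            gaussian_kernel([1], [1], sigma=0.0)


class TestLGPKernel:
    def test_pure_linear_reduction(self, rng):
        params = KernelParams(
            kind="lgp", beta=(1.0, 0.0, 0.0), eta=2.0, delta=1.0, degree=3, sigma=0.5
        )
        x, y = rng.normal(size=4), rng.normal(size=4)
        assert lgp_kernel(x, y, params) == pytest.approx(linear_kernel(x, y), abs=1e-12)

    def test_pure_constant_reduction(self, rng):
        # beta3 = 0 makes the exponential term exp(0) = 1 everywhere
        params = KernelParams(
            kind="lgp", beta=(0.0, 1.0, 0.0), eta=1.0, delta=0.0, degree=2, sigma=1.0
        )
        x, y = rng.normal(size=4), rng.normal(size=4)
        assert lgp_kernel(x, y, params) == pytest.approx(1.0)

    def test_hand_value(self):
        value = lgp_kernel([1, 0], [1, 0], LGP_EXAMPLE)
        assert value == pytest.approx(0.5 + 0.3 * math.exp(-0.1))
        assert value == pytest.approx(0.771451, abs=1e-6)

    def test_invalid_beta_simplex_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            KernelParams(
                kind="lgp", beta=(0.5, 0.5, 0.5), eta=1, delta=0, degree=2, sigma=1
            )

    def test_gamma_sigma_mapping(self):
        params = KernelParams.from_gamma("gaussian", 0.125)
        assert params.sigma == pytest.approx(2.0)
        assert params.gamma == pytest.approx(0.125)


class TestSeriesOracle:
    def test_zeroth_truncation(self):
        x, y = np.array([1.0, 0.5]), np.array([0.2, -0.3])
        assert lgp_series_oracle(x, y, LGP_EXAMPLE, 0) == pytest.approx(
            0.5 * float(x @ y) + 0.3
        )

    def test_thirty_terms_match_closed_form(self):
        direct = lgp_kernel([1, 0], [1, 0], LGP_EXAMPLE)
        series = lgp_series_oracle([1, 0], [1, 0], LGP_EXAMPLE, 30)
        assert abs(direct - series) < 1e-10

    def test_agreement_improves_with_depth(self):
        x, y = np.array([0.9, 0.1]), np.array([0.8, 0.2])
        params = KernelParams(
            kind="lgp", beta=(0.2, 0.5, 0.3), eta=2.0, delta=1.0, degree=3, sigma=0.8
        )
        direct = lgp_kernel(x, y, params)
        errors = [
            abs(direct - lgp_series_oracle(x, y, params, n)) for n in (5, 10, 20, 40)
        ]
        assert errors[0] > errors[-1]
        assert errors[-1] < 1e-12

    def test_random_draws_agree_at_sufficient_depth(self, rng):
        """Closed form equals the Taylor series across the search ranges.

        The plain truncation is asserted wherever double precision can
        carry it (|base| below ~17, with depth from the remainder bound);
        the scaling-and-squaring form of the same series covers every draw.
        """
        plain_checked = 0
        for _ in range(200):
            params = draw_table_params(rng)
            x, y = draw_unit_pair(rng)
            direct = lgp_kernel(x, y, params)
            scaled = lgp_series_oracle_scaled(x, y, params)
            if not (math.isfinite(direct) and math.isfinite(scaled)):
                assert direct == scaled  # both saturate together
                continue
            assert abs(direct - scaled) < 1e-8
            base = lgp_exponent_magnitude(x, y, params)
            if base < 17:  # float64 cancellation limit for the raw series
                n_terms = max(30, series_terms_needed(base, tol=1e-10))
                series = lgp_series_oracle(x, y, params, n_terms)
                assert abs(direct - series) < 1e-8
                plain_checked += 1
        assert plain_checked > 100  # the raw-series route is exercised heavily

    def test_terms_needed_bounds(self):
        assert series_terms_needed(0.0) == 1
        # exp(5) remainder: 5^n/n! < 1e-10 needs ~27 terms
        n = series_terms_needed(5.0, tol=1e-10)
        assert 20 < n < 40
        assert series_terms_needed(100.0, tol=1e-10) > 100


class TestGramMatrix:
    def test_orthonormal_rows_give_identity(self):
        A = np.eye(4)
        np.testing.assert_allclose(
            gram_matrix(A, A, KernelParams(kind="linear")), np.eye(4)
        )

    @pytest.mark.parametrize(
        "params",
        [
            KernelParams(kind="linear"),
            KernelParams(kind="polynomial", eta=0.7, delta=1.2, degree=3),
            KernelParams(kind="gaussian", sigma=0.9),
            KernelParams(kind="lgp", beta=(0.4, 0.4, 0.2), eta=1.1, delta=0.5, degree=2, sigma=1.3),
        ],
        ids=["linear", "polynomial", "gaussian", "lgp"],
    )
    def test_symmetry_and_loop_oracle(self, params, rng):
        A = rng.normal(size=(6, 4))
        K = gram_matrix(A, A, params)
        assert np.abs(K - K.T).max() < 1e-10
        scalar = {
            "linear": lambda x, y: linear_kernel(x, y),
            "polynomial": lambda x, y: polynomial_kernel(
                x, y, params.eta, params.delta, params.degree
            ),
            "gaussian": lambda x, y: gaussian_kernel(x, y, params.sigma),
            "lgp": lambda x, y: lgp_kernel(x, y, params),
        }[params.kind]
        B = rng.normal(size=(3, 4))
        K_cross = gram_matrix(A, B, params)
        for i in range(6):
            for j in range(3):
                assert K_cross[i, j] == pytest.approx(scalar(A[i], B[j]), abs=1e-10)

    def test_lgp_pure_linear_matches_linear_gram(self, rng):
        A = rng.normal(size=(5, 3))
        pure = KernelParams(
            kind="lgp", beta=(1.0, 0.0, 0.0), eta=1.0, delta=0.0, degree=2, sigma=1.0
        )
        K_lgp = gram_matrix(A, A, pure)
        K_lin = gram_matrix(A, A, KernelParams(kind="linear"))
        assert np.abs(K_lgp - K_lin).max() < 1e-12

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="feature mismatch"):
            gram_matrix(np.ones((2, 3)), np.ones((2, 4)), KernelParams(kind="linear"))


class TestPSD:
    def test_identity_is_psd(self):
        is_psd, min_eig = check_psd(np.eye(3))
        assert is_psd and min_eig == pytest.approx(1.0)

    def test_known_indefinite_matrix(self):
        is_psd, min_eig = check_psd(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert not is_psd
        assert min_eig == pytest.approx(-1.0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            check_psd(np.array([[1.0, 0.5], [0.0, 1.0]]))

    @pytest.mark.parametrize("kind", ["linear", "polynomial", "gaussian"])
    def test_standard_kernels_produce_psd_grams(self, kind, rng):
        for _ in range(30):
            m, p = int(rng.integers(3, 15)), int(rng.integers(2, 8))
            A = rng.normal(size=(m, p))
            params = {
                "linear": KernelParams(kind="linear"),
                "polynomial": KernelParams(
                    kind="polynomial",
                    eta=float(2.0 ** rng.uniform(-15, 3)),
                    delta=float(rng.uniform(0, 5)),
                    degree=int(rng.integers(2, 6)),
                ),
                "gaussian": KernelParams.from_gamma(
                    "gaussian", 2.0 ** rng.uniform(-15, 3)
                ),
            }[kind]
            is_psd, min_eig = check_psd(gram_matrix(A, A, params))
            assert is_psd, f"{kind} Gram indefinite: min eig {min_eig}"

    def test_convex_combination_of_psd_grams_is_psd(self, rng):
        A = rng.normal(size=(8, 4))
        K1 = gram_matrix(A, A, KernelParams(kind="linear"))
        K2 = gram_matrix(A, A, KernelParams(kind="gaussian", sigma=1.0))
        for w in (0.0, 0.25, 0.5, 0.9, 1.0):
            is_psd, _ = check_psd(w * K1 + (1 - w) * K2)
            assert is_psd

    def test_documented_lgp_counterexample_is_indefinite(self):
        K = gram_matrix(INDEFINITE_LGP_POINTS, INDEFINITE_LGP_POINTS, INDEFINITE_LGP_EXAMPLE)
        is_psd, min_eig = check_psd(K)
        assert not is_psd
        assert min_eig < -0.5
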