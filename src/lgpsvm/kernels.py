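"""Standard SVM kernels, the hybrid linear-Gaussian-polynomial (LGP) kernel,
Gram-matrix construction and numerical Mercer/PSD validation.

The LGP kernel blends a global linear term with a Gaussian envelope wrapped
around a polynomial kernel:

    K(x, y) = beta1 * (x . y) + beta2 * exp(-beta3 * (eta*(x . y) + delta)^d / (2*sigma^2))

with mixing weights beta1 + beta2 + beta3 = 1 on the simplex.  A truncated
Taylor expansion of the exponential term gives an independent series oracle
used to cross-check the closed form.  Validity (Mercer's condition) is not
guaranteed for every admissible parameter set — the expansion has
alternating signs — so positive semidefiniteness is checked numerically per
Gram matrix rather than assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

VALID_KINDS = ("linear", "polynomial", "gaussian", "lgp")
_SIMPLEX_TOL = 1e-9


@dataclass
class KernelParams:
    """Kernel kind plus its parameters; irrelevant fields may stay None.

    ``sigma`` is the Gaussian bandwidth; the equivalent precision is
    ``gamma = 1 / (2 * sigma^2)``.
    """

    kind: str
    beta: tuple[float, float, float] | None = None
    eta: float | None = None
    delta: float | None = None
    degree: int | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind in {"polynomial", "lgp"}:
            if self.eta is None or self.eta <= 0:
                raise ValueError("eta must be > 0")
            if self.delta is None or self.delta < 0:
                raise ValueError("delta must be >= 0")
            if self.degree not in {2, 3, 4, 5}:
                raise ValueError("degree must be in {2, 3, 4, 5}")
        if self.kind in {"gaussian", "lgp"}:
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("sigma must be > 0")
        if self.kind == "lgp":
            if self.beta is None or len(self.beta) != 3:
                raise ValueError("lgp requires a 3-vector beta")
            b = np.asarray(self.beta, dtype=float)
            if np.any(b < -_SIMPLEX_TOL) or np.any(b > 1 + _SIMPLEX_TOL):
                raise ValueError("each beta must lie in [0, 1]")
            if abs(b.sum() - 1.0) > _SIMPLEX_TOL:
                raise ValueError("beta must sum to 1")

    @property
    def gamma(self) -> float:
        if self.sigma is None:
            raise ValueError("sigma is unset")
        return 1.0 / (2.0 * self.sigma**2)

    @classmethod
    def from_gamma(cls, kind: str, gamma: float, **kw) -> "KernelParams":
        if gamma <= 0:
            raise ValueError("gamma must be > 0")
        return cls(kind=kind, sigma=math.sqrt(1.0 / (2.0 * gamma)), **kw)


def _check_pair(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"vector length mismatch: {x.shape} vs {y.shape}")
    return x, y


def linear_kernel(x, y) -> float:
    """Dot product x . y."""
    x, y = _check_pair(x, y)
    return float(x @ y)


def polynomial_kernel(x, y, eta: float, delta: float, degree: int) -> float:
    """(eta * (x . y) + delta) ** degree."""
    if degree <= 0 or int(degree) != degree:
        raise ValueError("degree must be a positive integer")
    if eta <= 0:
        raise ValueError("eta must be > 0")
    x, y = _check_pair(x, y)
    return float((eta * (x @ y) + delta) ** int(degree))


def gaussian_kernel(x, y, sigma: float) -> float:
    """exp(-||x - y||^2 / (2 sigma^2)); bounded in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x, y = _check_pair(x, y)
    d = x - y
    return float(np.exp(-(d @ d) / (2.0 * sigma**2)))


def lgp_kernel(x, y, params: KernelParams) -> float:
    """Hybrid kernel: beta1*(x.y) + beta2*exp(-beta3*poly/(2 sigma^2)).

    ``poly`` is the polynomial kernel (eta*(x.y) + delta)^d.  With
    beta = (1, 0, 0) this reduces exactly to the linear kernel.
    """
    if params.kind != "lgp":
        raise ValueError("params.kind must be 'lgp'")
    x, y = _check_pair(x, y)
    b1, b2, b3 = params.beta
    dot = float(x @ y)
    poly = (params.eta * dot + params.delta) ** params.degree
    exponent = -b3 * poly / (2.0 * params.sigma**2)
    # odd-degree negative projections can push the exponent past the float
    # range; saturate like np.exp instead of raising
    exp_term = math.inf if exponent > 709.0 else math.exp(exponent)
    return b1 * dot + b2 * exp_term


def lgp_series_oracle(x, y, params: KernelParams, n_terms: int) -> float:
    """Truncated Taylor expansion of the LGP kernel's exponential term.

    Returns beta1*K_lin + beta2 * sum_{i=0}^{n_terms} (-beta3*gamma)^i *
    K_poly^i / i!, with gamma = 1/(2 sigma^2).  Serves as an independent
    cross-check of :func:`lgp_kernel`; convergence is fast in the
    post-normalization regime where ||x||, ||y|| <= 1.
    """
    if n_terms < 0:
        raise ValueError("n_terms must be >= 0")
    x, y = _check_pair(x, y)
    b1, b2, b3 = params.beta
    dot = float(x @ y)
    poly = (params.eta * dot + params.delta) ** params.degree
    base = -b3 * params.gamma * poly
    total = 0.0
    term = 1.0  # base^0 / 0!
    for i in range(n_terms + 1):
        if i > 0:
            term *= base / i
        total += term
    return b1 * dot + b2 * total


def lgp_series_oracle_scaled(x, y, params: KernelParams, n_terms: int = 30) -> float:
    """Series oracle with scaling-and-squaring for large exponents.

    The plain truncated series is numerically unusable in double precision
    once the exponent magnitude exceeds ~17 (intermediate terms reach
    e^|base| and cancellation destroys the sum even though the series
    converges mathematically).  This variant evaluates the same Taylor
    series at base / 2^k with |base / 2^k| <= 1 — where ``n_terms`` = 30
    leaves a remainder below 1/31! — and squares the partial sum k times,
    exploiting exp(b) = exp(b/2^k)^(2^k).  Stays a series-based independent
    check of :func:`lgp_kernel` over the full parameter ranges.
    """
    x, y = _check_pair(x, y)
    b1, b2, b3 = params.beta
    dot = float(x @ y)
    poly = (params.eta * dot + params.delta) ** params.degree
    base = -b3 * params.gamma * poly
    k = max(0, math.ceil(math.log2(abs(base)))) if abs(base) > 1 else 0
    arg = base / 2**k
    total, term = 0.0, 1.0
    for i in range(n_terms + 1):
        if i > 0:
            term *= arg / i
        total += term
    for _ in range(k):
        total *= total
        if total == 0.0 or math.isinf(total):
            break
    return b1 * dot + b2 * total


def series_terms_needed(base_magnitude: float, tol: float = 1e-10) -> int:
    """Terms needed for the exponential Taylor series to converge within tol.

    The truncation remainder after n terms is bounded by
    |base|^(n+1)/(n+1)!, so large exponent magnitudes (big gamma, delta or
    degree) need proportionally deeper truncations.  Returns the smallest n
    with that bound below ``tol`` (at least 1).
    """
    if base_magnitude < 0:
        raise ValueError("base_magnitude must be >= 0")
    n = 1
    log_term = math.log(base_magnitude) if base_magnitude > 0 else -math.inf
    log_bound = log_term  # log(|base|^1 / 1!)
    log_tol = math.log(tol)
    while log_bound >= log_tol:
        n += 1
        log_bound += log_term - math.log(n)
    return n


def lgp_exponent_magnitude(x, y, params: KernelParams) -> float:
    """|beta3 * gamma * (eta*(x.y) + delta)^d|: the series' expansion base."""
    x, y = _check_pair(x, y)
    poly = (params.eta * float(x @ y) + params.delta) ** params.degree
    return abs(params.beta[2] * params.gamma * poly)


def gram_matrix(A: np.ndarray, B: np.ndarray, params: KernelParams) -> np.ndarray:
    """Pairwise kernel values between rows of A (m x p) and B (n x p)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature mismatch: {A.shape[1]} vs {B.shape[1]}")
    dot = A @ B.T
    if params.kind == "linear":
        return dot
    # extreme parameter draws can overflow to inf; callers screen for
    # non-finite Gram entries, so numpy's overflow warning is redundant
    with np.errstate(over="ignore"):
        if params.kind == "polynomial":
            return (params.eta * dot + params.delta) ** params.degree
        if params.kind == "gaussian":
            sq = (
                np.sum(A**2, axis=1)[:, None]
                + np.sum(B**2, axis=1)[None, :]
                - 2.0 * dot
            )
            return np.exp(-np.clip(sq, 0.0, None) / (2.0 * params.sigma**2))
        # lgp
        b1, b2, b3 = params.beta
        poly = (params.eta * dot + params.delta) ** params.degree
        return b1 * dot + b2 * np.exp(-b3 * poly / (2.0 * params.sigma**2))


def check_psd(K: np.ndarray, tol: float = 1e-8) -> tuple[bool, float]:
    """Numerical Mercer check: is this Gram matrix positive semidefinite?

    Returns ``(is_psd, min_eigenvalue)``; PSD means the smallest eigenvalue
    is above ``-tol * max(1, largest eigenvalue)``.  Asymmetry beyond tol is
    an error.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    scale = max(1.0, float(np.abs(K).max(initial=0.0)))
    if np.abs(K - K.T).max(initial=0.0) > tol * scale:
        raise ValueError("K is not symmetric within tolerance")
    eigs = np.linalg.eigvalsh((K + K.T) / 2.0)
    min_eig = float(eigs[0])
    is_psd = min_eig >= -tol * max(1.0, float(eigs[-1]))
    return is_psd, min_eig


#: An LGP parameter set (all values inside the search ranges) whose Gram
#: matrix on the two points (1,0) and (0,1) is indefinite: the exponential
#: term collapses the diagonal while off-diagonal entries stay near beta2,
#: giving a minimum eigenvalue around -0.81.  Demonstrates that the hybrid
#: kernel is not PSD for every admissible parameter set, which is why the
#: pipeline validates Gram matrices numerically.
INDEFINITE_LGP_EXAMPLE = KernelParams(
    kind="lgp",
    beta=(0.05, 0.9, 0.05),
    eta=8.0,
    delta=0.0,
    degree=2,
    sigma=2**-0.5,
)

#: Points realizing the indefinite Gram matrix of INDEFINITE_LGP_EXAMPLE.
INDEFINITE_LGP_POINTS = np.array([[1.0, 0.0], [0.0, 1.0]])
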