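"""Particle swarm optimization over the per-model hyperparameter spaces.

Each SVM variant searches a box-bounded space: the penalty C and the
Gaussian/polynomial scale parameters on a log2 scale, the polynomial degree
as a rounded integer, and the three LGP mixing weights as a simplex group
(raw values in [0, 1] renormalized to sum to 1 at decode time).  Swarm
sizing follows the 10 x D rule of thumb; the canonical update uses inertia
w = 1 and learning factors c1 = c2 = 2 for 50 iterations by default.  With
w = 1 the canonical swarm can diverge, so velocities are clamped to half
the box width per dimension and positions are clamped to their bounds (the
clamped component's velocity is zeroed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelParams

_LOG2C = ("log2_C", -5.0, 15.0, "log2")
_LOG2GAMMA = ("log2_gamma", -15.0, 3.0, "log2")
_LOG2ETA = ("log2_eta", -15.0, 3.0, "log2")
_DELTA = ("delta", 0.0, 5.0, "linear")
_DEGREE = ("degree", 2.0, 5.0, "integer")

MODEL_KINDS = ("L", "P", "G", "LGP")


@dataclass(frozen=True)
class Dim:
    """One bounded search dimension with its decoding scale."""

    name: str
    lower: float
    upper: float
    scale: str  # linear | log2 | integer | simplex

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("bounds must be finite")
        if self.lower >= self.upper:
            raise ValueError("lower bound must be below upper bound")


@dataclass
class SearchSpace:
    model_kind: str
    dims: list[Dim]

    @property
    def D(self) -> int:
        return len(self.dims)

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.lower for d in self.dims])

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.upper for d in self.dims])

    def simplex_groups(self) -> list[list[int]]:
        """Contiguous runs of simplex-scale dimensions, decoded jointly."""
        groups, current = [], []
        for i, d in enumerate(self.dims):
            if d.scale == "simplex":
                current.append(i)
            elif current:
                groups.append(current)
                current = []
        if current:
            groups.append(current)
        return groups


@dataclass
class SwarmConfig:
    """PSO run configuration; ``n_particles=None`` means the 10 x D rule."""

    n_particles: int | None = None
    max_iters: int = 50
    w: float = 1.0
    c1: float = 2.0
    c2: float = 2.0
    seed: int = 0

    def resolve_particles(self, D: int) -> int:
        return 10 * D if self.n_particles is None else self.n_particles


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float]  # gbest fitness: initial evaluation + one per iteration
    n_evaluations: int


def build_search_space(model_kind: str) -> SearchSpace:
    """Search space for an SVM variant: L (D=1), G (2), P (4), LGP (8)."""
    specs = {
        "L": [_LOG2C],
        "G": [_LOG2C, _LOG2GAMMA],
        "P": [_LOG2C, _LOG2ETA, _DELTA, _DEGREE],
        "LGP": [
            _LOG2C,
            ("beta1", 0.0, 1.0, "simplex"),
            ("beta2", 0.0, 1.0, "simplex"),
            ("beta3", 0.0, 1.0, "simplex"),
            _LOG2GAMMA,
            _LOG2ETA,
            _DELTA,
            _DEGREE,
        ],
    }
    if model_kind not in specs:
        raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")
    return SearchSpace(model_kind=model_kind, dims=[Dim(*s) for s in specs[model_kind]])


def decode_position(space: SearchSpace, raw: np.ndarray) -> tuple[float, KernelParams]:
    """Decode a raw in-bounds position into (C, KernelParams).

    log2-scaled dimensions are exponentiated, the degree is rounded to the
    nearest integer in range, and the beta simplex group is renormalized to
    sum to 1.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (space.D,):
        raise ValueError(f"position must have length {space.D}")
    tol = 1e-9
    if np.any(raw < space.lower - tol) or np.any(raw > space.upper + tol):
        raise ValueError("position out of bounds; clamp before decoding")
    vals = dict(zip([d.name for d in space.dims], raw))
    C = float(2.0 ** vals["log2_C"])
    kind = space.model_kind
    if kind == "L":
        return C, KernelParams(kind="linear")
    if kind == "G":
        return C, KernelParams.from_gamma("gaussian", 2.0 ** vals["log2_gamma"])
    degree = None
    if "degree" in vals:
        degree = int(np.clip(round(vals["degree"]), 2, 5))
    if kind == "P":
        return C, KernelParams(
            kind="polynomial",
            eta=float(2.0 ** vals["log2_eta"]),
            delta=float(vals["delta"]),
            degree=degree,
        )
    # LGP
    b = np.array([vals["beta1"], vals["beta2"], vals["beta3"]])
    s = b.sum()
    if s < 1e-6:
        raise ValueError("beta group sums below 1e-6; re-randomize before decoding")
    b = b / s
    return C, KernelParams.from_gamma(
        "lgp",
        2.0 ** vals["log2_gamma"],
        beta=(float(b[0]), float(b[1]), float(b[2])),
        eta=float(2.0 ** vals["log2_eta"]),
        delta=float(vals["delta"]),
        degree=degree,
    )


def _sanitize_simplex(space: SearchSpace, position: np.ndarray, rng) -> None:
    """Re-draw a simplex group whose raw sum collapsed below 1e-6 (in place)."""
    for group in space.simplex_groups():
        if position[group].sum() < 1e-6:
            position[group] = rng.uniform(0.0, 1.0, size=len(group))


def optimize(
    space: SearchSpace,
    fitness,
    config: SwarmConfig,
) -> OptimizeResult:
    """Maximize ``fitness(raw_position)`` with a canonical particle swarm.

    Runs exactly ``config.max_iters`` velocity/position updates after an
    initial seeding evaluation, evaluating every particle every iteration:

        v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)
        x <- clamp(x + v)

    ``fitness`` must be deterministic given the position (fix CV folds
    before the search).  NaN fitness is treated as -inf with a warning.
    The history of global-best fitness (initial evaluation plus one entry
    per iteration) is non-decreasing by construction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.resolve_particles(space.D)
    lo, hi = space.lower, space.upper
    span = hi - lo
    vmax = 0.5 * span

    def evaluate(x: np.ndarray) -> float:
        value = fitness(x)
        if value is None or np.isnan(value):
            warnings.warn("fitness returned NaN; treated as -inf", RuntimeWarning)
            return -np.inf
        return float(value)

    positions = rng.uniform(lo, hi, size=(n, space.D))
    for p in positions:
        _sanitize_simplex(space, p, rng)
    velocities = np.zeros_like(positions)

    pbest_pos = positions.copy()
    pbest_fit = np.array([evaluate(p) for p in positions])
    n_evals = n
    g = int(np.argmax(pbest_fit))
    gbest_pos = pbest_pos[g].copy()
    gbest_fit = float(pbest_fit[g])
    history = [gbest_fit]

    for _ in range(config.max_iters):
        r1 = rng.uniform(size=(n, space.D))
        r2 = rng.uniform(size=(n, space.D))
        velocities = (
            config.w * velocities
            + config.c1 * r1 * (pbest_pos - positions)
            + config.c2 * r2 * (gbest_pos[None, :] - positions)
        )
        np.clip(velocities, -vmax, vmax, out=velocities)
        positions = positions + velocities
        clamped = (positions < lo) | (positions > hi)
        np.clip(positions, lo, hi, out=positions)
        velocities[clamped] = 0.0
        for p in positions:
            _sanitize_simplex(space, p, rng)

        for i in range(n):
            f = evaluate(positions[i])
            n_evals += 1
            if f > pbest_fit[i]:
                pbest_fit[i] = f
                pbest_pos[i] = positions[i].copy()
                if f > gbest_fit:  # strict: first-achieved gbest retained on ties
                    gbest_fit = f
                    gbest_pos = positions[i].copy()
        history.append(gbest_fit)

    return OptimizeResult(
        best_position=gbest_pos,
        best_fitness=gbest_fit,
        history=history,
        n_evaluations=n_evals,
    )
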