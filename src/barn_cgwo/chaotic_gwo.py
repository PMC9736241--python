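"""Grey wolf optimization (GWO) and its chaotic-coefficient variant (CGWO).

Both variants are generic bound-constrained minimizers.  A pack of ``M``
candidate solutions ("wolves") moves toward the three best solutions found so
far (alpha, beta, delta).  Each wolf's step toward leader ``k`` is

    L_k = |C_k * U_k - U|          (distance term)
    U'_k = U_k - A_k * L_k         (move term)

and the proposed position is the mean of the three moves, clamped to the
search box.  ``A_k = 2a*r1 - a`` with ``a`` decaying linearly from 2 to 0.

The two variants differ only in the C coefficients:

* ``gwo``  — C_k = 2*r2, a fresh uniform random vector per wolf and leader.
* ``cgwo`` — three deterministic iteration-dependent scalar schedules
  (:func:`chaotic_coefficients`); no r2 randomness remains.

Replacement is greedy: a wolf keeps its new position only when the objective
improves, so the best-so-far fitness trace is non-increasing.

RNG consumption contract (relied on by the equivalence tests): positions are
initialized with one ``rng.uniform(lower, upper, (M, dim))`` call; then, per
iteration and per wolf in index order, for each leader alpha/beta/delta in
that order, ``r1 = rng.random(dim)`` is drawn for A and — for the ``gwo``
variant only — ``r2 = rng.random(dim)`` for C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SearchSpace",
    "Wolf",
    "PackState",
    "CoefficientSet",
    "linear_decay_a",
    "coeff_A",
    "chaotic_coefficients",
    "update_position",
    "optimize",
    "OptimizeResult",
]


@dataclass(frozen=True)
class SearchSpace:
    """A box of per-dimension bounds."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not np.all(lower < upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clamp(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower, self.upper)

    @classmethod
    def cube(cls, lo: float, hi: float, dim: int) -> "SearchSpace":
        return cls(np.full(dim, lo), np.full(dim, hi))


@dataclass
class Wolf:
    position: np.ndarray
    fitness: float


@dataclass
class PackState:
    """Positions, fitnesses and leaders of the pack at one iteration."""

    wolves: list[Wolf]
    alpha: Wolf
    beta: Wolf
    delta: Wolf
    n: int
    nmax: int


@dataclass(frozen=True)
class CoefficientSet:
    """Coefficients for one wolf update: decay a, step vectors A, scale C."""

    a: float
    A1: np.ndarray
    A2: np.ndarray
    A3: np.ndarray
    C1: np.ndarray | float
    C2: np.ndarray | float
    C3: np.ndarray | float


def linear_decay_a(n: int, nmax: int) -> float:
    """Decay coefficient ``a = 2 - 2*(n/nmax)``, from 2 at n=0 to 0 at n=nmax."""
    if nmax < 1:
        raise ValueError("nmax must be >= 1")
    if not 0 <= n <= nmax:
        raise ValueError("iteration n must satisfy 0 <= n <= nmax")
    return 2.0 - 2.0 * (n / nmax)


def coeff_A(a: float, rng: np.random.Generator, dim: int = 1) -> np.ndarray:
    """Random step vector ``A = 2a*r1 - a`` with ``r1 ~ U(0,1)`` per dimension."""
    if not 0.0 <= a <= 2.0:
        raise ValueError("a must lie in [0, 2]")
    r1 = rng.random(dim)
    return 2.0 * a * r1 - a


def chaotic_coefficients(n: int, nmax: int) -> tuple[float, float, float]:
    """Deterministic C1/C2/C3 schedules of the chaotic variant.

    C1 blends a decaying exponential with a bounded sinusoid, C2 the
    complementary rising exponential with the same sinusoid, and C3 a
    near-constant sigmoid times a negative quadratic ramp:

        C1 = 0.5 + 0.5*exp(-n/500) + 1.4*sin(n)/30
        C2 = 1 + 1.4*(1 - exp(-n/500)) + 1.4*sin(n)/30
        C3 = [1 / (1 + exp(-0.0001*n/nmax))] * (0.5 - 2.5) * (n/nmax)^2

    ``n`` is the integer iteration count, interpreted in radians by ``sin``.
    C3 is non-positive by construction; the absolute value in the distance
    term keeps distances non-negative regardless.
    """
    if nmax < 1:
        raise ValueError("nmax must be >= 1")
    if not 0 <= n <= nmax:
        raise ValueError("iteration n must satisfy 0 <= n <= nmax")
    c1 = 0.5 + 0.5 * math.exp(-n / 500.0) + 1.4 * math.sin(n) / 30.0
    c2 = 1.0 + 1.4 * (1.0 - math.exp(-n / 500.0)) + 1.4 * math.sin(n) / 30.0
    frac = n / nmax
    c3 = (1.0 / (1.0 + math.exp(-0.0001 * frac))) * (0.5 - 2.5) * frac**2
    return c1, c2, c3


def update_position(
    position: np.ndarray,
    leaders: tuple[np.ndarray, np.ndarray, np.ndarray],
    coeffs: CoefficientSet,
    space: SearchSpace,
) -> np.ndarray:
    """Propose a new position as the mean of the three leader-guided moves."""
    u = np.asarray(position, dtype=float)
    ua, ub, ud = (np.asarray(p, dtype=float) for p in leaders)
    for vec in (u, ua, ub, ud):
        if vec.shape != (space.dim,):
            raise ValueError("dimension mismatch between position and search space")
    la = np.abs(coeffs.C1 * ua - u)
    lb = np.abs(coeffs.C2 * ub - u)
    ld = np.abs(coeffs.C3 * ud - u)
    u1 = ua - coeffs.A1 * la
    u2 = ub - coeffs.A2 * lb
    u3 = ud - coeffs.A3 * ld
    return space.clamp((u1 + u2 + u3) / 3.0)


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[float] = field(default_factory=list)
    alpha_trace: list[np.ndarray] = field(default_factory=list)

    def trace_csv(self) -> str:
        dim = self.best_position.size
        lines = ["iteration,best_fitness," + ",".join(f"alpha_{j}" for j in range(dim))]
        for i, (fit, pos) in enumerate(zip(self.trace, self.alpha_trace)):
            lines.append(f"{i},{fit!r}," + ",".join(repr(x) for x in pos))
        return "\n".join(lines) + "\n"


def _rank_leaders(wolves: list[Wolf]) -> tuple[Wolf, Wolf, Wolf]:
    # stable sort: ties broken by wolf index
    order = sorted(range(len(wolves)), key=lambda i: (wolves[i].fitness, i))
    return wolves[order[0]], wolves[order[1]], wolves[order[2]]


def optimize(
    objective,
    space: SearchSpace,
    M: int = 20,
    nmax: int = 20,
    seed: int | None = None,
    variant: str = "cgwo",
    rng: np.random.Generator | None = None,
) -> OptimizeResult:
    """Minimize ``objective`` over ``space`` with a wolf pack.

    Parameters
    ----------
    objective
        Deterministic callable mapping a position vector to a scalar.
    M
        Pack size, at least 4 (three leaders plus a follower).
    nmax
        Number of iterations after initialization.
    variant
        ``"gwo"`` for random C coefficients, ``"cgwo"`` for the deterministic
        chaotic schedules.
    """
    if variant not in ("gwo", "cgwo"):
        raise ValueError(f"unknown variant {variant!r}")
    if M < 4:
        raise ValueError("pack size M must be >= 4")
    if nmax < 1:
        raise ValueError("nmax must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    def _eval(pos: np.ndarray) -> float:
        val = float(objective(pos))
        if not np.isfinite(val):
            raise ValueError(f"objective returned non-finite value at position {pos.tolist()}")
        return val

    positions = rng.uniform(space.lower, space.upper, size=(M, space.dim))
    wolves = [Wolf(position=positions[i].copy(), fitness=_eval(positions[i])) for i in range(M)]
    alpha, beta, delta = _rank_leaders(wolves)

    best = Wolf(position=alpha.position.copy(), fitness=alpha.fitness)
    trace = [best.fitness]
    alpha_trace = [best.position.copy()]

    for n in range(1, nmax + 1):
        a = linear_decay_a(n, nmax)
        if variant == "cgwo":
            c1, c2, c3 = chaotic_coefficients(n, nmax)
        # leaders are a snapshot from the end of the previous iteration
        lead_pos = (alpha.position.copy(), beta.position.copy(), delta.position.copy())
        for wolf in wolves:
            a1 = coeff_A(a, rng, space.dim)
            cc1 = 2.0 * rng.random(space.dim) if variant == "gwo" else c1
            a2 = coeff_A(a, rng, space.dim)
            cc2 = 2.0 * rng.random(space.dim) if variant == "gwo" else c2
            a3 = coeff_A(a, rng, space.dim)
            cc3 = 2.0 * rng.random(space.dim) if variant == "gwo" else c3
            coeffs = CoefficientSet(a=a, A1=a1, A2=a2, A3=a3, C1=cc1, C2=cc2, C3=cc3)
            proposal = update_position(wolf.position, lead_pos, coeffs, space)
            fit = _eval(proposal)
            if fit < wolf.fitness:  # greedy accept: improvement only
                wolf.position = proposal
                wolf.fitness = fit
        alpha, beta, delta = _rank_leaders(wolves)
        if alpha.fitness < best.fitness:
            best = Wolf(position=alpha.position.copy(), fitness=alpha.fitness)
        trace.append(best.fitness)
        alpha_trace.append(best.position.copy())

    return OptimizeResult(
        best_position=best.position, best_fitness=best.fitness, trace=trace, alpha_trace=alpha_trace
    )
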