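"""Fuzzy-set primitives.

Discrete fuzzy sets over a finite universe of subjects (children), piecewise-linear
membership functions over feature domains, alpha-cuts, the min/product t-norms with
their dual t-conorms, standard negation, and the fuzzy median operators that underpin
semi-fuzzy quantifier fuzzification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MembershipFunction",
    "triangular",
    "trapezoidal",
    "left_shoulder",
    "right_shoulder",
    "DiscreteFuzzySet",
    "CrispSubset",
    "alpha_cut",
    "t_norm_intersect",
    "t_conorm_union",
    "negate",
    "fuzzy_median",
    "generalized_fuzzy_median",
]

_SHAPES = ("triangular", "trapezoidal", "left_shoulder", "right_shoulder")


# ---------------------------------------------------------------------------
# Membership functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembershipFunction:
    """A piecewise-linear membership function mu: R -> [0, 1].

    Shapes and breakpoints:

    * ``triangular`` (a, b, c): 0 at a, peak 1 at b, 0 at c.
    * ``trapezoidal`` (a, b, c, d): 0 at a, plateau 1 on [b, c], 0 at d.
    * ``left_shoulder`` (b, c): 1 on (-inf, b], falling to 0 at c.
    * ``right_shoulder`` (a, b): 0 below a, rising to 1 at b, 1 on [b, +inf).

    Shoulders model the lowest/highest linguistic label of a variable: membership
    stays 1 all the way to the domain boundary.
    """

    shape: str
    breakpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown membership shape {self.shape!r}")
        bp = tuple(float(b) for b in self.breakpoints)
        expected = {"triangular": 3, "trapezoidal": 4,
                    "left_shoulder": 2, "right_shoulder": 2}[self.shape]
        if len(bp) != expected:
            raise ValueError(
                f"{self.shape} needs {expected} breakpoints, got {len(bp)}")
        if any(not math.isfinite(b) for b in bp):
            raise ValueError("breakpoints must be finite")
        if any(b2 < b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be non-decreasing")
        object.__setattr__(self, "breakpoints", bp)

    def __call__(self, x: float) -> float:
        return evaluate_membership(self, x)


def triangular(a: float, b: float, c: float) -> MembershipFunction:
    return MembershipFunction("triangular", (a, b, c))


def trapezoidal(a: float, b: float, c: float, d: float) -> MembershipFunction:
    return MembershipFunction("trapezoidal", (a, b, c, d))


def left_shoulder(b: float, c: float) -> MembershipFunction:
    """Plateau of 1 up to ``b``, linear descent to 0 at ``c``."""
    return MembershipFunction("left_shoulder", (b, c))


def right_shoulder(a: float, b: float) -> MembershipFunction:
    """0 below ``a``, linear ascent to 1 at ``b``, plateau of 1 beyond."""
    return MembershipFunction("right_shoulder", (a, b))


def _ramp_up(x: float, a: float, b: float) -> float:
    # 0 at a, 1 at b; degenerate a == b is a step
    if x <= a:
        return 0.0
    if x >= b:
        return 1.0
    return (x - a) / (b - a)


def evaluate_membership(mf: MembershipFunction, x: float) -> float:
    """Evaluate a piecewise-linear membership function at ``x``.

    Returns 0 outside the support on any non-shoulder side; shoulders evaluate
    to 1 beyond their plateau end.  Non-finite ``x`` raises ``ValueError``.
    """
    x = float(x)
    if not math.isfinite(x):
        raise ValueError("membership evaluation requires a finite input")
    bp = mf.breakpoints
    if mf.shape == "triangular":
        a, b, c = bp
        if x < b:
            return _ramp_up(x, a, b) if a < b else (1.0 if x == b else 0.0)
        if x > b:
            return 1.0 - _ramp_up(x, b, c) if b < c else 0.0
        return 1.0
    if mf.shape == "trapezoidal":
        a, b, c, d = bp
        if x < b:
            return _ramp_up(x, a, b) if a < b else (1.0 if x >= b else 0.0)
        if x > c:
            return 1.0 - _ramp_up(x, c, d) if c < d else 0.0
        return 1.0
    if mf.shape == "left_shoulder":
        b, c = bp
        if x <= b:
            return 1.0
        return 1.0 - _ramp_up(x, b, c) if b < c else 0.0
    # right shoulder
    a, b = bp
    if x >= b:
        return 1.0
    return _ramp_up(x, a, b) if a < b else 0.0


def evaluate_membership_array(mf: MembershipFunction, x) -> "np.ndarray":
    """Vectorized :func:`evaluate_membership` over a numpy array."""
    import numpy as np

    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("membership evaluation requires finite inputs")
    bp = mf.breakpoints

    def ramp(a: float, b: float) -> np.ndarray:
        if a == b:
            return (x >= b).astype(float)
        return np.clip((x - a) / (b - a), 0.0, 1.0)

    if mf.shape in ("triangular", "trapezoidal"):
        if mf.shape == "triangular":
            a, b, c = bp
            a, b, c, d = a, b, b, c
        else:
            a, b, c, d = bp
        up = ramp(a, b) if a < b else (x >= b).astype(float)
        down = 1.0 - ramp(c, d) if c < d else (x <= c).astype(float)
        return np.minimum(up, down)
    if mf.shape == "left_shoulder":
        b, c = bp
        return 1.0 - ramp(b, c) if b < c else (x <= b).astype(float)
    a, b = bp  # right shoulder
    return ramp(a, b) if a < b else (x >= b).astype(float)


# ---------------------------------------------------------------------------
# Discrete fuzzy sets
# ---------------------------------------------------------------------------

def _check_degree(v: float) -> float:
    v = float(v)
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"membership degree {v} outside [0, 1]")
    return v


@dataclass(frozen=True)
class DiscreteFuzzySet:
    """A fuzzy set over a finite, ordered universe of element identifiers."""

    universe: tuple
    memberships: Mapping

    def __post_init__(self) -> None:
        uni = tuple(self.universe)
        if not uni:
            raise ValueError("universe must be non-empty")
        if len(set(uni)) != len(uni):
            raise ValueError("universe elements must be unique")
        degs = dict(self.memberships)
        if set(degs) != set(uni):
            raise ValueError("memberships must cover exactly the universe")
        degs = {e: _check_degree(degs[e]) for e in uni}
        object.__setattr__(self, "universe", uni)
        object.__setattr__(self, "memberships", degs)

    def __getitem__(self, element) -> float:
        return self.memberships[element]

    def degrees(self) -> tuple[float, ...]:
        """Degrees in universe order."""
        return tuple(self.memberships[e] for e in self.universe)

    @staticmethod
    def from_degrees(universe: Sequence, degrees: Sequence[float]) -> "DiscreteFuzzySet":
        if len(universe) != len(degrees):
            raise ValueError("universe and degrees differ in length")
        return DiscreteFuzzySet(tuple(universe), dict(zip(universe, degrees)))


@dataclass(frozen=True)
class CrispSubset:
    """A crisp subset of a discrete universe."""

    universe: tuple
    elements: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        uni = tuple(self.universe)
        els = frozenset(self.elements)
        if not els <= set(uni):
            raise ValueError("elements must lie within the universe")
        object.__setattr__(self, "universe", uni)
        object.__setattr__(self, "elements", els)

    def __len__(self) -> int:
        return len(self.elements)

    def __contains__(self, e) -> bool:
        return e in self.elements

    def __le__(self, other: "CrispSubset") -> bool:
        return self.elements <= other.elements


def alpha_cut(A: DiscreteFuzzySet, alpha: float, strict: bool = False) -> CrispSubset:
    """Alpha-cut {x : mu(x) >= alpha}; strict uses > instead of >=."""
    alpha = float(alpha)
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if strict:
        els = {e for e in A.universe if A[e] > alpha}
    else:
        els = {e for e in A.universe if A[e] >= alpha}
    return CrispSubset(A.universe, frozenset(els))


def _check_same_universe(A: DiscreteFuzzySet, B: DiscreteFuzzySet) -> None:
    if A.universe != B.universe:
        raise ValueError("fuzzy sets are defined over different universes")


def t_norm_intersect(A: DiscreteFuzzySet, B: DiscreteFuzzySet,
                     t_norm: str = "min") -> DiscreteFuzzySet:
    """Element-wise fuzzy intersection under the chosen t-norm (min or product)."""
    _check_same_universe(A, B)
    op = combine_t_norm(t_norm)
    return DiscreteFuzzySet.from_degrees(
        A.universe, [op(A[e], B[e]) for e in A.universe])


def t_conorm_union(A: DiscreteFuzzySet, B: DiscreteFuzzySet,
                   t_conorm: str = "max") -> DiscreteFuzzySet:
    """Element-wise fuzzy union under the dual t-conorm (max or probabilistic sum)."""
    _check_same_universe(A, B)
    op = combine_t_conorm(t_conorm)
    return DiscreteFuzzySet.from_degrees(
        A.universe, [op(A[e], B[e]) for e in A.universe])


def combine_t_norm(name: str = "min"):
    if name == "min":
        return min
    if name == "product":
        return lambda a, b: a * b
    raise ValueError(f"unknown t-norm {name!r}")


def combine_t_conorm(name: str = "max"):
    if name == "max":
        return max
    if name == "probabilistic":
        return lambda a, b: a + b - a * b
    raise ValueError(f"unknown t-conorm {name!r}")


def negate(A: DiscreteFuzzySet) -> DiscreteFuzzySet:
    """Standard complement: mu -> 1 - mu."""
    return DiscreteFuzzySet.from_degrees(
        A.universe, [1.0 - A[e] for e in A.universe])


# ---------------------------------------------------------------------------
# Fuzzy medians
# ---------------------------------------------------------------------------

def fuzzy_median(u1: float, u2: float) -> float:
    """med_1/2: min if both degrees exceed 1/2, max if both fall below, else 1/2."""
    u1, u2 = _check_degree(u1), _check_degree(u2)
    if min(u1, u2) > 0.5:
        return min(u1, u2)
    if max(u1, u2) < 0.5:
        return max(u1, u2)
    return 0.5


def generalized_fuzzy_median(values: Iterable[float]) -> float:
    """med_1/2 of the infimum and supremum of a non-empty set of degrees."""
    vals = [_check_degree(v) for v in values]
    if not vals:
        raise ValueError("generalized fuzzy median of an empty set")
    return fuzzy_median(min(vals), max(vals))
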