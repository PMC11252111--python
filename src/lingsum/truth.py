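"""Truth-degree evaluation of quantified sentences.

Two routes are implemented:

* scalar-cardinality truth degrees — the quantifier MF applied to the
  (weighted) proportion of supporting subjects;
* the probabilistic quantifier-fuzzification mechanism, which evaluates a
  semi-fuzzy quantifier as the multiple integral of its value over all
  non-strict alpha-cut levels of the fuzzy arguments.  For discrete arguments
  the integral is an exact rectangle sum over the membership-level grid; a
  seeded Monte-Carlo estimator serves both as fallback for higher arities and
  as an independent oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .fuzzy_core import (
    CrispSubset,
    DiscreteFuzzySet,
    MembershipFunction,
    alpha_cut,
    combine_t_norm,
    evaluate_membership,
    evaluate_membership_array,
    generalized_fuzzy_median,
)
from .protoform import Composite, QuantifiedSentence, Quantifier

__all__ = [
    "UndefinedTruthError",
    "EvaluationConfig",
    "CutBounds",
    "truth_type1_scalar",
    "truth_type2_scalar",
    "cut_bounds",
    "q_gamma_evaluate",
    "semi_fuzzy_almost_all",
    "fi_evaluate",
    "fi_evaluate_details",
    "fi_monte_carlo",
    "fi_evaluate_binary_ratio",
    "fi_evaluate_unary_ratio",
    "evaluate_all",
]


class UndefinedTruthError(ValueError):
    """Raised when a truth degree is undefined (vacuous pre-summarizer)."""


@dataclass(frozen=True)
class EvaluationConfig:
    """How sentences are evaluated: method, t-norm, Monte-Carlo budget, seed."""

    method: str = "fi"  # "fi" | "scalar"
    t_norm: str = "min"
    t_conorm: str = "max"
    mc_samples: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("fi", "scalar"):
            raise ValueError(f"unknown evaluation method {self.method!r}")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be at least 1")


# ---------------------------------------------------------------------------
# Scalar-cardinality truth degrees
# ---------------------------------------------------------------------------

def truth_type1_scalar(quantifier: Quantifier,
                       summ_degrees: Sequence[float]) -> float:
    """Type-I truth: mu_Q(sum of summarizer degrees / R).

    R is the subject count for relative quantifiers, 1 for absolute ones.
    """
    degs = np.asarray(summ_degrees, dtype=float)
    if degs.size == 0:
        raise ValueError("no subjects in scope")
    r = degs.size if quantifier.kind == "relative" else 1
    return evaluate_membership(quantifier.mf, float(degs.sum()) / r)


def truth_type2_scalar(quantifier: Quantifier,
                       pre_degrees: Sequence[float],
                       summ_degrees: Sequence[float],
                       t_norm: str = "min") -> float:
    """Type-II truth: mu_Q(sum(pre x summ) / sum(pre)) under the t-norm.

    A zero denominator (no subject supports the pre-summarizer at all) raises
    :class:`UndefinedTruthError`; such sentences carry no evidence.
    """
    pre = np.asarray(pre_degrees, dtype=float)
    summ = np.asarray(summ_degrees, dtype=float)
    if pre.shape != summ.shape or pre.size == 0:
        raise ValueError("degree vectors must be non-empty and aligned")
    denom = float(pre.sum())
    if denom == 0.0:
        raise UndefinedTruthError("pre-summarizer supports no subject")
    if t_norm == "min":
        num = float(np.minimum(pre, summ).sum())
    elif t_norm == "product":
        num = float((pre * summ).sum())
    else:
        raise ValueError(f"unknown t-norm {t_norm!r}")
    return evaluate_membership(quantifier.mf, num / denom)


# ---------------------------------------------------------------------------
# Semi-fuzzy quantifier machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutBounds:
    """Lower/upper crisp envelopes of a fuzzy set at slack level gamma."""

    gamma: float
    lower: CrispSubset
    upper: CrispSubset


def cut_bounds(X: DiscreteFuzzySet, gamma: float) -> CutBounds:
    """Crisp envelope of X at slack gamma.

    gamma = 0: (strict cut at 1/2, cut at 1/2);
    gamma > 0: (cut at 1/2 + gamma/2, strict cut at 1/2 - gamma/2).
    """
    gamma = float(gamma)
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    if gamma == 0.0:
        lower = alpha_cut(X, 0.5, strict=True)
        upper = alpha_cut(X, 0.5, strict=False)
    else:
        lower = alpha_cut(X, 0.5 + 0.5 * gamma, strict=False)
        upper = alpha_cut(X, 0.5 - 0.5 * gamma, strict=True)
    return CutBounds(gamma, lower, upper)


def q_gamma_evaluate(Q: Callable[..., float],
                     args: Sequence[DiscreteFuzzySet],
                     gamma: float) -> float:
    """Generalized fuzzy median of Q over all crisp sets between the envelopes.

    Brute-force enumeration; restricted to universes of at most 15 elements.
    """
    bounds = [cut_bounds(X, gamma) for X in args]
    for X in args:
        if len(X.universe) > 15:
            raise ValueError(
                "universe too large for enumeration; use fi_evaluate")
    choices_per_arg = []
    for X, b in zip(args, bounds):
        slack = sorted(b.upper.elements - b.lower.elements,
                       key=X.universe.index)
        choices = []
        for r in range(len(slack) + 1):
            for extra in itertools.combinations(slack, r):
                choices.append(CrispSubset(
                    X.universe, b.lower.elements | frozenset(extra)))
        choices_per_arg.append(choices)
    values = [Q(*combo) for combo in itertools.product(*choices_per_arg)]
    return generalized_fuzzy_median(values)


def semi_fuzzy_almost_all(X1: CrispSubset, X2: CrispSubset) -> float:
    """Semi-fuzzy 'almost all': max{2(|X1 n X2| / |X1|) - 1, 0}; 1 if X1 empty."""
    if X1.universe != X2.universe:
        raise ValueError("crisp subsets live on different universes")
    if len(X1) == 0:
        return 1.0
    ratio = len(X1.elements & X2.elements) / len(X1)
    return max(2.0 * ratio - 1.0, 0.0)


# ---------------------------------------------------------------------------
# Probabilistic fuzzification: exact rectangle decomposition
# ---------------------------------------------------------------------------

def _level_intervals(S: DiscreteFuzzySet) -> list[tuple[float, float, CrispSubset]]:
    """Partition (0, 1] into intervals on which the non-strict cut is constant.

    Returns (lo, hi, cut) triples with cut = {e : mu(e) >= hi}; the alpha-cut
    equals that cut for every alpha in (lo, hi].
    """
    vals = sorted({d for d in S.degrees() if d > 0.0})
    bounds = [0.0] + vals
    if not vals or vals[-1] < 1.0:
        bounds.append(1.0)
    out = []
    for lo, hi in zip(bounds, bounds[1:]):
        out.append((lo, hi, alpha_cut(S, hi, strict=False)))
    return out


@dataclass(frozen=True)
class FiResult:
    """Exact rectangle decomposition of the fuzzification integral."""

    value: float
    exact: bool
    # per argument: list of (lo, hi] interval bounds
    intervals: tuple[tuple[tuple[float, float], ...], ...]
    # flat grid cells: (interval index per argument, width product, Q value)
    cells: tuple[tuple[tuple[int, ...], float, float], ...]


def fi_evaluate_details(Q: Callable[..., float],
                        args: Sequence[DiscreteFuzzySet]) -> FiResult:
    """Exact evaluation of the fuzzification integral with the full cell grid.

    For each argument the distinct membership values partition (0, 1] into
    intervals on which the non-strict alpha-cut is constant; the integral is
    the sum over the K-dimensional interval grid of (product of widths) x
    Q(cut tuple).  Supported for arity <= 3.
    """
    if not args:
        raise ValueError("need at least one fuzzy argument")
    if len(args) > 3:
        raise ValueError("exact path supports arity <= 3; use fi_monte_carlo")
    per_arg = [_level_intervals(S) for S in args]
    intervals = tuple(tuple((lo, hi) for lo, hi, _ in levels)
                      for levels in per_arg)
    cells = []
    total = 0.0
    for combo in itertools.product(*(enumerate(lv) for lv in per_arg)):
        idx = tuple(i for i, _ in combo)
        width = 1.0
        cuts = []
        for _, (lo, hi, cut) in combo:
            width *= (hi - lo)
            cuts.append(cut)
        qv = float(Q(*cuts))
        cells.append((idx, width, qv))
        total += width * qv
    return FiResult(total, True, intervals, tuple(cells))


def fi_evaluate(Q: Callable[..., float],
                args: Sequence[DiscreteFuzzySet],
                mc_samples: int = 100_000,
                seed: int = 0) -> float:
    """Fuzzified quantifier value: exact for arity <= 3, Monte-Carlo beyond."""
    if len(args) <= 3:
        return fi_evaluate_details(Q, args).value
    return fi_monte_carlo(Q, args, mc_samples, seed)


def fi_monte_carlo(Q: Callable[..., float],
                   args: Sequence[DiscreteFuzzySet],
                   n_samples: int = 100_000,
                   seed: int = 0) -> float:
    """Monte-Carlo estimate of the fuzzification integral.

    Draws alpha levels uniformly on (0, 1] per argument and averages the
    semi-fuzzy quantifier on the corresponding non-strict cuts.  Serves as the
    independent oracle for the exact rectangle decomposition.
    """
    rng = np.random.default_rng(seed)
    universes = [S.universe for S in args]
    degs = [np.array(S.degrees()) for S in args]
    total = 0.0
    alphas = 1.0 - rng.random((n_samples, len(args)))  # uniform on (0, 1]
    for row in alphas:
        cuts = [CrispSubset(uni,
                            frozenset(e for e, d in zip(uni, dg) if d >= a))
                for uni, dg, a in zip(universes, degs, row)]
        total += float(Q(*cuts))
    return total / n_samples


# ---------------------------------------------------------------------------
# Fast exact paths for ratio-form quantifiers (vectorized)
# ---------------------------------------------------------------------------

def _level_bounds(mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interval widths and representative cut levels for one degree vector."""
    vals = np.unique(mu[mu > 0.0])
    bounds = np.concatenate(([0.0], vals))
    if vals.size == 0 or vals[-1] < 1.0:
        bounds = np.concatenate((bounds, [1.0]))
    widths = np.diff(bounds)
    reps = bounds[1:]
    return widths, reps


def fi_evaluate_binary_ratio(ratio_mf: MembershipFunction,
                             mu1: np.ndarray, mu2: np.ndarray) -> float:
    """Exact fuzzification of a binary ratio quantifier Q(X1, X2).

    Q(X1, X2) = mu(|X1 n X2| / |X1|) with Q(empty, .) = 1.  Equivalent to the
    generic rectangle decomposition, but computed with a two-dimensional
    suffix-sum over membership levels so whole-cohort sentence sets stay fast.
    """
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    if mu1.shape != mu2.shape or mu1.size == 0:
        raise ValueError("degree vectors must be non-empty and aligned")
    w1, r1 = _level_bounds(mu1)
    w2, r2 = _level_bounds(mu2)
    # |X1| at each level of argument 1
    cnt1 = (mu1[None, :] >= r1[:, None]).sum(axis=1).astype(float)
    # joint histogram over (level index reached in arg1, in arg2)
    j1 = np.searchsorted(r1, mu1, side="right") - 1
    j2 = np.searchsorted(r2, mu2, side="right") - 1
    hist = np.zeros((r1.size, r2.size))
    mask = (j1 >= 0) & (j2 >= 0)
    np.add.at(hist, (j1[mask], j2[mask]), 1.0)
    inter = np.cumsum(np.cumsum(hist[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cnt1[:, None] > 0, inter / cnt1[:, None], 0.0)
    q = evaluate_membership_array(ratio_mf, ratio)
    q[cnt1 == 0, :] = 1.0
    return float(w1 @ q @ w2)


def fi_evaluate_unary_ratio(ratio_mf: MembershipFunction, mu1: np.ndarray,
                            total: Optional[int] = None) -> float:
    """Exact fuzzification of a unary relative quantifier Q(X1) = mu(|X1|/M)."""
    mu1 = np.asarray(mu1, dtype=float)
    if mu1.size == 0:
        raise ValueError("no subjects in scope")
    m = total if total is not None else mu1.size
    w, r = _level_bounds(mu1)
    cnt = (mu1[None, :] >= r[:, None]).sum(axis=1).astype(float)
    q = evaluate_membership_array(ratio_mf, cnt / m)
    return float(w @ q)


# ---------------------------------------------------------------------------
# Whole-sentence evaluation
# ---------------------------------------------------------------------------

def _composite_degrees(comp: Composite, degrees, mask: np.ndarray,
                       config: EvaluationConfig) -> np.ndarray:
    vecs = []
    for feat, label in comp.terms:
        vec = degrees[(feat, label)]
        vecs.append(np.asarray(vec, dtype=float)[mask])
    out = vecs[0]
    for v in vecs[1:]:
        if comp.connective == "and":
            out = (np.minimum(out, v) if config.t_norm == "min" else out * v)
        else:
            out = (np.maximum(out, v) if config.t_conorm == "max"
                   else out + v - out * v)
    return out


def evaluate_all(sentences: Sequence[QuantifiedSentence],
                 degrees, groups: Sequence[str],
                 config: EvaluationConfig = EvaluationConfig()) -> list[QuantifiedSentence]:
    """Assign truth degrees to sentences in place and return them.

    ``degrees`` maps (feature, label) to a per-subject degree vector aligned
    with ``groups``.  Scope restricts the subject universe before evaluation.
    Under the fuzzification method, the pre-summarizer degrees form X1 and the
    (t-norm-combined) summarizer degrees X2; the scalar method applies the
    weighted-proportion formulas.  Sentences whose scalar denominator is zero
    are flagged undefined rather than given a number.
    """
    groups = np.asarray(groups)
    for s in sentences:
        mask = (groups == s.scope) if s.scope != "all" else np.ones(
            groups.shape, dtype=bool)
        if not mask.any():
            raise ValueError(f"no subjects in scope {s.scope!r}")
        summ = _composite_degrees(s.summarizer, degrees, mask, config)
        try:
            if s.form == "type1":
                if config.method == "fi":
                    if s.quantifier.kind == "relative":
                        s.truth = fi_evaluate_unary_ratio(
                            s.quantifier.semi_fuzzy_mf, summ)
                    else:
                        w, r = _level_bounds(summ)
                        cnt = (summ[None, :] >= r[:, None]).sum(axis=1)
                        q = evaluate_membership_array(
                            s.quantifier.semi_fuzzy_mf, cnt.astype(float))
                        s.truth = float(w @ q)
                else:
                    s.truth = truth_type1_scalar(s.quantifier, summ)
            else:
                pre = _composite_degrees(s.pre_summarizer, degrees, mask, config)
                if config.method == "fi":
                    s.truth = fi_evaluate_binary_ratio(
                        s.quantifier.semi_fuzzy_mf, pre, summ)
                else:
                    s.truth = truth_type2_scalar(
                        s.quantifier, pre, summ, t_norm=config.t_norm)
            s.undefined = False
        except UndefinedTruthError:
            s.truth = None
            s.undefined = True
    return list(sentences)
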