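"""Linguistic-variable induction from cohort feature values.

Fuzzy c-means (FCM) places cluster centers on each feature; the sorted centers
anchor a Ruspini partition of shoulder + triangular membership functions, giving
three-level labels (low / medium / high) for attention and Bayley composite
features and five-level age-relative labels (far behind ... far ahead) for
Bayley subscale age-equivalents, computed on the difference
(age-equivalent - chronological age) in months.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fuzzy_core import (
    MembershipFunction,
    evaluate_membership,
    left_shoulder,
    right_shoulder,
    triangular,
)

__all__ = [
    "FcmResult",
    "LinguisticVariable",
    "fit_fcm",
    "variable_from_centers",
    "build_age_relative_variable",
    "fuzzify_record",
    "THREE_LEVEL_LABELS",
    "AGE_RELATIVE_LABELS",
]

THREE_LEVEL_LABELS = ("low", "medium", "high")
AGE_RELATIVE_LABELS = ("far behind", "behind", "equal", "ahead", "far ahead")


@dataclass(frozen=True)
class FcmResult:
    """Outcome of a fuzzy c-means fit on one feature.

    ``centers`` are sorted ascending (feature units); ``membership_matrix`` is
    n x k with rows summing to 1; ``objective_trace`` records the objective at
    each iteration (non-increasing).
    """

    centers: tuple[float, ...]
    membership_matrix: np.ndarray
    objective: float
    iterations: int
    objective_trace: tuple[float, ...]


def _init_centers(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style farthest-point spread, seeded."""
    centers = [values[rng.integers(len(values))]]
    for _ in range(1, k):
        d2 = np.min((values[:, None] - np.array(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a center
            centers.append(values[rng.integers(len(values))])
            continue
        centers.append(values[rng.choice(len(values), p=d2 / total)])
    return np.array(centers, dtype=float)


def fit_fcm(values: Sequence[float], k: int, fuzzifier: float = 2.0,
            tol: float = 1e-6, max_iter: int = 300, seed: int = 0) -> FcmResult:
    """Fit 1-D fuzzy c-means by alternating optimisation.

    Minimises sum_i sum_j u_ij^m (x_i - c_j)^2 subject to rows of u summing
    to 1.  Convergence: maximum center shift below ``tol`` or ``max_iter``.
    Centers (and membership columns) are returned sorted ascending.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if k < 1:
        raise ValueError("k must be at least 1")
    if n < k:
        raise ValueError(f"cannot fit {k} clusters to {n} values")
    if fuzzifier <= 1.0:
        raise ValueError("fuzzifier must exceed 1")
    if k > 1 and np.ptp(x) == 0.0:
        raise ValueError("degenerate clustering: all values identical")
    if k == 1:
        u = np.ones((n, 1))
        c = np.array([x.mean()])
        obj = float(np.sum((x - c[0]) ** 2))
        return FcmResult((float(c[0]),), u, obj, 0, (obj,))

    rng = np.random.default_rng(seed)
    centers = _init_centers(x, k, rng)
    m = float(fuzzifier)
    trace: list[float] = []
    u = None
    for it in range(1, max_iter + 1):
        d2 = (x[:, None] - centers[None, :]) ** 2
        # membership update; rows hitting a center exactly get crisp membership
        hit = d2 == 0.0
        anyhit = hit.any(axis=1)
        u = np.empty_like(d2)
        inv = d2[~anyhit] ** (-1.0 / (m - 1.0))
        u[~anyhit] = inv / inv.sum(axis=1, keepdims=True)
        if anyhit.any():
            h = hit[anyhit].astype(float)
            u[anyhit] = h / h.sum(axis=1, keepdims=True)
        um = u ** m
        new_centers = um.T @ x / um.sum(axis=0)
        trace.append(float(np.sum(um * (x[:, None] - centers[None, :]) ** 2)))
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            break
    order = np.argsort(centers)
    centers = centers[order]
    u = u[:, order]
    d2 = (x[:, None] - centers[None, :]) ** 2
    obj = float(np.sum((u ** m) * d2))
    trace.append(obj)
    return FcmResult(tuple(float(c) for c in centers), u, obj, it, tuple(trace))


@dataclass(frozen=True)
class LinguisticVariable:
    """A feature with an ordered set of labelled membership functions.

    Label order follows ascending MF centers; adjacent functions cross at 0.5
    at center midpoints, so memberships form a Ruspini partition inside the
    span of the centers.  ``display_name`` is the noun phrase used when
    rendering sentences ("animation net dwell time"); ``age_relative`` marks
    five-level variables defined on (age-equivalent - chronological age).
    """

    feature_name: str
    labels: tuple[str, ...]
    functions: Mapping[str, MembershipFunction]
    display_name: str = ""
    age_relative: bool = False

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        funcs = dict(self.functions)
        if set(funcs) != set(labels):
            raise ValueError("functions must cover exactly the labels")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "functions", funcs)
        if not self.display_name:
            object.__setattr__(
                self, "display_name", self.feature_name.replace("_", " "))

    def membership(self, label: str, x: float) -> float:
        return evaluate_membership(self.functions[label], x)


def variable_from_centers(centers: Sequence[float], labels: Sequence[str],
                          data_range: tuple[float, float],
                          feature_name: str = "feature",
                          display_name: str = "",
                          age_relative: bool = False) -> LinguisticVariable:
    """Build shoulder/triangular MFs anchored at sorted FCM centers.

    First label: left shoulder (plateau from the range minimum to c1, falling
    to 0 at c2).  Last label: right shoulder, mirrored.  Interior labels:
    triangular (c_{i-1}, c_i, c_{i+1}).  The construction is a Ruspini
    partition on [c1, ck].
    """
    cs = [float(c) for c in centers]
    labels = tuple(labels)
    if len(cs) != len(labels) or len(cs) < 2:
        raise ValueError("need equally many centers and labels, at least 2")
    if any(c2 < c1 for c1, c2 in zip(cs, cs[1:])):
        raise ValueError("centers must be sorted ascending")
    lo, hi = float(data_range[0]), float(data_range[1])
    if cs[0] < lo or cs[-1] > hi:
        raise ValueError("centers must lie within the data range")
    funcs: dict[str, MembershipFunction] = {labels[0]: left_shoulder(cs[0], cs[1])}
    for i in range(1, len(cs) - 1):
        funcs[labels[i]] = triangular(cs[i - 1], cs[i], cs[i + 1])
    funcs[labels[-1]] = right_shoulder(cs[-2], cs[-1])
    return LinguisticVariable(feature_name, labels, funcs,
                              display_name=display_name,
                              age_relative=age_relative)


def build_age_relative_variable(differences: Sequence[float], seed: int = 0,
                                feature_name: str = "age_difference",
                                display_name: str = "") -> LinguisticVariable:
    """Five-level age-relative variable from (age-equivalent - age) differences.

    FCM with k=5 on the differences in months; sorted centers map to
    far behind / behind / equal / ahead / far ahead.
    """
    diffs = np.asarray(differences, dtype=float).ravel()
    if np.unique(diffs).size < 5:
        raise ValueError("need at least 5 distinct difference values")
    fit = fit_fcm(diffs, k=5, seed=seed)
    return variable_from_centers(
        fit.centers, AGE_RELATIVE_LABELS,
        (float(diffs.min()), float(diffs.max())),
        feature_name=feature_name, display_name=display_name,
        age_relative=True)


class MissingValue:
    """Sentinel marking a feature value absent from a record (never silently 0)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"


MISSING = MissingValue()


def fuzzify_record(record: Mapping[str, float],
                   variables: Sequence[LinguisticVariable]) -> dict:
    """Map a record to (feature, label) -> degree across all variables.

    A feature absent from the record (or NaN) yields the MISSING sentinel for
    all its labels.
    """
    out: dict[tuple[str, str], object] = {}
    for var in variables:
        value = record.get(var.feature_name, None)
        absent = value is None or (isinstance(value, float) and np.isnan(value))
        for label in var.labels:
            if absent:
                out[(var.feature_name, label)] = MISSING
            else:
                out[(var.feature_name, label)] = var.membership(label, float(value))
    return out
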