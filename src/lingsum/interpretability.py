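"""Summary reduction: threshold, negation duals, contradictions, inclusion, merging.

Raw enumeration produces far more sentences than a reader can use.  This module
keeps only high-truth sentences, removes "few" sentences that merely restate a
retained "most" sentence by negation, reports contradictory pairs, removes
sentences whose quantifier and summarizer are pointwise dominated by another's
(inclusion redundancy), and merges sentences sharing a pre-summarizer (into
"and" summarizer composites) or a summarizer (into "or" pre-summarizer
composites), re-evaluating each merged sentence's truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .fuzzy_core import evaluate_membership_array
from .fuzzification import LinguisticVariable
from .protoform import Composite, QuantifiedSentence

__all__ = [
    "SummaryReport",
    "filter_by_threshold",
    "drop_negation_duals",
    "detect_contradiction",
    "detect_inclusion_redundancy",
    "merge_sentences",
    "reduce_summary",
    "DEFAULT_QUANTIFIER_ANTONYMS",
    "DEFAULT_LABEL_ANTONYMS",
]

DEFAULT_QUANTIFIER_ANTONYMS = {"few": "most", "most": "few"}
DEFAULT_LABEL_ANTONYMS = {
    "low": "high", "high": "low",
    "far behind": "far ahead", "far ahead": "far behind",
    "behind": "ahead", "ahead": "behind",
}


@dataclass
class SummaryReport:
    """Partition of an evaluated sentence set after reduction.

    ``retained`` and ``merged`` together form the final summary; every input
    sentence lands exactly once in ``retained`` or ``dropped`` (merge sources
    are dropped with reason ``merged_away``).  Contradictory retained pairs are
    reported, not resolved.
    """

    retained: list = field(default_factory=list)
    merged: list = field(default_factory=list)
    dropped: list = field(default_factory=list)  # (sentence, reason)
    contradictions: list = field(default_factory=list)  # (s1, s2)


def filter_by_threshold(sentences: Sequence[QuantifiedSentence],
                        tau: float) -> tuple[list, list]:
    """Keep sentences with truth >= tau (boundary inclusive); drop the rest.

    Undefined truths never pass.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau must lie in [0, 1]")
    kept, dropped = [], []
    for s in sentences:
        if s.truth is not None and s.truth >= tau:
            kept.append(s)
        else:
            dropped.append((s, "below_threshold"))
    return kept, dropped


def _antonym_composite(comp: Composite,
                       label_antonyms: Mapping[str, str]) -> Optional[tuple]:
    terms = []
    for feat, label in comp.terms:
        if label not in label_antonyms:
            return None
        terms.append((feat, label_antonyms[label]))
    return (comp.connective, tuple(sorted(terms)))


def drop_negation_duals(sentences: Sequence[QuantifiedSentence],
                        quantifier_antonyms: Mapping[str, str] = DEFAULT_QUANTIFIER_ANTONYMS,
                        label_antonyms: Mapping[str, str] = DEFAULT_LABEL_ANTONYMS,
                        preferred: str = "most") -> tuple[list, list]:
    """Drop "few"-family sentences that are negation duals of retained
    "most"-family sentences.

    A few-sentence is the dual of a most-sentence with the same scope and
    pre-summarizer whose summarizer labels are the declared antonyms.  The
    decision depends only on the input set, not its order.
    """
    preferred_keys = set()
    for s in sentences:
        if s.quantifier.name == preferred:
            pre = s.pre_summarizer.key() if s.pre_summarizer else None
            preferred_keys.add((s.form, s.scope, pre, s.summarizer.key()))
    kept, dropped = [], []
    for s in sentences:
        dual_of = quantifier_antonyms.get(s.quantifier.name)
        if dual_of == preferred:
            anto = _antonym_composite(s.summarizer, label_antonyms)
            pre = s.pre_summarizer.key() if s.pre_summarizer else None
            if anto is not None and (s.form, s.scope, pre, anto) in preferred_keys:
                dropped.append((s, "negation_dual"))
                continue
        kept.append(s)
    return kept, dropped


def detect_contradiction(s1: QuantifiedSentence, s2: QuantifiedSentence,
                         tau: float = 0.9,
                         quantifier_antonyms: Mapping[str, str] = DEFAULT_QUANTIFIER_ANTONYMS,
                         label_antonyms: Mapping[str, str] = DEFAULT_LABEL_ANTONYMS) -> bool:
    """True iff s2 asserts "not-Q B Y are A" or "Q B Y are not-A" against s1
    and both truths reach tau.

    Negation is read through the declared antonym pairs (quantifier few/most;
    summarizer labels low/high, behind/ahead).
    """
    if s1.scope != s2.scope or s1.form != s2.form:
        return False
    pre1 = s1.pre_summarizer.key() if s1.pre_summarizer else None
    pre2 = s2.pre_summarizer.key() if s2.pre_summarizer else None
    if pre1 != pre2:
        return False
    if s1.summarizer.features != s2.summarizer.features:
        return False
    if s1.truth is None or s2.truth is None:
        return False
    if s1.truth < tau or s2.truth < tau:
        return False
    if s1.key() == s2.key():
        return False
    anto_q = quantifier_antonyms.get(s1.quantifier.name)
    anto_s = _antonym_composite(s1.summarizer, label_antonyms)
    # not-Q B Y are A
    if anto_q == s2.quantifier.name and s1.summarizer.key() == s2.summarizer.key():
        return True
    # Q B Y are not-A
    if (s1.quantifier.name == s2.quantifier.name and anto_s is not None
            and anto_s == s2.summarizer.key()):
        return True
    return False


@lru_cache(maxsize=65536)
def _dominated(mf1, mf2, lo: float, hi: float,
               grid_points: int = 1001, tol: float = 1e-9) -> bool:
    xs = np.linspace(lo, hi, grid_points)
    return bool(np.all(evaluate_membership_array(mf1, xs)
                       <= evaluate_membership_array(mf2, xs) + tol))


def _compat_key(s: QuantifiedSentence) -> tuple:
    """Sentences can only contradict or include each other within this key."""
    pre = s.pre_summarizer.key() if s.pre_summarizer else None
    return (s.form, s.scope, pre, s.summarizer.features,
            s.summarizer.connective)


def detect_inclusion_redundancy(s1: QuantifiedSentence, s2: QuantifiedSentence,
                                variables: Mapping[str, LinguisticVariable],
                                grid_points: int = 1001,
                                tol: float = 1e-9) -> bool:
    """True iff s1 is included in s2 (so s1 is redundant and droppable).

    Requires equal scope, form and pre-summarizer, and summarizers on the same
    features; checks mu_Q1 <= mu_Q2 pointwise on a [0,1] grid and per-feature
    summarizer-MF dominance on the feature's breakpoint span.
    """
    if s1.scope != s2.scope or s1.form != s2.form:
        return False
    pre1 = s1.pre_summarizer.key() if s1.pre_summarizer else None
    pre2 = s2.pre_summarizer.key() if s2.pre_summarizer else None
    if pre1 != pre2:
        return False
    if s1.summarizer.features != s2.summarizer.features:
        return False
    if s1.summarizer.connective != s2.summarizer.connective:
        return False
    if not _dominated(s1.quantifier.mf, s2.quantifier.mf, 0.0, 1.0,
                      grid_points, tol):
        return False
    lab1 = dict(s1.summarizer.terms)
    lab2 = dict(s2.summarizer.terms)
    for feat in lab1:
        mf1 = variables[feat].functions[lab1[feat]]
        mf2 = variables[feat].functions[lab2[feat]]
        pts = mf1.breakpoints + mf2.breakpoints
        lo, hi = min(pts), max(pts)
        if lo == hi:
            lo, hi = lo - 1.0, hi + 1.0
        if not _dominated(mf1, mf2, lo, hi, grid_points, tol):
            return False
    return True


def _remove_inclusion_redundant(sentences, variables) -> tuple[list, list]:
    # inclusion needs identical scope/form/pre/summarizer-features, so only
    # sentences within one compatibility group can eliminate each other
    groups: dict[tuple, list[QuantifiedSentence]] = {}
    for s in sentences:
        groups.setdefault(_compat_key(s), []).append(s)
    dropped_ids: dict[int, QuantifiedSentence] = {}
    for group in groups.values():
        kept: list[QuantifiedSentence] = []
        for s in group:
            if any(detect_inclusion_redundancy(s, r, variables) for r in kept):
                dropped_ids[id(s)] = s
                continue
            still = []
            for r in kept:
                if detect_inclusion_redundancy(r, s, variables):
                    dropped_ids[id(r)] = r
                else:
                    still.append(r)
            kept = still + [s]
    keep = [s for s in sentences if id(s) not in dropped_ids]
    drop = [(s, "inclusion_redundant") for s in dropped_ids.values()]
    return keep, drop


def merge_sentences(sentences: Sequence[QuantifiedSentence],
                    evaluate_fn: Callable[[QuantifiedSentence], Optional[float]],
                    tau: Optional[float] = None) -> tuple[list, list, list]:
    """Merge sentence groups into composite sentences.

    Type-II sentences sharing (scope, quantifier, pre-summarizer) merge their
    summarizers into an "and" composite; sentences sharing (scope, quantifier,
    summarizer) merge their pre-summarizers into an "or" composite.  Merged
    truth is re-evaluated on the composite via ``evaluate_fn``, never inherited.
    A merge is only committed when the re-evaluated truth is defined and (when
    ``tau`` is given) still reaches the threshold; otherwise the sources stay.

    Returns (retained singles, merged sentences, merge-source drops).
    """
    retained, merged, dropped = [], [], []
    remaining = list(sentences)

    def try_merge(group: list[QuantifiedSentence],
                  build: Callable[[], QuantifiedSentence]) -> bool:
        try:
            new = build()
        except ValueError:  # e.g. duplicated features in the composite
            return False
        t = evaluate_fn(new)
        if t is None or (tau is not None and t < tau):
            return False
        new.truth = t
        merged.append(new)
        dropped.extend((s, "merged_away") for s in group)
        return True

    def _singleton(s: QuantifiedSentence) -> bool:
        # only simple sentences are merge candidates; composites produced by a
        # previous merge pass through untouched, which makes reduction idempotent
        return (len(s.summarizer.terms) == 1
                and s.pre_summarizer is not None
                and len(s.pre_summarizer.terms) == 1)

    # shared pre-summarizer -> "and" summarizer composite
    by_pre: dict[tuple, list[QuantifiedSentence]] = {}
    for s in remaining:
        if s.form != "type2" or not _singleton(s):
            continue
        key = (s.scope, s.quantifier.name, s.pre_summarizer.key())
        by_pre.setdefault(key, []).append(s)
    absorbed: set[int] = set()
    for group in by_pre.values():
        if len(group) < 2:
            continue
        feats = [f for s in group for f, _ in s.summarizer.terms]
        if len(set(feats)) != len(feats):
            continue
        g0 = group[0]
        terms = tuple(t for s in group for t in s.summarizer.terms)

        def build(g0=g0, terms=terms):
            return QuantifiedSentence(
                "type2", g0.quantifier, Composite(terms, "and"),
                pre_summarizer=g0.pre_summarizer, scope=g0.scope)

        if try_merge(group, build):
            absorbed.update(id(s) for s in group)
    remaining = [s for s in remaining if id(s) not in absorbed]

    # shared summarizer -> "or" pre-summarizer composite
    by_summ: dict[tuple, list[QuantifiedSentence]] = {}
    for s in remaining:
        if s.form != "type2" or not _singleton(s):
            continue
        key = (s.scope, s.quantifier.name, s.summarizer.key())
        by_summ.setdefault(key, []).append(s)
    absorbed = set()
    for group in by_summ.values():
        if len(group) < 2:
            continue
        feats = [f for s in group for f, _ in s.pre_summarizer.terms]
        if len(set(feats)) != len(feats):
            continue
        g0 = group[0]
        terms = tuple(t for s in group for t in s.pre_summarizer.terms)

        def build(g0=g0, terms=terms):
            return QuantifiedSentence(
                "type2", g0.quantifier, g0.summarizer,
                pre_summarizer=Composite(terms, "or"), scope=g0.scope)

        if try_merge(group, build):
            absorbed.update(id(s) for s in group)
    retained = [s for s in remaining if id(s) not in absorbed]
    return retained, merged, dropped


def reduce_summary(sentences: Sequence[QuantifiedSentence],
                   variables: Mapping[str, LinguisticVariable],
                   evaluate_fn: Callable[[QuantifiedSentence], Optional[float]],
                   tau: float = 0.9,
                   quantifier_antonyms: Mapping[str, str] = DEFAULT_QUANTIFIER_ANTONYMS,
                   label_antonyms: Mapping[str, str] = DEFAULT_LABEL_ANTONYMS) -> SummaryReport:
    """Full reduction pipeline.

    Order: threshold filter -> negation-dual removal -> contradiction report
    (pairs are reported, never auto-dropped) -> inclusion-redundancy removal ->
    merging.  Deterministic given input order; conservation holds: every input
    sentence appears exactly once across retained and dropped.
    """
    report = SummaryReport()
    kept, dropped = filter_by_threshold(sentences, tau)
    report.dropped.extend(dropped)
    kept, dropped = drop_negation_duals(kept, quantifier_antonyms, label_antonyms)
    report.dropped.extend(dropped)
    by_compat: dict[tuple, list[QuantifiedSentence]] = {}
    for s in kept:
        by_compat.setdefault(_compat_key(s), []).append(s)
    for group in by_compat.values():
        for i, s1 in enumerate(group):
            for s2 in group[i + 1:]:
                if detect_contradiction(s1, s2, tau, quantifier_antonyms,
                                        label_antonyms):
                    report.contradictions.append((s1, s2))
    kept, dropped = _remove_inclusion_redundant(kept, variables)
    report.dropped.extend(dropped)
    retained, merged, dropped = merge_sentences(kept, evaluate_fn, tau=tau)
    report.dropped.extend(dropped)
    report.retained = retained
    report.merged = merged
    return report
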