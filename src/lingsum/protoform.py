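"""Quantified-sentence protoforms and their natural-language rendering.

Type-I sentences read "Q Y's are/have S" ("Most of the children have high
animation dwell time"); type-II sentences add a pre-summarizer restricting the
subjects ("Most of the ASD child who is far behind by cognitive age also has
low language composite").  This module enumerates candidate sentences over
linguistic variables, quantifiers and group scopes, and renders them as text;
truth evaluation lives in :mod:`lingsum.truth`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .fuzzy_core import (
    MembershipFunction,
    evaluate_membership,
    right_shoulder,
    trapezoidal,
    triangular,
)
from .fuzzification import LinguisticVariable

__all__ = [
    "Quantifier",
    "Composite",
    "QuantifiedSentence",
    "default_quantifiers",
    "enumerate_sentences",
    "render_sentence",
]


# ---------------------------------------------------------------------------
# Quantifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Quantifier:
    """A linguistic quantifier with a relative (or absolute) membership function.

    ``mf`` grades the proportion (relative) or count (absolute) in scalar truth
    evaluation and interpretability checks.  ``semi_fuzzy_mf`` grades the crisp
    ratio |X1 n X2| / |X1| in the semi-fuzzy form consumed by the probabilistic
    fuzzification mechanism; it defaults to ``mf`` but can differ (the
    "almost all" quantifier uses max{2p - 1, 0}).
    """

    name: str
    kind: str  # "relative" | "absolute"
    mf: MembershipFunction
    semi_fuzzy_mf: Optional[MembershipFunction] = None

    def __post_init__(self) -> None:
        if self.kind not in ("relative", "absolute"):
            raise ValueError(f"unknown quantifier kind {self.kind!r}")
        if self.semi_fuzzy_mf is None:
            object.__setattr__(self, "semi_fuzzy_mf", self.mf)

    def semi_fuzzy(self, *crisp_sets) -> float:
        """Semi-fuzzy form on crisp argument sets.

        Binary: mu(|X1 n X2| / |X1|), with value 1 when X1 is empty.
        Unary (relative): mu(|X1| / |universe|); unary (absolute): mu(|X1|).
        """
        if len(crisp_sets) == 1:
            (x1,) = crisp_sets
            if self.kind == "absolute":
                return evaluate_membership(self.semi_fuzzy_mf, len(x1))
            return evaluate_membership(
                self.semi_fuzzy_mf, len(x1) / len(x1.universe))
        if len(crisp_sets) == 2:
            x1, x2 = crisp_sets
            if len(x1) == 0:
                return 1.0
            ratio = len(x1.elements & x2.elements) / len(x1)
            return evaluate_membership(self.semi_fuzzy_mf, ratio)
        raise ValueError("semi-fuzzy quantifiers of arity > 2 are not defined")


def default_quantifiers() -> tuple[Quantifier, ...]:
    """The default relative quantifier family.

    ``few`` is the exact dual of ``most`` (few(x) = most(1 - x)); ``almost
    all`` carries the crisp-ratio semi-fuzzy form max{2p - 1, 0} alongside a
    stricter relative MF used for scalar truth and inclusion checks.
    """
    return (
        Quantifier("few", "relative", trapezoidal(0.0, 0.0, 0.2, 0.4)),
        Quantifier("about half", "relative", triangular(0.3, 0.5, 0.7)),
        Quantifier("most", "relative", trapezoidal(0.6, 0.8, 1.0, 1.0)),
        Quantifier("almost all", "relative",
                   trapezoidal(0.8, 0.95, 1.0, 1.0),
                   semi_fuzzy_mf=right_shoulder(0.5, 1.0)),
    )


# ---------------------------------------------------------------------------
# Sentence structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Composite:
    """One or more (feature, label) terms joined by a connective.

    Features within a composite are distinct; "and" terms combine by t-norm,
    "or" terms by t-conorm.
    """

    terms: tuple[tuple[str, str], ...]
    connective: str = "and"

    def __post_init__(self) -> None:
        terms = tuple((str(f), str(l)) for f, l in self.terms)
        if not terms:
            raise ValueError("composite needs at least one term")
        feats = [f for f, _ in terms]
        if len(set(feats)) != len(feats):
            raise ValueError("composite features must be distinct")
        if self.connective not in ("and", "or"):
            raise ValueError(f"unknown connective {self.connective!r}")
        object.__setattr__(self, "terms", terms)

    @property
    def features(self) -> frozenset:
        return frozenset(f for f, _ in self.terms)

    def key(self) -> tuple:
        return (self.connective, tuple(sorted(self.terms)))


@dataclass
class QuantifiedSentence:
    """A type-I or type-II quantified protoform with an optional truth degree."""

    form: str  # "type1" | "type2"
    quantifier: Quantifier
    summarizer: Composite
    pre_summarizer: Optional[Composite] = None
    scope: str = "all"  # "ASD" | "TD" | "all"
    truth: Optional[float] = None
    undefined: bool = False
    text: str = ""

    def __post_init__(self) -> None:
        if self.form not in ("type1", "type2"):
            raise ValueError(f"unknown sentence form {self.form!r}")
        if self.form == "type2":
            if self.pre_summarizer is None:
                raise ValueError("type-II sentences need a pre-summarizer")
            if self.pre_summarizer.features & self.summarizer.features:
                raise ValueError(
                    "pre-summarizer and summarizer must not share features")
        elif self.pre_summarizer is not None:
            raise ValueError("type-I sentences take no pre-summarizer")

    def key(self) -> tuple:
        pre = self.pre_summarizer.key() if self.pre_summarizer else None
        return (self.form, self.quantifier.name, self.scope,
                pre, self.summarizer.key())


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def enumerate_sentences(variables: Sequence[LinguisticVariable],
                        quantifiers: Sequence[Quantifier],
                        scope: str = "all",
                        max_arity: int = 1) -> list[QuantifiedSentence]:
    """Enumerate all singleton type-I and type-II candidate sentences.

    Every (quantifier, summarizer term) pair gives a type-I sentence; every
    (quantifier, pre-summarizer term, summarizer term) triple with distinct
    features gives a type-II sentence.  Composites beyond arity 1 are produced
    only downstream by interpretability merging.  Output order is
    deterministic: terms sorted lexicographically by (feature, label index),
    quantifiers in input order, type-I before type-II.
    """
    if not variables or not quantifiers:
        raise ValueError("need at least one variable and one quantifier")
    if max_arity < 1:
        raise ValueError("max_arity must be at least 1")
    terms: list[tuple[str, str]] = []
    for var in sorted(variables, key=lambda v: v.feature_name):
        for label in var.labels:
            terms.append((var.feature_name, label))

    sentences: list[QuantifiedSentence] = []
    for q in quantifiers:
        for term in terms:
            sentences.append(QuantifiedSentence(
                "type1", q, Composite((term,)), scope=scope))
    for q in quantifiers:
        for pre, summ in itertools.product(terms, terms):
            if pre[0] == summ[0]:
                continue
            sentences.append(QuantifiedSentence(
                "type2", q, Composite((summ,)),
                pre_summarizer=Composite((pre,)), scope=scope))
    return sentences


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _term_clause(feature: str, label: str,
                 lexicon: Optional[Mapping[str, LinguisticVariable]]) -> tuple[str, str]:
    """Render one (feature, label) term as (singular verb, phrase)."""
    var = lexicon.get(feature) if lexicon else None
    display = var.display_name if var else feature.replace("_", " ")
    age_relative = bool(var.age_relative) if var else False
    if age_relative:
        suffix = display if display.endswith("age") else "age"
        label_phrase = (f"equal to {suffix}" if label == "equal"
                        else f"{label} by {suffix}")
        if display.endswith("age"):
            return "is", label_phrase
        return "has", f"{display} {label_phrase}"
    return "has", f"{label} {display}"


_PLURAL = {"is": "are", "has": "have"}


def _join_clauses(clauses: Sequence[tuple[str, str]], connective: str,
                  plural: bool = False) -> str:
    joiner = f" {connective} "
    verbs = [(_PLURAL[v] if plural else v) for v, _ in clauses]
    if len(set(verbs)) == 1:
        return f"{verbs[0]} " + joiner.join(p for _, p in clauses)
    return joiner.join(f"{v} {p}" for v, (_, p) in zip(verbs, clauses))


def render_sentence(s: QuantifiedSentence,
                    lexicon: Optional[Mapping[str, LinguisticVariable]] = None) -> str:
    """Render a sentence as natural-language text (deterministic template)."""
    q = s.quantifier.name
    q = q[0].upper() + q[1:]
    summ_clauses = [_term_clause(f, l, lexicon) for f, l in s.summarizer.terms]
    if s.form == "type1":
        subject = {"all": "the children", "ASD": "the ASD children",
                   "TD": "the TD children"}[s.scope]
        body = _join_clauses(summ_clauses, s.summarizer.connective, plural=True)
        return f"{q} of {subject} {body}"
    subject = {"all": "the child", "ASD": "the ASD child",
               "TD": "the TD child"}[s.scope]
    pre_clauses = [_term_clause(f, l, lexicon)
                   for f, l in s.pre_summarizer.terms]
    pre = _join_clauses(pre_clauses, s.pre_summarizer.connective)
    body = _join_clauses(summ_clauses, s.summarizer.connective)
    return f"{q} of {subject} who {pre} also {body}"


def sentence_record(s: QuantifiedSentence) -> dict:
    """Serialize a sentence to a plain JSON-compatible record."""
    return {
        "form": s.form,
        "quantifier": s.quantifier.name,
        "scope": s.scope,
        "pre_summarizer": ([list(t) for t in s.pre_summarizer.terms]
                           if s.pre_summarizer else None),
        "pre_connective": (s.pre_summarizer.connective
                           if s.pre_summarizer else None),
        "summarizer": [list(t) for t in s.summarizer.terms],
        "summ_connective": s.summarizer.connective,
        "truth": None if s.truth is None else round(float(s.truth), 4),
        "undefined": s.undefined,
        "text": s.text,
    }
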