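"""Truth-degree computation: scalar cardinality and the fuzzification integral."""

import numpy as np
import pytest

from lingsum import (
    DiscreteFuzzySet,
    EvaluationConfig,
    alpha_cut,
    cut_bounds,
    default_quantifiers,
    evaluate_all,
    fi_evaluate,
    fi_evaluate_details,
    fi_monte_carlo,
    negate,
    q_gamma_evaluate,
    semi_fuzzy_almost_all,
    truth_type1_scalar,
    truth_type2_scalar,
)
from lingsum.fuzzy_core import CrispSubset, evaluate_membership
from lingsum.protoform import Composite, QuantifiedSentence
from lingsum.truth import (
    UndefinedTruthError,
    fi_evaluate_binary_ratio,
    fi_evaluate_unary_ratio,
)

from conftest import UNIVERSE, random_fuzzy_set

QS = {q.name: q for q in default_quantifiers()}


class TestScalarTruth:
    def test_full_and_empty_support(self):
        assert truth_type1_scalar(QS["most"], [1.0] * 5) == 1.0
        assert truth_type1_scalar(QS["few"], [0.0] * 5) == 1.0

    def test_type1_weighted_proportion(self):
        # sum 2.6 over 5 subjects -> proportion 0.52, below most's support
        t = truth_type1_scalar(QS["most"], (1, 0.8, 0.6, 0.2, 0))
        assert t == 0.0

    def test_type1_empty_scope_rejected(self):
        with pytest.raises(ValueError):
            truth_type1_scalar(QS["most"], [])

    def test_type2_weighted_ratio(self):
        t = truth_type2_scalar(QS["most"], (0.8, 0.9, 1, 0.2),
                               (1, 0.8, 0.3, 0.1))
        assert t == pytest.approx((2.0 / 2.9 - 0.6) / 0.2, abs=1e-12)

    def test_type2_self_implication_is_full_truth(self):
        degs = (0.3, 0.9, 0.5)
        assert truth_type2_scalar(QS["most"], degs, degs) == pytest.approx(
            evaluate_membership(QS["most"].mf, 1.0))

    def test_type2_crisp_pre_reduces_to_type1_on_subset(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            summ = rng.random(n)
            pre = (rng.random(n) < 0.5).astype(float)
            if pre.sum() == 0:
                pre[0] = 1.0
            t2 = truth_type2_scalar(QS["most"], pre, summ)
            t1 = truth_type1_scalar(QS["most"], summ[pre == 1.0])
            assert t2 == pytest.approx(t1, abs=1e-12)

    def test_type2_zero_denominator_flagged(self):
        with pytest.raises(UndefinedTruthError):
            truth_type2_scalar(QS["most"], (0.0, 0.0), (1.0, 1.0))

    def test_few_most_negation_duality(self):
        # T_few(not S) = T_most(S) exactly, over random data
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            degs = rng.random(n)
            uni = tuple(range(n))
            s = DiscreteFuzzySet.from_degrees(uni, degs)
            t_most = truth_type1_scalar(QS["most"], degs)
            t_few = truth_type1_scalar(QS["few"], negate(s).degrees())
            assert t_few == pytest.approx(t_most, abs=1e-12)


class TestCutBounds:
    def test_gamma_zero(self, set_a):
        cb = cut_bounds(set_a, 0.0)
        assert cb.lower.elements == alpha_cut(set_a, 0.5, strict=True).elements
        assert cb.upper.elements == alpha_cut(set_a, 0.5).elements

    def test_gamma_one(self, set_a):
        cb = cut_bounds(set_a, 1.0)
        assert cb.lower.elements == {"e3"}          # membership exactly 1
        assert cb.upper.elements == set(UNIVERSE)   # membership > 0

    def test_gamma_070_reference_values(self, set_a):
        cb = cut_bounds(set_a, 0.7)
        assert cb.lower.elements == {"e2", "e3"}            # mu >= 0.85
        assert cb.upper.elements == {"e1", "e2", "e3", "e4"}  # mu > 0.15

    def test_crisp_set_bounds_coincide(self):
        crisp = DiscreteFuzzySet.from_degrees(UNIVERSE, (1, 0, 1, 0))
        cb = cut_bounds(crisp, 0.0)
        assert cb.lower.elements == cb.upper.elements == {"e1", "e3"}

    def test_lower_subset_of_upper_everywhere(self, set_b):
        for gamma in np.linspace(0, 1, 11):
            cb = cut_bounds(set_b, gamma)
            assert cb.lower.elements <= cb.upper.elements

    def test_gamma_out_of_range(self, set_a):
        with pytest.raises(ValueError):
            cut_bounds(set_a, 1.5)


class TestQGamma:
    def test_crisp_args_evaluated_directly(self):
        crisp = DiscreteFuzzySet.from_degrees(UNIVERSE, (1, 1, 0, 0))
        full = DiscreteFuzzySet.from_degrees(UNIVERSE, (1, 1, 1, 1))
        v = q_gamma_evaluate(semi_fuzzy_almost_all, [crisp, full], 0.3)
        assert v == 1.0

    def test_single_ambiguous_element_median_of_two(self):
        # one element at exactly 1/2: gamma=0 leaves it optional
        x1 = DiscreteFuzzySet.from_degrees(UNIVERSE, (1, 1, 0.5, 0))
        x2 = DiscreteFuzzySet.from_degrees(UNIVERSE, (1, 0, 0, 0))
        v = q_gamma_evaluate(semi_fuzzy_almost_all, [x1, x2], 0.0)
        # including e3: ratio 1/3 -> 0; excluding: 1/2 -> 0; median of {0, 0}
        assert v == 0.0

    def test_result_within_enumerated_range(self, set_a, set_b):
        for gamma in (0.0, 0.4, 0.9):
            v = q_gamma_evaluate(semi_fuzzy_almost_all, [set_a, set_b], gamma)
            assert 0.0 <= v <= 1.0

    def test_large_universe_rejected(self):
        uni = tuple(range(16))
        big = DiscreteFuzzySet.from_degrees(uni, [0.5] * 16)
        with pytest.raises(ValueError):
            q_gamma_evaluate(semi_fuzzy_almost_all, [big, big], 0.5)


class TestSemiFuzzyAlmostAll:
    def test_reference_cut_pair_cells(self, set_a, set_b):
        a_cuts = {0.95: {"e3"}, 0.85: {"e2", "e3"},
                  0.5: {"e1", "e2", "e3"}, 0.1: set(UNIVERSE)}
        b_cuts = {0.9: {"e1"}, 0.5: {"e1", "e2"},
                  0.2: {"e1", "e2", "e3"}, 0.05: set(UNIVERSE)}
        for alpha, expected in a_cuts.items():
            assert alpha_cut(set_a, alpha).elements == expected
        for alpha, expected in b_cuts.items():
            assert alpha_cut(set_b, alpha).elements == expected
        mk = lambda els: CrispSubset(UNIVERSE, frozenset(els))
        # the distinct quantifier values on the cut grid
        assert semi_fuzzy_almost_all(mk({"e3"}), mk({"e1"})) == 0.0
        assert semi_fuzzy_almost_all(
            mk({"e1", "e2", "e3"}), mk({"e1", "e2"})) == pytest.approx(1 / 3)
        assert semi_fuzzy_almost_all(
            mk(UNIVERSE), mk({"e1", "e2", "e3"})) == pytest.approx(0.5)
        assert semi_fuzzy_almost_all(mk(UNIVERSE), mk(UNIVERSE)) == 1.0

    def test_empty_first_argument(self):
        mk = lambda els: CrispSubset(UNIVERSE, frozenset(els))
        assert semi_fuzzy_almost_all(mk(set()), mk({"e1"})) == 1.0

    def test_subset_gives_one(self):
        mk = lambda els: CrispSubset(UNIVERSE, frozenset(els))
        assert semi_fuzzy_almost_all(mk({"e1"}), mk({"e1", "e2"})) == 1.0


class TestFiEvaluate:
    def test_worked_reference_value(self, set_a, set_b):
        v = fi_evaluate(semi_fuzzy_almost_all, [set_a, set_b])
        assert v == pytest.approx(0.38, abs=1e-12)

    def test_reference_rectangle_grid(self, set_a, set_b):
        res = fi_evaluate_details(semi_fuzzy_almost_all, [set_a, set_b])
        # interval partitions per argument (ascending)
        assert res.intervals[0] == ((0.0, 0.2), (0.2, 0.8), (0.8, 0.9),
                                    (0.9, 1.0))
        assert res.intervals[1] == ((0.0, 0.1), (0.1, 0.3), (0.3, 0.8),
                                    (0.8, 1.0))
        # the printed (width, Q) cells, keyed by interval indices
        expected = {
            (3, 3): (0.02, 0.0), (3, 2): (0.05, 0.0),
            (3, 1): (0.02, 1.0), (3, 0): (0.01, 1.0),
            (2, 3): (0.02, 0.0), (2, 2): (0.05, 0.0),
            (2, 1): (0.02, 1.0), (2, 0): (0.01, 1.0),
            (1, 3): (0.12, 0.0), (1, 2): (0.30, 1 / 3),
            (1, 1): (0.12, 1.0), (1, 0): (0.06, 1.0),
            (0, 3): (0.04, 0.0), (0, 2): (0.10, 0.0),
            (0, 1): (0.04, 0.5), (0, 0): (0.02, 1.0),
        }
        got = {idx: (w, q) for idx, w, q in res.cells}
        assert set(got) == set(expected)
        for idx, (w, q) in expected.items():
            assert got[idx][0] == pytest.approx(w, abs=1e-12)
            assert got[idx][1] == pytest.approx(q, abs=1e-12)

    def test_crisp_args_reduce_to_direct_application(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            uni = tuple(range(n))
            m1 = (rng.random(n) < 0.6).astype(float)
            m2 = (rng.random(n) < 0.6).astype(float)
            A = DiscreteFuzzySet.from_degrees(uni, m1)
            B = DiscreteFuzzySet.from_degrees(uni, m2)
            direct = semi_fuzzy_almost_all(
                alpha_cut(A, 0.5), alpha_cut(B, 0.5))
            assert fi_evaluate(semi_fuzzy_almost_all, [A, B]) == pytest.approx(
                direct, abs=1e-12)

    def test_monte_carlo_oracle_agreement(self):
        rng = np.random.default_rng(1234)
        for trial in range(10):
            a = random_fuzzy_set(rng, int(rng.integers(2, 9)))
            b = DiscreteFuzzySet.from_degrees(
                a.universe, np.round(rng.random(len(a.universe)), 3))
            exact = fi_evaluate(semi_fuzzy_almost_all, [a, b])
            mc = fi_monte_carlo(semi_fuzzy_almost_all, [a, b],
                                n_samples=20_000, seed=trial)
            assert abs(exact - mc) < 0.02

    def test_monotone_in_second_argument(self, set_a, set_b):
        base = fi_evaluate(semi_fuzzy_almost_all, [set_a, set_b])
        for e in UNIVERSE:
            bumped = dict(set_b.memberships)
            bumped[e] = min(1.0, bumped[e] + 0.3)
            b2 = DiscreteFuzzySet(set_b.universe, bumped)
            assert fi_evaluate(semi_fuzzy_almost_all, [set_a, b2]) >= base - 1e-12

    def test_fast_paths_match_generic(self):
        rng = np.random.default_rng(77)
        aa = QS["almost all"]
        for _ in range(25):
            n = int(rng.integers(2, 10))
            mu1 = np.round(rng.random(n), 2)
            mu2 = np.round(rng.random(n), 2)
            uni = tuple(range(n))
            A = DiscreteFuzzySet.from_degrees(uni, mu1)
            B = DiscreteFuzzySet.from_degrees(uni, mu2)
            generic = fi_evaluate(semi_fuzzy_almost_all, [A, B])
            fast = fi_evaluate_binary_ratio(aa.semi_fuzzy_mf, mu1, mu2)
            assert fast == pytest.approx(generic, abs=1e-12)
            g1 = fi_evaluate(lambda X: QS["most"].semi_fuzzy(X), [A])
            f1 = fi_evaluate_unary_ratio(QS["most"].mf, mu1)
            assert f1 == pytest.approx(g1, abs=1e-12)


class TestEvaluateAll:
    def _setup(self, rng, n=8):
        degrees = {
            ("f1", "high"): np.round(rng.random(n), 2),
            ("f2", "low"): np.round(rng.random(n), 2),
        }
        groups = np.array(["ASD"] * (n // 2) + ["TD"] * (n - n // 2))
        return degrees, groups

    def _sentence(self, form="type2"):
        if form == "type2":
            return QuantifiedSentence(
                "type2", QS["most"], Composite((("f2", "low"),)),
                pre_summarizer=Composite((("f1", "high"),)), scope="ASD")
        return QuantifiedSentence(
            "type1", QS["most"], Composite((("f1", "high"),)), scope="all")

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        degrees, groups = self._setup(rng)
        t = []
        for _ in range(2):
            s = self._sentence()
            evaluate_all([s], degrees, groups, EvaluationConfig())
            t.append(s.truth)
        assert t[0] == t[1]

    def test_crisp_degrees_scalar_equals_fi(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            n = 8
            degrees = {
                ("f1", "high"): (rng.random(n) < 0.5).astype(float),
                ("f2", "low"): (rng.random(n) < 0.5).astype(float),
            }
            if degrees[("f1", "high")][:4].sum() == 0:
                degrees[("f1", "high")][0] = 1.0
            groups = np.array(["ASD"] * 4 + ["TD"] * 4)
            s1, s2 = self._sentence(), self._sentence()
            evaluate_all([s1], degrees, groups,
                         EvaluationConfig(method="scalar"))
            evaluate_all([s2], degrees, groups, EvaluationConfig(method="fi"))
            # both reduce to the crisp conditional proportion
            assert s1.truth == pytest.approx(s2.truth, abs=1e-12)

    def test_undefined_zero_denominator_flagged(self):
        degrees = {("f1", "high"): np.zeros(4),
                   ("f2", "low"): np.ones(4)}
        groups = np.array(["ASD"] * 4)
        s = self._sentence()
        evaluate_all([s], degrees, groups, EvaluationConfig(method="scalar"))
        assert s.undefined and s.truth is None

    def test_truths_in_unit_interval(self):
        rng = np.random.default_rng(6)
        degrees, groups = self._setup(rng, n=12)
        sentences = [self._sentence(), self._sentence("type1")]
        evaluate_all(sentences, degrees, groups, EvaluationConfig())
        for s in sentences:
            assert 0.0 <= s.truth <= 1.0
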