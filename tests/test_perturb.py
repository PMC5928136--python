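"""Perturbation semantics, combination enumeration, and the screen."""

from itertools import product
from math import comb
from random import Random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boolscreen import (
    And,
    BooleanNetwork,
    Const,
    NetworkError,
    Not,
    Or,
    Perturbation,
    PerturbationType,
    RequirementMode,
    ScreenRequirement,
    TemporalAll,
    TemporalAny,
    Var,
    apply_perturbation,
    enumerate_perturbations,
    eval_expression,
    evaluate_requirement,
    find_attractors_exhaustive,
    parse_network,
    project_attractor,
    random_network,
    requirement_from_attractor,
    screen,
    simplify_fixed,
)
from conftest import all_states


class TestEnumeration:
    def test_three_candidates_both_types_size_two_gives_18(self):
        pset = enumerate_perturbations(["x1", "x2", "x4"], "both", 2)
        assert len(pset) == 18

    def test_nineteen_candidates_single_size_gives_38(self):
        pset = enumerate_perturbations([f"g{i}" for i in range(19)], "both", 1)
        assert len(pset) == 38

    def test_two_candidates_size_two_gives_8(self):
        # brute-force cross-check: 2*2 singles + 1*4 pairs
        pset = enumerate_perturbations(["a", "b"], "both", 2)
        labels = {p.label() for p in pset}
        assert len(pset) == len(labels) == 8
        assert "a=0" in labels and "a=0+b=1" in labels

    def test_enumeration_order_is_size_then_position_then_type(self):
        pset = enumerate_perturbations(["a", "b"], "both", 2)
        assert [p.label() for p in pset] == [
            "a=0", "a=1", "b=0", "b=1",
            "a=0+b=0", "a=0+b=1", "a=1+b=0", "a=1+b=1",
        ]

    def test_per_candidate_type_restrictions(self):
        pset = enumerate_perturbations(
            ["a", "b"], {"a": "knock_down", "b": "both"}, 1
        )
        assert [p.label() for p in pset] == ["a=0", "b=0", "b=1"]

    def test_oversized_bound_is_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            pset = enumerate_perturbations(["a"], "both", 3)
        assert pset.max_size == 1 and len(pset) == 2

    def test_empty_candidates_rejected(self):
        with pytest.raises(NetworkError):
            enumerate_perturbations([], "both", 1)

    @settings(max_examples=60, derandomize=True)
    @given(k=st.integers(1, 8), m=st.integers(1, 8))
    def test_count_matches_closed_form(self, k, m):
        m = min(m, k)
        pset = enumerate_perturbations([f"c{i}" for i in range(k)], "both", m)
        assert len(pset) == sum(comb(k, i) * 2 ** i for i in range(1, m + 1))


class TestApplyPerturbation:
    def test_knock_down_x1_leaves_two_steady_states(self, toy3):
        p = Perturbation((("x1", PerturbationType.KNOCK_DOWN),))
        perturbed = apply_perturbation(toy3, p)
        assert perturbed.functions[0] == Const(False)
        report = find_attractors_exhaustive(perturbed, fixed=p.fixed_map(toy3))
        assert {frozenset(s.current for s in a.states) for a in report.attractors} \
            == {frozenset({(0, 0, 0)}), frozenset({(0, 1, 0)})}

    def test_overexpressing_an_already_constant_component_changes_nothing(self):
        net = parse_network("a, 1\nb, a").network
        p = Perturbation((("a", PerturbationType.OVER_EXPRESSION),))
        before = find_attractors_exhaustive(net).attractors
        after = find_attractors_exhaustive(
            apply_perturbation(net, p), fixed=p.fixed_map(net)
        ).attractors
        assert before == after

    def test_knockdown_x2_changes_the_attractor_set(self, toy3):
        p = Perturbation((("x2", PerturbationType.KNOCK_DOWN),))
        before = {a.states for a in find_attractors_exhaustive(toy3).attractors}
        after = {a.states for a in find_attractors_exhaustive(
            apply_perturbation(toy3, p), fixed=p.fixed_map(toy3)
        ).attractors}
        assert before != after

    def test_overexpressing_x2_preserves_the_attractor_set(self, toy3):
        # the sole 2-cycle {010, 110} already has x2 active in every state,
        # so over-expressing x2 leaves the attractor set unchanged
        p = Perturbation((("x2", PerturbationType.OVER_EXPRESSION),))
        before = {a.states for a in find_attractors_exhaustive(toy3).attractors}
        after = {a.states for a in find_attractors_exhaustive(
            apply_perturbation(toy3, p), fixed=p.fixed_map(toy3)
        ).attractors}
        assert before == after

    def test_unknown_component_rejected(self, toy3):
        p = Perturbation((("nope", PerturbationType.KNOCK_DOWN),))
        with pytest.raises(NetworkError):
            apply_perturbation(toy3, p)

    @pytest.mark.parametrize("seed", range(8))
    def test_perturbed_components_hold_their_value_in_every_attractor(self, seed):
        rng = Random(seed)
        net = random_network(6, max_in_degree=3, temporal_fraction=0.3, seed=seed)
        name = rng.choice(net.names)
        ptype = rng.choice(list(PerturbationType))
        p = Perturbation(((name, ptype),))
        report = find_attractors_exhaustive(
            apply_perturbation(net, p), fixed=p.fixed_map(net)
        )
        i = net.index(name)
        for a in report.attractors:
            assert all(s.current[i] == ptype.value_bit for s in a.states)


def random_expression(rng: Random, n_vars: int, depth: int = 0):
    roll = rng.random()
    if depth >= 3 or roll < 0.25:
        return Var(rng.randrange(n_vars))
    if roll < 0.4:
        return Not(random_expression(rng, n_vars, depth + 1))
    if roll < 0.6:
        op = rng.choice((And, Or))
        return op(tuple(random_expression(rng, n_vars, depth + 1)
                        for _ in range(2)))
    cls = rng.choice((TemporalAll, TemporalAny))
    return cls(random_expression(rng, n_vars, depth + 1), rng.choice((1, 2, 3)))


class TestSimplifyFixed:
    def test_conjunction_with_knocked_down_literal_collapses(self):
        assert simplify_fixed(And((Var(0), Not(Var(1)))), {0: 0}) == Const(False)

    def test_disjunction_with_overexpressed_literal_dominates(self):
        assert simplify_fixed(Or((Var(0), Var(1))), {0: 1}) == Const(True)

    def test_temporal_window_over_a_constant_is_that_constant(self):
        assert simplify_fixed(TemporalAll(Var(0), 3), {0: 1}) == Const(True)
        assert simplify_fixed(TemporalAny(Var(0), 3), {0: 0}) == Const(False)

    @pytest.mark.parametrize("seed", range(20))
    def test_simplification_preserves_semantics_on_all_traces(self, seed):
        """A fixed component is constant at every time step, so the
        simplified expression must evaluate identically on every trace
        consistent with the fixed assignment."""
        rng = Random(seed)
        n = 4
        expr = random_expression(rng, n)
        fixed = {0: rng.randint(0, 1)}
        simp = simplify_fixed(expr, fixed)
        depth = 3  # traces long enough for windows up to 3 nested twice
        free = [i for i in range(n) if i not in fixed]
        for rows in product(list(all_states(len(free))), repeat=depth + 1):
            trace = []
            for row in rows:
                state = [0] * n
                for i, b in zip(free, row):
                    state[i] = b
                for i, v in fixed.items():
                    state[i] = v
                trace.append(tuple(state))
            try:
                expected = eval_expression(expr, trace, depth)
            except NetworkError:
                continue  # window deeper than this trace; not a valid input
            assert eval_expression(simp, trace, depth) == expected


class TestProjection:
    def test_two_cycle_collapses_on_constant_components(self, toy3):
        (a,) = find_attractors_exhaustive(toy3).attractors
        assert project_attractor(a, [1, 2]) == frozenset({(1, 0)})

    def test_projection_to_all_components_of_steady_state(self):
        net = parse_network("a, 1\nb, 0").network
        (a,) = find_attractors_exhaustive(net).attractors
        assert project_attractor(a, [0, 1]) == frozenset({(1, 0)})

    def test_projection_to_oscillating_component_keeps_both_values(self, toy3):
        (a,) = find_attractors_exhaustive(toy3).attractors
        assert project_attractor(a, [0]) == frozenset({(0,), (1,)})


class TestEvaluateRequirement:
    def test_must_not_exist_holds_when_pattern_removed(self, cascade6):
        fixed = {"dmg": 1, "inh": 1}  # over-expressed inhibitor
        report = find_attractors_exhaustive(cascade6, fixed)
        req = ScreenRequirement(("il",), frozenset({(1,)}),
                                RequirementMode.MUST_NOT_EXIST)
        assert evaluate_requirement(report.attractors, req, cascade6)

    def test_must_not_exist_is_vacuously_true_when_never_present(self, toy3):
        report = find_attractors_exhaustive(toy3)
        req = ScreenRequirement(("x2", "x3"), frozenset({(0, 1)}),
                                RequirementMode.MUST_NOT_EXIST)
        assert evaluate_requirement(report.attractors, req, toy3)

    def test_must_exist_matches_a_preserved_attractor(self, toy3):
        report = find_attractors_exhaustive(toy3)
        req = requirement_from_attractor(
            report.attractors[0], ("x2", "x3"), toy3, RequirementMode.MUST_EXIST
        )
        assert req.pattern == frozenset({(1, 0)})
        assert evaluate_requirement(report.attractors, req, toy3)

    def test_unknown_projection_component_rejected(self, toy3):
        req = ScreenRequirement(("ghost",), frozenset({(1,)}))
        with pytest.raises(NetworkError):
            evaluate_requirement(
                find_attractors_exhaustive(toy3).attractors, req, toy3
            )


class TestScreen:
    def test_toy_screen_finds_the_attractor_removing_knockdown(self, toy3):
        """Removing the {x2=1, x3=0} long-term pattern from the worked
        network: knocking down x2 must be among the valid perturbations
        (oracle-checked over all four single perturbations)."""
        req = ScreenRequirement(("x2", "x3"), frozenset({(1, 0)}),
                                RequirementMode.MUST_NOT_EXIST)
        with pytest.warns(UserWarning, match="projections"):
            result = screen(toy3, candidates=["x1", "x2"], requirements=[req],
                            max_size=1, engine="exhaustive")
        assert result.n_evaluated == 4
        labels = {p.label() for p in result.valid}
        assert "x2=0" in labels
        # oracle: recompute every verdict directly
        for row in result.rows:
            p = row.perturbation
            rep = find_attractors_exhaustive(
                apply_perturbation(toy3, p), fixed=p.fixed_map(toy3)
            )
            assert row.verdict == evaluate_requirement(rep.attractors, req, toy3)

    def test_empty_requirements_make_every_perturbation_valid(self, toy3):
        result = screen(toy3, candidates=["x1", "x2"], requirements=[],
                        max_size=1)
        assert len(result.valid) == result.n_evaluated == 4

    def test_single_knockdown_candidate_is_one_evaluation(self, toy3):
        result = screen(toy3, candidates=["x1"], allowed_types="knock_down",
                        requirements=[], max_size=1)
        assert result.n_evaluated == 1
        assert result.rows[0].perturbation.label() == "x1=0"

    def test_sat_and_exhaustive_screens_agree(self, cascade6):
        req = ScreenRequirement(("il",), frozenset({(1,)}),
                                RequirementMode.MUST_NOT_EXIST)
        kw = dict(candidates=["kin", "tf", "inh"], requirements=[req],
                  max_size=2, fixed={"dmg": 1})
        by_sat = screen(cascade6, engine="sat", **kw)
        by_oracle = screen(cascade6, engine="exhaustive", **kw)
        assert [r.verdict for r in by_sat.rows] == \
            [r.verdict for r in by_oracle.rows]
        assert by_sat.valid == by_oracle.valid
        assert len(by_sat.valid) > 0

    def test_per_perturbation_failures_are_recorded_not_fatal(self, toy3):
        req = ScreenRequirement(("x2",), frozenset({(1,)}))
        result = screen(toy3, candidates=["x1"], requirements=[req],
                        max_size=1, engine="exhaustive",
                        cap=2)  # cap too small: every search must fail
        assert all(r.verdict is None and "Cap" in (r.error or "")
                   for r in result.rows)
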