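"""Perturbation semantics and the automated screen.

A *knock-down* fixes a component permanently to 0, an *over-expression*
permanently to 1:

    x_i(t+1) = 0   if x_i is knocked down,
               1   if x_i is over-expressed,
               f_i(x(t)) otherwise.

Given k candidate components with per-candidate allowed perturbation types
and a maximum combination size m, the screen enumerates every combination
(with both types allowed everywhere, sum_{i=1..m} C(k,i) * 2^i of them),
computes the attractors of each perturbed network, projects them onto
user-chosen readout components, and returns the combinations whose
long-term behavior matches the declared requirements (attractor patterns
that must, or must not, exist after perturbation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

from joblib import Parallel, delayed

from .core import (
    And,
    Attractor,
    BooleanNetwork,
    Const,
    Expr,
    FixedMap,
    NetworkError,
    Not,
    Or,
    TemporalAll,
    TemporalAny,
    Var,
)
from .exhaustive import DEFAULT_STATE_CAP, find_attractors_exhaustive
from .satsearch import find_attractors_sat


class PerturbationType(str, Enum):
    KNOCK_DOWN = "knock_down"        # fix to 0
    OVER_EXPRESSION = "over_expression"  # fix to 1

    @property
    def value_bit(self) -> int:
        return 0 if self is PerturbationType.KNOCK_DOWN else 1


# ordered: knock-down enumerates before over-expression
_TYPE_ORDER = (PerturbationType.KNOCK_DOWN, PerturbationType.OVER_EXPRESSION)


@dataclass(frozen=True)
class Perturbation:
    """A non-empty assignment of perturbation types to distinct components."""

    assignments: tuple[tuple[str, PerturbationType], ...]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise NetworkError("a perturbation must touch at least one component")
        names = [c for c, _ in self.assignments]
        if len(set(names)) != len(names):
            raise NetworkError("a component may appear only once in a perturbation")

    @property
    def size(self) -> int:
        return len(self.assignments)

    def fixed_map(self, network: BooleanNetwork) -> dict[int, int]:
        return {
            network.index(name): ptype.value_bit for name, ptype in self.assignments
        }

    def label(self) -> str:
        return "+".join(
            f"{name}={'1' if t is PerturbationType.OVER_EXPRESSION else '0'}"
            for name, t in self.assignments
        )


@dataclass
class PerturbationSet:
    """All candidate perturbation combinations up to the size bound."""

    candidates: tuple[str, ...]
    allowed_types: tuple[tuple[PerturbationType, ...], ...]
    max_size: int
    perturbations: tuple[Perturbation, ...]

    def __len__(self) -> int:
        return len(self.perturbations)

    def __iter__(self):
        return iter(self.perturbations)


def _normalize_allowed(
    candidates: Sequence[str], allowed_types
) -> tuple[tuple[PerturbationType, ...], ...]:
    def norm_one(choice) -> tuple[PerturbationType, ...]:
        if choice in ("both", None):
            return _TYPE_ORDER
        if isinstance(choice, (str, PerturbationType)):
            return (PerturbationType(choice),)
        return tuple(
            sorted((PerturbationType(t) for t in choice), key=_TYPE_ORDER.index)
        )

    if isinstance(allowed_types, Mapping):
        return tuple(norm_one(allowed_types.get(c, "both")) for c in candidates)
    return tuple(norm_one(allowed_types) for _ in candidates)


def enumerate_perturbations(
    candidates: Sequence[str],
    allowed_types="both",
    max_size: int = 1,
) -> PerturbationSet:
    """Every knock-down/over-expression combination of 1..max_size of the
    candidate components, in deterministic order.

    Order: by combination size, then lexicographically by candidate
    positions, then by type pattern with knock-down before over-expression.
    ``allowed_types`` is ``"both"``, a single type, or a mapping
    ``candidate -> "both" | type | iterable of types``.  ``max_size`` larger
    than the number of candidates is clamped with a warning.
    """
    candidates = tuple(candidates)
    if not candidates:
        raise NetworkError("need at least one perturbation candidate")
    if max_size < 1:
        raise NetworkError("maximum combination size must be >= 1")
    k = len(candidates)
    if max_size > k:
        warnings.warn(
            f"maximum combination size {max_size} exceeds the {k} candidates; "
            f"clamping to {k}",
            stacklevel=2,
        )
        max_size = k
    allowed = _normalize_allowed(candidates, allowed_types)
    perts: list[Perturbation] = []
    for size in range(1, max_size + 1):
        for idxs in combinations(range(k), size):
            for types in product(*(allowed[i] for i in idxs)):
                perts.append(
                    Perturbation(
                        tuple((candidates[i], t) for i, t in zip(idxs, types))
                    )
                )
    return PerturbationSet(
        candidates=candidates,
        allowed_types=allowed,
        max_size=max_size,
        perturbations=tuple(perts),
    )


def apply_perturbation(network: BooleanNetwork, p: Perturbation) -> BooleanNetwork:
    """Replace each perturbed component's transition function by the
    constant its perturbation type dictates; all others are untouched."""
    fixed = p.fixed_map(network)  # validates component names
    functions = tuple(
        Const(bool(fixed[i])) if i in fixed else f
        for i, f in enumerate(network.functions)
    )
    return BooleanNetwork(network.names, functions)


def simplify_fixed(expr: Expr, fixed: Mapping[int, int]) -> Expr:
    """Propagate fixed component values symbolically.

    A fixed component is constant at *every* time step (its history holds
    the constant too), so substitution is valid inside temporal windows.
    Applies the usual laws: !1 -> 0, e&0 -> 0, e&1 -> e, e|1 -> 1,
    e|0 -> e, ALL/ANY of a constant -> that constant; window-1 temporal
    nodes collapse to their argument.
    """
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Var):
        if expr.index in fixed:
            return Const(bool(fixed[expr.index]))
        return expr
    if isinstance(expr, Not):
        c = simplify_fixed(expr.child, fixed)
        if isinstance(c, Const):
            return Const(not c.value)
        if isinstance(c, Not):
            return c.child
        return Not(c)
    if isinstance(expr, (And, Or)):
        dominating = isinstance(expr, Or)  # Or: 1 dominates; And: 0 dominates
        kept: list[Expr] = []
        for child in expr.children:
            c = simplify_fixed(child, fixed)
            if isinstance(c, Const):
                if c.value == dominating:
                    return Const(dominating)
                continue
            kept.append(c)
        if not kept:
            return Const(not dominating)
        if len(kept) == 1:
            return kept[0]
        return Or(tuple(kept)) if dominating else And(tuple(kept))
    if isinstance(expr, (TemporalAll, TemporalAny)):
        c = simplify_fixed(expr.child, fixed)
        if isinstance(c, Const):
            return c
        if expr.window == 1:
            return c
        return type(expr)(c, expr.window)
    raise NetworkError(f"unknown expression node {expr!r}")


def simplify_network(network: BooleanNetwork, fixed: Mapping[int, int]) -> BooleanNetwork:
    """Symbolic simplification of every transition function under ``fixed``;
    the fixed components themselves become constants."""
    functions = tuple(
        Const(bool(fixed[i])) if i in fixed else simplify_fixed(f, fixed)
        for i, f in enumerate(network.functions)
    )
    return BooleanNetwork(network.names, functions)


# ---------------------------------------------------------------------------
# Attractor projection and requirements
# ---------------------------------------------------------------------------

def project_attractor(
    attractor: Attractor, components: Sequence[int]
) -> frozenset[tuple[int, ...]]:
    """The set of the attractor's states restricted to ``components``
    (indices), duplicates collapsed, history ignored."""
    if not components:
        raise NetworkError("projection needs at least one component")
    return frozenset(
        tuple(s.current[i] for i in components) for s in attractor.states
    )


def project_attractor_cyclic(
    attractor: Attractor, components: Sequence[int]
) -> tuple[tuple[int, ...], ...]:
    """Order-sensitive projection: the cyclic sequence of projected states
    with consecutive duplicates (including around the wrap) collapsed, in
    canonical rotation (lexicographically smallest rotation)."""
    if not components:
        raise NetworkError("projection needs at least one component")
    seq = [tuple(s.current[i] for i in components) for s in attractor.states]
    collapsed: list[tuple[int, ...]] = []
    for x in seq:
        if not collapsed or collapsed[-1] != x:
            collapsed.append(x)
    if len(collapsed) > 1 and collapsed[0] == collapsed[-1]:
        collapsed.pop()
    rotations = [
        tuple(collapsed[j:] + collapsed[:j]) for j in range(len(collapsed))
    ]
    return min(rotations)


class RequirementMode(str, Enum):
    MUST_EXIST = "must_exist"
    MUST_NOT_EXIST = "must_not_exist"


@dataclass(frozen=True)
class ScreenRequirement:
    """One target pattern: a projected attractor that must (or must not)
    exist among the perturbed network's attractors.

    ``pattern`` is the projection of one attractor onto ``components``: a
    set of partial states, each a bit tuple in ``components`` order.
    """

    components: tuple[str, ...]
    pattern: frozenset[tuple[int, ...]]
    mode: RequirementMode = RequirementMode.MUST_NOT_EXIST

    def __post_init__(self) -> None:
        if not self.components:
            raise NetworkError("a requirement needs at least one component")
        for state in self.pattern:
            if len(state) != len(self.components):
                raise NetworkError(
                    "pattern states must have one bit per requirement component"
                )


def requirement_from_attractor(
    attractor: Attractor,
    components: Sequence[str],
    network: BooleanNetwork,
    mode: RequirementMode = RequirementMode.MUST_NOT_EXIST,
) -> ScreenRequirement:
    """Convenience: turn an observed (reference) attractor into a
    requirement over the given readout components."""
    idx = [network.index(c) for c in components]
    return ScreenRequirement(
        components=tuple(components),
        pattern=project_attractor(attractor, idx),
        mode=mode,
    )


def evaluate_requirement(
    attractors: Sequence[Attractor],
    requirement: ScreenRequirement,
    network: BooleanNetwork,
) -> bool:
    """Whether the perturbed attractor set satisfies one requirement.

    ``must_exist``: some attractor's projection equals the pattern;
    ``must_not_exist``: no attractor's projection equals the pattern.
    """
    idx = [network.index(c) for c in requirement.components]
    present = any(
        project_attractor(a, idx) == requirement.pattern for a in attractors
    )
    if requirement.mode is RequirementMode.MUST_EXIST:
        return present
    return not present


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenRow:
    """Evaluation record of one perturbation combination."""

    perturbation: Perturbation
    verdict: bool | None  # None when the evaluation failed
    n_attractors: int | None
    projections: tuple[frozenset[tuple[int, ...]], ...] | None
    error: str | None = None


@dataclass
class ScreenResult:
    rows: tuple[ScreenRow, ...]
    requirements: tuple[ScreenRequirement, ...]
    readout_components: tuple[str, ...]

    @property
    def valid(self) -> tuple[Perturbation, ...]:
        return tuple(r.perturbation for r in self.rows if r.verdict)

    @property
    def n_evaluated(self) -> int:
        return len(self.rows)


def _search_attractors(network, fixed, engine, cap):
    if engine == "exhaustive":
        return find_attractors_exhaustive(network, fixed, cap=cap)
    return find_attractors_sat(network, fixed)


def _evaluate_one(
    network: BooleanNetwork,
    base_fixed: dict[int, int],
    p: Perturbation,
    requirements: tuple[ScreenRequirement, ...],
    readout_idx: tuple[int, ...],
    engine: str,
    cap: int,
) -> ScreenRow:
    try:
        total_fixed = dict(base_fixed)
        total_fixed.update(p.fixed_map(network))
        perturbed = apply_perturbation(network, p)
        perturbed = simplify_network(perturbed, total_fixed)
        report = _search_attractors(perturbed, total_fixed, engine, cap)
        verdict = all(
            evaluate_requirement(report.attractors, req, perturbed)
            for req in requirements
        )
        projections = tuple(
            project_attractor(a, list(readout_idx)) for a in report.attractors
        ) if readout_idx else ()
        return ScreenRow(
            perturbation=p,
            verdict=verdict,
            n_attractors=report.n_attractors,
            projections=projections,
        )
    except Exception as exc:  # per-perturbation failures are recorded, not fatal
        return ScreenRow(
            perturbation=p,
            verdict=None,
            n_attractors=None,
            projections=None,
            error=f"{type(exc).__name__}: {exc}",
        )


def screen(
    network: BooleanNetwork,
    candidates: Sequence[str],
    requirements: Sequence[ScreenRequirement],
    allowed_types="both",
    max_size: int = 1,
    fixed: FixedMap | None = None,
    engine: str = "sat",
    workers: int = 1,
    cap: int = DEFAULT_STATE_CAP,
) -> ScreenResult:
    """The automated perturbation screen.

    Enumerates all candidate combinations, evaluates each (perturb ->
    simplify -> attractor search -> requirement check) and returns every
    row in enumeration order.  ``fixed`` holds network inputs pinned for
    the whole experiment (applied on top of each perturbation).  Results
    are independent of ``workers``; rows are always collected back into
    enumeration order.
    """
    if engine not in ("sat", "exhaustive"):
        raise NetworkError(f"unknown engine {engine!r}")
    base_fixed = network.resolve_fixed(fixed)
    requirements = tuple(requirements)
    readout = tuple(
        dict.fromkeys(c for req in requirements for c in req.components)
    )
    readout_idx = tuple(network.index(c) for c in readout)
    overlap = set(candidates) & set(readout)
    if overlap:
        warnings.warn(
            f"candidates {sorted(overlap)} also appear in requirement "
            "projections; a fixed component trivially determines its own readout",
            stacklevel=2,
        )
    pset = enumerate_perturbations(candidates, allowed_types, max_size)
    jobs = [
        delayed(_evaluate_one)(
            network, base_fixed, p, requirements, readout_idx, engine, cap
        )
        for p in pset
    ]
    if workers == 1:
        rows = [job[0](*job[1], **job[2]) for job in jobs]
    else:
        rows = Parallel(n_jobs=workers)(jobs)
    return ScreenResult(
        rows=tuple(rows),
        requirements=requirements,
        readout_components=readout,
    )
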