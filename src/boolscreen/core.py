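"""Synchronous Boolean networks with bounded temporal look-back.

A Boolean network of ``n`` components evolves under the synchronous update
rule ``x(t+1) = (f_1(x(t)), ..., f_n(x(t)))``.  Each transition function is a
Boolean expression over component values; in addition to NOT/AND/OR it may
use the temporal predicates

* ``ALL(phi, d)`` — true iff ``phi`` held on *every* step of the window
  ``t, t-1, ..., t-d+1`` (the window includes the current step);
* ``ANY(phi, d)`` — true iff ``phi`` held on *at least one* step of that
  window.

Temporal predicates make the next state depend on more than the previous
state, so the unit of dynamics is the :class:`AugmentedState`: the current
Boolean vector together with a per-component history of exactly the depth
the network's expressions require.  Two augmented states are equal only if
their current vectors *and* all histories agree; attractor detection is
defined over this equality.

History convention: at ``t = 0`` the history is padded by replicating the
initial state backwards in time, which makes every plain Boolean vector a
legal initial condition and keeps the augmented state space finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Iterable, Mapping, Sequence, Union


class NetworkError(ValueError):
    """Structural problem in a network, expression or fixed-value map."""


class InsufficientHistoryError(NetworkError):
    """A temporal window reached back before the start of the given trace."""


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------

class Expr:
    """Base class of all expression nodes. Nodes are immutable and hashable."""

    __slots__ = ()


@dataclass(frozen=True)
class Const(Expr):
    value: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", bool(self.value))


@dataclass(frozen=True)
class Var(Expr):
    """Reference to component ``index`` at the current evaluation time."""

    index: int

    def __post_init__(self) -> None:
        if self.index < 0:
            raise NetworkError(f"negative component index {self.index}")


@dataclass(frozen=True)
class Not(Expr):
    child: Expr


@dataclass(frozen=True)
class And(Expr):
    children: tuple[Expr, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 2:
            raise NetworkError("AND requires at least two operands")


@dataclass(frozen=True)
class Or(Expr):
    children: tuple[Expr, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 2:
            raise NetworkError("OR requires at least two operands")


@dataclass(frozen=True)
class TemporalAll(Expr):
    """True iff ``child`` holds at every step in the last ``window`` steps."""

    child: Expr
    window: int

    def __post_init__(self) -> None:
        if self.window < 1:
            raise NetworkError(f"temporal window must be >= 1, got {self.window}")


@dataclass(frozen=True)
class TemporalAny(Expr):
    """True iff ``child`` holds at >= 1 step in the last ``window`` steps."""

    child: Expr
    window: int

    def __post_init__(self) -> None:
        if self.window < 1:
            raise NetworkError(f"temporal window must be >= 1, got {self.window}")


def free_vars(expr: Expr) -> frozenset[int]:
    """Indices of all components referenced anywhere in ``expr``."""
    out: set[int] = set()
    _scan_lookback(expr, 0, out_vars=out)
    return frozenset(out)


def _scan_lookback(
    expr: Expr,
    offset: int,
    out_depth: dict[int, int] | None = None,
    out_vars: set[int] | None = None,
) -> None:
    """Walk ``expr`` accumulating the deepest look-back applied to each VAR.

    ``offset`` is the look-back already contributed by enclosing temporal
    nodes; windows sum along nesting, so ``ALL(ANY(x,2),2)`` reads ``x`` up
    to two steps before the current one.
    """
    if isinstance(expr, Var):
        if out_vars is not None:
            out_vars.add(expr.index)
        if out_depth is not None:
            prev = out_depth.get(expr.index, 0)
            if offset > prev:
                out_depth[expr.index] = offset
    elif isinstance(expr, Not):
        _scan_lookback(expr.child, offset, out_depth, out_vars)
    elif isinstance(expr, (And, Or)):
        for c in expr.children:
            _scan_lookback(c, offset, out_depth, out_vars)
    elif isinstance(expr, (TemporalAll, TemporalAny)):
        _scan_lookback(expr.child, offset + expr.window - 1, out_depth, out_vars)
    elif isinstance(expr, Const):
        pass
    else:  # pragma: no cover - guards against foreign node types
        raise NetworkError(f"unknown expression node {expr!r}")


def eval_with_lookup(
    expr: Expr, lookup: Callable[[int, int], int], offset: int = 0
) -> bool:
    """Evaluate ``expr`` where ``lookup(i, d)`` yields component ``i`` at
    ``d`` steps before the evaluation time."""
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Var):
        return bool(lookup(expr.index, offset))
    if isinstance(expr, Not):
        return not eval_with_lookup(expr.child, lookup, offset)
    if isinstance(expr, And):
        return all(eval_with_lookup(c, lookup, offset) for c in expr.children)
    if isinstance(expr, Or):
        return any(eval_with_lookup(c, lookup, offset) for c in expr.children)
    if isinstance(expr, TemporalAll):
        return all(
            eval_with_lookup(expr.child, lookup, offset + k)
            for k in range(expr.window)
        )
    if isinstance(expr, TemporalAny):
        return any(
            eval_with_lookup(expr.child, lookup, offset + k)
            for k in range(expr.window)
        )
    raise NetworkError(f"unknown expression node {expr!r}")


def eval_expression(
    expr: Expr, trace: Sequence[Sequence[int]], t: int
) -> bool:
    """Evaluate ``expr`` on a trace of plain states at time index ``t``.

    ``trace[k]`` is the network state at time ``k``; temporal windows read
    earlier entries of the trace.  Reaching before ``trace[0]`` raises
    :class:`InsufficientHistoryError` — callers are responsible for any
    padding convention.
    """
    if not 0 <= t < len(trace):
        raise InsufficientHistoryError(f"time index {t} outside trace of length {len(trace)}")

    def lookup(i: int, d: int) -> int:
        k = t - d
        if k < 0:
            raise InsufficientHistoryError(
                f"expression looks back {d} steps from t={t}, before trace start"
            )
        return trace[k][i]

    return eval_with_lookup(expr, lookup)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

FixedMap = Mapping[Union[str, int], Union[bool, int]]


@dataclass
class BooleanNetwork:
    """An ordered set of named components with one transition function each.

    Component order (declaration order in a network file) defines bit order
    for all state vectors, canonicalization and output.  Indices are 0-based
    internally; names are the external interface.
    """

    names: tuple[str, ...]
    functions: tuple[Expr, ...]

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.functions = tuple(self.functions)
        if len(self.names) == 0:
            raise NetworkError("a network needs at least one component")
        if len(self.names) != len(self.functions):
            raise NetworkError("one transition function per component required")
        if len(set(self.names)) != len(self.names):
            raise NetworkError("component names must be unique")
        n = len(self.names)
        for name, f in zip(self.names, self.functions):
            bad = [i for i in free_vars(f) if i >= n]
            if bad:
                raise NetworkError(
                    f"function of {name!r} references undeclared component index {bad[0]}"
                )

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise NetworkError(f"unknown component {name!r}") from None

    @cached_property
    def delay_profile(self) -> tuple[int, ...]:
        """Per-component history depth D_i: the deepest look-back beyond the
        previous step that any transition function applies to component i."""
        depth: dict[int, int] = {}
        for f in self.functions:
            _scan_lookback(f, 0, out_depth=depth)
        return tuple(depth.get(i, 0) for i in range(self.n))

    @property
    def max_delay(self) -> int:
        return max(self.delay_profile, default=0)

    def is_input(self, i: int) -> bool:
        """A component whose function is its own identity acts as an input."""
        return self.functions[i] == Var(i)

    def resolve_fixed(self, fixed: FixedMap | None) -> dict[int, int]:
        """Normalize a name-or-index keyed fixed-value map to {index: 0/1}."""
        out: dict[int, int] = {}
        for key, val in (fixed or {}).items():
            i = key if isinstance(key, int) else self.index(key)
            if not 0 <= i < self.n:
                raise NetworkError(f"fixed component index {i} out of range")
            out[i] = 1 if val else 0
        return out


def max_delay_profile(network: BooleanNetwork) -> tuple[int, ...]:
    """Per-component history depths D_i (see :attr:`BooleanNetwork.delay_profile`)."""
    return network.delay_profile


# ---------------------------------------------------------------------------
# Augmented states and the synchronous step
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentedState:
    """Current state plus the bounded history the network's windows need.

    ``history[i]`` holds the last ``D_i`` values of component ``i``, most
    recent first (``history[i][d-1]`` is the value ``d`` steps ago, the
    oldest entry last).
    """

    current: tuple[int, ...]
    history: tuple[tuple[int, ...], ...]

    def lookup(self, i: int, d: int) -> int:
        if d == 0:
            return self.current[i]
        h = self.history[i]
        if d <= len(h):
            return h[d - 1]
        raise InsufficientHistoryError(
            f"component {i} has history depth {len(h)}, needed look-back {d}"
        )

    def key(self) -> tuple[int, ...]:
        """Flat bit tuple (current bits then history bits, component order);
        the basis of lexicographic canonicalization."""
        return self.current + tuple(b for h in self.history for b in h)


def initial_state(
    network: BooleanNetwork,
    bits: Sequence[int],
    fixed: FixedMap | None = None,
) -> AugmentedState:
    """Build the augmented state for a plain initial condition.

    History is padded by replicating the initial value backwards; fixed
    components are overridden to their constant in both current value and
    history.
    """
    fx = network.resolve_fixed(fixed)
    if len(bits) != network.n:
        raise NetworkError(f"expected {network.n} bits, got {len(bits)}")
    cur = tuple(fx.get(i, 1 if bits[i] else 0) for i in range(network.n))
    D = network.delay_profile
    hist = tuple((cur[i],) * D[i] for i in range(network.n))
    return AugmentedState(cur, hist)


def step(
    network: BooleanNetwork,
    s: AugmentedState,
    fixed: FixedMap | None = None,
) -> AugmentedState:
    """One synchronous update of the (possibly perturbed/fixed) network.

    Non-fixed components get their transition function evaluated on the
    augmented state; fixed components keep their constant.  Histories shift
    by one step, discarding the oldest entry.
    """
    fx = network.resolve_fixed(fixed)
    n = network.n
    if len(s.current) != n:
        raise NetworkError("state width does not match network")
    new_cur = tuple(
        fx[i] if i in fx else (1 if eval_with_lookup(network.functions[i], s.lookup) else 0)
        for i in range(n)
    )
    D = network.delay_profile
    new_hist = tuple(
        (s.current[i],) + s.history[i][: D[i] - 1] if D[i] > 0 else ()
        for i in range(n)
    )
    return AugmentedState(new_cur, new_hist)


# ---------------------------------------------------------------------------
# Attractors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Attractor:
    """A cycle of augmented states the dynamics cannot leave.

    Stored in canonical rotation: the first element is the lexicographically
    smallest augmented state by :meth:`AugmentedState.key`.  ``basin_size``
    (when known) counts the padded initial conditions whose trajectory ends
    in this attractor; it does not take part in equality.
    """

    states: tuple[AugmentedState, ...]
    basin_size: int | None = field(default=None, compare=False)

    @property
    def period(self) -> int:
        return len(self.states)

    @classmethod
    def from_cycle(
        cls, states: Sequence[AugmentedState], basin_size: int | None = None
    ) -> "Attractor":
        states = tuple(states)
        if not states:
            raise NetworkError("an attractor has at least one state")
        if len(set(states)) != len(states):
            raise NetworkError("attractor states must be pairwise distinct")
        k = min(range(len(states)), key=lambda j: states[j].key())
        rotated = states[k:] + states[:k]
        return cls(rotated, basin_size)

    def current_states(self) -> tuple[tuple[int, ...], ...]:
        """The cycle's plain state vectors (history stripped), cycle order."""
        return tuple(s.current for s in self.states)
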