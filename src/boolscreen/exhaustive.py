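"""Brute-force attractor search over the full augmented state space.

This engine iterates the synchronous step map from every admissible initial
condition and labels states with the attractor they reach (memoized forward
iteration with per-state coloring).  It is the reference oracle for the
SAT-based engine and the only place basin sizes come from.

Initial conditions are the *padded* augmented states: every plain Boolean
vector consistent with the fixed-value map, history replicated backwards.
Basin sizes therefore partition the set of padded starts, and sum to
``2^(number of free components)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .core import (
    Attractor,
    AugmentedState,
    BooleanNetwork,
    FixedMap,
    NetworkError,
    initial_state,
    step,
)

DEFAULT_STATE_CAP = 2 ** 22


class StateSpaceCapError(NetworkError):
    """The augmented state space exceeds the configured enumeration cap."""

    def __init__(self, size: int, cap: int):
        super().__init__(
            f"augmented state space has {size} states, exceeding the cap of {cap}; "
            "raise the cap or use the SAT engine"
        )
        self.size = size
        self.cap = cap


def augmented_space_size(network: BooleanNetwork, fixed: FixedMap | None = None) -> int:
    """``2^(free components + total history depth of free components)``.

    Fixed components contribute no freedom: their value and history are
    pinned to the fixed constant.
    """
    fx = network.resolve_fixed(fixed)
    D = network.delay_profile
    bits = sum(1 + D[i] for i in range(network.n) if i not in fx)
    return 2 ** bits


@dataclass
class AttractorReport:
    """Outcome of an exhaustive or SAT attractor search.

    ``total_states`` is the number of padded initial conditions examined
    (the basis of basin counts); the SAT engine leaves basins and the count
    unset.
    """

    attractors: tuple[Attractor, ...]
    total_states: int | None
    engine: str
    state_space_size: int

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)


def _iter_start_states(network: BooleanNetwork, fx: dict[int, int]):
    free = [i for i in range(network.n) if i not in fx]
    for bits in product((0, 1), repeat=len(free)):
        vec = [0] * network.n
        for i, b in zip(free, bits):
            vec[i] = b
        for i, v in fx.items():
            vec[i] = v
        yield initial_state(network, vec)


def find_attractors_exhaustive(
    network: BooleanNetwork,
    fixed: FixedMap | None = None,
    cap: int = DEFAULT_STATE_CAP,
) -> AttractorReport:
    """Every attractor of the (possibly fixed-constrained) network, with
    basin sizes over all padded initial conditions.

    Raises :class:`StateSpaceCapError` when the augmented state space is
    larger than ``cap``.
    """
    fx = network.resolve_fixed(fixed)
    space = augmented_space_size(network, fixed)
    if space > cap:
        raise StateSpaceCapError(space, cap)

    label: dict[AugmentedState, int] = {}
    attractors: list[Attractor] = []
    basin: list[int] = []
    n_starts = 0

    for s0 in _iter_start_states(network, fx):
        n_starts += 1
        path: list[AugmentedState] = []
        on_path: dict[AugmentedState, int] = {}
        s = s0
        while s not in label and s not in on_path:
            on_path[s] = len(path)
            path.append(s)
            s = step(network, s, fx)
        if s in label:
            aid = label[s]
        else:
            j = on_path[s]
            aid = len(attractors)
            attractors.append(Attractor.from_cycle(path[j:]))
            basin.append(0)
        for p in path:
            label[p] = aid
        basin[label[s0]] += 1

    result = tuple(
        sorted(
            (Attractor(a.states, basin[i]) for i, a in enumerate(attractors)),
            key=lambda a: a.states[0].key(),
        )
    )
    return AttractorReport(
        attractors=result,
        total_states=n_starts,
        engine="exhaustive",
        state_space_size=space,
    )


@dataclass
class TrajectoryResult:
    """A simulated path up to (and including) the first repeated state.

    ``states[entry_index:]`` minus the final repeat is the attractor cycle;
    ``attractor`` is that cycle in canonical rotation.
    """

    states: tuple[AugmentedState, ...]
    entry_index: int
    attractor: Attractor

    @property
    def transient_length(self) -> int:
        return self.entry_index


def trajectory(
    network: BooleanNetwork,
    start: AugmentedState,
    fixed: FixedMap | None = None,
    max_steps: int | None = None,
) -> TrajectoryResult:
    """Iterate the step map from ``start`` until an augmented state repeats.

    ``max_steps`` bounds the number of transitions; the default is the full
    augmented state space size, for which repetition is guaranteed.
    """
    fx = network.resolve_fixed(fixed)
    if max_steps is None:
        max_steps = augmented_space_size(network, fixed) + 1
    seen: dict[AugmentedState, int] = {}
    path: list[AugmentedState] = []
    s = start
    for _ in range(max_steps + 1):
        if s in seen:
            j = seen[s]
            path.append(s)
            return TrajectoryResult(
                states=tuple(path),
                entry_index=j,
                attractor=Attractor.from_cycle(path[j:-1]),
            )
        seen[s] = len(path)
        path.append(s)
        s = step(network, s, fx)
    raise NetworkError(
        f"no repeated state within {max_steps} steps; max_steps is too small"
    )
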