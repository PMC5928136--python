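"""SAT-based exhaustive attractor search via bounded path unfolding.

The transition relation of a synchronous Boolean network,

    T(x(t), x(t+1)) = AND_i [ x_i(t+1) <-> f_i(x(t)) ],

is unfolded over ``l`` consecutive time slots so that every satisfying
assignment of the resulting CNF is a valid path of ``l`` states.  Each model
found by the solver is scanned for a repeated state — everything between
two equal states is an attractor.  A found attractor is blocked by clauses
forbidding any of its states at any slot (which removes its entire basin
from the search space), and solving continues; an attractor-free model
means the path is still too short, so the unfolding length is grown and
the search restarted with all exclusions re-emitted.  The loop ends when
the solver reports UNSAT: all attractors have been found.

Temporal networks need two refinements.  Each component at each time slot
maps to its own solver variable (``l*n`` main variables for a delay-free
network); a look-back of ``d`` steps from slot ``s`` maps to slot ``s-d``
when it exists and is pinned to the slot-0 variable otherwise (the padded
history convention of :mod:`boolscreen.core`).  And repetition detection
compares *augmented* states — a state plus its history — because a temporal
network may sit on the same plain state for several steps without being in
an attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .core import (
    And,
    Attractor,
    AugmentedState,
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
from .exhaustive import AttractorReport, augmented_space_size
from .solver import DpllSolver, SolverContract, SolverError

# ---------------------------------------------------------------------------
# Symbolic Boolean formulas over (component, slot) atoms
# ---------------------------------------------------------------------------
# Formulas are nested tuples: ("atom", a) | ("const", b) | ("not", f)
# | ("and", (f, ...)) | ("or", (f, ...)) | ("iff", f, g).

Formula = tuple


def fconst(b: bool) -> Formula:
    return ("const", bool(b))


def fatom(a) -> Formula:
    return ("atom", a)


def fnot(f: Formula) -> Formula:
    return ("not", f)


def fand(fs: Sequence[Formula]) -> Formula:
    return ("and", tuple(fs))


def for_(fs: Sequence[Formula]) -> Formula:
    return ("or", tuple(fs))


def fiff(a: Formula, b: Formula) -> Formula:
    return ("iff", a, b)


def fold_constants(f: Formula) -> Formula:
    """Propagate constants so that only a top-level formula can be constant."""
    kind = f[0]
    if kind in ("atom", "const"):
        return f
    if kind == "not":
        c = fold_constants(f[1])
        if c[0] == "const":
            return fconst(not c[1])
        if c[0] == "not":
            return c[1]
        return ("not", c)
    if kind in ("and", "or"):
        dominating = kind == "and"  # and: False dominates; or: True dominates
        kept = []
        for child in f[1]:
            c = fold_constants(child)
            if c[0] == "const":
                if c[1] != dominating:
                    return fconst(not dominating)
                continue
            kept.append(c)
        if not kept:
            return fconst(dominating)
        if len(kept) == 1:
            return kept[0]
        return (kind, tuple(kept))
    if kind == "iff":
        a = fold_constants(f[1])
        b = fold_constants(f[2])
        if a[0] == "const":
            return b if a[1] else fold_constants(("not", b))
        if b[0] == "const":
            return a if b[1] else fold_constants(("not", a))
        return ("iff", a, b)
    raise NetworkError(f"unknown formula node {kind!r}")


def eval_formula(f: Formula, assignment: Mapping) -> bool:
    """Two-valued semantics; ``assignment`` maps atoms to booleans."""
    kind = f[0]
    if kind == "const":
        return f[1]
    if kind == "atom":
        return bool(assignment[f[1]])
    if kind == "not":
        return not eval_formula(f[1], assignment)
    if kind == "and":
        return all(eval_formula(c, assignment) for c in f[1])
    if kind == "or":
        return any(eval_formula(c, assignment) for c in f[1])
    if kind == "iff":
        return eval_formula(f[1], assignment) == eval_formula(f[2], assignment)
    raise NetworkError(f"unknown formula node {kind!r}")


def formula_atoms(f: Formula) -> list:
    """Atoms of ``f`` in first-occurrence (depth-first) order."""
    out: list = []
    seen = set()

    def walk(g: Formula) -> None:
        kind = g[0]
        if kind == "atom":
            if g[1] not in seen:
                seen.add(g[1])
                out.append(g[1])
        elif kind == "not":
            walk(g[1])
        elif kind in ("and", "or"):
            for c in g[1]:
                walk(c)
        elif kind == "iff":
            walk(g[1])
            walk(g[2])

    walk(f)
    return out


# ---------------------------------------------------------------------------
# Encoding network expressions into formulas
# ---------------------------------------------------------------------------

def encode_expr(expr: Expr, at_slot: int) -> Formula:
    """Translate a transition expression evaluated at time slot ``at_slot``
    into a formula over (component, slot) atoms.

    A look-back of ``d`` steps maps to slot ``at_slot - d``, clamped at
    slot 0: history before the path start is pinned to the initial slot
    (padded-history convention).
    """

    def enc(e: Expr, lookback: int) -> Formula:
        if isinstance(e, Const):
            return fconst(e.value)
        if isinstance(e, Var):
            return fatom((e.index, max(at_slot - lookback, 0)))
        if isinstance(e, Not):
            return fnot(enc(e.child, lookback))
        if isinstance(e, And):
            return fand([enc(c, lookback) for c in e.children])
        if isinstance(e, Or):
            return for_([enc(c, lookback) for c in e.children])
        if isinstance(e, TemporalAll):
            return fand([enc(e.child, lookback + k) for k in range(e.window)])
        if isinstance(e, TemporalAny):
            return for_([enc(e.child, lookback + k) for k in range(e.window)])
        raise NetworkError(f"unknown expression node {e!r}")

    return enc(expr, 0)


@dataclass
class TransitionFormula:
    """Symbolic single-step transition relation between two time slots.

    ``formula`` is the conjunction over components of the biconditionals
    ``x_i(to_slot) <-> f_i(slots <= from_slot)``; fixed components appear as
    unit constraints instead.  Satisfying assignments over the atoms are in
    one-to-one correspondence with valid single-step transitions.
    """

    from_slot: int
    to_slot: int
    per_component: tuple[tuple[Formula, Formula], ...]  # (target atom, rhs)
    formula: Formula

    def atoms(self) -> list:
        return formula_atoms(self.formula)


def encode_transition(
    network: BooleanNetwork,
    from_slot: int,
    to_slot: int,
    fixed: FixedMap | None = None,
) -> TransitionFormula:
    """Build T(x(from_slot), x(to_slot)) symbolically."""
    if from_slot == to_slot:
        raise NetworkError("from_slot and to_slot must differ")
    fx = network.resolve_fixed(fixed)
    parts: list[Formula] = []
    per_comp: list[tuple[Formula, Formula]] = []
    for i in range(network.n):
        target = fatom((i, to_slot))
        if i in fx:
            rhs = fconst(bool(fx[i]))
            parts.append(target if fx[i] else fnot(target))
        else:
            rhs = encode_expr(network.functions[i], from_slot)
            parts.append(fiff(target, rhs))
        per_comp.append((target, rhs))
    return TransitionFormula(
        from_slot=from_slot,
        to_slot=to_slot,
        per_component=tuple(per_comp),
        formula=fand(parts) if len(parts) > 1 else parts[0],
    )


# ---------------------------------------------------------------------------
# Tseitin transformation
# ---------------------------------------------------------------------------

class _Tseitin:
    """Structure-sharing Tseitin encoder over a fixed atom->variable map."""

    def __init__(self, atom_var: Mapping, next_var: int):
        self.atom_var = dict(atom_var)
        self.next_var = next_var
        self.clauses: list[list[int]] = []
        self.aux_of: dict = {}  # gate signature -> aux literal

    def _fresh(self) -> int:
        v = self.next_var
        self.next_var += 1
        return v

    def lit(self, f: Formula) -> int:
        kind = f[0]
        if kind == "atom":
            return self.atom_var[f[1]]
        if kind == "not":
            return -self.lit(f[1])
        if kind in ("and", "or"):
            lits = tuple(self.lit(c) for c in f[1])
            sig = (kind, tuple(sorted(lits)))
            g = self.aux_of.get(sig)
            if g is not None:
                return g
            g = self._fresh()
            if kind == "and":
                for l in lits:
                    self.clauses.append([-g, l])
                self.clauses.append([g] + [-l for l in lits])
            else:
                for l in lits:
                    self.clauses.append([g, -l])
                self.clauses.append([-g] + list(lits))
            self.aux_of[sig] = g
            return g
        if kind == "iff":
            a = self.lit(f[1])
            b = self.lit(f[2])
            sig = ("iff", tuple(sorted((a, b))))
            g = self.aux_of.get(sig)
            if g is not None:
                return g
            g = self._fresh()
            self.clauses.append([-g, -a, b])
            self.clauses.append([-g, a, -b])
            self.clauses.append([g, a, b])
            self.clauses.append([g, -a, -b])
            self.aux_of[sig] = g
            return g
        raise NetworkError(f"cannot encode formula node {kind!r}")

    def assert_iff(self, x: int, f: Formula) -> None:
        """Add clauses for x <-> f without an extra gate for the iff."""
        f = fold_constants(f)
        if f[0] == "const":
            self.clauses.append([x] if f[1] else [-x])
            return
        g = self.lit(f)
        self.clauses.append([-x, g])
        self.clauses.append([x, -g])

    def assert_true(self, f: Formula) -> None:
        f = fold_constants(f)
        if f[0] == "const":
            if not f[1]:
                self.clauses.append([])
            return
        if f[0] == "and":  # flatten the top conjunction: no gate needed
            for c in f[1]:
                self.assert_true(c)
            return
        self.clauses.append([self.lit(f)])


@dataclass
class TseitinResult:
    clauses: list[list[int]]
    atom_var: dict
    n_vars: int

    @property
    def aux_vars(self) -> list[int]:
        main = set(self.atom_var.values())
        return [v for v in range(1, self.n_vars + 1) if v not in main]


def tseitin_cnf(formula: Formula) -> TseitinResult:
    """Equisatisfiable CNF of an arbitrary formula.

    Atoms get variables 1..k in first-occurrence order; auxiliary gate
    variables follow.  Every model of the CNF restricted to the atom
    variables satisfies the formula, and every satisfying assignment of the
    formula extends to exactly one CNF model.
    """
    atoms = formula_atoms(formula)
    atom_var = {a: i + 1 for i, a in enumerate(atoms)}
    ctx = _Tseitin(atom_var, len(atoms) + 1)
    ctx.assert_true(formula)
    return TseitinResult(clauses=ctx.clauses, atom_var=atom_var, n_vars=ctx.next_var - 1)


# ---------------------------------------------------------------------------
# Path unfolding
# ---------------------------------------------------------------------------

@dataclass
class UnfoldedPathCNF:
    """CNF whose models (projected to the main variables) are the valid
    ``length``-state paths of the network.

    Main variables number ``length * n``: component ``i`` at slot ``s`` is
    variable ``s*n + i + 1``.  Auxiliary Tseitin variables follow.
    """

    network: BooleanNetwork
    length: int
    fixed: dict[int, int]
    clauses: list[list[int]]
    n_vars: int

    @property
    def n_main_vars(self) -> int:
        return self.length * self.network.n

    def var(self, component: int, slot: int) -> int:
        n = self.network.n
        if not (0 <= component < n and 0 <= slot < self.length):
            raise NetworkError(f"no variable for component {component} at slot {slot}")
        return slot * n + component + 1

    def main_vars(self) -> list[int]:
        return list(range(1, self.n_main_vars + 1))

    def decode_path(self, model: Mapping[int, bool]) -> list[tuple[int, ...]]:
        n = self.network.n
        return [
            tuple(1 if model.get(self.var(i, s), False) else 0 for i in range(n))
            for s in range(self.length)
        ]


def unfold_path(
    network: BooleanNetwork,
    length: int,
    fixed: FixedMap | None = None,
) -> UnfoldedPathCNF:
    """Conjoin ``length - 1`` transition formulas over slots 0..length-1 and
    Tseitin-convert the result to CNF."""
    if length < 2:
        raise NetworkError("path length must be >= 2")
    fx = network.resolve_fixed(fixed)
    n = network.n
    atom_var = {(i, s): s * n + i + 1 for s in range(length) for i in range(n)}
    ctx = _Tseitin(atom_var, length * n + 1)
    for i, v in fx.items():
        ctx.clauses.append([atom_var[(i, 0)] if v else -atom_var[(i, 0)]])
    for s in range(length - 1):
        for i in range(n):
            x = atom_var[(i, s + 1)]
            if i in fx:
                ctx.clauses.append([x if fx[i] else -x])
            else:
                ctx.assert_iff(x, encode_expr(network.functions[i], s))
    return UnfoldedPathCNF(
        network=network,
        length=length,
        fixed=fx,
        clauses=ctx.clauses,
        n_vars=ctx.next_var - 1,
    )


def _augmented_bit_slots(cnf: UnfoldedPathCNF, slot: int):
    """(component, source slot) pairs spelling out the augmented state at
    ``slot``: current bits, then each component's history bits (clamped to
    slot 0 below the path start, matching the padding convention)."""
    D = cnf.network.delay_profile
    n = cnf.network.n
    pairs = [(i, slot) for i in range(n)]
    for i in range(n):
        for d in range(1, D[i] + 1):
            pairs.append((i, max(slot - d, 0)))
    return pairs


def exclude_attractor(cnf: UnfoldedPathCNF, attractor: Attractor) -> UnfoldedPathCNF:
    """Forbid every state of ``attractor`` at every slot of the unfolding.

    After exclusion, any path containing any of the attractor's augmented
    states — in particular every path through its basin that reaches it —
    is no longer a model.  Mutates and returns ``cnf``.
    """
    for state in attractor.states:
        bits = state.key()
        for slot in range(cnf.length):
            pairs = _augmented_bit_slots(cnf, slot)
            lits: dict[int, int] = {}
            tautology = False
            for (i, src), b in zip(pairs, bits):
                v = cnf.var(i, src)
                lit = -v if b else v
                if lits.get(v, lit) != lit:
                    # slot clamping demands two different values of one
                    # variable: this augmented state cannot occur here
                    tautology = True
                    break
                lits[v] = lit
            if not tautology:
                cnf.clauses.append(list(lits.values()))
    return cnf


# ---------------------------------------------------------------------------
# The attractor search loop
# ---------------------------------------------------------------------------

def _augment_path(
    network: BooleanNetwork, path: Sequence[tuple[int, ...]]
) -> list[AugmentedState]:
    D = network.delay_profile
    n = network.n
    out = []
    for j in range(len(path)):
        cur = path[j]
        hist = tuple(
            tuple(path[max(j - d, 0)][i] for d in range(1, D[i] + 1))
            for i in range(n)
        )
        out.append(AugmentedState(cur, hist))
    return out


def _first_repeat(states: Sequence[AugmentedState]) -> tuple[int, int] | None:
    seen: dict[AugmentedState, int] = {}
    for j, s in enumerate(states):
        if s in seen:
            return seen[s], j
        seen[s] = j
    return None


def find_attractors_sat(
    network: BooleanNetwork,
    fixed: FixedMap | None = None,
    initial_length: int = 2,
    growth: int = 2,
    solver_factory: Callable[[], SolverContract] = DpllSolver,
    max_length: int | None = None,
) -> AttractorReport:
    """All attractors of the network by SAT path unfolding.

    Path length starts at ``initial_length`` and is multiplied by ``growth``
    whenever an attractor-free path shows the unfolding is too short;
    geometric growth bounds the number of solver rounds by the logarithm of
    the longest transient.  Basin sizes are not computed by this engine.
    """
    if initial_length < 2:
        raise NetworkError("initial path length must be >= 2")
    if growth < 2:
        raise NetworkError("growth factor must be >= 2")
    space = augmented_space_size(network, fixed)
    if max_length is None:
        # any path longer than the augmented space must repeat a state
        max_length = 2 * space + 2
    found: list[Attractor] = []
    length = initial_length
    while True:
        cnf = unfold_path(network, length, fixed)
        for a in found:
            exclude_attractor(cnf, a)
        solver = solver_factory()
        for c in cnf.clauses:
            solver.add_clause(c)
        prolong = False
        while True:
            try:
                sat = solver.solve()
            except SolverError as exc:  # pragma: no cover - backend failure path
                raise SolverError(
                    f"solver failed at path length {length} "
                    f"({len(cnf.clauses)} clauses): {exc}"
                ) from exc
            if not sat:
                break
            path = cnf.decode_path(solver.model())
            aug = _augment_path(network, path)
            rep = _first_repeat(aug)
            if rep is None:
                prolong = True
                break
            j1, j2 = rep
            attractor = Attractor.from_cycle(aug[j1:j2])
            found.append(attractor)
            before = len(cnf.clauses)
            exclude_attractor(cnf, attractor)
            for c in cnf.clauses[before:]:
                solver.add_clause(c)
        if not prolong:
            break
        length *= growth
        if length > max_length:
            raise SolverError(
                f"path length {length} exceeds bound {max_length} without "
                "convergence; this indicates an encoding defect"
            )
    attractors = tuple(sorted(found, key=lambda a: a.states[0].key()))
    return AttractorReport(
        attractors=attractors,
        total_states=None,
        engine="sat",
        state_space_size=space,
    )


# ---------------------------------------------------------------------------
# DIMACS interchange
# ---------------------------------------------------------------------------

def to_dimacs(cnf: UnfoldedPathCNF, comments: Sequence[str] = ()) -> str:
    """Standard DIMACS CNF text (``p cnf V C`` header, 0-terminated lines)."""
    lines = [f"c {c}" for c in comments]
    lines.append(
        f"c boolscreen path unfolding: n={cnf.network.n} length={cnf.length} "
        f"main_vars={cnf.n_main_vars}"
    )
    lines.append(f"p cnf {cnf.n_vars} {len(cnf.clauses)}")
    for c in cnf.clauses:
        lines.append(" ".join(str(l) for l in c) + " 0")
    return "\n".join(lines) + "\n"
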