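"""A complete propositional SAT solver with a minimal, pluggable contract.

The attractor-search engine only needs three things from a solver: accept
clauses over integer DIMACS-style literals, answer SAT/UNSAT, and hand back
a model so that blocking clauses can be added between calls.  That contract
is captured by :class:`SolverContract`; the bundled implementation is a
two-watched-literal DPLL with chronological backtracking.  It is complete
(never answers UNSAT when a model exists) and entirely self-contained, so
the package has no hard dependency on an external solver binary.  Any
CDCL library exposing the same three methods can be dropped in instead.

Path-unfolding CNFs are nearly functional: once the first time slot is
decided, unit propagation determines every later slot, so the plain
lowest-index branching heuristic (which reaches the slot-0 variables first)
behaves well on this workload.
"""

from __future__ import annotations

from typing import Iterable, Protocol, Sequence, runtime_checkable


@runtime_checkable
class SolverContract(Protocol):
    """What satsearch requires of a SAT backend."""

    def add_clause(self, lits: Iterable[int]) -> None: ...

    def solve(self) -> bool: ...

    def model(self) -> dict[int, bool]: ...


class SolverError(RuntimeError):
    """Raised when a backend fails; carries context added by callers."""


class DpllSolver:
    """Iterative DPLL with two watched literals.

    Each :meth:`solve` call searches from scratch over the current clause
    set (clauses may be added between calls); on SAT the full model is
    retained until the next call.
    """

    def __init__(self, clauses: Iterable[Sequence[int]] = ()) -> None:
        self.nvars = 0
        self.clauses: list[list[int]] = []
        self._model: dict[int, bool] | None = None
        self._trivially_unsat = False
        for c in clauses:
            self.add_clause(c)

    def add_clause(self, lits: Iterable[int]) -> None:
        clause = list(dict.fromkeys(int(l) for l in lits))
        if any(l == 0 for l in clause):
            raise SolverError("literal 0 is reserved for clause termination")
        lset = set(clause)
        if any(-l in lset for l in clause):
            return  # tautology
        for l in clause:
            v = abs(l)
            if v > self.nvars:
                self.nvars = v
        if not clause:
            self._trivially_unsat = True
        self.clauses.append(clause)

    def model(self) -> dict[int, bool]:
        if self._model is None:
            raise SolverError("no model available; last solve() was UNSAT or never ran")
        return self._model

    def solve(self) -> bool:  # noqa: C901 - single hot loop, kept flat on purpose
        self._model = None
        if self._trivially_unsat:
            return False
        nv = self.nvars
        assign = [0] * (nv + 1)  # 0 unassigned, +1 true, -1 false
        # watches[lit] lists indices of clauses currently watching `lit`
        watches: dict[int, list[int]] = {}
        trail: list[int] = []
        top_units: list[int] = []
        clauses = self.clauses
        for ci, c in enumerate(clauses):
            if len(c) == 1:
                top_units.append(c[0])
            else:
                watches.setdefault(c[0], []).append(ci)
                watches.setdefault(c[1], []).append(ci)

        def litval(l: int) -> int:
            v = assign[l if l > 0 else -l]
            if v == 0:
                return 0
            return v if l > 0 else -v

        def enqueue(l: int) -> bool:
            v = litval(l)
            if v == -1:
                return False
            if v == 0:
                assign[abs(l)] = 1 if l > 0 else -1
                trail.append(l)
            return True

        qhead = 0

        def propagate() -> bool:
            """Exhaust unit propagation; False on conflict."""
            nonlocal qhead
            while qhead < len(trail):
                p = trail[qhead]
                qhead += 1
                falsified = -p
                wl = watches.get(falsified)
                if not wl:
                    continue
                i = 0
                while i < len(wl):
                    ci = wl[i]
                    c = clauses[ci]
                    if c[0] == falsified:
                        c[0], c[1] = c[1], c[0]
                    first = c[0]
                    if litval(first) == 1:
                        i += 1
                        continue
                    moved = False
                    for k in range(2, len(c)):
                        if litval(c[k]) != -1:
                            c[1], c[k] = c[k], c[1]
                            watches.setdefault(c[1], []).append(ci)
                            wl[i] = wl[-1]
                            wl.pop()
                            moved = True
                            break
                    if moved:
                        continue
                    if not enqueue(first):  # unit or conflict
                        return False
                    i += 1
            return True

        for l in top_units:
            if not enqueue(l):
                return False
        if not propagate():
            return False

        # decision stack: (trail length before the decision, literal, flipped?)
        decisions: list[list[int]] = []
        var_ptr = 1

        def undo_to(mark: int) -> None:
            nonlocal qhead
            for l in trail[mark:]:
                assign[abs(l)] = 0
            del trail[mark:]
            qhead = mark

        while True:
            while var_ptr <= nv and assign[var_ptr] != 0:
                var_ptr += 1
            if var_ptr > nv:
                self._model = {v: assign[v] == 1 for v in range(1, nv + 1)}
                return True
            decisions.append([len(trail), -var_ptr, 0])
            enqueue(-var_ptr)
            while not propagate():
                while decisions and decisions[-1][2]:
                    undo_to(decisions[-1][0])
                    decisions.pop()
                if not decisions:
                    return False
                d = decisions[-1]
                undo_to(d[0])
                d[1] = -d[1]
                d[2] = 1
                enqueue(d[1])
                var_ptr = 1
            var_ptr = 1


def enumerate_models(
    clauses: Iterable[Sequence[int]],
    over_vars: Sequence[int],
    limit: int | None = None,
    solver_factory=DpllSolver,
) -> list[dict[int, bool]]:
    """All satisfying assignments projected onto ``over_vars``.

    Enumerates by repeatedly solving and blocking the projection of each
    model; distinct projections are returned (each once), in discovery
    order.
    """
    solver = solver_factory()
    for c in clauses:
        solver.add_clause(c)
    out: list[dict[int, bool]] = []
    while solver.solve():
        m = solver.model()
        proj = {v: m.get(v, False) for v in over_vars}
        out.append(proj)
        if limit is not None and len(out) >= limit:
            break
        solver.add_clause([-v if proj[v] else v for v in over_vars])
        if not over_vars:
            break
    return out
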