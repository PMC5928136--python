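# Methods

## Model

A synchronous Boolean network has `n` named components; the state at time
`t` is the vector `x(t) ∈ {0,1}^n`, and all components update together:
`x(t+1) = (f_1(x(t)), ..., f_n(x(t)))`.  Because the state space is finite,
every trajectory ends in a cycle of states — an attractor — and the set of
states draining into an attractor is its basin.  Asynchronous and
probabilistic update schemes are out of scope by design; all semantics here
are synchronous and deterministic.

### Temporal predicates

Transition functions may use two window operators in addition to NOT/AND/OR:
`ALL(φ, δ)` is true iff `φ` held at every time in `{t, t−1, …, t−δ+1}`, and
`ANY(φ, δ)` iff it held at least once in that window.  Two conventions had
to be fixed where genuine alternatives exist:

* **Window endpoint.** The window of length `δ` *includes the current step*
  and reaches back `δ−1` further steps.  `ALL(φ,1)` and `ANY(φ,1)` therefore
  degenerate to `φ` (a property the tests enforce).  Only single-length
  windows are supported, not `[a,b]` intervals.
* **History initialization.** At `t = 0` the history is padded by
  replicating the initial state backwards in time.  This makes every plain
  Boolean vector a legal initial condition and keeps the augmented state
  space finite.

Windows sum along nesting: `ALL(ANY(x,2),2)` reads `x` up to two steps
before the current one.  The per-component history depth `D_i` is the
deepest look-back any function applies to component `i`; the unit of
dynamics and of attractor equality is the *augmented state* (current vector
plus the last `D_i` values of each component).  Two augmented states are
equal only if histories agree — without this, a temporal network that idles
on one plain state for several steps would be misread as a steady state.

### Perturbations

A knock-down fixes a component to 0, an over-expression to 1, from the
initial state onward; the fixed constant also populates the component's
history.  Network inputs pinned for a whole experiment (e.g. a damage
signal held on) use the same mechanism and are applied to the unperturbed
reference as well as to every perturbed evaluation.

## Attractor search

### Exhaustive engine

Memoized forward iteration with per-state attractor labeling: walk the step
map from every padded initial condition consistent with the fixed-value
map, stopping at the first state already labeled or repeated on the current
path.  Each distinct augmented state is stepped at most once.  Basin sizes
count padded initial conditions, the only well-defined finite start-state
space for temporal networks, and always sum to `2^(free components)`.  The
engine refuses state spaces above a configurable cap (default `2^22`
augmented states) rather than running unbounded; Tarjan-style SCC detection
was not needed at oracle scale.

### SAT engine

The transition relation `T(x(t), x(t+1)) = AND_i [x_i(t+1) ↔ f_i(...)]` is
unfolded over `l` slots; component `i` at slot `s` is solver variable
`s·n + i + 1` (so a delay-free unfolding has exactly `l·n` main variables),
and the unfolding is converted to CNF by a structure-sharing Tseitin
transformation.  Temporal look-backs map to earlier slots; below slot 0
they are pinned to the slot-0 variables, which is exactly the padded
history convention, so both engines explore the same trajectory space.

Each model is decoded into a path of augmented states and scanned for the
first repeat; the states between the repeats form an attractor.  Found
attractors are blocked by one clause per attractor state per slot,
forbidding that augmented state anywhere in the path (clauses on history
bits map to the earlier slots that carry them; a clause made vacuous by
slot-0 clamping is dropped as a tautology).  An attractor-free model means
the path is too short: `l` starts at 2 and doubles, bounding the number of
rounds by the logarithm of the longest transient.  UNSAT terminates the
search with the complete attractor set, returned in the same canonical
rotation (lexicographically smallest augmented state first) as the
exhaustive engine, which the equivalence tests compare element for element.
The SAT engine does not compute basins.

The bundled backend is a two-watched-literal DPLL with chronological
backtracking.  Path CNFs are nearly functional — deciding the slot-0
variables unit-propagates everything else — so plain lowest-index branching
suffices at the problem sizes the package targets (tens of components).
The backend sits behind a three-method contract (add clause / solve /
model) so a CDCL library can replace it without touching the search.

## The screen

For `k` candidates with per-candidate allowed types and size bound `m`, all
combinations of size 1..m are enumerated in a fixed order (size, then
candidate positions, then knock-down before over-expression); `m > k` is
clamped with a warning.  Each combination is evaluated independently:
perturb → symbolically simplify every function under the total fixed map
(constant propagation, including `ALL`/`ANY` of a constant collapsing to
that constant) → attractor search (SAT engine by default) → compare.

Comparison projects each attractor onto the readout components and uses
*set* equality of projected states, duplicates collapsed, cyclic order
ignored — robust to period changes that leave the biological readout
identical.  An order-sensitive variant (`project_attractor_cyclic`) exists
for strict comparisons.  A requirement is a projected pattern plus a mode:
`must_not_exist` holds iff no perturbed attractor projects to the pattern,
`must_exist` iff some does; a screen's verdict is the conjunction over its
requirements, so an empty requirement list accepts every perturbation.
Requirement patterns may be written explicitly in the screen config or
derived from an unperturbed reference attractor (`from_reference`); an
explicit pattern wins.  A perturbation that freezes the whole network into
one steady state is a legal outcome.  Per-perturbation failures (e.g. a
cap refusal) are recorded in the result row, not fatal to the screen.
Rows are evaluated in parallel (joblib) but always collected back into
enumeration order, so results are independent of the worker count.

## Synthetic fixtures

The random-network generator draws, per component, up to `max_in_degree`
distinct regulators (default 3, a modest connectivity typical of curated
regulatory models), negates each with probability 1/2, and joins them with
random AND/OR; with probability `temporal_fraction` one regulator literal
is wrapped in `ALL`/`ANY` with window 2 or 3.  The same seed always yields
the same network.  The equivalence suites run on 200 such fixtures with
`n ∈ [3,10]`, half containing temporal operators, a quarter with one fixed
component — sizes chosen so the exhaustive oracle stays comfortably under
its cap while still covering period-1 and longer attractors, transients,
histories and fixing.  What these fixtures do *not* emulate: the scale of
published disease models (tens of components), scale-free in-degree
distributions, canalizing-function bias, or biologically curated logic;
passing the equivalence suite demonstrates correctness of the engines on
the state spaces it explores, not biological realism of the fixtures.

## Numerical and degenerate-input choices

* Component order is declaration order; it fixes bit order everywhere.
* Attractor canonical rotation minimizes the concatenated current+history
  bit string; reports sort attractors by that key.
* The identity function marks a component as an input (`dmg, dmg`).
* A network where every candidate perturbation search fails still returns
  a complete `ScreenResult` with per-row errors.
* Parser: `!` binds tightest, then `&`, then `|`; `ALL`/`ANY` (any case)
  followed by `(` are reserved words; identifiers are
  `[A-Za-z_][A-Za-z0-9_]*`, case-sensitive.

## Known limitations

* The exhaustive engine, and hence basin sizes, stop at the state-space
  cap; the SAT engine scales further but reports no basins.
* SBML-qual and other graphical/interchange formats are not supported; the
  text dialect's temporal operators are not portable to other BoolNet
  consumers.
* The bundled DPLL has no clause learning; adversarial CNFs far from the
  path-unfolding shape (e.g. large pigeonhole instances) will be slow.
  The solver contract exists precisely so a CDCL backend can be swapped in.
* Attractor comparison ignores cyclic order by default; phenotypes that
  differ only in the phase ordering of the same state set are not
  distinguished unless the strict projection is used.
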