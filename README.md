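# boolscreen

Attractor search and automated perturbation screening for synchronous
Boolean networks, including networks with temporal predicates.

## Who this is for

Systems biologists who model regulatory processes as Boolean networks — each
gene or protein is a binary component `x_i`, and the synchronous update rule

    x(t+1) = (f_1(x(t)), ..., f_n(x(t)))

drives the system into cycles of states, the *attractors*, which often
correspond to biologically meaningful phenotypes.  A central modeling
question is interventionist: which knock-downs (fix a component to 0) and
over-expressions (fix to 1), alone or in combination, remove an unwanted
long-term behavior or create a desired one?

`boolscreen` answers that question automatically.  Given a network, a set of
candidate components, allowed perturbation types and a maximum combination
size `m`, it enumerates every combination (for `k` candidates with both
types allowed there are `sum_{i=1..m} C(k,i) * 2^i` of them), recomputes the
attractors of each perturbed network, projects them onto user-chosen readout
components, and returns exactly the combinations whose long-term behavior
matches the declared requirements (attractor patterns that *must* or *must
not* exist after perturbation).

## What is inside

* **Two attractor-search engines.**  A brute-force engine enumerates the
  full state space (and is the only source of basin-of-attraction sizes),
  and a SAT-based engine encodes the transition relation
  `T(x(t), x(t+1)) = AND_i [x_i(t+1) <-> f_i(x(t))]`, unfolds it over `l`
  time slots, and extracts attractors from repeated states in satisfying
  paths, blocking each found attractor and prolonging the path until the
  formula is unsatisfiable.  The bundled solver is a complete DPLL; any
  CDCL library with the same three-method contract can be plugged in.
* **Temporal predicates.**  Transition functions may use `ALL(expr, d)`
  (true iff `expr` held on every one of the last `d` steps, current step
  included) and `ANY(expr, d)` (at least one step).  Dynamics and attractor
  equality are then defined over *augmented states* — the current vector
  plus the bounded history the windows require.
* **A BoolNet-compatible text format** (`name, expression` with `!`, `&`,
  `|`, constants, optional `targets, factors` header); the temporal
  operators are a documented extension.  DIMACS CNF export, TSV/JSON screen
  results, and a seeded random-network fixture generator round out the I/O.

## Worked example

`examples/toy3.bnet` is the three-component network
`f1 = !x1`, `f2 = x1 | x2`, `f3 = x1 & !x2`:

```
$ boolscreen attractors examples/toy3.bnet
# components: x1 x2 x3
attractor 1: period=2 basin=8: 010 -> 110
```

All eight states drain into the single period-2 attractor that alternates
between `x=(0,1,0)` and `(1,1,0)`.  `examples/cascade_screen.yaml` screens a
six-component damage→inflammation relay (input `dmg` fixed on) for the
perturbation combinations, up to pairs drawn from `{kin, tf, inh}` with
both types allowed (18 combinations), that prevent any attractor in which
the cytokine `il` is active:

```
$ boolscreen screen examples/cascade_screen.yaml
evaluated 18 perturbations; 7 valid
  tf=0
  inh=1
  kin=0+tf=0
  kin=1+tf=0
  kin=0+inh=1
  tf=0+inh=0
  tf=0+inh=1
```

Knocking down the transcription factor (`tf=0`) or over-expressing its
inhibitor (`inh=1`) — alone or combined with anything compatible — silences
the cytokine; knocking down the upstream kinase alone does not, because the
transcription factor's self-loop keeps a cytokine-active attractor alive.
`boolscreen perturb-path`, `convert` and `export-dimacs` cover single
trajectories, canonical rewriting and solver interchange; see `--help`.

The Python API mirrors the CLI: `parse_network`, `find_attractors_sat` /
`find_attractors_exhaustive`, `enumerate_perturbations`, `screen`.

A screen of a published 51-component senescence (SASP) model can be
reproduced by placing that model file at `examples/sasp/sasp.bnet`; it is
not redistributed here.

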