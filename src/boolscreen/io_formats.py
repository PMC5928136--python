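"""Network text format, fixture generation and result serialization.

The network grammar is BoolNet-compatible at its core — one line per
component, ``name, expression`` with ``!``/``&``/``|``, parentheses and the
constants ``0``/``1``, an optional ``targets, factors`` header and ``#``
comments — so existing delay-free models load unchanged.  The temporal
predicates ``ALL(expr, d)`` and ``ANY(expr, d)`` are an extension of this
dialect and are not portable to other BoolNet consumers.

Identifiers are letters, digits and underscore, not starting with a digit,
case-sensitive.  ``ALL``/``ANY`` (any capitalization) directly followed by
``(`` are reserved for the temporal operators.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from random import Random
from typing import Sequence

from .core import (
    And,
    BooleanNetwork,
    Const,
    Expr,
    NetworkError,
    Not,
    Or,
    TemporalAll,
    TemporalAny,
    Var,
)
from .perturb import ScreenResult
from .satsearch import UnfoldedPathCNF, to_dimacs


class ParseError(NetworkError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class NetworkDocument:
    """A parsed network plus the source line of each component definition."""

    network: BooleanNetwork
    line_of: dict[str, int]
    source: str


_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_TOKEN_RE = re.compile(
    r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_]*)|(?P<num>\d+)|(?P<op>[!&|(),]))"
)


class _ExprParser:
    """Recursive-descent parser for one transition expression.

    Precedence: NOT binds tightest, then AND, then OR; AND/OR are n-ary
    with left-to-right association.
    """

    def __init__(self, text: str, index_of: dict[str, int], line: int):
        self.tokens: list[tuple[str, str]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                if text[pos:].strip():
                    raise ParseError(f"unexpected character {text[pos:].strip()[0]!r}", line)
                break
            pos = m.end()
            for kind in ("ident", "num", "op"):
                val = m.group(kind)
                if val is not None:
                    self.tokens.append((kind, val))
                    break
        self.pos = 0
        self.index_of = index_of
        self.line = line

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of expression", self.line)
        self.pos += 1
        return tok

    def expect_op(self, op: str) -> None:
        tok = self.take()
        if tok != ("op", op):
            raise ParseError(f"expected {op!r}, found {tok[1]!r}", self.line)

    def parse(self) -> Expr:
        e = self.parse_or()
        if self.peek() is not None:
            raise ParseError(f"trailing input {self.peek()[1]!r}", self.line)
        return e

    def parse_or(self) -> Expr:
        parts = [self.parse_and()]
        while self.peek() == ("op", "|"):
            self.take()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> Expr:
        parts = [self.parse_unary()]
        while self.peek() == ("op", "&"):
            self.take()
            parts.append(self.parse_unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_unary(self) -> Expr:
        if self.peek() == ("op", "!"):
            self.take()
            return Not(self.parse_unary())
        return self.parse_atom()

    def parse_atom(self) -> Expr:
        kind, val = self.take()
        if kind == "num":
            if val in ("0", "1"):
                return Const(val == "1")
            raise ParseError(f"unexpected number {val!r}", self.line)
        if kind == "ident":
            if val.upper() in ("ALL", "ANY") and self.peek() == ("op", "("):
                return self.parse_temporal(val.upper())
            try:
                return Var(self.index_of[val])
            except KeyError:
                raise ParseError(f"unknown identifier {val!r}", self.line) from None
        if (kind, val) == ("op", "("):
            e = self.parse_or()
            self.expect_op(")")
            return e
        raise ParseError(f"unexpected token {val!r}", self.line)

    def parse_temporal(self, name: str) -> Expr:
        self.expect_op("(")
        child = self.parse_or()
        self.expect_op(",")
        kind, val = self.take()
        if kind != "num" or int(val) < 1:
            raise ParseError(
                f"{name} window must be a positive integer, found {val!r}", self.line
            )
        self.expect_op(")")
        cls = TemporalAll if name == "ALL" else TemporalAny
        return cls(child, int(val))


def parse_network(text: str) -> NetworkDocument:
    """Parse a network document; errors carry 1-based source line numbers."""
    raw_lines = text.splitlines()
    entries: list[tuple[int, str, str]] = []  # (lineno, name, expr text)
    for lineno, raw in enumerate(raw_lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," not in line:
            raise ParseError("expected 'name, expression'", lineno)
        name, rhs = line.split(",", 1)
        name = name.strip()
        if name.lower() == "targets":  # BoolNet header line
            continue
        if not _IDENT_RE.fullmatch(name):
            raise ParseError(f"invalid component name {name!r}", lineno)
        entries.append((lineno, name, rhs.strip()))
    if not entries:
        raise ParseError("no component definitions found", len(raw_lines) or 1)
    names = [name for _, name, _ in entries]
    seen: set[str] = set()
    for lineno, name, _ in entries:
        if name in seen:
            raise ParseError(f"duplicate component {name!r}", lineno)
        seen.add(name)
    index_of = {n: i for i, n in enumerate(names)}
    functions = []
    for lineno, name, rhs in entries:
        if not rhs:
            raise ParseError(f"empty expression for {name!r}", lineno)
        functions.append(_ExprParser(rhs, index_of, lineno).parse())
    network = BooleanNetwork(tuple(names), tuple(functions))
    return NetworkDocument(
        network=network,
        line_of={name: lineno for lineno, name, _ in entries},
        source=text,
    )


def load_network(path: str | Path) -> NetworkDocument:
    path = Path(path)
    return parse_network(path.read_text())


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_PREC_OR, _PREC_AND, _PREC_NOT = 1, 2, 3


def format_expr(expr: Expr, names: Sequence[str], _prec: int = 0) -> str:
    if isinstance(expr, Const):
        return "1" if expr.value else "0"
    if isinstance(expr, Var):
        return names[expr.index]
    if isinstance(expr, Not):
        return "!" + format_expr(expr.child, names, _PREC_NOT)
    if isinstance(expr, (And, Or)):
        prec = _PREC_AND if isinstance(expr, And) else _PREC_OR
        sep = " & " if isinstance(expr, And) else " | "
        body = sep.join(format_expr(c, names, prec) for c in expr.children)
        return f"({body})" if prec < _prec else body
    if isinstance(expr, (TemporalAll, TemporalAny)):
        op = "ALL" if isinstance(expr, TemporalAll) else "ANY"
        return f"{op}({format_expr(expr.child, names)}, {expr.window})"
    raise NetworkError(f"unknown expression node {expr!r}")


def write_network(network: BooleanNetwork) -> str:
    """Canonical serialization; ``parse(write(net))`` preserves attractors."""
    lines = ["targets, factors"]
    for name, f in zip(network.names, network.functions):
        lines.append(f"{name}, {format_expr(f, network.names)}")
    return "\n".join(lines) + "\n"


def save_network(network: BooleanNetwork, path: str | Path) -> None:
    Path(path).write_text(write_network(network))


# ---------------------------------------------------------------------------
# Random fixtures
# ---------------------------------------------------------------------------

def random_network(
    n: int,
    max_in_degree: int = 3,
    temporal_fraction: float = 0.0,
    seed: int = 0,
    name_prefix: str = "x",
) -> BooleanNetwork:
    """Seeded random network fixture for oracle-equivalence suites.

    Each component's function is a random NOT/AND/OR combination of at most
    ``max_in_degree`` regulators; with probability ``temporal_fraction`` one
    regulator literal is wrapped in ALL or ANY with a window of 2 or 3.
    The same seed always yields the identical network.
    """
    if n < 1 or max_in_degree < 1:
        raise NetworkError("need n >= 1 and max_in_degree >= 1")
    rng = Random(seed)
    names = tuple(f"{name_prefix}{i + 1}" for i in range(n))
    functions: list[Expr] = []
    for _ in range(n):
        k = rng.randint(1, min(max_in_degree, n))
        regulators = rng.sample(range(n), k)
        literals: list[Expr] = [
            Not(Var(j)) if rng.random() < 0.5 else Var(j) for j in regulators
        ]
        if rng.random() < temporal_fraction:
            w = rng.choice((2, 3))
            cls = rng.choice((TemporalAll, TemporalAny))
            pos = rng.randrange(len(literals))
            literals[pos] = cls(literals[pos], w)
        expr = literals[0]
        for lit in literals[1:]:
            op = rng.choice((And, Or))
            expr = op((expr, lit))
        functions.append(expr)
    return BooleanNetwork(names, tuple(functions))


# ---------------------------------------------------------------------------
# Results and DIMACS
# ---------------------------------------------------------------------------

def _projection_fingerprint(proj: frozenset[tuple[int, ...]]) -> str:
    return "|".join("".join(str(b) for b in state) for state in sorted(proj))


def screen_result_records(result: ScreenResult) -> list[dict]:
    """One flat record per evaluated perturbation, enumeration order."""
    records = []
    for row in result.rows:
        records.append(
            {
                "perturbation": row.perturbation.label(),
                "components": ",".join(c for c, _ in row.perturbation.assignments),
                "types": ",".join(t.value for _, t in row.perturbation.assignments),
                "size": row.perturbation.size,
                "verdict": (
                    "" if row.verdict is None else ("valid" if row.verdict else "invalid")
                ),
                "n_attractors": "" if row.n_attractors is None else row.n_attractors,
                "projections": (
                    ""
                    if row.projections is None
                    else ";".join(_projection_fingerprint(p) for p in row.projections)
                ),
                "error": row.error or "",
            }
        )
    return records


_TSV_COLUMNS = (
    "perturbation",
    "components",
    "types",
    "size",
    "verdict",
    "n_attractors",
    "projections",
    "error",
)


def write_results(
    result: ScreenResult,
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Serialize a screen: TSV table (one row per perturbation) and/or a
    JSON document with the rows plus the valid subset."""
    records = screen_result_records(result)
    if tsv_path is not None:
        lines = ["\t".join(_TSV_COLUMNS)]
        for rec in records:
            lines.append("\t".join(str(rec[c]) for c in _TSV_COLUMNS))
        Path(tsv_path).write_text("\n".join(lines) + "\n")
    if json_path is not None:
        doc = {
            "readout_components": list(result.readout_components),
            "requirements": [
                {
                    "mode": req.mode.value,
                    "components": list(req.components),
                    "pattern": sorted(list(state) for state in req.pattern),
                }
                for req in result.requirements
            ],
            "rows": records,
            "valid": [p.label() for p in result.valid],
        }
        Path(json_path).write_text(json.dumps(doc, indent=2) + "\n")


def export_dimacs(cnf: UnfoldedPathCNF, path: str | Path, comments: Sequence[str] = ()) -> None:
    Path(path).write_text(to_dimacs(cnf, comments))
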