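"""Boolean formulas that an average person can evaluate mentally.

A *human knowledge model* (HKM) is a Boolean decision rule constrained by
what cognitive research says people can compute in their head, in real
time, without external aids:

* operators drawn from ``AND``, ``OR``, ``NOT`` and the thresholded
  Boolean ``SUM`` ("at least *t* of these *k* conditions hold");
* at most four variables, each used at most once (read-once formulas);
* at most four operators.

This module provides the expression tree (:class:`Var`, :class:`Not`,
:class:`And`, :class:`Or`, :class:`SumGe`), vectorised evaluation over
observation matrices, truth tables as semantic fingerprints, the
operator-cost accounting that defines admissibility, the combinatorial
helpers behind the search-space size estimate, and a round-trip text
grammar (``(x1 AND NOT x3) OR x7``, ``SUM(x0, x1, x2) >= 2``).

Operator-counting convention
----------------------------
An ``a``-ary AND/OR chain counts as ``a - 1`` binary connectives; every
NOT counts as one operator; a thresholded SUM counts as a *single*
operator regardless of arity, treating "count how many of these hold and
compare" as one cognitive act.  Under this convention the majority-of-3
rule costs one operator and is admissible, while its four-minterm DNF is
not.  A NOT that merely flips the direction of a numeric threshold atom
("age > 60" vs "age <= 60") is free; that discount is applied by the
searcher, which knows the atom kinds — here NOT always costs 1.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence, Union

import numpy as np

from .errors import InputError

__all__ = [
    "OP_AND",
    "OP_OR",
    "OP_NOT",
    "OP_SUMGE",
    "DEFAULT_OPS",
    "Var",
    "Not",
    "And",
    "Or",
    "SumGe",
    "Formula",
    "TruthTable",
    "HKMConstraints",
    "ComplexityEstimate",
    "variable_indices",
    "variable_count",
    "is_read_once",
    "operator_count",
    "evaluate",
    "truth_table",
    "is_admissible",
    "count_subsets",
    "estimate_complexity",
    "render",
    "parse",
]

OP_AND = "AND"
OP_OR = "OR"
OP_NOT = "NOT"
OP_SUMGE = "SUMGE"

#: The full operator set of the model class.
DEFAULT_OPS = frozenset({OP_AND, OP_OR, OP_NOT, OP_SUMGE})

_KIND_RANK = {"Var": 0, "Not": 1, "And": 2, "Or": 3, "SumGe": 4}


# ---------------------------------------------------------------------------
# expression nodes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Var:
    """A Boolean variable, identified by a non-negative column index."""

    index: int

    def __post_init__(self) -> None:
        if not isinstance(self.index, int) or self.index < 0:
            raise InputError(f"variable index must be a non-negative int, got {self.index!r}")


@dataclass(frozen=True)
class Not:
    """Logical negation of a single child expression."""

    child: "Formula"


@dataclass(frozen=True)
class And:
    """n-ary conjunction (arity >= 2); children kept in canonical order."""

    children: tuple["Formula", ...]

    def __post_init__(self) -> None:
        children = tuple(self.children)
        if len(children) < 2:
            raise InputError("AND requires at least 2 children")
        object.__setattr__(self, "children", _canonical_children(children))


@dataclass(frozen=True)
class Or:
    """n-ary disjunction (arity >= 2); children kept in canonical order."""

    children: tuple["Formula", ...]

    def __post_init__(self) -> None:
        children = tuple(self.children)
        if len(children) < 2:
            raise InputError("OR requires at least 2 children")
        object.__setattr__(self, "children", _canonical_children(children))


@dataclass(frozen=True)
class SumGe:
    """Thresholded Boolean SUM: true iff at least ``threshold`` children hold.

    Children must be literals (a variable or a negated variable): the
    operator models a person counting how many of a list of *conditions*
    are met.  The threshold is restricted to ``2 <= t <= arity - 1``
    because ``t = 1`` is an OR and ``t = arity`` is an AND, which must be
    written as such.
    """

    children: tuple["Formula", ...]
    threshold: int

    def __post_init__(self) -> None:
        children = tuple(self.children)
        if len(children) < 2:
            raise InputError("SUM requires at least 2 children")
        for c in children:
            if not _is_literal(c):
                raise InputError("SUM children must be variables or negated variables")
        if not (2 <= self.threshold <= len(children) - 1):
            raise InputError(
                f"SUM threshold must satisfy 2 <= t <= arity-1, got t={self.threshold} "
                f"with arity {len(children)} (t=1 is OR, t=arity is AND)"
            )
        object.__setattr__(self, "children", _canonical_children(children))


Formula = Union[Var, Not, And, Or, SumGe]


def _is_literal(node: "Formula") -> bool:
    return isinstance(node, Var) or (isinstance(node, Not) and isinstance(node.child, Var))


def _min_var(node: "Formula") -> int:
    if isinstance(node, Var):
        return node.index
    if isinstance(node, Not):
        return _min_var(node.child)
    return min(_min_var(c) for c in node.children)


def _sort_key(node: "Formula") -> tuple:
    return (_KIND_RANK[type(node).__name__], _min_var(node), render(node))


def _canonical_children(children: tuple) -> tuple:
    return tuple(sorted(children, key=_sort_key))


# ---------------------------------------------------------------------------
# structural accounting
# ---------------------------------------------------------------------------


def variable_indices(formula: Formula) -> tuple[int, ...]:
    """Sorted tuple of distinct variable indices used in the formula."""
    return tuple(sorted(set(_var_list(formula))))


def _var_list(formula: Formula) -> list[int]:
    if isinstance(formula, Var):
        return [formula.index]
    if isinstance(formula, Not):
        return _var_list(formula.child)
    out: list[int] = []
    for c in formula.children:
        out.extend(_var_list(c))
    return out


def variable_count(formula: Formula) -> int:
    """Number of distinct variables in the formula."""
    return len(variable_indices(formula))


def is_read_once(formula: Formula) -> bool:
    """True iff every variable occurs at most once in the whole tree."""
    vs = _var_list(formula)
    return len(vs) == len(set(vs))


def operator_count(formula: Formula) -> int:
    """Cognitive operator cost under the package's counting convention.

    NOT costs 1, an a-ary AND/OR costs ``a - 1``, a thresholded SUM costs
    1 regardless of arity.
    """
    if isinstance(formula, Var):
        return 0
    if isinstance(formula, Not):
        return 1 + operator_count(formula.child)
    child_cost = sum(operator_count(c) for c in formula.children)
    if isinstance(formula, SumGe):
        return 1 + child_cost
    return len(formula.children) - 1 + child_cost


def _kinds(formula: Formula, acc: set) -> set:
    name = type(formula).__name__
    if isinstance(formula, Not):
        acc.add(OP_NOT)
        _kinds(formula.child, acc)
    elif isinstance(formula, And):
        acc.add(OP_AND)
        for c in formula.children:
            _kinds(c, acc)
    elif isinstance(formula, Or):
        acc.add(OP_OR)
        for c in formula.children:
            _kinds(c, acc)
    elif isinstance(formula, SumGe):
        acc.add(OP_SUMGE)
        for c in formula.children:
            _kinds(c, acc)
    return acc


# ---------------------------------------------------------------------------
# evaluation and truth tables
# ---------------------------------------------------------------------------


def evaluate(formula: Formula, rows) -> np.ndarray:
    """Evaluate a formula element-wise on a Boolean observation matrix.

    Parameters
    ----------
    formula
        Expression tree over variable indices.
    rows
        Boolean array of shape ``(observations, variables)``.  Column ``i``
        supplies the values of ``Var(i)``; there must be no missing
        entries (missingness is handled upstream by the binarizer).

    Returns
    -------
    numpy.ndarray
        Boolean vector with one truth value per observation.
    """
    mat = np.asarray(rows, dtype=bool)
    if mat.ndim == 1:
        mat = mat.reshape(1, -1)
    if mat.ndim != 2:
        raise InputError("rows must be a 2-D observations x variables matrix")
    idx = variable_indices(formula)
    if idx and idx[-1] >= mat.shape[1]:
        raise InputError(
            f"formula refers to variable x{idx[-1]} but the matrix has only "
            f"{mat.shape[1]} columns"
        )
    return _eval(formula, mat)


def _eval(formula: Formula, mat: np.ndarray) -> np.ndarray:
    if isinstance(formula, Var):
        return mat[:, formula.index]
    if isinstance(formula, Not):
        return ~_eval(formula.child, mat)
    vals = [_eval(c, mat) for c in formula.children]
    if isinstance(formula, And):
        return np.logical_and.reduce(vals)
    if isinstance(formula, Or):
        return np.logical_or.reduce(vals)
    return np.sum(np.stack(vals), axis=0) >= formula.threshold


@dataclass(frozen=True)
class TruthTable:
    """Semantic fingerprint of a Boolean function on ``n <= 4`` variables.

    Row ``r`` (``0 <= r < 2**n``) is the assignment in which variable ``i``
    takes bit ``i`` of ``r`` (least significant bit = variable 0);
    ``bits`` packs the 2**n outcomes as an integer with bit ``r`` set iff
    the function is true on row ``r``.
    """

    n: int
    bits: int

    def __post_init__(self) -> None:
        if not (1 <= self.n <= 4):
            raise InputError(f"truth tables support 1..4 variables, got n={self.n}")
        if not (0 <= self.bits < 1 << (1 << self.n)):
            raise InputError("bits out of range for 2**n rows")

    @property
    def n_rows(self) -> int:
        return 1 << self.n

    def value(self, row: int) -> bool:
        return bool((self.bits >> row) & 1)

    def to_array(self) -> np.ndarray:
        return np.array([self.value(r) for r in range(self.n_rows)], dtype=bool)

    def bitstring(self) -> str:
        """Row-0-first string of '0'/'1', e.g. '0001' for AND of 2 variables."""
        return "".join("1" if self.value(r) else "0" for r in range(self.n_rows))

    @classmethod
    def from_bitstring(cls, s: str) -> "TruthTable":
        n = int(math.log2(len(s)))
        if 1 << n != len(s):
            raise InputError("bitstring length must be a power of two")
        bits = sum(1 << r for r, ch in enumerate(s) if ch == "1")
        return cls(n, bits)

    @classmethod
    def from_array(cls, values) -> "TruthTable":
        arr = np.asarray(values, dtype=bool)
        n = int(math.log2(arr.size))
        if 1 << n != arr.size:
            raise InputError("array length must be a power of two")
        bits = int(sum(1 << r for r in range(arr.size) if arr[r]))
        return cls(n, bits)

    def is_constant(self) -> bool:
        return self.bits == 0 or self.bits == (1 << self.n_rows) - 1

    def depends_on(self, i: int) -> bool:
        """True iff flipping variable ``i`` changes the output somewhere."""
        for r in range(self.n_rows):
            if self.value(r) != self.value(r ^ (1 << i)):
                return True
        return False

    def is_proper(self) -> bool:
        """True iff the function depends on all of its n variables."""
        return all(self.depends_on(i) for i in range(self.n))

    def complement(self) -> "TruthTable":
        return TruthTable(self.n, self.bits ^ ((1 << self.n_rows) - 1))

    def permuted(self, perm: Sequence[int]) -> "TruthTable":
        """Relabel variables: new variable ``j`` is old variable ``perm[j]``."""
        if sorted(perm) != list(range(self.n)):
            raise InputError("perm must be a permutation of 0..n-1")
        bits = 0
        for r in range(self.n_rows):
            old = 0
            for j in range(self.n):
                if (r >> j) & 1:
                    old |= 1 << perm[j]
            if self.value(old):
                bits |= 1 << r
        return TruthTable(self.n, bits)

    def canonical_class(self) -> int:
        """Smallest ``bits`` over all variable relabelings (class invariant)."""
        return min(
            self.permuted(p).bits for p in itertools.permutations(range(self.n))
        )


def truth_table(formula: Formula) -> TruthTable:
    """Full truth table of a formula using variables ``0..n-1`` contiguously."""
    idx = variable_indices(formula)
    if not idx:
        raise InputError("formula has no variables")
    n = len(idx)
    if idx != tuple(range(n)):
        raise InputError(f"formula must use variables 0..{n - 1} contiguously, uses {idx}")
    if n > 4:
        raise InputError("truth tables are only defined for n <= 4")
    assignments = ((np.arange(1 << n)[:, None] >> np.arange(n)) & 1).astype(bool)
    vals = evaluate(formula, assignments)
    return TruthTable.from_array(vals)


# ---------------------------------------------------------------------------
# admissibility
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HKMConstraints:
    """The admissibility envelope of the model class.

    Defaults encode the human-computability constraint set: at most four
    variables (each used once), at most four operators, operator kinds
    AND/OR/NOT/thresholded-SUM.
    """

    max_vars: int = 4
    max_ops: int = 4
    allowed_ops: frozenset = DEFAULT_OPS

    def __post_init__(self) -> None:
        if not (1 <= self.max_vars <= 4):
            raise InputError("max_vars must be between 1 and 4")
        if self.max_ops < 0:
            raise InputError("max_ops must be non-negative")
        extra = frozenset(self.allowed_ops) - DEFAULT_OPS
        if extra:
            raise InputError(f"unknown operators: {sorted(extra)}")
        object.__setattr__(self, "allowed_ops", frozenset(self.allowed_ops))


def is_admissible(formula: Formula, constraints: HKMConstraints | None = None) -> bool:
    """Check a formula against the human-computability constraints."""
    c = constraints or HKMConstraints()
    if not is_read_once(formula):
        return False
    if variable_count(formula) > c.max_vars:
        return False
    if operator_count(formula) > c.max_ops:
        return False
    return _kinds(formula, set()) <= c.allowed_ops


# ---------------------------------------------------------------------------
# search-space accounting
# ---------------------------------------------------------------------------


def count_subsets(N: int, K: int, n: int) -> int:
    """Number of n-variable subsets drawn from N features with K thresholds each.

    K thresholds per feature produce at most ``N * K`` Boolean atoms, so the
    subset count is the binomial coefficient ``C(N*K, n)``; returns 0 when
    ``N*K < n``.
    """
    if N < 1 or K < 1:
        raise InputError("N and K must be >= 1")
    if not (1 <= n <= 4):
        raise InputError("n must be between 1 and 4")
    if N * K < n:
        return 0
    return math.comb(N * K, n)


@dataclass(frozen=True)
class ComplexityEstimate:
    """Decomposition of the exhaustive-search cost into its principal factors.

    ``total = subset_count x formula_bound x per_pair_cost``, where
    ``subset_count`` enumerates variable subsets, ``formula_bound`` bounds
    the number of admissible Boolean expressions per subset (a small
    constant, below 100), and ``per_pair_cost`` is linear in the number of
    observations L.
    """

    N: int
    K: int
    L: int
    n: int
    subset_count: int
    formula_bound: int
    per_pair_cost: int
    total: int


def estimate_complexity(
    N: int, K: int, L: int, n: int, constraints: HKMConstraints | None = None
) -> ComplexityEstimate:
    """Estimate the exhaustive-search cost for a dataset of the given shape."""
    if L < 1:
        raise InputError("L must be >= 1")
    from .simplifier import build_catalog  # deferred: simplifier imports this module

    subset_count = count_subsets(N, K, n)
    catalog = build_catalog(constraints or HKMConstraints())
    classes = catalog.class_count(max_n=n)
    formula_bound = min(classes, 100)
    per_pair_cost = L
    return ComplexityEstimate(
        N=N,
        K=K,
        L=L,
        n=n,
        subset_count=subset_count,
        formula_bound=formula_bound,
        per_pair_cost=per_pair_cost,
        total=subset_count * formula_bound * per_pair_cost,
    )


# ---------------------------------------------------------------------------
# rendering and parsing
# ---------------------------------------------------------------------------


def render(formula: Formula, names: Mapping[int, str] | Sequence[str] | None = None) -> str:
    """Human-readable text form, e.g. ``(x0 AND NOT x1) OR x2``.

    ``names`` optionally maps variable indices to display names; by default
    variables render as ``x<i>``.  Output round-trips through :func:`parse`
    when default names are used.
    """

    def name(i: int) -> str:
        if names is None:
            return f"x{i}"
        return names[i]

    def rec(node: Formula, parent: str) -> str:
        if isinstance(node, Var):
            return name(node.index)
        if isinstance(node, Not):
            inner = rec(node.child, "Not")
            if isinstance(node.child, Var):
                return f"NOT {inner}"
            return f"NOT ({inner})"
        if isinstance(node, SumGe):
            args = ", ".join(rec(c, "SumGe") for c in node.children)
            s = f"SUM({args}) >= {node.threshold}"
            return f"({s})" if parent in ("And", "Or", "Not") else s
        sep = " AND " if isinstance(node, And) else " OR "
        parts = []
        for c in node.children:
            text = rec(c, type(node).__name__)
            if isinstance(c, (And, Or)):
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)

    return rec(formula, "")


_TOKEN_RE = re.compile(r"\s*(\(|\)|,|>=|\d+|[A-Za-z_][A-Za-z_0-9]*)")


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise InputError(f"cannot tokenize formula text at position {pos}: {text[pos:]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for the rendering grammar (x<i> variables)."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self, expected: str | None = None) -> str:
        tok = self.peek()
        if tok is None:
            raise InputError("unexpected end of formula text")
        if expected is not None and tok != expected:
            raise InputError(f"expected {expected!r}, got {tok!r}")
        self.pos += 1
        return tok

    def parse(self) -> Formula:
        node = self.expr()
        if self.peek() is not None:
            raise InputError(f"trailing tokens after formula: {self.tokens[self.pos:]}")
        return node

    def expr(self) -> Formula:
        parts = [self.conjunction()]
        while self.peek() == "OR":
            self.take("OR")
            parts.append(self.conjunction())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def conjunction(self) -> Formula:
        parts = [self.unary()]
        while self.peek() == "AND":
            self.take("AND")
            parts.append(self.unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def unary(self) -> Formula:
        if self.peek() == "NOT":
            self.take("NOT")
            return Not(self.unary())
        return self.primary()

    def primary(self) -> Formula:
        tok = self.peek()
        if tok == "(":
            self.take("(")
            node = self.expr()
            self.take(")")
            return node
        if tok == "SUM":
            self.take("SUM")
            self.take("(")
            children = [self.expr()]
            while self.peek() == ",":
                self.take(",")
                children.append(self.expr())
            self.take(")")
            self.take(">=")
            t = self.take()
            if not t.isdigit():
                raise InputError(f"SUM threshold must be an integer, got {t!r}")
            return SumGe(tuple(children), int(t))
        tok = self.take()
        m = re.fullmatch(r"x(\d+)", tok)
        if m is None:
            raise InputError(f"expected a variable like x0, got {tok!r}")
        return Var(int(m.group(1)))


def parse(text: str) -> Formula:
    """Parse a formula rendered with default ``x<i>`` variable names."""
    return _Parser(_tokenize(text)).parse()
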