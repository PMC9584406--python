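"""Shortest admissible expression per Boolean function ("simplification").

The learner starts from Boolean functions as truth tables.  A table's DNF
is rarely human-computable (it repeats variables and piles up operators),
so every reachable table is mapped to its *shortest* admissible
expression instead, including thresholded-SUM forms: the majority-of-3
function costs four minterms as a DNF but a single counting operator as
``SUM(x0, x1, x2) >= 2``.  Tables that no admissible expression can
produce (e.g. XOR, which needs a repeated variable) are simply absent and
are excluded from any further processing.

The catalog is built by exhaustive enumeration of read-once expression
trees over 1..4 variables.  Each entry also records cost *variants*: the
same table may be reachable by formulas with different numbers of
NOT-on-variable nodes, and those NOTs become free when the variable is a
numeric threshold atom (direction flips cost nothing).  The searcher uses
the variants to pick the cheapest formula for a concrete atom subset.

Construction is deterministic and cached per constraints object.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .errors import DegenerateDataError, InputError
from .formula_core import (
    OP_AND,
    OP_NOT,
    OP_OR,
    OP_SUMGE,
    And,
    Formula,
    HKMConstraints,
    Not,
    Or,
    SumGe,
    TruthTable,
    Var,
    operator_count,
    render,
    truth_table,
)

__all__ = [
    "CatalogEntry",
    "CostVariant",
    "SimplificationCatalog",
    "build_catalog",
    "dnf_of",
    "simplify",
    "count_semantic_classes",
]


# ---------------------------------------------------------------------------
# DNF construction
# ---------------------------------------------------------------------------


def dnf_of(table: TruthTable) -> Formula:
    """Disjunction of full minterms reproducing ``table`` exactly.

    The result is generally *not* admissible: variables repeat across
    minterms and the operator count can far exceed the human limit.  It is
    the intermediate form that simplification starts from.
    """
    if table.is_constant():
        raise DegenerateDataError("constant truth table has no DNF over its variables")
    minterms: list[Formula] = []
    for r in range(table.n_rows):
        if not table.value(r):
            continue
        literals: list[Formula] = [
            Var(i) if (r >> i) & 1 else Not(Var(i)) for i in range(table.n)
        ]
        minterms.append(literals[0] if len(literals) == 1 else And(tuple(literals)))
    return minterms[0] if len(minterms) == 1 else Or(tuple(minterms))


# ---------------------------------------------------------------------------
# exhaustive enumeration of admissible expression trees
# ---------------------------------------------------------------------------


def _set_partitions(items: tuple[int, ...]) -> Iterator[list[tuple[int, ...]]]:
    """All partitions of ``items`` into unordered non-empty blocks."""
    if len(items) == 1:
        yield [items]
        return
    head, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [(head,) + part[i]] + part[i + 1 :]
        yield [(head,)] + part


@dataclass(frozen=True)
class CostVariant:
    """One way of expressing a table: (total operators, leaf-NOT positions).

    ``leaf_not_mask`` has bit ``i`` set when the formula contains a NOT
    applied directly to variable ``i``; those NOTs cost nothing when the
    variable is bound to a threshold atom (the comparison direction simply
    flips), so the effective cost for a concrete subset is
    ``ops - popcount(leaf_not_mask & free_mask)``.
    """

    ops: int
    leaf_not_mask: int
    formula: Formula

    def effective_ops(self, free_mask: int) -> int:
        return self.ops - (self.leaf_not_mask & free_mask).bit_count()


@dataclass(frozen=True)
class CatalogEntry:
    """Shortest admissible expression for one labeled truth table."""

    table: TruthTable
    formula: Formula
    ops: int
    variants: tuple[CostVariant, ...]

    def best_for(self, free_mask: int) -> tuple[int, Formula]:
        """Cheapest (effective ops, formula) given free-negation variables."""
        best = min(
            self.variants,
            key=lambda v: (v.effective_ops(free_mask), render(v.formula)),
        )
        return best.effective_ops(free_mask), best.formula


class _Builder:
    """Bottom-up enumeration of read-once trees over one variable set."""

    def __init__(self, n: int, constraints: HKMConstraints):
        self.n = n
        self.c = constraints
        self.assignments = ((np.arange(1 << n)[:, None] >> np.arange(n)) & 1).astype(bool)
        self.memo: dict[tuple[int, ...], dict[int, list]] = {}

    def entries(self, varset: tuple[int, ...]) -> dict[int, list]:
        if varset in self.memo:
            return self.memo[varset]
        store: dict[int, list] = {}
        if len(varset) == 1:
            v = varset[0]
            vals = self.assignments[:, v].copy()
            self._add(store, vals, 0, 0, Var(v))
            if OP_NOT in self.c.allowed_ops:
                self._add(store, ~vals, 1, 1 << v, Not(Var(v)))
        else:
            for blocks in _set_partitions(varset):
                if len(blocks) < 2:
                    continue
                self._combine(store, [self.entries(tuple(sorted(b))) for b in blocks])
        self.memo[varset] = store
        return store

    def _combine(self, store: dict, block_entries: list[dict]) -> None:
        k = len(block_entries)
        max_ops = self.c.max_ops
        pools = [
            [(bits, var) for bits, lst in be.items() for var in lst]
            for be in block_entries
        ]
        for combo in itertools.product(*pools):
            child_ops = sum(v.ops for _, v in combo)
            child_mask = 0
            for _, v in combo:
                child_mask |= v.leaf_not_mask
            # cheapest any connective can add is 1, and leaf NOTs inside
            # children are already discounted in the budget check
            if child_ops - child_mask.bit_count() + 1 > max_ops:
                continue
            children = tuple(v.formula for _, v in combo)
            vals_list = [self._vals(bits) for bits, _ in combo]
            if OP_AND in self.c.allowed_ops and not any(
                isinstance(f, And) for f in children
            ):
                self._emit(
                    store, np.logical_and.reduce(vals_list),
                    child_ops + k - 1, child_mask, And(children),
                )
            if OP_OR in self.c.allowed_ops and not any(
                isinstance(f, Or) for f in children
            ):
                self._emit(
                    store, np.logical_or.reduce(vals_list),
                    child_ops + k - 1, child_mask, Or(children),
                )
            if (
                OP_SUMGE in self.c.allowed_ops
                and k >= 3
                and all(isinstance(f, Var) or isinstance(f, Not) for f in children)
                and all(
                    isinstance(f, Var) or isinstance(f.child, Var) for f in children
                )
            ):
                counts = np.sum(np.stack(vals_list), axis=0)
                for t in range(2, k):
                    self._emit(
                        store, counts >= t, child_ops + 1, child_mask,
                        SumGe(children, t),
                    )

    def _vals(self, bits: int) -> np.ndarray:
        rows = self.assignments.shape[0]
        return np.array([(bits >> r) & 1 for r in range(rows)], dtype=bool)

    def _emit(self, store, vals, ops, mask, formula) -> None:
        added = self._add(store, vals, ops, mask, formula)
        if OP_NOT in self.c.allowed_ops and not isinstance(formula, Not):
            self._add(store, ~vals, ops + 1, mask, Not(formula))

    def _add(self, store, vals, ops, mask, formula) -> bool:
        """Insert a candidate unless some stored variant dominates it.

        Variant (o1, m1) dominates (o2, m2) iff for every possible set F of
        free-negation variables o1 - |m1 & F| <= o2 - |m2 & F|, which
        reduces to o1 + |m2 \\ m1| <= o2.
        """
        if ops - mask.bit_count() > self.c.max_ops:
            return False
        bits = int(
            sum(1 << r for r in range(vals.shape[0]) if vals[r])
        )
        new = CostVariant(ops, mask, formula)
        lst = store.get(bits)
        if lst is None:
            store[bits] = [new]
            return True
        kept = []
        for old in lst:
            if old.ops == ops and old.leaf_not_mask == mask:
                # same cost profile: keep the canonically smaller rendering
                if render(old.formula) <= render(formula):
                    return False
                continue
            if old.ops + (mask & ~old.leaf_not_mask).bit_count() <= ops:
                return False  # dominated by old
            if not (ops + (old.leaf_not_mask & ~mask).bit_count() <= old.ops):
                kept.append(old)  # old not dominated by new
        kept.append(new)
        store[bits] = kept
        return True


@dataclass
class SimplificationCatalog:
    """Lookup from truth table to shortest admissible expression, n = 1..4.

    ``strict(n)`` maps each reachable labeled table to its minimal formula
    under the standard operator counting (NOT on a variable costs 1).
    Variants additionally expose formulas that become cheapest when some
    variables allow free direction flips.
    """

    constraints: HKMConstraints

    def __post_init__(self) -> None:
        self._strict: dict[int, dict[int, CatalogEntry]] = {}
        self._all_variants: dict[int, dict[int, tuple[CostVariant, ...]]] = {}
        self._array_cache: dict[tuple[int, int], tuple] = {}
        for n in range(1, self.constraints.max_vars + 1):
            self._build_size(n)

    def _build_size(self, n: int) -> None:
        builder = _Builder(n, self.constraints)
        raw = builder.entries(tuple(range(n)))
        strict: dict[int, CatalogEntry] = {}
        variants: dict[int, tuple[CostVariant, ...]] = {}
        for bits in sorted(raw):
            table = TruthTable(n, bits)
            assert table.is_proper(), "read-once enumeration produced a dummy variable"
            vs = tuple(
                sorted(raw[bits], key=lambda v: (v.ops, v.leaf_not_mask, render(v.formula)))
            )
            variants[bits] = vs
            admissible = [v for v in vs if v.ops <= self.constraints.max_ops]
            if admissible:
                best = min(admissible, key=lambda v: (v.ops, render(v.formula)))
                strict[bits] = CatalogEntry(
                    table=table, formula=best.formula, ops=best.ops, variants=vs
                )
        self._strict[n] = strict
        self._all_variants[n] = variants

    # -- lookups ----------------------------------------------------------

    def sizes(self) -> tuple[int, ...]:
        return tuple(sorted(self._strict))

    def tables(self, n: int) -> dict[int, CatalogEntry]:
        """Reachable labeled tables of exactly n variables (strict costing)."""
        return self._strict[n]

    def lookup(self, table: TruthTable) -> CatalogEntry | None:
        return self._strict.get(table.n, {}).get(table.bits)

    def admissible_for(self, n: int, free_mask: int = 0):
        """Arrays for the search loop: tables admissible given free flips.

        Returns ``(bits_matrix, ops, formulas)`` where ``bits_matrix`` is an
        int64 matrix of shape (tables, 2**n) with the table outcomes,
        ``ops`` the effective operator cost per table, and ``formulas`` the
        representative expression per table.  Ordered by table bits for
        determinism; cached per (n, free_mask).
        """
        key = (n, free_mask)
        if key in self._array_cache:
            return self._array_cache[key]
        rows = []
        ops_list = []
        formulas = []
        max_ops = self.constraints.max_ops
        for bits in sorted(self._all_variants[n]):
            vs = self._all_variants[n][bits]
            eff, formula = min(
                ((v.effective_ops(free_mask), v.formula) for v in vs),
                key=lambda p: (p[0], render(p[1])),
            )
            if eff > max_ops:
                continue
            rows.append([(bits >> r) & 1 for r in range(1 << n)])
            ops_list.append(eff)
            formulas.append(formula)
        result = (
            np.asarray(rows, dtype=np.int64),
            np.asarray(ops_list, dtype=np.int64),
            tuple(formulas),
        )
        self._array_cache[key] = result
        return result

    # -- class accounting --------------------------------------------------

    def class_representatives(self, n: int) -> list[CatalogEntry]:
        """One entry per permutation-distinct class of n-variable tables."""
        seen: dict[int, CatalogEntry] = {}
        # ascending bits order: the canonical (smallest-bits) member of each
        # class is reached first, so first-seen is the class representative
        for bits in sorted(self._strict[n]):
            entry = self._strict[n][bits]
            canon = entry.table.canonical_class()
            seen.setdefault(canon, entry)
        return [seen[c] for c in sorted(seen)]

    def class_count(self, n: int | None = None, max_n: int | None = None) -> int:
        """Permutation-distinct semantic classes (proper tables only)."""
        if n is not None:
            sizes = [n]
        else:
            sizes = [s for s in self.sizes() if max_n is None or s <= max_n]
        return sum(len(self.class_representatives(s)) for s in sizes)

    # -- export ------------------------------------------------------------

    def export(self) -> dict:
        """JSON-ready mapping ``{n: {bitstring: formula string}}``."""
        return {
            str(n): {
                entry.table.bitstring(): render(entry.formula)
                for entry in self._strict[n].values()
            }
            for n in self.sizes()
        }

    def export_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.export(), fh, indent=1, sort_keys=True)


_CACHE: dict[HKMConstraints, SimplificationCatalog] = {}


def build_catalog(constraints: HKMConstraints | None = None) -> SimplificationCatalog:
    """Build (or fetch the cached) catalog for a constraints object."""
    c = constraints or HKMConstraints()
    if c not in _CACHE:
        _CACHE[c] = SimplificationCatalog(c)
    return _CACHE[c]


def simplify(table: TruthTable, catalog: SimplificationCatalog) -> Formula | None:
    """Shortest admissible expression for ``table``, or None if unreachable."""
    if table.is_constant():
        raise DegenerateDataError("constant truth table cannot be simplified")
    entry = catalog.lookup(table)
    return None if entry is None else entry.formula


def count_semantic_classes(
    catalog: SimplificationCatalog, n: int | None = None
) -> int:
    """Permutation-distinct admissible function classes (all sizes by default)."""
    return catalog.class_count(n=n)
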