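"""Independent brute-force reference for the exhaustive rule search.

Everything here is coded from first principles, differently from the
package: formulas are enumerated as *binary* connective trees (cost 1 per
binary AND/OR, 1 per NOT, 1 + negated-literal-count per thresholded SUM)
over global truth-table bitmasks, and scores are computed with plain
Python integer arithmetic.  Used to cross-check catalog minimality and
the searcher's top-M lists on small instances.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_tables(n: int, max_ops: int = 4) -> dict[int, int]:
    """Minimal operator count per reachable *proper* labeled table.

    Fixpoint dynamic programming over states (used-variable mask, table
    bitmask): literals cost 0 (or 1 negated), a binary AND/OR costs 1, a
    NOT costs 1, a SUM over k >= 3 literals with threshold 2..k-1 costs
    1 plus one per negated literal.  Read-once is enforced by requiring
    disjoint used-variable masks when combining.
    """
    n_rows = 1 << n
    full = (1 << n_rows) - 1
    var_bits = []
    for v in range(n):
        b = 0
        for r in range(n_rows):
            if (r >> v) & 1:
                b |= 1 << r
        var_bits.append(b)

    best: dict[tuple[int, int], int] = {}

    def offer(used: int, bits: int, ops: int) -> bool:
        if ops > max_ops:
            return False
        key = (used, bits)
        if key in best and best[key] <= ops:
            return False
        best[key] = ops
        return True

    for v in range(n):
        offer(1 << v, var_bits[v], 0)
        offer(1 << v, var_bits[v] ^ full, 1)

    # thresholded SUM over literal sets (children are single variables,
    # possibly negated)
    for k in range(3, n + 1):
        for combo in itertools.combinations(range(n), k):
            for signs in itertools.product((0, 1), repeat=k):
                used = 0
                lits = []
                for v, s in zip(combo, signs):
                    used |= 1 << v
                    lits.append(var_bits[v] ^ (full if s else 0))
                for t in range(2, k):
                    bits = 0
                    for r in range(n_rows):
                        count = sum((lb >> r) & 1 for lb in lits)
                        if count >= t:
                            bits |= 1 << r
                    offer(used, bits, 1 + sum(signs))

    changed = True
    while changed:
        changed = False
        states = list(best.items())
        for (u1, b1), o1 in states:
            if offer(u1, b1 ^ full, o1 + 1):  # NOT
                changed = True
        states = list(best.items())
        for i, ((u1, b1), o1) in enumerate(states):
            for (u2, b2), o2 in states:
                if u1 & u2:
                    continue
                if offer(u1 | u2, b1 & b2, o1 + o2 + 1):  # binary AND
                    changed = True
                if offer(u1 | u2, b1 | b2, o1 + o2 + 1):  # binary OR
                    changed = True

    all_vars = (1 << n) - 1
    out: dict[int, int] = {}
    for (used, bits), ops in best.items():
        if used != all_vars:
            continue
        if _is_proper(bits, n):
            out[bits] = min(ops, out.get(bits, max_ops + 1))
    return out


def _is_proper(bits: int, n: int) -> bool:
    for i in range(n):
        if all(
            ((bits >> r) & 1) == ((bits >> (r ^ (1 << i))) & 1)
            for r in range(1 << n)
        ):
            return False
    return True


def oracle_f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return float(2 * tp) / float(denom) if denom else 0.0


def oracle_top_m(
    X: np.ndarray,
    y: np.ndarray,
    sources,
    n_values,
    m: int,
    renderer,
    max_ops: int = 4,
) -> list[tuple]:
    """Naive all-pairs top-M search over Boolean atoms without missing values.

    ``renderer(n, table_bits, subset)`` must supply the display string used
    only for deterministic tie-breaking.  Returns the ordered list of
    ``(score, n_vars, ops, subset, table_bits, rendering)``.
    """
    X = np.asarray(X, dtype=bool)
    y = np.asarray(y, dtype=bool)
    n_atoms = X.shape[1]
    candidates = []
    for n in sorted(set(n_values)):
        tabs = oracle_tables(n, max_ops=max_ops)
        for subset in itertools.combinations(range(n_atoms), n):
            if len({sources[j] for j in subset}) < n:
                continue
            r = np.zeros(X.shape[0], dtype=np.int64)
            for i, j in enumerate(subset):
                r |= X[:, j].astype(np.int64) << i
            for bits in sorted(tabs):
                preds = ((bits >> r) & 1).astype(bool)
                tp = int(np.sum(preds & y))
                fp = int(np.sum(preds & ~y))
                fn = int(np.sum(~preds & y))
                s = oracle_f1(tp, fp, fn)
                candidates.append(
                    (s, n, tabs[bits], subset, bits, renderer(n, bits, subset))
                )
    # higher score, fewer variables, fewer operators, (coverage all 1.0),
    # lexicographically smaller rendering
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[5]))
    return candidates[:m]


def game_tree_nim_win(piles: tuple[int, ...], memo=None) -> bool:
    """Exhaustive minimax over Nim positions: mover wins iff some move
    leaves the opponent in a losing position."""
    if memo is None:
        memo = {}
    key = tuple(sorted(piles))
    if key in memo:
        return memo[key]
    result = False
    for i, p in enumerate(piles):
        for take in range(1, p + 1):
            child = piles[:i] + (p - take,) + piles[i + 1 :]
            if not game_tree_nim_win(child, memo):
                result = True
                break
        if result:
            break
    memo[key] = result
    return result
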