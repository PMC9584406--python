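"""Exhaustive search over (formula, variable-subset) pairs.

For each subset of ``n`` atoms (never two atoms of the same source
column), every admissible Boolean function of those atoms is evaluated by
table lookup and scored against the target; a stack of the M best pairs
is maintained throughout.  Because both the subset loop and the formula
catalog are enumerated in a fixed order, and ties are broken by a total
deterministic order, training is deterministic: the same data and
configuration always yield the same model list.

Per subset the work is one pass over the covered rows to build a
2**n-cell contingency table, after which every candidate formula costs
O(2**n) — the observation count enters once, not per formula.  Missing
values are never imputed: rows with a masked cell among the subset's
atoms are dropped, and the retained fraction (coverage) is part of the
model record.  Subsets whose coverage falls below the configured minimum
are skipped entirely.

Scoring covers both target polarities automatically because the formula
catalog is closed under output negation (wherever the negated form is
itself admissible).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from heapq import heappush, heapreplace
from typing import Callable, Iterable, Sequence

import numpy as np

from .binarizer import Atom, BinarizedDataset
from .errors import DegenerateDataError, InputError
from .formula_core import (
    Formula,
    HKMConstraints,
    Not,
    Var,
    evaluate,
    operator_count,
    parse,
    render,
    variable_count,
)
from .simplifier import build_catalog

__all__ = [
    "METRICS",
    "SearchConfig",
    "ScoredModel",
    "score",
    "fit",
    "predict",
    "score_on",
    "merge_model_lists",
]

METRICS = ("f1", "precision", "recall", "accuracy")


def _scores_from_counts(tp, fp, fn, tn, metric: str):
    """Vectorised confusion-matrix metric; zero denominators score 0."""
    tp = np.asarray(tp, dtype=np.float64)
    fp = np.asarray(fp, dtype=np.float64)
    fn = np.asarray(fn, dtype=np.float64)
    tn = np.asarray(tn, dtype=np.float64)
    if metric == "f1":
        denom = 2 * tp + fp + fn
        num = 2 * tp
    elif metric == "precision":
        denom = tp + fp
        num = tp
    elif metric == "recall":
        denom = tp + fn
        num = tp
    elif metric == "accuracy":
        denom = tp + fp + fn + tn
        num = tp + tn
    else:
        raise InputError(f"unknown metric {metric!r}; choose from {METRICS}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def score(predictions, target, metric: str = "f1") -> float:
    """Confusion-matrix score of Boolean predictions against a Boolean target."""
    p = np.asarray(predictions, dtype=bool)
    t = np.asarray(target, dtype=bool)
    if p.shape != t.shape:
        raise InputError(f"length mismatch: {p.shape} predictions vs {t.shape} target")
    if p.size == 0:
        raise InputError("cannot score empty vectors")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return float(_scores_from_counts(tp, fp, fn, tn, metric))


@dataclass(frozen=True)
class SearchConfig:
    """Settings for one exhaustive training run.

    ``m`` follows the practice of keeping several near-optimal models
    (10-50) for the user to choose among; F1 is the default quality
    metric.  ``subsample`` caps the number of rows actually scanned (a
    seeded draw, recorded for reproducibility) and is off by default.
    """

    n_values: tuple[int, ...] = (1, 2, 3, 4)
    m: int = 25
    metric: str = "f1"
    min_coverage: float = 0.8
    subsample: int | None = None
    seed: int | None = None
    constraints: HKMConstraints = field(default_factory=HKMConstraints)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_values", tuple(sorted(set(self.n_values))))
        if self.m < 1:
            raise InputError("m must be >= 1")
        if self.metric not in METRICS:
            raise InputError(f"metric must be one of {METRICS}")
        if not self.n_values or any(
            n < 1 or n > self.constraints.max_vars for n in self.n_values
        ):
            raise InputError(
                f"n_values must lie in 1..{self.constraints.max_vars}, got {self.n_values}"
            )
        if not (0.0 <= self.min_coverage <= 1.0):
            raise InputError("min_coverage must be in [0, 1]")


@dataclass(frozen=True)
class ScoredModel:
    """One trained rule: formula, atoms, and its quality bookkeeping.

    ``formula`` is expressed over local variables ``x0..x{n-1}`` which map
    positionally to ``atom_names``; ``rendering`` substitutes the real
    atom text (free negations folded into flipped threshold directions).
    """

    formula: Formula
    atom_names: tuple[str, ...]
    atom_indices: tuple[int, ...]
    score: float
    metric: str
    coverage: float
    n_vars: int
    n_ops: int
    rendering: str

    def to_dict(self) -> dict:
        return {
            "model": self.rendering,
            "formula": render(self.formula),
            "atoms": list(self.atom_names),
            "metric": self.metric,
            "score": self.score,
            "coverage": self.coverage,
            "n_vars": self.n_vars,
            "n_ops": self.n_ops,
        }

    @classmethod
    def from_dict(cls, d: dict, atom_indices: tuple[int, ...] = ()) -> "ScoredModel":
        formula = parse(d["formula"])
        return cls(
            formula=formula,
            atom_names=tuple(d["atoms"]),
            atom_indices=tuple(atom_indices),
            score=float(d["score"]),
            metric=d["metric"],
            coverage=float(d["coverage"]),
            n_vars=int(d["n_vars"]),
            n_ops=int(d["n_ops"]),
            rendering=d["model"],
        )


def render_with_atoms(formula: Formula, atoms: Sequence[Atom]) -> str:
    """Render a formula substituting atom text; threshold NOTs flip direction."""

    def rec(node: Formula, parent: str) -> str:
        from .formula_core import And, Or, SumGe  # local alias for readability

        if isinstance(node, Var):
            return atoms[node.index].name
        if isinstance(node, Not):
            if isinstance(node.child, Var):
                return atoms[node.child.index].negated_name()
            return f"NOT ({rec(node.child, 'Not')})"
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


class _RevStr(str):
    """String with inverted ordering (smaller text = better tie-break)."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def _goodness_key(model: ScoredModel) -> tuple:
    """Total order: higher score, fewer variables, fewer operators, higher
    coverage, lexicographically smaller rendering."""
    return (
        model.score,
        -model.n_vars,
        -model.n_ops,
        model.coverage,
        _RevStr(model.rendering),
    )


class _Item:
    __slots__ = ("key", "model")

    def __init__(self, model: ScoredModel):
        self.key = _goodness_key(model)
        self.model = model

    def __lt__(self, other: "_Item") -> bool:
        return self.key < other.key

    def __eq__(self, other) -> bool:
        return self.key == other.key


class _TopM:
    """Bounded best-M stack with a deterministic total order."""

    def __init__(self, m: int):
        self.m = m
        self.heap: list[_Item] = []

    @property
    def cutoff(self) -> float:
        """Scores strictly below this cannot enter the stack."""
        if len(self.heap) < self.m:
            return -np.inf
        return self.heap[0].key[0]

    def push(self, model: ScoredModel) -> None:
        item = _Item(model)
        if len(self.heap) < self.m:
            heappush(self.heap, item)
        elif self.heap[0] < item:
            heapreplace(self.heap, item)

    def result(self) -> list[ScoredModel]:
        return [it.model for it in sorted(self.heap, key=lambda i: i.key, reverse=True)]


def _candidate_subsets(source_ids: np.ndarray, n: int) -> Iterable[tuple[int, ...]]:
    """Size-n atom subsets with pairwise distinct source columns, sorted order."""
    n_atoms = source_ids.size
    for subset in itertools.combinations(range(n_atoms), n):
        if len({int(source_ids[j]) for j in subset}) == n:
            yield subset


def fit(
    dataset: BinarizedDataset,
    config: SearchConfig | None = None,
    progress: Callable[[int, float], None] | None = None,
) -> list[ScoredModel]:
    """Exhaustively train the M best human-computable rules.

    Iterates every candidate atom subset of each size in
    ``config.n_values``, every admissible Boolean function of that size
    (from the simplification catalog, with threshold-direction negations
    costed as free), and keeps the M best scoring (formula, subset)
    pairs.  Deterministic for fixed input and configuration.

    ``progress``, if given, is called periodically with
    ``(subsets_scanned, best_score_so_far)``.
    """
    config = config or SearchConfig()
    if dataset.n_atoms == 0:
        raise DegenerateDataError("dataset has no atoms to search over")
    X, mask, y = dataset.X, dataset.mask, dataset.target
    if y.all() or not y.any():
        raise DegenerateDataError("target has a single class; nothing to learn")

    if config.subsample is not None and config.subsample < dataset.n_rows:
        rng = np.random.default_rng(config.seed)
        rows = np.sort(rng.choice(dataset.n_rows, size=config.subsample, replace=False))
        X, mask, y = X[rows], mask[rows], y[rows]

    catalog = build_catalog(config.constraints)
    free_atoms = np.array([a.negation_free for a in dataset.atoms], dtype=bool)
    n_rows = X.shape[0]
    min_cov = config.min_coverage - 1e-12
    stack = _TopM(config.m)
    weights = (1 << np.arange(max(config.n_values))).astype(np.int64)

    scanned = 0
    any_covered = False
    for n in config.n_values:
        for subset in _candidate_subsets(dataset.source_ids, n):
            scanned += 1
            if progress is not None and scanned % 50000 == 0:
                progress(scanned, stack.cutoff)
            sub = list(subset)
            ok = ~mask[:, sub].any(axis=1)
            coverage = float(ok.sum() / n_rows)
            if coverage < min_cov:
                continue
            any_covered = True
            ys = y[ok]
            pos_total = int(ys.sum())
            neg_total = int(ys.size - pos_total)
            r = X[ok][:, sub].astype(np.int64) @ weights[:n]
            pos = np.bincount(r[ys], minlength=1 << n)
            neg = np.bincount(r[~ys], minlength=1 << n)

            free_mask = 0
            for local_i, j in enumerate(sub):
                if free_atoms[j]:
                    free_mask |= 1 << local_i
            bits_mat, ops_arr, formulas = catalog.admissible_for(n, free_mask)

            tp = bits_mat @ pos
            fp = bits_mat @ neg
            fn = pos_total - tp
            tn = neg_total - fp
            scores = _scores_from_counts(tp, fp, fn, tn, config.metric)

            cutoff = stack.cutoff
            for t_idx in np.flatnonzero(scores >= cutoff):
                formula = formulas[t_idx]
                atoms = [dataset.atoms[j] for j in sub]
                model = ScoredModel(
                    formula=formula,
                    atom_names=tuple(a.name for a in atoms),
                    atom_indices=tuple(int(j) for j in sub),
                    score=float(scores[t_idx]),
                    metric=config.metric,
                    coverage=coverage,
                    n_vars=n,
                    n_ops=int(ops_arr[t_idx]),
                    rendering=render_with_atoms(formula, atoms),
                )
                stack.push(model)

    if not any_covered:
        warnings.warn(
            "no candidate atom subset was scorable (sibling exclusion or "
            "minimum coverage); returning no models",
            stacklevel=2,
        )
        return []
    return stack.result()


def merge_model_lists(lists: Sequence[Sequence[ScoredModel]], m: int) -> list[ScoredModel]:
    """Merge partial top-M lists (e.g. from a partitioned subset loop).

    The result is independent of partitioning and merge order because the
    ordering key is total.
    """
    stack = _TopM(m)
    for lst in lists:
        for model in lst:
            stack.push(model)
    return stack.result()


def _resolve(model: ScoredModel, dataset: BinarizedDataset) -> list[int]:
    index = dataset.atom_index()
    missing = [name for name in model.atom_names if name not in index]
    if missing:
        raise InputError(f"model atoms not present in dataset: {missing}")
    return [index[name] for name in model.atom_names]


def predict(
    model: ScoredModel, dataset: BinarizedDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a trained rule; abstain on rows with missing model inputs.

    Returns ``(predictions, abstain)``.  Rows where any of the model's
    atoms is masked are flagged in ``abstain`` (their prediction slot is
    False and carries no meaning) — missing values are never imputed.
    """
    idx = _resolve(model, dataset)
    cols = dataset.X[:, idx]
    abstain = dataset.mask[:, idx].any(axis=1)
    preds = evaluate(model.formula, cols)
    preds = preds.copy()
    preds[abstain] = False
    return preds, abstain


def score_on(
    model: ScoredModel, dataset: BinarizedDataset, metric: str | None = None
) -> float:
    """Score a model on the rows of ``dataset`` it can evaluate."""
    preds, abstain = predict(model, dataset)
    usable = ~abstain
    if not usable.any():
        raise DegenerateDataError("model abstains on every row of the dataset")
    return score(preds[usable], dataset.target[usable], metric or model.metric)
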