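"""Conversion of raw tabular features into Boolean atoms.

Human-computable rules operate on Boolean conditions, so every raw column
is turned into one or more *atoms*:

* numeric columns -> up to K threshold comparisons (``age > 60``) placed
  at evenly spaced quantiles and rounded to two significant digits, so
  the cut-points stay humanly memorable;
* native Boolean columns pass through unchanged;
* categorical columns -> one indicator per level (``color = A``);
* any column with missing cells additionally yields an is-missing
  indicator (``age is missing``) — missingness can itself be informative.

Missing cells are **never imputed**.  Each atom carries a missingness
mask mirroring its source column; the search later drops the rows where
any atom of a candidate subset is masked, and tracks the retained
fraction as the subset's *coverage*.  Atoms derived from the same source
column are *siblings* and never enter one formula together.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputError

__all__ = [
    "ThresholdRule",
    "Atom",
    "BinarizedDataset",
    "propose_thresholds",
    "binarize",
    "subset_coverage",
    "read_table",
]

#: Values treated as missing when reading CSV/TSV files.
DEFAULT_NA_VALUES = ("", "NA", "N/A", "NaN", "nan", "null", "NULL", "?")


def _round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant digits (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return float(x)
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


@dataclass(frozen=True)
class ThresholdRule:
    """A one-sided numeric comparison, e.g. ``age > 60``."""

    feature: str
    direction: str  # ">" or "<="
    value: float

    def __post_init__(self) -> None:
        if self.direction not in (">", "<="):
            raise InputError(f"direction must be '>' or '<=', got {self.direction!r}")

    def apply(self, values) -> np.ndarray:
        """Boolean outcome per value; NaN cells yield False (masked upstream)."""
        arr = np.asarray(values, dtype=float)
        with np.errstate(invalid="ignore"):
            out = arr > self.value if self.direction == ">" else arr <= self.value
        out[np.isnan(arr)] = False
        return out

    def complement(self) -> "ThresholdRule":
        """The opposite direction at the same cut; XORs to true with self."""
        return ThresholdRule(
            self.feature, "<=" if self.direction == ">" else ">", self.value
        )

    def __str__(self) -> str:
        return f"{self.feature} {self.direction} {self.value:g}"


@dataclass(frozen=True)
class Atom:
    """One Boolean feature with provenance back to its raw column."""

    name: str
    source: str
    kind: str  # "threshold" | "boolean" | "indicator" | "missing"
    rule: ThresholdRule | None = None
    level: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("threshold", "boolean", "indicator", "missing"):
            raise InputError(f"unknown atom kind {self.kind!r}")

    @property
    def negation_free(self) -> bool:
        """True when negating the atom is a free direction flip."""
        return self.kind == "threshold"

    def negated_name(self) -> str:
        if self.rule is not None:
            return str(self.rule.complement())
        if " " in self.name:
            return f"NOT ({self.name})"
        return f"NOT {self.name}"


@dataclass
class BinarizedDataset:
    """Boolean atom matrix with missingness mask and provenance.

    ``X[i, j]`` is atom j's value on row i; ``mask[i, j]`` is True exactly
    where the source cell was missing (the stored value there is False and
    must never be used — coverage filtering guarantees it is not).
    """

    X: np.ndarray
    mask: np.ndarray
    atoms: list[Atom]
    target: np.ndarray
    target_name: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.target = np.asarray(self.target, dtype=bool)
        if self.X.shape != self.mask.shape:
            raise InputError("atom matrix and mask shapes differ")
        if self.X.shape[0] != self.target.size:
            raise InputError("target length does not match atom matrix")
        if self.X.shape[1] != len(self.atoms):
            raise InputError("atom metadata does not match matrix width")
        sources = sorted({a.source for a in self.atoms})
        src_id = {s: i for i, s in enumerate(sources)}
        self.source_ids = np.array([src_id[a.source] for a in self.atoms], dtype=int)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.X.shape[1]

    def atom_index(self) -> dict[str, int]:
        return {a.name: j for j, a in enumerate(self.atoms)}

    def take(self, rows) -> "BinarizedDataset":
        """Row subset (e.g. a train/test split) sharing atom provenance."""
        rows = np.asarray(rows)
        return BinarizedDataset(
            X=self.X[rows],
            mask=self.mask[rows],
            atoms=list(self.atoms),
            target=self.target[rows],
            target_name=self.target_name,
        )

    def subset_coverage(self, atom_indices) -> tuple[np.ndarray, float]:
        """Rows usable for a candidate atom subset, and the retained fraction.

        A row is excluded as soon as any chosen atom is masked there; no
        value is ever imputed.
        """
        idx = np.asarray(list(atom_indices), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
            raise InputError("atom index out of range")
        keep = ~self.mask[:, idx].any(axis=1)
        coverage = float(keep.mean()) if self.n_rows else 0.0
        return keep, coverage

    def report(self) -> dict:
        """JSON-ready summary of atoms, thresholds and missingness."""
        return {
            "n_rows": int(self.n_rows),
            "n_atoms": int(self.n_atoms),
            "target": self.target_name,
            "positive_rate": float(self.target.mean()) if self.n_rows else 0.0,
            "atoms": [
                {
                    "name": a.name,
                    "source": a.source,
                    "kind": a.kind,
                    "threshold": None if a.rule is None else a.rule.value,
                    "direction": None if a.rule is None else a.rule.direction,
                    "missing_fraction": float(self.mask[:, j].mean()),
                }
                for j, a in enumerate(self.atoms)
            ],
        }


def subset_coverage(dataset: BinarizedDataset, atom_indices) -> tuple[np.ndarray, float]:
    """Module-level convenience mirroring :meth:`BinarizedDataset.subset_coverage`."""
    return dataset.subset_coverage(atom_indices)


def propose_thresholds(column, k: int, feature: str = "") -> list[ThresholdRule]:
    """Candidate cut-points for a numeric column.

    Up to ``k`` thresholds at evenly spaced quantiles of the non-missing
    values, each rounded to two significant digits and deduplicated;
    cuts that would produce a constant atom are dropped.  Both comparison
    directions are equally available (the complement of each returned
    rule is a free flip); the returned rules use ``>``.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    vals = np.asarray(pd.to_numeric(pd.Series(column), errors="raise"), dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0 or np.unique(vals).size < 2:
        return []
    qs = np.quantile(vals, [(i + 1) / (k + 1) for i in range(k)])
    lo, hi = float(vals.min()), float(vals.max())
    out: list[ThresholdRule] = []
    seen: set[float] = set()
    for q in qs:
        t = _round_sig(float(q))
        # "value > t" must be non-constant on the observed data
        if t in seen or not (lo <= t < hi):
            continue
        seen.add(t)
        out.append(ThresholdRule(feature, ">", t))
    return out


def _infer_kind(series: pd.Series) -> str:
    if pd.api.types.is_bool_dtype(series):
        return "boolean"
    if pd.api.types.is_numeric_dtype(series):
        uniq = set(pd.unique(series.dropna()))
        if uniq <= {0, 1, 0.0, 1.0, True, False}:
            return "boolean"
        return "numeric"
    return "categorical"


def _target_vector(series: pd.Series, name: str) -> np.ndarray:
    if series.isna().any():
        raise InputError(f"target column {name!r} contains missing values")
    uniq = set(pd.unique(series))
    if not uniq <= {0, 1, 0.0, 1.0, True, False}:
        raise InputError(
            f"target column {name!r} must be Boolean (0/1), found values {sorted(map(str, uniq))[:6]}"
        )
    return series.astype(bool).to_numpy()


def binarize(
    table: pd.DataFrame,
    target: str,
    k: int = 3,
    column_types: Mapping[str, str] | None = None,
) -> BinarizedDataset:
    """Turn a raw data frame into a :class:`BinarizedDataset`.

    Parameters
    ----------
    table
        Raw data with numeric, Boolean and categorical columns; missing
        cells as NaN/None.
    target
        Name of the Boolean outcome column (must have no missing values).
    k
        Maximum threshold atoms per numeric column.
    column_types
        Optional overrides, mapping column name to ``"numeric"``,
        ``"boolean"`` or ``"categorical"``.
    """
    if target not in table.columns:
        raise InputError(f"target column {target!r} not found in data")
    y = _target_vector(table[target], target)
    overrides = dict(column_types or {})

    columns: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    atoms: list[Atom] = []

    for col in table.columns:
        if col == target:
            continue
        s = table[col]
        kind = overrides.get(col, _infer_kind(s))
        miss = s.isna().to_numpy()
        if kind == "boolean":
            vals = s.fillna(False).astype(bool).to_numpy()
            columns.append(vals)
            masks.append(miss)
            atoms.append(Atom(name=str(col), source=str(col), kind="boolean"))
        elif kind == "numeric":
            for rule in propose_thresholds(s, k, feature=str(col)):
                columns.append(rule.apply(s.to_numpy(dtype=float)))
                masks.append(miss)
                atoms.append(
                    Atom(name=str(rule), source=str(col), kind="threshold", rule=rule)
                )
        elif kind == "categorical":
            levels = sorted(map(str, pd.unique(s.dropna().astype(str))))
            for level in levels:
                vals = (s.astype(str) == level).to_numpy() & ~miss
                columns.append(vals)
                masks.append(miss)
                atoms.append(
                    Atom(
                        name=f"{col} = {level}",
                        source=str(col),
                        kind="indicator",
                        level=level,
                    )
                )
        else:
            raise InputError(f"unknown column type override {kind!r} for column {col!r}")
        # informative missingness indicator (itself never missing)
        if miss.any() and not miss.all():
            columns.append(miss.copy())
            masks.append(np.zeros_like(miss))
            atoms.append(Atom(name=f"{col} is missing", source=str(col), kind="missing"))

    if not atoms:
        warnings.warn("binarization produced no atoms (all columns constant or empty)")
        X = np.zeros((len(table), 0), dtype=bool)
        mask = np.zeros((len(table), 0), dtype=bool)
    else:
        X = np.column_stack(columns)
        mask = np.column_stack(masks)
    return BinarizedDataset(X=X, mask=mask, atoms=atoms, target=y, target_name=target)


def read_table(
    path,
    na_values: Sequence[str] = DEFAULT_NA_VALUES,
) -> pd.DataFrame:
    """Read a CSV or TSV file, treating the given sentinels as missing."""
    return pd.read_csv(
        path, sep=None, engine="python", na_values=list(na_values), keep_default_na=True
    )
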