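"""Seeded generators for datasets with planted human-computable structure.

Two families:

* **Planted-rule tables** — independent feature columns (Bernoulli or
  Gaussian-with-threshold marginals), a Boolean label generated by an
  admissible formula over a few of them, optional label-flip noise,
  optional missing cells, and distractor features.  These emulate the
  shape of real screening datasets: an unbalanced Boolean outcome
  (typically 7-40% positive), a handful of informative variables buried
  among irrelevant ones, and informative missingness.  They make every
  stage of the learner testable without external downloads.

* **Nim games** — uniformly drawn pile configurations labelled with the
  first player's fate under optimal play.  The mover wins iff the bitwise
  XOR of the pile sizes (the nim-sum) is nonzero; this game-theoretic
  fact serves as an exact oracle.  The default layout is 2000 games with
  pile sizes padded by empty piles to 10 feature columns; whether the
  winner is expressible as a small Boolean rule over raw pile sizes is
  an open property of the layout, so an alternative per-bit layout is
  available as a config option, not a default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import reduce
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .formula_core import (
    And,
    Formula,
    HKMConstraints,
    Or,
    Var,
    evaluate,
    is_admissible,
    render,
    truth_table,
    variable_count,
)

__all__ = [
    "FeatureSpec",
    "PlantedRuleSpec",
    "NimSpec",
    "generate_planted",
    "generate_nim",
    "analytic_prevalence",
    "nim_winner",
    "default_planted_spec",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Marginal distribution of one feature column.

    ``bernoulli`` features are emitted as 0/1 columns with success
    probability ``p``.  ``numeric`` features are Gaussian with the given
    ``mean``/``sd``; when used inside the generating rule their Boolean
    reading is ``value > threshold``.
    """

    name: str
    kind: str = "bernoulli"  # "bernoulli" | "numeric"
    p: float = 0.5
    mean: float = 0.0
    sd: float = 1.0
    threshold: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("bernoulli", "numeric"):
            raise InputError(f"unknown feature kind {self.kind!r}")
        if self.kind == "bernoulli" and not (0.0 < self.p < 1.0):
            raise InputError(f"bernoulli p must be in (0,1), got {self.p}")
        if self.sd <= 0:
            raise InputError("numeric sd must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InputError("missing_rate must be in [0, 1)")

    @property
    def bool_probability(self) -> float:
        """P(Boolean reading is true) under the marginal."""
        if self.kind == "bernoulli":
            return self.p
        z = (self.threshold - self.mean) / self.sd
        return 0.5 * math.erfc(z / math.sqrt(2.0))


@dataclass(frozen=True)
class PlantedRuleSpec:
    """A dataset recipe with a known generating rule.

    ``formula`` is an admissible expression over local variables that map
    positionally onto ``rule_features`` (names drawn from ``features``).
    The label is the formula's output with each row's label independently
    flipped with probability ``noise``.  Missing cells are inserted per
    feature after labelling and never touch the target.
    """

    formula: Formula
    rule_features: tuple[str, ...]
    features: tuple[FeatureSpec, ...]
    n_obs: int = 2000
    noise: float = 0.0
    prevalence: float | None = None
    target_name: str = "y"
    seed: int = 0

    def __post_init__(self) -> None:
        if not is_admissible(self.formula, HKMConstraints()):
            raise InputError("generating formula must be HKM-admissible")
        if variable_count(self.formula) != len(self.rule_features):
            raise InputError("rule_features must match the formula's variable count")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise InputError("duplicate feature names")
        unknown = set(self.rule_features) - set(names)
        if unknown:
            raise InputError(f"rule features not defined: {sorted(unknown)}")
        if not (0.0 <= self.noise < 0.5):
            raise InputError("label noise must be in [0, 0.5)")
        if self.prevalence is not None and not (0.0 < self.prevalence < 1.0):
            raise InputError("prevalence target must be in (0, 1)")
        if self.n_obs < 1:
            raise InputError("n_obs must be >= 1")

    def feature(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise InputError(f"no feature named {name!r}")


def analytic_prevalence(spec: PlantedRuleSpec) -> float:
    """Exact positive-class probability implied by the recipe.

    Expectation of the generating formula over the independent feature
    marginals, mixed with the label-flip noise:
    ``p = p_rule * (1 - eps) + (1 - p_rule) * eps``.
    """
    table = truth_table(spec.formula)
    probs = [spec.feature(name).bool_probability for name in spec.rule_features]
    p_rule = 0.0
    for r in range(table.n_rows):
        if not table.value(r):
            continue
        w = 1.0
        for i, q in enumerate(probs):
            w *= q if (r >> i) & 1 else 1.0 - q
        p_rule += w
    return p_rule * (1.0 - spec.noise) + (1.0 - p_rule) * spec.noise


def generate_planted(spec: PlantedRuleSpec) -> pd.DataFrame:
    """Draw a dataset from a planted-rule recipe (seeded, reproducible)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_obs
    columns: dict[str, np.ndarray] = {}
    bools: dict[str, np.ndarray] = {}
    for f in spec.features:
        if f.kind == "bernoulli":
            b = rng.random(n) < f.p
            columns[f.name] = b.astype(float)
            bools[f.name] = b
        else:
            x = rng.normal(f.mean, f.sd, n)
            columns[f.name] = x
            bools[f.name] = x > f.threshold
    rule_matrix = np.column_stack([bools[name] for name in spec.rule_features])
    labels = evaluate(spec.formula, rule_matrix)
    if spec.noise > 0:
        labels = labels ^ (rng.random(n) < spec.noise)
    for f in spec.features:
        if f.missing_rate > 0:
            miss = rng.random(n) < f.missing_rate
            col = columns[f.name].copy()
            col[miss] = np.nan
            columns[f.name] = col
    df = pd.DataFrame(columns)
    df[spec.target_name] = labels.astype(int)
    if spec.prevalence is not None:
        achieved = analytic_prevalence(spec)
        if abs(achieved - spec.prevalence) > 0.02:
            warnings.warn(
                f"requested prevalence {spec.prevalence:.3f} is not attainable with "
                f"this rule and marginals; analytic prevalence is {achieved:.3f}",
                stacklevel=2,
            )
    return df


def default_planted_spec(
    seed: int = 0,
    n_obs: int = 2000,
    noise: float = 0.05,
    missing_rate: float = 0.05,
) -> PlantedRuleSpec:
    """A screening-style recipe: ``(a AND b) OR c`` among distractors.

    Three informative Bernoulli markers generate the outcome at ~27%
    noise-free prevalence (label noise nudges it toward 0.5); five
    distractor columns (three Bernoulli, two Gaussian) and light
    missingness on two features reproduce the texture of real tabular
    screening data.
    """
    formula = Or((And((Var(0), Var(1))), Var(2)))
    features = (
        FeatureSpec("marker_a", "bernoulli", p=0.5),
        FeatureSpec("marker_b", "bernoulli", p=0.4),
        FeatureSpec("marker_c", "bernoulli", p=0.09),
        FeatureSpec("noise_a", "bernoulli", p=0.3, missing_rate=missing_rate),
        FeatureSpec("noise_b", "bernoulli", p=0.5),
        FeatureSpec("noise_c", "bernoulli", p=0.15),
        FeatureSpec("lab_1", "numeric", mean=50.0, sd=10.0, threshold=55.0,
                    missing_rate=missing_rate),
        FeatureSpec("lab_2", "numeric", mean=1.0, sd=0.5, threshold=1.5),
    )
    return PlantedRuleSpec(
        formula=formula,
        rule_features=("marker_a", "marker_b", "marker_c"),
        features=features,
        n_obs=n_obs,
        noise=noise,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Nim
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NimSpec:
    """Recipe for a Nim game-winner dataset.

    ``width`` pads the pile-size columns with always-empty piles (an empty
    pile changes nothing about the game) so the default yields 2000 rows
    by 10 feature columns.  ``layout="bits"`` instead emits the binary
    digits of every pile as Boolean columns.
    """

    games: int = 2000
    piles: int = 3
    max_pile: int = 7
    width: int = 10
    layout: str = "piles"  # "piles" | "bits"
    target_name: str = "first_player_wins"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.games < 1 or self.piles < 1 or self.max_pile < 1:
            raise InputError("games, piles and max_pile must be >= 1")
        if self.width < self.piles:
            raise InputError("width must be >= the number of piles")
        if self.layout not in ("piles", "bits"):
            raise InputError("layout must be 'piles' or 'bits'")


def nim_winner(piles: Sequence[int]) -> bool:
    """True iff the player to move wins under optimal play.

    Classic result: the mover wins exactly when the nim-sum (bitwise XOR)
    of the pile sizes is nonzero.
    """
    sizes = [int(p) for p in piles]
    if any(p < 0 for p in sizes):
        raise InputError("pile sizes must be non-negative")
    return reduce(lambda a, b: a ^ b, sizes, 0) != 0


def generate_nim(spec: NimSpec) -> pd.DataFrame:
    """Draw uniform pile configurations labelled by the game-theoretic oracle."""
    rng = np.random.default_rng(spec.seed)
    piles = rng.integers(0, spec.max_pile + 1, size=(spec.games, spec.piles))
    nim_sum = np.bitwise_xor.reduce(piles, axis=1)
    wins = nim_sum != 0
    data: dict[str, np.ndarray] = {}
    if spec.layout == "piles":
        for j in range(spec.width):
            if j < spec.piles:
                data[f"pile_{j + 1}"] = piles[:, j]
            else:
                data[f"pile_{j + 1}"] = np.zeros(spec.games, dtype=piles.dtype)
    else:
        n_bits = max(1, spec.max_pile.bit_length())
        for j in range(spec.piles):
            for b in range(n_bits):
                data[f"pile_{j + 1}_bit_{b}"] = (piles[:, j] >> b) & 1
    df = pd.DataFrame(data)
    df[spec.target_name] = wins.astype(int)
    return df
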