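"""Multi-instance experiments: splits, stability, precision-recall summaries.

A model's practical value depends not just on its average quality but on
how consistently it transfers from training to unseen data.  The
*stability factor* of one trained instance is the absolute relative
change in quality between train and test:

    S = |Q_train - Q_test| / Q_train        (Q = F1 by default)

and the *stability curve* P(s) is the empirical probability, over many
independently seeded 80/20 splits, that S stays below a threshold s.
P is an empirical CDF: monotone non-decreasing from 0 to 1.

The harness deliberately contains no black-box baselines; any external
model can be slotted into the same split protocol through the
``model_hook`` argument of :func:`run_experiments`, which receives the
train/test row indices of every instance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .binarizer import BinarizedDataset
from .errors import DegenerateDataError, InputError
from .searcher import ScoredModel, SearchConfig, fit, predict, score, score_on

__all__ = [
    "stability",
    "stability_curve",
    "ExperimentRecord",
    "StabilityReport",
    "run_experiments",
    "pr_summary",
]

logger = logging.getLogger(__name__)

#: Fixed grid (and histogram bin edges) on [0, 1] in steps of 0.01.
DEFAULT_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


def stability(train_score: float, test_score: float) -> float:
    """Absolute relative train-to-test change, ``|train - test| / train``."""
    if train_score <= 0:
        raise InputError("stability is undefined for a non-positive train score")
    return abs(train_score - test_score) / train_score


def stability_curve(s_values, thresholds=None) -> np.ndarray:
    """Empirical P(s) = fraction of instances with stability factor S < s."""
    s = np.asarray(s_values, dtype=float)
    if s.size == 0:
        raise InputError("need at least one stability record")
    thr = DEFAULT_GRID if thresholds is None else np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thr) < 0):
        raise InputError("thresholds must be sorted ascending")
    return (s[:, None] < thr[None, :]).mean(axis=0)


@dataclass(frozen=True)
class ExperimentRecord:
    """Outcome of one seeded train/test instance."""

    index: int
    seed: int
    train_score: float
    test_score: float
    stability: float
    cv_scores: tuple[float, ...] | None = None

    def to_dict(self) -> dict:
        d = {
            "index": self.index,
            "seed": self.seed,
            "train_score": self.train_score,
            "test_score": self.test_score,
            "stability": self.stability,
        }
        if self.cv_scores is not None:
            d["cv_scores"] = list(self.cv_scores)
        return d


@dataclass
class StabilityReport:
    """Stability records, the empirical P(S) curve, and test-score histogram."""

    records: list[ExperimentRecord]
    thresholds: np.ndarray
    p_values: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    n_requested: int
    n_skipped: int
    master_seed: int
    config: SearchConfig

    @property
    def n_completed(self) -> int:
        return len(self.records)

    def stabilities(self) -> np.ndarray:
        return np.array([r.stability for r in self.records])

    def to_dict(self) -> dict:
        return {
            "n_requested": self.n_requested,
            "n_completed": self.n_completed,
            "n_skipped": self.n_skipped,
            "master_seed": self.master_seed,
            "config": {
                "n_values": list(self.config.n_values),
                "m": self.config.m,
                "metric": self.config.metric,
                "min_coverage": self.config.min_coverage,
                "subsample": self.config.subsample,
                "seed": self.config.seed,
            },
            "records": [r.to_dict() for r in self.records],
            "thresholds": self.thresholds.tolist(),
            "p_values": self.p_values.tolist(),
            "hist_counts": self.hist_counts.tolist(),
            "hist_edges": self.hist_edges.tolist(),
        }


def run_experiments(
    dataset: BinarizedDataset,
    config: SearchConfig | None = None,
    n_exp: int = 100,
    seed: int = 0,
    cv_folds: int = 0,
    test_fraction: float = 0.2,
    model_hook: Callable | None = None,
) -> StabilityReport:
    """Repeat seeded 80/20 train/test instances and collect stability data.

    Instance ``i`` uses seed ``seed + i`` for its split.  The best trained
    model's train score, its score on the held-out rows, and the stability
    factor S are recorded; instances with a single-class training target
    (or where no model can be scored) are skipped and logged.  With
    ``cv_folds > 0``, diagnostic k-fold cross-validation scores on the
    training portion are attached to each record; the 80/20 test score
    remains the authoritative quality number.

    ``model_hook(train_ds, test_ds, instance_seed)`` — if given — may
    return ``(train_score, test_score)`` for an external model trained
    under the identical protocol; the pair replaces the built-in search
    for that instance.
    """
    if n_exp < 1:
        raise InputError("n_exp must be >= 1")
    config = config or SearchConfig()
    L = dataset.n_rows
    n_test = max(1, int(round(L * test_fraction)))
    if n_test >= L:
        raise InputError("dataset too small for the requested test fraction")

    records: list[ExperimentRecord] = []
    skipped = 0
    for i in range(n_exp):
        inst_seed = seed + i
        rng = np.random.default_rng(inst_seed)
        perm = rng.permutation(L)
        test_rows = np.sort(perm[:n_test])
        train_rows = np.sort(perm[n_test:])
        train_ds = dataset.take(train_rows)
        test_ds = dataset.take(test_rows)
        if train_ds.target.all() or not train_ds.target.any():
            logger.info("instance %d skipped: single-class training target", i)
            skipped += 1
            continue
        try:
            if model_hook is not None:
                tr, te = model_hook(train_ds, test_ds, inst_seed)
            else:
                models = fit(train_ds, config)
                if not models:
                    raise DegenerateDataError("no model met the coverage requirement")
                best = models[0]
                tr = best.score
                te = score_on(best, test_ds)
        except DegenerateDataError as exc:
            logger.info("instance %d skipped: %s", i, exc)
            skipped += 1
            continue
        if tr <= 0:
            logger.info("instance %d skipped: zero train score", i)
            skipped += 1
            continue
        cv_scores = None
        if cv_folds > 0 and model_hook is None:
            cv_scores = _cv_scores(train_ds, config, cv_folds, inst_seed)
        records.append(
            ExperimentRecord(
                index=i,
                seed=inst_seed,
                train_score=float(tr),
                test_score=float(te),
                stability=stability(tr, te),
                cv_scores=cv_scores,
            )
        )

    if not records:
        raise DegenerateDataError("every experiment instance was skipped")
    s_vals = np.array([r.stability for r in records])
    p_vals = stability_curve(s_vals, DEFAULT_GRID)
    hist_counts, hist_edges = np.histogram(
        [r.test_score for r in records], bins=DEFAULT_GRID
    )
    return StabilityReport(
        records=records,
        thresholds=DEFAULT_GRID.copy(),
        p_values=p_vals,
        hist_counts=hist_counts,
        hist_edges=hist_edges,
        n_requested=n_exp,
        n_skipped=skipped,
        master_seed=seed,
        config=config,
    )


def _cv_scores(
    train_ds: BinarizedDataset, config: SearchConfig, folds: int, seed: int
) -> tuple[float, ...]:
    from sklearn.model_selection import KFold

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
    out = []
    for fold_train, fold_val in kf.split(np.arange(train_ds.n_rows)):
        sub = train_ds.take(fold_train)
        if sub.target.all() or not sub.target.any():
            continue
        models = fit(sub, config)
        if not models:
            continue
        try:
            out.append(score_on(models[0], train_ds.take(fold_val)))
        except DegenerateDataError:
            continue
    return tuple(out)


def pr_summary(
    models_by_size: Mapping[int, Sequence[ScoredModel]],
    dataset: BinarizedDataset,
) -> pd.DataFrame:
    """Precision-recall points for top-M model lists keyed by rule size.

    Evaluates every model on the rows of ``dataset`` it can cover and
    returns a scatter-ready table with columns ``size``, ``model``,
    ``precision``, ``recall`` — the two quality axes used to compare
    human-computable rules of growing size against richer model classes.
    """
    rows = []
    for size in sorted(models_by_size):
        for model in models_by_size[size]:
            preds, abstain = predict(model, dataset)
            usable = ~abstain
            if not usable.any():
                continue
            y = dataset.target[usable]
            p = preds[usable]
            rows.append(
                {
                    "size": size,
                    "model": model.rendering,
                    "precision": score(p, y, "precision"),
                    "recall": score(p, y, "recall"),
                }
            )
    return pd.DataFrame(rows, columns=["size", "model", "precision", "recall"])
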