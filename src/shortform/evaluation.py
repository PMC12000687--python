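"""Data partitioning, the R² metric, test-set evaluation, and the
sample-size sensitivity bootstrap.

The three-way split mirrors standard predictive-modelling practice: train
(fit the weights), validation (choose the regularization), test (report
final accuracy). Holdout sizes use a ceiling rule — validation and test get
``ceil(n · p)`` rows each and training the remainder — which reproduces the
972/325/325 partition of a 1622-participant sample at 60/20/20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reducer import ReducedModel, predict
from .targets import TargetScores

__all__ = [
    "SplitSpec",
    "SampleSizeCurve",
    "split",
    "r_squared",
    "evaluate",
    "sample_size_curve",
]


@dataclass
class SplitSpec:
    """A disjoint, exhaustive row-index partition into train/validation/test."""

    proportions: tuple[float, float, float]
    seed: int
    sizes: tuple[int, int, int]
    train_idx: np.ndarray
    validation_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class SampleSizeCurve:
    """Bootstrap summary of accuracy as a function of training sample size.

    ``table`` has one row per (sample size, retained-item count) with the
    mean and 2.5/97.5 percentile bounds of min-dimension test R² across
    subsamples.
    """

    table: pd.DataFrame
    sample_sizes: tuple[int, ...]
    n_boot: int
    seed: int


def split(n: int, proportions: tuple[float, float, float], seed: int) -> SplitSpec:
    """Seeded three-way partition of ``n`` row indices.

    Validation and test receive ``ceil(n · p)`` rows; train the remainder.
    Assignment is by a seeded permutation: the first block is train, then
    validation, then test.
    """
    if n < 3:
        raise ValueError("n must be at least 3")
    if len(proportions) != 3 or any(p < 0 for p in proportions):
        raise ValueError("proportions must be three non-negative numbers")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")

    n_val = math.ceil(n * proportions[1])
    n_test = math.ceil(n * proportions[2])
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) <= 0:
        raise ValueError(
            f"split of n={n} at {proportions} yields an empty partition "
            f"({n_train}/{n_val}/{n_test})"
        )

    perm = np.random.default_rng(seed).permutation(n)
    return SplitSpec(
        proportions=tuple(proportions),
        seed=seed,
        sizes=(n_train, n_val, n_test),
        train_idx=np.sort(perm[:n_train]),
        validation_idx=np.sort(perm[n_train : n_train + n_val]),
        test_idx=np.sort(perm[n_train + n_val :]),
    )


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, ``1 − SS_res / SS_tot``; may be negative."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-d vectors of equal length")
    if obs.size < 2:
        raise ValueError("at least 2 observations are required")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed scores have zero variance; R² is undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def evaluate(
    model: ReducedModel,
    responses: pd.DataFrame,
    targets: TargetScores,
) -> dict:
    """Per-dimension R² of a fitted model on held-out data.

    Returns ``{"r2": Series per dimension, "predictions": DataFrame}`` with
    predicted-vs-observed pairs for scatter export.
    """
    if len(responses) != len(targets.values):
        raise ValueError("responses and targets have different participant counts")
    pred = predict(model, responses)
    if pred.dimension_names != targets.dimension_names:
        raise ValueError(
            f"model dimensions {pred.dimension_names} do not match "
            f"target dimensions {targets.dimension_names}"
        )
    r2 = pd.Series(
        {
            d: r_squared(targets.values[d].to_numpy(), pred.values[d].to_numpy())
            for d in targets.dimension_names
        }
    )
    pairs = pd.concat(
        [
            targets.values.add_prefix("observed_").reset_index(drop=True),
            pred.values.add_prefix("predicted_").reset_index(drop=True),
        ],
        axis=1,
    )
    return {"r2": r2, "predictions": pairs}


def sample_size_curve(
    train_responses: pd.DataFrame,
    train_targets: TargetScores,
    test_responses: pd.DataFrame,
    test_targets: TargetScores,
    sample_sizes: tuple[int, ...] = (50, 100, 200, 300, 400, 500),
    n_boot: int = 1000,
    seed: int = 0,
    n_iterations: int = 50,
    scale: float = 8.0,
    val_proportion: float = 0.25,
) -> SampleSizeCurve:
    """Sensitivity of accuracy to training sample size.

    For each sample size, ``n_boot`` subsamples are drawn with replacement
    from the training pool. Each subsample is split 1−p/p into train and
    validation, the full randomized search reruns with a reduced iteration
    budget, and for every retained-item count observed in that search the
    best candidate (by min-dimension validation R²) is evaluated on the
    *fixed* test partition, so curves are comparable across sizes.
    """
    from .search import run_search  # deferred: evaluation <-> search layering

    pool = len(train_responses)
    for size in sample_sizes:
        if size > pool:
            raise ValueError(f"sample size {size} exceeds the training pool ({pool})")
        if math.ceil(size * val_proportion) >= size:
            raise ValueError(f"sample size {size} leaves no training rows")

    rng = np.random.default_rng(seed)
    rows = []
    for size in sample_sizes:
        n_val = math.ceil(size * val_proportion)
        for b in range(n_boot):
            idx = rng.integers(0, pool, size=size)
            sub_resp = train_responses.iloc[idx].reset_index(drop=True)
            sub_targ = TargetScores(
                values=train_targets.values.iloc[idx].reset_index(drop=True),
                kind=train_targets.kind,
            )
            tr = slice(0, size - n_val)
            va = slice(size - n_val, size)
            frontier = run_search(
                sub_resp.iloc[tr],
                TargetScores(sub_targ.values.iloc[tr], kind=sub_targ.kind),
                sub_resp.iloc[va],
                TargetScores(sub_targ.values.iloc[va], kind=sub_targ.kind),
                n_iterations=n_iterations,
                scale=scale,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            best_per_k: dict[int, object] = {}
            for rec in frontier.records:
                cur = best_per_k.get(rec.n_included)
                if cur is None or rec.r2_validation.min() > cur.r2_validation.min():
                    best_per_k[rec.n_included] = rec
            for k, rec in best_per_k.items():
                report = evaluate(rec.model, test_responses, test_targets)
                rows.append(
                    {
                        "sample_size": size,
                        "subsample": b,
                        "n_included": k,
                        "test_min_r2": float(report["r2"].min()),
                    }
                )

    raw = pd.DataFrame(rows)
    grouped = raw.groupby(["sample_size", "n_included"])["test_min_r2"]
    table = grouped.agg(
        mean_r2="mean",
        lower=lambda s: float(np.percentile(s, 2.5)),
        upper=lambda s: float(np.percentile(s, 97.5)),
        n_subsamples="count",
    ).reset_index()
    return SampleSizeCurve(
        table=table, sample_sizes=tuple(sample_sizes), n_boot=n_boot, seed=seed
    )
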