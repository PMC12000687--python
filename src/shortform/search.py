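"""Randomized search over per-dimension regularization strengths.

Each iteration draws one L1 strength per target dimension from a scaled
Beta(1, 3) distribution (over-sampling small strengths, which tend to be
the useful ones), selects items per dimension, refits the union, and scores
the candidate on a validation set. The scalar selection score balances
brevity against accuracy::

    score = min(R²_validation over dimensions) · (1 − n_included / n_total)

The Beta shape and the scale multiplier are exposed because an appropriate
scale depends on the measure; the default scale of 8 suits a ~22-item
scale. Because selection works on standardized items and targets, high
draws simply regularize every item away — those iterations are dropped —
while the dense low end of Beta(1, 3) sweeps the whole brevity range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reducer import ReducedModel, predict, refit_union, select_items_lasso, union_included
from .targets import TargetScores

__all__ = [
    "AlphaDraw",
    "CandidateRecord",
    "CandidateFrontier",
    "draw_alphas",
    "selection_score",
    "run_search",
    "fit_at_size",
    "best_model",
    "frontier_curve",
]

logger = logging.getLogger(__name__)

BETA_SHAPE = (1.0, 3.0)


@dataclass(frozen=True)
class AlphaDraw:
    """One iteration's per-dimension L1 strengths, each in [0, scale]."""

    alphas: np.ndarray
    scale: float
    iteration: int


@dataclass
class CandidateRecord:
    """One evaluated candidate model from the randomized search."""

    alphas: AlphaDraw
    model: ReducedModel
    n_included: int
    r2_validation: pd.Series
    score: float


@dataclass
class CandidateFrontier:
    """All candidates from one search run; iterations whose union was empty
    are dropped (and logged), so ``len(records) <= n_iterations``."""

    records: list[CandidateRecord] = field(default_factory=list)
    n_iterations: int = 0
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view for export: one row per candidate."""
        rows = []
        for rec in self.records:
            row = {
                "iteration": rec.alphas.iteration,
                "n_included": rec.n_included,
                "score": rec.score,
            }
            for d, a in zip(rec.r2_validation.index, rec.alphas.alphas):
                row[f"alpha_{d}"] = a
            for d, r2 in rec.r2_validation.items():
                row[f"r2_{d}"] = r2
            rows.append(row)
        return pd.DataFrame(rows)


def draw_alphas(n_dims: int, scale: float, rng: np.random.Generator, iteration: int = 0) -> AlphaDraw:
    """Draw independent Beta(1, 3) strengths, multiplied by ``scale``."""
    if n_dims < 1:
        raise ValueError("n_dims must be at least 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    alphas = scale * rng.beta(*BETA_SHAPE, size=n_dims)
    return AlphaDraw(alphas=alphas, scale=float(scale), iteration=iteration)


def selection_score(r2_by_dim, n_included: int, n_total: int) -> float:
    """Brevity/accuracy balance: ``min(R²) · (1 − n_included/n_total)``.

    May be negative when the worst dimension's R² is negative.
    """
    r2 = np.asarray(list(r2_by_dim), float)
    if r2.size == 0:
        raise ValueError("r2_by_dim must contain at least one dimension")
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if not 0 <= n_included <= n_total:
        raise ValueError("n_included must lie in [0, n_total]")
    return float(r2.min() * (1.0 - n_included / n_total))


def _evaluate_candidate(
    model: ReducedModel,
    val_responses: pd.DataFrame,
    val_targets: TargetScores,
) -> pd.Series:
    pred = predict(model, val_responses).values.to_numpy(float)
    obs = val_targets.values.to_numpy(float)
    ss_res = np.sum((obs - pred) ** 2, axis=0)
    ss_tot = np.sum((obs - obs.mean(axis=0)) ** 2, axis=0)
    return pd.Series(1.0 - ss_res / ss_tot, index=val_targets.dimension_names)


def fit_candidate(
    train_responses: pd.DataFrame,
    train_targets: TargetScores,
    alphas: AlphaDraw,
) -> ReducedModel | None:
    """Run the two-step fit for one alpha draw; None if the union is empty."""
    selections = [
        select_items_lasso(train_responses, train_targets.values[d], a, dimension=d)
        for d, a in zip(train_targets.dimension_names, alphas.alphas)
    ]
    included = union_included(selections, item_order=list(train_responses.columns))
    if not included:
        return None
    model = refit_union(train_responses, train_targets, included)
    model.alphas_used = pd.Series(alphas.alphas, index=train_targets.dimension_names)
    return model


def run_search(
    train_responses: pd.DataFrame,
    train_targets: TargetScores,
    val_responses: pd.DataFrame,
    val_targets: TargetScores,
    n_iterations: int = 1000,
    scale: float = 8.0,
    seed: int = 0,
) -> CandidateFrontier:
    """The randomized search loop.

    Per iteration: draw per-dimension alphas, select items per dimension on
    the training set, union, refit, and record per-dimension validation R²
    and the selection score. Fully reproducible for a fixed seed.
    """
    if list(train_responses.columns) != list(val_responses.columns):
        raise ValueError("train and validation responses must share identical item columns")
    if train_targets.dimension_names != val_targets.dimension_names:
        raise ValueError("train and validation targets must share identical dimensions")

    rng = np.random.default_rng(seed)
    n_total = train_responses.shape[1]
    frontier = CandidateFrontier(n_iterations=n_iterations, seed=seed)
    n_empty = 0
    for it in range(n_iterations):
        draw = draw_alphas(train_targets.n_dimensions, scale, rng, iteration=it)
        model = fit_candidate(train_responses, train_targets, draw)
        if model is None:
            n_empty += 1
            continue
        r2_val = _evaluate_candidate(model, val_responses, val_targets)
        frontier.records.append(
            CandidateRecord(
                alphas=draw,
                model=model,
                n_included=model.n_included,
                r2_validation=r2_val,
                score=selection_score(r2_val, model.n_included, n_total),
            )
        )
    if n_empty:
        logger.info("dropped %d iterations whose retained-item union was empty", n_empty)
    return frontier


def fit_at_size(
    train_responses: pd.DataFrame,
    train_targets: TargetScores,
    n_items: int,
    scale: float = 8.0,
    max_bisections: int = 60,
) -> ReducedModel | None:
    """Fit a reduced model with exactly ``n_items`` retained items.

    Bisects the regularization strength, exploiting that the retained-item
    count decreases (stepwise) in alpha. Intended for single-dimension
    targets, where the candidate at a given item count is unique; with
    several dimensions every dimension gets the same alpha, which reaches a
    size but not necessarily the best candidate of that size. Returns None
    if the count is never hit (ties in the path can skip a count).
    """
    if not 1 <= n_items <= train_responses.shape[1]:
        raise ValueError("n_items must lie in [1, item count]")

    def model_at(alpha: float) -> ReducedModel | None:
        draw = AlphaDraw(
            alphas=np.full(train_targets.n_dimensions, alpha), scale=scale, iteration=-1
        )
        return fit_candidate(train_responses, train_targets, draw)

    lo, hi = 0.0, float(scale)
    m = model_at(hi)
    while m is not None and m.n_included > n_items:  # scale too small to prune enough
        hi *= 2.0
        m = model_at(hi)
    for _ in range(max_bisections):
        mid = 0.5 * (lo + hi)
        m = model_at(mid)
        k = 0 if m is None else m.n_included
        if k == n_items:
            return m
        if k > n_items:
            lo = mid
        else:
            hi = mid
    return None


def best_model(frontier: CandidateFrontier) -> CandidateRecord:
    """Candidate maximizing the selection score.

    Ties break toward fewer retained items, then the earlier iteration.
    """
    if not frontier.records:
        raise ValueError("the candidate frontier is empty")
    return min(
        frontier.records,
        key=lambda rec: (-rec.score, rec.n_included, rec.alphas.iteration),
    )


def frontier_curve(frontier: CandidateFrontier) -> pd.DataFrame:
    """Best achievable min-dimension validation R² per retained-item count.

    One row per observed ``n_included``, sorted ascending; the raw material
    of a brevity/accuracy frontier plot.
    """
    if not frontier.records:
        raise ValueError("the candidate frontier is empty")
    rows = [
        {"n_included": rec.n_included, "min_r2": float(rec.r2_validation.min())}
        for rec in frontier.records
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby("n_included", as_index=False)["min_r2"]
        .max()
        .sort_values("n_included", ignore_index=True)
    )
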