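"""The item-reduction core: Lasso selection, union, and unregularized refit.

A reduced measure predicts each target dimension as a weighted sum of the
retained items, ``y_hat = w_1 x_1 + w_2 x_2 + ... + b``; items outside the
retained set have weight zero. Item selection runs per dimension with an
L1 penalty (each dimension gets its own strength ``alpha``), the retained
sets are unioned, and plain least squares re-weights the union for every
dimension so that information selected for one dimension also serves the
others.

Conventions: inside selection, items *and* the target are z-scored with
training-set mean/SD, so ``alpha`` is a correlation-scale quantity with the
same meaning whether the target is a sum score (SD in the tens) or a
centred factor score (SD near 1) — a single draw distribution then spans
the whole brevity range for every target kind. The L1 objective is
``(1/2n)·RSS + alpha·||w||_1``. The refit runs on raw responses so exported
weights apply directly to raw item codes. Intercepts are estimated in both
steps (sum-score targets on the full item set still come out with unit
weights and a zero intercept).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from .targets import TargetScores

__all__ = [
    "LassoSelection",
    "ReducedModel",
    "select_items_lasso",
    "union_included",
    "refit_union",
    "predict",
]

logger = logging.getLogger(__name__)

# sklearn's tol is a dual-gap bound (scaled by ||y||^2/n); 1e-10 yields
# coefficient agreement around 1e-7 with an exact solver on small problems
_LASSO_TOL = 1e-10
_LASSO_MAX_ITER = 10_000


@dataclass
class LassoSelection:
    """Step-1 result for one target dimension.

    ``coefficients`` are on the standardized-item scale (the solver's
    native scale); the zero pattern — hence ``included_items`` — does not
    depend on that choice.
    """

    dimension: str
    alpha: float
    coefficients: pd.Series
    included_items: list[str]
    training_r2: float


@dataclass
class ReducedModel:
    """A fitted reduced measure: retained items plus per-dimension weights.

    ``weights`` has one row per retained item and one column per target
    dimension; items absent from ``included_items`` have implicit weight
    zero everywhere. Weights apply to raw item codes.
    """

    included_items: list[str]
    weights: pd.DataFrame
    intercepts: pd.Series
    alphas_used: pd.Series
    n_items_total: int
    target_kind: str = "sum"
    training_r2: pd.Series = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n_included(self) -> int:
        return len(self.included_items)

    @property
    def dimension_names(self) -> list[str]:
        return list(self.weights.columns)

    def to_json(self) -> str:
        payload = {
            "included_items": self.included_items,
            "weights": {d: self.weights[d].to_dict() for d in self.weights.columns},
            "intercepts": self.intercepts.to_dict(),
            "alphas_used": self.alphas_used.to_dict(),
            "n_items_total": self.n_items_total,
            "target_kind": self.target_kind,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ReducedModel":
        payload = json.loads(text)
        dims = list(payload["weights"])
        weights = pd.DataFrame(
            {d: pd.Series(payload["weights"][d]) for d in dims}
        ).reindex(payload["included_items"])
        return cls(
            included_items=list(payload["included_items"]),
            weights=weights,
            intercepts=pd.Series(payload["intercepts"]).reindex(dims),
            alphas_used=pd.Series(payload["alphas_used"]).reindex(dims),
            n_items_total=int(payload["n_items_total"]),
            target_kind=payload.get("target_kind", "sum"),
        )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = np.zeros_like(X, dtype=float)
    Z[:, keep] = (X[:, keep] - mean[keep]) / sd[keep]
    return Z, mean, sd


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def select_items_lasso(
    train_responses: pd.DataFrame,
    train_targets_dim: pd.Series,
    alpha: float,
    dimension: str | None = None,
) -> LassoSelection:
    """L1-penalized selection of informative items for one dimension.

    Minimizes ``(1/2n)·||y_z - Zw - b||² + alpha·||w||_1`` where ``Z`` are
    z-scored items and ``y_z`` the z-scored target; at ``alpha = 0`` this is
    ordinary least squares. The retained set is what matters downstream and
    is invariant to any rescaling of the raw target. Zero-variance items
    receive a zero coefficient with a logged warning; a zero-variance
    target is an error. ``coefficients`` are on the standardized scale.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if len(train_responses) < 2:
        raise ValueError("at least 2 participants are required")
    y_raw = np.asarray(train_targets_dim, float)
    if len(y_raw) != len(train_responses):
        raise ValueError("responses and targets have different lengths")
    if y_raw.std() == 0:
        raise ValueError("target dimension has zero variance")
    y = (y_raw - y_raw.mean()) / y_raw.std()
    name = dimension if dimension is not None else str(getattr(train_targets_dim, "name", "y"))

    X = train_responses.to_numpy(float)
    Z, _, sd = _standardize(X)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        logger.warning(
            "zero-variance items receive zero coefficients: %s",
            [train_responses.columns[i] for i in dead],
        )

    if alpha == 0.0:
        A = np.column_stack([np.ones(len(Z)), Z])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        coef = beta[1:]
    else:
        model = Lasso(alpha=alpha, fit_intercept=True, tol=_LASSO_TOL, max_iter=_LASSO_MAX_ITER)
        model.fit(Z, y)
        coef = model.coef_.copy()
    coef[dead] = 0.0
    yhat = Z @ coef + (y.mean() - Z.mean(axis=0) @ coef)

    coefficients = pd.Series(coef, index=train_responses.columns)
    included = [c for c, w in coefficients.items() if w != 0.0]
    return LassoSelection(
        dimension=name,
        alpha=float(alpha),
        coefficients=coefficients,
        included_items=included,
        training_r2=_r2(y, yhat),
    )


def union_included(selections: list[LassoSelection], item_order: list[str] | None = None) -> list[str]:
    """Union of per-dimension retained item sets, in original item order."""
    if not selections:
        raise ValueError("at least one selection is required")
    if item_order is None:
        item_order = list(selections[0].coefficients.index)
    chosen = set()
    for sel in selections:
        chosen.update(sel.included_items)
    return [item for item in item_order if item in chosen]


def refit_union(
    train_responses: pd.DataFrame,
    train_targets: TargetScores,
    included: list[str],
) -> ReducedModel:
    """Unregularized per-dimension refit on the union of retained items.

    Ordinary least squares on raw item responses with an intercept, fitted
    independently for every target dimension. Rank-deficient designs fall
    back to the minimum-norm solution with a logged warning.
    """
    if not included:
        raise ValueError("the retained item set is empty; lower alpha to include items")
    missing = [c for c in included if c not in train_responses.columns]
    if missing:
        raise KeyError(f"retained items absent from responses: {missing}")
    if len(train_responses) <= len(included):
        raise ValueError("participant count must exceed the retained-item count")

    X = train_responses[included].to_numpy(float)
    A = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        logger.warning("rank-deficient refit design; using the minimum-norm solution")

    Y = train_targets.values.to_numpy(float)
    beta, *_ = np.linalg.lstsq(A, Y, rcond=None)

    dims = train_targets.dimension_names
    weights = pd.DataFrame(beta[1:], index=included, columns=dims)
    intercepts = pd.Series(beta[0], index=dims)
    r2 = pd.Series(
        [_r2(Y[:, j], A @ beta[:, j]) for j in range(len(dims))], index=dims
    )
    return ReducedModel(
        included_items=list(included),
        weights=weights,
        intercepts=intercepts,
        alphas_used=pd.Series(np.nan, index=dims),
        n_items_total=train_responses.shape[1],
        target_kind=train_targets.kind,
        training_r2=r2,
    )


def predict(model: ReducedModel, responses: pd.DataFrame) -> TargetScores:
    """Predicted scores: retained responses · weights + intercepts.

    Extra (non-retained) columns in ``responses`` are ignored, so
    predictions are unaffected by items the model excluded.
    """
    missing = [c for c in model.included_items if c not in responses.columns]
    if missing:
        raise KeyError(f"responses are missing retained item columns: {missing}")
    X = responses[model.included_items].to_numpy(float)
    Y = X @ model.weights.to_numpy(float) + model.intercepts.to_numpy(float)
    values = pd.DataFrame(Y, index=responses.index, columns=model.dimension_names)
    return TargetScores(values=values, kind=model.target_kind)
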