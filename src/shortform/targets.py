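"""Target ("true") scores that a reduced item set learns to predict.

Three kinds of target are supported, mirroring common scoring practice:
total sum scores, subscale sum scores over a partition of the items, and
factor scores from an exploratory factor analysis (maximum-likelihood
estimation, oblimin rotation, regression/Thurstone score estimates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor import Factor

__all__ = [
    "TargetScores",
    "EfaSolution",
    "sum_scores",
    "subscale_scores",
    "fit_efa",
    "choose_n_factors",
]


@dataclass
class TargetScores:
    """Participants x dimensions matrix of observed scores.

    ``kind`` is one of ``"sum"``, ``"subscale"`` or ``"factor"``.
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in {"sum", "subscale", "factor"}:
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.values.shape[1] < 1:
            raise ValueError("at least one target dimension is required")
        if self.values.columns.duplicated().any():
            raise ValueError("dimension names must be unique")

    @property
    def dimension_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_dimensions(self) -> int:
        return self.values.shape[1]


@dataclass
class EfaSolution:
    """An exploratory factor analysis fit.

    ``loadings`` are the oblimin-rotated pattern loadings, ``eigenvalues``
    those of the item Pearson correlation matrix (descending), and
    ``factor_scores`` regression-method score estimates.
    """

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    factor_scores: pd.DataFrame
    n_factors: int


def _check_no_missing(responses: pd.DataFrame, impute_mean: bool) -> pd.DataFrame:
    if responses.isna().any().any():
        if impute_mean:
            return responses.fillna(responses.mean())
        missing = responses.columns[responses.isna().any()].tolist()
        raise ValueError(
            f"responses contain missing cells in columns {missing}; "
            "pass impute_mean=True to enable per-item mean imputation"
        )
    return responses


def sum_scores(responses: pd.DataFrame, impute_mean: bool = False) -> TargetScores:
    """Total sum score: the row sum of all item responses."""
    responses = _check_no_missing(responses, impute_mean)
    values = responses.sum(axis=1).to_frame("total")
    return TargetScores(values=values.astype(float), kind="sum")


def subscale_scores(
    responses: pd.DataFrame,
    assignment: dict[str, str],
    impute_mean: bool = False,
) -> TargetScores:
    """Subscale sum scores over a partition of the items.

    ``assignment`` maps every item name to exactly one subscale name;
    subscale column order follows first appearance in the item order.
    """
    responses = _check_no_missing(responses, impute_mean)
    items = list(responses.columns)
    unassigned = [c for c in items if c not in assignment]
    if unassigned:
        raise ValueError(f"items not assigned to any subscale: {unassigned}")
    extra = [c for c in assignment if c not in items]
    if extra:
        raise ValueError(f"assignment references unknown items: {extra}")

    subscales: dict[str, list[str]] = {}
    for item in items:
        subscales.setdefault(assignment[item], []).append(item)
    values = pd.DataFrame(
        {name: responses[cols].sum(axis=1).astype(float) for name, cols in subscales.items()}
    )
    return TargetScores(values=values, kind="subscale")


def fit_efa(
    responses: pd.DataFrame,
    n_factors: int,
    impute_mean: bool = False,
    max_iter: int = 500,
) -> EfaSolution:
    """Maximum-likelihood exploratory factor analysis with oblimin rotation.

    Factor scores are computed by the regression (Thurstone) method, the
    de-facto default of common factor-analysis toolchains. Eigenvalues are
    those of the item Pearson correlation matrix.
    """
    responses = _check_no_missing(responses, impute_mean)
    n, p = responses.shape
    if not 1 <= n_factors < p:
        raise ValueError("n_factors must be at least 1 and less than the item count")
    if n <= p:
        raise ValueError("sample size must exceed the item count")

    X = responses.to_numpy(float)
    corr = np.corrcoef(X, rowvar=False)
    eigenvalues = np.sort(np.linalg.eigvalsh(corr))[::-1]

    model = Factor(X, n_factor=n_factors, method="ml")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(maxiter=max_iter)
    except Exception as exc:  # statsmodels raises plain Exceptions on failure
        raise RuntimeError(
            f"maximum-likelihood factor analysis failed to converge "
            f"(n_factors={n_factors}, max_iter={max_iter}): {exc}"
        ) from exc
    if n_factors > 1:
        # rotation of a single factor is the identity up to sign
        result.rotate("oblimin")

    scores = result.factor_scoring(X, method="regression")
    factor_names = [f"factor_{k + 1}" for k in range(n_factors)]
    return EfaSolution(
        loadings=pd.DataFrame(result.loadings, index=responses.columns, columns=factor_names),
        eigenvalues=eigenvalues,
        factor_scores=pd.DataFrame(scores, index=responses.index, columns=factor_names),
        n_factors=n_factors,
    )


def factor_scores(responses: pd.DataFrame, n_factors: int, **kwargs) -> TargetScores:
    """EFA factor-score targets; convenience wrapper around :func:`fit_efa`."""
    solution = fit_efa(responses, n_factors, **kwargs)
    return TargetScores(values=solution.factor_scores, kind="factor")


def choose_n_factors(eigenvalues: np.ndarray) -> int:
    """Number of factors to retain: eigenvalues of the correlation matrix > 1.

    The Kaiser rule serves as the programmatic stand-in for a visual scree
    judgment; callers can always overrule via an explicit ``n_factors``.
    """
    eigenvalues = np.asarray(eigenvalues, float)
    if eigenvalues.size < 1:
        raise ValueError("at least one eigenvalue is required")
    k = int(np.sum(eigenvalues > 1.0))
    if k == 0:
        warnings.warn("no eigenvalue exceeds 1; no common factor is indicated")
    return k
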