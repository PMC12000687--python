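"""Synthetic Likert response data with a known common-factor structure.

Responses are generated from a linear common-factor model: latent factor
scores are drawn from a zero-mean multivariate normal with a given factor
correlation matrix, each item's latent response is a loading-weighted sum of
factors plus a normal residual scaled so the latent item has unit total
variance, and the latent value is discretized through a fixed set of ordered
thresholds into integer Likert categories (``1 .. k+1`` for ``k``
thresholds).

The ``sticsa_like`` preset emulates a 22-item trait-anxiety questionnaire
with two correlated factors of 11 items each, high primary loadings and
four response categories, so the full item-reduction pipeline can be
exercised without any external dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneratorSpec", "SyntheticDataset", "make_preset", "generate", "PRESETS"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Population definition for the synthetic Likert generator.

    Parameters
    ----------
    n_items, n_factors
        Questionnaire dimensions.
    loading_matrix
        ``(n_items, n_factors)`` factor loadings. Each row's communality
        (``l' @ factor_correlation @ l``) must be at most 1 so the residual
        variance is non-negative.
    factor_correlation
        ``(n_factors, n_factors)`` correlation matrix of the latent factors;
        symmetric, unit diagonal, positive definite.
    thresholds
        Strictly increasing cut-points on the latent item scale; ``k``
        thresholds yield ``k + 1`` integer response categories coded
        ``1 .. k+1``.
    n_respondents
        Default sample size for :func:`generate`.
    seed
        Default seed for :func:`generate`.
    """

    n_items: int
    n_factors: int
    loading_matrix: np.ndarray
    factor_correlation: np.ndarray
    thresholds: np.ndarray
    n_respondents: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "loading_matrix", np.asarray(self.loading_matrix, float))
        object.__setattr__(self, "factor_correlation", np.asarray(self.factor_correlation, float))
        object.__setattr__(self, "thresholds", np.asarray(self.thresholds, float))
        self.validate()

    def validate(self) -> None:
        if self.n_items < 1 or self.n_factors < 1:
            raise ValueError("n_items and n_factors must be positive")
        if self.loading_matrix.shape != (self.n_items, self.n_factors):
            raise ValueError(
                f"loading_matrix must be {(self.n_items, self.n_factors)}, "
                f"got {self.loading_matrix.shape}"
            )
        phi = self.factor_correlation
        if phi.shape != (self.n_factors, self.n_factors):
            raise ValueError("factor_correlation has wrong shape")
        if not np.allclose(phi, phi.T):
            raise ValueError("factor_correlation must be symmetric")
        if not np.allclose(np.diag(phi), 1.0):
            raise ValueError("factor_correlation must have unit diagonal")
        if np.any(np.linalg.eigvalsh(phi) <= 0):
            raise ValueError("factor_correlation must be positive definite")
        if self.thresholds.ndim != 1 or len(self.thresholds) < 1:
            raise ValueError("thresholds must be a non-empty 1-d sequence")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        comm = np.einsum("if,fg,ig->i", self.loading_matrix, phi, self.loading_matrix)
        if np.any(comm > 1.0 + 1e-12):
            bad = np.where(comm > 1.0 + 1e-12)[0]
            raise ValueError(f"items {bad.tolist()} have communality > 1")
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be positive")

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    @property
    def communalities(self) -> np.ndarray:
        L, phi = self.loading_matrix, self.factor_correlation
        return np.einsum("if,fg,ig->i", L, phi, L)

    @property
    def item_names(self) -> list[str]:
        width = max(2, len(str(self.n_items)))
        return [f"item_{i + 1:0{width}d}" for i in range(self.n_items)]

    def latent_item_correlation(self) -> np.ndarray:
        """Model-implied correlation matrix of the latent (pre-threshold) items."""
        L, phi = self.loading_matrix, self.factor_correlation
        sigma = L @ phi @ L.T
        np.fill_diagonal(sigma, 1.0)  # unit residual-completed total variance
        return sigma

    def replace(self, **kwargs) -> "GeneratorSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticDataset:
    """A generated sample: integer responses plus the true latent factor scores."""

    responses: pd.DataFrame
    true_factor_scores: pd.DataFrame
    spec: GeneratorSpec = field(repr=False)


def _sticsa_like() -> GeneratorSpec:
    # One fixed population: primary loadings drawn U(0.80, 0.95) once under a
    # preset-internal seed; simple structure, 11 items per factor.
    rng = np.random.default_rng(20220411)
    loadings = np.zeros((22, 2))
    loadings[:11, 0] = rng.uniform(0.80, 0.95, size=11)
    loadings[11:, 1] = rng.uniform(0.80, 0.95, size=11)
    return GeneratorSpec(
        n_items=22,
        n_factors=2,
        loading_matrix=loadings,
        factor_correlation=np.array([[1.0, 0.6], [0.6, 1.0]]),
        thresholds=np.array([-1.0, 0.0, 1.0]),
        n_respondents=1622,
    )


def _unidim() -> GeneratorSpec:
    rng = np.random.default_rng(20220412)
    loadings = rng.uniform(0.70, 0.90, size=(10, 1))
    return GeneratorSpec(
        n_items=10,
        n_factors=1,
        loading_matrix=loadings,
        factor_correlation=np.eye(1),
        thresholds=np.array([-1.0, 0.0, 1.0]),
        n_respondents=1000,
    )


PRESETS = {"sticsa_like": _sticsa_like, "unidim": _unidim}


def make_preset(name: str) -> GeneratorSpec:
    """Return a registered generator preset.

    ``"sticsa_like"``
        22 items, two factors of 11 items each (simple structure), primary
        loadings U(0.80, 0.95) fixed once, factor correlation 0.6,
        thresholds (-1, 0, 1) giving four Likert categories.
    ``"unidim"``
        A single-factor 10-item scale.
    """
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; registered presets: {sorted(PRESETS)}"
        ) from None


def generate(spec: GeneratorSpec, seed: int | None = None, n: int | None = None) -> SyntheticDataset:
    """Draw a synthetic sample from the population defined by ``spec``.

    Deterministic for a fixed ``(spec, seed)`` pair. ``n`` overrides
    ``spec.n_respondents``.
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    if n is None:
        n = spec.n_respondents
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)

    phi = spec.factor_correlation
    chol = np.linalg.cholesky(phi)
    factors = rng.standard_normal((n, spec.n_factors)) @ chol.T

    resid_sd = np.sqrt(np.clip(1.0 - spec.communalities, 0.0, None))
    latent = factors @ spec.loading_matrix.T
    latent += rng.standard_normal((n, spec.n_items)) * resid_sd

    # category = number of thresholds below the latent value, plus one
    codes = np.searchsorted(spec.thresholds, latent, side="left") + 1

    responses = pd.DataFrame(codes.astype(np.int64), columns=spec.item_names)
    factor_names = [f"factor_{k + 1}" for k in range(spec.n_factors)]
    scores = pd.DataFrame(factors, columns=factor_names)
    return SyntheticDataset(responses=responses, true_factor_scores=scores, spec=spec)
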