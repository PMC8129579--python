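"""Bounded-area gene selection against a log-normal replicate null.

Each gene's differential profile is scored by the area enclosed between
its piecewise-linear time course and the zero baseline.  The null
distribution of areas is fitted from replicate-versus-mean deviations
pooled over all genes, and genes are labelled seeds (Bonferroni-adjusted
p below alpha) or candidates (unadjusted p below alpha).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from stagewise.errors import (
    ConfigurationError,
    DataError,
    InsufficientReplicationError,
)
from stagewise.preprocess import LOG_SCALE, DifferentialProfiles, StageSeries

SEED = "seed"
CANDIDATE = "candidate"
NONE = "none"

#: areas at or below this are treated as exactly zero when pooling nulls
#: (large enough to absorb TSV round-trip noise on replicates that match
#: the mean profile, far below any biologically meaningful deviation)
AREA_EPS = 1e-6


@dataclass(frozen=True)
class NullModel:
    """Log-normal null for areas: ln(area) ~ Normal(log_mu, log_sigma)."""

    log_mu: float
    log_sigma: float
    n_null: int = 0

    def __post_init__(self) -> None:
        if not self.log_sigma > 0:
            raise ConfigurationError(f"log_sigma must be > 0, got {self.log_sigma}")

    @classmethod
    def from_natural_moments(cls, mean: float, sd: float, n_null: int = 0) -> "NullModel":
        """Build from the mean and standard deviation of the area itself.

        Converts natural-scale log-normal moments to the parameters of
        ln(area): sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2.
        """
        if mean <= 0 or sd <= 0:
            raise ConfigurationError("natural moments must be positive")
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return cls(float(mu), float(np.sqrt(sigma2)), n_null)


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.01
    correction: str = "bonferroni"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.correction != "bonferroni":
            raise ConfigurationError(f"unsupported correction {self.correction!r}")


def bounded_area(d: np.ndarray) -> float:
    """Area between the piecewise-linear profile and the zero baseline.

    Stages are unit-spaced.  Segments that cross zero contribute the two
    triangles on either side of the crossing, so the result is the exact
    integral of ``|d(x)|`` for the linearly interpolated profile.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise DataError("profile must be a 1-D array with at least 2 stages")
    if not np.all(np.isfinite(d)):
        raise DataError("non-finite entries in profile")
    return float(_segment_areas(d[None, :])[0])


def bounded_areas(matrix: np.ndarray) -> np.ndarray:
    """Vectorized :func:`bounded_area` over rows of a profile matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise DataError("profile matrix must be 2-D with at least 2 stages")
    if not np.all(np.isfinite(matrix)):
        raise DataError("non-finite entries in profile matrix")
    return _segment_areas(matrix)


def _segment_areas(m: np.ndarray) -> np.ndarray:
    a, b = m[:, :-1], m[:, 1:]
    crossing = a * b < 0
    trapezoid = np.abs(a + b) / 2.0  # same-sign segments: (|a|+|b|)/2
    with np.errstate(divide="ignore", invalid="ignore"):
        split = (a * a + b * b) / (2.0 * np.abs(a - b))
    return np.where(crossing, split, trapezoid).sum(axis=1)


def estimate_null(series: StageSeries) -> NullModel:
    """Fit the log-normal null from replicate-versus-mean deviation areas.

    For every gene and replicate, the bounded area of (replicate profile
    minus the gene's cross-replicate mean profile) is computed; all
    strictly positive areas are pooled and a normal distribution is fit
    to their natural logs by maximum likelihood.
    """
    if series.scale != LOG_SCALE:
        raise DataError("null estimation requires log2-scale input")
    if series.n_replicates < 2:
        raise InsufficientReplicationError(
            f"need at least 2 replicates, got {series.n_replicates}"
        )
    mean_profiles = series.values.mean(axis=2)
    deviations = series.values - mean_profiles[:, :, None]
    # (genes * replicates) x stages
    flat = np.moveaxis(deviations, 2, 1).reshape(-1, series.axis.n_stages)
    areas = _segment_areas(flat)
    # strictly positive with a numerical guard: a replicate that matches
    # the mean profile must not contribute a float-noise area
    areas = areas[areas > AREA_EPS]
    if areas.size == 0:
        raise InsufficientReplicationError(
            "no replicate variability: all replicates identical"
        )
    logs = np.log(areas)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    if sigma == 0:
        raise InsufficientReplicationError("degenerate replicate variability")
    return NullModel(mu, sigma, int(areas.size))


def area_pvalue(area: float, null: NullModel) -> float:
    """Upper-tail p-value of an area under the log-normal null."""
    if area < 0:
        raise DataError(f"area must be >= 0, got {area}")
    if area == 0:
        return 1.0
    z = (np.log(area) - null.log_mu) / null.log_sigma
    return float(stats.norm.sf(z))


def area_pvalues(areas: np.ndarray, null: NullModel) -> np.ndarray:
    areas = np.asarray(areas, dtype=float)
    if np.any(areas < 0):
        raise DataError("areas must be >= 0")
    p = np.ones_like(areas)
    pos = areas > 0
    z = (np.log(areas[pos]) - null.log_mu) / null.log_sigma
    p[pos] = stats.norm.sf(z)
    return p


def classify_genes(
    pvalues: pd.Series,
    config: SelectionConfig,
    n_tests: int,
) -> pd.DataFrame:
    """Bonferroni-adjust p-values and label genes seed/candidate/none."""
    if n_tests < len(pvalues):
        raise ConfigurationError(
            f"n_tests={n_tests} smaller than number of p-values {len(pvalues)}"
        )
    p = pvalues.astype(float)
    p_adj = np.minimum(1.0, p * n_tests)
    label = np.where(
        p_adj < config.alpha, SEED, np.where(p < config.alpha, CANDIDATE, NONE)
    )
    return pd.DataFrame({"p": p, "p_adj": p_adj, "label": label}, index=pvalues.index)


def select_genes(
    profiles: DifferentialProfiles,
    null: NullModel,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Score all profiles and classify genes.

    Returns a DataFrame indexed by gene id with columns
    ``area, p, p_adj, label``.
    """
    config = config or SelectionConfig()
    areas = bounded_areas(profiles.matrix)
    p = area_pvalues(areas, null)
    table = classify_genes(
        pd.Series(p, index=pd.Index(profiles.genes, name="gene_id")),
        config,
        n_tests=len(profiles.genes),
    )
    table.insert(0, "area", areas)
    return table
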