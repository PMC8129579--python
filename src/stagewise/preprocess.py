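"""Expression filtering, log transformation and differential profiles.

The pipeline consumes a gene x stage x replicate tensor of normalized
counts on an ordered stage axis whose first stage is the baseline.
Differential profiles are replicate means on the log2 scale with the
baseline-stage mean subtracted, so every profile is exactly zero at the
baseline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from stagewise.errors import AxisError, DataError, ScaleError

COUNT_SCALE = "count"
LOG_SCALE = "log2"


@dataclass(frozen=True)
class StageAxis:
    """Ordered stage labels; the first stage is the baseline."""

    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.stages) < 3:
            raise AxisError(f"need at least 3 stages, got {len(self.stages)}")
        if len(set(self.stages)) != len(self.stages):
            raise AxisError(f"duplicate stage labels: {self.stages}")

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def baseline(self) -> str:
        return self.stages[0]

    def index(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise AxisError(f"unknown stage label {stage!r}") from None


@dataclass
class StageSeries:
    """Gene x stage x replicate value tensor tagged with its scale.

    ``values`` has shape ``(n_genes, n_stages, n_replicates)``; replicate
    counts are uniform across stages.  ``scale`` is ``"count"`` for
    non-negative normalized counts and ``"log2"`` after transformation.
    """

    genes: list[str]
    values: np.ndarray
    axis: StageAxis
    scale: str = COUNT_SCALE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DataError(f"values must be 3-D, got shape {self.values.shape}")
        g, t, r = self.values.shape
        if g != len(self.genes):
            raise DataError(f"{len(self.genes)} gene ids but {g} rows of values")
        if t != self.axis.n_stages:
            raise AxisError(f"{self.axis.n_stages} stages on axis but {t} in values")
        if r < 1:
            raise DataError("every stage needs at least one replicate")
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene identifiers")
        if self.scale not in (COUNT_SCALE, LOG_SCALE):
            raise ScaleError(f"unknown scale tag {self.scale!r}")
        if self.scale == COUNT_SCALE and np.any(self.values < 0):
            raise DataError("negative values on count scale")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def subset(self, keep: np.ndarray) -> "StageSeries":
        """Return a new series restricted to a boolean gene mask."""
        keep = np.asarray(keep, dtype=bool)
        genes = [g for g, k in zip(self.genes, keep) if k]
        return StageSeries(genes, self.values[keep], self.axis, self.scale)


@dataclass
class DifferentialProfiles:
    """Per-gene baseline-subtracted mean log2 profiles, zero at baseline."""

    genes: list[str]
    matrix: np.ndarray  # (n_genes, n_stages)
    axis: StageAxis

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.genes), self.axis.n_stages):
            raise DataError(
                f"profile matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {self.axis.n_stages} stages"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise DataError("non-finite entries in differential profiles")

    def profile(self, gene: str) -> np.ndarray:
        return self.matrix[self.genes.index(gene)]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {g: self.matrix[i] for i, g in enumerate(self.genes)}


def filter_low_expression(series: StageSeries, min_mean: float = 10.0) -> StageSeries:
    """Drop genes whose replicate-averaged count is below ``min_mean`` in every stage.

    A gene is kept as soon as any single stage reaches the threshold
    (the comparison is strict: a stage average exactly at ``min_mean``
    keeps the gene).
    """
    if series.scale != COUNT_SCALE:
        raise ScaleError("low-expression filter requires count-scale input")
    stage_means = series.values.mean(axis=2)
    keep = (stage_means >= min_mean).any(axis=1)
    return series.subset(keep)


def log2_transform(series: StageSeries) -> StageSeries:
    """log2-transform counts; zeros are kept as 0."""
    if series.scale != COUNT_SCALE:
        raise ScaleError("log2_transform requires count-scale input")
    if np.any(series.values < 0):
        raise DataError("negative counts")
    out = np.zeros_like(series.values)
    pos = series.values > 0
    out[pos] = np.log2(series.values[pos])
    return StageSeries(list(series.genes), out, series.axis, LOG_SCALE)


def differential_profiles(series: StageSeries) -> DifferentialProfiles:
    """Replicate-mean profiles minus each gene's baseline-stage mean."""
    if series.scale != LOG_SCALE:
        raise ScaleError("differential profiles require log2-scale input")
    means = series.values.mean(axis=2)
    d = means - means[:, [0]]
    return DifferentialProfiles(list(series.genes), d, series.axis)
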