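"""Synthetic multi-stage count matrices with planted temporal structure.

The generator plants differentially expressed genes with step / ramp /
pulse / decay shapes at known break stages and signs, non-DE genes whose
baseline-anchored differential areas follow the configured log-normal
null, and replicate noise constructed so that replicate-versus-mean
deviation areas follow that same log-normal exactly.  Matching gene-set
annotations, a term hierarchy and a category map give the downstream
clustering and enrichment stages planted signal.

Replicate noise is injected as antithetic pairs: for each pair of
replicates a smooth unit-area deviation shape is scaled by a log-normal
draw and added with opposite signs (a leftover odd replicate gets zero
deviation).  The pairs cancel in the cross-replicate mean, so the pooled
deviation-from-mean areas are exactly log-normal and planted mean
profiles are recovered exactly (up to count rounding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stagewise.errors import ConfigurationError
from stagewise.patterns import AnnotationSet, Hierarchy
from stagewise.preprocess import StageAxis, StageSeries
from stagewise.select import _segment_areas

SHAPES = ("step", "ramp", "pulse", "decay")

#: natural-scale (mean, sd) of the default log-normal replicate null
DEFAULT_NOISE_LOG_MU = 1.09
DEFAULT_NOISE_LOG_SIGMA = 0.44


@dataclass(frozen=True)
class SimConfig:
    """Configuration for the synthetic data generator."""

    n_genes: int = 1000
    n_stages: int = 6
    n_replicates: int = 3
    baseline_stage_index: int = 0
    frac_de: float = 0.25
    shape_mix: dict[str, float] = field(
        default_factory=lambda: {"step": 0.25, "ramp": 0.25, "pulse": 0.25, "decay": 0.25}
    )
    effect_log2: float = 2.0
    noise_log_mu: float = DEFAULT_NOISE_LOG_MU
    noise_log_sigma: float = DEFAULT_NOISE_LOG_SIGMA
    base_expression_log2: float = 8.0
    n_terms: int = 40
    term_size: int = 25
    term_purity: float = 0.9
    seed: int = 0
    breaks_by_shape: dict[str, tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_stages < 3 or self.term_size < 1:
            raise ConfigurationError("sizes must be positive (and n_stages >= 3)")
        if self.n_replicates < 2:
            raise ConfigurationError("need at least 2 replicates")
        if self.baseline_stage_index != 0:
            raise ConfigurationError("baseline stage must be the first stage")
        if not 0 <= self.frac_de <= 1:
            raise ConfigurationError(f"frac_de must be in [0, 1], got {self.frac_de}")
        if not 0 <= self.term_purity <= 1:
            raise ConfigurationError("term_purity must be in [0, 1]")
        if self.effect_log2 <= 0:
            raise ConfigurationError("effect_log2 must be positive")
        if self.noise_log_sigma <= 0:
            raise ConfigurationError("noise_log_sigma must be positive")
        if self.term_size > self.n_genes:
            raise ConfigurationError("term_size cannot exceed n_genes")
        weights = dict(self.shape_mix)
        if any(w < 0 for w in weights.values()) or not weights:
            raise ConfigurationError("shape_mix proportions must be non-negative")
        unknown = set(weights) - set(SHAPES)
        if unknown:
            raise ConfigurationError(f"unknown shapes in shape_mix: {sorted(unknown)}")
        total = sum(weights.values())
        if self.frac_de > 0 and not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"shape_mix proportions must sum to 1, got {total}")
        if self.frac_de > 0 and weights.get("pulse", 0) > 0 and self.n_stages < 5:
            raise ConfigurationError("pulse shapes require at least 5 stages")

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_genes))

    @property
    def stage_labels(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_stages))


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene DE status and per-term dominant class."""

    genes: pd.DataFrame  # gene_id(index), is_de, shape, break_stage, sign
    terms: pd.DataFrame  # term_id(index), shape, break_stage, sign (filled later)

    def de_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_de"]])


def default_breaks_by_shape(n_stages: int) -> dict[str, tuple[int, ...]]:
    """Break stages (0-based indices, never the baseline) planted per shape.

    Chosen so that every planted profile keeps a broad enough area to be
    detectable, while spreading breaks over early and late stages.
    """
    t = n_stages
    return {
        "step": tuple(i for i in (1, 2) if i < t),
        "ramp": tuple(range(2, t - 2)) or (1,),
        "pulse": tuple(range(1, max(2, t - 3))),
        "decay": (1,),
    }


def shape_profile(shape: str, break_index: int, n_stages: int) -> np.ndarray:
    """Unit-amplitude template for a planted shape breaking at ``break_index``.

    The break stage is where the shape first reaches its full amplitude.
    """
    t = n_stages
    k = break_index
    if not 1 <= k < t:
        raise ConfigurationError(f"break index {k} outside 1..{t - 1}")
    x = np.zeros(t)
    if shape == "step":
        x[k:] = 1.0
    elif shape == "ramp":
        x = np.minimum(np.arange(t) / k, 1.0)
    elif shape == "pulse":
        if k + 2 > t - 1:
            raise ConfigurationError(f"pulse break {k} needs {k + 2} <= {t - 1}")
        x[k : k + 3] = 1.0
        for i in range(k + 3, t):  # gradual fall keeps the area detectable
            x[i] = max(0.0, 1.0 - 0.5 * (i - (k + 2)))
    elif shape == "decay":
        x[1:] = np.linspace(1.0, 0.0, t - 1)
    else:
        raise ConfigurationError(f"unknown shape {shape!r}")
    return x


def _smooth_noise(rng: np.random.Generator, n_stages: int) -> np.ndarray:
    raw = rng.standard_normal(n_stages + 2)
    kernel = np.array([0.25, 0.5, 0.25])
    return np.convolve(raw, kernel, mode="valid")


def _unit_area_shape(
    rng: np.random.Generator, n_stages: int, anchor_baseline: bool
) -> np.ndarray:
    """Smooth random profile scaled to bounded area exactly 1."""
    while True:
        z = _smooth_noise(rng, n_stages)
        if anchor_baseline:
            z = z - z[0]
        area = float(_segment_areas(z[None, :])[0])
        if area > 1e-6:
            return z / area


def simulate_counts(config: SimConfig) -> tuple[StageSeries, SyntheticTruth]:
    """Generate a count-scale StageSeries and its planted truth.

    DE genes have mean log2 profile = base + sign * effect * shape; non-DE
    genes carry a baseline-anchored smooth deviation whose bounded area is
    drawn from LogNormal(noise_log_mu, noise_log_sigma), which makes the
    gene-level area statistic follow the null exactly.  Counts are
    ``2**log2value`` (continuous, like normalized counts).
    """
    rng = np.random.default_rng(config.seed)
    g, t, r = config.n_genes, config.n_stages, config.n_replicates
    width = len(str(g))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(g)]

    n_de = config.n_de
    if config.frac_de > 0 and n_de < 1:
        raise ConfigurationError("frac_de > 0 but it yields zero DE genes")
    de_idx = np.sort(rng.choice(g, size=n_de, replace=False))
    is_de = np.zeros(g, dtype=bool)
    is_de[de_idx] = True

    breaks_by_shape = config.breaks_by_shape or default_breaks_by_shape(t)
    shape_names = [s for s in SHAPES if config.shape_mix.get(s, 0) > 0]
    shape_w = np.array([config.shape_mix[s] for s in shape_names], dtype=float)
    shape_w = shape_w / shape_w.sum() if shape_names else shape_w

    shapes = np.full(g, "", dtype=object)
    break_stage = np.full(g, -1)
    sign = np.zeros(g, dtype=int)
    log2_mean = np.full((g, t), config.base_expression_log2, dtype=float)

    for i in range(g):
        if is_de[i]:
            s = str(rng.choice(shape_names, p=shape_w))
            allowed = breaks_by_shape.get(s) or (1,)
            b = int(allowed[rng.integers(len(allowed))])
            sg = 1 if rng.random() < 0.5 else -1
            shapes[i] = s
            break_stage[i] = b
            sign[i] = sg
            log2_mean[i] += sg * config.effect_log2 * shape_profile(s, b, t)
        else:
            amp = rng.lognormal(config.noise_log_mu, config.noise_log_sigma)
            log2_mean[i] += amp * _unit_area_shape(rng, t, anchor_baseline=True)

    # antithetic replicate deviations: exact log-normal deviation areas
    deviations = np.zeros((g, t, r))
    n_pairs = r // 2
    for i in range(g):
        perm = rng.permutation(r)
        for j in range(n_pairs):
            amp = rng.lognormal(config.noise_log_mu, config.noise_log_sigma)
            shp = amp * _unit_area_shape(rng, t, anchor_baseline=False)
            deviations[i, :, perm[2 * j]] = shp
            deviations[i, :, perm[2 * j + 1]] = -shp

    # counts stay continuous (normalized counts are not integers); rounding
    # would break the exact antithetic cancellation of replicate noise
    counts = 2.0 ** (log2_mean[:, :, None] + deviations)
    axis = StageAxis(config.stage_labels)
    series = StageSeries(gene_ids, counts, axis, scale="count")

    gene_table = pd.DataFrame(
        {
            "is_de": is_de,
            "shape": [s if d else "" for s, d in zip(shapes, is_de)],
            "break_stage": np.where(is_de, break_stage, -1),
            "sign": np.where(is_de, sign, 0),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    term_table = pd.DataFrame(
        columns=["shape", "break_stage", "sign"], index=pd.Index([], name="term_id")
    )
    return series, SyntheticTruth(gene_table, term_table)


def simulate_annotations(
    config: SimConfig, truth: SyntheticTruth
) -> tuple[AnnotationSet, Hierarchy]:
    """Gene sets whose members share a planted temporal class, plus a hierarchy.

    Each leaf term is assigned a dominant (shape, break, sign) class; a
    fraction ``term_purity`` of its members are DE genes of that class and
    the rest are drawn from the other genes.  Every fifth-ish group of
    leaves is unioned under a parent term, giving an acyclic child->parent
    table.  ``truth.terms`` is filled with the dominant class per term.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = list(truth.genes.index)
    de = truth.genes[truth.genes["is_de"]]

    classes: list[tuple[str, int, int]] = sorted(
        {(row.shape, int(row.break_stage), int(row.sign)) for row in de.itertuples()}
    )
    class_members = {
        c: sorted(de.index[(de["shape"] == c[0]) & (de["break_stage"] == c[1]) & (de["sign"] == c[2])])
        for c in classes
    }

    width = len(str(config.n_terms))
    sets: dict[str, frozenset[str]] = {}
    term_rows = []
    for j in range(config.n_terms):
        term_id = f"T{j + 1:0{width}d}"
        if classes:
            cls = classes[j % len(classes)]
            pool = class_members[cls]
            n_pure = min(int(round(config.term_purity * config.term_size)), len(pool))
            pure = list(rng.choice(pool, size=n_pure, replace=False)) if n_pure else []
        else:
            cls = ("", -1, 0)
            pure = []
        others = [x for x in genes if x not in set(pure)]
        n_fill = config.term_size - len(pure)
        fill = list(rng.choice(others, size=n_fill, replace=False)) if n_fill else []
        sets[term_id] = frozenset(pure + fill)
        term_rows.append((term_id, cls[0], cls[1], cls[2]))

    leaf_ids = sorted(sets)
    edges: list[tuple[str, str]] = []
    for p, start in enumerate(range(0, len(leaf_ids), 5)):
        block = leaf_ids[start : start + 5]
        if len(block) < 2:
            break
        parent_id = f"P{p + 1:03d}"
        union: set[str] = set()
        for child in block:
            union |= sets[child]
            edges.append((child, parent_id))
        sets[parent_id] = frozenset(union)
        term_rows.append((parent_id, "", -1, 0))

    truth.terms = pd.DataFrame(
        [(s, b, g_) for _, s, b, g_ in term_rows],
        columns=["shape", "break_stage", "sign"],
        index=pd.Index([t for t, *_ in term_rows], name="term_id"),
    )
    return AnnotationSet(sets), Hierarchy(tuple(edges))


def make_category_map(truth: SyntheticTruth) -> pd.DataFrame:
    """Map each term to a category named after its dominant shape and sign."""
    rows = []
    for term_id, row in truth.terms.iterrows():
        if row["shape"]:
            label = f"{row['shape']}_{'up' if row['sign'] > 0 else 'down'}"
        else:
            label = "unclassified"
        rows.append((term_id, label, "functional_category"))
    return pd.DataFrame(rows, columns=["term_id", "category", "kind"])
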