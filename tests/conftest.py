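"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from stagewise.preprocess import StageAxis, StageSeries


def brute_force_area(d: np.ndarray) -> float:
    """Independent piecewise-linear area oracle.

    Inserts explicit zero-crossing points into the unit-spaced grid and
    integrates the absolute interpolated profile with the trapezoid rule;
    exact because |interp| is linear between the refined knots.
    """
    d = np.asarray(d, dtype=float)
    xs = [0.0]
    ys = [d[0]]
    for i in range(len(d) - 1):
        a, b = d[i], d[i + 1]
        if a * b < 0:
            t = a / (a - b)
            xs.append(i + t)
            ys.append(0.0)
        xs.append(i + 1.0)
        ys.append(b)
    return float(np.trapezoid(np.abs(ys), xs))


def hypergeom_upper_tail(a: int, b: int, c: int, d: int):
    """Exact P(X >= a) by enumeration over all tables with fixed margins."""
    from fractions import Fraction

    n_total = a + b + c + d
    k_cat = a + c
    n_case = a + b
    lo = max(0, n_case - (n_total - k_cat))
    hi = min(n_case, k_cat)
    total = Fraction(0)
    for x in range(max(a, lo), hi + 1):
        total += Fraction(
            math.comb(k_cat, x) * math.comb(n_total - k_cat, n_case - x),
            math.comb(n_total, n_case),
        )
    return min(total, Fraction(1))


@pytest.fixture
def axis6() -> StageAxis:
    return StageAxis(("S1", "S2", "S3", "S4", "S5", "S6"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_series(values: np.ndarray, axis: StageAxis, scale: str = "count") -> StageSeries:
    values = np.asarray(values, dtype=float)
    genes = [f"g{i + 1:03d}" for i in range(values.shape[0])]
    return StageSeries(genes, values, axis, scale)
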