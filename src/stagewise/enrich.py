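"""Category enrichment of main-pattern gene groups.

Terms retained in temporal patterns are grouped into user-supplied
categories; gene groups defined by MP sign (and, separately, by sign x
break group) are tested for category enrichment with a one-sided
Fisher's exact test, with Benjamini-Hochberg FDR control within each
case family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from stagewise.errors import ConfigurationError, DataError
from stagewise.timebreaks import BreakConfig, MainPattern, NEGATIVE, POSITIVE


@dataclass(frozen=True)
class CategoryMap:
    """term id -> category label, per category kind."""

    table: pd.DataFrame  # columns: term_id, category, kind

    def __post_init__(self) -> None:
        required = {"term_id", "category", "kind"}
        if not required.issubset(self.table.columns):
            raise DataError(f"category map needs columns {sorted(required)}")
        dup = self.table.duplicated(subset=["term_id", "kind"])
        if dup.any():
            bad = self.table.loc[dup, "term_id"].iloc[0]
            raise DataError(f"term {bad!r} maps to more than one category of a kind")

    def kinds(self) -> list[str]:
        return sorted(self.table["kind"].unique())

    def categories(self, kind: str) -> dict[str, list[str]]:
        """category -> sorted term ids, for one kind."""
        sub = self.table[self.table["kind"] == kind]
        return {
            cat: sorted(grp["term_id"]) for cat, grp in sub.groupby("category", sort=True)
        }


def fisher_exact_one_sided(table: tuple[int, int, int, int]) -> tuple[float, float]:
    """One-sided (enrichment) Fisher test on a 2x2 table (a, b, c, d).

    Returns (odds_ratio, p) where p = P(X >= a) for the hypergeometric
    distribution with the table's margins and the odds ratio is
    a*d / (b*c) with an infinity convention for zero denominators.
    """
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise DataError(f"negative counts in table {table}")
    n_total = a + b + c + d
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    # margins: draw the case row (a+b) from a population with (a+c) category members
    p = float(stats.hypergeom.sf(a - 1, n_total, a + c, a + b))
    return odds, min(1.0, p)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def case_gene_sets(
    mps: list[MainPattern], config: BreakConfig
) -> dict[str, set[str]]:
    """Gene groups per case: each sign overall and sign x break group."""
    cases: dict[str, set[str]] = {f"{POSITIVE}_all": set(), f"{NEGATIVE}_all": set()}
    group_labels = sorted(set(config.grouping.values()))
    for sign in (POSITIVE, NEGATIVE):
        for grp in group_labels:
            cases[f"{sign}_{grp}"] = set()
    for mp in mps:
        if mp.sign is None:
            continue
        genes = set(mp.member_genes)
        cases[f"{mp.sign}_all"] |= genes
        grp = config.grouping.get(mp.time_break)
        if grp is not None:
            cases[f"{mp.sign}_{grp}"] |= genes
    return cases


def build_cases(
    mps: list[MainPattern],
    category_map: CategoryMap,
    config: BreakConfig,
    background: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of every (kind, case, category) combination.

    The 2x2 table counts genes of the case group versus the rest of the
    background, split by category membership; a gene belongs to a
    category when any TP term mapping to that category contains it.
    Benjamini-Hochberg q-values are computed within each (kind, case)
    family and ``significant`` flags q < alpha.
    """
    if not background:
        raise ConfigurationError("empty background gene set")
    background = set(background)
    cases = case_gene_sets(mps, config)
    for name, genes in cases.items():
        extra = genes - background
        if extra:
            raise ConfigurationError(
                f"case {name!r} contains genes outside the background: {sorted(extra)[:5]}"
            )

    term_genes: dict[str, set[str]] = {}
    for mp in mps:
        for tp in mp.members:
            term_genes.setdefault(tp.term_id, set()).update(tp.members)

    rows = []
    for kind in category_map.kinds():
        for case_name in sorted(cases):
            case_genes = cases[case_name] & background
            family = []
            for category, terms in category_map.categories(kind).items():
                cat_genes = set()
                for t in terms:
                    cat_genes |= term_genes.get(t, set())
                cat_genes &= background
                a = len(case_genes & cat_genes)
                b = len(case_genes - cat_genes)
                c = len(cat_genes - case_genes)
                d = len(background) - a - b - c
                odds, p = fisher_exact_one_sided((a, b, c, d))
                family.append((kind, case_name, category, a, b, c, d, odds, p))
            if not family:
                continue
            q = bh_adjust(np.array([r[-1] for r in family]))
            for r, qv in zip(family, q):
                rows.append(r + (qv, bool(qv < alpha)))

    return pd.DataFrame(
        rows,
        columns=[
            "kind",
            "case",
            "category",
            "a",
            "b",
            "c",
            "d",
            "odds_ratio",
            "p",
            "q",
            "significant",
        ],
    )
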