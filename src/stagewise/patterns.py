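"""Function-term-specific temporal pattern (TP) clustering.

Seed and candidate genes annotated to the same functional term are
clustered by how well simple linear regression maps their differential
profiles onto a template; terms are processed leaves-first along the
term hierarchy, and genes captured by a TP at a specific term are
removed from the annotation sets of all ancestor terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from stagewise.errors import ConfigurationError, DataError
from stagewise.preprocess import DifferentialProfiles
from stagewise.select import CANDIDATE, SEED


@dataclass(frozen=True)
class AnnotationSet:
    """Mapping of term id to annotated gene set."""

    sets: dict[str, frozenset[str]]
    namespace: str = "GO"

    def restrict(self, universe: set[str]) -> "AnnotationSet":
        """Intersect every term with a gene universe, dropping empty terms."""
        kept = {
            t: frozenset(g & universe)
            for t, g in self.sets.items()
            if g & universe
        }
        return AnnotationSet(kept, self.namespace)

    def __contains__(self, term: str) -> bool:
        return term in self.sets

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.sets[term]


@dataclass(frozen=True)
class Hierarchy:
    """Directed child -> parent edges over term ids; must be acyclic."""

    edges: tuple[tuple[str, str], ...] = ()

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise DataError("term hierarchy contains a cycle")

    def terms(self) -> set[str]:
        return {t for e in self.edges for t in e}


@dataclass(frozen=True)
class ClusterConfig:
    min_r2: float = 0.8
    require_positive_slope: bool = True
    max_iter: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.min_r2 <= 1:
            raise ConfigurationError(f"min_r2 must be in (0, 1], got {self.min_r2}")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")


@dataclass(frozen=True)
class TemporalPattern:
    """A term-specific gene cluster with a mean differential template."""

    term_id: str
    index: int
    members: tuple[str, ...]
    seed_members: tuple[str, ...]
    template: np.ndarray

    @property
    def key(self) -> str:
        return f"{self.term_id}#{self.index}"


def regression_fit(profile: np.ndarray, template: np.ndarray) -> tuple[float, float]:
    """R^2 and slope of the simple linear regression of profile on template."""
    t = np.asarray(template, dtype=float)
    y = np.asarray(profile, dtype=float)
    tc = t - t.mean()
    yc = y - y.mean()
    stt = float(tc @ tc)
    syy = float(yc @ yc)
    if stt <= 0:
        return 0.0, 0.0
    slope = float(tc @ yc) / stt
    if syy <= 0:
        return 1.0, slope  # constant profile: fit exact, slope 0 blocks joining
    r2 = (float(tc @ yc) ** 2) / (stt * syy)
    return r2, slope


def _qualifies(r2: float, slope: float, config: ClusterConfig) -> bool:
    if r2 < config.min_r2:
        return False
    if config.require_positive_slope and not slope > 0:
        return False
    return True


def cluster_term(
    profiles: dict[str, np.ndarray],
    seeds: set[str],
    config: ClusterConfig | None = None,
    seed_order: dict[str, float] | None = None,
    term_id: str = "",
) -> list[TemporalPattern]:
    """Greedy template clustering of one term's annotated genes.

    Seeds are visited in increasing ``seed_order`` value (p-value; gene id
    breaks ties); a seed that fits no existing template founds a new TP.
    Membership is then re-evaluated against mean templates until stable
    or ``max_iter``: every gene joins the best-fitting TP with
    R^2 >= min_r2 and positive slope, a seed fitting nothing founds a new
    TP, candidates fitting nothing stay unassigned.  TPs that end up
    without a seed are dropped.
    """
    config = config or ClusterConfig()
    seeds = set(seeds) & set(profiles)
    if not seeds:
        return []
    order = seed_order or {}
    seed_list = sorted(seeds, key=lambda gid: (order.get(gid, 0.0), gid))
    gene_list = sorted(profiles)

    templates: list[np.ndarray] = []
    members: list[set[str]] = []
    for s in seed_list:
        best = _best_fit(profiles[s], templates, config)
        if best is None:
            templates.append(np.array(profiles[s], dtype=float))
            members.append({s})
        else:
            members[best].add(s)

    for _ in range(config.max_iter):
        templates = [
            np.mean([profiles[g] for g in sorted(ms)], axis=0) if ms else tpl
            for tpl, ms in zip(templates, members)
        ]
        new_members: list[set[str]] = [set() for _ in templates]
        for g in gene_list:
            best = _best_fit(profiles[g], templates, config)
            if best is not None:
                new_members[best].add(g)
            elif g in seeds:
                templates.append(np.array(profiles[g], dtype=float))
                new_members.append({g})
        if new_members == members:
            break
        members = new_members

    out = []
    idx = 0
    for ms in members:
        seed_ms = tuple(sorted(ms & seeds))
        if not seed_ms:
            continue
        member_tuple = tuple(sorted(ms))
        template = np.mean([profiles[g] for g in member_tuple], axis=0)
        out.append(TemporalPattern(term_id, idx, member_tuple, seed_ms, template))
        idx += 1
    return out


def _best_fit(
    profile: np.ndarray, templates: list[np.ndarray], config: ClusterConfig
) -> int | None:
    best_k, best_r2 = None, -1.0
    for k, tpl in enumerate(templates):
        r2, slope = regression_fit(profile, tpl)
        if _qualifies(r2, slope, config) and r2 > best_r2:
            best_k, best_r2 = k, r2
    return best_k


@dataclass
class PatternResult:
    patterns: list[TemporalPattern]
    de_genes: set[str]
    skipped_terms: list[str] = field(default_factory=list)


def find_patterns(
    selection: pd.DataFrame,
    profiles: DifferentialProfiles,
    annotations: AnnotationSet,
    hierarchy: Hierarchy | None = None,
    config: ClusterConfig | None = None,
) -> PatternResult:
    """Cluster every annotated term leaves-first and collect DE genes.

    ``selection`` is the per-gene table from :func:`stagewise.select.select_genes`
    (columns ``p`` and ``label``).  Terms present in the hierarchy are
    processed in reverse topological order (children before parents, term
    id breaking ties); after a term is clustered, its TP members are
    removed from the annotation sets of all its ancestors.  Terms outside
    the hierarchy are processed afterwards in term-id order, without any
    gene removal.  DE genes are all seeds plus every candidate belonging
    to at least one TP.
    """
    config = config or ClusterConfig()
    hierarchy = hierarchy or Hierarchy()
    hierarchy.validate()

    labels = selection["label"]
    seeds = set(labels.index[labels == SEED])
    candidates = set(labels.index[labels == CANDIDATE])
    universe = seeds | candidates
    pmap = selection["p"].to_dict()
    profile_map = {g: m for g, m in zip(profiles.genes, profiles.matrix) if g in universe}

    ann = annotations.restrict(universe)
    graph = hierarchy.graph()
    hier_terms = [
        t for t in nx.lexicographical_topological_sort(graph) if t in ann
    ]
    flat_terms = sorted(set(ann.sets) - set(graph.nodes))
    removed: dict[str, set[str]] = {}

    patterns: list[TemporalPattern] = []
    skipped: list[str] = []
    for term in hier_terms + flat_terms:
        genes_t = set(ann[term]) - removed.get(term, set())
        seeds_t = genes_t & seeds
        if not seeds_t:
            skipped.append(term)
            continue
        term_profiles = {g: profile_map[g] for g in genes_t}
        tps = cluster_term(term_profiles, seeds_t, config, pmap, term_id=term)
        patterns.extend(tps)
        if term in graph.nodes:
            captured = set().union(*(set(tp.members) for tp in tps)) if tps else set()
            for anc in nx.descendants(graph, term):
                removed.setdefault(anc, set()).update(captured)

    in_tp = set().union(*(set(tp.members) for tp in patterns)) if patterns else set()
    de_genes = seeds | (candidates & in_tp)
    return PatternResult(patterns, de_genes, skipped)
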