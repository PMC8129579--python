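"""Time-break assignment and main-pattern (MP) summarization.

A stage is a candidate break for a TP when the profile changes by more
than a threshold fraction (default 20%) of the pattern mean between the
stage and one of its neighbours; the main break is the candidate with
the largest deviation from baseline.  TPs sharing a main break are
clustered into MPs with the same template-clustering operator used for
genes, and each MP is classified positive or negative by its sign at
the break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stagewise.errors import ConfigurationError
from stagewise.patterns import ClusterConfig, TemporalPattern, cluster_term

POSITIVE = "positive"
NEGATIVE = "negative"


def default_grouping(n_stages: int) -> dict[int, str]:
    """Stage-index -> break-group labels: x2 embryonic, x3-x4 nascent, rest older."""
    groups = {1: "embryonic"}
    for i in range(2, n_stages):
        groups[i] = "nascent" if i <= 3 else "older"
    return groups


@dataclass(frozen=True)
class BreakConfig:
    threshold: float = 0.2
    search_start: int = 1  # 0-based stage index of the first searchable stage
    grouping: dict[int, str] = field(default_factory=lambda: default_grouping(6))
    pattern_mean: str = "abs"  # "abs" or "signed"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ConfigurationError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.search_start < 1:
            raise ConfigurationError("search must start at or after the second stage")
        if self.pattern_mean not in ("abs", "signed"):
            raise ConfigurationError(f"unknown pattern_mean mode {self.pattern_mean!r}")


@dataclass(frozen=True)
class BreakAssignment:
    tp: TemporalPattern | None
    template: np.ndarray
    candidate_breaks: tuple[int, ...]
    main_break: int | None
    pattern_mean: float

    @property
    def classifiable(self) -> bool:
        return self.main_break is not None


@dataclass(frozen=True)
class MainPattern:
    mp_id: str
    members: tuple[TemporalPattern, ...]
    profile: np.ndarray
    time_break: int
    sign: str | None

    @property
    def member_genes(self) -> tuple[str, ...]:
        return tuple(sorted({g for tp in self.members for g in tp.members}))


def assign_time_breaks(
    tp: TemporalPattern | np.ndarray, config: BreakConfig | None = None
) -> BreakAssignment:
    """Find candidate breaks of a TP template and select the main one.

    The pattern mean is the mean of |TP(x)| over all stages (signed mode
    available via config).  Stage i (from ``search_start`` on) is a
    candidate when the change from the previous or to the next stage
    exceeds ``threshold`` times the pattern mean; the last stage uses its
    backward difference and, failing that, the difference to the latest
    previously identified break.
    """
    config = config or BreakConfig()
    pattern = tp if isinstance(tp, TemporalPattern) else None
    d = np.asarray(tp.template if pattern else tp, dtype=float)
    t = d.size
    tpbar = float(np.abs(d).mean()) if config.pattern_mean == "abs" else float(d.mean())
    if tpbar == 0:
        return BreakAssignment(pattern, d, (), None, 0.0)

    thr = config.threshold
    candidates: list[int] = []
    for i in range(config.search_start, t):
        backward = abs(d[i] - d[i - 1]) / abs(tpbar) > thr
        if i < t - 1:
            forward = abs(d[i + 1] - d[i]) / abs(tpbar) > thr
            if backward or forward:
                candidates.append(i)
        else:
            versus_break = bool(candidates) and (
                abs(d[i] - d[candidates[-1]]) / abs(tpbar) > thr
            )
            if backward or versus_break:
                candidates.append(i)

    if not candidates:
        return BreakAssignment(pattern, d, (), None, tpbar)
    main = _main_break(d, candidates)
    return BreakAssignment(pattern, d, tuple(candidates), main, tpbar)


def _main_break(d: np.ndarray, candidates: list[int]) -> int:
    return max(candidates, key=lambda i: (abs(d[i]), -i))


def select_main_break(assignment: BreakAssignment) -> int:
    """Candidate break with the largest |TP| (ties go to the earlier stage)."""
    if not assignment.candidate_breaks:
        raise ConfigurationError("no candidate breaks: TP is unclassifiable")
    return _main_break(assignment.template, list(assignment.candidate_breaks))


def summarize_main_patterns(
    assignments: list[BreakAssignment],
    config: ClusterConfig | None = None,
) -> tuple[list[MainPattern], list[BreakAssignment]]:
    """Cluster TP templates within each break group into main patterns.

    Returns the MPs (ordered by break stage, then cluster index) and the
    unclassifiable assignments (no break).  Every cluster is retained, so
    singleton TPs become singleton MPs.
    """
    config = config or ClusterConfig()
    unclassified = [a for a in assignments if not a.classifiable]
    by_break: dict[int, list[BreakAssignment]] = {}
    for a in assignments:
        if a.classifiable:
            by_break.setdefault(a.main_break, []).append(a)

    mps: list[MainPattern] = []
    counter = 0
    for brk in sorted(by_break):
        group = sorted(by_break[brk], key=lambda a: a.tp.key if a.tp else "")
        profiles = {
            (a.tp.key if a.tp else f"tp{k}"): np.asarray(a.template, dtype=float)
            for k, a in enumerate(group)
        }
        keys = sorted(profiles)
        order = {k: float(i) for i, k in enumerate(keys)}
        clusters = cluster_term(profiles, set(keys), config, order, term_id=f"break{brk}")
        tp_by_key = {(a.tp.key if a.tp else f"tp{k}"): a.tp for k, a in enumerate(group)}
        for cl in clusters:
            counter += 1
            member_tps = tuple(
                tp_by_key[k] for k in cl.members if tp_by_key.get(k) is not None
            )
            profile = np.mean([profiles[k] for k in cl.members], axis=0)
            mp = MainPattern(
                mp_id=f"MP{counter:03d}",
                members=member_tps,
                profile=profile,
                time_break=brk,
                sign=None,
            )
            mps.append(
                MainPattern(mp.mp_id, mp.members, mp.profile, brk, classify_mp_sign(mp))
            )
    return mps, unclassified


def classify_mp_sign(mp: MainPattern) -> str | None:
    """Positive iff the MP profile is above baseline at its time break."""
    value = float(mp.profile[mp.time_break])
    if value > 0:
        return POSITIVE
    if value < 0:
        return NEGATIVE
    return None
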