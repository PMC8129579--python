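"""Readers and writers for the plain-text formats used by the pipeline.

Counts travel as TSV with a ``gene_id`` column followed by
``<stage>_<replicate>`` columns; gene sets as GMT; the term hierarchy as
a two-column child/parent TSV; category maps as three-column TSV; run
manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from stagewise.enrich import CategoryMap
from stagewise.errors import ParseError
from stagewise.patterns import AnnotationSet, Hierarchy
from stagewise.preprocess import StageAxis, StageSeries

FLOAT_FORMAT = "%.10g"


def write_counts(series: StageSeries, path: str | Path) -> None:
    cols = {}
    for t, stage in enumerate(series.axis.stages):
        for r in range(series.n_replicates):
            cols[f"{stage}_{r + 1}"] = series.values[:, t, r]
    frame = pd.DataFrame(cols, index=pd.Index(series.genes, name="gene_id"))
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_counts(
    path: str | Path,
    stage_order: list[str] | None = None,
    scale: str = "count",
) -> StageSeries:
    """Parse a counts TSV into a StageSeries.

    Stage order follows ``stage_order`` when given, otherwise the order of
    first appearance in the header.  Every stage must carry the same
    number of replicates.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if frame.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id', got {frame.columns[0]!r}")
    genes = frame["gene_id"].tolist()
    dup = frame["gene_id"][frame["gene_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax()) + 2
        raise ParseError(f"{path}: missing values (ragged row near line {row})")

    stage_reps: dict[str, list[tuple[int, str]]] = {}
    for col in frame.columns[1:]:
        if "_" not in col:
            raise ParseError(f"{path}: column {col!r} is not of the form <stage>_<rep>")
        stage, rep = col.rsplit("_", 1)
        if not rep.isdigit():
            raise ParseError(f"{path}: column {col!r} has a non-numeric replicate tag")
        stage_reps.setdefault(stage, []).append((int(rep), col))

    if stage_order is None:
        stage_order = list(stage_reps)
    else:
        unknown = set(stage_reps) - set(stage_order)
        if unknown:
            raise ParseError(f"{path}: unknown stage labels {sorted(unknown)}")
        missing = set(stage_order) - set(stage_reps)
        if missing:
            raise ParseError(f"{path}: stages {sorted(missing)} missing from header")

    rep_counts = {s: len(v) for s, v in stage_reps.items()}
    if len(set(rep_counts.values())) != 1:
        raise ParseError(f"{path}: unequal replicate counts per stage: {rep_counts}")

    n_rep = next(iter(rep_counts.values()))
    values = np.empty((len(genes), len(stage_order), n_rep))
    for t, stage in enumerate(stage_order):
        for r, (_, col) in enumerate(sorted(stage_reps[stage])):
            values[:, t, r] = frame[col].to_numpy(dtype=float)
    return StageSeries(genes, values, StageAxis(tuple(stage_order)), scale)


def write_gmt(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotations.sets):
            genes = "\t".join(sorted(annotations.sets[term]))
            fh.write(f"{term}\t{annotations.namespace}\t{genes}\n")


def read_gmt(path: str | Path, namespace: str = "GO") -> AnnotationSet:
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT rows need term, description, genes")
            term = parts[0]
            if term in sets:
                raise ParseError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = frozenset(g for g in parts[2:] if g)
    return AnnotationSet(sets, namespace)


def write_hierarchy(hierarchy: Hierarchy, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("child\tparent\n")
        for child, parent in sorted(hierarchy.edges):
            fh.write(f"{child}\t{parent}\n")


def read_hierarchy(path: str | Path) -> Hierarchy:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns) != ["child", "parent"]:
        raise ParseError(f"{path}: expected columns child, parent")
    edges = tuple(
        (str(c), str(p)) for c, p in zip(frame["child"], frame["parent"])
    )
    hierarchy = Hierarchy(edges)
    hierarchy.validate()
    return hierarchy


def write_category_map(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_category_map(path: str | Path) -> CategoryMap:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "kind" not in frame.columns:
        frame["kind"] = "functional_category"
    return CategoryMap(frame[["term_id", "category", "kind"]])


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
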