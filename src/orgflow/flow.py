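"""Fold-change annotation of metabolic-pathway topologies.

A pathway is a directed reaction graph whose nodes (enzymes, labelled by
EC number or gene name) map to zero or more scaffolds of the assembly.
Given a normalized expression matrix and a split of the samples into a
*target* group and a *reference* group, each node is labelled with:

* a direction — which group expresses it more;
* a fold tier, following the arrow convention: one arrow for > 2-fold,
  two for > 10-fold, three for > 100-fold, and ``≈`` within 2-fold;
* the sample with the highest expression of the node;
* an absent flag when no mapped scaffold carries expression.

Coordinated tiers along consecutive reactions let a reader trace the
likely direction of substance flow through the network.  Comparisons are
strict ("more than 2-fold"): a node at exactly 2.0-fold is ``≈``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .counts import ValidationError

__all__ = [
    "PathwayGraph",
    "read_pathway",
    "FlowAnnotation",
    "node_expression",
    "fold_class",
    "annotate_pathway",
    "annotation_table",
    "to_dot",
    "TIER_THRESHOLDS",
]

TIER_THRESHOLDS = (2.0, 10.0, 100.0)  # strict lower bounds for tiers 1..3
TIER_GLYPHS = {0: "≈", 1: "↑", 2: "↑↑", 3: "↑↑↑"}

TARGET_UP = "target_up"
REF_UP = "ref_up"
APPROX = "approx"


@dataclass
class PathwayGraph:
    """Directed reaction topology with scaffold mappings per node."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        for node, data in self.graph.nodes(data=True):
            data.setdefault("label", str(node))
            data.setdefault("scaffolds", [])
        for u, v in self.graph.edges():
            if u not in self.graph or v not in self.graph:  # pragma: no cover
                raise ValidationError(f"edge ({u}, {v}) references unknown node")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def scaffolds_of(self, node: str) -> list[str]:
        return list(self.graph.nodes[node]["scaffolds"])


def read_pathway(nodes_tsv, edges_tsv) -> PathwayGraph:
    """Build a pathway from a node table and an edge table.

    Node TSV columns: ``node_id``, ``label``, ``scaffold_ids``
    (comma-joined, may be empty).  Edge TSV columns: ``from``, ``to``
    and optionally ``metabolite``.
    """
    nodes = pd.read_csv(nodes_tsv, sep="\t", dtype=str).fillna("")
    edges = pd.read_csv(edges_tsv, sep="\t", dtype=str).fillna("")
    g = nx.DiGraph()
    for _, row in nodes.iterrows():
        scaffolds = [s for s in str(row["scaffold_ids"]).split(",") if s]
        g.add_node(str(row["node_id"]), label=str(row["label"]),
                   scaffolds=scaffolds)
    for _, row in edges.iterrows():
        u, v = str(row["from"]), str(row["to"])
        if u not in g or v not in g:
            raise ValidationError(f"edge ({u}, {v}) references unknown node")
        g.add_edge(u, v, metabolite=str(row.get("metabolite", "")))
    return PathwayGraph(graph=g)


@dataclass
class FlowAnnotation:
    """Per-node comparison of target versus reference expression."""

    node: str
    target_level: float
    ref_level: float
    fold: float               # >= 1 after orientation; inf if one side is 0
    direction: str            # target_up | ref_up | approx
    tier: int                 # 0 (≈), 1 (>2x), 2 (>10x), 3 (>100x)
    max_sample: str | None
    absent: bool = False

    @property
    def glyph(self) -> str:
        return TIER_GLYPHS[self.tier] if not self.absent else "∅"


def node_expression(pathway: PathwayGraph, normalized: pd.DataFrame
                    ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Sum mapped scaffold levels per node per sample.

    Returns the node × sample level table and a report of scaffold IDs
    that could not be resolved in the matrix (not fatal).
    """
    levels = {}
    unresolved: dict[str, list[str]] = {}
    for node in pathway.nodes:
        scaffolds = pathway.scaffolds_of(node)
        known = [s for s in scaffolds if s in normalized.index]
        missing = [s for s in scaffolds if s not in normalized.index]
        if missing:
            unresolved[node] = missing
        if known:
            levels[node] = normalized.loc[known].sum(axis=0)
        else:
            levels[node] = pd.Series(0.0, index=normalized.columns)
    table = pd.DataFrame(levels).T.reindex(pathway.nodes)
    table.columns = normalized.columns
    return table, unresolved


def fold_class(target_levels: pd.Series, ref_levels: pd.Series,
               aggregate: str = "mean", node: str = "") -> FlowAnnotation:
    """Classify one node's target-vs-reference fold change.

    Group levels are aggregated by mean (default) or max, the fold is
    the larger aggregate over the smaller, and the tier follows the
    strict thresholds >2, >10, >100.  A zero denominator with a non-zero
    numerator is an infinite fold (tier 3).  ``max_sample`` is the
    highest-expressing sample across both groups (first on ties).
    """
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    agg = pd.Series.mean if aggregate == "mean" else pd.Series.max
    t = float(agg(target_levels))
    r = float(agg(ref_levels))
    all_levels = pd.concat([target_levels, ref_levels])
    if t == 0.0 and r == 0.0:
        return FlowAnnotation(node=node, target_level=0.0, ref_level=0.0,
                              fold=float("nan"), direction=APPROX, tier=0,
                              max_sample=None, absent=True)
    max_sample = str(all_levels.idxmax())
    if r == 0.0 or t == 0.0:
        direction = TARGET_UP if t > r else REF_UP
        return FlowAnnotation(node=node, target_level=t, ref_level=r,
                              fold=math.inf, direction=direction, tier=3,
                              max_sample=max_sample)
    fold = max(t, r) / min(t, r)
    tier = sum(fold > thr for thr in TIER_THRESHOLDS)
    if tier == 0:
        direction = APPROX
    else:
        direction = TARGET_UP if t > r else REF_UP
    return FlowAnnotation(node=node, target_level=t, ref_level=r, fold=fold,
                          direction=direction, tier=tier,
                          max_sample=max_sample)


def annotate_pathway(pathway: PathwayGraph, normalized: pd.DataFrame,
                     target_samples: list[str], ref_samples: list[str],
                     aggregate: str = "mean"
                     ) -> dict[str, FlowAnnotation]:
    """Annotate every node of the pathway with its fold class."""
    samples = set(normalized.columns)
    for group, name in ((target_samples, "target"), (ref_samples, "reference")):
        if not group:
            raise ValidationError(f"{name} sample group is empty")
        unknown = [s for s in group if s not in samples]
        if unknown:
            raise ValidationError(f"unknown {name} samples: {unknown}")
    if set(target_samples) & set(ref_samples):
        raise ValidationError("target and reference groups must be disjoint")
    levels, _unresolved = node_expression(pathway, normalized)
    annotations = {}
    for node in pathway.nodes:
        row = levels.loc[node]
        annotations[node] = fold_class(row[target_samples], row[ref_samples],
                                       aggregate=aggregate, node=node)
    return annotations


def annotation_table(annotations: dict[str, FlowAnnotation]) -> pd.DataFrame:
    """Flat TSV-ready table of one row per node."""
    rows = []
    for node, ann in annotations.items():
        rows.append({
            "node": node,
            "target_level": ann.target_level,
            "ref_level": ann.ref_level,
            "fold": ann.fold,
            "direction": ann.direction,
            "tier": ann.tier,
            "glyph": ann.glyph,
            "max_sample": ann.max_sample if ann.max_sample else "",
            "absent": ann.absent,
        })
    return pd.DataFrame(rows).set_index("node")


_DIR_COLOR = {TARGET_UP: "red", REF_UP: "green", APPROX: "gray50"}


def to_dot(pathway: PathwayGraph,
           annotations: dict[str, FlowAnnotation]) -> str:
    """GraphViz DOT rendering with arrow glyph and sample letter per node."""
    lines = ["digraph pathway {", '  node [shape=box];']
    for node in pathway.nodes:
        ann = annotations[node]
        label = pathway.graph.nodes[node]["label"]
        glyph = ann.glyph
        tag = f" {ann.max_sample}" if ann.max_sample else ""
        color = _DIR_COLOR.get(ann.direction, "black")
        lines.append(
            f'  "{node}" [label="{label}\\n{glyph}{tag}", color={color}];'
        )
    for u, v, data in pathway.graph.edges(data=True):
        met = data.get("metabolite", "")
        attr = f' [label="{met}"]' if met else ""
        lines.append(f'  "{u}" -> "{v}"{attr};')
    lines.append("}")
    return "\n".join(lines)
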