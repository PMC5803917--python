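"""Expression overlay onto pathway interaction graphs.

Each pathway gene is assigned a discrete state per fold-change column —
``up`` (log2FC >= +cutoff), ``down`` (log2FC <= -cutoff), ``unchanged``
or ``not_measured`` — so the signed interaction edges of a pathway can be
read together with the direction of transcriptional change.  The
continuous log2 fold change is retained as a node attribute.  Exports are
plain TSVs plus GraphML for external graph viewers; no rendering is done
here.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import networkx as nx
import pandas as pd

from .errors import ConfigError, DataError
from .diffexp import FoldChangeTable
from .knowledge_base import InteractionEdge, KnowledgeBase

STATE_UP = "up"
STATE_DOWN = "down"
STATE_UNCHANGED = "unchanged"
STATE_NOT_MEASURED = "not_measured"


@dataclass
class OverlayGraph:
    """A pathway's genes with per-column states plus its interaction edges.

    ``log2fc`` is a pathway-gene × column frame (NaN where not measured);
    ``states`` is the parallel frame of discrete state strings.
    """

    pathway: str
    cutoff: float
    log2fc: pd.DataFrame
    states: pd.DataFrame
    edges: list[InteractionEdge]

    @property
    def genes(self) -> list[str]:
        return list(self.states.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.states.columns)


def _state(value: float, cutoff: float) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return STATE_NOT_MEASURED
    if value >= cutoff:
        return STATE_UP
    if value <= -cutoff:
        return STATE_DOWN
    return STATE_UNCHANGED


def overlay(
    pathway_name: str,
    kb: KnowledgeBase,
    fc: FoldChangeTable,
    cutoff: float = 1.0,
) -> OverlayGraph:
    """Assign a state to every pathway gene in every fold-change column.

    The state discretization matches DEG calling exactly, so the ``up``
    genes of a column are the pathway's intersection with that column's
    up-regulated DEG set at the same cutoff.
    """
    if pathway_name not in kb:
        raise DataError(f"unknown pathway {pathway_name!r}")
    if not cutoff > 0:
        raise ConfigError(f"overlay cutoff must be > 0, got {cutoff}")
    genes = sorted(kb[pathway_name].genes)
    log2fc = fc.values.reindex(genes)[fc.values.columns]
    states = log2fc.map(lambda v: _state(v, cutoff))
    return OverlayGraph(
        pathway=pathway_name,
        cutoff=cutoff,
        log2fc=log2fc,
        states=states,
        edges=kb.edges_of(pathway_name),
    )


_SIGN_TO_RELATION = {"activation": "activates", "inhibition": "inhibits", "unspecified": "interacts"}


def export_overlay(g: OverlayGraph, out_dir) -> dict[str, str]:
    """Write node/edge TSVs and a GraphML file; returns the paths written.

    The node table has one row per (gene, column); the GraphML graph
    carries per-column ``state__<col>`` / ``log2fc__<col>`` node
    attributes and a ``sign`` edge attribute, readable by standard graph
    viewers.  Output is deterministic for fixed inputs.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    slug = g.pathway.replace(" ", "_").lower()
    nodes_path = os.path.join(out_dir, f"{slug}_nodes.tsv")
    edges_path = os.path.join(out_dir, f"{slug}_edges.tsv")
    graph_path = os.path.join(out_dir, f"{slug}.graphml")
    try:
        with open(nodes_path, "wt", encoding="utf-8") as fh:
            fh.write("gene\tcolumn\tlog2fc\tstate\n")
            for gene in g.genes:
                for col in g.column_ids:
                    value = g.log2fc.at[gene, col]
                    text = "" if pd.isna(value) else f"{value:.6g}"
                    fh.write(f"{gene}\t{col}\t{text}\t{g.states.at[gene, col]}\n")
        with open(edges_path, "wt", encoding="utf-8") as fh:
            fh.write("source\trelation\ttarget\n")
            for e in g.edges:
                fh.write(f"{e.source}\t{_SIGN_TO_RELATION[e.sign]}\t{e.target}\n")
        graph = nx.DiGraph(pathway=g.pathway, cutoff=g.cutoff)
        for gene in g.genes:
            attrs = {}
            for col in g.column_ids:
                attrs[f"state__{col}"] = g.states.at[gene, col]
                value = g.log2fc.at[gene, col]
                if not pd.isna(value):
                    attrs[f"log2fc__{col}"] = float(value)
            graph.add_node(gene, **attrs)
        for e in g.edges:
            graph.add_edge(e.source, e.target, sign=e.sign)
        nx.write_graphml(graph, graph_path)
    except OSError as exc:
        raise DataError(f"failed writing overlay under {out_dir!r}: {exc}") from exc
    return {"nodes": nodes_path, "edges": edges_path, "graphml": graph_path}


def read_overlay_nodes(path) -> pd.DataFrame:
    """Re-parse an exported node table (round-trip partner of export_overlay)."""
    return pd.read_csv(path, sep="\t", dtype={"gene": str, "column": str, "state": str})


def profile_table(genes, fc: FoldChangeTable) -> pd.DataFrame:
    """Gene × column log2FC table restricted to the requested genes.

    Duplicates in the request are collapsed (first occurrence order kept);
    genes absent from the fold-change table appear as all-NaN rows, i.e.
    not measured.
    """
    ordered = list(dict.fromkeys(g.upper() for g in genes))
    out = fc.values.reindex(ordered)
    out.index.name = "gene"
    return out
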