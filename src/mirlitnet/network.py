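"""The bipartite miRNA-disease association network.

miRNAs and disease/identifier groups are the two node classes; each scored
association contributes one edge weighted by its Fisher p-value (and its
-log10, for strength rendering in downstream viewers) plus the supporting
paper count. Node count is therefore |unique miRNAs| + |unique groups| and
edge count equals the number of association records.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Sequence

import networkx as nx

from .errors import StructureError
from .stats import AssociationRecord
from .xgmml import read_xgmml, write_xgmml

EXPORT_FORMATS = ("graphml", "sif", "xgmml", "edge_tsv")


def build_bipartite(records: Sequence[AssociationRecord]) -> nx.Graph:
    """Bipartite association graph; duplicate (miRNA, group) records are
    rejected rather than silently merged."""
    seen: set[tuple[str, str]] = set()
    graph = nx.Graph()
    for r in records:
        key = (r.mirna_id, r.disease_group)
        if key in seen:
            raise StructureError(f"duplicate association record for pair {key}")
        seen.add(key)
        for name, role in ((r.mirna_id, "mirna"), (r.disease_group, "disease")):
            if name in graph and graph.nodes[name]["role"] != role:
                raise StructureError(
                    f"name {name!r} appears as both a miRNA and a disease group"
                )
            graph.add_node(name, role=role)
        graph.add_edge(
            r.mirna_id,
            r.disease_group,
            p_value=r.p_value,
            paper_count=r.paper_count,
            neg_log10_p=-math.log10(r.p_value) if r.p_value > 0 else math.inf,
        )
    validate_bipartite(graph)
    return graph


def validate_bipartite(graph: nx.Graph) -> None:
    """Structural checks: two roles, edges strictly across roles, no
    isolated nodes."""
    for node, data in graph.nodes(data=True):
        if data.get("role") not in ("mirna", "disease"):
            raise StructureError(f"node {node!r} lacks a valid role attribute")
        if graph.degree(node) == 0:
            raise StructureError(f"isolated node {node!r}")
    for u, v in graph.edges:
        if graph.nodes[u]["role"] == graph.nodes[v]["role"]:
            raise StructureError(f"edge {u!r}-{v!r} joins two {graph.nodes[u]['role']} nodes")


def export_network(graph: nx.Graph, fmt: str, path: str | Path) -> Path:
    """Serialize to graphml/xgmml (lossless) or sif/edge_tsv (topology+weight)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    elif fmt == "xgmml":
        write_xgmml(graph, path, label=graph.graph.get("label", "association network"))
    elif fmt == "sif":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for u, v in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
                rel = graph.edges[u, v].get("relation", "assoc")
                fh.write(f"{u}\t{rel}\t{v}\n")
            for node in sorted(nx.isolates(graph), key=str):
                fh.write(f"{node}\n")
    elif fmt == "edge_tsv":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("source\ttarget\tp_value\tpaper_count\n")
            for u, v in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
                d = graph.edges[u, v]
                p = d.get("p_value", "")
                p = f"{p:.6E}" if isinstance(p, float) else p
                fh.write(f"{u}\t{v}\t{p}\t{d.get('paper_count', '')}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}; expected one of {EXPORT_FORMATS}")
    return path


def import_network(fmt: str, path: str | Path) -> nx.Graph:
    """Re-import a graphml or xgmml export (lossless round-trip formats)."""
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "xgmml":
        return read_xgmml(path)
    raise ValueError(f"format {fmt!r} is not round-trippable (use graphml or xgmml)")


def read_edge_tsv(path: str | Path) -> list[tuple[str, str, float, int]]:
    rows = []
    with Path(path).open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append((row["source"], row["target"],
                         float(row["p_value"]), int(row["paper_count"])))
    return rows
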