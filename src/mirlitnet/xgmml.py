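"""Minimal XGMML (eXtensible Graph Markup and Modeling Language) I/O.

XGMML is the XML dialect Cytoscape-ecosystem tools exchange networks in.
This writer/reader covers the subset needed for association and regulatory
interaction networks: labelled nodes and edges with string/real/integer
attributes. Round-trips are lossless for that subset.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
from lxml import etree

from .errors import ParseError

XGMML_NS = "http://www.cs.rpi.edu/XGMML"

_TYPE_NAMES = {str: "string", float: "real", int: "integer", bool: "boolean"}


def _att_elem(parent, name: str, value) -> None:
    t = _TYPE_NAMES.get(type(value), "string")
    if isinstance(value, bool):
        value = str(value).lower()
    elif isinstance(value, float):
        value = repr(value)
    etree.SubElement(parent, f"{{{XGMML_NS}}}att",
                     name=name, type=t, value=str(value))


def write_xgmml(graph: nx.Graph, path: str | Path, label: str = "network") -> None:
    directed = "1" if graph.is_directed() else "0"
    root = etree.Element(f"{{{XGMML_NS}}}graph", nsmap={None: XGMML_NS},
                         label=label, directed=directed)
    ids = {node: str(i) for i, node in enumerate(sorted(graph.nodes, key=str))}
    for node in sorted(graph.nodes, key=str):
        el = etree.SubElement(root, f"{{{XGMML_NS}}}node",
                              id=ids[node], label=str(node))
        for k, v in sorted(graph.nodes[node].items()):
            _att_elem(el, k, v)
    sep = "->" if graph.is_directed() else "-"
    for u, v in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
        el = etree.SubElement(root, f"{{{XGMML_NS}}}edge",
                              source=ids[u], target=ids[v],
                              label=f"{u} {sep} {v}")
        for k, val in sorted(graph.edges[u, v].items()):
            _att_elem(el, k, val)
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


def _parse_att(el) -> tuple[str, object]:
    name = el.get("name")
    t = el.get("type", "string")
    raw = el.get("value", "")
    if t == "real":
        return name, float(raw)
    if t == "integer":
        return name, int(raw)
    if t == "boolean":
        return name, raw == "true"
    return name, raw


def read_xgmml(path: str | Path) -> nx.Graph:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: malformed XGMML ({exc})") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "graph":
        raise ParseError(f"{path}: root element is not <graph>")
    directed = root.get("directed") in ("1", "true", "yes")
    graph: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    graph.graph["label"] = root.get("label", "")
    by_id: dict[str, str] = {}
    for el in root:
        tag = etree.QName(el).localname
        if tag == "node":
            label = el.get("label", el.get("id"))
            by_id[el.get("id")] = label
            attrs = dict(_parse_att(a) for a in el if etree.QName(a).localname == "att")
            graph.add_node(label, **attrs)
        elif tag == "edge":
            src, tgt = el.get("source"), el.get("target")
            if src not in by_id or tgt not in by_id:
                line = el.sourceline
                raise ParseError(
                    f"{path}:{line}: edge references unknown node id "
                    f"{src if src not in by_id else tgt!r}"
                )
            attrs = dict(_parse_att(a) for a in el if etree.QName(a).localname == "att")
            graph.add_edge(by_id[src], by_id[tgt], **attrs)
    return graph
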