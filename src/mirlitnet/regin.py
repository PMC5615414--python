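"""Regulatory interaction network (RegIN) extension and overlap filtering.

A RegIN is a directed regulator->target edge list from one source database
(e.g. an experimentally validated MTI collection and two prediction
databases). Seed miRNAs (as accessions) are extended with their targets
and/or regulators across all loaded RegINs; each extended edge carries the
set of source databases supporting it. The overlap threshold retains only
edges supported by at least k sources ("or more"), and hide/show
temporarily masks sources without destroying the underlying support sets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, ParseError
from .xgmml import read_xgmml, write_xgmml

DIRECTIONS = ("targets", "regulators", "both")


@dataclass(frozen=True)
class RegIN:
    """One source database's directed (regulator accession, target gene) edges."""

    source_name: str
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for reg, tgt in self.edges:
            if not reg or not tgt:
                raise ParseError(
                    f"RegIN {self.source_name!r}: empty identifier in edge {(reg, tgt)!r}"
                )

    def targets_of(self, regulator: str) -> frozenset[str]:
        return frozenset(t for r, t in self.edges if r == regulator)

    def regulators_of(self, target: str) -> frozenset[str]:
        return frozenset(r for r, t in self.edges if t == target)


def load_regin(path: str | Path, dialect: str = "tsv",
               source_name: str | None = None) -> RegIN:
    """Load a RegIN from a 3-column TSV (regulator, target, source) or XGMML.

    The source label comes from the file's own metadata (source column /
    graph label) falling back to the file name stem.
    """
    path = Path(path)
    if dialect == "tsv":
        edges: set[tuple[str, str]] = set()
        file_source = None
        with path.open("r", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header: list[str] | None = None
            for lineno, row in enumerate(reader, start=1):
                if not row or row[0].startswith("#"):
                    continue
                if header is None:
                    header = [c.strip().lower() for c in row]
                    if "regulator" not in header or "target" not in header:
                        raise ParseError(
                            f"{path}:{lineno}: expected columns 'regulator' and "
                            f"'target', got {row!r}"
                        )
                    continue
                if len(row) < 2:
                    raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {row!r}")
                rec = dict(zip(header, (c.strip() for c in row)))
                edges.add((rec["regulator"], rec["target"]))
                if rec.get("source"):
                    file_source = rec["source"]
        name = source_name or file_source or path.stem
        return RegIN(name, frozenset(edges))
    if dialect == "xgmml":
        graph = read_xgmml(path)
        name = source_name or graph.graph.get("label") or path.stem
        return RegIN(name, frozenset((str(u), str(v)) for u, v in graph.edges))
    raise ConfigurationError(f"unknown RegIN dialect {dialect!r}")


def write_regin_tsv(regin: RegIN, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("regulator\ttarget\tsource\n")
        for reg, tgt in sorted(regin.edges):
            fh.write(f"{reg}\t{tgt}\t{regin.source_name}\n")


def write_regin_xgmml(regin: RegIN, path: str | Path) -> None:
    graph = nx.DiGraph()
    for reg, tgt in sorted(regin.edges):
        graph.add_edge(reg, tgt, source=regin.source_name)
    write_xgmml(graph, path, label=regin.source_name)


@dataclass(frozen=True)
class ExtendedNetwork:
    """Seed miRNAs plus one-hop RegIN neighbours with per-edge source support.

    ``edges`` maps (regulator, target) to the full supporting source set;
    ``hidden`` masks sources non-destructively (visible support is computed
    on demand, so unhiding restores the original network exactly).
    """

    seeds: tuple[str, ...]
    sources: tuple[str, ...]
    direction: str
    edges: Mapping[tuple[str, str], frozenset[str]]
    hidden: frozenset[str] = field(default_factory=frozenset)

    def visible_support(self, edge: tuple[str, str]) -> frozenset[str]:
        return self.edges[edge] - self.hidden

    @property
    def visible_edges(self) -> dict[tuple[str, str], frozenset[str]]:
        out = {}
        for edge, support in self.edges.items():
            vis = support - self.hidden
            if vis:
                out[edge] = vis
        return out

    @property
    def added_nodes(self) -> frozenset[str]:
        seeds = set(self.seeds)
        return frozenset(
            n for edge in self.visible_edges for n in edge if n not in seeds
        )

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.seeds) | self.added_nodes

    def defined_targets(self, seeds: Iterable[str] | None = None) -> frozenset[str]:
        """Distinct visible targets of the given seeds (default: all seeds)."""
        pool = set(self.seeds if seeds is None else seeds)
        return frozenset(
            tgt for (reg, tgt) in self.visible_edges if reg in pool and tgt not in pool
        ) | frozenset(
            reg for (reg, tgt) in self.visible_edges if tgt in pool and reg not in pool
        )

    def to_graph(self) -> nx.DiGraph:
        graph = nx.DiGraph()
        for seed in self.seeds:
            graph.add_node(seed, role="seed")
        for (reg, tgt), support in sorted(self.visible_edges.items()):
            for node in (reg, tgt):
                if node not in graph:
                    graph.add_node(node, role="added")
            graph.add_edge(
                reg, tgt,
                support_sources="|".join(sorted(support)),
                support_count=len(support),
            )
        return graph


def extend_network(
    seeds: Sequence[str], regins: Sequence[RegIN], direction: str = "targets"
) -> ExtendedNetwork:
    """One-hop extension of the seed set across all RegINs.

    ``targets`` adds genes regulated by a seed, ``regulators`` adds
    upstream regulators of a seed, ``both`` adds both. Seeds absent from
    every RegIN simply gain no neighbours.
    """
    if not seeds:
        raise ConfigurationError("seed list is empty")
    if not regins:
        raise ConfigurationError("at least one RegIN is required")
    if direction not in DIRECTIONS:
        raise ConfigurationError(
            f"direction must be one of {DIRECTIONS}, got {direction!r}"
        )
    names = [r.source_name for r in regins]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate RegIN source names: {names}")
    seed_set = set(seeds)
    edges: dict[tuple[str, str], set[str]] = {}
    for regin in regins:
        for reg, tgt in regin.edges:
            keep = (direction in ("targets", "both") and reg in seed_set) or (
                direction in ("regulators", "both") and tgt in seed_set
            )
            if keep:
                edges.setdefault((reg, tgt), set()).add(regin.source_name)
    return ExtendedNetwork(
        seeds=tuple(seeds),
        sources=tuple(names),
        direction=direction,
        edges={e: frozenset(s) for e, s in edges.items()},
    )


def overlap_threshold(extnet: ExtendedNetwork, k: int) -> ExtendedNetwork:
    """Retain edges supported by >= k visible sources; added nodes with no
    surviving incident edge drop out, seeds always remain."""
    if k < 1:
        raise ConfigurationError(f"overlap threshold must be >= 1, got {k}")
    kept = {
        edge: support
        for edge, support in extnet.edges.items()
        if len(support - extnet.hidden) >= k
    }
    return replace(extnet, edges=kept)


def hide_sources(extnet: ExtendedNetwork, hidden: Iterable[str]) -> ExtendedNetwork:
    """Mask the given sources (replace semantics: pass an empty set to
    unhide everything and recover the original network)."""
    hidden = frozenset(hidden)
    unknown = hidden - set(extnet.sources)
    if unknown:
        raise ConfigurationError(f"unknown source names: {sorted(unknown)}")
    return replace(extnet, hidden=hidden)


def mti_accounting(
    extnet: ExtendedNetwork,
    seed_sets: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Summary tables of the extended network.

    ``summary``: one row per seed set (default: one set with every seed)
    with node/edge counts and per-source edge counts. ``defined_targets``:
    distinct targets per seed set plus a grand-total row that is the plain
    sum of the per-set counts (sets sharing targets count them repeatedly,
    matching the per-set bookkeeping of threshold accounting).
    """
    if seed_sets is None:
        seed_sets = {"all": list(extnet.seeds)}
    summary_rows = []
    target_rows = []
    for set_name, set_seeds in seed_sets.items():
        sub_edges = {
            e: s for e, s in extnet.visible_edges.items()
            if e[0] in set(set_seeds) or e[1] in set(set_seeds)
        }
        nodes = set(set_seeds) | {n for e in sub_edges for n in e}
        row: dict[str, object] = {
            "set": set_name,
            "nodes": len(nodes),
            "edges": len(sub_edges),
        }
        for source in extnet.sources:
            row[source] = sum(1 for s in sub_edges.values() if source in s)
        summary_rows.append(row)
        target_rows.append({
            "set": set_name,
            "defined_targets": len(extnet.defined_targets(set_seeds)),
        })
    target_rows.append({
        "set": "Total",
        "defined_targets": sum(r["defined_targets"] for r in target_rows),
    })
    return {
        "summary": pd.DataFrame(summary_rows),
        "defined_targets": pd.DataFrame(target_rows),
    }


def write_targets_tsv(extnet: ExtendedNetwork, path: str | Path,
                      names: Mapping[str, str] | None = None) -> None:
    """Per-seed target lists (seed, comma-separated targets), seeds with no
    targets omitted; optional accession->name mapping for display."""
    names = names or {}
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("mirna\ttargets\n")
        for seed in extnet.seeds:
            targets = sorted(extnet.defined_targets([seed]))
            if targets:
                fh.write(f"{names.get(seed, seed)}\t{', '.join(targets)}\n")
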