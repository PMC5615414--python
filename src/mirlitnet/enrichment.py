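"""GO term overrepresentation: right-sided hypergeometric test with
Benjamini-Hochberg control.

Annotations are closed under the true-path rule (a gene annotated to a
term is annotated to all its is_a ancestors) before counting, matching
standard GO enrichment semantics; ``propagate_annotations=False`` keeps
raw direct counts. For a term annotating K of the N background genes, the
probability that a random query of n genes contains >= k annotated ones is
the hypergeometric right tail; BH step-up adjustment runs over the family
of terms actually tested (those with k >= 1 in the query), which defines
the family size m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

from .errors import ConfigurationError, ParseError, StatisticsError, StructureError
from .stats import ContingencyTable, fisher_one_sided


@dataclass(frozen=True)
class GoDag:
    """Acyclic is_a hierarchy of GO terms."""

    terms: Mapping[str, tuple[str, str]]  # id -> (name, namespace)
    parents: Mapping[str, frozenset[str]]  # child -> direct is_a parents

    def __post_init__(self) -> None:
        for child, ps in self.parents.items():
            missing = [p for p in ps if p not in self.terms]
            if missing:
                raise ParseError(
                    f"term {child!r} references undeclared parent(s) {missing}"
                )
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            graph.add_edges_from((child, p) for p in ps)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise StructureError(f"is_a hierarchy contains a cycle: {cycle}")

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of a term (excluding the term itself)."""
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return frozenset(out)

    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents.get(t))

    def name(self, term: str) -> str:
        return self.terms[term][0]


@dataclass(frozen=True)
class AnnotationTable:
    """Direct gene -> GO term annotations over a background universe."""

    annotations: Mapping[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        universe = self.universe or frozenset(self.annotations)
        object.__setattr__(self, "universe", universe)
        stray = set(self.annotations) - set(universe)
        if stray:
            raise ConfigurationError(
                f"annotated genes outside the universe: {sorted(stray)[:5]}"
            )

    def genes_for(self, term: str) -> frozenset[str]:
        return frozenset(g for g, ts in self.annotations.items() if term in ts)


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    description: str
    background_annotated: int  # "Total genes" column
    query_annotated: int       # "Partner genes" column
    raw_p: float
    adjusted_p: float
    significant: bool


def parse_obo(path: str | Path) -> GoDag:
    """Parse a minimal OBO file ([Term] stanzas with id/name/namespace/is_a)."""
    try:
        graph = obonet.read_obo(str(path))
    except Exception as exc:  # malformed stanza / missing header
        raise ParseError(f"{path}: cannot parse OBO ({exc})") from exc
    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, frozenset[str]] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data:  # referenced but never declared
            raise ParseError(f"{path}: term {node!r} referenced but not declared")
        terms[node] = (data["name"], data.get("namespace", ""))
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        parents[child] = parents.get(child, frozenset()) | {parent}
    return GoDag(terms=terms, parents=parents)


def write_obo(dag: GoDag, path: str | Path,
              ontology_name: str = "synthetic-go") -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"format-version: 1.2\nontology: {ontology_name}\n")
        for term in sorted(dag.terms):
            name, namespace = dag.terms[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {name}\n")
            if namespace:
                fh.write(f"namespace: {namespace}\n")
            for parent in sorted(dag.parents.get(term, ())):
                fh.write(f"is_a: {parent} ! {dag.name(parent)}\n")


def load_annotations(path: str | Path,
                     universe: Iterable[str] | None = None) -> AnnotationTable:
    """Read a 2-column (gene, term) TSV."""
    annotations: dict[str, set[str]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'gene<TAB>term'")
            annotations.setdefault(parts[0], set()).add(parts[1])
    return AnnotationTable(
        annotations={g: frozenset(ts) for g, ts in annotations.items()},
        universe=frozenset(universe) if universe else frozenset(),
    )


def write_annotations(annot: AnnotationTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(annot.annotations):
            for term in sorted(annot.annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def propagate(annot: AnnotationTable, dag: GoDag) -> AnnotationTable:
    """Close every gene's term set under is_a ancestors (idempotent)."""
    closed = {
        gene: frozenset(
            t for term in terms for t in (term, *dag.ancestors(term))
        )
        for gene, terms in annot.annotations.items()
    }
    return AnnotationTable(annotations=closed, universe=annot.universe)


def hypergeom_term_p(
    term: str,
    query_genes: Iterable[str],
    annot_propagated: AnnotationTable,
) -> float:
    """Right-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    query = frozenset(query_genes)
    stray = query - annot_propagated.universe
    if stray:
        raise ConfigurationError(
            f"query genes outside the universe: {sorted(stray)[:5]}"
        )
    annotated = annot_propagated.genes_for(term)
    N = len(annot_propagated.universe)
    K = len(annotated)
    n = len(query)
    k = len(query & annotated)
    # the right tail over k with margins (n, K) fixed is exactly the
    # one-sided Fisher tail of the (k, n-k, K-k, N-K-n+k) table
    return float(fisher_one_sided(ContingencyTable(k, n - k, K - k, N - K - n + k)))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise StatisticsError(f"p-value outside [0,1]: {p}")
    if not pvals:
        return []
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(list(pvals), method="fdr_bh")[1])


def enrich(
    query_genes: Iterable[str],
    annot: AnnotationTable,
    dag: GoDag,
    alpha: float = 0.05,
    propagate_annotations: bool = True,
    adjusted: bool = True,
) -> list[EnrichmentRow]:
    """Score every term hit by the query; BH over the tested family.

    Rows come back sorted by ascending raw p (ties by term id); the
    significance flag applies ``alpha`` to adjusted p-values (or raw ones
    with ``adjusted=False``).
    """
    query = frozenset(query_genes)
    if not query:
        raise StatisticsError("empty query gene set")
    table = propagate(annot, dag) if propagate_annotations else annot
    stray = query - table.universe
    if stray:
        raise ConfigurationError(
            f"query genes outside the universe: {sorted(stray)[:5]}"
        )
    term_genes: dict[str, set[str]] = {}
    for gene, terms in table.annotations.items():
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)
    tested = sorted(t for t, genes in term_genes.items() if genes & query)
    raw = [hypergeom_term_p(t, query, table) for t in tested]
    adj = bh_adjust(raw)
    rows = [
        EnrichmentRow(
            term_id=t,
            description=dag.name(t) if t in dag.terms else t,
            background_annotated=len(term_genes[t]),
            query_annotated=len(term_genes[t] & query),
            raw_p=p,
            adjusted_p=q,
            significant=(q if adjusted else p) <= alpha,
        )
        for t, p, q in zip(tested, raw, adj)
    ]
    rows.sort(key=lambda r: (r.raw_p, r.term_id))
    return rows


def write_enrichment_tsv(rows: Iterable[EnrichmentRow], path: str | Path) -> None:
    """Enrichment table: GO ID, description, total (background) and partner
    (query) gene counts, raw and BH-adjusted p in scientific notation."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("go_id\tdescription\ttotal_genes\tpartner_genes\t"
                 "p_value\tcorrected_p_value\tsignificant\n")
        for r in rows:
            fh.write(
                f"{r.term_id}\t{r.description}\t{r.background_annotated}\t"
                f"{r.query_annotated}\t{r.raw_p:.2E}\t{r.adjusted_p:.2E}\t"
                f"{str(r.significant).lower()}\n"
            )
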