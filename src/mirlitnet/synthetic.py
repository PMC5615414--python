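"""Synthetic corpora, RegINs, and GO fixtures with planted ground truth.

The corpus generator emulates an abstract collection in which some
(miRNA, disease group) pairs are genuinely associated: each abstract is
dedicated to one planted pair and co-mentions it with probability
``p_comention``, while every other entity appears independently at small
background rates. Entities are rendered through the nomenclature surface
families the recognizer must handle (plain, species- and precursor-
prefixed, long forms, loci suffixes, lin-4/let-7, slash and ampersand
compounds) and embedded in filler sentences whose vocabulary is checked
against the lexicons for collisions, so NER on synthetic text is exact by
construction. Ground truth records the intended entity sets per abstract.

RegINs are generated from an explicit overlap specification (target ->
supporting source subset), and the GO fixture plants one designated
enriched term annotating a chosen gene block. All generators are
bit-reproducible under their seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from random import Random

from .corpus import AbstractRecord
from .enrichment import AnnotationTable, GoDag
from .errors import ConfigurationError, GenerationError
from .lexicon import DiseaseGroup, default_disease_groups
from .ner import MIRNA_PATTERN, canonicalize_dashes
from .regin import RegIN

TEMPLATE_FAMILIES = ("plain", "species", "precursor", "long", "cap",
                     "compound_slash", "compound_amp")

DEFAULT_MIRNA_IDS = (
    "miR-33a", "miR-33b", "miR-122", "miR-155", "miR-15", "miR-16",
    "miR-221", "miR-222", "miR-199a-1", "miR-17-92", "let-7", "lin-4",
)
DEFAULT_DISEASE_GROUPS = (
    "HDL-Cholesterol", "Triglyceride", "Hyperlipidemia", "LDL",
)
DEFAULT_PLANTED_PAIRS = (
    ("miR-33a", "HDL-Cholesterol"),
    ("miR-122", "Triglyceride"),
)

# filler vocabulary; must never collide with miRNA patterns or disease synonyms
FILLER_WORDS = (
    "observational", "findings", "metabolic", "cohort", "participants",
    "enrolled", "clinical", "assessment", "plasma", "samples", "profiling",
    "quantitative", "measurements", "baseline", "follow-up", "analysis",
    "revealed", "moderate", "variation", "across", "subjects", "hepatic",
    "tissue", "expression", "patterns", "examined", "during", "study",
    "period", "consistent", "replication", "independent", "series",
)

_MIRNA_SENTENCES = (
    "Expression of {e} was markedly altered in this cohort.",
    "We observed that {e} correlated with the measured phenotype.",
    "Quantification revealed {e} among the regulated transcripts.",
)
_DISEASE_SENTENCES = (
    "Participants presented with {e} at enrollment.",
    "The {e} phenotype was recorded for each subject.",
    "Clinical records documented {e} across the series.",
)


@dataclass(frozen=True)
class CorpusConfig:
    n_abstracts: int = 300
    mirna_ids: tuple[str, ...] = DEFAULT_MIRNA_IDS
    disease_groups: tuple[str, ...] = DEFAULT_DISEASE_GROUPS
    planted_pairs: tuple[tuple[str, str], ...] = DEFAULT_PLANTED_PAIRS
    p_comention: float = 0.6
    p_background_mirna: float = 0.05
    p_background_disease: float = 0.05
    p_compound: float = 0.2  # chance of pulling in a sibling as a compound form
    surface_form_templates: tuple[str, ...] = TEMPLATE_FAMILIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_abstracts < 0:
            raise ConfigurationError("n_abstracts must be >= 0")
        if self.planted_pairs and not 0 < self.p_comention <= 1:
            raise ConfigurationError("p_comention must be in (0, 1]")
        for name, p in (("p_background_mirna", self.p_background_mirna),
                        ("p_background_disease", self.p_background_disease),
                        ("p_compound", self.p_compound)):
            if not 0 <= p < 1:
                raise ConfigurationError(f"{name} must be in [0, 1), got {p}")
        for m, g in self.planted_pairs:
            if m not in self.mirna_ids or g not in self.disease_groups:
                raise ConfigurationError(
                    f"planted pair {(m, g)} outside mirna_ids x disease_groups"
                )
        unknown = set(self.surface_form_templates) - set(TEMPLATE_FAMILIES)
        if unknown:
            raise ConfigurationError(f"unknown surface templates: {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    """Intended entity sets per abstract, recorded before text rendering."""

    abstracts: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...]
    planted_pairs: frozenset[tuple[str, str]]

    def comention_counts(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for _, mirnas, groups in self.abstracts:
            for m in mirnas:
                for g in groups:
                    counts[(m, g)] = counts.get((m, g), 0) + 1
        return counts

    def entity_sets(self) -> dict[str, tuple[frozenset[str], frozenset[str]]]:
        return {aid: (frozenset(m), frozenset(g)) for aid, m, g in self.abstracts}


def _resolve_groups(names: Sequence[str]) -> list[DiseaseGroup]:
    by_name = {g.name: g for g in default_disease_groups()}
    missing = [n for n in names if n not in by_name]
    if missing:
        raise ConfigurationError(f"unknown disease groups: {missing}")
    return [by_name[n] for n in names]


def _check_filler_safety(groups: Sequence[DiseaseGroup]) -> None:
    """Filler vocabulary and sentence scaffolds must contain no lexicon hits."""
    from .ner import _disease_pattern  # shared compiled pattern builder

    scaffold = " ".join(FILLER_WORDS) + " " + " ".join(
        t.replace("{e}", "") for t in _MIRNA_SENTENCES + _DISEASE_SENTENCES
    )
    if MIRNA_PATTERN.search(canonicalize_dashes(scaffold)):
        raise ConfigurationError("filler vocabulary collides with miRNA patterns")
    if groups:
        pattern, _ = _disease_pattern(groups)
        if pattern.search(canonicalize_dashes(scaffold)):
            raise ConfigurationError(
                "filler vocabulary collides with disease synonyms"
            )


_LETTER_MEMBER_RE = re.compile(r"^miR-(\d+)([a-z])$")
_PLAIN_NUMBER_RE = re.compile(r"^miR-(\d+)$")


def _compound_partner(mirna: str, pool: Iterable[str]) -> str | None:
    """Sibling usable in a compound abbreviation: same-number letter member
    (miR-33a/miR-33b) or the numerically next plain member (miR-15/miR-16)."""
    pool = set(pool)
    m = _LETTER_MEMBER_RE.match(mirna)
    if m:
        num, letter = m.groups()
        sib = f"miR-{num}{chr(ord(letter) + 1)}"
        return sib if sib in pool else None
    m = _PLAIN_NUMBER_RE.match(mirna)
    if m:
        sib = f"miR-{int(m.group(1)) + 1}"
        return sib if sib in pool else None
    return None


def _render_compound(first: str, second: str, rng: Random,
                     allow_amp: bool) -> str:
    m1 = _LETTER_MEMBER_RE.match(first)
    m2 = _LETTER_MEMBER_RE.match(second)
    if m1 and m2 and m1.group(1) == m2.group(1):
        return f"miR-{m1.group(1)}{m1.group(2)}/{m2.group(2)}"
    n1 = _PLAIN_NUMBER_RE.match(first).group(1)
    n2 = _PLAIN_NUMBER_RE.match(second).group(1)
    if allow_amp and rng.random() < 0.5:
        return f"miR-{n1} & -{n2}"
    return f"miR-{n1}/{n2}"


def _applicable_templates(mirna: str, enabled: Sequence[str]) -> list[str]:
    singles = ["plain", "species", "precursor", "long", "cap"]
    if not mirna.startswith("miR-"):
        singles = ["plain", "species", "precursor"]  # let-7 / lin-4 families
    out = [t for t in singles if t in enabled]
    return out or ["plain"]


def _render_single(mirna: str, template: str) -> str:
    if template == "plain":
        return mirna
    if template == "species":
        return f"hsa-{mirna}"
    if template == "precursor":
        return f"pre-{mirna}"
    core = mirna.split("-", 1)[1]
    if template == "long":
        return f"microRNA-{core}"
    if template == "cap":
        return f"MiRNA-{core}"
    raise ConfigurationError(f"unknown template {template!r}")


def generate_corpus(config: CorpusConfig) -> tuple[list[AbstractRecord], GroundTruth]:
    """Generate an abstract corpus with planted associations.

    Raises :class:`GenerationError` if a planted pair ends up with zero
    co-mention abstracts (possible for tiny corpora or small p_comention);
    callers should enlarge the corpus in that case.
    """
    groups = _resolve_groups(config.disease_groups)
    _check_filler_safety(groups)
    rng = Random(config.seed)
    syn_by_group = {g.name: sorted(g.synonyms) for g in groups}
    records: list[AbstractRecord] = []
    truth_rows: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = []
    planted = list(config.planted_pairs)
    compound_enabled = any(
        t in config.surface_form_templates
        for t in ("compound_slash", "compound_amp")
    )
    allow_amp = "compound_amp" in config.surface_form_templates

    for i in range(config.n_abstracts):
        intended_m: set[str] = set()
        intended_g: set[str] = set()
        if planted:
            pm, pg = planted[i % len(planted)]
            if rng.random() < config.p_comention:
                intended_m.add(pm)
                intended_g.add(pg)
            elif rng.random() < 0.5:
                intended_m.add(pm)
            else:
                intended_g.add(pg)
        for m in config.mirna_ids:
            if m not in intended_m and rng.random() < config.p_background_mirna:
                intended_m.add(m)
        for g in config.disease_groups:
            if g not in intended_g and rng.random() < config.p_background_disease:
                intended_g.add(g)

        # compound planning: optionally pull in a sibling rendered jointly
        compound_plan: list[tuple[str, str]] = []
        consumed: set[str] = set()
        if compound_enabled:
            for m in sorted(intended_m):
                if m in consumed:
                    continue
                sib = _compound_partner(m, config.mirna_ids)
                if sib and sib not in consumed and rng.random() < config.p_compound:
                    intended_m.add(sib)
                    compound_plan.append((m, sib))
                    consumed.update((m, sib))

        sentences: list[str] = []
        for first, second in compound_plan:
            surface = _render_compound(first, second, rng, allow_amp)
            sentences.append(rng.choice(_MIRNA_SENTENCES).format(e=surface))
        for m in sorted(intended_m - consumed):
            template = rng.choice(
                _applicable_templates(m, config.surface_form_templates)
            )
            sentences.append(
                rng.choice(_MIRNA_SENTENCES).format(e=_render_single(m, template))
            )
        for g in sorted(intended_g):
            synonym = rng.choice(syn_by_group[g])
            sentences.append(rng.choice(_DISEASE_SENTENCES).format(e=synonym))
        rng.shuffle(sentences)
        opener = " ".join(rng.sample(FILLER_WORDS, 6))
        title = " ".join(rng.sample(FILLER_WORDS, 5)).capitalize()
        body = (opener.capitalize() + ". " + " ".join(sentences)).strip()
        aid = f"SYN-{i + 1:05d}"
        records.append(AbstractRecord(
            id=aid, source="synthetic", year=rng.randint(2000, 2013),
            title=title, body=body,
        ))
        truth_rows.append((aid, tuple(sorted(intended_m)), tuple(sorted(intended_g))))

    truth = GroundTruth(tuple(truth_rows), frozenset(config.planted_pairs))
    if config.n_abstracts > 0 and planted and config.p_comention > 0:
        counts = truth.comention_counts()
        unrealized = [p for p in planted if counts.get(p, 0) == 0]
        if unrealized:
            raise GenerationError(
                f"planted pairs never co-mentioned: {unrealized}; "
                f"increase n_abstracts or p_comention"
            )
    return records, truth


def generate_regins(
    n_sources: int,
    seed_mirnas: Sequence[str],
    n_targets: int,
    overlap_spec: Mapping[str, Iterable[str]] | None = None,
    seed: int = 0,
    source_names: Sequence[str] | None = None,
) -> list[RegIN]:
    """RegINs with controlled target overlap.

    With an explicit ``overlap_spec`` (target gene -> non-empty subset of
    source labels), target g appears in source s iff s is in the subset.
    Without one, ``n_targets`` genes get random non-empty source subsets.
    Each target's regulator is drawn from ``seed_mirnas``.
    """
    if n_sources < 1:
        raise ConfigurationError("n_sources must be >= 1")
    rng = Random(seed)
    if source_names is not None:
        names = list(source_names)
    elif overlap_spec:
        names = sorted({s for subset in overlap_spec.values() for s in subset})
        while len(names) < n_sources:
            names.append(f"RegIN-{len(names) + 1}")
    else:
        names = [f"RegIN-{i + 1}" for i in range(n_sources)]
    if len(names) != n_sources:
        raise ConfigurationError(
            f"{n_sources} sources requested but {len(names)} labels given"
        )
    if overlap_spec is None:
        spec: dict[str, frozenset[str]] = {}
        for j in range(n_targets):
            size = rng.randint(1, n_sources)
            spec[f"G{j + 1:04d}"] = frozenset(rng.sample(names, size))
    else:
        spec = {}
        for target, subset in overlap_spec.items():
            subset = frozenset(subset)
            if not subset:
                raise ConfigurationError(f"target {target!r} has an empty source set")
            if not subset <= set(names):
                raise ConfigurationError(
                    f"target {target!r} references unknown sources "
                    f"{sorted(subset - set(names))}"
                )
            spec[target] = subset
    regulator: dict[str, str] = {}
    if spec and not seed_mirnas:
        raise ConfigurationError("seed_mirnas must be non-empty when targets exist")
    for target in sorted(spec):
        regulator[target] = seed_mirnas[rng.randrange(len(seed_mirnas))]
    return [
        RegIN(
            source_name=name,
            edges=frozenset(
                (regulator[t], t) for t, subset in spec.items() if name in subset
            ),
        )
        for name in names
    ]


def generate_go_fixture(
    n_genes: int,
    n_terms: int,
    enriched_term: str | None = None,
    enriched_genes: Iterable[str] = (),
    seed: int = 0,
    genes: Sequence[str] | None = None,
) -> tuple[GoDag, AnnotationTable]:
    """A small GO DAG with one designated enriched term.

    The enriched term annotates exactly ``enriched_genes``
    (pre-propagation); all other genes receive one or two uniformly random
    annotations among the remaining non-root terms, and unannotated genes
    fall back to the root. Single root, acyclic by construction.
    """
    if n_terms < 1:
        raise ConfigurationError("n_terms must be >= 1")
    rng = Random(seed)
    gene_list = list(genes) if genes is not None else [
        f"GENE{j + 1:03d}" for j in range(n_genes)
    ]
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    root = term_ids[0]
    if enriched_term is None:
        enriched_term = term_ids[-1]
    if enriched_term not in term_ids:
        raise ConfigurationError(f"enriched term {enriched_term!r} not in the DAG")
    enriched = frozenset(enriched_genes)
    if not enriched <= set(gene_list):
        raise ConfigurationError("enriched_genes outside the gene universe")
    terms = {root: ("synthetic biological process root", "biological_process")}
    parents: dict[str, frozenset[str]] = {}
    for i, term in enumerate(term_ids[1:], start=1):
        terms[term] = (f"synthetic process {i}", "biological_process")
        parents[term] = frozenset({term_ids[rng.randrange(0, i)]})
    dag = GoDag(terms=terms, parents=parents)

    other_terms = [t for t in term_ids[1:] if t != enriched_term]
    annotations: dict[str, set[str]] = {g: set() for g in gene_list}
    for g in sorted(enriched):
        annotations[g].add(enriched_term)
    for g in gene_list:
        if other_terms:
            for t in rng.sample(other_terms, rng.randint(1, min(2, len(other_terms)))):
                annotations[g].add(t)
        if not annotations[g]:
            annotations[g].add(root)
    annot = AnnotationTable(
        annotations={g: frozenset(ts) for g, ts in annotations.items()},
        universe=frozenset(gene_list),
    )
    return dag, annot
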