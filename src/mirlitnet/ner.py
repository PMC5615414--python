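"""Dictionary + pattern recognition of miRNA and disease mentions.

miRNA names occur in abstracts under several surface families: the plain
name (``miR-122``), long forms (``microRNA-122``, ``MiRNA-122``), species
prefix (``hsa-miR-1``), precursor prefix (``pre-miR-1``), loci/variant
suffixes (``miR-199a-1``), the historical names ``lin-4``/``let-7``, and
compound abbreviations naming several miRNAs at once (``miR-221/222``,
``miR-33a/b``, ``miR-15 & -16``). Recognition is case-insensitive,
word-boundary anchored, and treats en-dashes as hyphens; every recognized
mention is normalized back to canonical lexicon ids. Unresolvable tokens
are flagged on the span, never silently dropped.

Disease/identifier groups are matched against their synonym sets with a
longest-match-wins rule (an abstract containing only ``HDL-Cholesterol``
counts toward that group, not also toward ``HDL``), and each group is
reported at most once per abstract: the unit of co-occurrence counting is
the abstract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import AbstractRecord
from .lexicon import DiseaseGroup, MirnaLexiconEntry

# characters treated as the ASCII hyphen during matching (en/em dash, minus)
_DASH_TRANSLATION = str.maketrans({"–": "-", "—": "-", "−": "-"})

_CORE_KEYWORDS = ("microrna", "mirna", "mir", "let", "lin")

MIRNA_PATTERN = re.compile(
    r"""
    (?<![\w-])
    (?:[a-z]{3}-)*                                  # species and/or pre- prefixes
    (?:microrna|mirna|mir|let|lin)
    [-\s]?
    \d+[a-z]?(?:-\d+)?                              # number, family letter, locus
    (?:
        \s*/\s*(?:\d+[a-z]?(?:-\d+)?|[a-z])         # slash compound: /222, /b
      | \s*&\s*-?\s*\d+[a-z]?(?:-\d+)?              # ampersand compound: & -16
    )*
    \b
    """,
    re.IGNORECASE | re.VERBOSE,
)

_CORE_RE = re.compile(r"(microrna|mirna|mir|let|lin)[-\s]?(\d+[a-z]?(?:-\d+)?)")
_COMPOUND_TOKEN_RE = re.compile(
    r"\s*(?:/|&)\s*-?\s*(\d+[a-z]?(?:-\d+)?|[a-z])"
)


@dataclass(frozen=True)
class MentionSpan:
    """One recognized entity mention, with 0-based half-open offsets into
    ``title + "\\n" + body``."""

    abstract_id: str
    start: int
    end: int
    matched_text: str
    normalized: tuple[str, ...]
    entity_type: str = "mirna"  # "mirna" | "disease"
    precursor: bool = False
    unresolved: tuple[str, ...] = ()


def canonicalize_dashes(text: str) -> str:
    """Map en/em dashes and the minus sign to the ASCII hyphen (same length)."""
    return text.translate(_DASH_TRANSLATION)


def _canonical_prefix(keyword: str) -> str:
    if keyword in ("microrna", "mirna", "mir"):
        return "miR"
    return keyword  # let / lin keep their lowercase capitalization


def _numeric_stem(token: str) -> str:
    """'33a' -> '33'; '221' -> '221'; '199a-1' -> '199a-1' (loci kept whole)."""
    m = re.fullmatch(r"(\d+)([a-z])", token)
    return m.group(1) if m else token


def parse_mirna_mention(matched_text: str) -> tuple[list[str], bool, str | None]:
    """Full parse of a recognized mention.

    Returns ``(canonical_ids, precursor_flag, compound_key)`` where
    ``compound_key`` is the canonical slash rendering of a compound mention
    (``miR-33a/b``) or None for a single-miRNA mention. Raises ValueError on
    an unresolvable token.
    """
    s = canonicalize_dashes(matched_text).strip().casefold()
    precursor = False
    # strip species / precursor prefixes until the core keyword is reached
    while not s.startswith(_CORE_KEYWORDS):
        m = re.match(r"([a-z]{3})-", s)
        if not m:
            raise ValueError(f"unresolvable miRNA token: {matched_text!r}")
        if m.group(1) == "pre":
            precursor = True
        s = s[m.end():]
    m = _CORE_RE.match(s)
    if not m:
        raise ValueError(f"unresolvable miRNA token: {matched_text!r}")
    prefix = _canonical_prefix(m.group(1))
    tokens = [m.group(2)]
    rest = s[m.end():]
    pos = 0
    while pos < len(rest):
        cm = _COMPOUND_TOKEN_RE.match(rest, pos)
        if not cm:
            raise ValueError(f"unresolvable compound tail in {matched_text!r}")
        tokens.append(cm.group(1))
        pos = cm.end()
    ids: list[str] = []
    for tok in tokens:
        if re.fullmatch(r"[a-z]", tok):  # family letter riding the previous stem
            tok = _numeric_stem(tokens[0]) + tok
        ids.append(f"{prefix}-{tok}")
    compound_key = None
    if len(tokens) > 1:
        compound_key = f"{prefix}-{'/'.join(tokens)}"
    return ids, precursor, compound_key


def normalize_mirna_mention(matched_text: str) -> list[str]:
    """Canonical ids named by a mention; compound forms expand to several."""
    ids, _, _ = parse_mirna_mention(matched_text)
    return ids


def _lexicon_index(lexicon: Sequence[MirnaLexiconEntry]) -> dict[str, str]:
    index: dict[str, str] = {}
    for entry in lexicon:
        index[entry.canonical_id.casefold()] = entry.canonical_id
        for alias in entry.aliases:
            index[alias.casefold()] = entry.canonical_id
    return index


def _alias_pattern(lexicon: Sequence[MirnaLexiconEntry]) -> re.Pattern | None:
    """Alternation over explicit aliases that the nomenclature pattern cannot
    derive (arbitrary strings supplied in the lexicon TSV)."""
    aliases = sorted(
        {a for e in lexicon for a in e.aliases}, key=len, reverse=True
    )
    if not aliases:
        return None
    body = "|".join(re.escape(canonicalize_dashes(a)) for a in aliases)
    return re.compile(rf"\b(?:{body})\b", re.IGNORECASE)


def recognize_mirnas(
    record: AbstractRecord, lexicon: Sequence[MirnaLexiconEntry]
) -> list[MentionSpan]:
    """All maximal, non-overlapping miRNA mentions in title+body."""
    text = record.text
    canon = canonicalize_dashes(text)
    index = _lexicon_index(lexicon)
    candidates: list[tuple[int, int]] = [
        (m.start(), m.end()) for m in MIRNA_PATTERN.finditer(canon)
    ]
    alias_re = _alias_pattern(lexicon)
    if alias_re is not None:
        candidates.extend((m.start(), m.end()) for m in alias_re.finditer(canon))
    # leftmost-longest sweep for non-overlapping maximal matches
    candidates.sort(key=lambda se: (se[0], -(se[1] - se[0])))
    spans: list[MentionSpan] = []
    cursor = -1
    for start, end in candidates:
        if start <= cursor:
            continue
        cursor = end - 1
        matched = text[start:end]
        try:
            ids, precursor, compound_key = parse_mirna_mention(matched)
        except ValueError:
            key = canonicalize_dashes(matched).casefold()
            if key in index:  # plain alias hit
                spans.append(MentionSpan(record.id, start, end, matched,
                                         (index[key],)))
                continue
            spans.append(MentionSpan(record.id, start, end, matched, (),
                                     unresolved=(matched,)))
            continue
        resolved = [index[i.casefold()] for i in ids if i.casefold() in index]
        unresolved = tuple(i for i in ids if i.casefold() not in index)
        if compound_key is not None and compound_key.casefold() in index:
            resolved.append(index[compound_key.casefold()])
        spans.append(MentionSpan(record.id, start, end, matched,
                                 tuple(resolved), precursor=precursor,
                                 unresolved=unresolved))
    return spans


def _disease_pattern(
    groups: Sequence[DiseaseGroup],
) -> tuple[re.Pattern, dict[str, str]]:
    """Longest-first synonym alternation plus capture-group -> group-name map."""
    pairs = sorted(
        ((syn, g.name) for g in groups for syn in g.synonyms),
        key=lambda p: len(p[0]), reverse=True,
    )
    body = "|".join(
        f"(?P<g{i}>{re.escape(canonicalize_dashes(syn))})"
        for i, (syn, _) in enumerate(pairs)
    )
    pattern = re.compile(rf"\b(?:{body})\b", re.IGNORECASE)
    return pattern, {f"g{i}": name for i, (_, name) in enumerate(pairs)}


def recognize_disease_spans(
    record: AbstractRecord, groups: Sequence[DiseaseGroup]
) -> list[MentionSpan]:
    """Disease/identifier mention spans, longest-match-wins."""
    text = record.text
    canon = canonicalize_dashes(text)
    pattern, names = _disease_pattern(groups)
    spans = []
    for m in pattern.finditer(canon):
        group_name = next(names[k] for k, v in m.groupdict().items() if v is not None)
        spans.append(MentionSpan(record.id, m.start(), m.end(),
                                 text[m.start():m.end()], (group_name,),
                                 entity_type="disease"))
    return spans


def recognize_diseases(
    record: AbstractRecord, groups: Sequence[DiseaseGroup]
) -> set[str]:
    """Group names mentioned in the abstract (each at most once)."""
    return {s.normalized[0] for s in recognize_disease_spans(record, groups)}


@dataclass(frozen=True)
class AnnotatedAbstract:
    abstract_id: str
    mirna_ids: frozenset[str]
    disease_groups: frozenset[str]
    mirna_spans: tuple[MentionSpan, ...] = ()
    disease_spans: tuple[MentionSpan, ...] = ()


@dataclass(frozen=True)
class AnnotatedCorpus:
    """NER output over a whole corpus plus the vocabularies it was run with."""

    abstracts: tuple[AnnotatedAbstract, ...]
    mirna_vocabulary: frozenset[str]
    group_vocabulary: frozenset[str]

    def __len__(self) -> int:
        return len(self.abstracts)


def annotate_corpus(
    records: Iterable[AbstractRecord],
    lexicon: Sequence[MirnaLexiconEntry],
    groups: Sequence[DiseaseGroup],
) -> AnnotatedCorpus:
    annotated = []
    for rec in records:
        mspans = recognize_mirnas(rec, lexicon)
        dspans = recognize_disease_spans(rec, groups)
        annotated.append(AnnotatedAbstract(
            abstract_id=rec.id,
            mirna_ids=frozenset(i for s in mspans for i in s.normalized),
            disease_groups=frozenset(i for s in dspans for i in s.normalized),
            mirna_spans=tuple(mspans),
            disease_spans=tuple(dspans),
        ))
    return AnnotatedCorpus(
        abstracts=tuple(annotated),
        mirna_vocabulary=frozenset(e.canonical_id for e in lexicon),
        group_vocabulary=frozenset(g.name for g in groups),
    )


def write_mentions_tsv(corpus: AnnotatedCorpus, path) -> None:
    """Mention table: abstract_id, entity_type, start, end, matched_text,
    pipe-separated normalized ids."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("abstract_id\tentity_type\tstart\tend\tmatched_text\tnormalized\n")
        for ab in corpus.abstracts:
            for span in (*ab.mirna_spans, *ab.disease_spans):
                fh.write(
                    f"{span.abstract_id}\t{span.entity_type}\t{span.start}\t"
                    f"{span.end}\t{span.matched_text}\t"
                    f"{'|'.join(span.normalized)}\n"
                )
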