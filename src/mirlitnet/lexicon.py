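"""miRNA and disease/identifier lexicons.

The miRNA lexicon maps canonical names (``miR-33a``, ``let-7``) to optional
miRBase-style accessions and explicit aliases. Surface variants produced by
nomenclature (species prefix ``hsa-``, precursor prefix ``pre-``, the
``microRNA-``/``miRNA-`` long forms, compound abbreviations) are handled by
normalization in :mod:`mirlitnet.ner`, not by alias enumeration.

The disease lexicon holds the four lipid diseases (dyslipidemia,
hyperlipidemia, hypercholesterolemia, hypertriglyceridemia) and seven lipid
phenotype identifiers (HDL-Cholesterol, HDL, LDL-Cholesterol, LDL,
Triglyceride, Low HDL-C, High LDL-C), each with its synonym set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import LexiconError


@dataclass(frozen=True)
class MirnaLexiconEntry:
    canonical_id: str
    accession: str | None = None
    aliases: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class DiseaseGroup:
    name: str
    synonyms: frozenset[str]
    kind: str  # "disease" | "identifier"

    def __post_init__(self) -> None:
        if self.kind not in ("disease", "identifier"):
            raise LexiconError(f"group {self.name!r}: bad kind {self.kind!r}")
        if not self.synonyms:
            raise LexiconError(f"group {self.name!r}: empty synonym set")


def _validate_mirna_entries(entries: Sequence[MirnaLexiconEntry]) -> None:
    seen_ids: dict[str, str] = {}
    seen_aliases: dict[str, str] = {}
    dup_ids: list[str] = []
    dup_aliases: list[str] = []
    for entry in entries:
        key = entry.canonical_id.casefold()
        if key in seen_ids:
            dup_ids.append(entry.canonical_id)
        seen_ids[key] = entry.canonical_id
        for alias in sorted(entry.aliases | {entry.canonical_id}):
            akey = alias.casefold()
            owner = seen_aliases.get(akey)
            if owner is not None and owner != entry.canonical_id:
                dup_aliases.append(alias)
            seen_aliases.setdefault(akey, entry.canonical_id)
    if dup_ids:
        raise LexiconError(f"duplicate canonical ids: {sorted(set(dup_ids))}")
    if dup_aliases:
        raise LexiconError(
            f"aliases shared across entries: {sorted(set(dup_aliases))}"
        )


def load_mirna_lexicon(path: str | Path) -> list[MirnaLexiconEntry]:
    """Load a miRNA lexicon TSV (canonical_id, accession, pipe-separated aliases).

    Lines starting with ``#`` are comments. A header row naming the first
    column ``canonical_id`` is skipped if present.
    """
    entries: list[MirnaLexiconEntry] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "canonical_id":
                continue
            canonical = row[0].strip()
            if not canonical:
                continue
            accession = row[1].strip() if len(row) > 1 and row[1].strip() else None
            aliases = frozenset(
                a.strip() for a in (row[2].split("|") if len(row) > 2 and row[2] else [])
                if a.strip()
            )
            entries.append(MirnaLexiconEntry(canonical, accession, aliases))
    _validate_mirna_entries(entries)
    return entries


def load_disease_lexicon(path: str | Path) -> list[DiseaseGroup]:
    """Load a disease lexicon TSV (name, kind, pipe-separated synonyms)."""
    groups: list[DiseaseGroup] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "name":
                continue
            name = row[0].strip()
            if not name:
                continue
            kind = row[1].strip() if len(row) > 1 else "disease"
            syns = frozenset(
                s.strip() for s in (row[2].split("|") if len(row) > 2 and row[2] else [])
                if s.strip()
            ) or frozenset({name})
            groups.append(DiseaseGroup(name, syns, kind))
    validate_disease_groups(groups)
    return groups


def validate_disease_groups(groups: Sequence[DiseaseGroup]) -> None:
    seen: dict[str, str] = {}
    collisions: list[str] = []
    names: set[str] = set()
    for g in groups:
        if g.name in names:
            raise LexiconError(f"duplicate group name {g.name!r}")
        names.add(g.name)
        for syn in sorted(g.synonyms):
            key = syn.casefold()
            owner = seen.get(key)
            if owner is not None and owner != g.name:
                collisions.append(syn)
            seen.setdefault(key, g.name)
    if collisions:
        raise LexiconError(f"synonyms shared across groups: {sorted(set(collisions))}")


def default_disease_groups() -> list[DiseaseGroup]:
    """The 4 lipid diseases + 7 identifier groups with common synonym spellings."""
    spec: list[tuple[str, str, tuple[str, ...]]] = [
        ("Dyslipidemia", "disease", ("dyslipidemia", "dyslipidaemia")),
        ("Hyperlipidemia", "disease", ("hyperlipidemia", "hyperlipidaemia")),
        ("Hypercholesterolemia", "disease",
         ("hypercholesterolemia", "hypercholesterolaemia")),
        ("Hypertriglyceridemia", "disease",
         ("hypertriglyceridemia", "hypertriglyceridaemia")),
        ("HDL-Cholesterol", "identifier",
         ("HDL-Cholesterol", "HDL cholesterol", "HDL-C",
          "high-density lipoprotein cholesterol")),
        ("HDL", "identifier", ("HDL", "high-density lipoprotein")),
        ("LDL-Cholesterol", "identifier",
         ("LDL-Cholesterol", "LDL cholesterol", "LDL-C",
          "low-density lipoprotein cholesterol")),
        ("LDL", "identifier", ("LDL", "low-density lipoprotein")),
        ("Triglyceride", "identifier", ("triglyceride", "triglycerides")),
        ("Low HDL-C", "identifier", ("low HDL-C", "low HDL cholesterol")),
        ("High LDL-C", "identifier", ("high LDL-C", "high LDL cholesterol")),
    ]
    groups = [DiseaseGroup(n, frozenset(s), k) for n, k, s in spec]
    validate_disease_groups(groups)
    return groups


def default_mirna_lexicon() -> list[MirnaLexiconEntry]:
    """The packaged default miRNA lexicon (reconstructed human miRNA roster)."""
    ref = resources.files("mirlitnet.data").joinpath("mirna_lexicon.tsv")
    with resources.as_file(ref) as path:
        return load_mirna_lexicon(path)


def default_disease_lexicon() -> list[DiseaseGroup]:
    ref = resources.files("mirlitnet.data").joinpath("disease_lexicon.tsv")
    with resources.as_file(ref) as path:
        return load_disease_lexicon(path)


def accession_map(entries: Iterable[MirnaLexiconEntry]) -> dict[str, str]:
    """canonical_id -> accession for entries that carry one."""
    return {e.canonical_id: e.accession for e in entries if e.accession}


def name_by_accession(entries: Iterable[MirnaLexiconEntry]) -> dict[str, str]:
    return {e.accession: e.canonical_id for e in entries if e.accession}


def write_mirna_lexicon(entries: Iterable[MirnaLexiconEntry], path: str | Path,
                        header_comment: str | None = None) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("canonical_id\taccession\taliases\n")
        for e in entries:
            fh.write(f"{e.canonical_id}\t{e.accession or ''}\t"
                     f"{'|'.join(sorted(e.aliases))}\n")


def write_disease_lexicon(groups: Iterable[DiseaseGroup], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("name\tkind\tsynonyms\n")
        for g in groups:
            fh.write(f"{g.name}\t{g.kind}\t{'|'.join(sorted(g.synonyms))}\n")
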