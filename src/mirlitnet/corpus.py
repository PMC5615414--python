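"""Abstract records and the line-delimited corpus format.

A corpus is a plain text file with one JSON object per line carrying the
fields ``id``, ``source``, ``year``, ``title`` and ``text`` (the abstract
body). Mention offsets produced by the recognizers index into
``title + "\\n" + body``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ParseError

VALID_SOURCES = frozenset({"pubmed", "scopus", "synthetic"})


@dataclass(frozen=True)
class AbstractRecord:
    """One literature abstract."""

    id: str
    source: str
    year: int
    title: str
    body: str

    def __post_init__(self) -> None:
        if self.source not in VALID_SOURCES:
            raise ParseError(
                f"abstract {self.id!r}: unknown source {self.source!r} "
                f"(expected one of {sorted(VALID_SOURCES)})"
            )

    @property
    def text(self) -> str:
        """Title and body joined by a single newline; the offset reference."""
        return f"{self.title}\n{self.body}"


def write_corpus(records: Iterable[AbstractRecord], path: str | Path) -> None:
    """Write records as line-delimited JSON (UTF-8, ``\\n`` line endings)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            obj = {
                "id": rec.id,
                "source": rec.source,
                "year": rec.year,
                "title": rec.title,
                "text": rec.body,
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_corpus(path: str | Path) -> list[AbstractRecord]:
    """Read a line-delimited corpus; duplicate ids are rejected."""
    records: list[AbstractRecord] = []
    seen: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
            try:
                rec = AbstractRecord(
                    id=str(obj["id"]),
                    source=str(obj["source"]),
                    year=int(obj["year"]),
                    title=str(obj["title"]),
                    body=str(obj["text"]),
                )
            except KeyError as exc:
                raise ParseError(f"{path}:{lineno}: missing field {exc}") from exc
            if rec.id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate abstract id {rec.id!r}")
            seen.add(rec.id)
            records.append(rec)
    return records


def iter_corpus(path: str | Path) -> Iterator[AbstractRecord]:
    yield from read_corpus(path)
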