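"""Co-occurrence contingency tables and one-sided Fisher's exact scoring.

Each (miRNA, disease group) pair over a corpus of n abstracts yields a 2x2
table: a abstracts mention both, b only the miRNA, c only the disease, d
neither. Under the null of independent mention, a follows the
hypergeometric law with the table's margins fixed,

    P(a) = (a+b)! (c+d)! (a+c)! (b+d)! / (a! b! c! d! n!),

and the association p-value is the enrichment (right) tail P(X >= a): the
probability of co-mention at least as extreme as observed. A pair is called
associated when p <= alpha (0.05 by default). No multiple-testing
correction is applied at this stage by default; an optional
Benjamini-Hochberg flag is available.

Numerics: for n <= EXACT_N_MAX point probabilities are exact binomial
coefficient ratios rounded once to float (and available as
:class:`fractions.Fraction` with ``exact=True``); larger tables use
log-gamma arithmetic with a log-sum-exp tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from .errors import StatisticsError
from .ner import AnnotatedCorpus

EXACT_N_MAX = 500  # exact rational path bound; above, log-space


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a (both), b (miRNA only), c (disease only), d (neither)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise StatisticsError(f"negative cell count in {self!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row1(self) -> int:  # miRNA margin
        return self.a + self.b

    @property
    def col1(self) -> int:  # disease margin
        return self.a + self.c

    def admissible_range(self) -> range:
        """Values of a consistent with this table's margins."""
        lo = max(0, self.row1 + self.col1 - self.n)
        hi = min(self.row1, self.col1)
        return range(lo, hi + 1)

    def with_a(self, a: int) -> "ContingencyTable":
        """The table with the same margins and cell a replaced."""
        return ContingencyTable(
            a, self.row1 - a, self.col1 - a, self.n - self.row1 - self.col1 + a
        )


@dataclass(frozen=True)
class AssociationRecord:
    mirna_id: str
    disease_group: str
    paper_count: int  # the a cell: abstracts supporting the pair
    p_value: float
    significant: bool


def _point_fraction(t: ContingencyTable) -> Fraction:
    num = math.comb(t.row1, t.a) * math.comb(t.n - t.row1, t.col1 - t.a)
    return Fraction(num, math.comb(t.n, t.col1))


def _log_point(t: ContingencyTable) -> float:
    lg = math.lgamma

    def lf(x: int) -> float:
        return lg(x + 1)

    return (
        lf(t.row1) + lf(t.c + t.d) + lf(t.col1) + lf(t.b + t.d)
        - lf(t.a) - lf(t.b) - lf(t.c) - lf(t.d) - lf(t.n)
    )


def point_hypergeometric(
    table: ContingencyTable, exact: bool = False
) -> float | Fraction:
    """Probability of this exact table under fixed margins.

    With ``exact=True`` returns a :class:`fractions.Fraction` (any n).
    """
    if table.n == 0:
        raise StatisticsError("point probability undefined for an empty table (n=0)")
    if exact or table.n <= EXACT_N_MAX:
        frac = _point_fraction(table)
        return frac if exact else float(frac)
    return math.exp(_log_point(table))


def fisher_one_sided(
    table: ContingencyTable, exact: bool = False
) -> float | Fraction:
    """Right-tail (enrichment) one-sided Fisher p-value, P(X >= a)."""
    if table.n == 0:
        raise StatisticsError("Fisher test undefined for an empty table (n=0)")
    tail = [a for a in table.admissible_range() if a >= table.a]
    if exact or table.n <= EXACT_N_MAX:
        total = sum((_point_fraction(table.with_a(a)) for a in tail), Fraction(0))
        total = min(total, Fraction(1))
        return total if exact else float(total)
    logs = [_log_point(table.with_a(a)) for a in tail]
    top = max(logs)
    return min(1.0, math.exp(top) * sum(math.exp(lp - top) for lp in logs))


def build_contingency(
    annotated_corpus: AnnotatedCorpus, mirna_id: str, disease_group: str
) -> ContingencyTable:
    """Count the 2x2 table for one pair; every abstract lands in one cell."""
    if mirna_id not in annotated_corpus.mirna_vocabulary:
        raise KeyError(f"unknown miRNA id {mirna_id!r}")
    if disease_group not in annotated_corpus.group_vocabulary:
        raise KeyError(f"unknown disease group {disease_group!r}")
    a = b = c = d = 0
    for ab in annotated_corpus.abstracts:
        has_m = mirna_id in ab.mirna_ids
        has_d = disease_group in ab.disease_groups
        if has_m and has_d:
            a += 1
        elif has_m:
            b += 1
        elif has_d:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def score_all_pairs(
    annotated_corpus: AnnotatedCorpus,
    alpha: float = 0.05,
    bh: bool = False,
) -> list[AssociationRecord]:
    """Score every co-occurring pair (a >= 1) with the one-sided Fisher test.

    Pairs never co-mentioned are not scored: co-occurrence is the
    association signal. With ``bh=True`` significance is called on
    Benjamini-Hochberg adjusted p-values instead of raw ones.
    """
    if not 0 < alpha < 1:
        raise StatisticsError(f"alpha must be in (0,1), got {alpha}")
    pairs = sorted({
        (m, g)
        for ab in annotated_corpus.abstracts
        for m in ab.mirna_ids
        for g in ab.disease_groups
    })
    raw: list[tuple[str, str, int, float]] = []
    for mirna, group in pairs:
        table = build_contingency(annotated_corpus, mirna, group)
        if table.a < 1:
            continue
        raw.append((mirna, group, table.a, float(fisher_one_sided(table))))
    pvals = [p for *_, p in raw]
    if bh and pvals:
        from statsmodels.stats.multitest import multipletests

        flags = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        flags = [p <= alpha for p in pvals]
    return [
        AssociationRecord(m, g, count, p, bool(sig))
        for (m, g, count, p), sig in zip(raw, flags)
    ]


def top_k(records: Sequence[AssociationRecord], k: int = 20) -> list[AssociationRecord]:
    """Most significant pairs: ascending p, ties by descending paper count,
    then lexicographic miRNA name, then group name."""
    if k <= 0:
        raise StatisticsError(f"k must be positive, got {k}")
    ordered = sorted(
        records,
        key=lambda r: (r.p_value, -r.paper_count, r.mirna_id, r.disease_group),
    )
    return ordered[:k]


def write_associations_tsv(
    records: Iterable[AssociationRecord], path: str | Path
) -> None:
    """Ranked association table: rank, miRNA, disease group, paper count,
    p-value in scientific notation (3 significant digits)."""
    recs = list(records)
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("rank\tmirna\tdisease_group\tpaper_count\tp_value\tsignificant\n")
        for rank, r in enumerate(recs, start=1):
            fh.write(
                f"{rank}\t{r.mirna_id}\t{r.disease_group}\t{r.paper_count}\t"
                f"{r.p_value:.2E}\t{str(r.significant).lower()}\n"
            )
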