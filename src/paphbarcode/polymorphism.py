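"""Per-locus polymorphism profiling: site classes, variable-site totals, indels.

Gaps, N and IUPAC ambiguity codes are dropped from a column before
classification; a column left with fewer than two residues is
uninformative.  The reported identity V = P + S (variable =
parsimony-informative + singleton) holds by construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .seqio import NUCLEOTIDES, Alignment


class SiteClass(Enum):
    CONSTANT = "constant"
    SINGLETON = "singleton"
    PARSIMONY_INFORMATIVE = "parsimony_informative"
    UNINFORMATIVE_MISSING = "uninformative_missing"


@dataclass(frozen=True)
class IndelFragment:
    """A maximal gap run: 1-based closed interval plus the vouchers carrying it.

    ``terminal`` marks runs touching the alignment boundary (typically
    trimming artifacts rather than indels).
    """

    start: int
    end: int
    carriers: frozenset[str]
    terminal: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("indel fragment start must not exceed end")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class LocusStats:
    """The genetic-characteristics row for one locus."""

    locus: str
    L: int
    P_pi: int
    S_single: int
    indel_count: int

    @property
    def V(self) -> int:
        return self.P_pi + self.S_single

    @property
    def rate_pct(self) -> float:
        """Variable-site percentage 100*V/L, rounded to one decimal."""
        return round(100.0 * self.V / self.L, 1)

    @classmethod
    def from_counts(
        cls, locus: str, L: int, P_pi: int, S_single: int, indel_count: int = 0
    ) -> "LocusStats":
        return cls(locus, L, P_pi, S_single, indel_count)


def classify_site(column_states) -> SiteClass:
    """Classify one alignment column (iterable of residue characters)."""
    states = list(column_states)
    if not states:
        raise ValueError("empty column")
    if len(states) < 2:
        raise ValueError("a column needs residues from at least 2 sequences")
    counts = Counter(s for s in states if s in NUCLEOTIDES)
    if sum(counts.values()) < 2:
        return SiteClass.UNINFORMATIVE_MISSING
    if len(counts) <= 1:
        return SiteClass.CONSTANT
    n_common = sum(1 for c in counts.values() if c >= 2)
    if n_common >= 2:
        return SiteClass.PARSIMONY_INFORMATIVE
    return SiteClass.SINGLETON


def find_indel_fragments(
    aln: Alignment, *, include_terminal: bool = False
) -> list[IndelFragment]:
    """Distinct maximal gap runs, identical (start, end) spans merged.

    Fragment identity is the exact span; overlapping but unequal runs stay
    distinct.  Terminal runs are excluded unless ``include_terminal``.
    """
    spans: dict[tuple[int, int], set[str]] = {}
    L = aln.length
    for rec in aln.records:
        seq = rec.sequence
        col = 1
        while col <= L:
            if seq[col - 1] == "-":
                start = col
                while col <= L and seq[col - 1] == "-":
                    col += 1
                spans.setdefault((start, col - 1), set()).add(rec.voucher)
            else:
                col += 1
    out = []
    for (start, end), carriers in sorted(spans.items()):
        terminal = start == 1 or end == L
        if terminal and not include_terminal:
            continue
        out.append(IndelFragment(start, end, frozenset(carriers), terminal))
    return out


def locus_stats(aln: Alignment) -> LocusStats:
    """Site-class counts and indel-fragment count for one alignment."""
    P = S = 0
    for col in range(1, aln.length + 1):
        cls = classify_site(aln.column(col))
        if cls is SiteClass.PARSIMONY_INFORMATIVE:
            P += 1
        elif cls is SiteClass.SINGLETON:
            S += 1
    indels = find_indel_fragments(aln)
    return LocusStats(aln.locus, aln.length, P, S, len(indels))


def stats_table(stats: list[LocusStats]) -> "pandas.DataFrame":
    """Report mirroring the genetic-characteristics table layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "locus": s.locus,
                "L": s.L,
                "P": s.P_pi,
                "S": s.S_single,
                "V": s.V,
                "rate_pct": s.rate_pct,
                "indel_fragments": s.indel_count,
            }
            for s in stats
        ]
    )
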