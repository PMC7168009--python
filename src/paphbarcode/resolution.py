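"""Species-resolution scoring on trees and screening-rate tabulation.

A species is *tree-resolved* for a barcode when (a) its samples form a
monophyletic clade on the rooted tree and (b) none of its samples is
sequence-identical (over sites where both sequences carry a base) to a
sample of another species.  Condition (b) keeps a singleton species - a
leaf, hence trivially monophyletic - from being scored as resolved when its
sequence is indistinguishable from another species.

The screening side parses specimen x assay status tables with paired
amplification/sequencing marks ("+/+", "+/-", "-/", blank = not attempted)
and tabulates per-assay success rates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqio import MISSING, Alignment, SpeciesMap
from .tree import Tree, TreeError


def is_monophyletic(tree: Tree, tips) -> bool:
    """True iff the smallest clade containing ``tips`` holds no other leaf."""
    if not tree.rooted:
        raise TreeError("monophyly is assessed on a rooted tree")
    tips = frozenset(tips)
    if not tips:
        raise TreeError("empty tip set")
    unknown = tips - tree.leaf_names()
    if unknown:
        raise TreeError(f"unknown tips: {sorted(unknown)}")
    if len(tips) == 1:
        return True
    return tree.mrca(tips).leaf_names() == tips


def identical_pairs(aln: Alignment) -> set[tuple[str, str]]:
    """Unordered voucher pairs identical over mutually non-missing sites.

    Pairs with zero comparable sites are *not* reported identical.
    """
    mat = aln.matrix()
    valid = mat != MISSING
    both = valid.astype(np.float64) @ valid.T.astype(np.float64)
    agree = np.zeros_like(both)
    for code in range(4):
        hit = ((mat == code) & valid).astype(np.float64)
        agree += hit @ hit.T
    same = (both > 0) & (agree == both)
    out = set()
    vouchers = aln.vouchers
    for i, j in zip(*np.nonzero(np.triu(same, k=1))):
        out.add((vouchers[i], vouchers[j]))
    return out


@dataclass
class SpeciesVerdict:
    species: str
    barcode: str
    n_samples: int
    monophyletic: bool
    distinct: bool
    support: Optional[int] = None
    rationale: str = ""

    @property
    def resolved_tree(self) -> bool:
        return self.monophyletic and self.distinct


@dataclass
class ResolutionReport:
    barcode: str
    verdicts: dict[str, SpeciesVerdict]
    warnings: list[str] = field(default_factory=list)

    @property
    def resolved_count(self) -> int:
        return sum(1 for v in self.verdicts.values() if v.resolved_tree)

    def resolved_species(self) -> frozenset[str]:
        return frozenset(s for s, v in self.verdicts.items() if v.resolved_tree)


def species_resolution(
    tree: Tree, aln: Alignment, sm: SpeciesMap, *, barcode: Optional[str] = None
) -> ResolutionReport:
    """Score every ingroup species on the rooted tree; outgroup excluded."""
    sm.validate(aln)
    barcode = barcode or aln.locus
    shared = identical_pairs(aln)
    outgroup = sm.outgroup_species
    cross_species = {
        voucher
        for a, b in shared
        if sm.species_of(a) != sm.species_of(b)
        and outgroup not in (sm.species_of(a), sm.species_of(b))
        for voucher in (a, b)
    }
    report = ResolutionReport(barcode, {})
    present = set(aln.vouchers)
    for species in sm.ingroup_species():
        vouchers = [v for v in sm.vouchers_of(species) if v in present]
        if not vouchers:
            report.warnings.append(f"species {species!r} has no sample; skipped")
            continue
        mono = is_monophyletic(tree, vouchers)
        distinct = not any(v in cross_species for v in vouchers)
        support = None
        if mono and len(vouchers) >= 2:
            node = tree.mrca(vouchers)
            support = node.support
        if mono and distinct:
            rationale = "monophyletic with no cross-species identical sequence"
        elif not mono:
            rationale = "samples do not form an exclusive clade"
        else:
            rationale = "sequence identical to another species over compared sites"
        report.verdicts[species] = SpeciesVerdict(
            species, barcode, len(vouchers), mono, distinct, support, rationale
        )
    return report


def write_resolution_tsv(reports: list[ResolutionReport], path) -> None:
    """Species x barcode matrix of +/- verdicts with a summary row."""
    species_order: list[str] = []
    for rep in reports:
        for sp in rep.verdicts:
            if sp not in species_order:
                species_order.append(sp)
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(r.barcode for r in reports) + "\n")
        for sp in species_order:
            cells = [
                ("+" if r.verdicts[sp].resolved_tree else "-") if sp in r.verdicts else ""
                for r in reports
            ]
            fh.write(sp + "\t" + "\t".join(cells) + "\n")
        fh.write(
            "resolved_species\t"
            + "\t".join(str(r.resolved_count) for r in reports)
            + "\n"
        )


# -- screening status tables ---------------------------------------------

_MINUS = {"-", "−"}  # ASCII hyphen and the typographic minus


@dataclass(frozen=True)
class StatusCell:
    """Paired amplification/sequencing marks; ``None`` = not attempted."""

    amplification: Optional[bool]
    sequencing: Optional[bool]

    def __post_init__(self):
        if self.sequencing is not None and self.amplification is None:
            raise ValueError("sequencing mark requires an amplification attempt")

    @classmethod
    def parse(cls, text: str) -> "StatusCell":
        text = text.strip()
        if not text:
            return cls(None, None)
        parts = text.split("/")
        if len(parts) == 1:
            parts.append("")
        amp, seq = (p.strip() for p in parts[:2])

        def mark(p: str) -> Optional[bool]:
            if not p:
                return None
            if p == "+":
                return True
            if p in _MINUS:
                return False
            raise ValueError(f"bad status mark {p!r}")

        return cls(mark(amp), mark(seq))


@dataclass
class StatusTable:
    specimens: list[str]  # row order
    assays: list[str]  # column order
    cells: dict[tuple[str, str], StatusCell]

    def cell(self, specimen: str, assay: str) -> StatusCell:
        return self.cells.get((specimen, assay), StatusCell(None, None))


@dataclass(frozen=True)
class AssayRates:
    assay: str
    attempted: int
    amplified: int
    sequenced: int
    amplification_rate_pct: Optional[float]
    sequencing_rate_pct: Optional[float]


def status_rates(st: StatusTable) -> dict[str, AssayRates]:
    """Per-assay amplification and sequencing success percentages.

    Amplification rate = 100 * successes / attempts (non-blank cells);
    sequencing rate = 100 * sequencing successes / amplification successes.
    Rates with a zero denominator are reported as ``None`` (undefined).
    Two-decimal rounding.
    """
    out = {}
    for assay in st.assays:
        cells = [st.cell(sp, assay) for sp in st.specimens]
        attempted = sum(1 for c in cells if c.amplification is not None)
        amplified = sum(1 for c in cells if c.amplification is True)
        sequenced = sum(1 for c in cells if c.sequencing is True)
        amp_rate = round(100.0 * amplified / attempted, 2) if attempted else None
        seq_rate = round(100.0 * sequenced / amplified, 2) if amplified else None
        out[assay] = AssayRates(assay, attempted, amplified, sequenced, amp_rate, seq_rate)
    return out


def read_status_table(path) -> StatusTable:
    """TSV: first column specimen voucher, optional second column species
    (detected by header), remaining columns assay cells."""
    with open(path) as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    header = rows[0]
    skip = 2 if len(header) > 1 and header[1].lower() == "species" else 1
    assays = header[skip:]
    specimens = []
    cells = {}
    for row in rows[1:]:
        voucher = row[0]
        specimens.append(voucher)
        for k, assay in enumerate(assays):
            raw = row[skip + k] if skip + k < len(row) else ""
            cells[(voucher, assay)] = StatusCell.parse(raw)
    return StatusTable(specimens, assays, cells)


def write_status_rates_tsv(rates: dict[str, AssayRates], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "assay\tattempted\tamplified\tsequenced\t"
            "amplification_rate_pct\tsequencing_rate_pct\n"
        )
        for r in rates.values():
            amp = "" if r.amplification_rate_pct is None else f"{r.amplification_rate_pct:.2f}"
            seq = "" if r.sequencing_rate_pct is None else f"{r.sequencing_rate_pct:.2f}"
            fh.write(f"{r.assay}\t{r.attempted}\t{r.amplified}\t{r.sequenced}\t{amp}\t{seq}\n")
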