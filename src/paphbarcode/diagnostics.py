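"""Character-based identification: diagnostic substitutions and indels.

A column is diagnostic for a species when every sample of the species
carries one fixed base there (no missing data allowed in the species) and
no sample of any other ingroup species carries that base.  An indel
fragment is diagnostic when presence/absence of the exact gap span
perfectly separates the species from the rest of the ingroup; the polarity
records whether the species carries the gap (``indel_absence`` of the
fragment, i.e. a deletion relative to the rest) or uniquely lacks it
(``indel_presence``: the species alone retains residues - an insertion).
The outgroup never takes part in either side of the comparison.

Alignment columns map to ungapped positions of a chosen reference sample
for reporting against published reference coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .polymorphism import IndelFragment, find_indel_fragments
from .resolution import ResolutionReport
from .seqio import NUCLEOTIDES, Alignment, SpeciesMap


@dataclass(frozen=True)
class DiagnosticCharacter:
    species: str
    locus: str
    kind: str  # substitution | indel_presence | indel_absence
    start: int  # 1-based alignment columns, closed interval
    end: int
    state: str  # base for substitutions, gap-span text for indels
    ref_voucher: Optional[str] = None
    ref_start: Optional[int] = None
    ref_end: Optional[int] = None

    def __post_init__(self):
        if self.kind not in ("substitution", "indel_presence", "indel_absence"):
            raise ValueError(f"bad diagnostic kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError("diagnostic interval start must not exceed end")


def _ingroup_records(aln: Alignment, sm: SpeciesMap):
    return [
        rec for rec in aln.records if sm.species_of(rec.voucher) != sm.outgroup_species
    ]


def diagnostic_substitutions(
    aln: Alignment, sm: SpeciesMap, *, ref_voucher: Optional[str] = None
) -> list[DiagnosticCharacter]:
    """All (species, column) pairs where one fixed base marks the species."""
    sm.validate(aln)
    records = _ingroup_records(aln, sm)
    species_of = {rec.voucher: sm.species_of(rec.voucher) for rec in records}
    species_list = sorted(set(species_of.values()))
    if len(species_list) < 2:
        raise ValueError("diagnostics need at least 2 ingroup species")
    out = []
    for col in range(1, aln.length + 1):
        by_species: dict[str, set[str]] = {}
        for rec in records:
            by_species.setdefault(species_of[rec.voucher], set()).add(
                rec.sequence[col - 1]
            )
        for species in species_list:
            states = by_species[species]
            if len(states) != 1:
                continue
            state = next(iter(states))
            if state not in NUCLEOTIDES:
                continue  # gap or ambiguity: not a fixed base
            others = set().union(
                *(by_species[sp] for sp in species_list if sp != species)
            )
            if state in others:
                continue
            out.append(
                _with_reference(
                    DiagnosticCharacter(
                        species, aln.locus, "substitution", col, col, state
                    ),
                    aln,
                    ref_voucher,
                )
            )
    return out


def diagnostic_indels(
    aln: Alignment,
    sm: SpeciesMap,
    fragments: Optional[list[IndelFragment]] = None,
    *,
    ref_voucher: Optional[str] = None,
) -> list[DiagnosticCharacter]:
    """Fragments whose exact-span gap presence partitions one species."""
    sm.validate(aln)
    if fragments is None:
        fragments = find_indel_fragments(aln)
    records = _ingroup_records(aln, sm)
    species_of = {rec.voucher: sm.species_of(rec.voucher) for rec in records}
    species_list = sorted(set(species_of.values()))
    out = []
    for frag in fragments:
        gapped = {
            rec.voucher
            for rec in records
            if all(rec.sequence[c - 1] == "-" for c in range(frag.start, frag.end + 1))
        }
        for species in species_list:
            members = {rec.voucher for rec in records if species_of[rec.voucher] == species}
            rest = {rec.voucher for rec in records} - members
            span = f"{frag.start}-{frag.end}"
            if members <= gapped and not (rest & gapped):
                kind = "indel_absence"  # the species alone carries the gap
            elif not (members & gapped) and rest <= gapped:
                kind = "indel_presence"  # the species alone retains residues
            else:
                continue
            out.append(
                _with_reference(
                    DiagnosticCharacter(
                        species, aln.locus, kind, frag.start, frag.end, span
                    ),
                    aln,
                    ref_voucher,
                )
            )
    return out


def map_to_reference(aln: Alignment, ref_voucher: str, column: int) -> tuple[int, bool]:
    """Ungapped 1-based reference position for an alignment column.

    Returns ``(position, in_gap)``: the count of reference residues in
    columns 1..column; when the reference itself is gapped at the column the
    position of the last preceding residue is returned (0 if none) with
    ``in_gap`` set.
    """
    ref = aln.record(ref_voucher).sequence
    if not 1 <= column <= aln.length:
        raise ValueError(f"column {column} out of range 1..{aln.length}")
    prefix = ref[:column]
    position = len(prefix) - prefix.count("-")
    return position, prefix.endswith("-")


def _with_reference(
    diag: DiagnosticCharacter, aln: Alignment, ref_voucher: Optional[str]
) -> DiagnosticCharacter:
    if ref_voucher is None:
        return diag
    start, _ = map_to_reference(aln, ref_voucher, diag.start)
    end, _ = map_to_reference(aln, ref_voucher, diag.end)
    return DiagnosticCharacter(
        diag.species,
        diag.locus,
        diag.kind,
        diag.start,
        diag.end,
        diag.state,
        ref_voucher,
        start,
        end,
    )


def verify_diagnostic(aln: Alignment, sm: SpeciesMap, diag: DiagnosticCharacter) -> bool:
    """Independent brute-force re-check of one reported character."""
    members = []
    rest = []
    for rec in _ingroup_records(aln, sm):
        (members if sm.species_of(rec.voucher) == diag.species else rest).append(rec)
    if not members:
        return False
    if diag.kind == "substitution":
        col = diag.start
        if any(rec.sequence[col - 1] != diag.state for rec in members):
            return False
        return all(rec.sequence[col - 1] != diag.state for rec in rest)
    span = range(diag.start, diag.end + 1)

    def has_gap(rec):
        return all(rec.sequence[c - 1] == "-" for c in span)

    if diag.kind == "indel_absence":
        return all(has_gap(r) for r in members) and not any(has_gap(r) for r in rest)
    return not any(has_gap(r) for r in members) and all(has_gap(r) for r in rest)


@dataclass
class CombinedVerdict:
    species: str
    barcode: str
    resolved_tree: bool
    n_characters: int
    resolved_final: bool
    rationale: str


def combined_resolution(
    tree_report: ResolutionReport, diags: list[DiagnosticCharacter]
) -> dict[str, CombinedVerdict]:
    """Tree verdicts augmented by the character route (monotone: never
    unresolves a tree-resolved species)."""
    per_species: dict[str, int] = {}
    for d in diags:
        per_species[d.species] = per_species.get(d.species, 0) + 1
    out = {}
    for species, verdict in tree_report.verdicts.items():
        n_chars = per_species.get(species, 0)
        resolved = verdict.resolved_tree or n_chars > 0
        if verdict.resolved_tree:
            rationale = "tree-based"
        elif n_chars:
            rationale = "character-based"
        else:
            rationale = "unresolved"
        out[species] = CombinedVerdict(
            species, tree_report.barcode, verdict.resolved_tree, n_chars, resolved, rationale
        )
    return out


def write_diagnostics_tsv(diags: list[DiagnosticCharacter], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "species\tlocus\tkind\talignment_start\talignment_end\tstate\t"
            "ref_voucher\tref_start\tref_end\n"
        )
        for d in diags:
            fh.write(
                f"{d.species}\t{d.locus}\t{d.kind}\t{d.start}\t{d.end}\t{d.state}\t"
                f"{d.ref_voucher or ''}\t{d.ref_start or ''}\t{d.ref_end or ''}\n"
            )
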