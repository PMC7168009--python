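"""Multilocus barcodes: concatenation with a partition map, and assignment
of query (e.g. trade) samples against a reference panel.

Concatenation policies: ``strict`` keeps only vouchers present in every
locus; ``pad`` keeps the union and fills a missing locus with gaps (used
when one species has no sequence for some locus).  Identification is
conservative: the final species call requires the tree placement and the
nearest-species call of every available locus to agree, otherwise the
query is reported ambiguous with the conflict spelled out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .distance import compare_pair, distance_matrix, k2p
from .seqio import Alignment, AlignmentError, SampleRecord, SpeciesMap
from .treeinfer import neighbor_joining, root_with_outgroup
from .tree import Tree


@dataclass
class ConcatenatedAlignment(Alignment):
    """An alignment plus locus -> 1-based closed column interval."""

    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def locus_columns(self, locus: str) -> tuple[int, int]:
        return self.partitions[locus]


def concatenate(
    alignments: list[Alignment],
    sm: Optional[SpeciesMap] = None,
    policy: str = "strict",
) -> ConcatenatedAlignment:
    """Join per-locus alignments into one supermatrix, loci in given order."""
    if policy not in ("strict", "pad"):
        raise ValueError(f"unknown policy {policy!r}")
    if len(alignments) < 2:
        raise ValueError("concatenation needs at least 2 loci")
    seen = [aln.locus for aln in alignments]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate locus in concatenation")

    all_vouchers: list[str] = []
    for aln in alignments:
        for v in aln.vouchers:
            if v not in all_vouchers:
                all_vouchers.append(v)
    if policy == "strict":
        keep = [
            v
            for v in all_vouchers
            if all(v in set(aln.vouchers) for aln in alignments)
        ]
    else:
        keep = all_vouchers
    if not keep:
        raise AlignmentError("no voucher present in the required loci")

    partitions = {}
    offset = 0
    for aln in alignments:
        partitions[aln.locus] = (offset + 1, offset + aln.length)
        offset += aln.length

    name = "+".join(seen)
    records = []
    for voucher in keep:
        parts = []
        species = ""
        for aln in alignments:
            if voucher in set(aln.vouchers):
                rec = aln.record(voucher)
                parts.append(rec.sequence)
                species = species or rec.species_label
            else:
                parts.append("-" * aln.length)
        if not species and sm is not None:
            species = sm.mapping.get(voucher, "")
        records.append(SampleRecord(voucher, species, name, "".join(parts)))
    return ConcatenatedAlignment(name, records, partitions=partitions)


def write_partitions(caln: ConcatenatedAlignment, path) -> None:
    """RAxML-style plain-text partition file."""
    with open(path, "w") as fh:
        for locus, (start, end) in caln.partitions.items():
            fh.write(f"DNA, {locus} = {start}-{end}\n")


# -- query identification -------------------------------------------------


@dataclass
class LocusMatch:
    locus: str
    nearest_species: Optional[str]  # None when tied across species
    nearest_distance: float
    exact_match: bool
    tied_species: tuple[str, ...] = ()


@dataclass
class IdentificationResult:
    query: str
    per_locus: dict[str, LocusMatch]
    tree_placement: str  # species, "between species", or "unplaced"
    final_call: str  # species label or "ambiguous"
    conflict: bool
    notes: str = ""


def _nearest(query_seq: str, aln: Alignment, sm: SpeciesMap) -> LocusMatch:
    best: dict[str, float] = {}
    exact = False
    for rec in aln.records:
        if sm.species_of(rec.voucher) == sm.outgroup_species:
            continue
        pc = compare_pair(query_seq, rec.sequence)
        d = k2p(pc)
        sp = sm.species_of(rec.voucher)
        if sp not in best or d < best[sp]:
            best[sp] = d
        if pc.p_distance == 0.0:
            exact = True
    dmin = min(best.values())
    tied = tuple(sorted(sp for sp, d in best.items() if d <= dmin + 1e-12))
    nearest = tied[0] if len(tied) == 1 else None
    return LocusMatch(aln.locus, nearest, dmin, exact, tied)


def _placement(tree: Tree, query_voucher: str, sm: SpeciesMap) -> str:
    """Species of the smallest clade enclosing the query, if single-species."""
    leaf = tree.find_leaf(query_voucher)
    node = leaf.parent
    while node is not None:
        others = node.leaf_names() - {query_voucher}
        others -= set(sm.outgroup_vouchers)
        if others:
            species = {sm.species_of(v) for v in others}
            return next(iter(species)) if len(species) == 1 else "between species"
        node = node.parent
    return "unplaced"


def identify_query(
    reference: dict[str, Alignment],
    sm: SpeciesMap,
    queries: dict[str, dict[str, str]],
    *,
    model: str = "k2p",
) -> dict[str, IdentificationResult]:
    """Assign queries to reference species.

    ``reference`` maps locus -> reference alignment; ``queries`` maps query
    voucher -> {locus: aligned sequence on reference columns}.  Queries may
    lack loci; sequences must match the reference column count of each
    locus they do provide.
    """
    results: dict[str, IdentificationResult] = {}
    for qv, seqs in queries.items():
        per_locus = {}
        for locus, seq in seqs.items():
            aln = reference[locus]
            if len(seq) != aln.length:
                raise AlignmentError(
                    f"query {qv!r} has {len(seq)} columns for {locus}, "
                    f"reference has {aln.length}"
                )
            per_locus[locus] = _nearest(seq, aln, sm)

        # tree of references + query over the query's available loci
        loci = [l for l in reference if l in seqs]
        if len(loci) > 1:
            base: Alignment = concatenate([reference[l] for l in loci], sm)
            qseq = "".join(seqs[l] for l in loci)
        else:
            base = reference[loci[0]]
            qseq = seqs[loci[0]]
        aug = Alignment(
            base.locus,
            base.records + [SampleRecord(qv, "query", base.locus, qseq)],
        )
        tree = root_with_outgroup(
            neighbor_joining(distance_matrix(aug, model)), sm.outgroup_vouchers
        )
        placement = _placement(tree, qv, sm)

        calls = {m.nearest_species for m in per_locus.values()}
        conflict = len(calls) > 1 or None in calls
        notes = ""
        if conflict:
            notes = "loci disagree: " + ", ".join(
                f"{l}->{m.nearest_species or '/'.join(m.tied_species)}"
                for l, m in per_locus.items()
            )
        if not conflict and placement in calls:
            final = placement
        else:
            final = "ambiguous"
            if not notes:
                notes = f"tree placement {placement!r} vs sequence call"
        results[qv] = IdentificationResult(
            qv, per_locus, placement, final, bool(conflict), notes
        )
    return results


def write_identification_tsv(results: dict[str, IdentificationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "query\tfinal_call\ttree_placement\tconflict\t"
            "locus\tnearest_species\tnearest_distance\texact_match\tnotes\n"
        )
        for res in results.values():
            for locus, m in res.per_locus.items():
                fh.write(
                    f"{res.query}\t{res.final_call}\t{res.tree_placement}\t"
                    f"{'yes' if res.conflict else 'no'}\t{locus}\t"
                    f"{m.nearest_species or 'tied'}\t{m.nearest_distance:.6f}\t"
                    f"{'yes' if m.exact_match else 'no'}\t{res.notes}\n"
                )
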