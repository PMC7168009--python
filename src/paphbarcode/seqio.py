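"""Reading and writing of aligned multi-FASTA, Newick trees and metadata sidecars.

Record headers follow the grammar ``voucher|species|locus`` by default; the
delimiter is configurable, and a TSV sidecar (voucher -> species) is accepted
instead for panels whose FASTA headers carry only the voucher.  Sequences are
stored upper-cased with U mapped to T; gaps (``-``), ``N`` and IUPAC ambiguity
codes are retained verbatim and treated as missing data by the analysis
modules.  Alignment columns are 1-based throughout the package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import numpy as np
from Bio import SeqIO

from .tree import Node, Tree, TreeError

NUCLEOTIDES = "ACGT"
#: numeric codes used by the vectorised analysis modules
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
MISSING = 255


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class SampleRecord:
    """One specimen sequence: voucher id, species label, locus and residues."""

    voucher: str
    species_label: str
    locus: str
    sequence: str

    def __post_init__(self):
        if not self.voucher:
            raise AlignmentError("voucher must be non-empty")
        if not self.sequence:
            raise AlignmentError(f"record {self.voucher!r} has an empty sequence")


@dataclass
class Alignment:
    """A per-locus alignment: ordered records of identical length."""

    locus: str
    records: list[SampleRecord]

    def __post_init__(self):
        if len(self.records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        length = len(self.records[0].sequence)
        for rec in self.records:
            if len(rec.sequence) != length:
                raise AlignmentError(
                    f"not aligned: record {rec.voucher!r} has length "
                    f"{len(rec.sequence)}, expected {length}"
                )
        seen = set()
        for rec in self.records:
            if rec.voucher in seen:
                raise AlignmentError(f"duplicate voucher {rec.voucher!r}")
            seen.add(rec.voucher)

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def vouchers(self) -> list[str]:
        return [rec.voucher for rec in self.records]

    def record(self, voucher: str) -> SampleRecord:
        for rec in self.records:
            if rec.voucher == voucher:
                return rec
        raise AlignmentError(f"unknown voucher {voucher!r}")

    def column(self, col: int) -> list[str]:
        """Residues of 1-based column ``col`` in record order."""
        if not 1 <= col <= self.length:
            raise AlignmentError(f"column {col} out of range 1..{self.length}")
        return [rec.sequence[col - 1] for rec in self.records]

    def matrix(self) -> np.ndarray:
        """(n_records, length) uint8 matrix; non-ACGT residues become MISSING."""
        return np.vstack([encode(rec.sequence) for rec in self.records])


def encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    out = np.full(arr.shape, MISSING, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class SpeciesMap:
    """voucher -> species mapping plus the designated outgroup species."""

    mapping: dict[str, str]
    outgroup_species: str

    def species_of(self, voucher: str) -> str:
        try:
            return self.mapping[voucher]
        except KeyError:
            raise AlignmentError(f"voucher {voucher!r} not in species map") from None

    def vouchers_of(self, species: str) -> list[str]:
        return [v for v, s in self.mapping.items() if s == species]

    @property
    def outgroup_vouchers(self) -> list[str]:
        return self.vouchers_of(self.outgroup_species)

    def ingroup_species(self) -> list[str]:
        seen: list[str] = []
        for sp in self.mapping.values():
            if sp != self.outgroup_species and sp not in seen:
                seen.append(sp)
        return seen

    def validate(self, aln: Alignment) -> None:
        for voucher in aln.vouchers:
            self.species_of(voucher)
        if not self.outgroup_vouchers:
            raise AlignmentError(
                f"outgroup species {self.outgroup_species!r} has no voucher"
            )


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(
    path,
    locus: str,
    *,
    delimiter: str = "|",
    species_map: Optional[SpeciesMap] = None,
) -> Alignment:
    """Read an aligned multi-FASTA into an :class:`Alignment`.

    Headers are split on ``delimiter`` as voucher|species|locus; trailing
    fields may be absent, in which case the species label is looked up in
    ``species_map`` (empty if neither source provides it).
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split(delimiter)
        voucher = parts[0]
        species = parts[1] if len(parts) > 1 else ""
        if not species and species_map is not None:
            species = species_map.mapping.get(voucher, "")
        rec_locus = parts[2] if len(parts) > 2 else locus
        records.append(
            SampleRecord(voucher, species, rec_locus, _normalise(str(rec.seq)))
        )
    if not records:
        raise AlignmentError(f"empty FASTA file: {path}")
    return Alignment(locus, records)


def read_records(path, locus: str, *, delimiter: str = "|") -> list[SampleRecord]:
    """Like :func:`read_alignment` but without alignment invariants (queries
    may arrive one per file)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split(delimiter)
        voucher = parts[0]
        species = parts[1] if len(parts) > 1 else ""
        rec_locus = parts[2] if len(parts) > 2 else locus
        records.append(
            SampleRecord(voucher, species, rec_locus, _normalise(str(rec.seq)))
        )
    if not records:
        raise AlignmentError(f"empty FASTA file: {path}")
    return records


def write_alignment(aln: Alignment, path, *, delimiter: str = "|") -> None:
    with open(path, "w") as fh:
        for rec in aln.records:
            header = delimiter.join([rec.voucher, rec.species_label, rec.locus])
            fh.write(f">{header}\n{rec.sequence}\n")


def read_species_map(path, outgroup_species: str) -> SpeciesMap:
    """TSV sidecar with columns voucher, species (header optional)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0].lower() == "voucher":
                continue
            if len(row) < 2:
                raise AlignmentError(f"bad species-map row: {row!r}")
            mapping[row[0]] = row[1]
    return SpeciesMap(mapping, outgroup_species)


def write_species_map(sm: SpeciesMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("voucher\tspecies\n")
        for voucher, species in sm.mapping.items():
            fh.write(f"{voucher}\t{species}\n")


# -- Newick ---------------------------------------------------------------


def write_newick(tree: Tree, path) -> None:
    """Serialize with 6-decimal branch lengths and integer internal supports."""
    if len(tree.leaves()) < 2:
        raise TreeError("refusing to write a tree with fewer than 2 leaves")
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path_or_text) -> Tree:
    """Parse Newick (file path or literal string) into the package Tree."""
    text = None
    p = Path(str(path_or_text))
    if p.exists():
        text = p.read_text()
    else:
        text = str(path_or_text)
    dtree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )

    def convert(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon is not None else None
        support = None
        if dnode.label is not None and not dnode.is_leaf():
            support = int(round(float(dnode.label)))
        node = Node(
            name=name,
            length=float(dnode.edge.length or 0.0),
            support=support,
        )
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    root = convert(dtree.seed_node)
    return Tree(root, rooted=len(root.children) == 2)
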