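"""Bundled example data.

``pilot_screening_status()`` returns the amplification/sequencing status
matrix of the eight-locus pilot screen on eight endemic Vietnamese
Paphiopedilum species (23 specimens): candidate barcodes ITS, matK, trnL,
rpoB, rpoC1 and trnH-psbA plus the two low-copy nuclear genes ACO and LEAFY,
each of the latter attempted with two primer pairs.  Cells pair the
amplification and sequencing outcomes ("+/-" = amplified, sequencing
failed; blank = not attempted).

``locus_profiles()`` returns the published-style genetic characteristics
(alignment length, parsimony-informative, singleton and variable sites,
variable rate, indel fragments) of the five loci that sequenced cleanly in
that screen; the synthetic generator uses these as emulation targets.
"""

from __future__ import annotations

from importlib import resources

from .polymorphism import LocusStats
from .resolution import StatusTable, read_status_table


def pilot_screening_status() -> StatusTable:
    path = resources.files("paphbarcode.data") / "pilot_screening_status.tsv"
    with resources.as_file(path) as p:
        return read_status_table(p)


#: per-locus (L, P, S, indel fragments) of the pilot-screen alignments
_LOCUS_PROFILE_COUNTS = {
    "ITS": (725, 166, 71, 20),
    "matK": (1132, 74, 39, 1),
    "trnL": (466, 25, 9, 3),
    "rpoB": (483, 7, 5, 0),
    "rpoC1": (460, 5, 3, 0),
}


def locus_profiles() -> dict[str, LocusStats]:
    return {
        locus: LocusStats.from_counts(locus, L, P, S, indels)
        for locus, (L, P, S, indels) in _LOCUS_PROFILE_COUNTS.items()
    }
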