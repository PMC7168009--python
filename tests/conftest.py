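import pytest
from hypothesis import settings

from paphbarcode.seqio import Alignment, SampleRecord, SpeciesMap

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


def make_alignment(locus, rows, species=None):
    """rows: list of (voucher, sequence); species defaults to voucher prefix."""
    records = []
    for voucher, seq in rows:
        sp = (species or {}).get(voucher, voucher.split("-")[0])
        records.append(SampleRecord(voucher, sp, locus, seq))
    return Alignment(locus, records)


@pytest.fixture
def toy_alignment():
    # 4 sequences x 10 columns: 2 parsimony-informative columns (1, 2),
    # 1 singleton column (3), one 2-column gap run in one sequence (7-8)
    return make_alignment(
        "toy",
        [
            ("a-1", "AAAACCGGTT"),
            ("a-2", "AAAACCGGTT"),
            ("b-1", "TTAACCGGTT"),
            ("b-2", "TTGACC--TT"),
        ],
    )


@pytest.fixture
def two_species_map():
    return SpeciesMap(
        {"a-1": "A", "a-2": "A", "b-1": "B", "b-2": "B", "og-1": "OG"},
        outgroup_species="OG",
    )
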