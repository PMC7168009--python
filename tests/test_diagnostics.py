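"""Diagnostic characters, reference-coordinate mapping, combined verdicts."""

import pytest
from hypothesis import given, settings, strategies as st

from paphbarcode.diagnostics import (
    DiagnosticCharacter,
    combined_resolution,
    diagnostic_indels,
    diagnostic_substitutions,
    map_to_reference,
    verify_diagnostic,
)
from paphbarcode.polymorphism import find_indel_fragments
from paphbarcode.resolution import ResolutionReport, SpeciesVerdict
from paphbarcode.seqio import SpeciesMap

from conftest import make_alignment


def six_sample_map():
    return SpeciesMap(
        {
            "x-1": "X", "x-2": "X",
            "y-1": "Y", "y-2": "Y",
            "z-1": "Z", "z-2": "Z",
            "og-1": "OG",
        },
        "OG",
    )


class TestSubstitutions:
    def test_single_planted_column_found(self):
        # species X alone carries C at column 4
        rows = [
            ("x-1", "AAAC" + "ACGTAG"[:6]),
            ("x-2", "AAAC" + "ACGTAG"[:6]),
            ("y-1", "AAAA" + "ACGTAG"[:6]),
            ("y-2", "AAAA" + "ACGTAG"[:6]),
            ("z-1", "AAAG" + "ACGTAG"[:6]),
            ("z-2", "AAAG" + "ACGTAG"[:6]),
        ]
        aln = make_alignment("L", rows)
        diags = diagnostic_substitutions(aln, six_sample_map())
        by_x = [d for d in diags if d.species == "X"]
        assert [(d.start, d.state) for d in by_x] == [(4, "C")]
        # Y and Z also each own their column-4 state? Y has A (shared by
        # nothing else? Z carries G, X carries C -> A is unique to Y) etc.
        assert all(verify_diagnostic(aln, six_sample_map(), d) for d in diags)

    def test_all_identical_yields_nothing(self):
        rows = [(v, "ACGTACGTAC") for v in ("x-1", "x-2", "y-1", "y-2", "z-1", "z-2")]
        assert diagnostic_substitutions(make_alignment("L", rows), six_sample_map()) == []

    def test_polymorphic_target_disqualified(self):
        rows = [
            ("x-1", "AAAAACGTAC"),
            ("x-2", "GAAAACGTAC"),  # X split A/G at column 1
            ("y-1", "CAAAACGTAC"),
            ("y-2", "CAAAACGTAC"),
            ("z-1", "TAAAACGTAC"),
            ("z-2", "TAAAACGTAC"),
        ]
        diags = diagnostic_substitutions(make_alignment("L", rows), six_sample_map())
        assert [d for d in diags if d.species == "X" and d.start == 1] == []

    def test_missing_data_in_target_disqualifies(self):
        rows = [
            ("x-1", "CAAAACGTAC"),
            ("x-2", "NAAAACGTAC"),  # ambiguity in target at the candidate column
            ("y-1", "AAAAACGTAC"),
            ("y-2", "AAAAACGTAC"),
            ("z-1", "GAAAACGTAC"),
            ("z-2", "GAAAACGTAC"),
        ]
        diags = diagnostic_substitutions(make_alignment("L", rows), six_sample_map())
        assert [d for d in diags if d.species == "X" and d.start == 1] == []

    def test_outgroup_state_ignored(self):
        rows = [
            ("x-1", "CAAAACGTAC"),
            ("x-2", "CAAAACGTAC"),
            ("y-1", "AAAAACGTAC"),
            ("y-2", "AAAAACGTAC"),
            ("z-1", "GAAAACGTAC"),
            ("z-2", "GAAAACGTAC"),
            ("og-1", "CAAAACGTAC"),  # outgroup shares X's state; still diagnostic
        ]
        diags = diagnostic_substitutions(make_alignment("L", rows), six_sample_map())
        assert any(d.species == "X" and d.start == 1 for d in diags)


class TestIndelDiagnostics:
    def rows_with_gap(self, carriers, start0, length, L=20):
        base = ("ACGT" * 6)[:L]
        rows = []
        for v in ("x-1", "x-2", "y-1", "y-2", "z-1", "z-2", "og-1"):
            seq = base
            if v.split("-")[0] in carriers:
                seq = base[:start0] + "-" * length + base[start0 + length :]
            rows.append((v, seq))
        return rows

    def test_species_specific_deletion(self):
        aln = make_alignment("L", self.rows_with_gap({"x"}, 5, 3))
        diags = diagnostic_indels(aln, six_sample_map())
        assert [(d.species, d.kind, d.start, d.end) for d in diags] == [
            ("X", "indel_absence", 6, 8)
        ]

    def test_species_specific_insertion(self):
        # everyone except X gapped: X uniquely retains residues
        aln = make_alignment("L", self.rows_with_gap({"y", "z", "og"}, 5, 3))
        diags = diagnostic_indels(aln, six_sample_map())
        assert [(d.species, d.kind) for d in diags] == [("X", "indel_presence")]

    def test_shared_fragment_not_diagnostic_for_carriers(self):
        aln = make_alignment("L", self.rows_with_gap({"x", "y"}, 5, 3))
        diags = diagnostic_indels(aln, six_sample_map())
        # neither carrier owns the fragment; the sole ungapped ingroup
        # species legitimately scores it as a unique insertion
        assert {d.species for d in diags} == {"Z"}
        assert all(d.kind == "indel_presence" for d in diags)

    def test_no_gaps_no_diagnostics(self):
        aln = make_alignment("L", self.rows_with_gap(set(), 5, 3))
        assert diagnostic_indels(aln, six_sample_map()) == []

    def test_brute_force_verifier_accepts_all_reported(self):
        aln = make_alignment("L", self.rows_with_gap({"x"}, 5, 3))
        sm = six_sample_map()
        frags = find_indel_fragments(aln)
        for d in diagnostic_indels(aln, sm, frags):
            assert verify_diagnostic(aln, sm, d)


class TestMapToReference:
    def test_gapless_identity(self):
        aln = make_alignment("L", [("r-1", "ACGTACGTAC"), ("o-1", "ACGTACGTAC")])
        assert map_to_reference(aln, "r-1", 7) == (7, False)

    def test_gapped_reference_counts_residues(self):
        aln = make_alignment("L", [("r-1", "AC--GT"), ("o-1", "ACGTGT")])
        assert map_to_reference(aln, "r-1", 5) == (3, False)

    def test_in_gap_column_flags_and_returns_previous(self):
        aln = make_alignment("L", [("r-1", "AC--GT"), ("o-1", "ACGTGT")])
        assert map_to_reference(aln, "r-1", 3) == (2, True)

    def test_leading_gap_maps_to_zero(self):
        aln = make_alignment("L", [("r-1", "--GTAC"), ("o-1", "ACGTAC")])
        assert map_to_reference(aln, "r-1", 1) == (0, True)

    def test_out_of_range(self):
        aln = make_alignment("L", [("r-1", "ACGT"), ("o-1", "ACGT")])
        with pytest.raises(ValueError):
            map_to_reference(aln, "r-1", 5)

    @settings(deadline=None, max_examples=50)
    @given(st.text(alphabet="ACGT-", min_size=2, max_size=30))
    def test_monotone_and_identity_when_gapless(self, ref):
        if set(ref) == {"-"}:
            ref = "A" + ref[1:]
        aln = make_alignment("L", [("r-1", ref), ("o-1", "A" * len(ref))])
        positions = [map_to_reference(aln, "r-1", c)[0] for c in range(1, len(ref) + 1)]
        assert positions == sorted(positions)
        if "-" not in ref:
            assert positions == list(range(1, len(ref) + 1))


class TestCombinedResolution:
    def report(self, resolved):
        verdicts = {
            sp: SpeciesVerdict(sp, "L", 2, ok, ok) for sp, ok in resolved.items()
        }
        return ResolutionReport("L", verdicts)

    def diag(self, sp):
        return DiagnosticCharacter(sp, "L", "substitution", 3, 3, "C")

    def test_character_rescues_unresolved(self):
        out = combined_resolution(self.report({"X": False}), [self.diag("X")])
        assert out["X"].resolved_final and out["X"].rationale == "character-based"

    def test_tree_route_reported(self):
        out = combined_resolution(self.report({"X": True}), [])
        assert out["X"].resolved_final and out["X"].rationale == "tree-based"

    def test_neither_route(self):
        out = combined_resolution(self.report({"X": False}), [])
        assert not out["X"].resolved_final

    def test_never_unresolves(self):
        out = combined_resolution(self.report({"X": True, "Y": False}), [self.diag("Y")])
        assert out["X"].resolved_final and out["Y"].resolved_final
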