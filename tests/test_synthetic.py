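"""The panel generator: species trees, sequence evolution, planting, truth."""

import numpy as np
import pytest

from paphbarcode.diagnostics import diagnostic_indels, diagnostic_substitutions
from paphbarcode.distance import compare_pair, distance_matrix
from paphbarcode.polymorphism import locus_stats
from paphbarcode.seqio import read_alignment, write_alignment
from paphbarcode.synthetic import (
    LOCUS_PRESETS,
    HybridSpec,
    LocusConfig,
    SimConfig,
    _evolve_states,
    emit_panel,
    evolve_alignment,
    evolve_haplotypes,
    make_hybrid,
    paph21_panel,
    plant_diagnostics,
    simulate_panel,
    simulate_species_tree,
)


class TestSpeciesTree:
    def test_two_species_cherry(self):
        tree = simulate_species_tree(2, 0)
        assert len(tree.leaves()) == 3  # outgroup included

    def test_leaf_count_and_names(self):
        tree = simulate_species_tree(12, 3)
        names = {l.name for l in tree.leaves()}
        assert len(names) == 13 and "outgroup" in names

    def test_deterministic_given_seed(self):
        assert (
            simulate_species_tree(8, 42).to_newick()
            == simulate_species_tree(8, 42).to_newick()
        )

    def test_ultrametric_ingroup(self):
        tree = simulate_species_tree(10, 7, outgroup_divergence=1.5)

        def depth(leaf):
            d, n = 0.0, leaf
            while n.parent is not None:
                d += n.length
                n = n.parent
            return d

        depths = [depth(l) for l in tree.leaves()]
        assert all(abs(d - depths[0]) < 1e-9 for d in depths)


class TestEvolution:
    def test_rate_zero_identical(self):
        tree = simulate_species_tree(6, 1)
        haps = evolve_haplotypes(
            tree, LocusConfig("X", 100, 0.0), np.random.default_rng(0)
        )
        seqs = set(haps.values())
        assert len(seqs) == 1

    def test_kappa_controls_observed_ts_tv(self):
        rng = np.random.default_rng(7)
        parent = rng.integers(0, 4, size=60_000).astype(np.int8)
        ts = tv = 0
        for _ in range(10):
            child = _evolve_states(parent, 0.02, 5.0, rng)
            diff = child != parent
            trans = diff & ((child % 2) == (parent % 2))
            ts += int(trans.sum())
            tv += int((diff & ~trans).sum())
        ratio = ts / tv
        assert 4.4 < ratio < 5.6  # binomial error around kappa=5

    def test_divergence_increases_with_rate(self):
        tree = simulate_species_tree(6, 5)
        means = []
        for scale in (0.005, 0.02, 0.08):
            rng = np.random.default_rng(11)
            haps = evolve_haplotypes(tree, LocusConfig("X", 2000, scale), rng)
            names = sorted(haps)
            ds = [
                compare_pair(haps[a], haps[b]).p_distance
                for i, a in enumerate(names)
                for b in names[i + 1 :]
            ]
            means.append(float(np.mean(ds)))
        assert means[0] < means[1] < means[2]

    def test_evolve_alignment_expands_samples(self):
        tree = simulate_species_tree(4, 2)
        aln = evolve_alignment(tree, LocusConfig("X", 50, 0.05), 3, seed=0)
        assert len(aln.records) == 5 * 3  # 4 species + outgroup, 3 samples each
        assert aln.record("sp01-1").sequence == aln.record("sp01-2").sequence


class TestPlanting:
    def base_panel(self):
        cfg = SimConfig(
            seed=5,
            n_species=6,
            n_hard_cluster_species=0,
            with_hybrid=False,
            n_diagnostic_substitutions=0,
            n_diagnostic_indels=0,
            intra_variant_prob=0.0,
            loci=[LocusConfig("X", 300, 0.05)],
        )
        return simulate_panel(cfg)

    def test_planted_substitution_recovered_exactly(self):
        panel = self.base_panel()
        aln, truth = plant_diagnostics(
            panel.alignments["X"], panel.species_map, [("sp03", "substitution")], 9
        )
        (entry,) = truth
        found = [
            d
            for d in diagnostic_substitutions(aln, panel.species_map)
            if d.species == "sp03"
        ]
        assert (entry.start, entry.state) in {(d.start, d.state) for d in found}

    def test_planted_insertion_polarity(self):
        panel = self.base_panel()
        aln, truth = plant_diagnostics(
            panel.alignments["X"], panel.species_map, [("sp02", "indel_presence")], 9
        )
        diags = diagnostic_indels(aln, panel.species_map)
        assert any(d.species == "sp02" and d.kind == "indel_presence" for d in diags)

    def test_unknown_species_rejected(self):
        panel = self.base_panel()
        with pytest.raises(ValueError):
            plant_diagnostics(
                panel.alignments["X"], panel.species_map, [("nope", "substitution")], 0
            )


class TestHybrid:
    def test_zero_noise_copies_parents_exactly(self):
        cfg = SimConfig(
            seed=3,
            n_species=6,
            n_hard_cluster_species=0,
            with_hybrid=False,
            n_diagnostic_substitutions=0,
            intra_variant_prob=0.0,
            loci=[LocusConfig("X", 200, 0.05), LocusConfig("Y", 200, 0.05)],
        )
        panel = simulate_panel(cfg)
        spec = HybridSpec("hyb", "sp01", "sp04", {"X": 1, "Y": 2})
        alignments, sm = make_hybrid(panel.alignments, panel.species_map, spec)
        assert (
            alignments["X"].record("hyb-1").sequence
            == alignments["X"].record(sm.vouchers_of("sp01")[0]).sequence
        )
        assert (
            alignments["Y"].record("hyb-1").sequence
            == alignments["Y"].record(sm.vouchers_of("sp04")[0]).sequence
        )

    def test_missing_parent_rejected(self):
        cfg = SimConfig(
            seed=3, n_species=4, n_hard_cluster_species=0, with_hybrid=False,
            loci=[LocusConfig("X", 100, 0.05)],
        )
        panel = simulate_panel(cfg)
        with pytest.raises(ValueError):
            make_hybrid(
                panel.alignments, panel.species_map,
                HybridSpec("hyb", "sp01", "ghost", {"X": 1}),
            )


class TestPanelShape:
    def test_paph21_composition(self):
        panel = paph21_panel(seed=4)
        species = set(panel.species_map.mapping.values())
        assert len(species - {"outgroup"}) == 21  # 20 + hybrid
        assert len(panel.truth.hard_cluster) == 5
        assert set(panel.alignments) == {"ITS", "matK", "trnL"}
        assert panel.truth.barcodes == ["ITS", "matK", "trnL", "ITS+matK"]

    def test_deterministic_given_seed(self):
        p1, p2 = paph21_panel(seed=6), paph21_panel(seed=6)
        for locus in p1.alignments:
            assert [r.sequence for r in p1.alignments[locus].records] == [
                r.sequence for r in p2.alignments[locus].records
            ]
        assert p1.truth.expected_resolvable == p2.truth.expected_resolvable

    def test_hard_cluster_shares_haplotypes(self):
        panel = paph21_panel(seed=4)
        cluster = panel.truth.hard_cluster
        aln = panel.alignments["matK"]
        seqs = {aln.record(f"{sp}-1").sequence for sp in cluster}
        assert len(seqs) == 1

    def test_cluster_absent_from_expected_sets(self):
        panel = paph21_panel(seed=4)
        for name, resolved in panel.truth.expected_tree_resolved.items():
            assert not (set(panel.truth.hard_cluster) & resolved)

    def test_variable_rate_calibration(self):
        its = [
            locus_stats(paph21_panel(seed=s).alignments["ITS"]).rate_pct
            for s in range(3)
        ]
        assert all(22.7 <= r <= 42.7 for r in its)  # within 10 points of 32.7
        slow = []
        for s in range(3):
            cfg = SimConfig(
                seed=s, loci=[LOCUS_PRESETS["rpoC1"], LOCUS_PRESETS["trnL"]]
            )
            slow.append(
                locus_stats(simulate_panel(cfg).alignments["rpoC1"]).rate_pct
            )
        assert all(r <= 3.7 for r in slow)  # within 2 points of 1.7

    def test_emitted_files_reparse(self, tmp_path):
        panel = paph21_panel(seed=2)
        paths = emit_panel(panel, tmp_path)
        for locus in panel.alignments:
            back = read_alignment(paths[f"fasta:{locus}"], locus)
            assert back == panel.alignments[locus]
        assert paths["truth"].exists() and paths["species_tree"].exists()
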