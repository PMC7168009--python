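"""Synthetic barcode panels with known ground truth.

The generator emulates the shape of a multi-species orchid barcoding study:
an ultrametric Yule species tree plus outgroup, per-locus sequences evolved
under a Kimura 2-parameter process at locus-specific rates (an ITS-like
fast nuclear locus versus slowly evolving plastid loci), a handful of
conspecific samples per species that are identical up to occasional
single-substitution variants, one "hard" cluster of species sharing
identical sequences, one hybrid species whose loci copy different parents,
and planted species-diagnostic substitutions and indel fragments.

Ground truth (which species each barcode should resolve) is computed
constructively from the emitted sequences with a plain haplotype-identity
rule plus the planting registry - never by running tree inference - so the
closed-loop tests genuinely exercise the analysis pipeline.

Indels are planted rather than evolved: truth must be exact.
One master seed drives per-purpose substreams (``numpy`` SeedSequence
spawning), so adding a locus does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .diagnostics import DiagnosticCharacter
from .multilocus import concatenate
from .seqio import Alignment, NUCLEOTIDES, SampleRecord, SpeciesMap
from .tree import Node, Tree

_BASES = np.array(list(NUCLEOTIDES))


@dataclass(frozen=True)
class LocusConfig:
    """Per-locus generator settings.

    ``rate_scale`` multiplies tree branch lengths (substitutions/site over
    the whole tree height); ``kappa`` is the transition/transversion rate
    ratio; ``n_background_indels`` shared (two-species) gap fragments keep
    the indel machinery exercised without minting diagnostics.
    """

    name: str
    length: int
    rate_scale: float
    kappa: float = 2.0
    n_background_indels: int = 0
    indel_span: tuple[int, int] = (4, 12)


#: presets calibrated so emitted variable rates track the study-like profile
#: (fast ITS-like nuclear locus ~33%, slow plastid loci down to ~2%)
LOCUS_PRESETS: dict[str, LocusConfig] = {
    "ITS": LocusConfig("ITS", 725, 0.044, kappa=2.0, n_background_indels=6),
    "matK": LocusConfig("matK", 1132, 0.011, kappa=2.0, n_background_indels=1),
    "trnL": LocusConfig("trnL", 466, 0.0075, kappa=2.0, n_background_indels=2),
    "rpoB": LocusConfig("rpoB", 483, 0.0028, kappa=2.0),
    "rpoC1": LocusConfig("rpoC1", 460, 0.0014, kappa=2.0),
}


@dataclass(frozen=True)
class HybridSpec:
    child: str
    parent1: str
    parent2: str
    origin: dict[str, int] = field(default_factory=dict)  # locus -> 1 or 2
    noise_substitutions: int = 0


@dataclass
class SimConfig:
    n_species: int = 20  # non-hybrid ingroup species on the tree
    samples_per_species: tuple[int, int] = (3, 5)
    loci: list[LocusConfig] = field(
        default_factory=lambda: [
            LOCUS_PRESETS["ITS"],
            LOCUS_PRESETS["matK"],
            LOCUS_PRESETS["trnL"],
        ]
    )
    intra_variant_prob: float = 0.3  # chance a species carries one 1-sub variant
    n_hard_cluster_species: int = 5
    hybrid: Optional[HybridSpec] = None  # default: built against tree-distant parents
    with_hybrid: bool = True
    outgroup_divergence: float = 1.5
    min_interspecies_diff: int = 3
    n_diagnostic_substitutions: int = 3  # species receiving planted substitutions
    substitutions_per_target: int = 3  # columns per species: keeps the planted
    # species several sites from any haplotype it may have merged with
    n_diagnostic_indels: int = 2  # planted on hard-cluster species, first locus
    diagnostic_indel_span: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.samples_per_species[0] < 1:
            raise ValueError("samples per species must be positive")
        if any(l.kappa <= 0 for l in self.loci):
            raise ValueError("kappa must be positive")


@dataclass
class SyntheticTruth:
    species_tree_newick: str
    species_map: SpeciesMap
    planted: dict[str, list[DiagnosticCharacter]]  # locus -> characters
    hybrid: Optional[HybridSpec]
    hard_cluster: tuple[str, ...]
    barcodes: list[str]
    expected_tree_resolved: dict[str, frozenset[str]]
    expected_resolvable: dict[str, frozenset[str]]


@dataclass
class SyntheticPanel:
    alignments: dict[str, Alignment]
    species_map: SpeciesMap
    truth: SyntheticTruth
    config: SimConfig


# -- species tree ---------------------------------------------------------


def simulate_species_tree(
    n_species: int, seed, *, outgroup_divergence: float = 1.5
) -> Tree:
    """Ultrametric Yule (pure-birth) tree, unit crown height, plus outgroup.

    Ingroup leaves are named sp01..spNN in traversal order, the outgroup
    leaf "outgroup"; the outgroup attaches below the ingroup crown so every
    leaf sits at depth ``outgroup_divergence``.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    crown = Node()
    birth = {id(crown): 0.0}
    tips = [crown]
    t = 0.0
    while len(tips) < n_species:
        t += rng.exponential(1.0 / len(tips))
        node = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            child = Node()
            birth[id(child)] = t
            node.add(child)
            tips.append(child)
    t += rng.exponential(1.0 / n_species)
    # normalise so the crown (first split) sits at height 1 above the leaves
    height = t - birth[id(crown.children[0])]
    for node in crown.walk():
        if node is crown:
            continue
        end = t if node.is_leaf else birth[id(node.children[0])]
        node.length = (end - birth[id(node)]) / height
    for k, leaf in enumerate(crown.leaves(), start=1):
        leaf.name = f"sp{k:02d}"

    root = Node()
    crown.length = max(outgroup_divergence - 1.0, 0.0)
    root.add(crown)
    root.add(Node("outgroup", outgroup_divergence))
    return Tree(root, rooted=True)


# -- sequence evolution ---------------------------------------------------


def _k2p_probabilities(t: float, kappa: float) -> np.ndarray:
    """4x4 K2P transition-probability matrix for branch length t (subs/site).

    ``kappa`` is the transition:transversion bias expressed as the expected
    ratio of observed transition to transversion counts at low divergence
    (total transition rate over total transversion rate).  Rates are
    normalised to one expected substitution per site per unit length; base
    codes A=0, C=1, G=2, T=3 (the transition partner of code c is
    (c + 2) mod 4).
    """
    alpha = kappa / (kappa + 1.0)
    beta = 1.0 / (2.0 * (kappa + 1.0))
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    same = 0.25 + 0.25 * e1 + 0.5 * e2
    ts = 0.25 + 0.25 * e1 - 0.5 * e2
    tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), tv)
    np.fill_diagonal(P, same)
    for c in range(4):
        P[c, (c + 2) % 4] = ts
    return P


def _evolve_states(parent: np.ndarray, t: float, kappa: float, rng) -> np.ndarray:
    if t <= 0:
        return parent.copy()
    P = _k2p_probabilities(t, kappa)
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent.shape[0])
    return (u[:, None] > cum[parent]).sum(axis=1).astype(np.int8)


def evolve_haplotypes(tree: Tree, cfg: LocusConfig, rng) -> dict[str, str]:
    """One sequence per leaf: root uniform over ACGT, K2P along branches."""
    root_states = rng.integers(0, 4, size=cfg.length).astype(np.int8)
    out: dict[str, str] = {}

    def rec(node: Node, states: np.ndarray):
        for child in node.children:
            child_states = _evolve_states(
                states, child.length * cfg.rate_scale, cfg.kappa, rng
            )
            if child.is_leaf:
                out[child.name] = "".join(_BASES[child_states])
            else:
                rec(child, child_states)

    rec(tree.root, root_states)
    return out


def evolve_alignment(
    tree: Tree, cfg: LocusConfig, samples_per_species, seed
) -> Alignment:
    """Haplotypes expanded to conspecific samples (voucher "<species>-<k>").

    ``samples_per_species`` is an int or an (lo, hi) inclusive range drawn
    per species.  Intraspecific variation is not added here; the panel
    generator plants it explicitly so truth stays exact.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    haplotypes = evolve_haplotypes(tree, cfg, rng)
    records = []
    for species, seq in haplotypes.items():
        if isinstance(samples_per_species, int):
            k = samples_per_species
        else:
            lo, hi = samples_per_species
            k = int(rng.integers(lo, hi + 1))
        for i in range(1, k + 1):
            records.append(SampleRecord(f"{species}-{i}", species, cfg.name, seq))
    return Alignment(cfg.name, records)


# -- panel assembly -------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _enforce_min_diff(
    haps: dict[str, str], species: list[str], min_diff: int
) -> dict[str, str]:
    """Collapse species pairs separated by fewer than ``min_diff`` sites.

    Pairs that evolved identical haplotypes stay identical, and pairs one or
    two substitutions apart are merged onto the alphabetically first
    species' haplotype - emulating the chance haplotype sharing that makes
    low-variability plastid loci resolve few species, while ensuring that
    any two *distinct* species haplotypes differ at several sites (so
    species monophyly on the inferred tree is not left to tie-breaking).
    """
    haps = dict(haps)
    for _ in range(len(species)):
        dirty = False
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                if 0 < _hamming(haps[a], haps[b]) < min_diff:
                    haps[b] = haps[a]
                    dirty = True
        if not dirty:
            return haps
    raise RuntimeError("haplotype merging did not converge")


def _choose_parents(
    species: list[str],
    haps1: dict[str, str],
    haps2: dict[str, str],
    avoid_parent1: frozenset[str] = frozenset(),
    avoid_parent2: frozenset[str] = frozenset(),
) -> tuple[str, str]:
    """The maximally separated eligible parent pair.

    On the combined barcode the hybrid sits at distance d_locus2(p1, p2)
    from parent1 and d_locus1(p1, p2) from parent2, so the pair maximising
    the smaller of the two keeps the hybrid's placement well away from both
    parents.  Each parent is distinguishable from the hybrid only through
    the locus donated by the *other* parent and must not share a haplotype
    with a third species there (the ``avoid`` sets), otherwise its own
    placement is not predictable.
    """
    def search(c1, c2):
        best = None
        for a in c1:
            for b in c2:
                if a == b:
                    continue
                score = min(
                    _hamming(haps1[a], haps1[b]), _hamming(haps2[a], haps2[b])
                )
                key = (-score, a, b)
                if best is None or key < best:
                    best = key
        return best

    c1 = [s for s in species if s not in avoid_parent1] or list(species)
    c2 = [s for s in species if s not in avoid_parent2] or list(species)
    best = search(c1, c2) or search(list(species), list(species))
    if best is None:
        raise ValueError("no eligible hybrid parent pair")
    return best[1], best[2]


def make_hybrid(
    alignments: dict[str, Alignment],
    sm: SpeciesMap,
    hybrid: HybridSpec,
    *,
    n_samples: int = 3,
    rng=None,
) -> tuple[dict[str, Alignment], SpeciesMap]:
    """Add hybrid samples copying parent1 or parent2 per locus.

    With ``noise_substitutions`` = 0 (default) the hybrid sequences equal the
    parental haplotype exactly on every locus.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    for parent in (hybrid.parent1, hybrid.parent2):
        if not sm.vouchers_of(parent):
            raise ValueError(f"hybrid parent {parent!r} not sampled")
    new_alignments = {}
    mapping = dict(sm.mapping)
    for k in range(1, n_samples + 1):
        mapping[f"{hybrid.child}-{k}"] = hybrid.child
    for locus, aln in alignments.items():
        parent = hybrid.parent1 if hybrid.origin.get(locus, 1) == 1 else hybrid.parent2
        donor = aln.record(sm.vouchers_of(parent)[0]).sequence
        records = list(aln.records)
        for k in range(1, n_samples + 1):
            seq = list(donor)
            for _ in range(hybrid.noise_substitutions):
                col = int(rng.integers(len(seq)))
                if seq[col] in NUCLEOTIDES:
                    alt = [x for x in NUCLEOTIDES if x != seq[col]]
                    seq[col] = alt[int(rng.integers(3))]
            records.append(
                SampleRecord(f"{hybrid.child}-{k}", hybrid.child, locus, "".join(seq))
            )
        new_alignments[locus] = Alignment(locus, records)
    return new_alignments, SpeciesMap(mapping, sm.outgroup_species)


def _free_span(
    aln_cols: set[int], length: int, span: int, rng, *, margin: int = 2
) -> tuple[int, int]:
    """A non-terminal span of ``span`` columns avoiding ``aln_cols``."""
    for _ in range(500):
        start = int(rng.integers(1 + margin, length - span - margin))
        cols = set(range(start, start + span))
        if not (cols & aln_cols):
            return start, start + span - 1
    raise RuntimeError("no free span for indel planting")


def _visible_diff_outside(a: str, b: str, start: int, end: int, cap: int) -> int:
    """Site differences at mutually unambiguous columns outside [start, end]
    (1-based); counting stops at ``cap``."""
    d = 0
    for c, (x, y) in enumerate(zip(a, b), start=1):
        if start <= c <= end:
            continue
        if x in NUCLEOTIDES and y in NUCLEOTIDES and x != y:
            d += 1
            if d >= cap:
                return d
    return d


def _masking_ok(
    rep: dict[str, str], carriers: set[str], start: int, end: int, min_diff: int
) -> bool:
    """Would gapping [start, end] in ``carriers`` leave every affected pair
    of species either identical or >= min_diff visible sites apart?

    Gap spans hide the columns they cover, so an unvalidated span can pull
    two distinct species to within a couple of visible sites - close enough
    that neighbor joining may interleave their samples - or collapse them
    to apparent identity, silently changing which species count as
    distinct.  Only pairs that were already identical may stay identical.
    """
    species = list(rep)
    for i, x in enumerate(species):
        for y in species[i + 1 :]:
            if x not in carriers and y not in carriers:
                continue
            d_out = _visible_diff_outside(rep[x], rep[y], start, end, min_diff)
            if d_out >= min_diff:
                continue
            d_in = sum(
                1
                for c in range(start, end + 1)
                if rep[x][c - 1] in NUCLEOTIDES
                and rep[y][c - 1] in NUCLEOTIDES
                and rep[x][c - 1] != rep[y][c - 1]
            )
            if d_out + d_in > 0:  # a distinct pair would fall below min_diff
                return False
    return True


def plant_diagnostics(
    aln: Alignment,
    sm: SpeciesMap,
    spec: list[tuple[str, str]],
    seed,
    *,
    indel_span: int = 8,
    reserved_columns: Optional[set[int]] = None,
    min_interspecies_diff: int = 3,
) -> tuple[Alignment, list[DiagnosticCharacter]]:
    """Overwrite the alignment with planted diagnostics and return the truth.

    ``spec`` lists (species, kind) with kind in substitution / indel_absence
    (the species alone is gapped) / indel_presence (everyone else is gapped).
    Raises when no suitable column or span is free.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqs = {rec.voucher: list(rec.sequence) for rec in aln.records}
    used = set(reserved_columns or set())
    for voucher, seq in seqs.items():
        for c, ch in enumerate(seq, start=1):
            if ch == "-":
                used.add(c)
    truth: list[DiagnosticCharacter] = []
    ingroup = [v for v in aln.vouchers if sm.species_of(v) != sm.outgroup_species]

    for species, kind in spec:
        members = [v for v in ingroup if sm.species_of(v) == species]
        if not members:
            raise ValueError(f"species {species!r} not sampled")
        others = [v for v in ingroup if v not in members]
        if kind == "substitution":
            planted = False
            for _ in range(1000):
                col = int(rng.integers(1, aln.length + 1))
                if col in used:
                    continue
                present = {seqs[v][col - 1] for v in aln.vouchers}
                free = [b for b in NUCLEOTIDES if b not in present]
                if not free:
                    continue
                base = free[int(rng.integers(len(free)))]
                for v in members:
                    seqs[v][col - 1] = base
                used.add(col)
                truth.append(
                    DiagnosticCharacter(species, aln.locus, kind, col, col, base)
                )
                planted = True
                break
            if not planted:
                raise RuntimeError(f"no free column to plant for {species!r}")
        elif kind in ("indel_absence", "indel_presence"):
            ingroup_species = sorted({sm.species_of(v) for v in ingroup})
            rep = {
                sp: "".join(seqs[next(v for v in ingroup if sm.species_of(v) == sp)])
                for sp in ingroup_species
            }
            carrier_species = (
                {species}
                if kind == "indel_absence"
                else set(ingroup_species) - {species}
            )
            for _ in range(200):
                start, end = _free_span(used, aln.length, indel_span, rng)
                if _masking_ok(rep, carrier_species, start, end, min_interspecies_diff):
                    break
            else:
                raise RuntimeError(f"no maskable span for {species!r}")
            targets = members if kind == "indel_absence" else [
                v for v in aln.vouchers if v not in members
            ]
            for v in targets:
                for c in range(start, end + 1):
                    seqs[v][c - 1] = "-"
            used.update(range(start, end + 1))
            truth.append(
                DiagnosticCharacter(
                    species, aln.locus, kind, start, end, f"{start}-{end}"
                )
            )
        else:
            raise ValueError(f"bad planting kind {kind!r}")

    records = [
        SampleRecord(rec.voucher, rec.species_label, rec.locus, "".join(seqs[rec.voucher]))
        for rec in aln.records
    ]
    return Alignment(aln.locus, records), truth


def _species_reps(aln: Alignment, sm: SpeciesMap) -> dict[str, str]:
    ingroup = sorted(
        {sm.species_of(r.voucher) for r in aln.records} - {sm.outgroup_species}
    )
    return {sp: aln.record(sm.vouchers_of(sp)[0]).sequence for sp in ingroup}


def _one_sided_victims(rep: dict[str, str]) -> list[tuple[str, str]]:
    """(victim, neighbor) pairs where the victim holds the bare ancestral
    haplotype: every site separating it from the neighbor is either shared
    with a third species or private to the neighbor.  Species identical to
    some other species are not victims (their verdict ignores monophyly).
    """
    ingroup = sorted(rep)
    nondistinct = set()
    for i, a in enumerate(ingroup):
        for b in ingroup[i + 1 :]:
            if _identical_over_comparable(rep[a], rep[b]):
                nondistinct |= {a, b}

    def a_private_exists(a: str, b: str) -> bool:
        sa, sb = rep[a], rep[b]
        for c in range(len(sa)):
            x, y = sa[c], sb[c]
            if x in NUCLEOTIDES and y in NUCLEOTIDES and x != y:
                if not any(rep[o][c] == x for o in ingroup if o not in (a, b)):
                    return True
        return False

    out = []
    for a in ingroup:
        if a in nondistinct:
            continue
        for b in ingroup:
            if b == a or _identical_over_comparable(rep[a], rep[b]):
                continue
            if not a_private_exists(a, b):
                out.append((a, b))
    return out


def _inject_private_site(aln: Alignment, sm: SpeciesMap, species: str, rng) -> Alignment:
    """Overwrite one gap-free column of the species' samples with a base
    carried by no other sample."""
    seqs = {rec.voucher: list(rec.sequence) for rec in aln.records}
    members = sm.vouchers_of(species)
    for _ in range(1000):
        col = int(rng.integers(1, aln.length + 1))
        column = {q[col - 1] for q in seqs.values()}
        if "-" in column:
            continue
        free = [x for x in NUCLEOTIDES if x not in column]
        if not free:
            continue
        base = free[int(rng.integers(len(free)))]
        for v in members:
            seqs[v][col - 1] = base
        break
    else:
        raise RuntimeError(f"no free column for asymmetry guard on {species!r}")
    return Alignment(
        aln.locus,
        [
            SampleRecord(r.voucher, r.species_label, r.locus, "".join(seqs[r.voucher]))
            for r in aln.records
        ],
    )


def _apply_asymmetry_guard(aln: Alignment, sm: SpeciesMap, rng) -> Alignment:
    """Remove one-sided species pairs on a single locus.

    Neighbor joining's rate correction makes a species paraphyletic when a
    close neighbor differs from it only by neighbor-private sites; every
    distinct species therefore receives at least one private site of its
    own (an extra chance-diagnostic column, reported by the truth scan).
    """
    victims = {a for a, _ in _one_sided_victims(_species_reps(aln, sm))}
    for species in sorted(victims):
        aln = _inject_private_site(aln, sm, species, rng)
    return aln


def _combined_asymmetry_guard(
    alignments: dict[str, Alignment],
    sm: SpeciesMap,
    locus_names: list[str],
    min_diff: int,
    rng,
) -> dict[str, Alignment]:
    """Remove one-sided pairs on the two-locus supermatrix.

    A pair can be one-sided on the concatenation without being one-sided on
    either locus (the hybrid versus its parents is the canonical case: it
    differs from one parent only by the other parent's sites).  The private
    site is injected into a locus where the pair already differs by at
    least ``min_diff`` visible sites, so no locus acquires a new
    near-identical pair.
    """
    for _ in range(5):
        combined = concatenate([alignments[l] for l in locus_names], sm)
        victims = _one_sided_victims(_species_reps(combined, sm))
        if not victims:
            return alignments
        injected: set[tuple[str, str]] = set()
        progress = False
        for a, b in victims:
            reps_by_locus = {
                l: _species_reps(alignments[l], sm) for l in locus_names
            }
            for l in locus_names:
                rep = reps_by_locus[l]
                d = _visible_diff_outside(rep[a], rep[b], 0, 0, min_diff)
                # the locus must keep every pair involving ``a`` non-fragile:
                # ``a`` has to be distinct from *all* species there already
                # (the hybrid, identical to a parent on each locus, never
                # qualifies and is simply skipped)
                distinct_everywhere = all(
                    o == a or not _identical_over_comparable(rep[a], rep[o])
                    for o in rep
                )
                if d >= min_diff and distinct_everywhere and (a, l) not in injected:
                    alignments = dict(alignments)
                    alignments[l] = _inject_private_site(alignments[l], sm, a, rng)
                    injected.add((a, l))
                    progress = True
                    break
        if not progress:
            return alignments
    return alignments


# -- truth: haplotype-identity rule (independent of tree inference) -------


def _identical_over_comparable(a: str, b: str) -> bool:
    comparable = False
    for x, y in zip(a, b):
        if x in NUCLEOTIDES and y in NUCLEOTIDES:
            comparable = True
            if x != y:
                return False
    return comparable


def naive_diagnostic_species(aln: Alignment, sm: SpeciesMap) -> frozenset[str]:
    """Species holding at least one diagnostic character, by brute force.

    A deliberately plain reimplementation (per-column loops, per-sequence
    gap-run scans) used only for ground truth: planted characters plus any
    chance collisions - a column or gap span that happens to single out a
    species - must both appear in the expected sets.
    """
    records = [
        rec for rec in aln.records if sm.species_of(rec.voucher) != sm.outgroup_species
    ]
    species_of = {rec.voucher: sm.species_of(rec.voucher) for rec in records}
    out: set[str] = set()
    n_cols = aln.length
    for col in range(n_cols):
        states: dict[str, set[str]] = {}
        for rec in records:
            states.setdefault(species_of[rec.voucher], set()).add(rec.sequence[col])
        for sp, own in states.items():
            if sp in out or len(own) != 1:
                continue
            base = next(iter(own))
            if base not in NUCLEOTIDES:
                continue
            if not any(base in other for s, other in states.items() if s != sp):
                out.add(sp)
    # gap spans: maximal runs per sequence, then the exact-span partition test
    spans: set[tuple[int, int]] = set()
    for rec in records:
        start = None
        for c, ch in enumerate(rec.sequence + "x"):
            if ch == "-" and start is None:
                start = c
            elif ch != "-" and start is not None:
                if start > 0 and c < n_cols:  # non-terminal runs only
                    spans.add((start, c - 1))
                start = None
    for start, end in spans:
        gapped = {
            rec.voucher
            for rec in records
            if all(ch == "-" for ch in rec.sequence[start : end + 1])
        }
        for sp in set(species_of.values()) - out:
            members = {v for v, s in species_of.items() if s == sp}
            rest = set(species_of) - members
            if (members <= gapped and not (rest & gapped)) or (
                not (members & gapped) and rest <= gapped
            ):
                out.add(sp)
    return frozenset(out)


def expected_tree_resolved(aln: Alignment, sm: SpeciesMap) -> frozenset[str]:
    """Species with no cross-species identical sample (identity rule).

    Conspecific samples in the generated panels are identical up to planted
    single-site variants while distinct species differ at several sites, so
    species monophyly on the inferred tree is expected exactly when no
    sample is sequence-identical to another species; this predicts the tree
    verdict without running tree inference.
    """
    groups: dict[str, list[str]] = {}
    rep: dict[str, str] = {}
    for rec in aln.records:
        if sm.species_of(rec.voucher) == sm.outgroup_species:
            continue
        rep.setdefault(rec.sequence, rec.sequence)
        groups.setdefault(rec.sequence, []).append(rec.voucher)
    uniques = list(groups)
    clash: set[str] = set()
    for i, a in enumerate(uniques):
        for b in uniques[i:]:
            species_a = {sm.species_of(v) for v in groups[a]}
            species_b = {sm.species_of(v) for v in groups[b]}
            if a is b:
                if len(species_a) > 1:
                    clash |= species_a
                continue
            if _identical_over_comparable(a, b) and species_a != species_b:
                clash |= species_a | species_b
    return frozenset(sp for sp in sm.ingroup_species() if sp not in clash)


# -- the full generator ---------------------------------------------------


def simulate_panel(cfg: SimConfig) -> SyntheticPanel:
    """Generate a panel plus exact truth under the configured conditions."""
    ss = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["tree", "layout"] + [f"locus:{l.name}" for l in cfg.loci],
            ss.spawn(2 + len(cfg.loci)),
        )
    }
    tree = simulate_species_tree(
        cfg.n_species, streams["tree"], outgroup_divergence=cfg.outgroup_divergence
    )
    layout = streams["layout"]
    species = [f"sp{k:02d}" for k in range(1, cfg.n_species + 1)]

    # pass A: evolve haplotypes per locus, merging near-identical species,
    # so that hybrid parents and diagnostic targets can be chosen among
    # species that share a haplotype with no one on any locus
    haplotypes: dict[str, dict[str, str]] = {}
    for lc in cfg.loci:
        rng = streams[f"locus:{lc.name}"]
        haps = evolve_haplotypes(tree, lc, rng)
        haps = {
            **_enforce_min_diff(
                {sp: haps[sp] for sp in species}, species, cfg.min_interspecies_diff
            ),
            "outgroup": haps["outgroup"],
        }
        haplotypes[lc.name] = haps

    def _entangled_map() -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for lc in cfg.loci:
            haps = haplotypes[lc.name]
            tangle: set[str] = set()
            for i, a in enumerate(species):
                for b in species[i + 1 :]:
                    if haps[a] == haps[b]:
                        tangle |= {a, b}
            out[lc.name] = tangle
        return out

    entangled_on = _entangled_map()
    if len(cfg.loci) >= 2:
        # cross-locus consolidation: a pair identical on one combined-barcode
        # locus whose only separating locus is itself shared with a third
        # species would be distinct on the concatenation yet unable to own a
        # private site there (deterministic NJ paraphyly); such pairs are made
        # identical on both loci and scored non-distinct instead
        l1, l2 = cfg.loci[0].name, cfg.loci[1].name
        for _ in range(10):
            changed = False
            for i, a in enumerate(species):
                for b in species[i + 1 :]:
                    e1 = haplotypes[l1][a] == haplotypes[l1][b]
                    e2 = haplotypes[l2][a] == haplotypes[l2][b]
                    if e1 == e2:
                        continue
                    l_other = l2 if e1 else l1
                    if {a, b} & entangled_on[l_other]:
                        haplotypes[l_other][b] = haplotypes[l_other][a]
                        changed = True
            if not changed:
                break
            entangled_on = _entangled_map()
    entangled: set[str] = set().union(*entangled_on.values())

    hybrid = cfg.hybrid
    if hybrid is None and cfg.with_hybrid:
        # parent1 donates the first locus, parent2 the rest: each must be
        # clean on the other's combined-barcode partition
        first, second = cfg.loci[0].name, cfg.loci[min(1, len(cfg.loci) - 1)].name
        p1, p2 = _choose_parents(
            species,
            haplotypes[first],
            haplotypes[second],
            frozenset(entangled_on[second]),
            frozenset(entangled_on[first]),
        )
        origin = {l.name: (1 if i == 0 else 2) for i, l in enumerate(cfg.loci)}
        hybrid = HybridSpec("hybrid01", p1, p2, origin)
    protected = {hybrid.parent1, hybrid.parent2} if hybrid else set()
    eligible = [sp for sp in species if sp not in protected]
    cluster = tuple(
        sorted(
            layout.choice(eligible, size=min(cfg.n_hard_cluster_species, len(eligible)), replace=False)
        )
    )
    for lc in cfg.loci:
        for sp in cluster[1:]:
            haplotypes[lc.name][sp] = haplotypes[lc.name][cluster[0]]
    entangled |= set(cluster)

    n_samples = {
        sp: int(layout.integers(cfg.samples_per_species[0], cfg.samples_per_species[1] + 1))
        for sp in species
    }
    n_samples["outgroup"] = 1
    variant_species = {
        sp for sp in species if layout.random() < cfg.intra_variant_prob
    }

    # diagnostic targets: substitutions on clean species, indels on cluster
    safe = [
        sp
        for sp in species
        if sp not in cluster and sp not in protected and sp not in entangled
    ]
    sub_targets = list(
        layout.choice(safe, size=min(cfg.n_diagnostic_substitutions, len(safe)), replace=False)
    )
    indel_targets = list(cluster[: cfg.n_diagnostic_indels])
    indel_kinds = ["indel_absence", "indel_presence"]

    alignments: dict[str, Alignment] = {}
    planted: dict[str, list[DiagnosticCharacter]] = {}
    mapping: dict[str, str] = {}

    for locus_idx, lc in enumerate(cfg.loci):
        rng = streams[f"locus:{lc.name}"]
        haps = haplotypes[lc.name]

        records = []
        for sp in species + ["outgroup"]:
            for i in range(1, n_samples[sp] + 1):
                seq = haps[sp]
                if sp in variant_species and i == n_samples[sp]:
                    chars = list(seq)
                    col = int(rng.integers(lc.length))
                    alt = [b for b in NUCLEOTIDES if b != chars[col]]
                    chars[col] = alt[int(rng.integers(3))]
                    seq = "".join(chars)
                records.append(SampleRecord(f"{sp}-{i}", sp, lc.name, seq))
                mapping[f"{sp}-{i}"] = sp
        aln = Alignment(lc.name, records)

        # background indels: same fragment carried by two species
        seqs = {rec.voucher: list(rec.sequence) for rec in aln.records}
        used: set[int] = set()
        for _ in range(lc.n_background_indels):
            span = int(rng.integers(lc.indel_span[0], lc.indel_span[1] + 1))
            carriers = rng.choice(species, size=2, replace=False)
            carrier_set = set(carriers)
            if carrier_set & set(cluster):
                carrier_set |= set(cluster)  # keep the cluster sequence-identical
            rep = {sp: "".join(seqs[f"{sp}-1"]) for sp in species}
            for _ in range(200):
                start, end = _free_span(used, lc.length, span, rng)
                if _masking_ok(rep, carrier_set, start, end, cfg.min_interspecies_diff):
                    break
            else:
                continue  # no safe span for these carriers; skip this indel
            for sp in carrier_set:
                for v in [f"{sp}-{i}" for i in range(1, n_samples[sp] + 1)]:
                    for c in range(start, end + 1):
                        seqs[v][c - 1] = "-"
            used.update(range(start, end + 1))
        aln = Alignment(
            lc.name,
            [
                SampleRecord(r.voucher, r.species_label, r.locus, "".join(seqs[r.voucher]))
                for r in aln.records
            ],
        )
        alignments[lc.name] = aln
        planted[lc.name] = []

    sm = SpeciesMap(mapping, "outgroup")
    if hybrid:
        alignments, sm = make_hybrid(
            alignments, sm, hybrid, n_samples=3, rng=layout
        )

    # plant diagnostics after the hybrid so its copies cannot erase them
    for locus_idx, lc in enumerate(cfg.loci):
        rng = streams[f"locus:{lc.name}"]
        spec: list[tuple[str, str]] = [
            (sp, "substitution")
            for sp in sub_targets
            for _ in range(cfg.substitutions_per_target)
        ]
        if locus_idx == 0:
            spec += list(zip(indel_targets, indel_kinds))
        aln, truth_entries = plant_diagnostics(
            alignments[lc.name],
            sm,
            spec,
            rng,
            indel_span=cfg.diagnostic_indel_span,
            min_interspecies_diff=cfg.min_interspecies_diff,
        )
        aln = _apply_asymmetry_guard(aln, sm, rng)
        alignments[lc.name] = aln
        planted[lc.name] = truth_entries

    barcodes = [lc.name for lc in cfg.loci]
    if len(cfg.loci) >= 2:
        alignments = _combined_asymmetry_guard(
            alignments, sm, barcodes[:2], cfg.min_interspecies_diff, layout
        )

    # truth: per-locus barcodes plus the two-locus combination
    combined_name = None
    if len(cfg.loci) >= 2:
        combined = concatenate([alignments[barcodes[0]], alignments[barcodes[1]]], sm)
        combined_name = combined.locus
    tree_resolved: dict[str, frozenset[str]] = {}
    resolvable: dict[str, frozenset[str]] = {}
    char_species: dict[str, frozenset[str]] = {}
    for name in barcodes:
        tree_resolved[name] = expected_tree_resolved(alignments[name], sm)
        char_species[name] = naive_diagnostic_species(alignments[name], sm)
        resolvable[name] = tree_resolved[name] | char_species[name]
    if combined_name:
        tree_resolved[combined_name] = expected_tree_resolved(combined, sm)
        # a column diagnostic on a locus stays diagnostic on the supermatrix
        char_species[combined_name] = char_species[barcodes[0]] | char_species[barcodes[1]]
        resolvable[combined_name] = (
            tree_resolved[combined_name] | char_species[combined_name]
        )

    truth = SyntheticTruth(
        species_tree_newick=tree.to_newick(),
        species_map=sm,
        planted=planted,
        hybrid=hybrid,
        hard_cluster=cluster,
        barcodes=barcodes + ([combined_name] if combined_name else []),
        expected_tree_resolved=tree_resolved,
        expected_resolvable=resolvable,
    )
    return SyntheticPanel(alignments, sm, truth, cfg)


def paph21_panel(seed: int = 0) -> SyntheticPanel:
    """The packaged default panel: 21 ingroup species (20 on the tree plus
    one hybrid) and an outgroup, three loci of contrasting variability,
    a five-species hard cluster and planted diagnostics."""
    return simulate_panel(SimConfig(seed=seed))


# -- emission -------------------------------------------------------------


def emit_panel(panel: SyntheticPanel, outdir) -> dict[str, Path]:
    """Write FASTA per locus, metadata TSV, species tree and truth JSON."""
    from .seqio import write_alignment, write_species_map

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for locus, aln in panel.alignments.items():
        p = outdir / f"{locus}.fasta"
        write_alignment(aln, p)
        paths[f"fasta:{locus}"] = p
    p = outdir / "species_map.tsv"
    write_species_map(panel.species_map, p)
    paths["species_map"] = p
    p = outdir / "species_tree.nwk"
    p.write_text(panel.truth.species_tree_newick + "\n")
    paths["species_tree"] = p
    truth = {
        "barcodes": panel.truth.barcodes,
        "hard_cluster": list(panel.truth.hard_cluster),
        "hybrid": asdict(panel.truth.hybrid) if panel.truth.hybrid else None,
        "expected_tree_resolved": {
            k: sorted(v) for k, v in panel.truth.expected_tree_resolved.items()
        },
        "expected_resolvable": {
            k: sorted(v) for k, v in panel.truth.expected_resolvable.items()
        },
        "planted": {
            locus: [asdict(d) for d in diags]
            for locus, diags in panel.truth.planted.items()
        },
    }
    p = outdir / "truth.json"
    p.write_text(json.dumps(truth, indent=2) + "\n")
    paths["truth"] = p
    return paths
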