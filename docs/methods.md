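# Methods

## Scope and data model

The package evaluates candidate DNA barcodes on a panel of pre-aligned
per-locus sequences. Alignment construction, chromatogram handling and
primer design are out of scope: inputs are aligned multi-FASTA files with
one record per specimen (voucher, species label, locus), plus a
designated outgroup species used only for rooting. Columns are 1-based
closed intervals throughout. Gaps (`-`), `N` and IUPAC ambiguity codes
are stored verbatim but treated as missing data by every analysis step.

## Polymorphism profiling

Each column is classified after dropping missing residues:
parsimony-informative (at least two bases each carried by at least two
sequences), singleton (variable but not informative), constant, or
uninformative (fewer than two residues left). Variable sites satisfy
V = P + S by construction; the reported variable rate is 100·V/L rounded
to one decimal. An indel fragment is a maximal run of gap characters
identified by its exact (start, end) span; identical spans in different
sequences are one fragment with several carriers, overlapping-but-unequal
spans are distinct fragments. Runs touching the alignment boundary are
flagged terminal and excluded by default, since trimmed ends produce
terminal gaps that are not indels.

## Distances

Pairwise comparisons use pairwise deletion by default (complete deletion
is available): a column contributes only when both sequences carry an
unambiguous base. Transitions are A↔G and C↔T; everything else is a
transversion. The Kimura 2-parameter distance is
d = −½·ln[(1 − 2P − Q)·√(1 − 2Q)] with P and Q the transition and
transversion difference proportions. When the log argument is
non-positive the pair is flagged saturated and assigned a finite ceiling
(default 10 substitutions/site) instead of failing, so degenerate inputs
still produce a tree. Group summaries (overall / within-species /
between-species mean) are unweighted means over unordered pairs; empty
strata are reported as undefined.

## Tree inference

Neighbor joining follows the Saitou–Nei agglomeration: join the pair
minimising Q(i,j) = (m−2)·d(i,j) − r(i) − r(j), with limb lengths from
the standard formulas and negative limbs clamped to zero without
redistribution. Ties in the Q minimum are broken on the
lexicographically smallest pair of cluster keys, a cluster's key being
the alphabetically first leaf it contains; this makes runs reproducible
where the classical algorithm is order-dependent. Outgroup rooting
places the root on the edge separating the outgroup from the ingroup,
splitting that edge's length equally; the outgroup must form one side of
a single edge, else the run fails with "outgroup not monophyletic".

Bootstrap supports resample columns with replacement, rebuild the
distance matrix and NJ tree per replicate, and count how often each
internal bipartition of the full-data tree recurs; supports are
integer-rounded percentages mapped onto the full-data tree rather than a
consensus, and a replicate that leaves some pair with no comparable
sites is redrawn and counted in the diagnostics log. The replicate
stream is driven by one seed, so supports are exactly reproducible.

## Species resolution

A species is tree-resolved on a barcode when (a) its samples form a
monophyletic clade on the rooted tree and (b) no sample of the species
is identical, over columns where both sequences carry a base, to a
sample of another ingroup species. Condition (b) exists because a
single-sample species is trivially a clade: without it, a singleton
whose sequence is indistinguishable from another species would be
scored resolved. Bootstrap support of the species clade is reported but
never thresholded — support and resolution are separate statements.

Diagnostic characters provide the second route: a column is diagnostic
for a species when every one of its samples carries the same base there
(missing data disqualifies — trimming artifacts must not mint
diagnostics) and no other ingroup sample carries that base; an indel
fragment is diagnostic when gap presence over its exact span perfectly
partitions the species from the rest of the ingroup, with the polarity
(unique deletion vs unique insertion) recorded. The outgroup never
participates. Alignment coordinates can be mapped to ungapped positions
of a chosen reference sample (count of reference residues up to the
column; columns inside a reference gap report the preceding residue with
a flag). The final verdict is monotone: tree-resolved OR at least one
diagnostic character.

## Multilocus combination and identification

Concatenation preserves locus order in a partition map. The default
policy is strict (only vouchers present in every locus); gap-padding is
explicit, because padding distorts distances even under pairwise
deletion. Query identification computes, per locus, the K2P-nearest
reference species and an exact-match flag, then places the query on an
outgroup-rooted NJ tree of references plus query; the final call
requires the tree placement and every locus's nearest species to agree,
anything less is reported ambiguous with the conflict spelled out. The
unanimity rule is deliberately conservative: the intended use is
flagging mislabeled or illegally traded material, where a false species
call is worse than no call.

## The synthetic panel generator

The generator emulates the shape of a multi-species orchid barcoding
study so that every pipeline stage can be tested against exact ground
truth. Components and defaults:

- **Species tree**: Yule pure-birth, 20 ingroup species, crown height
  normalised to 1, outgroup attached so every leaf sits at depth 1.5.
- **Sequences**: K2P evolution along the tree; `kappa` is the expected
  observed transition:transversion count ratio (default 2). Locus
  presets (length, rate scale) are calibrated so emitted variable rates
  track the pilot-screen profile: ITS-like 725 bp ≈ 33% variable, matK
  1132 bp ≈ 10%, trnL 466 bp ≈ 7%, rpoB ≈ 2.5%, rpoC1 ≈ 1.7%.
- **Samples**: 3–5 identical conspecific copies per species; ~30% of
  species carry one sample with a single-site variant.
- **Hard cluster**: five species share one haplotype on every locus —
  the unresolvable group every real panel contains.
- **Hybrid**: copies one parent's haplotype on the nuclear locus and the
  other parent's on the plastid loci (zero noise by default), so it is
  non-distinct per locus but owns a unique combined haplotype.
- **Planted characters**: three species receive three diagnostic
  substitution columns each on every locus; two hard-cluster species
  receive diagnostic indel fragments (one unique deletion, one unique
  insertion) on the fast locus — character-only resolution, since
  gap columns do not enter distances. Background (two-species) indel
  fragments keep the indel machinery exercised without being diagnostic.
- **Indels are planted, never evolved**: truth must be exact.
- One master seed drives per-purpose substreams (numpy `SeedSequence`
  spawning).

**Ground truth** is constructed, not inferred: the expected tree-resolved
set per barcode comes from a plain haplotype-identity rule (a species is
expected resolved iff none of its samples is identical-over-comparable-
sites to another species), and the expected character-resolved set from
a deliberately naive per-column / per-span scan of the emitted
alignments — planted characters plus any chance collisions. No tree is
ever built while computing truth, so the closed-loop tests genuinely
exercise the inference path.

Three generator guardrails make the identity rule a sound predictor of
NJ monophyly; all were driven by an actual property of neighbor joining:
the rate-corrected Q criterion deterministically interleaves a species'
identical samples with a close neighbor when that neighbor differs from
it only by neighbor-private sites (the species then holds the bare
ancestral haplotype and is paraphyletic — real NJ behaviour, not an
implementation artifact).

1. Species haplotypes closer than 3 sites on a locus are merged onto one
   haplotype (chance haplotype sharing, as slow plastid loci show);
   gap spans (background or planted) are validated so they never pull a
   distinct pair below that margin.
2. Every distinct species is given at least one private site against
   each neighbor (a fresh column with a base found nowhere else) when
   evolution left it without one — on each locus and again on the
   two-locus supermatrix, where injections go into a locus on which the
   species is already distinct from everyone.
3. Hybrid parents are chosen as the pair maximising the smaller
   per-locus distance among species that can own private sites on the
   locus the other parent donates; pairs identical on one combined-
   barcode locus whose only separating locus is itself shared with a
   third species are consolidated to full identity (scored non-distinct)
   rather than left in an unpredictable in-between state.

What the synthetic data does **not** emulate: realistic indel evolution,
recombination, heterozygous/chromatogram noise, rate heterogeneity
across sites, and base-composition bias. Passing the closed loop
therefore shows the pipeline is correct under the stated model, not that
any particular real panel will resolve a given number of species.

## Problem sizes and numerical choices

The closed-loop check runs the full study (three loci plus the combined
barcode, ~82 samples) on 20 fresh panels; it verifies the resolution
sets exactly and was additionally validated over 150 consecutive seeds
during development. Resolution verdicts do not depend on bootstrap
supports, so the closed loop runs with supports off; bootstrap behaviour
is checked separately (a constant-pattern alignment must give 100%
everywhere; a 6%-divergent split over 500 sites must reach ≥95% at 100
replicates). NJ correctness is checked against random additive matrices
(n ≤ 8, bipartition sets and branch lengths to 1e-9) and, in the unit
suite, cross-checked against an independent NJ implementation
(scikit-bio). Pipeline defaults follow the study conditions (K2P,
pairwise deletion, 1000 bootstrap replicates); the analysis drivers
accept `--replicates` for quicker runs.

## Known limitations

- NJ is the only tree method; likelihood/parsimony/Bayesian comparisons
  are out of scope by design.
- The identity rule used for ground truth presumes the generator's
  guardrails; arbitrary external alignments can of course produce
  monophyly patterns the rule would not predict (that is the pipeline's
  job to measure, not the generator's to anticipate).
- Diagnostic characters use strict fixation; majority or probabilistic
  diagnosability is not implemented.
- Query sequences must already be on reference coordinates; only a
  length check guards against unaligned input.
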