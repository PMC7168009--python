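"""End-to-end orchestration: resolution studies and query identification.

A run takes per-locus alignments (from files or an in-memory panel), builds
each configured barcode (single loci and concatenations), and produces the
full report bundle: locus statistics, distance matrix, rooted NJ tree with
optional bootstrap supports, tree-based resolution matrix, diagnostic
characters and combined verdicts, plus a cross-barcode summary.  Outputs
are deterministic given the configured seed; every run writes a resolved
copy of its configuration and a log naming package version and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .diagnostics import (
    CombinedVerdict,
    DiagnosticCharacter,
    combined_resolution,
    diagnostic_indels,
    diagnostic_substitutions,
    write_diagnostics_tsv,
)
from .distance import distance_matrix, group_mean_distances, write_distance_tsv
from .multilocus import (
    IdentificationResult,
    concatenate,
    identify_query,
    write_identification_tsv,
    write_partitions,
)
from .polymorphism import locus_stats, stats_table
from .resolution import (
    ResolutionReport,
    species_resolution,
    write_resolution_tsv,
)
from .seqio import (
    Alignment,
    SpeciesMap,
    read_alignment,
    read_records,
    read_species_map,
    write_newick,
)
from .treeinfer import (
    BootstrapConfig,
    bootstrap_support,
    neighbor_joining,
    root_with_outgroup,
)

logger = logging.getLogger("paphbarcode")

EXIT_VALIDATION = 2
EXIT_STAGE = 3


@dataclass
class RunConfig:
    locus_paths: dict[str, str] = field(default_factory=dict)  # locus -> FASTA
    metadata_path: Optional[str] = None  # TSV voucher -> species
    outgroup_species: str = "outgroup"
    model: str = "k2p"
    deletion: str = "pairwise"
    bootstrap_replicates: int = 1000
    seed: int = 0
    barcodes: Optional[list[list[str]]] = None  # default: singles + first two
    output_dir: str = "results"
    query_paths: dict[str, str] = field(default_factory=dict)  # identification mode

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class BarcodeBundle:
    barcode: str
    alignment: Alignment
    stats: "object"
    report: ResolutionReport
    diagnostics: list[DiagnosticCharacter]
    combined: dict[str, CombinedVerdict]
    tree: "object"

    @property
    def final_resolved(self) -> frozenset[str]:
        return frozenset(s for s, v in self.combined.items() if v.resolved_final)


@dataclass
class StudyResult:
    bundles: dict[str, BarcodeBundle]
    summary: dict[str, dict[str, int]]


def load_inputs(cfg: RunConfig) -> tuple[dict[str, Alignment], SpeciesMap]:
    if not cfg.locus_paths:
        raise ValueError("config names no locus input")
    sm = None
    if cfg.metadata_path:
        sm = read_species_map(cfg.metadata_path, cfg.outgroup_species)
    alignments = {
        locus: read_alignment(path, locus, species_map=sm)
        for locus, path in cfg.locus_paths.items()
    }
    if sm is None:
        mapping = {}
        for aln in alignments.values():
            for rec in aln.records:
                mapping[rec.voucher] = rec.species_label
        sm = SpeciesMap(mapping, cfg.outgroup_species)
    for aln in alignments.values():
        sm.validate(aln)
    return alignments, sm


def _barcode_plan(cfg: RunConfig, loci: list[str]) -> list[list[str]]:
    if cfg.barcodes:
        return cfg.barcodes
    plan = [[l] for l in loci]
    if len(loci) >= 2:
        plan.append(loci[:2])
    return plan


def analyse_barcode(
    name: str,
    aln: Alignment,
    sm: SpeciesMap,
    *,
    model: str = "k2p",
    deletion: str = "pairwise",
    bootstrap_replicates: int = 0,
    seed: int = 0,
) -> BarcodeBundle:
    """The per-barcode stage: stats, distances, rooted tree, verdicts."""
    stats = locus_stats(aln)
    if bootstrap_replicates > 0:
        tree, _diag = bootstrap_support(
            aln, model, BootstrapConfig(bootstrap_replicates, seed), deletion=deletion
        )
    else:
        tree = neighbor_joining(distance_matrix(aln, model, deletion=deletion))
    rooted = root_with_outgroup(tree, sm.outgroup_vouchers)
    report = species_resolution(rooted, aln, sm, barcode=name)
    diags = diagnostic_substitutions(aln, sm) + diagnostic_indels(aln, sm)
    combined = combined_resolution(report, diags)
    return BarcodeBundle(name, aln, stats, report, diags, combined, rooted)


def run_resolution_study(
    cfg: RunConfig,
    *,
    alignments: Optional[dict[str, Alignment]] = None,
    species_map: Optional[SpeciesMap] = None,
    write: bool = True,
) -> StudyResult:
    """Evaluate every configured barcode; optionally write the report bundle."""
    if alignments is None or species_map is None:
        alignments, species_map = load_inputs(cfg)
    loci = list(alignments)
    plan = _barcode_plan(cfg, loci)

    outdir = Path(cfg.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(outdir / "config.resolved.yaml")
        logging.basicConfig()
    logger.info("paphbarcode %s seed=%d", __version__, cfg.seed)

    bundles: dict[str, BarcodeBundle] = {}
    for combo in plan:
        name = "+".join(combo)
        try:
            if len(combo) == 1:
                aln = alignments[combo[0]]
            else:
                aln = concatenate([alignments[l] for l in combo], species_map)
            bundle = analyse_barcode(
                name,
                aln,
                species_map,
                model=cfg.model,
                deletion=cfg.deletion,
                bootstrap_replicates=cfg.bootstrap_replicates,
                seed=cfg.seed,
            )
        except Exception as exc:  # abort with stage identity in the log
            logger.error("barcode %s failed: %s", name, exc)
            raise RuntimeError(f"stage 'analyse_barcode[{name}]' failed: {exc}") from exc
        bundles[name] = bundle
        if write:
            _write_bundle(outdir, bundle, species_map, cfg)

    summary = {
        name: {
            "tree_resolved": b.report.resolved_count,
            "final_resolved": len(b.final_resolved),
            "n_species": len(b.report.verdicts),
        }
        for name, b in bundles.items()
    }
    if write:
        with open(outdir / "summary.tsv", "w") as fh:
            fh.write("barcode\ttree_resolved\tfinal_resolved\tn_species\n")
            for name, row in summary.items():
                fh.write(
                    f"{name}\t{row['tree_resolved']}\t{row['final_resolved']}\t"
                    f"{row['n_species']}\n"
                )
        write_resolution_tsv([b.report for b in bundles.values()], outdir / "resolution.tsv")
        with open(outdir / "run.log", "w") as fh:
            fh.write(f"paphbarcode {__version__}\nseed {cfg.seed}\n")
            for name in bundles:
                fh.write(f"barcode {name}: ok\n")
    return StudyResult(bundles, summary)


def _write_bundle(outdir: Path, bundle: BarcodeBundle, sm: SpeciesMap, cfg: RunConfig):
    tag = bundle.barcode.replace("+", "_")
    stats_table([bundle.stats]).to_csv(outdir / f"stats_{tag}.tsv", sep="\t", index=False)
    dm = distance_matrix(bundle.alignment, cfg.model, deletion=cfg.deletion)
    write_distance_tsv(dm, outdir / f"distances_{tag}.tsv")
    means = group_mean_distances(dm, sm)
    with open(outdir / f"mean_distances_{tag}.tsv", "w") as fh:
        fh.write("stratum\tmean_distance\n")
        for key in ("overall", "within_species", "between_species"):
            v = getattr(means, key)
            fh.write(f"{key}\t{'' if v is None else f'{v:.6f}'}\n")
    write_newick(bundle.tree, outdir / f"tree_{tag}.nwk")
    write_diagnostics_tsv(bundle.diagnostics, outdir / f"diagnostics_{tag}.tsv")
    if hasattr(bundle.alignment, "partitions"):
        write_partitions(bundle.alignment, outdir / f"partitions_{tag}.txt")
    with open(outdir / f"verdicts_{tag}.tsv", "w") as fh:
        fh.write(
            "species\tn_samples\tmonophyletic\tdistinct\tresolved_tree\t"
            "n_characters\tresolved_final\tsupport\trationale\n"
        )
        for sp, v in bundle.report.verdicts.items():
            cv = bundle.combined[sp]
            fh.write(
                f"{sp}\t{v.n_samples}\t{v.monophyletic}\t{v.distinct}\t"
                f"{v.resolved_tree}\t{cv.n_characters}\t{cv.resolved_final}\t"
                f"{'' if v.support is None else v.support}\t{cv.rationale}\n"
            )


def run_identify(
    cfg: RunConfig,
    *,
    alignments: Optional[dict[str, Alignment]] = None,
    species_map: Optional[SpeciesMap] = None,
    queries: Optional[dict[str, dict[str, str]]] = None,
    write: bool = True,
) -> dict[str, IdentificationResult]:
    """Assign query samples against the reference panel."""
    if alignments is None or species_map is None:
        alignments, species_map = load_inputs(cfg)
    if queries is None:
        queries = {}
        for locus, path in cfg.query_paths.items():
            for rec in read_records(path, locus):
                queries.setdefault(rec.voucher, {})[locus] = rec.sequence
    if not queries:
        return {}
    results = identify_query(alignments, species_map, queries, model=cfg.model)
    if write:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_identification_tsv(results, outdir / "identification.tsv")
    return results
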