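"""End-to-end orchestration: bin -> place -> classify -> profile.

Stages run in pipeline order: reads are binned to marker genes from the
tabular hit file, the hit-aligned span of each binned read is placed on its
gene's tree (by the built-in similarity placer, or supplied externally as
jplace documents), reads are classified against the support threshold, and
the classifications pooled into an abundance profile.  A run manifest
records per-stage counts and the configuration.

The two presets differ only in placement source and support threshold:
maximum-likelihood placements with threshold 0.90 (default mode) versus a
faster placer with threshold 0.95 (fast mode).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from Bio import SeqIO

from . import __version__
from .binning import (
    BinAssignment,
    assign_reads,
    parse_tabular_hits,
    sniff_read_format,
    write_assignments_tsv,
)
from .classify import (
    DEFAULT_THRESHOLD,
    UNCLASSIFIED,
    ReadClassification,
    classify_all,
    write_classifications_tsv,
)
from .placement import PlacementSet, naive_place_all, read_jplace, write_jplace
from .profile import aggregate_profile, write_profile
from .refpkg import ReferencePackage, load_refpkg
from .taxonomy import CANONICAL_RANKS

logger = logging.getLogger("markerprof")

EXIT_OK = 0
EXIT_ERROR = 1
EXIT_EMPTY = 2


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    refpkg_path: str
    reads_path: str
    hits_path: str
    jplace_paths: Sequence[str] = ()          # external placements (optional)
    support_threshold: float = DEFAULT_THRESHOLD
    min_coverage: int = 50
    ranks: Sequence[str] = CANONICAL_RANKS
    output_dir: Optional[str] = None
    seed: int = 0
    output_format: str = "tsv"
    sample_id: str = "sample"

    def validate(self) -> None:
        if not (0 < self.support_threshold <= 1):
            raise ValueError("support_threshold must be in (0, 1]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def run_end_to_end(config: RunConfig):
    """Run all stages; returns ``(profile, manifest)``.

    The manifest is a JSON-serializable dict of per-stage counts and the
    echoed configuration.  When ``output_dir`` is set, the per-stage
    artifacts (assignments TSV, jplace documents, classifications TSV,
    profile, manifest) are written there.
    """
    config.validate()
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    try:
        pkg = load_refpkg(config.refpkg_path)
    except Exception as exc:
        raise PipelineError("load_refpkg", str(exc)) from exc

    fmt = sniff_read_format(config.reads_path)
    try:
        reads = {rec.id: str(rec.seq) for rec in SeqIO.parse(config.reads_path, fmt)}
    except Exception as exc:
        raise PipelineError("read_input", str(exc)) from exc
    logger.info("stage=input reads_in=%d", len(reads))

    try:
        hits = parse_tabular_hits(config.hits_path)
        assignments = assign_reads(hits, min_coverage=config.min_coverage)
    except Exception as exc:
        raise PipelineError("binning", str(exc)) from exc
    logger.info("stage=binning hits=%d binned=%d", len(hits), len(assignments))
    if outdir:
        write_assignments_tsv(assignments, outdir / "assignments.tsv")

    try:
        if config.jplace_paths:
            psets = {
                Path(p).stem: read_jplace(p) for p in config.jplace_paths
            }
            placed = sum(len(ps.records) for ps in psets.values())
            classifications = _classify_external(pkg, psets, config)
        else:
            classifications, placed = _place_and_classify(
                pkg, reads, assignments, config, outdir
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("place/classify", str(exc)) from exc
    n_classified = sum(
        1 for c in classifications if c.lowest_rank != UNCLASSIFIED
    )
    logger.info(
        "stage=classify placed=%d classified=%d", placed, n_classified
    )
    if outdir:
        write_classifications_tsv(classifications, outdir / "classifications.tsv")

    profile = aggregate_profile(
        classifications, pkg.taxonomy, sample_id=config.sample_id
    )
    manifest = {
        "tool": "markerprof",
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "counts": {
            "reads_in": len(reads),
            "binned": len(assignments),
            "placed": placed,
            "n": profile.n,
            "n_l": {r: profile.n_l.get(r) for r in CANONICAL_RANKS},
        },
        "warnings": [],
    }
    if profile.n == 0:
        manifest["warnings"].append("no reads were classified; profile is empty")
        logger.warning("no reads were classified; profile is empty")
    if outdir:
        ext = "cami.tsv" if config.output_format == "cami" else "tsv"
        write_profile(
            profile,
            outdir / f"profile.{ext}",
            format=config.output_format,
            taxonomy=pkg.taxonomy,
        )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
            fh.write("\n")
    return profile, manifest


def _place_and_classify(
    pkg: ReferencePackage,
    reads: Dict[str, str],
    assignments: Sequence[BinAssignment],
    config: RunConfig,
    outdir: Optional[Path],
):
    """Naive placement of the hit-aligned span of each binned read."""
    by_gene: Dict[str, List[BinAssignment]] = {}
    for a in assignments:
        by_gene.setdefault(a.gene, []).append(a)
    classifications: List[ReadClassification] = []
    placed = 0
    for gene_name in sorted(by_gene):
        if gene_name not in pkg.genes:
            raise PipelineError(
                "placement", f"hits reference unknown gene {gene_name!r}"
            )
        gene = pkg.genes[gene_name]
        queries: Dict[str, str] = {}
        for a in by_gene[gene_name]:
            if a.read_id not in reads:
                raise PipelineError(
                    "placement", f"assigned read {a.read_id!r} missing from input"
                )
            seq = reads[a.read_id]
            if a.read_start is not None and a.read_end is not None:
                seq = seq[a.read_start - 1 : a.read_end]
            queries[a.read_id] = seq
        pset = naive_place_all(queries, gene)
        placed += len(pset.records)
        if outdir:
            write_jplace(pset, outdir / f"{gene_name}.jplace")
        classifications.extend(
            classify_all(pset, gene, pkg.taxonomy, threshold=config.support_threshold)
        )
    return classifications, placed


def _classify_external(
    pkg: ReferencePackage,
    psets: Dict[str, PlacementSet],
    config: RunConfig,
) -> List[ReadClassification]:
    """Classify externally produced jplace documents, one per marker gene.

    Each document is matched to the gene whose tree leaves cover the
    placement tree's leaves.
    """
    classifications: List[ReadClassification] = []
    for name in sorted(psets):
        pset = psets[name]
        leaves = set(pset.tree.leaf_labels())
        gene = next(
            (
                g
                for gname, g in sorted(pkg.genes.items())
                if leaves <= set(g.tree.leaf_labels())
            ),
            None,
        )
        if gene is None:
            raise PipelineError(
                "classify",
                f"jplace {name!r} matches no marker gene in the package",
            )
        classifications.extend(
            classify_all(pset, gene, pkg.taxonomy, threshold=config.support_threshold)
        )
    return classifications
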