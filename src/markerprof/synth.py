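"""Mock-community and fixture generation for end-to-end testing.

This module emulates, at desk scale, everything the pipeline consumes: a
small multi-rank taxonomy; marker genes evolved along it under a
Jukes-Cantor substitution model (no indels, so alignments are trivially
correct); mock communities of genomes with known relative abundances,
optionally including *novel* genomes absent from the reference package;
reads with a uniform substitution-error model; the tabular hit files an
external aligner would produce; and the matching truth profiles.

Communities mirror the known/mixed/novel study design: a genome is "known"
when its species is a leaf of the reference trees, "novel" when it was
evolved onward from a reference leaf and then excluded from the package.
All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profile import AbundanceProfile
from .refpkg import MarkerGene, ReferencePackage
from .taxonomy import CANONICAL_RANKS, Taxonomy, TaxonomyNode
from .tree import EdgeNumberedTree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

NON_MARKER = "non-marker"

#: Minimum read/gene overlap for a read to count as a marker read,
#: matching the binning coverage filter.
MARKER_OVERLAP = 50


# -- taxonomy ----------------------------------------------------------

_DEFAULT_BRANCHING = {
    "phylum": 2,
    "class": 2,
    "order": 2,
    "family": 2,
    "genus": 2,
    "species": 2,
}

_RANK_PREFIX = {
    "superkingdom": "sk",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
}


def gen_taxonomy(
    n_species: int,
    branching: Optional[Dict[str, int]] = None,
    seed: int = 0,
) -> Taxonomy:
    """Build a balanced-ish 7-rank taxonomy with exactly ``n_species`` species.

    ``branching`` maps each rank below superkingdom to its children-per-node
    count (default 2 everywhere).  A balanced tree of that shape is built
    and truncated to the first ``n_species`` species in left-to-right
    order; construction is deterministic (the seed is accepted for
    interface uniformity).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    branch = dict(_DEFAULT_BRANCHING)
    if branching:
        branch.update(branching)
    capacity = 1
    for rank in CANONICAL_RANKS[1:]:
        if branch[rank] < 1:
            raise ValueError(f"branching at {rank} must be >= 1")
        capacity *= branch[rank]
    if capacity < n_species:
        raise ValueError(
            f"branching yields only {capacity} species, need {n_species}"
        )
    nodes = [
        TaxonomyNode("root", None, "no rank", "root"),
        TaxonomyNode("sk1", "root", "superkingdom", "Superkingdom_1"),
    ]
    parents = ["sk1"]
    counters = {rank: 0 for rank in CANONICAL_RANKS[1:]}
    kept_per_rank: Dict[str, List[str]] = {}
    for depth, rank in enumerate(CANONICAL_RANKS[1:], start=2):
        children: List[Tuple[str, str]] = []  # (tax_id, parent_id)
        for parent in parents:
            for _ in range(branch[rank]):
                counters[rank] += 1
                children.append((f"{_RANK_PREFIX[rank]}{counters[rank]}", parent))
        # how many nodes at this rank are needed to hold n_species leaves
        below = 1
        for r in CANONICAL_RANKS[CANONICAL_RANKS.index(rank) + 1:]:
            below *= branch[r]
        needed = math.ceil(n_species / below)
        children = children[:needed]
        for tax_id, parent in children:
            pretty = rank.capitalize() + "_" + tax_id[len(_RANK_PREFIX[rank]):]
            nodes.append(TaxonomyNode(tax_id, parent, rank, pretty))
        parents = [c[0] for c in children]
        kept_per_rank[rank] = parents
    return Taxonomy(nodes)


# -- reference package -------------------------------------------------


def _evolve(seq: np.ndarray, distance: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor step: substitute each site with prob 3/4(1-e^(-4d/3)).

    Conditional on substitution the new base is uniform over the three
    alternatives, which composes exactly along consecutive branches.
    """
    p = 0.75 * (1.0 - math.exp(-4.0 * distance / 3.0))
    out = seq.copy()
    mask = rng.random(len(seq)) < p
    k = int(mask.sum())
    if k:
        shift = rng.integers(1, 4, size=k)
        out[mask] = (out[mask] + shift) % 4
    return out


def jc_expected_diff(distance: float) -> float:
    """Expected fraction of differing sites after total branch length d."""
    return 0.75 * (1.0 - math.exp(-4.0 * distance / 3.0))


def _taxonomy_dendropy_tree(taxonomy: Taxonomy) -> dendropy.Tree:
    """Mirror the taxonomy as a dendropy tree with species leaves.

    Degree-2 chains (e.g. root -> sole superkingdom) are collapsed so the
    marker trees look like ordinary phylogenies.
    """
    children: Dict[str, List[str]] = {}
    for tax_id, node in taxonomy.nodes.items():
        if node.parent_id is not None:
            children.setdefault(node.parent_id, []).append(tax_id)
    for v in children.values():
        v.sort()
    tree = dendropy.Tree()
    namespace = tree.taxon_namespace

    def build(tax_id: str, dnode: dendropy.Node) -> None:
        kids = children.get(tax_id, [])
        if not kids:
            taxon = namespace.new_taxon(label=tax_id)
            dnode.taxon = taxon
            return
        for kid in kids:
            child = dendropy.Node()
            dnode.add_child(child)
            child.label = kid
            build(kid, child)

    root_id = taxonomy.root.tax_id
    tree.seed_node.label = root_id
    build(root_id, tree.seed_node)
    tree.suppress_unifurcations()
    seed = tree.seed_node
    while seed.num_child_nodes() == 1:
        child = seed.child_nodes()[0]
        child.parent_node = None
        tree.seed_node = seed = child
    return tree


def gen_refpkg(
    taxonomy: Taxonomy,
    n_genes: int,
    gene_length: int = 400,
    mutation_rate: float = 0.15,
    seed: int = 0,
) -> ReferencePackage:
    """Evolve ``n_genes`` marker genes along the taxonomy tree.

    Each gene gets an independent random root sequence and per-branch
    lengths drawn uniformly in ``[0.5, 1.5] * mutation_rate`` substitutions
    per site; sites then evolve under Jukes-Cantor.  With no indels the
    leaf sequences are the gene MSA as-is.  Trees take the taxonomy shape
    with the simulated branch lengths and preorder edge numbers; each leaf
    is labeled ``L_<species tax_id>``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if gene_length < 50:
        raise ValueError(
            "gene_length must be >= 50 (reads must be able to meet the "
            "50 bp coverage filter)"
        )
    rng = np.random.default_rng(seed)
    genes: Dict[str, MarkerGene] = {}
    for gi in range(1, n_genes + 1):
        dtree = _taxonomy_dendropy_tree(taxonomy)
        root_seq = rng.integers(0, 4, size=gene_length, dtype=np.int64)
        msa: Dict[str, str] = {}
        leaf_taxa: Dict[str, str] = {}

        def descend(node: dendropy.Node, seq: np.ndarray) -> None:
            for child in node.child_nodes():
                d = float(rng.uniform(0.5, 1.5)) * mutation_rate
                child.edge.length = d
                child_seq = _evolve(seq, d, rng)
                if child.is_leaf():
                    species = child.taxon.label
                    label = f"L_{species}"
                    child.taxon.label = label
                    msa[label] = _to_str(child_seq)
                    leaf_taxa[label] = species
                else:
                    descend(child, child_seq)

        descend(dtree.seed_node, root_seq)
        tree = EdgeNumberedTree.from_dendropy(dtree, number_edges=True)
        name = f"gene{gi}"
        genes[name] = MarkerGene(name=name, msa=msa, tree=tree, leaf_taxa=leaf_taxa)
    pkg = ReferencePackage(taxonomy=taxonomy, genes=genes)
    pkg.validate()
    return pkg


def _to_str(codes: np.ndarray) -> str:
    return _BASES[np.asarray(codes, dtype=np.int64)].tobytes().decode()


def _to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.zeros(len(seq), dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    return codes


# -- mock community ----------------------------------------------------


@dataclass
class Genome:
    """One community member: lineage, assembled sequence, gene layout."""

    genome_id: str
    lineage: Dict[str, Optional[str]]  # rank -> tax_id
    sequence: str
    true_abundance: float
    gene_intervals: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    # 0-based half-open intervals of each marker gene within `sequence`

    @property
    def species(self) -> str:
        return self.lineage["species"]  # type: ignore[return-value]


@dataclass
class MockCommunity:
    """Synthetic genomes with known lineages and true relative abundances."""

    genomes: List[Genome]
    novel_flags: Dict[str, bool]

    def validate(self) -> None:
        total = sum(g.true_abundance for g in self.genomes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"true abundances sum to {total}, expected 1")


def gen_community(
    refpkg: ReferencePackage,
    n_known: int,
    n_novel: int = 0,
    abundance_model: str | Tuple[str, float] = "uniform",
    seed: int = 0,
    novel_branch_length: float = 0.2,
    filler_length: int = 150,
) -> MockCommunity:
    """Assemble a mock community of known and novel genomes.

    Known genomes carry the reference marker-gene sequences of distinct
    reference species.  Novel genomes are created by evolving every marker
    gene of a (distinct) reference species onward by
    ``novel_branch_length`` substitutions/site and assigning a fresh
    species id under the same genus — the species is then absent from the
    reference trees, as "novel" requires.  Genome sequences concatenate the
    gene copies in gene-name order, separated (and flanked) by uniform
    random filler.  Abundances are uniform or lognormal(sigma), normalized
    to sum to 1.
    """
    if n_known + n_novel == 0:
        raise ValueError("community must contain at least one genome")
    gene_names = sorted(refpkg.genes)
    if not gene_names:
        raise ValueError("reference package has no genes")
    first_gene = refpkg.genes[gene_names[0]]
    species_pool = sorted(
        {first_gene.leaf_taxa[leaf] for leaf in first_gene.tree.leaf_labels()}
    )
    if n_known + n_novel > len(species_pool):
        raise ValueError(
            f"requested {n_known}+{n_novel} genomes but only "
            f"{len(species_pool)} reference species are available as sources"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(species_pool), size=n_known + n_novel, replace=False)
    known_species = [species_pool[i] for i in sorted(picked[:n_known])]
    novel_sources = [species_pool[i] for i in sorted(picked[n_known:])]

    genomes: List[Genome] = []
    novel_flags: Dict[str, bool] = {}

    def assemble(gene_seqs: Dict[str, str]) -> Tuple[str, Dict[str, Tuple[int, int]]]:
        parts: List[str] = []
        intervals: Dict[str, Tuple[int, int]] = {}
        pos = 0
        for gene in gene_names:
            filler = _to_str(rng.integers(0, 4, size=filler_length))
            parts.append(filler)
            pos += filler_length
            seq = gene_seqs[gene]
            intervals[gene] = (pos, pos + len(seq))
            parts.append(seq)
            pos += len(seq)
        filler = _to_str(rng.integers(0, 4, size=filler_length))
        parts.append(filler)
        return "".join(parts), intervals

    for species in known_species:
        gene_seqs = {
            g: refpkg.genes[g].degapped(f"L_{species}") for g in gene_names
        }
        sequence, intervals = assemble(gene_seqs)
        gid = f"G_{species}"
        genomes.append(
            Genome(
                genome_id=gid,
                lineage=dict(refpkg.taxonomy.lineage(species)),
                sequence=sequence,
                true_abundance=0.0,
                gene_intervals=intervals,
            )
        )
        novel_flags[gid] = False

    for i, source in enumerate(novel_sources, start=1):
        gene_seqs = {}
        for g in gene_names:
            codes = _to_codes(refpkg.genes[g].degapped(f"L_{source}"))
            gene_seqs[g] = _to_str(_evolve(codes, novel_branch_length, rng))
        sequence, intervals = assemble(gene_seqs)
        lineage = dict(refpkg.taxonomy.lineage(source))
        lineage["species"] = f"novel_s{i}"
        gid = f"G_novel_s{i}"
        genomes.append(
            Genome(
                genome_id=gid,
                lineage=lineage,
                sequence=sequence,
                true_abundance=0.0,
                gene_intervals=intervals,
            )
        )
        novel_flags[gid] = True

    k = len(genomes)
    if abundance_model == "uniform":
        weights = np.full(k, 1.0 / k)
    elif (
        isinstance(abundance_model, tuple)
        and len(abundance_model) == 2
        and abundance_model[0] == "lognormal"
    ):
        draws = rng.lognormal(mean=0.0, sigma=float(abundance_model[1]), size=k)
        weights = draws / draws.sum()
    else:
        raise ValueError(
            f"unknown abundance model {abundance_model!r}; "
            "use 'uniform' or ('lognormal', sigma)"
        )
    for genome, w in zip(genomes, weights):
        genome.true_abundance = float(w)
    community = MockCommunity(genomes=genomes, novel_flags=novel_flags)
    community.validate()
    return community


# -- reads -------------------------------------------------------------


@dataclass(frozen=True)
class ReadTruth:
    genome_id: str
    gene: str  # marker-gene name or "non-marker"
    species: str
    start: int  # 0-based start on the genome


@dataclass
class SimulatedReadSet:
    """FASTQ records plus, per read, its true source genome/gene/species."""

    reads: List[SeqRecord]
    truth: Dict[str, ReadTruth]
    genomes: Dict[str, Genome] = field(default_factory=dict)

    def validate(self) -> None:
        ids = [r.id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate read ids")
        if set(ids) != set(self.truth):
            raise ValueError("read ids and truth keys differ")

    def write_fastq(self, path: str | Path) -> None:
        SeqIO.write(self.reads, str(path), "fastq")


def gen_reads(
    community: MockCommunity,
    n_reads: int,
    read_length: int = 150,
    error_rate: float = 0.002,
    seed: int = 0,
) -> SimulatedReadSet:
    """Draw reads from genomes in proportion to their true abundances.

    Read counts per genome are multinomial; start positions are uniform;
    each base is substituted independently with probability ``error_rate``
    (uniform over the three alternatives).  Qualities are constant ('I');
    they are never used downstream.  The truth records the source genome,
    the marker gene the read overlaps by at least 50 bp (else
    "non-marker"), and the source species.
    """
    shortest = min(len(g.sequence) for g in community.genomes)
    if read_length > shortest:
        raise ValueError(
            f"read_length {read_length} exceeds shortest genome ({shortest})"
        )
    rng = np.random.default_rng(seed)
    abunds = np.array([g.true_abundance for g in community.genomes])
    counts = rng.multinomial(n_reads, abunds / abunds.sum())
    reads: List[SeqRecord] = []
    truth: Dict[str, ReadTruth] = {}
    idx = 0
    for genome, count in zip(community.genomes, counts):
        codes = _to_codes(genome.sequence)
        starts = rng.integers(0, len(codes) - read_length + 1, size=count)
        for start in starts:
            start = int(start)
            seq = codes[start : start + read_length].copy()
            if error_rate > 0:
                mask = rng.random(read_length) < error_rate
                k = int(mask.sum())
                if k:
                    seq[mask] = (seq[mask] + rng.integers(1, 4, size=k)) % 4
            idx += 1
            read_id = f"r{idx:06d}"
            gene = _overlapping_gene(genome, start, start + read_length)
            rec = SeqRecord(
                Seq(_to_str(seq)),
                id=read_id,
                description=f"{genome.genome_id} pos={start}",
            )
            rec.letter_annotations["phred_quality"] = [40] * read_length
            reads.append(rec)
            truth[read_id] = ReadTruth(
                genome_id=genome.genome_id,
                gene=gene,
                species=genome.species,
                start=start,
            )
    out = SimulatedReadSet(
        reads=reads,
        truth=truth,
        genomes={g.genome_id: g for g in community.genomes},
    )
    out.validate()
    return out


def _overlapping_gene(genome: Genome, start: int, end: int) -> str:
    best_gene, best_overlap = NON_MARKER, 0
    for gene, (gs, ge) in sorted(genome.gene_intervals.items()):
        overlap = min(end, ge) - max(start, gs)
        if overlap > best_overlap:
            best_gene, best_overlap = gene, overlap
    return best_gene if best_overlap >= MARKER_OVERLAP else NON_MARKER


# -- tabular hits ------------------------------------------------------


def gen_hits(
    readset: SimulatedReadSet,
    refpkg: ReferencePackage,
    out_path: Optional[str | Path] = None,
) -> List[str]:
    """Emit outfmt-6 rows emulating an aligner binning reads to genes.

    Each marker read gets one hit against the most similar reference
    sequence of its true gene: qstart/qend span the read/gene overlap,
    mismatches are counted against that reference over the overlap, and
    the bitscore is proportional to the match count.  Non-marker reads get
    no row.  Returns the rows; writes them if ``out_path`` is given.
    """
    rows: List[str] = []
    by_id = {rec.id: rec for rec in readset.reads}
    for read_id in sorted(readset.truth):
        info = readset.truth[read_id]
        if info.gene == NON_MARKER:
            continue
        genome = readset.genomes.get(info.genome_id)
        if genome is None:
            raise ValueError(
                f"read set lacks genome coordinates for {info.genome_id!r}"
            )
        gs, ge = genome.gene_intervals[info.gene]
        start, end = info.start, info.start + len(by_id[read_id].seq)
        a, b = max(start, gs), min(end, ge)  # overlap on the genome
        span = b - a
        read_seg = str(by_id[read_id].seq)[a - start : b - start].upper()
        gene = refpkg.genes[info.gene]
        offset = a - gs  # position of the overlap within the gene
        best_leaf, best_matches = None, -1
        seg = np.frombuffer(read_seg.encode(), dtype=np.uint8)
        for leaf in gene.tree.leaf_labels():
            ref = gene.degapped(leaf)[offset : offset + span]
            matches = int(
                (np.frombuffer(ref.encode(), dtype=np.uint8) == seg).sum()
            )
            if matches > best_matches:
                best_leaf, best_matches = leaf, matches
        pident = 100.0 * best_matches / span
        rows.append(
            "\t".join(
                [
                    read_id,
                    f"{info.gene}|{best_leaf}",
                    f"{pident:.2f}",
                    str(span),
                    str(span - best_matches),
                    "0",
                    str(a - start + 1),  # qstart, 1-based
                    str(b - start),      # qend, inclusive
                    str(offset + 1),
                    str(offset + span),
                    "1e-9",
                    f"{2.0 * best_matches:.1f}",
                ]
            )
        )
    if out_path is not None:
        Path(out_path).write_text("\n".join(rows) + ("\n" if rows else ""))
    return rows


# -- truth profile -----------------------------------------------------


def truth_profile(
    community: MockCommunity,
    taxonomy: Optional[Taxonomy] = None,
    sample_id: str = "truth",
) -> AbundanceProfile:
    """Sum genome abundances into every ancestor taxon at every rank.

    The result is complete by construction: per-rank sums equal 1 and the
    read counts are unknown (n = None), which evaluation treats as full
    coverage.  Lineages come from the genomes themselves, so novel species
    absent from the taxonomy are handled.
    """
    per_rank: Dict[str, Dict[str, float]] = {r: {} for r in CANONICAL_RANKS}
    for genome in community.genomes:
        for rank in CANONICAL_RANKS:
            taxon = genome.lineage.get(rank)
            if taxon is None:
                continue
            per_rank[rank][taxon] = (
                per_rank[rank].get(taxon, 0.0) + genome.true_abundance
            )
    profile = AbundanceProfile(
        per_rank=per_rank,
        n=None,
        n_l={r: None for r in CANONICAL_RANKS},
        sample_id=sample_id,
    )
    profile.validate()
    return profile
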