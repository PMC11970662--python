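# Methods

## The profiling model

The pipeline estimates the taxonomic composition of a read set from marker
genes only. The premises: marker genes are single-copy and universal in
Bacteria/Archaea, so the fraction of (marker-mapped) reads per taxon is an
unbiased estimate of that taxon's relative cell abundance, without
genome-size or copy-number correction; and phylogenetic placement on a
taxonomically labeled reference tree carries calibrated uncertainty (the
likelihood weight ratios, LWR) that can be aggregated into per-rank
support.

### Binning

Reads are searched against the pooled marker-gene sequences by an external
aligner; we consume its 12-column tabular output. Coverage is the aligned
span on the read of the single best HSP for a (read, gene) pair — spans
are not summed across HSPs, which is the simplest reproducible definition.
A read hitting several genes is assigned to the gene of its best hit
(bitscore, then span, then lexicographically smaller gene name), so every
read contributes to at most one gene downstream. The default minimum
coverage is 50 bp; reads below it, or with no hit, are discarded.
Reverse-orientation hits are normalized by swapping read coordinates;
strand is otherwise ignored.

### Placement

Production placements come from external likelihood-based placers as
jplace documents (versions 2 and 3; fields resolved by name, `{N}` edge
tags in the tree string, multifurcations preserved). LWR values are taken
as-is; a record whose mass exceeds 1 + 1e-6 is rejected rather than
silently renormalized, because silent renormalization would hide upstream
errors.

The built-in **naive placer** exists so the downstream stages can be run
and tested end-to-end at desk scale; it is a similarity method, not a
likelihood method, and should not be used where placement accuracy
matters. For each reference leaf it computes the maximum count of matching
positions over all ungapped offsets of the query against the leaf's
degapped sequence (ambiguous bases never match); all leaves within
`tie_margin` (default 0) of the best score share the mass equally on their
pendant edges. The pipeline places only the hit-aligned span of each read
(the binning stage records qstart..qend of the chosen HSP), mirroring how
production pipelines align only the homologous region of a read into the
marker MSA; placing the full read would let flanking non-marker sequence
add noise to the similarity scores.

### Classification

Each edge implies, at each of the seven canonical ranks (superkingdom …
species), the taxon shared by all leaves of its far-from-root clade, or
"undefined". Support for taxon *t* at rank *r* is the summed LWR over
edges labeled *t* at *r*. Mass on edges undefined at a rank counts toward
no taxon there: it dilutes support rather than being redistributed, which
is what makes deep placements conservative.

Top taxa are chosen by lineage-consistent descent — walking root-to-tip,
at each rank taking the maximum-mass taxon consistent with the already
chosen ancestors (ties broken by smaller tax id) — rather than independent
per-rank argmax, which could produce labels that do not form a single
lineage. A read is classified at every rank whose support is at least the
threshold (compared with a 1e-9 tolerance; "at least" rather than strictly
greater), stopping at the first failure, so classified ranks always form a
contiguous root-anchored prefix. Reads failing even superkingdom are
reported unclassified and excluded from the profile's *n*.

Thresholds: 0.90 by default (maximum-likelihood placements), 0.95 for the
fast preset. These are presets of one pipeline, differing only in
placement source and threshold.

### Profiles

Abundance of taxon *x* at rank *l* is (reads classified to *x* at *l*)/*n*
with *n* the reads classified at any rank. Per-rank sums therefore equal
`n_l/n` and can be below 1; the profile stores the raw values plus *n* and
every `n_l`, and renormalization happens only inside evaluation. Output
formats: a native TSV with the counts in header comments, and the CAMI
(Bioboxes) profiling format with percentages = abundance × 100 (the counts
travel in `@__markerprof_*` headers; CAMI files without them load with *n*
unknown and per-rank coverage falling back to the abundance sum).

### Evaluation

With truth `T` (complete: sums to 1 per rank) and estimate `E`
renormalized over reads classified at the rank,

    H_l  = sqrt( Σ_x (√T_x − √E_x)² / 2 )            ∈ [0, 1]
    H*_l = sqrt( Σ_x (√T_x − √E_x)² / (1 + n_l/n) )  ∈ [0, √2]

summed over the union of taxa. The renormalization implements "reads
unclassified at the level are not counted"; H* then restores the missing
penalty: it equals H when `n_l = n` and grows as classification gets
shallower. With `n = 0` both metrics are undefined (an error is raised);
with `n_l = 0` H* is computed against an empty estimate with denominator 1
(value 1 for any truth) and a RuntimeWarning is emitted rather than
failing, so batch evaluations can proceed while the condition stays
visible. Per-taxon estimation error is `(est − ref)/ref` on the
renormalized estimate; the error table covers the truth's taxa and, when
filtered, keeps errors strictly greater than the cutoff (default 10%) in
magnitude.

## Synthetic data

The generator emulates the full input stack at desk scale.

- **Taxonomy**: a balanced tree over the seven canonical ranks (default
  branching 2 per rank), truncated to the requested species count.
- **Marker genes**: per gene, an independent random root sequence evolves
  along the taxonomy shape under Jukes–Cantor: per branch of length *d*,
  each site substitutes with probability `3/4 (1 − e^(−4d/3))`, uniformly
  to one of the other three bases — exactly the JC transition matrix, so
  divergence composes correctly along paths (the test suite checks
  observed leaf-pair differences against the closed form at a 10 kb gene).
  Branch lengths are Uniform(0.5, 1.5) × `mutation_rate` (default 0.15
  substitutions/site, giving well-separated sister species at the default
  400 bp gene length). No indels anywhere, so alignments are trivially
  exact and the naive placer is honest.
- **Communities**: *known* genomes carry reference marker sequences of
  distinct reference species; *novel* genomes evolve every gene of a
  source species onward by an extra branch (default 0.2 subs/site) and get
  a fresh species id under the same genus — novel means "absent from the
  reference package", not unrelated random sequence. Genomes concatenate
  gene copies in gene-name order separated by 150 bp of uniform random
  filler. Abundances are uniform or lognormal(σ), normalized.
- **Reads**: multinomial across genomes by abundance, uniform start
  positions, independent per-base substitution errors (default 0.002);
  constant FASTQ qualities (never used downstream). Truth records source
  genome, the gene overlapped by ≥ 50 bp (else non-marker), and species.
- **Hits**: for each marker read, one tabular row against the most similar
  reference leaf over the true overlap window, with the exact overlap
  coordinates and a match-proportional bitscore.

What this does *not* emulate: realistic sequencing-error profiles and
read-length distributions, indels, chimeras, contamination, incomplete or
mislabeled taxonomies, and reference packages at real scale (tens of
thousands of leaves). Passing end-to-end tests therefore demonstrates the
correctness of the binning/classification/profiling arithmetic under the
model's assumptions, not profiling accuracy on real instruments or real
reference databases.

## Reference-package subsampling

Reduced ("small") packages keep, per genus and per gene, a uniform-random
subset of leaves with size drawn uniformly in `[min_per_genus,
max_per_genus]` (default 1–3), capped at availability; leaves without a
genus ancestor are always retained. Trees are pruned with suppressed
degree-2 branch lengths summed (pairwise leaf path lengths are preserved
to 1e-9) and edges renumbered in preorder. The selection rule is a design
choice; only the 1–3-per-genus bound is externally specified.

## Numerical and interface choices

- Support threshold comparison uses a 1e-9 tolerance; LWR sums may exceed
  1 by at most 1e-6; profile conservation is validated to 1e-9.
- Tie-breaks are deterministic everywhere (lexicographic smallest id), so
  byte-identical reruns are guaranteed; `--threads` never changes results.
- Newick serialization uses Python float repr, making tree round-trips
  exact; jplace round-trips preserve LWR to ≥ 9 significant digits.
- Degenerate inputs: empty hit files yield empty (flagged, exit code 2)
  profiles; empty MSAs, cyclic taxonomies, unknown edges and negative
  masses are rejected with named errors.
- The end-to-end benchmarks in the test suite use 8 known genomes ×
  4 genes × 2000 error-free 150 bp reads (and a 6-known + 2-novel
  variant), sizes at which multinomial noise keeps the species-level
  Hellinger distance comfortably below 0.05 while the whole suite stays
  fast.

## Known limitations

- The naive placer scores ungapped similarity; it cannot model indels or
  rate heterogeneity and is unsuitable for production accuracy claims.
- One gene per read: conflicting placements of a read across genes are
  resolved at binning, not reconciled afterwards.
- Strain-level classification is out of scope; ranks are fixed to the
  seven canonical ones.
- H* behavior at `n_l = 0` (flag + denominator 1) is a convention for an
  edge case that real profilers rarely hit at shallow ranks.
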