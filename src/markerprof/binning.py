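"""Stage 1: bin metagenomic reads to marker genes from tabular hits.

Reads are searched against the pooled marker-gene sequences by an external
aligner (BLAST); this module consumes the standard 12-column tabular output
(outfmt 6), picks one marker gene per read, applies the minimum aligned-span
("coverage") filter of 50 bp, and discards reads that map to no gene.
Optionally the surviving reads are exported so other profilers can be run on
the marker-mapped subset only.

Coverage is the aligned span on the read of the single best HSP for the
chosen (read, gene) pair.  A read hitting several genes is assigned to the
gene of its highest-bitscore hit (ties: longer span, then lexicographically
smaller gene name); reverse-orientation hits are normalized by swapping the
read coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from Bio import SeqIO

DEFAULT_MIN_COVERAGE = 50

_N_COLUMNS = 12


class HitParseError(ValueError):
    """Raised for malformed tabular hit files (carries the line number)."""


class ReadSetError(ValueError):
    """Raised when assignments reference reads absent from the read file."""


@dataclass(frozen=True)
class AlignmentHit:
    """One HSP row: read vs a reference sequence of one marker gene."""

    read_id: str
    gene: str
    subject_id: str
    read_start: int   # 1-based inclusive, read_start <= read_end
    read_end: int
    bitscore: float
    percent_identity: float

    @property
    def span(self) -> int:
        return self.read_end - self.read_start + 1


@dataclass(frozen=True)
class BinAssignment:
    """A read's single marker-gene assignment with its aligned span."""

    read_id: str
    gene: str
    coverage_bp: int
    read_start: Optional[int] = None  # span of the chosen HSP on the read
    read_end: Optional[int] = None


def parse_tabular_hits(path: str | Path) -> List[AlignmentHit]:
    """Parse a 12-column tabular (outfmt-6 dialect) hit file.

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore.  Subject ids carry the marker
    gene name as a prefix ``gene|seqid``.  Read coordinates are normalized
    so ``read_start <= read_end``.
    """
    hits: List[AlignmentHit] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _N_COLUMNS:
                raise HitParseError(
                    f"line {lineno}: expected {_N_COLUMNS} columns, got {len(fields)}"
                )
            subject = fields[1]
            gene = subject.split("|", 1)[0]
            try:
                pident = float(fields[2])
                qstart = int(fields[6])
                qend = int(fields[7])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise HitParseError(f"line {lineno}: non-numeric field ({exc})") from exc
            if bitscore < 0:
                raise HitParseError(f"line {lineno}: negative bitscore")
            start, end = (qstart, qend) if qstart <= qend else (qend, qstart)
            hits.append(
                AlignmentHit(
                    read_id=fields[0],
                    gene=gene,
                    subject_id=subject,
                    read_start=start,
                    read_end=end,
                    bitscore=bitscore,
                    percent_identity=pident,
                )
            )
    return hits


def assign_reads(
    hits: Iterable[AlignmentHit],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> List[BinAssignment]:
    """Assign each read to one marker gene; drop reads below the filter.

    Per read the best HSP of each gene is found, the best gene chosen
    (bitscore, then span, then smaller gene name), and the assignment kept
    only if its span covers at least ``min_coverage`` bases.  Output is
    sorted by read id, so any row order of the input yields the same result.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    best: Dict[str, AlignmentHit] = {}
    for hit in hits:
        cur = best.get(hit.read_id)
        if cur is None or _hit_rank(hit) > _hit_rank(cur):
            best[hit.read_id] = hit
    out = []
    for read_id in sorted(best):
        hit = best[read_id]
        if hit.span >= min_coverage:
            out.append(
                BinAssignment(
                    read_id=read_id,
                    gene=hit.gene,
                    coverage_bp=hit.span,
                    read_start=hit.read_start,
                    read_end=hit.read_end,
                )
            )
    return out


def _hit_rank(hit: AlignmentHit):
    # higher is better; gene name compared inverted for lexicographic-min
    return (hit.bitscore, hit.span, _NegStr(hit.gene))


class _NegStr(str):
    """String with inverted ordering, for 'smallest wins' tie-breaks."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def write_filtered_reads(
    reads_path: str | Path,
    assignments: Sequence[BinAssignment],
    out_path: str | Path,
) -> int:
    """Write the assigned reads, preserving sequence, quality and order.

    Returns the number of reads written.  Raises :class:`ReadSetError` if
    an assignment references a read absent from the input file.
    """
    fmt = sniff_read_format(reads_path)
    wanted = {a.read_id for a in assignments}
    seen = set()
    count = 0
    with open(out_path, "w") as out:
        for rec in SeqIO.parse(str(reads_path), fmt):
            if rec.id in wanted:
                seen.add(rec.id)
                SeqIO.write([rec], out, fmt)
                count += 1
    missing = wanted - seen
    if missing:
        raise ReadSetError(
            f"{len(missing)} assigned read(s) absent from {reads_path}: "
            f"{sorted(missing)[:5]}"
        )
    return count


def sniff_read_format(path: str | Path) -> str:
    """Detect FASTA vs FASTQ from the extension, else the first character."""
    suffix = Path(path).suffix.lower()
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    with open(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def write_assignments_tsv(assignments: Sequence[BinAssignment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["read_id", "gene", "coverage_bp", "read_start", "read_end"])
        for a in assignments:
            writer.writerow(
                [a.read_id, a.gene, a.coverage_bp, a.read_start or "", a.read_end or ""]
            )


def read_assignments_tsv(path: str | Path) -> List[BinAssignment]:
    out: List[BinAssignment] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)
        for row in reader:
            if not row:
                continue
            out.append(
                BinAssignment(
                    read_id=row[0],
                    gene=row[1],
                    coverage_bp=int(row[2]),
                    read_start=int(row[3]) if len(row) > 3 and row[3] else None,
                    read_end=int(row[4]) if len(row) > 4 and row[4] else None,
                )
            )
    return out
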