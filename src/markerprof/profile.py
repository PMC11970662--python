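"""Stage 3: pool read classifications into per-rank abundance profiles.

The relative abundance of a taxon at a rank is the number of reads
classified to it at that rank divided by *n*, the total number of reads
classified at any rank.  Because some reads are classified only at shallow
ranks, the per-rank abundances sum to ``n_l / n`` (the fraction of
classified reads that reach rank *l*), which may be below 1; the profile
stores the raw n-denominated values and the counts, and renormalization
happens only inside evaluation.

Two on-disk formats: a native TSV with the counts in header comments, and
the CAMI (Bioboxes) profiling format with percentages = abundance x 100.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

from .classify import UNCLASSIFIED, ReadClassification
from .taxonomy import CANONICAL_RANKS, Taxonomy

_TOL = 1e-9


class ProfileError(ValueError):
    """Raised for malformed profile files or invariant violations."""


@dataclass
class AbundanceProfile:
    """Per-rank taxon abundances plus the classified-read counts.

    ``n`` is None for profiles without read-count provenance (truth
    profiles, CAMI files lacking the metadata); such profiles are treated
    as complete at every rank unless their abundances say otherwise.
    """

    per_rank: Dict[str, Dict[str, float]]
    n: Optional[int]
    n_l: Dict[str, Optional[int]]
    sample_id: str = "sample"

    def coverage(self, rank: str) -> float:
        """Fraction n_l/n of classified reads classified at this rank.

        Falls back to the per-rank abundance sum when counts are unknown.
        """
        nl = self.n_l.get(rank)
        if self.n and nl is not None:
            return nl / self.n
        return sum(self.per_rank.get(rank, {}).values())

    def validate(self) -> None:
        for rank, abunds in self.per_rank.items():
            for taxon, value in abunds.items():
                if value < -_TOL:
                    raise ProfileError(
                        f"negative abundance {value} for {taxon!r} at {rank}"
                    )
            if self.n and self.n_l.get(rank) is not None:
                expect = self.n_l[rank] / self.n
                if abs(sum(abunds.values()) - expect) > 1e-9:
                    raise ProfileError(
                        f"abundances at {rank} sum to {sum(abunds.values())}, "
                        f"expected n_l/n = {expect}"
                    )
        if self.n is not None:
            last = self.n
            for rank in CANONICAL_RANKS:
                nl = self.n_l.get(rank)
                if nl is None:
                    continue
                if nl > last:
                    raise ProfileError(
                        f"n_{rank} = {nl} exceeds count at the parent rank ({last})"
                    )
                last = nl


def aggregate_profile(
    classifications: Sequence[ReadClassification],
    taxonomy: Optional[Taxonomy] = None,
    sample_id: str = "sample",
) -> AbundanceProfile:
    """Pool classifications (typically across all marker genes) into a profile.

    ``n`` counts reads classified at any rank; unclassified reads are
    excluded.  If no read is classified the profile is empty with n = 0.
    """
    n = sum(1 for c in classifications if c.lowest_rank != UNCLASSIFIED)
    per_rank: Dict[str, Dict[str, float]] = {r: {} for r in CANONICAL_RANKS}
    n_l: Dict[str, Optional[int]] = {r: 0 for r in CANONICAL_RANKS}
    if n == 0:
        return AbundanceProfile(per_rank=per_rank, n=0, n_l=n_l, sample_id=sample_id)
    counts: Dict[str, Dict[str, int]] = {r: {} for r in CANONICAL_RANKS}
    for c in classifications:
        for rank, (taxon, _support) in c.per_rank.items():
            counts[rank][taxon] = counts[rank].get(taxon, 0) + 1
            n_l[rank] += 1  # type: ignore[operator]
    for rank in CANONICAL_RANKS:
        per_rank[rank] = {t: k / n for t, k in sorted(counts[rank].items())}
    profile = AbundanceProfile(per_rank=per_rank, n=n, n_l=n_l, sample_id=sample_id)
    profile.validate()
    return profile


# -- I/O ---------------------------------------------------------------

FORMATS = ("tsv", "cami")

_CAMI_RANKS = "|".join(CANONICAL_RANKS)


def write_profile(
    profile: AbundanceProfile,
    path: str | Path,
    format: str = "tsv",
    taxonomy: Optional[Taxonomy] = None,
) -> None:
    """Write a profile as native TSV or CAMI (Bioboxes) profiling format."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    profile.validate()
    if format == "tsv":
        _write_tsv(profile, path, taxonomy)
    else:
        _write_cami(profile, path, taxonomy)


def _lineage_str(taxon: str, taxonomy: Optional[Taxonomy]) -> str:
    if taxonomy is not None and taxon in taxonomy:
        return taxonomy.lineage_string(taxon)
    return taxon


def _write_tsv(
    profile: AbundanceProfile, path: str | Path, taxonomy: Optional[Taxonomy]
) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# sample_id={profile.sample_id}\n")
        if profile.n is not None:
            fh.write(f"# n={profile.n}\n")
            for rank in CANONICAL_RANKS:
                nl = profile.n_l.get(rank)
                if nl is not None:
                    fh.write(f"# n_{rank}={nl}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rank", "tax_id", "lineage", "abundance"])
        for rank in CANONICAL_RANKS:
            for taxon, value in sorted(profile.per_rank.get(rank, {}).items()):
                writer.writerow(
                    [rank, taxon, _lineage_str(taxon, taxonomy), repr(value)]
                )


def _write_cami(
    profile: AbundanceProfile, path: str | Path, taxonomy: Optional[Taxonomy]
) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"@SampleID:{profile.sample_id}\n")
        fh.write("@Version:0.9.1\n")
        fh.write(f"@Ranks:{_CAMI_RANKS}\n")
        if profile.n is not None:
            fh.write(f"@__markerprof_n:{profile.n}\n")
            for rank in CANONICAL_RANKS:
                nl = profile.n_l.get(rank)
                if nl is not None:
                    fh.write(f"@__markerprof_n_{rank}:{nl}\n")
        fh.write("@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE\n")
        for rank in CANONICAL_RANKS:
            for taxon, value in sorted(profile.per_rank.get(rank, {}).items()):
                taxpath = _lineage_str(taxon, taxonomy)
                if taxonomy is not None and taxon in taxonomy:
                    names = "|".join(
                        taxonomy.name_of(t) if t else ""
                        for t in taxpath.split("|")
                    )
                else:
                    names = taxpath
                fh.write(
                    f"{taxon}\t{rank}\t{taxpath}\t{names}\t{repr(value * 100.0)}\n"
                )


def read_profile(path: str | Path, format: str = "tsv") -> AbundanceProfile:
    """Read a profile written by :func:`write_profile` (or a CAMI file).

    CAMI files lacking the read-count metadata load with ``n`` unknown;
    their per-rank coverage is then the per-rank abundance sum.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    return _read_tsv(path) if format == "tsv" else _read_cami(path)


def _read_tsv(path: str | Path) -> AbundanceProfile:
    per_rank: Dict[str, Dict[str, float]] = {r: {} for r in CANONICAL_RANKS}
    n: Optional[int] = None
    n_l: Dict[str, Optional[int]] = {r: None for r in CANONICAL_RANKS}
    sample_id = "sample"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, value = body.split("=", 1)
                    key = key.strip()
                    if key == "sample_id":
                        sample_id = value.strip()
                    elif key == "n":
                        n = int(value)
                    elif key.startswith("n_"):
                        n_l[key[2:]] = int(value)
                continue
            fields = line.split("\t")
            if fields[0] == "rank":
                continue
            if len(fields) != 4:
                raise ProfileError(f"{path}:{lineno}: expected 4 columns")
            rank, taxon, _lineage, abundance = fields
            try:
                value = float(abundance)
            except ValueError as exc:
                raise ProfileError(f"{path}:{lineno}: bad abundance ({exc})") from exc
            if value < 0:
                raise ProfileError(f"{path}:{lineno}: negative abundance")
            if rank not in per_rank:
                raise ProfileError(f"{path}:{lineno}: unknown rank {rank!r}")
            per_rank[rank][taxon] = value
    profile = AbundanceProfile(
        per_rank=per_rank, n=n, n_l=n_l, sample_id=sample_id
    )
    profile.validate()
    return profile


def _read_cami(path: str | Path) -> AbundanceProfile:
    per_rank: Dict[str, Dict[str, float]] = {r: {} for r in CANONICAL_RANKS}
    n: Optional[int] = None
    n_l: Dict[str, Optional[int]] = {r: None for r in CANONICAL_RANKS}
    sample_id = "sample"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("@@"):
                continue
            if line.startswith("@"):
                key, _, value = line[1:].partition(":")
                if key == "SampleID":
                    sample_id = value.strip()
                elif key == "__markerprof_n":
                    n = int(value)
                elif key.startswith("__markerprof_n_"):
                    n_l[key[len("__markerprof_n_"):]] = int(value)
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ProfileError(f"{path}:{lineno}: expected 5 columns")
            taxon, rank, _taxpath, _names, pct = fields[:5]
            try:
                value = float(pct)
            except ValueError as exc:
                raise ProfileError(f"{path}:{lineno}: bad percentage ({exc})") from exc
            if value < 0:
                raise ProfileError(f"{path}:{lineno}: negative percentage")
            if rank not in per_rank:
                continue  # ranks outside the canonical seven are ignored
            per_rank[rank][taxon] = value / 100.0
    profile = AbundanceProfile(per_rank=per_rank, n=n, n_l=n_l, sample_id=sample_id)
    profile.validate()
    return profile
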