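"""Evaluation metrics for abundance profiles.

Hellinger distance between a true profile T and an estimated profile E at
one taxonomic level::

    H_l = sqrt( sum_x ( sqrt(T_x) - sqrt(E_x) )^2 / 2 )

over the union of taxa (a taxon absent from one side contributes its full
mass).  Reads unclassified at the evaluated level are not counted: the
estimate is renormalized over the reads classified at that level before the
distance is taken.

That renormalization makes H_l blind to *how many* reads were left
unclassified, so a profiler that classifies almost nothing can still score
well.  The normalized Hellinger distance replaces the constant 2 with
``1 + n_l/n`` — where n is the total number of classified reads and n_l the
number classified at level l — penalizing incomplete classification::

    H*_l = sqrt( sum_x ( sqrt(T_x) - sqrt(E_x) )^2 / (1 + n_l/n) )

When every classified read reaches the level (n_l = n) this is exactly the
Hellinger distance; as n_l falls, the denominator shrinks toward 1 and the
distance grows, up to sqrt(2) in the worst case.

Also here: the per-taxon fractional estimation error (est - ref) / ref and
the error table used to inspect which taxa drive profiling error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .profile import AbundanceProfile

_TOL = 1e-6


class UndefinedMetricError(ValueError):
    """Raised where a metric has no defined value (e.g. empty estimate)."""


@dataclass
class ProfilePair:
    """A complete truth profile and an estimate carrying n / n_l counts."""

    truth: AbundanceProfile
    estimate: AbundanceProfile

    def validate(self) -> None:
        for rank, abunds in self.truth.per_rank.items():
            if abunds and abs(sum(abunds.values()) - 1.0) > _TOL:
                raise ValueError(
                    f"truth abundances at {rank} sum to {sum(abunds.values())}, "
                    "expected 1"
                )


def _sq_hellinger_sum(truth: Dict[str, float], est: Dict[str, float]) -> float:
    total = 0.0
    for taxon in set(truth) | set(est):
        t = truth.get(taxon, 0.0)
        e = est.get(taxon, 0.0)
        total += (math.sqrt(t) - math.sqrt(e)) ** 2
    return total


def hellinger(
    truth_at_rank: Dict[str, float], est_at_rank: Dict[str, float]
) -> float:
    """Hellinger distance between two distributions over taxa, in [0, 1].

    Both arguments must sum to 1; renormalize the estimate over reads
    classified at this rank first (see :func:`renormalized_estimate`).
    """
    if not est_at_rank:
        raise UndefinedMetricError("estimate is empty at this rank (n_l = 0)")
    for name, dist in (("truth", truth_at_rank), ("estimate", est_at_rank)):
        total = sum(dist.values())
        if dist and abs(total - 1.0) > _TOL:
            raise ValueError(f"{name} must sum to 1, got {total}")
    return math.sqrt(_sq_hellinger_sum(truth_at_rank, est_at_rank) / 2.0)


def renormalized_estimate(
    profile: AbundanceProfile, rank: str
) -> Dict[str, float]:
    """Estimated abundances renormalized over reads classified at the rank.

    Divides the raw n-denominated abundances by n_l/n so they sum to 1,
    dropping the reads unclassified at this rank from the comparison.
    """
    cov = profile.coverage(rank)
    raw = profile.per_rank.get(rank, {})
    if cov <= 0 or not raw:
        return {}
    return {t: v / cov for t, v in raw.items()}


def normalized_hellinger(
    truth_at_rank: Dict[str, float],
    est_profile: AbundanceProfile,
    rank: str,
) -> float:
    """Normalized Hellinger distance H* at one rank.

    Uses denominator ``1 + n_l/n`` so that unclassified-at-rank reads,
    which the plain Hellinger distance ignores, increase the distance.
    Equals :func:`hellinger` exactly when n_l = n.
    """
    if est_profile.n == 0:
        raise UndefinedMetricError("profile has no classified reads (n = 0)")
    total = sum(truth_at_rank.values())
    if truth_at_rank and abs(total - 1.0) > _TOL:
        raise ValueError(f"truth must sum to 1, got {total}")
    cov = est_profile.coverage(rank)
    est = renormalized_estimate(est_profile, rank)
    if not est:
        warnings.warn(
            f"no reads classified at rank {rank!r}; normalized Hellinger "
            "computed against an empty estimate",
            RuntimeWarning,
            stacklevel=2,
        )
        cov = 0.0
    return math.sqrt(_sq_hellinger_sum(truth_at_rank, est) / (1.0 + cov))


def per_taxon_error(est: float, ref: float) -> float:
    """Fractional estimation error (est - ref) / ref for one taxon."""
    if ref <= 0:
        raise UndefinedMetricError("reference abundance must be positive")
    return (est - ref) / ref


def error_table(
    pair: ProfilePair,
    rank: str,
    min_abs_error: Optional[float] = 0.10,
) -> List[Tuple[str, float]]:
    """Per-taxon fractional errors at a rank, over the truth's taxa.

    Estimates are renormalized over reads classified at the rank.  When
    ``min_abs_error`` is given, only taxa with |error| strictly greater
    than it are kept.  Rows are sorted from overestimation to
    underestimation.
    """
    pair.validate()
    truth = pair.truth.per_rank.get(rank, {})
    est = renormalized_estimate(pair.estimate, rank)
    rows = [
        (taxon, per_taxon_error(est.get(taxon, 0.0), ref))
        for taxon, ref in sorted(truth.items())
        if ref > 0
    ]
    if min_abs_error is not None:
        rows = [r for r in rows if abs(r[1]) > min_abs_error]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows
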