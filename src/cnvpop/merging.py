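"""Two-level consensus merging of multi-caller CNV calls.

Level 1 merges the call sets of several callers within one sample; level 2
merges per-sample consensus calls across the cohort.  Both levels cluster
calls of the same type on the same chromosome by >= 50% reciprocal overlap,
using a greedy representative-anchored pass (a call joins the first
existing cluster whose *representative* it matches, never another member),
which prevents transitive chaining of marginally overlapping calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median_low

import numpy as np
import pandas as pd

from .core import SV_TYPES, CNVCall, ConsensusVariant, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerRanking:
    """Confidence orderings of callers, best first.

    Separate orderings may be given for breakpoint coordinates and for
    genotypes; by default the genotype ordering follows the coordinate one.
    """

    coordinates: tuple[str, ...]
    genotypes: tuple[str, ...] | None = None

    def __post_init__(self):
        for ordering in (self.coordinates, self.genotypes or ()):
            if len(set(ordering)) != len(ordering):
                raise ValueError("duplicate caller in ranking")

    def coord_rank(self, caller: str) -> int:
        try:
            return self.coordinates.index(caller)
        except ValueError:
            raise KeyError(f"caller {caller!r} missing from coordinate ranking") from None

    def genotype_rank(self, caller: str) -> int:
        ordering = self.genotypes if self.genotypes is not None else self.coordinates
        try:
            return ordering.index(caller)
        except ValueError:
            raise KeyError(f"caller {caller!r} missing from genotype ranking") from None


def reciprocal_overlap(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> tuple[float, float]:
    """Overlap of two intervals as a fraction of each interval's own length.

    Intervals are (chrom, start, end), 0-based half-open.  Different
    chromosomes give (0, 0).
    """
    chrom_a, start_a, end_a = a
    chrom_b, start_b, end_b = b
    if start_a >= end_a or start_b >= end_b:
        raise ValueError("intervals must be non-empty")
    if chrom_a != chrom_b:
        return 0.0, 0.0
    overlap = max(0, min(end_a, end_b) - max(start_a, start_b))
    return overlap / (end_a - start_a), overlap / (end_b - start_b)


@dataclass
class Cluster:
    """A group of mutually matching calls with a current representative."""

    members: list[CNVCall] = field(default_factory=list)
    rep_start: int = 0
    rep_end: int = 0
    rep_rank: float = np.inf

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def svtype(self) -> str:
        return self.members[0].svtype


def cluster_calls(
    calls: list[CNVCall],
    threshold: float = 0.5,
    rank_of=None,
    representative: str = "best_rank",
) -> list[Cluster]:
    """Greedy reciprocal-overlap clustering of same-type, same-chromosome calls.

    Calls are sorted by (start, end, rank) and each joins the first cluster
    whose current representative it reciprocally overlaps at ``threshold``
    on *both* fractions, else seeds a new cluster.  The representative is
    the best-ranked member's interval (``representative="best_rank"``) or
    the member-wise low median of endpoints (``"median"``, used for the
    cross-sample level).
    """
    if not calls:
        return []
    svtypes = {c.svtype for c in calls}
    chroms = {c.chrom for c in calls}
    if len(svtypes) > 1:
        raise ValueError(f"cluster_calls got mixed types {sorted(svtypes)}; "
                         "cluster deletions and duplications separately")
    if len(chroms) > 1:
        raise ValueError("cluster_calls processes one chromosome at a time")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if rank_of is None:
        rank_of = lambda call: 0  # noqa: E731 - order of appearance decides ties

    order = sorted(calls, key=lambda c: (c.start, c.end, rank_of(c), c.caller, c.sample))
    clusters: list[Cluster] = []
    for call in order:
        for cl in clusters:
            fa, fb = reciprocal_overlap(
                (call.chrom, call.start, call.end), (cl.chrom, cl.rep_start, cl.rep_end)
            )
            if fa >= threshold and fb >= threshold:
                cl.members.append(call)
                _update_representative(cl, call, rank_of, representative)
                break
        else:
            clusters.append(
                Cluster(members=[call], rep_start=call.start, rep_end=call.end,
                        rep_rank=rank_of(call))
            )
    return clusters


def _update_representative(cl: Cluster, call: CNVCall, rank_of, mode: str) -> None:
    if mode == "best_rank":
        rank = rank_of(call)
        if rank < cl.rep_rank:
            cl.rep_rank = rank
            cl.rep_start, cl.rep_end = call.start, call.end
    elif mode == "median":
        cl.rep_start = median_low([m.start for m in cl.members])
        cl.rep_end = median_low([m.end for m in cl.members])
    else:  # pragma: no cover
        raise ValueError(f"unknown representative mode {mode!r}")


def resolve_cluster(cluster: Cluster, ranking: CallerRanking) -> CNVCall:
    """Collapse a cluster to one call using the dual caller ranking.

    Coordinates come from the member whose caller ranks highest in the
    coordinate ordering; the genotype from the member ranking highest in
    the genotype ordering.  Quality fields follow the coordinate member.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    coord_m = min(cluster.members, key=lambda m: ranking.coord_rank(m.caller))
    gt_m = min(cluster.members, key=lambda m: ranking.genotype_rank(m.caller))
    return CNVCall(
        chrom=coord_m.chrom, start=coord_m.start, end=coord_m.end,
        svtype=coord_m.svtype, genotype=gt_m.genotype,
        caller=coord_m.caller, sample=coord_m.sample, qual=dict(coord_m.qual),
    )


def merge_sample_calls(
    per_caller: dict[str, list[CNVCall]],
    ranking: CallerRanking,
    threshold: float = 0.5,
    min_callers: int = 1,
) -> list[CNVCall]:
    """Merge one sample's multi-caller call sets into a per-sample consensus.

    Clusters with fewer than ``min_callers`` distinct callers are dropped.
    Returned calls are sorted by (chrom, start, end); each carries the
    caller-support count in ``qual["n_callers"]``.
    """
    calls = [c for calls in per_caller.values() for c in calls]
    samples = {c.sample for c in calls}
    if len(samples) > 1:
        raise ValueError(f"merge_sample_calls got calls from several samples: {sorted(samples)}")
    rank_of = lambda c: ranking.coord_rank(c.caller)  # noqa: E731
    out: list[CNVCall] = []
    for chrom in sorted({c.chrom for c in calls}):
        for svtype in SV_TYPES:
            group = [c for c in calls if c.chrom == chrom and c.svtype == svtype]
            if not group:
                continue
            for cl in cluster_calls(group, threshold, rank_of):
                if len({m.caller for m in cl.members}) < min_callers:
                    continue
                resolved = resolve_cluster(cl, ranking)
                resolved.qual["n_callers"] = len({m.caller for m in cl.members})
                out.append(resolved)
    out.sort(key=lambda c: (c.chrom, c.start, c.end))
    return out


def merge_cohort(
    per_sample: dict[str, list[CNVCall]],
    threshold: float = 0.5,
    sample_populations: pd.Series | None = None,
) -> tuple[list[ConsensusVariant], GenotypeMatrix | None]:
    """Merge per-sample consensus calls into a cohort variant table.

    Clustering is the same greedy pass with the representative kept at the
    member-wise low-median start/end.  Per-sample genotypes come from that
    sample's member call; samples with no member get reference dosage 0.
    A duplicate member from one sample within a cluster keeps the
    better-supported call and logs a warning.

    Returns the sorted list of :class:`ConsensusVariant` and, when
    ``sample_populations`` is given, the cohort :class:`GenotypeMatrix`.
    """
    calls = [c for calls in per_sample.values() for c in calls]
    all_samples = sorted(per_sample)
    variants: list[ConsensusVariant] = []
    chroms = sorted({c.chrom for c in calls})
    for chrom in chroms:
        for svtype in SV_TYPES:
            group = [c for c in calls if c.chrom == chrom and c.svtype == svtype]
            if not group:
                continue
            for cl in cluster_calls(group, threshold, representative="median"):
                genotypes = {s: 0.0 for s in all_samples}
                support: dict[str, CNVCall] = {}
                n_callers: dict[str, int] = {}
                for m in cl.members:
                    if m.sample in support:
                        log.warning(
                            "duplicate member for sample %s in cluster at %s:%d-%d; "
                            "keeping the better-supported call",
                            m.sample, chrom, cl.rep_start, cl.rep_end,
                        )
                        keep = max(
                            (support[m.sample], m),
                            key=lambda c: (c.qual.get("n_callers", 1), -c.start),
                        )
                        support[m.sample] = keep
                    else:
                        support[m.sample] = m
                for s, m in support.items():
                    genotypes[s] = m.genotype
                    n_callers[s] = int(m.qual.get("n_callers", 1))
                variants.append(
                    ConsensusVariant(
                        vid="", chrom=chrom, start=cl.rep_start, end=cl.rep_end,
                        svtype=svtype, members=list(cl.members),
                        genotypes=genotypes, n_callers=n_callers,
                    )
                )
    variants.sort(key=lambda v: (v.chrom, v.start, v.end))
    for i, v in enumerate(variants):
        v.vid = f"cnv_{i:05d}"

    matrix = None
    if sample_populations is not None:
        meta = pd.DataFrame(
            {
                "chrom": [v.chrom for v in variants],
                "start": [v.start for v in variants],
                "end": [v.end for v in variants],
                "svtype": [v.svtype for v in variants],
            },
            index=pd.Index([v.vid for v in variants], name="variant"),
        )
        dosages = pd.DataFrame(
            [[v.genotypes[s] for s in all_samples] for v in variants],
            index=meta.index, columns=all_samples, dtype=float,
        )
        matrix = GenotypeMatrix(meta, dosages, sample_populations)
    return variants, matrix
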