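"""Length-preserving region randomization test.

Tests whether a query region set (e.g. genic deletions of one population)
overlaps a target set (e.g. introns of LoF-intolerant genes) more or less
often than expected when the query regions are relocated uniformly across
the genome with their lengths preserved.  The evaluation statistic is the
number of query regions with >= 1 bp of overlap against the merged target
set; the empirical p-value uses the add-one convention
p = (#{permutation >= observed} + 1) / (n_perm + 1), so it is never zero
and is floored at 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import merge_intervals
from .core import GenomeLayout

Regions = dict[str, list[tuple[int, int]]]  # chrom -> [(start, end), ...]


@dataclass(frozen=True)
class PermutationResult:
    observed: int
    n_perm: int
    perm_mean: float
    perm_sd: float
    z: float | None
    p: float
    alternative: str
    seed: int | None = None


def _flatten(regions: Regions, layout: GenomeLayout):
    """Map per-chromosome regions onto one global coordinate line."""
    offsets = {}
    off = 0
    for name, length in layout.chromosomes:
        offsets[name] = off
        off += length
    starts, ends = [], []
    for chrom, ivs in regions.items():
        if chrom not in offsets:
            raise ValueError(f"region chromosome {chrom!r} absent from layout")
        o = offsets[chrom]
        for s, e in ivs:
            starts.append(o + s)
            ends.append(o + e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _merged_target(target: Regions, layout: GenomeLayout):
    merged = {c: merge_intervals(ivs) for c, ivs in target.items()}
    t_start, t_end = _flatten(merged, layout)
    order = np.argsort(t_start)
    return t_start[order], t_end[order]


def _count_hits(q_start, q_end, t_start, t_end) -> np.ndarray:
    """Element-wise: does each query interval touch any merged target interval?

    Targets are disjoint and sorted; a query [s, e) overlaps some target
    iff the first target whose end exceeds s starts before e.
    """
    idx = np.searchsorted(t_end, q_start, side="right")
    hit = (idx < len(t_start)) & (t_start[np.minimum(idx, len(t_start) - 1)] < q_end)
    return hit


def count_overlaps(query: Regions, target: Regions, layout: GenomeLayout) -> int:
    """Number of query regions overlapping the merged target set by >= 1 bp.

    Each query region counts at most once even when it spans several
    target intervals.
    """
    t_start, t_end = _merged_target(target, layout)
    if len(t_start) == 0:
        return 0
    q_start, q_end = _flatten(query, layout)
    return int(_count_hits(q_start, q_end, t_start, t_end).sum())


def randomize_regions(
    query: Regions, layout: GenomeLayout, rng: np.random.Generator
) -> Regions:
    """Relocate each region independently, preserving its length.

    The chromosome is chosen with probability proportional to the number
    of valid start positions (length - region length + 1) and the start is
    uniform among them.  Randomized regions may overlap each other.
    """
    lengths = np.asarray(
        [e - s for ivs in query.values() for s, e in ivs], dtype=np.int64
    )
    chrom_idx, starts = _random_placements(lengths, layout, rng)
    out: Regions = {}
    for ci, s, length in zip(chrom_idx, starts, lengths):
        chrom = layout.names[int(ci)]
        out.setdefault(chrom, []).append((int(s), int(s + length)))
    return out


def _random_placements(lengths: np.ndarray, layout: GenomeLayout, rng, size=None):
    """Vectorised placement of regions of given lengths; returns (chrom_idx, start).

    ``size`` may extend the draw to shape (n_perm, n_regions) for batched
    permutation.  Raises when some region fits on no chromosome.
    """
    chrom_len = layout.lengths  # (C,)
    valid = chrom_len[None, :] - lengths[:, None] + 1  # (R, C) valid start counts
    valid = np.maximum(valid, 0)
    totals = valid.sum(axis=1)
    if (totals == 0).any():
        too_long = lengths[totals == 0]
        raise ValueError(f"region length(s) {too_long.tolist()} exceed every chromosome")
    probs = valid / totals[:, None]
    shape = (len(lengths),) if size is None else (size, len(lengths))
    u = rng.random(shape)
    cum = probs.cumsum(axis=1)  # (R, C)
    chrom_idx = (u[..., None] > cum[None, ...] if size is not None
                 else u[:, None] > cum).sum(axis=-1)
    n_valid = valid[np.arange(len(lengths)), chrom_idx]
    starts = (rng.random(shape) * n_valid).astype(np.int64)
    return chrom_idx, starts


def permutation_test(
    query: Regions,
    target: Regions,
    layout: GenomeLayout,
    n_perm: int = 5000,
    alternative: str = "greater",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    batch: int = 500,
) -> PermutationResult:
    """Randomization test of query-target overlap abundance.

    ``alternative="greater"`` asks whether the observed overlap count is
    higher than expected under uniform relocation; ``"less"`` the
    opposite.  Placement and counting are vectorised in batches.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if not any(query.values()) or not any(target.values()):
        raise ValueError("query and target must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(seed)

    t_start, t_end = _merged_target(target, layout)
    observed = count_overlaps(query, target, layout)
    lengths = np.asarray(
        [e - s for ivs in query.values() for s, e in ivs], dtype=np.int64
    )
    offsets = np.concatenate([[0], np.cumsum(layout.lengths)])[:-1]

    stats = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        chrom_idx, starts = _random_placements(lengths, layout, rng, size=b)
        g_start = offsets[chrom_idx] + starts  # (b, R)
        g_end = g_start + lengths[None, :]
        hits = _count_hits(g_start.ravel(), g_end.ravel(), t_start, t_end)
        stats[done:done + b] = hits.reshape(b, -1).sum(axis=1)
        done += b

    if alternative == "greater":
        extreme = int(np.sum(stats >= observed))
    else:
        extreme = int(np.sum(stats <= observed))
    p = (extreme + 1) / (n_perm + 1)
    mean = float(stats.mean())
    sd = float(stats.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else None
    return PermutationResult(observed=observed, n_perm=n_perm, perm_mean=mean,
                             perm_sd=sd, z=z, p=float(p),
                             alternative=alternative, seed=seed)
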