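"""CNV breakpoint–boundary distance statistics and SV classification.

Breakpoints are the endpoints of non-neutral copy-number segments.  Their
distances to the nearest TAD boundary midpoint are compared against a
location-randomized null (uniform redraws preserving per-chromosome
counts).  SVs are classified by class label, length range (2 Mb cutoff),
and TAD placement: ``span`` when the interval fully covers at least one
boundary region (midpoint ± half the 75 kb boundary length), ``within``
when it lies inside one TAD, else ``other``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .tads import BoundarySet, TADSet

log = logging.getLogger(__name__)

PROXIMITY_THRESHOLD_BP = 120_000
BOUNDARY_LEN_BP = 75_000
RANGE_CUTOFF_BP = 2_000_000
CN_STATUSES = (0, 1, 3, 4, 5)


def cn_direction(cn: int) -> str:
    return "gain" if cn > 2 else ("loss" if cn < 2 else "neutral")


def extract_breakpoints(segments: pd.DataFrame) -> pd.DataFrame:
    """Start and end of every non-neutral segment, deduplicated per (chrom, pos).

    Overlapping segments on one chromosome are rejected; neutral (cn == 2)
    segments contribute nothing.  Coordinates shared by adjacent segments
    appear once.
    """
    if (segments["start"] >= segments["end"]).any():
        raise ValueError("segment with start >= end")
    for chrom, sub in segments.groupby("chrom"):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segments on {chrom}")
    nn = segments[segments["cn"] != 2]
    rows = set()
    for _, r in nn.iterrows():
        rows.add((r["chrom"], int(r["start"])))
        rows.add((r["chrom"], int(r["end"])))
    return (
        pd.DataFrame(sorted(rows), columns=["chrom", "pos"])
        .reset_index(drop=True)
    )


def _nearest_distance(pos: np.ndarray, mids: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(mids, pos)
    best = np.full(len(pos), np.inf)
    for shift in (-1, 0):
        j = np.clip(idx + shift, 0, len(mids) - 1)
        best = np.minimum(best, np.abs(mids[j] - pos))
    return best


def breakpoint_boundary_distances(
    bps: pd.DataFrame, boundaries: BoundarySet
) -> np.ndarray:
    """|breakpoint - nearest boundary midpoint| in bp, pooled over chromosomes.

    Breakpoints on chromosomes without boundaries are excluded (logged).
    """
    out = []
    n_excluded = 0
    for chrom, sub in bps.groupby("chrom"):
        mids = boundaries.midpoints(chrom) if chrom in boundaries.bins else np.array([])
        if len(mids) == 0:
            n_excluded += len(sub)
            continue
        out.append(_nearest_distance(sub["pos"].to_numpy(float), np.sort(mids)))
    if n_excluded:
        log.info("excluded %d breakpoints on boundary-free chromosomes", n_excluded)
    return np.concatenate(out) if out else np.array([])


def randomized_null_distances(
    bps: pd.DataFrame,
    boundaries: BoundarySet,
    genome: BinnedGenome,
    n_rand: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Pooled nearest-boundary distances of location-randomized breakpoints.

    Each of ``n_rand`` replicates preserves per-chromosome breakpoint counts
    with positions uniform over the chromosome.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    rng = np.random.default_rng(seed)
    counts = bps.groupby("chrom").size()
    pooled = []
    for _ in range(n_rand):
        for chrom, k in counts.items():
            mids = (
                np.sort(boundaries.midpoints(chrom))
                if chrom in boundaries.bins and len(boundaries.bins[chrom])
                else np.array([])
            )
            if len(mids) == 0:
                continue
            pos = rng.integers(0, genome.size(chrom), size=int(k)).astype(float)
            pooled.append(_nearest_distance(pos, mids))
    return np.concatenate(pooled) if pooled else np.array([])


def proximity_fraction(
    distances: np.ndarray, threshold_bp: int = PROXIMITY_THRESHOLD_BP
) -> tuple[int, float]:
    """Count and fraction of distances within the threshold (inclusive)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances")
    count = int((d <= threshold_bp).sum())
    return count, count / d.size


def distances_by_cn_status(
    segments: pd.DataFrame, boundaries: BoundarySet
) -> dict[int, np.ndarray]:
    """Breakpoint distances grouped by the source segment's CN status.

    A coordinate shared by two non-neutral segments is attributed to both
    statuses.
    """
    groups: dict[int, list] = {s: [] for s in CN_STATUSES}
    for chrom, sub in segments.groupby("chrom"):
        mids = (
            np.sort(boundaries.midpoints(chrom)) if chrom in boundaries.bins else np.array([])
        )
        if len(mids) == 0:
            continue
        for _, r in sub[sub["cn"] != 2].iterrows():
            d = _nearest_distance(
                np.array([float(r["start"]), float(r["end"])]), mids
            )
            groups[int(r["cn"])].extend(d.tolist())
    return {s: np.array(v) for s, v in groups.items()}


def classify_svs(
    svs: pd.DataFrame,
    tads: TADSet,
    boundaries: BoundarySet,
    boundary_len_bp: int = BOUNDARY_LEN_BP,
    range_cutoff_bp: int = RANGE_CUTOFF_BP,
) -> pd.DataFrame:
    """Assign length, range, and TAD placement to every SV call.

    Interchromosomal calls get NA length/range/placement.  For
    intrachromosomal calls the interval runs between the two break-end
    starts (order-insensitive); range is ``long`` when length >= 2 Mb.
    Placement: ``span`` if the interval fully covers at least one boundary
    region, else ``within`` if it lies inside one TAD, else ``other``.
    """
    hl = boundary_len_bp / 2
    out = svs.copy()
    lengths, ranges, placements = [], [], []
    for _, r in svs.iterrows():
        if r["chrom1"] != r["chrom2"]:
            lengths.append(np.nan)
            ranges.append("NA")
            placements.append("NA")
            continue
        chrom = r["chrom1"]
        s = int(min(r["start1"], r["start2"]))
        e = int(max(r["start1"], r["start2"]))
        length = e - s
        lengths.append(length)
        ranges.append("long" if length >= range_cutoff_bp else "short")
        mids = boundaries.midpoints(chrom) if chrom in boundaries.bins else np.array([])
        covers = np.any((s <= mids - hl) & (mids + hl <= e)) if len(mids) else False
        if covers:
            placements.append("span")
            continue
        ivals = tads.intervals.get(chrom, np.empty((0, 2)))
        inside = np.any((ivals[:, 0] <= s) & (e <= ivals[:, 1])) if len(ivals) else False
        placements.append("within" if inside else "other")
    out["length"] = lengths
    out["range"] = ranges
    out["placement"] = placements
    return out


def sv_counts_by_placement(classified: pd.DataFrame) -> pd.DataFrame:
    """Contingency counts over (class, range, placement)."""
    if classified.empty:
        return pd.DataFrame(columns=["sv_class", "range", "placement", "count"])
    return (
        classified.groupby(["sv_class", "range", "placement"])
        .size()
        .rename("count")
        .reset_index()
    )
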