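"""Insulation-score TAD boundary calling and cross-sample boundary comparison.

The insulation value of a bin is the mean balanced contact between the ``w``
bins on its left and the ``w`` bins on its right; local minima of the
log2-normalized track mark domain boundaries.  TADs are the intervals
between consecutive boundary midpoints.  Two boundary sets are compared by
bin-tolerance matching (common boundaries), a bootstrap overlap test, and a
five-mode change classification (conserved / shifted / de novo / gain /
loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .hic import ContactMap

MAX_WINDOW_BP = 2_000_000  # insulation / TAD-signal windows flank at most 2 Mb


@dataclass
class InsulationTrack:
    """Per-chromosome insulation values and their normalized / z-scored forms."""

    genome: BinnedGenome
    window_bins: int
    raw: dict[str, np.ndarray]  # NaN where undefined
    normalized: dict[str, np.ndarray]  # log2(raw / chromosome mean of raw)
    zscore: dict[str, np.ndarray]

    @property
    def bin_size(self) -> int:
        return self.genome.bin_size


@dataclass
class BoundarySet:
    """Sorted boundary bins per chromosome, with calling strength."""

    genome: BinnedGenome
    bins: dict[str, np.ndarray]
    strength: dict[str, np.ndarray] = field(default_factory=dict)
    sample: str = ""

    def __post_init__(self) -> None:
        for chrom, b in self.bins.items():
            b = np.asarray(b, dtype=int)
            if len(np.unique(b)) != len(b) or np.any(np.diff(b) <= 0):
                b = np.unique(b)
            self.bins[chrom] = b
            if chrom not in self.strength:
                self.strength[chrom] = np.full(len(b), np.nan)

    def midpoints(self, chrom: str) -> np.ndarray:
        return (self.bins[chrom] + 0.5) * self.genome.bin_size

    def n_boundaries(self) -> int:
        return int(sum(len(b) for b in self.bins.values()))

    def to_bed(self) -> pd.DataFrame:
        rows = []
        half = self.genome.bin_size // 2
        for chrom in self.genome.chrom_names:
            if chrom not in self.bins:
                continue
            for b, s in zip(self.bins[chrom], self.strength[chrom]):
                mid = int((b + 0.5) * self.genome.bin_size)
                rows.append((chrom, mid - half, mid + half, f"boundary_{chrom}_{b}", s, "."))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


@dataclass
class TADSet:
    """Non-overlapping inter-boundary intervals (bp, half-open) per chromosome."""

    genome: BinnedGenome
    intervals: dict[str, np.ndarray]  # (n, 2) float arrays
    sample: str = ""

    def lengths(self) -> np.ndarray:
        parts = [iv[:, 1] - iv[:, 0] for iv in self.intervals.values() if len(iv)]
        return np.concatenate(parts) if parts else np.array([])

    def n_tads(self) -> int:
        return int(sum(len(iv) for iv in self.intervals.values()))

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for chrom in self.genome.chrom_names:
            for i, (s, e) in enumerate(self.intervals.get(chrom, [])):
                rows.append((chrom, int(s), int(e), f"tad_{chrom}_{i}", 0, "."))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


@dataclass
class TADChangeRecord:
    """One boundary's classification between a query and a reference sample."""

    chrom: str
    mode: str  # conserved | shifted | de_novo | gain | loss
    query_bin: int | None
    ref_bin: int | None
    offset_bins: int | None

    @property
    def is_de_novo_like(self) -> bool:
        """Gain boundaries are de-novo boundaries that subdivide a reference TAD."""
        return self.mode in ("de_novo", "gain")


# ----------------------------------------------------------------- insulation


def insulation_track(cmap: ContactMap, window_bins: int = 10) -> InsulationTrack:
    """Mean balanced contact across each bin within a square window.

    ``raw[i]`` averages ``M[j, k]`` for ``j in [i-w, i-1]``, ``k in
    [i+1, i+w]`` over unmasked cells; undefined where the window does not
    fit, the bin is masked, or no valid cell exists.
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    if window_bins * cmap.genome.bin_size > MAX_WINDOW_BP:
        raise ValueError(f"insulation window exceeds {MAX_WINDOW_BP} bp of flank")
    if not cmap.is_balanced:
        raise ValueError("insulation requires a balanced map")
    raw_d, norm_d, z_d = {}, {}, {}
    w = window_bins
    for chrom in cmap.genome.chrom_names:
        b = cmap.balanced(chrom)
        mask = cmap.mask[chrom]
        n = b.shape[0]
        if n < 2 * w + 1:
            raise ValueError(f"{chrom}: window of {w} bins larger than chromosome")
        raw = np.full(n, np.nan)
        for i in range(w, n - w):
            if mask[i]:
                continue
            block = b[i - w : i, i + 1 : i + w + 1]
            if np.isnan(block).all():
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                raw[i] = np.nanmean(block)
        defined = ~np.isnan(raw)
        norm = np.full(n, np.nan)
        z = np.full(n, np.nan)
        if defined.any():
            mean_raw = raw[defined].mean()
            if mean_raw > 0:
                with np.errstate(divide="ignore"):
                    norm[defined] = np.log2(raw[defined] / mean_raw)
                norm[np.isneginf(norm)] = np.nan
            nd = ~np.isnan(norm)
            if nd.sum() >= 2 and norm[nd].std() > 0:
                z[nd] = (norm[nd] - norm[nd].mean()) / norm[nd].std()
            elif nd.any():
                z[nd] = 0.0
        raw_d[chrom], norm_d[chrom], z_d[chrom] = raw, norm, z
    return InsulationTrack(cmap.genome, w, raw_d, norm_d, z_d)


def tad_signal_track(cmap: ContactMap, window_bp: int = 500_000) -> dict[str, np.ndarray]:
    """log2 of each bin's near-diagonal contact sum over the chromosome mean.

    The sum at bin ``i`` pools ``M[i, j]`` for ``|i - j| * bin_size <=
    window_bp`` (unmasked cells).
    """
    if window_bp > MAX_WINDOW_BP:
        raise ValueError(f"window_bp exceeds {MAX_WINDOW_BP}")
    if not cmap.is_balanced:
        raise ValueError("TAD signal requires a balanced map")
    w = window_bp // cmap.genome.bin_size
    out = {}
    for chrom in cmap.genome.chrom_names:
        b = cmap.balanced(chrom)
        mask = cmap.mask[chrom]
        n = b.shape[0]
        sums = np.full(n, np.nan)
        # defined only where the full window fits, so the chromosome mean is
        # comparable across bins
        for i in range(w, n - w):
            if mask[i]:
                continue
            row = b[i, i - w : i + w + 1]
            if np.isnan(row).all():
                continue
            sums[i] = np.nansum(row)
        defined = ~np.isnan(sums)
        sig = np.full(n, np.nan)
        if defined.any():
            mean_sum = sums[defined].mean()
            if mean_sum > 0:
                with np.errstate(divide="ignore"):
                    sig[defined] = np.log2(sums[defined] / mean_sum)
        out[chrom] = sig
    return out


# ------------------------------------------------------------ boundary calls


def call_boundaries(
    track: InsulationTrack,
    delta_bins: int = 2,
    strength_min: float = 0.1,
    sample: str = "",
) -> BoundarySet:
    """Local insulation minima by zero-crossings of the left-right delta.

    ``delta[i]`` is the mean normalized insulation over the ``delta_bins``
    bins left of ``i`` minus the mean over the bins right of ``i``; a
    boundary sits where delta crosses zero from + to - and the local swing
    (max delta before minus min delta after) reaches ``strength_min``.
    """
    if delta_bins < 1:
        raise ValueError("delta_bins must be >= 1")
    bins_d, strength_d = {}, {}
    for chrom in track.genome.chrom_names:
        norm = track.normalized[chrom]
        n = len(norm)
        delta = np.full(n, np.nan)
        for i in range(delta_bins, n - delta_bins):
            left = norm[i - delta_bins : i]
            right = norm[i + 1 : i + 1 + delta_bins]
            if np.isnan(left).any() or np.isnan(right).any():
                continue
            delta[i] = left.mean() - right.mean()
        found_bins, found_str = [], []
        for i in range(n - 1):
            if np.isnan(delta[i]) or np.isnan(delta[i + 1]):
                continue
            if not (delta[i] > 0 and delta[i + 1] <= 0):
                continue
            # local swing: max delta over the positive run before the
            # crossing minus min delta over the non-positive run after it
            j = i
            best_before = delta[i]
            while j - 1 >= 0 and not np.isnan(delta[j - 1]) and delta[j - 1] > 0:
                j -= 1
                best_before = max(best_before, delta[j])
            k = i + 1
            best_after = delta[i + 1]
            while k + 1 < n and not np.isnan(delta[k + 1]) and delta[k + 1] <= 0:
                k += 1
                best_after = min(best_after, delta[k])
            strength = best_before - best_after
            if strength < strength_min:
                continue
            cand = [i, i + 1]
            vals = [norm[c] if not np.isnan(norm[c]) else np.inf for c in cand]
            b = cand[int(np.argmin(vals))]
            found_bins.append(b)
            found_str.append(strength)
        # merge adjacent qualifying bins to the minimum-insulation bin
        merged_bins, merged_str = [], []
        for b, s in zip(found_bins, found_str):
            if merged_bins and b - merged_bins[-1] <= 1:
                prev = merged_bins[-1]
                pv = norm[prev] if not np.isnan(norm[prev]) else np.inf
                cv = norm[b] if not np.isnan(norm[b]) else np.inf
                if cv < pv:
                    merged_bins[-1] = b
                merged_str[-1] = max(merged_str[-1], s)
            else:
                merged_bins.append(b)
                merged_str.append(s)
        bins_d[chrom] = np.array(merged_bins, dtype=int)
        strength_d[chrom] = np.array(merged_str, dtype=float)
    return BoundarySet(track.genome, bins_d, strength_d, sample)


def boundaries_to_tads(bset: BoundarySet) -> TADSet:
    """Intervals between consecutive boundary midpoints; <2 boundaries -> none."""
    intervals = {}
    for chrom in bset.genome.chrom_names:
        b = bset.bins.get(chrom, np.array([], dtype=int))
        if len(b) < 2:
            warnings.warn(f"{chrom}: fewer than 2 boundaries, no TADs emitted")
            intervals[chrom] = np.empty((0, 2))
            continue
        mids = (b + 0.5) * bset.genome.bin_size
        intervals[chrom] = np.column_stack([mids[:-1], mids[1:]]).astype(float)
    return TADSet(bset.genome, intervals, bset.sample)


# --------------------------------------------------------- set comparisons


def _nearest_offset(query: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per query bin, distance (bins) to the nearest target; inf if none."""
    if len(targets) == 0:
        return np.full(len(query), np.inf)
    idx = np.searchsorted(targets, query)
    best = np.full(len(query), np.inf)
    for shift in (-1, 0):
        j = np.clip(idx + shift, 0, len(targets) - 1)
        best = np.minimum(best, np.abs(targets[j] - query))
    return best


def match_boundaries(
    sets: list[BoundarySet], tol_bins: int = 2
) -> tuple[BoundarySet, dict]:
    """Boundaries of the first set present in every other set within tolerance.

    A boundary is common when each other set holds a boundary within
    ``tol_bins`` on the same chromosome (nearest matching, leftmost-first
    ordering).  Returns the common set and spacing statistics (median bp
    between consecutive common boundaries).
    """
    if len(sets) < 2:
        raise ValueError("need at least two boundary sets")
    genome = sets[0].genome
    for s in sets[1:]:
        if s.genome != genome:
            raise ValueError("boundary sets disagree on the genome")
    common_bins = {}
    spacings = []
    for chrom in genome.chrom_names:
        a = sets[0].bins.get(chrom, np.array([], dtype=int))
        ok = np.ones(len(a), dtype=bool)
        for other in sets[1:]:
            t = other.bins.get(chrom, np.array([], dtype=int))
            ok &= _nearest_offset(a, t) <= tol_bins
        common = a[ok]
        common_bins[chrom] = common
        if len(common) >= 2:
            spacings.extend(np.diff((common + 0.5) * genome.bin_size).tolist())
    stats = {
        "n_common": int(sum(len(b) for b in common_bins.values())),
        "median_spacing_bp": float(np.median(spacings)) if spacings else float("nan"),
        "mean_spacing_bp": float(np.mean(spacings)) if spacings else float("nan"),
    }
    return BoundarySet(genome, common_bins, sample="common"), stats


def boundary_overlap_pvalue(
    a: BoundarySet,
    b: BoundarySet,
    tol_bins: int = 2,
    n_boot: int = 1000,
    seed: int = 0,
    eligible: dict[str, np.ndarray] | None = None,
) -> tuple[int, float]:
    """Bootstrap significance of the overlap between two boundary sets.

    Observed statistic: number of ``a`` boundaries with a ``b`` boundary
    within ``tol_bins``.  Null: ``b``'s per-chromosome boundary counts are
    redrawn uniformly (without replacement) over eligible bins.  Returns the
    observed overlap and the add-one Monte-Carlo p-value
    ``(1 + #{null >= observed}) / (n_boot + 1)``.
    """
    if a.genome != b.genome:
        raise ValueError("boundary sets disagree on the genome")
    if a.n_boundaries() == 0 or b.n_boundaries() == 0:
        raise ValueError("overlap p-value undefined for an empty boundary set")
    genome = a.genome
    rng = np.random.default_rng(seed)
    observed = 0
    for chrom in genome.chrom_names:
        aa = a.bins.get(chrom, np.array([], dtype=int))
        bb = b.bins.get(chrom, np.array([], dtype=int))
        observed += int((_nearest_offset(aa, bb) <= tol_bins).sum())
    null = np.zeros(n_boot, dtype=int)
    for chrom in genome.chrom_names:
        aa = np.sort(a.bins.get(chrom, np.array([], dtype=int)))
        k = len(b.bins.get(chrom, []))
        if k == 0 or len(aa) == 0:
            continue
        pool = (
            np.asarray(eligible[chrom])
            if eligible is not None
            else np.arange(genome.n_bins(chrom))
        )
        for r in range(n_boot):
            draw = np.sort(rng.choice(pool, size=min(k, len(pool)), replace=False))
            null[r] += int((_nearest_offset(aa, draw) <= tol_bins).sum())
    p = (1 + int((null >= observed).sum())) / (n_boot + 1)
    return observed, p


def classify_tad_changes(
    query: BoundarySet,
    ref: BoundarySet,
    tol_bins: int = 2,
    shift_max_bins: int = 6,
) -> tuple[list[TADChangeRecord], dict[str, float]]:
    """Classify boundary-level changes between a query and a reference sample.

    Per query boundary: conserved (nearest reference within ``tol_bins``),
    shifted (within ``shift_max_bins``), otherwise de novo.  A de-novo
    boundary whose two neighboring query boundaries are both conserved
    subdivides a reference TAD and is recorded as a gain.  Reference
    boundaries with no query boundary within ``shift_max_bins`` are losses.
    Fractions are over non-conserved records.
    """
    if query.genome != ref.genome:
        raise ValueError("boundary sets disagree on the genome")
    if tol_bins >= shift_max_bins:
        raise ValueError("tol_bins must be < shift_max_bins")
    records: list[TADChangeRecord] = []
    for chrom in query.genome.chrom_names:
        q = np.sort(query.bins.get(chrom, np.array([], dtype=int)))
        r = np.sort(ref.bins.get(chrom, np.array([], dtype=int)))
        offs = _nearest_offset(q, r)
        modes = np.where(
            offs <= tol_bins, "conserved", np.where(offs <= shift_max_bins, "shifted", "de_novo")
        )
        for i, (qb, off, mode) in enumerate(zip(q, offs, modes)):
            if mode == "de_novo":
                left_ok = i > 0 and modes[i - 1] == "conserved"
                right_ok = i + 1 < len(q) and modes[i + 1] == "conserved"
                if left_ok and right_ok:
                    mode = "gain"
            ref_bin = None
            if np.isfinite(off) and mode in ("conserved", "shifted"):
                j = np.searchsorted(r, qb)
                cands = [c for c in (j - 1, j) if 0 <= c < len(r)]
                best = min(cands, key=lambda c: abs(int(r[c]) - int(qb)))
                ref_bin = int(r[best])
            records.append(
                TADChangeRecord(
                    chrom,
                    str(mode),
                    int(qb),
                    ref_bin,
                    int(off) if np.isfinite(off) else None,
                )
            )
        roffs = _nearest_offset(r, q)
        for rb, off in zip(r[roffs > shift_max_bins], roffs[roffs > shift_max_bins]):
            records.append(TADChangeRecord(chrom, "loss", None, int(rb), None))
    changed = [rec for rec in records if rec.mode != "conserved"]
    n = len(changed)
    fractions = {
        m: (sum(rec.mode == m for rec in changed) / n if n else 0.0)
        for m in ("de_novo", "loss", "shifted", "gain")
    }
    return records, fractions


def short_long_ratio(tads: TADSet, cutoff_bp: int = 2_000_000) -> float:
    """#TADs shorter than the cutoff over #TADs at least as long (inf-flagged)."""
    lengths = tads.lengths()
    if lengths.size == 0:
        raise ValueError("empty TAD set")
    n_short = int((lengths < cutoff_bp).sum())
    n_long = int((lengths >= cutoff_bp).sum())
    if n_long == 0:
        warnings.warn("no TADs at or above the cutoff; ratio is infinite")
        return float("inf")
    return n_short / n_long


def change_records_to_frame(records: list[TADChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "mode": r.mode,
                "query_bin": r.query_bin,
                "ref_bin": r.ref_bin,
                "offset_bins": r.offset_bins,
            }
            for r in records
        ],
        columns=["chrom", "mode", "query_bin", "ref_bin", "offset_bins"],
    )
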