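"""Somatic co-mutation statistics on TADs and the Hi-C contact matrix.

PASS-filtered SNVs are aggregated to genes; the number of mutated genes
whose midpoint falls in a TAD is its CoMut count, and a TAD with CoMut
strictly greater than 10 is a hotspot.  Spatial proximity of co-mutated
gene pairs is read off the balanced contact matrix at their TSS bins and
compared against two distance-matched backgrounds — pairs of annotated
genes (gene-level) and pairs of unmasked bins (overall) — with a two-sample
Kolmogorov–Smirnov test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hic import ContactMap
from .tads import TADSet

log = logging.getLogger(__name__)

HOTSPOT_THRESHOLD = 10  # strict: a hotspot TAD has CoMut > 10


@dataclass
class CoMutRecord:
    """CoMut count and hotspot flag for one TAD."""

    chrom: str
    tad_index: int
    start: float
    end: float
    comut: int
    hotspot: bool
    mean_pair_frequency: float = float("nan")


def assign_mutations_to_genes(muts: pd.DataFrame, genes: pd.DataFrame) -> set[str]:
    """Genes hit by at least one PASS SNV (1-based position vs half-open interval).

    A 1-based position ``p`` overlaps gene ``[start, end)`` (0-based) iff
    ``start <= p - 1 < end``.  Non-PASS records are ignored; intergenic PASS
    records are assigned to no gene but stay in the table.
    """
    if (muts["pos"] < 1).any():
        raise ValueError("malformed 1-based positions (< 1)")
    mutated: set[str] = set()
    passing = muts[muts["filter"] == "PASS"]
    for chrom, sub in passing.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        names = g["name"].to_numpy()
        pos0 = sub["pos"].to_numpy() - 1
        for p in pos0:
            hit = (starts <= p) & (p < ends)
            mutated.update(names[hit])
    return mutated


def comut_per_tad(
    mutated_genes: set[str],
    genes: pd.DataFrame,
    tads: TADSet,
    threshold: int = HOTSPOT_THRESHOLD,
) -> list[CoMutRecord]:
    """Count mutated genes per TAD by the gene-midpoint rule.

    Genes outside every TAD are uncounted.  The hotspot flag is strict
    (``comut > threshold``).
    """
    mut = genes[genes["name"].isin(mutated_genes)]
    records: list[CoMutRecord] = []
    for chrom in tads.genome.chrom_names:
        ivals = tads.intervals.get(chrom, np.empty((0, 2)))
        g = mut[mut["chrom"] == chrom]
        mids = ((g["start"] + g["end"]) // 2).to_numpy()
        for i, (s, e) in enumerate(ivals):
            c = int(((mids >= s) & (mids < e)).sum())
            records.append(CoMutRecord(chrom, i, float(s), float(e), c, c > threshold))
    return records


def pair_contact_frequencies(
    mutated_genes: set[str],
    genes: pd.DataFrame,
    cmap: ContactMap,
) -> pd.DataFrame:
    """Balanced contact frequency for every same-chromosome mutated gene pair.

    The frequency of a pair is the balanced matrix entry at their TSS bins;
    pairs on different chromosomes are excluded, pairs sharing a bin use the
    diagonal entry and are flagged, pairs with a masked TSS bin are dropped
    (logged).
    """
    if not cmap.is_balanced:
        raise ValueError("pair frequencies require a balanced map")
    mut = genes[genes["name"].isin(mutated_genes)]
    rows = []
    n_dropped = 0
    for chrom, g in mut.groupby("chrom"):
        if chrom not in cmap.genome.chrom_names:
            continue
        b = cmap.balanced(chrom)
        mask = cmap.mask[chrom]
        names = g["name"].to_numpy()
        tss = g["tss"].to_numpy()
        bins = tss // cmap.genome.bin_size
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                bi, bj = int(bins[i]), int(bins[j])
                if mask[bi] or mask[bj]:
                    n_dropped += 1
                    continue
                rows.append(
                    {
                        "gene_a": names[i],
                        "gene_b": names[j],
                        "chrom": chrom,
                        "distance": int(abs(tss[i] - tss[j])),
                        "frequency": float(b[bi, bj]),
                        "same_bin": bi == bj,
                        "group": "comut",
                    }
                )
    if n_dropped:
        log.info("dropped %d gene pairs with a masked TSS bin", n_dropped)
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "chrom", "distance", "frequency", "same_bin", "group"],
    )


def sample_background(
    genes: pd.DataFrame,
    cmap: ContactMap,
    observed: pd.DataFrame,
    kind: str = "overall",
    n_per_obs: int = 10,
    distance_tol: float = 0.10,
    seed: int = 0,
    max_widen: int = 6,
) -> pd.DataFrame:
    """Distance-matched background pair frequencies.

    For each observed pair, draw ``n_per_obs`` background units on the same
    chromosome with linear distance within ``±distance_tol`` (relative) of
    the observed distance.  ``kind="gene_level"`` samples pairs of annotated
    genes regardless of mutation status; ``kind="overall"`` samples pairs of
    unmasked bins.  When no candidate exists the tolerance is doubled
    (logged) up to ``max_widen`` times, after which the pair is skipped with
    a warning.
    """
    if kind not in ("gene_level", "overall"):
        raise ValueError("kind must be 'gene_level' or 'overall'")
    if observed.empty:
        raise ValueError("observed sample is empty")
    if not cmap.is_balanced:
        raise ValueError("backgrounds require a balanced map")
    rng = np.random.default_rng(seed)
    bs = cmap.genome.bin_size
    tss_by_chrom = {
        chrom: np.sort(g["tss"].to_numpy()) for chrom, g in genes.groupby("chrom")
    }
    rows = []
    for _, obs in observed.iterrows():
        chrom = obs["chrom"]
        d = float(obs["distance"])
        b = cmap.balanced(chrom)
        mask = cmap.mask[chrom]
        n = b.shape[0]
        tol = distance_tol
        got = 0
        for attempt in range(max_widen + 1):
            lo, hi = d * (1 - tol), d * (1 + tol)
            if kind == "overall":
                # offsets in bins compatible with the distance window
                k_lo = max(0, int(np.ceil(lo / bs)))
                k_hi = int(np.floor(hi / bs))
                ks = np.arange(k_lo, min(k_hi, n - 1) + 1)
                cand = []
                for k in ks:
                    ii = np.arange(n - k)
                    ok = ~mask[ii] & ~mask[ii + k]
                    cand.extend(zip(ii[ok], ii[ok] + k))
                if cand:
                    take = rng.choice(len(cand), size=min(n_per_obs - got, len(cand)))
                    for t in np.atleast_1d(take):
                        bi, bj = cand[int(t)]
                        rows.append(
                            {
                                "gene_a": f"bin{bi}",
                                "gene_b": f"bin{bj}",
                                "chrom": chrom,
                                "distance": int((bj - bi) * bs),
                                "frequency": float(b[bi, bj]),
                                "same_bin": bi == bj,
                                "group": "overall_bg",
                            }
                        )
                        got += 1
            else:
                tss = tss_by_chrom.get(chrom, np.array([]))
                cand = []
                for ai, a_pos in enumerate(tss):
                    j_lo = np.searchsorted(tss, a_pos + lo, side="left")
                    j_hi = np.searchsorted(tss, a_pos + hi, side="right")
                    cand.extend((ai, jj) for jj in range(j_lo, j_hi))
                cand = [
                    (ai, jj)
                    for ai, jj in cand
                    if not mask[int(tss[ai] // bs)] and not mask[int(tss[jj] // bs)]
                ]
                if cand:
                    take = rng.choice(len(cand), size=min(n_per_obs - got, len(cand)))
                    for t in np.atleast_1d(take):
                        ai, jj = cand[int(t)]
                        bi, bj = int(tss[ai] // bs), int(tss[jj] // bs)
                        rows.append(
                            {
                                "gene_a": f"tss{ai}",
                                "gene_b": f"tss{jj}",
                                "chrom": chrom,
                                "distance": int(tss[jj] - tss[ai]),
                                "frequency": float(b[bi, bj]),
                                "same_bin": bi == bj,
                                "group": "gene_level_bg",
                            }
                        )
                        got += 1
            if got >= n_per_obs:
                break
            tol *= 2
            log.info(
                "widened %s background tolerance to %.3f for pair at distance %d",
                kind,
                tol,
                int(d),
            )
        if got == 0:
            warnings.warn(
                f"no {kind} background candidates for a pair at distance {int(d)}; skipped"
            )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "chrom", "distance", "frequency", "same_bin", "group"],
    )


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test; returns (D, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS comparison requires two non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def chromosome_hotspot_counts(records: list[CoMutRecord]) -> pd.DataFrame:
    """Per-chromosome counts of TADs with and without the hotspot flag."""
    rows: dict[str, dict[str, int]] = {}
    for r in records:
        d = rows.setdefault(r.chrom, {"with": 0, "without": 0})
        d["with" if r.hotspot else "without"] += 1
    return pd.DataFrame(
        [
            {"chrom": c, "with_hotspot": d["with"], "without_hotspot": d["without"]}
            for c, d in sorted(rows.items())
        ],
        columns=["chrom", "with_hotspot", "without_hotspot"],
    )


def variant_tad_lookup(
    chrom: str, position: int, tads: TADSet
) -> tuple[float, float] | None:
    """The TAD whose half-open interval contains a position, or None.

    Positions falling in a boundary gap (before the first or after the last
    boundary midpoint) belong to no TAD.
    """
    ivals = tads.intervals.get(chrom)
    if ivals is None or not len(ivals):
        return None
    hit = (ivals[:, 0] <= position) & (position < ivals[:, 1])
    idx = np.flatnonzero(hit)
    if not len(idx):
        return None
    s, e = ivals[int(idx[0])]
    return float(s), float(e)


def comut_records_to_frame(records: list[CoMutRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "tad_index": r.tad_index,
                "start": r.start,
                "end": r.end,
                "comut": r.comut,
                "hotspot": r.hotspot,
            }
            for r in records
        ],
        columns=["chrom", "tad_index", "start", "end", "comut", "hotspot"],
    )
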