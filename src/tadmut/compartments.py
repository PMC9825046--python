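"""A/B compartment calling, switch detection, and expression integration.

Compartments come from the leading eigenvector of the per-chromosome O/E
correlation matrix, oriented so it correlates positively with a covariate
(gene density by default): positive entries are A (open), negative B
(closed), exact zeros B with a logged count.  Switches between two samples
are maximal runs of jointly labeled bins whose labels differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinnedGenome

log = logging.getLogger(__name__)


@dataclass
class CompartmentTrack:
    """Oriented eigenvector values and A/B labels per chromosome."""

    genome: BinnedGenome
    eigenvector: dict[str, np.ndarray]  # NaN at masked bins
    labels: dict[str, np.ndarray]  # "A" | "B" | "masked"
    eigenvalue_share: dict[str, float] = field(default_factory=dict)
    sample: str = ""

    def n_bins_by_label(self) -> dict[str, int]:
        out = {"A": 0, "B": 0, "masked": 0}
        for lab in self.labels.values():
            for key in out:
                out[key] += int((lab == key).sum())
        return out


@dataclass
class SwitchRegion:
    """A maximal run of bins switching between the same pair of labels."""

    chrom: str
    start: int  # bp
    end: int
    from_label: str
    to_label: str
    n_bins: int


def gene_density_covariate(genes: pd.DataFrame, genome: BinnedGenome) -> dict[str, np.ndarray]:
    """Genes-per-bin track (TSS rule), the default orientation covariate."""
    out = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        track = np.zeros(n)
        g = genes[genes["chrom"] == chrom]
        if not g.empty:
            bins = (g["tss"].to_numpy() // genome.bin_size).astype(int)
            np.add.at(track, np.clip(bins, 0, n - 1), 1.0)
        out[chrom] = track
    return out


def compartment_track(
    corr: dict[str, np.ndarray],
    covariate: dict[str, np.ndarray],
    genome: BinnedGenome,
    sample: str = "",
) -> CompartmentTrack:
    """Leading eigenvector of each chromosome's correlation matrix, oriented.

    The sign is flipped so the Pearson correlation between the eigenvector
    and the covariate over unmasked bins is non-negative.  Labels follow the
    sign of the oriented value; exact zeros are labeled B (logged).
    """
    evec_d, label_d, share_d = {}, {}, {}
    n_zero = 0
    for chrom in genome.chrom_names:
        c = corr[chrom]
        n = c.shape[0]
        keep = ~np.all(np.isnan(c), axis=0)
        sub = c[np.ix_(keep, keep)]
        sub = np.nan_to_num(sub, nan=0.0)
        if sub.shape[0] < 2:
            raise ValueError(f"{chrom}: no leading eigenpair (fewer than 2 unmasked bins)")
        vals, vecs = np.linalg.eigh(sub)
        lead = vecs[:, -1]
        share_d[chrom] = float(vals[-1] / np.abs(vals).sum())
        cov = np.asarray(covariate[chrom], dtype=float)[keep]
        if np.std(cov) > 0 and np.std(lead) > 0:
            r = np.corrcoef(lead, cov)[0, 1]
            if r < 0:
                lead = -lead
        ev = np.full(n, np.nan)
        ev[keep] = lead
        labels = np.array(["masked"] * n, dtype=object)
        labels[keep & np.isfinite(ev) & (ev > 0)] = "A"
        labels[keep & np.isfinite(ev) & (ev <= 0)] = "B"
        n_zero += int((ev[keep] == 0).sum())
        evec_d[chrom], label_d[chrom] = ev, labels
    if n_zero:
        log.info("assigned %d exact-zero eigenvector bins to compartment B", n_zero)
    return CompartmentTrack(genome, evec_d, label_d, share_d, sample)


def count_compartments(track: CompartmentTrack) -> dict[str, int]:
    """Bin counts and maximal-run counts of each label."""
    bins_a = bins_b = runs_a = runs_b = 0
    for lab in track.labels.values():
        bins_a += int((lab == "A").sum())
        bins_b += int((lab == "B").sum())
        prev = None
        for x in lab:
            if x in ("A", "B") and x != prev:
                if x == "A":
                    runs_a += 1
                else:
                    runs_b += 1
            prev = x if x in ("A", "B") else None
    return {"bins_A": bins_a, "bins_B": bins_b, "runs_A": runs_a, "runs_B": runs_b}


def detect_switches(
    track_a: CompartmentTrack, track_b: CompartmentTrack
) -> tuple[list[SwitchRegion], dict[str, float]]:
    """Maximal runs of bins labeled differently in the two samples.

    Fractions are switched bins over jointly labeled bins, reported for
    A→B and B→A separately (direction is sample a → sample b).
    """
    if track_a.genome != track_b.genome:
        raise ValueError("tracks disagree on the genome binning")
    regions: list[SwitchRegion] = []
    joint = 0
    switched = {"A->B": 0, "B->A": 0}
    bs = track_a.genome.bin_size
    for chrom in track_a.genome.chrom_names:
        la, lb = track_a.labels[chrom], track_b.labels[chrom]
        n = len(la)
        both = (la != "masked") & (lb != "masked")
        joint += int(both.sum())
        i = 0
        while i < n:
            if not both[i] or la[i] == lb[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and both[j + 1] and la[j + 1] == la[i] and lb[j + 1] == lb[i]:
                j += 1
            key = f"{la[i]}->{lb[i]}"
            switched[key] += j - i + 1
            regions.append(
                SwitchRegion(chrom, i * bs, (j + 1) * bs, str(la[i]), str(lb[i]), j - i + 1)
            )
            i = j + 1
    fractions = {
        "A->B": switched["A->B"] / joint if joint else 0.0,
        "B->A": switched["B->A"] / joint if joint else 0.0,
    }
    return regions, fractions


def switch_regions_to_frame(regions: list[SwitchRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "from": r.from_label,
                "to": r.to_label,
                "n_bins": r.n_bins,
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "from", "to", "n_bins"],
    )


def switch_expression_fractions(
    switches: list[SwitchRegion] | pd.DataFrame,
    expr: pd.DataFrame,
    genes: pd.DataFrame,
    genome: BinnedGenome,
) -> dict[str, float | int]:
    """Fractions of DE genes whose TSS sits in a matching switch region.

    Down-regulated genes are checked against A→B regions, up-regulated
    against B→A.  Raises when the expression table holds no DE genes.
    """
    if isinstance(switches, list):
        sw = switch_regions_to_frame(switches)
    else:
        sw = switches
    de = expr[expr["status"].isin(["up", "down"])]
    if de.empty:
        raise ValueError("no differentially expressed genes")
    tss_of = genes.set_index("name")["tss"]
    chrom_of = genes.set_index("name")["chrom"]

    def _in_regions(gene_ids: pd.Series, frm: str, to: str) -> int:
        reg = sw[(sw["from"] == frm) & (sw["to"] == to)]
        count = 0
        for gid in gene_ids:
            if gid not in tss_of.index:
                continue
            tss, chrom = tss_of[gid], chrom_of[gid]
            hit = reg[(reg["chrom"] == chrom) & (reg["start"] <= tss) & (tss < reg["end"])]
            if len(hit):
                count += 1
        return count

    down = expr[expr["status"] == "down"]["gene"]
    up = expr[expr["status"] == "up"]["gene"]
    n_down_sw = _in_regions(down, "A", "B")
    n_up_sw = _in_regions(up, "B", "A")
    return {
        "n_down": int(len(down)),
        "n_down_in_AB": n_down_sw,
        "frac_down_in_AB": n_down_sw / len(down) if len(down) else 0.0,
        "n_up": int(len(up)),
        "n_up_in_BA": n_up_sw,
        "frac_up_in_BA": n_up_sw / len(up) if len(up) else 0.0,
    }
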