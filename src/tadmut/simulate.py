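"""Synthetic data with the statistical structure the downstream analyses assume.

One master seed drives independent per-generator streams (fixed offsets), so
adding a generator never perturbs earlier ones.  :func:`simulate_truth` plants
all structural ground truth — TAD boundaries with log-normal spacing
(median 541 kb), block compartments, genes, hotspot TADs, plus a perturbed
"reference" boundary set and a "normal" compartment labelling used for the
two-sample comparisons.  The remaining generators draw contact maps,
mutations, CNV segments, SVs, and expression conditioned on that truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .hic import ContactMap

SV_CLASSES = (
    "deletion",
    "tandem-duplication",
    "duplication",
    "inversion",
    "amplified-inversion",
    "foldback-inversion",
    "intrachromosomal",
    "interchromosomal",
    "complex",
)

_STREAMS = {
    "truth": 0,
    "contacts": 1,
    "contacts_ref": 2,
    "mutations": 3,
    "cnv": 4,
    "sv": 5,
    "expression": 6,
    "features": 7,
}

_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """All generator rates and sizes.

    Contact model: ``E[i, j] = L * (1 + |i-j|)**(-alpha) * tau**same_tad *
    exp(kappa * e_i * e_j)`` with independent Poisson counts on the upper
    triangle, mirrored.
    """

    # contact map
    L: float = 100.0
    alpha: float = 1.0
    tau: float = 3.0
    kappa: float = 0.4
    # boundary spacing (log-normal, bp); median = exp(spacing_mu) = 541 kb
    spacing_mu: float = math.log(541_000.0)
    spacing_sigma: float = 0.4
    # compartments: geometric run length, mean bins
    comp_run_mean_bins: float = 20.0
    # genes; compartment A is gene-rich (ratio of per-bin gene density A:B),
    # which is what lets gene density orient the compartment eigenvector
    genes_per_mb: float = 20.0
    gene_length: int = 10_000
    gene_ab_density_ratio: float = 3.0
    # mutations
    p_bg: float = 0.01
    m_hot: int = 12
    n_hotspots: int = 5
    decoy_frac: float = 0.1
    # CNV
    n_cnv_events: int = 50
    pi_near: float = 0.6
    lambda_near: float = 40_000.0
    # SV
    n_svs: int = 200
    sv_class_probs: dict = field(
        default_factory=lambda: {
            "deletion": 0.20,
            "tandem-duplication": 0.15,
            "duplication": 0.10,
            "inversion": 0.15,
            "amplified-inversion": 0.10,
            "foldback-inversion": 0.05,
            "intrachromosomal": 0.15,
            "interchromosomal": 0.05,
            "complex": 0.05,
        }
    )
    sv_len_mu: float = math.log(150_000.0)
    sv_len_sigma: float = 1.0
    sv_place_probs: dict = field(
        default_factory=lambda: {"within": 0.70, "span": 0.12, "other": 0.18}
    )
    boundary_len_bp: int = 75_000
    # expression
    mu_de: float = 1.5
    sigma_expr: float = 0.5
    lfc_cutoff: float = 1.0
    nb_dispersion: float = 0.1
    base_mean_mu: float = math.log(500.0)
    base_mean_sigma: float = 1.0
    # compartment switches (fraction of bins, normal -> primary)
    switch_frac_ab: float = 0.006
    switch_frac_ba: float = 0.009
    # reference-sample boundary perturbation
    p_boundary_drop: float = 0.20
    p_boundary_shift: float = 0.12
    shift_bins: int = 3
    p_boundary_add: float = 0.12
    min_gap_bins: int = 7
    # regulatory features
    feat_bg_per_mb: float = 5.0
    feat_per_boundary: float = 3.0
    feat_sd_bp: float = 25_000.0
    feat_width: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        for name in ("p_bg", "pi_near", "decoy_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        total = sum(self.sv_class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("sv_class_probs must sum to 1")
        if self.m_hot <= 10:
            raise ValueError("m_hot must exceed the CoMut hotspot threshold of 10")


def _rng(params: SimParams, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(params.seed), _STREAMS[stream]])


@dataclass
class GroundTruth:
    """Planted structure plus everything recovery tests need."""

    genome: BinnedGenome
    boundaries: dict[str, np.ndarray]  # primary sample, sorted bin indices
    compartment_labels: dict[str, np.ndarray]  # primary sample, +1/-1 per bin
    genes: pd.DataFrame  # chrom, start, end, name, strand, tss
    hotspot_tads: list[tuple[str, int]]  # (chrom, tad index) into tad_intervals
    params: SimParams
    ref_boundaries: dict[str, np.ndarray] = field(default_factory=dict)
    ref_compartment_labels: dict[str, np.ndarray] = field(default_factory=dict)
    switch_regions: pd.DataFrame | None = None  # chrom, start, end, from, to
    mutated_genes: set[str] = field(default_factory=set)
    cnv_breakpoints: pd.DataFrame | None = None  # chrom, pos, near_boundary

    def tad_intervals(self, sample: str = "primary") -> dict[str, np.ndarray]:
        """Inter-boundary TAD intervals (bp, midpoint convention) per chromosome."""
        bounds = self.boundaries if sample == "primary" else self.ref_boundaries
        out = {}
        for chrom, b in bounds.items():
            mids = (np.asarray(b) + 0.5) * self.genome.bin_size
            out[chrom] = (
                np.column_stack([mids[:-1], mids[1:]]).astype(float)
                if len(mids) >= 2
                else np.empty((0, 2))
            )
        return out

    def domain_id(self, chrom: str) -> np.ndarray:
        """Planted segment index of every bin (segments between boundaries)."""
        n = self.genome.n_bins(chrom)
        return np.searchsorted(self.boundaries[chrom], np.arange(n), side="right")


def simulate_truth(genome: BinnedGenome, params: SimParams) -> GroundTruth:
    """Plant boundaries, compartments, genes, hotspots, and the paired sample."""
    rng = _rng(params, "truth")
    boundaries: dict[str, np.ndarray] = {}
    compartments: dict[str, np.ndarray] = {}
    genes_rows = []
    for chrom in genome.chrom_names:
        size = genome.size(chrom)
        n = genome.n_bins(chrom)
        # boundary positions: cumulative log-normal spacings
        pos = []
        p = float(rng.lognormal(params.spacing_mu, params.spacing_sigma))
        while p < size:
            pos.append(p)
            p += float(rng.lognormal(params.spacing_mu, params.spacing_sigma))
        bins = np.unique(np.clip(np.round(np.array(pos) / genome.bin_size).astype(int), 1, n - 1))
        if len(bins) < 2:
            raise ValueError(f"chromosome {chrom} too short to hold two boundaries")
        boundaries[chrom] = bins
        # compartments: alternating blocks with geometric run lengths
        labels = np.empty(n, dtype=np.int8)
        lab = 1 if rng.random() < 0.5 else -1
        i = 0
        while i < n:
            run = int(rng.geometric(1.0 / params.comp_run_mean_bins))
            labels[i : i + run] = lab
            lab = -lab
            i += run
        compartments[chrom] = labels
        # genes: bin chosen with A-compartment preference, position uniform
        # within the bin; no overlap guarantee
        n_genes = int(round(params.genes_per_mb * size / 1e6))
        w = np.where(labels == 1, params.gene_ab_density_ratio, 1.0)
        gene_bins = rng.choice(n, size=n_genes, p=w / w.sum())
        offsets = rng.integers(0, genome.bin_size, size=n_genes)
        starts = np.sort(
            np.minimum(
                gene_bins * genome.bin_size + offsets,
                max(0, size - params.gene_length),
            )
        )
        for k, s in enumerate(starts):
            genes_rows.append((chrom, int(s), int(s) + params.gene_length, f"g_{chrom}_{k}", "+"))
    genes = pd.DataFrame(genes_rows, columns=["chrom", "start", "end", "name", "strand"])
    genes["tss"] = genes["start"]

    truth = GroundTruth(genome, boundaries, compartments, genes, [], params)

    # hotspot TADs, sampled without replacement across the genome
    all_tads = [
        (chrom, i)
        for chrom, ivals in truth.tad_intervals().items()
        for i in range(len(ivals))
    ]
    k = min(params.n_hotspots, len(all_tads))
    idx = rng.choice(len(all_tads), size=k, replace=False)
    truth.hotspot_tads = [all_tads[i] for i in sorted(idx)]
    _top_up_hotspot_genes(truth, rng)

    _perturb_reference_boundaries(truth, rng)
    _plant_compartment_switches(truth, rng)
    return truth


def _top_up_hotspot_genes(truth: GroundTruth, rng: np.random.Generator) -> None:
    """Guarantee every hotspot TAD holds at least m_hot + 2 genes (midpoint rule)."""
    params = truth.params
    ivals = truth.tad_intervals()
    extra = []
    for chrom, ti in truth.hotspot_tads:
        start, end = ivals[chrom][ti]
        g = truth.genes[truth.genes["chrom"] == chrom]
        mid = (g["start"] + g["end"]) // 2
        have = int(((mid >= start) & (mid < end)).sum())
        need = params.m_hot + 2 - have
        for k in range(max(0, need)):
            lo, hi = int(start), int(end) - params.gene_length
            s = int(rng.integers(lo, max(lo + 1, hi)))
            extra.append(
                (chrom, s, s + params.gene_length, f"g_{chrom}_hot{ti}_{k}", "+", s)
            )
    if extra:
        extra_df = pd.DataFrame(
            extra, columns=["chrom", "start", "end", "name", "strand", "tss"]
        )
        truth.genes = (
            pd.concat([truth.genes, extra_df], ignore_index=True)
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
        )


def _perturb_reference_boundaries(truth: GroundTruth, rng: np.random.Generator) -> None:
    """Build the paired reference sample's boundaries by drop/shift/add."""
    p = truth.params
    for chrom, bins in truth.boundaries.items():
        n_bins = truth.genome.n_bins(chrom)
        kept = []
        for b in bins:
            u = rng.random()
            if u < p.p_boundary_drop:
                continue
            if u < p.p_boundary_drop + p.p_boundary_shift:
                shift = int(rng.integers(2, p.shift_bins + 1)) * (1 if rng.random() < 0.5 else -1)
                kept.append(int(np.clip(b + shift, 1, n_bins - 1)))
            else:
                kept.append(int(b))
        n_add = int(round(p.p_boundary_add * len(bins)))
        existing = np.array(sorted(set(kept) | set(bins.tolist())), dtype=int)
        added = 0
        attempts = 0
        while added < n_add and attempts < 50 * max(1, n_add):
            attempts += 1
            cand = int(rng.integers(1, n_bins - 1))
            if existing.size == 0 or np.abs(existing - cand).min() >= p.min_gap_bins:
                kept.append(cand)
                existing = np.sort(np.append(existing, cand))
                added += 1
        truth.ref_boundaries[chrom] = np.unique(np.array(kept, dtype=int))


def _plant_compartment_switches(truth: GroundTruth, rng: np.random.Generator) -> None:
    """Derive the normal sample's labels by flipping whole runs of the primary.

    Switch direction is reported normal -> primary: an A->B region is A in
    the reference (normal) labels and B in the primary labels.
    """
    p = truth.params
    regions = []
    for chrom, labels in truth.compartment_labels.items():
        ref = labels.copy()
        n = len(labels)
        # maximal runs of the primary labelling
        edges = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [n]])
        order = rng.permutation(len(starts))
        target_ab = p.switch_frac_ab * n  # normal A -> primary B: primary label -1
        target_ba = p.switch_frac_ba * n  # normal B -> primary A: primary label +1
        got_ab = got_ba = 0
        for ri in order:
            s, e = starts[ri], ends[ri]
            run_lab = labels[s]
            run_len = e - s
            if run_lab == -1 and got_ab < target_ab:
                ref[s:e] = 1
                got_ab += run_len
                regions.append((chrom, int(s), int(e), "A", "B"))
            elif run_lab == 1 and got_ba < target_ba:
                ref[s:e] = -1
                got_ba += run_len
                regions.append((chrom, int(s), int(e), "B", "A"))
            if got_ab >= target_ab and got_ba >= target_ba:
                break
        truth.ref_compartment_labels[chrom] = ref
    df = pd.DataFrame(regions, columns=["chrom", "start_bin", "end_bin", "from", "to"])
    bs = truth.genome.bin_size
    df["start"] = df["start_bin"] * bs
    df["end"] = df["end_bin"] * bs
    truth.switch_regions = df.sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_contact_map(
    genome: BinnedGenome,
    truth: GroundTruth,
    params: SimParams,
    sample: str = "primary",
) -> ContactMap:
    """Poisson contact counts with distance decay, TAD blocks, and plaid.

    ``sample`` selects which planted structure the map reflects: ``"primary"``
    uses ``truth.boundaries``/``compartment_labels``, ``"reference"`` the
    perturbed boundary set and normal compartment labels.
    """
    if sample not in ("primary", "reference"):
        raise ValueError("sample must be 'primary' or 'reference'")
    rng = _rng(params, "contacts" if sample == "primary" else "contacts_ref")
    matrices = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        expected = params.L * (1.0 + d) ** (-params.alpha)
        bounds = (
            truth.boundaries[chrom] if sample == "primary" else truth.ref_boundaries[chrom]
        )
        dom = np.searchsorted(bounds, np.arange(n), side="right")
        expected = expected * np.where(np.equal.outer(dom, dom), params.tau, 1.0)
        labels = (
            truth.compartment_labels[chrom]
            if sample == "primary"
            else truth.ref_compartment_labels[chrom]
        )
        e = labels.astype(float)
        expected = expected * np.exp(params.kappa * np.outer(e, e))
        upper = rng.poisson(np.triu(expected))
        m = np.triu(upper) + np.triu(upper, 1).T
        matrices[chrom] = m.astype(float)
    return ContactMap(genome, matrices)


def simulate_mutations(
    truth: GroundTruth, params: SimParams, on_sparse_hotspot: str = "pad"
) -> pd.DataFrame:
    """Plant PASS SNVs: ``m_hot`` genes per hotspot TAD plus background genes.

    Hotspot TADs holding fewer than ``m_hot`` genes are padded with new genes
    (appended to ``truth.genes``) or raise, per ``on_sparse_hotspot``.
    An extra ``decoy_frac`` of non-PASS records exercises filter handling.
    """
    if on_sparse_hotspot not in ("pad", "error"):
        raise ValueError("on_sparse_hotspot must be 'pad' or 'error'")
    if truth.genes.empty:
        raise ValueError("truth has no genes")
    rng = _rng(params, "mutations")
    ivals = truth.tad_intervals()
    planted: list[str] = []
    for chrom, ti in truth.hotspot_tads:
        start, end = ivals[chrom][ti]
        g = truth.genes[truth.genes["chrom"] == chrom]
        mid = (g["start"] + g["end"]) // 2
        inside = g[(mid >= start) & (mid < end)]
        if len(inside) < params.m_hot:
            if on_sparse_hotspot == "error":
                raise ValueError(
                    f"hotspot TAD {chrom}:{ti} holds {len(inside)} < m_hot genes"
                )
            _pad_tad_genes(truth, chrom, ti, params.m_hot - len(inside), rng)
            g = truth.genes[truth.genes["chrom"] == chrom]
            mid = (g["start"] + g["end"]) // 2
            inside = g[(mid >= start) & (mid < end)]
        chosen = inside.iloc[rng.choice(len(inside), size=params.m_hot, replace=False)]
        planted.extend(chosen["name"].tolist())
    hot_set = set(planted)
    others = truth.genes[~truth.genes["name"].isin(hot_set)]
    bg_mask = rng.random(len(others)) < params.p_bg
    planted.extend(others["name"][bg_mask].tolist())

    gene_ix = truth.genes.set_index("name")
    rows = []
    for k, name in enumerate(planted):
        g = gene_ix.loc[name]
        pos = int(rng.integers(g["start"], g["end"])) + 1  # 1-based
        ref, alt = rng.choice(4, size=2, replace=False)
        rows.append(
            (g["chrom"], pos, f"snv{k}", _BASES[ref], _BASES[alt], 60, "PASS", name)
        )
    n_decoys = int(round(params.decoy_frac * len(planted)))
    decoy_filters = np.array(["germline_risk", "LowQual"])
    for k in range(n_decoys):
        g = truth.genes.iloc[int(rng.integers(0, len(truth.genes)))]
        pos = int(rng.integers(g["start"], g["end"])) + 1
        ref, alt = rng.choice(4, size=2, replace=False)
        rows.append(
            (
                g["chrom"],
                pos,
                f"decoy{k}",
                _BASES[ref],
                _BASES[alt],
                20,
                str(rng.choice(decoy_filters)),
                g["name"],
            )
        )
    muts = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "ref", "alt", "qual", "filter", "gene"]
    )
    truth.mutated_genes = set(planted)
    return muts.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _pad_tad_genes(
    truth: GroundTruth, chrom: str, ti: int, n_new: int, rng: np.random.Generator
) -> None:
    start, end = truth.tad_intervals()[chrom][ti]
    rows = []
    for k in range(n_new):
        lo, hi = int(start), max(int(start) + 1, int(end) - truth.params.gene_length)
        s = int(rng.integers(lo, hi))
        rows.append((chrom, s, s + truth.params.gene_length, f"g_{chrom}_pad{ti}_{k}", "+", s))
    truth.genes = (
        pd.concat(
            [truth.genes, pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand", "tss"])],
            ignore_index=True,
        )
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )


def simulate_cnv_segments(truth: GroundTruth, params: SimParams) -> pd.DataFrame:
    """CNV segments whose breakpoints cluster near TAD boundaries.

    Each event contributes two breakpoints; with probability ``pi_near`` a
    breakpoint sits at a boundary midpoint plus a signed exponential offset
    (mean ``lambda_near``), otherwise uniform on the chromosome.  Sorted
    positions are paired into alternating neutral / non-neutral segments, so
    every planted position is a breakpoint of exactly one non-neutral
    segment.  Non-neutral CN status is uniform over {0, 1, 3, 4, 5}.
    """
    if not 0 <= params.pi_near <= 1:
        raise ValueError("pi_near must be in [0, 1]")
    rng = _rng(params, "cnv")
    genome = truth.genome
    sizes = np.array([genome.size(c) for c in genome.chrom_names], dtype=float)
    n_per_chrom = rng.multinomial(params.n_cnv_events, sizes / sizes.sum())
    seg_rows = []
    bp_rows = []
    statuses = np.array([0, 1, 3, 4, 5])
    for chrom, n_events in zip(genome.chrom_names, n_per_chrom):
        if n_events == 0:
            continue
        size = genome.size(chrom)
        mids = (truth.boundaries[chrom] + 0.5) * genome.bin_size
        positions = []
        for _ in range(2 * n_events):
            if rng.random() < params.pi_near and len(mids):
                mid = float(mids[rng.integers(0, len(mids))])
                off = float(rng.exponential(params.lambda_near))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                pos = int(np.clip(round(mid + sign * off), 1, size - 1))
                near = True
            else:
                pos = int(rng.integers(1, size))
                near = False
            positions.append((pos, near))
        positions.sort()
        uniq = []
        for pos, near in positions:
            if not uniq or uniq[-1][0] != pos:
                uniq.append((pos, near))
        if len(uniq) % 2:
            uniq = uniq[:-1]
        cuts = [0] + [p for p, _ in uniq] + [size]
        for i in range(len(cuts) - 1):
            cn = 2 if i % 2 == 0 else int(rng.choice(statuses))
            seg_rows.append((chrom, cuts[i], cuts[i + 1], cn))
        bp_rows.extend((chrom, p, near) for p, near in uniq)
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "cn"])
    truth.cnv_breakpoints = pd.DataFrame(bp_rows, columns=["chrom", "pos", "near_boundary"])
    return segments


def simulate_svs(truth: GroundTruth, params: SimParams, max_retry: int = 100) -> pd.DataFrame:
    """SV calls over the nine-class vocabulary with planted TAD placement.

    Intrachromosomal calls get log-normal lengths and a planted placement
    mode — fully inside one TAD (``within``), fully covering one boundary
    region (``span``), or straddling a boundary without covering its region
    (``other``).  Interchromosomal calls have no length or placement.
    """
    rng = _rng(params, "sv")
    genome = truth.genome
    class_probs = dict(params.sv_class_probs)
    if len(genome.chrom_names) < 2 and class_probs.get("interchromosomal", 0) > 0:
        import warnings

        warnings.warn(
            "single-chromosome genome: interchromosomal SV probability "
            "redistributed over the remaining classes"
        )
        class_probs.pop("interchromosomal")
    classes = list(class_probs)
    probs = np.array([class_probs[c] for c in classes])
    probs = probs / probs.sum()
    place_modes = list(params.sv_place_probs)
    place_p = np.array([params.sv_place_probs[m] for m in place_modes])
    place_p = place_p / place_p.sum()
    sizes = np.array([genome.size(c) for c in genome.chrom_names], dtype=float)
    chrom_p = sizes / sizes.sum()
    tads = truth.tad_intervals()
    hl = params.boundary_len_bp / 2
    rows = []
    for k in range(params.n_svs):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        if cls == "interchromosomal":
            if len(genome.chrom_names) < 2:
                raise ValueError("interchromosomal SV needs >= 2 chromosomes")
            c1, c2 = rng.choice(len(genome.chrom_names), size=2, replace=False)
            chrom1, chrom2 = genome.chrom_names[c1], genome.chrom_names[c2]
            p1 = int(rng.integers(0, genome.size(chrom1)))
            p2 = int(rng.integers(0, genome.size(chrom2)))
            rows.append((chrom1, p1, p1 + 1, chrom2, p2, p2 + 1, f"sv{k}", cls, "NA"))
            continue
        mode = place_modes[int(rng.choice(len(place_modes), p=place_p))]
        placed = None
        for _ in range(max_retry):
            chrom = genome.chrom_names[int(rng.choice(len(genome.chrom_names), p=chrom_p))]
            size = genome.size(chrom)
            length = int(rng.lognormal(params.sv_len_mu, params.sv_len_sigma))
            length = max(length, 1000)
            if length >= size:
                continue
            mids = (truth.boundaries[chrom] + 0.5) * genome.bin_size
            if mode == "within":
                ivals = tads[chrom]
                ok = np.flatnonzero((ivals[:, 1] - ivals[:, 0]) > length + 2)
                if not len(ok):
                    continue
                t = ivals[int(rng.choice(ok))]
                s = int(rng.integers(int(t[0]) + 1, int(t[1]) - length))
                placed = (chrom, s, s + length)
            elif mode == "span":
                if length <= 2 * hl:
                    continue
                mid = float(mids[rng.integers(0, len(mids))])
                r_start, r_end = mid - hl, mid + hl
                lo = int(max(0, r_end - length))
                hi = int(min(r_start, size - length))
                if lo > hi:
                    continue
                s = int(rng.integers(lo, hi + 1))
                placed = (chrom, s, s + length)
            else:  # other: straddle a boundary, region only partially covered
                if length <= hl:
                    continue
                mid = float(mids[rng.integers(0, len(mids))])
                lo = int(mid - hl) + 1
                hi = int(mid) - 1
                if lo > hi:
                    continue
                s = int(rng.integers(lo, hi + 1))
                if s + length >= size:
                    continue
                placed = (chrom, s, s + length)
            if placed is not None:
                break
        if placed is None:
            raise RuntimeError(f"could not place SV of mode {mode} after {max_retry} tries")
        chrom, s, e = placed
        rows.append((chrom, s, s + 1, chrom, e, e + 1, f"sv{k}", cls, mode))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom1",
            "start1",
            "end1",
            "chrom2",
            "start2",
            "end2",
            "name",
            "sv_class",
            "placement_truth",
        ],
    )


def simulate_expression(
    truth: GroundTruth, switch_regions: pd.DataFrame, params: SimParams
) -> pd.DataFrame:
    """Per-gene log2 fold changes coupled to compartment switches.

    Baseline ``log2FC ~ Normal(0, sigma_expr)``; genes whose TSS falls in an
    A->B region are shifted by ``-mu_de``, in B->A by ``+mu_de``.  Negative-
    binomial counts for the two conditions are drawn consistently with the
    fold change.  Status labels use a symmetric ``lfc_cutoff``.
    """
    rng = _rng(params, "expression")
    genes = truth.genes
    shift = np.zeros(len(genes))
    in_switch = np.array(["none"] * len(genes), dtype=object)
    if switch_regions is not None and len(switch_regions):
        for _, r in switch_regions.iterrows():
            hit = (
                (genes["chrom"] == r["chrom"])
                & (genes["tss"] >= r["start"])
                & (genes["tss"] < r["end"])
            ).to_numpy()
            tag = f"{r['from']}->{r['to']}"
            shift[hit] += -params.mu_de if r["to"] == "B" else params.mu_de
            in_switch[hit] = tag
    lfc = rng.normal(0.0, params.sigma_expr, size=len(genes)) + shift
    base = rng.lognormal(params.base_mean_mu, params.base_mean_sigma, size=len(genes))
    disp = params.nb_dispersion

    def _nb(mean: np.ndarray) -> np.ndarray:
        r = 1.0 / disp
        p = r / (r + mean)
        return rng.negative_binomial(r, p)

    count_ref = _nb(base)
    count_alt = _nb(base * np.power(2.0, lfc))
    status = np.where(
        lfc >= params.lfc_cutoff, "up", np.where(lfc <= -params.lfc_cutoff, "down", "ns")
    )
    return pd.DataFrame(
        {
            "gene": genes["name"],
            "chrom": genes["chrom"],
            "tss": genes["tss"],
            "base_mean": base,
            "count_ref": count_ref,
            "count_alt": count_alt,
            "log2fc": lfc,
            "status": status,
            "switch": in_switch,
        }
    )


def simulate_features(truth: GroundTruth, params: SimParams) -> pd.DataFrame:
    """Regulatory-mark intervals: uniform background plus boundary-attracted sites."""
    rng = _rng(params, "features")
    rows = []
    w = params.feat_width
    for chrom in truth.genome.chrom_names:
        size = truth.genome.size(chrom)
        n_bg = int(round(params.feat_bg_per_mb * size / 1e6))
        for s in rng.integers(0, max(1, size - w), size=n_bg):
            rows.append((chrom, int(s), int(s) + w))
        mids = (truth.boundaries[chrom] + 0.5) * truth.genome.bin_size
        for mid in mids:
            for _ in range(int(rng.poisson(params.feat_per_boundary))):
                s = int(np.clip(round(mid + rng.normal(0, params.feat_sd_bp)), 0, size - w))
                rows.append((chrom, s, s + w))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"feat{i}" for i in range(len(df))]
    df["score"] = 1.0
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ------------------------------------------------------------- serialization


def truth_to_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "genome": {
            "chrom_names": list(truth.genome.chrom_names),
            "chrom_sizes": list(truth.genome.chrom_sizes),
            "bin_size": truth.genome.bin_size,
        },
        "boundaries": {c: b.tolist() for c, b in truth.boundaries.items()},
        "compartment_labels": {c: v.tolist() for c, v in truth.compartment_labels.items()},
        "ref_boundaries": {c: b.tolist() for c, b in truth.ref_boundaries.items()},
        "ref_compartment_labels": {
            c: v.tolist() for c, v in truth.ref_compartment_labels.items()
        },
        "genes": truth.genes.to_dict(orient="list"),
        "hotspot_tads": [list(t) for t in truth.hotspot_tads],
        "mutated_genes": sorted(truth.mutated_genes),
        "switch_regions": (
            truth.switch_regions.to_dict(orient="list")
            if truth.switch_regions is not None
            else None
        ),
        "cnv_breakpoints": (
            truth.cnv_breakpoints.to_dict(orient="list")
            if truth.cnv_breakpoints is not None
            else None
        ),
        "params": asdict(truth.params),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def truth_from_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    g = payload["genome"]
    genome = BinnedGenome(tuple(g["chrom_names"]), tuple(g["chrom_sizes"]), g["bin_size"])
    truth = GroundTruth(
        genome,
        {c: np.array(b, dtype=int) for c, b in payload["boundaries"].items()},
        {c: np.array(v, dtype=np.int8) for c, v in payload["compartment_labels"].items()},
        pd.DataFrame(payload["genes"]),
        [tuple(t) for t in payload["hotspot_tads"]],
        SimParams(**payload["params"]),
        ref_boundaries={c: np.array(b, dtype=int) for c, b in payload["ref_boundaries"].items()},
        ref_compartment_labels={
            c: np.array(v, dtype=np.int8) for c, v in payload["ref_compartment_labels"].items()
        },
        mutated_genes=set(payload["mutated_genes"]),
    )
    if payload["switch_regions"] is not None:
        truth.switch_regions = pd.DataFrame(payload["switch_regions"])
    if payload["cnv_breakpoints"] is not None:
        truth.cnv_breakpoints = pd.DataFrame(payload["cnv_breakpoints"])
    return truth
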