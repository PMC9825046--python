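"""End-to-end driver: simulate → balance → TADs → CoMut → CNV/SV → compartments → profiles.

A :class:`PipelineConfig` either names input files for each stage or carries
a ``simulate`` block, in which case the whole pipeline runs self-contained
on synthetic data.  Every analysis parameter is serialized into the run
report, and a fixed seed makes the summary byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .genome import BinnedGenome
from .hic import kr_balance, mask_low_coverage_bins, observed_over_expected, correlation_matrix
from .simulate import (
    GroundTruth,
    SimParams,
    simulate_cnv_segments,
    simulate_contact_map,
    simulate_expression,
    simulate_features,
    simulate_mutations,
    simulate_svs,
    simulate_truth,
    truth_to_json,
)
from .tads import (
    boundaries_to_tads,
    boundary_overlap_pvalue,
    call_boundaries,
    change_records_to_frame,
    classify_tad_changes,
    insulation_track,
    match_boundaries,
    short_long_ratio,
)
from .comut import (
    assign_mutations_to_genes,
    chromosome_hotspot_counts,
    comut_per_tad,
    comut_records_to_frame,
    ks_compare,
    pair_contact_frequencies,
    sample_background,
)
from .cnvsv import (
    breakpoint_boundary_distances,
    classify_svs,
    extract_breakpoints,
    proximity_fraction,
    randomized_null_distances,
    sv_counts_by_placement,
)
from .compartments import (
    compartment_track,
    count_compartments,
    detect_switches,
    gene_density_covariate,
    switch_expression_fractions,
    switch_regions_to_frame,
)
from .profiles import mark_distance_density, profile_by_change_mode

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class AnalysisParams:
    """Fixed analysis constants; defaults are the pipeline-wide conventions."""

    bin_size: int = 50_000
    low_coverage_quantile: float = 0.02
    kr_tol: float = 1e-6
    kr_max_iter: int = 300
    insulation_window_bins: int = 10
    delta_bins: int = 2
    strength_min: float = 0.1
    tol_bins: int = 2
    shift_max_bins: int = 6
    hotspot_threshold: int = 10
    proximity_bp: int = 120_000
    boundary_len_bp: int = 75_000
    range_cutoff_bp: int = 2_000_000
    n_boot: int = 1000
    n_rand: int = 10
    n_per_obs: int = 10
    distance_tol: float = 0.10
    profile_window_bp: int = 500_000

    def __post_init__(self) -> None:
        for name in (
            "bin_size",
            "insulation_window_bins",
            "delta_bins",
            "tol_bins",
            "shift_max_bins",
            "hotspot_threshold",
            "proximity_bp",
            "boundary_len_bp",
            "range_cutoff_bp",
            "n_boot",
            "n_rand",
            "n_per_obs",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class PipelineConfig:
    out_dir: str = "tadmut_out"
    seed: int = 0
    simulate: dict | None = None  # SimParams overrides + chrom_names/chrom_sizes
    inputs: dict = field(default_factory=dict)  # paths keyed by input name
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        params = AnalysisParams(**raw.get("params", {}))
        return cls(
            out_dir=raw.get("out_dir", "tadmut_out"),
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs", {}),
            params=params,
        )


def _default_genome(bin_size: int) -> BinnedGenome:
    return BinnedGenome(("chr1", "chr2"), (60_000_000, 60_000_000), bin_size)


def _simulate_inputs(config: PipelineConfig, out: Path) -> dict:
    block = dict(config.simulate or {})
    chrom_names = tuple(block.pop("chrom_names", ())) or None
    chrom_sizes = tuple(block.pop("chrom_sizes", ())) or None
    if chrom_names and chrom_sizes:
        genome = BinnedGenome(chrom_names, chrom_sizes, config.params.bin_size)
    else:
        genome = _default_genome(config.params.bin_size)
    block.setdefault("seed", config.seed)
    sim = SimParams(**block)
    truth = simulate_truth(genome, sim)
    data = {
        "genome": genome,
        "truth": truth,
        "map_primary": simulate_contact_map(genome, truth, sim, "primary"),
        "map_reference": simulate_contact_map(genome, truth, sim, "reference"),
        "mutations": simulate_mutations(truth, sim),
        "genes": truth.genes,
        "cnv": simulate_cnv_segments(truth, sim),
        "svs": simulate_svs(truth, sim),
        "features": simulate_features(truth, sim),
    }
    data["expression"] = simulate_expression(truth, truth.switch_regions, sim)
    truth_to_json(truth, out / "truth.json")
    tio.write_chrom_sizes(genome, out / "chrom.sizes")
    tio.write_contact_map(data["map_primary"], out / "contacts_primary.coo.tsv")
    tio.write_contact_map(data["map_reference"], out / "contacts_reference.coo.tsv")
    tio.write_bed(truth.genes, out / "genes.bed")
    tio.write_vcf(data["mutations"], out / "mutations.vcf")
    tio.write_seg(data["cnv"], out / "cnv.seg.tsv")
    tio.write_bedpe(data["svs"], out / "svs.bedpe")
    tio.write_expression(data["expression"], out / "expression.tsv")
    tio.write_bed(data["features"], out / "features.bed")
    return data


def _load_inputs(config: PipelineConfig) -> dict:
    inputs = config.inputs
    need = ("chrom_sizes", "contacts_primary", "genes")
    for key in need:
        if key not in inputs:
            raise ConfigError(f"missing required input '{key}' (or provide a simulate block)")
    genome = tio.read_chrom_sizes(inputs["chrom_sizes"], config.params.bin_size)
    data = {
        "genome": genome,
        "truth": None,
        "map_primary": tio.read_contact_map(inputs["contacts_primary"], genome),
        "genes": tio.read_bed(inputs["genes"]).rename(columns={"name": "name"}),
    }
    data["genes"]["tss"] = data["genes"]["start"]
    if "contacts_reference" in inputs:
        data["map_reference"] = tio.read_contact_map(inputs["contacts_reference"], genome)
    if "mutations" in inputs:
        data["mutations"] = tio.read_vcf(inputs["mutations"])
    if "cnv" in inputs:
        data["cnv"] = tio.read_seg(inputs["cnv"])
    if "svs" in inputs:
        data["svs"] = tio.read_bedpe(inputs["svs"])
    if "expression" in inputs:
        data["expression"] = tio.read_expression(inputs["expression"])
    if "features" in inputs:
        data["features"] = tio.read_bed(inputs["features"])
    return data


def _process_map(cmap, p: AnalysisParams):
    masked = mask_low_coverage_bins(cmap, p.low_coverage_quantile)
    balanced, report = kr_balance(masked, p.kr_tol, p.kr_max_iter)
    return balanced, report


def run_all(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are present and write a joint report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    if config.simulate is not None:
        data = _simulate_inputs(config, out)
    else:
        data = _load_inputs(config)
    genome = data["genome"]
    summary: dict = {
        "seed": config.seed,
        "parameters": asdict(p),
        "simulated": config.simulate is not None,
    }

    # --- Hi-C core, boundaries, TADs -------------------------------------
    bal_primary, rep_primary = _process_map(data["map_primary"], p)
    track_primary = insulation_track(bal_primary, p.insulation_window_bins)
    bset_primary = call_boundaries(track_primary, p.delta_bins, p.strength_min, "primary")
    tads_primary = boundaries_to_tads(bset_primary)
    summary["balance"] = {
        "max_rowsum_deviation": rep_primary.max_rowsum_deviation,
        "converged": rep_primary.converged,
    }
    summary["boundaries"] = {"primary": bset_primary.n_boundaries()}
    summary["n_tads"] = {"primary": tads_primary.n_tads()}
    summary["short_long_ratio"] = (
        short_long_ratio(tads_primary, p.range_cutoff_bp) if tads_primary.n_tads() else None
    )
    bset_primary.to_bed().pipe(tio.write_bed, out / "boundaries_primary.bed")
    tads_primary.to_bed().pipe(tio.write_bed, out / "tads_primary.bed")

    have_ref = "map_reference" in data
    if have_ref:
        bal_ref, _ = _process_map(data["map_reference"], p)
        track_ref = insulation_track(bal_ref, p.insulation_window_bins)
        bset_ref = call_boundaries(track_ref, p.delta_bins, p.strength_min, "reference")
        summary["boundaries"]["reference"] = bset_ref.n_boundaries()
        common, spacing_stats = match_boundaries([bset_primary, bset_ref], p.tol_bins)
        observed, pval = boundary_overlap_pvalue(
            bset_primary, bset_ref, p.tol_bins, p.n_boot, config.seed
        )
        summary["common_boundaries"] = {**spacing_stats, "overlap": observed, "p": pval}
        records, fractions = classify_tad_changes(
            bset_primary, bset_ref, p.tol_bins, p.shift_max_bins
        )
        summary["tad_change_fractions"] = fractions
        change_records_to_frame(records).to_csv(out / "tad_changes.tsv", sep="\t", index=False)
        bset_ref.to_bed().pipe(tio.write_bed, out / "boundaries_reference.bed")
    else:
        records = []

    # --- CoMut ------------------------------------------------------------
    if "mutations" in data:
        mutated = assign_mutations_to_genes(data["mutations"], data["genes"])
        comut_records = comut_per_tad(mutated, data["genes"], tads_primary, p.hotspot_threshold)
        comut_df = comut_records_to_frame(comut_records)
        comut_df.to_csv(out / "comut_per_tad.tsv", sep="\t", index=False)
        hotspots = comut_df[comut_df["hotspot"]]
        summary["comut"] = {
            "n_mutated_genes": len(mutated),
            "n_hotspot_tads": int(len(hotspots)),
            "hotspots": hotspots[["chrom", "start", "end", "comut"]].to_dict("records"),
        }
        chromosome_hotspot_counts(comut_records).to_csv(
            out / "hotspot_counts_by_chrom.tsv", sep="\t", index=False
        )
        pairs = pair_contact_frequencies(mutated, data["genes"], bal_primary)
        if len(pairs):
            bg_overall = sample_background(
                data["genes"], bal_primary, pairs, "overall", p.n_per_obs, p.distance_tol,
                config.seed,
            )
            bg_gene = sample_background(
                data["genes"], bal_primary, pairs, "gene_level", p.n_per_obs, p.distance_tol,
                config.seed + 1,
            )
            pd.concat([pairs, bg_overall, bg_gene]).to_csv(
                out / "pair_frequencies.tsv", sep="\t", index=False
            )
            d_o, p_o = ks_compare(pairs["frequency"], bg_overall["frequency"])
            d_g, p_g = ks_compare(pairs["frequency"], bg_gene["frequency"])
            summary["comut"]["ks_vs_overall"] = {"D": d_o, "p": p_o}
            summary["comut"]["ks_vs_gene_level"] = {"D": d_g, "p": p_g}

    # --- CNV --------------------------------------------------------------
    if "cnv" in data:
        bps = extract_breakpoints(data["cnv"])
        dists = breakpoint_boundary_distances(bps, bset_primary)
        null = randomized_null_distances(bps, bset_primary, genome, p.n_rand, config.seed)
        if dists.size and null.size:
            count, frac = proximity_fraction(dists, p.proximity_bp)
            d_ks, p_ks = ks_compare(dists, null)
            summary["cnv"] = {
                "n_breakpoints": int(len(bps)),
                "within_proximity": count,
                "proximity_fraction": frac,
                "ks_vs_random": {"D": d_ks, "p": p_ks},
            }
            pd.DataFrame({"distance": dists}).to_csv(
                out / "cnv_boundary_distances.tsv", sep="\t", index=False
            )

    # --- SV ---------------------------------------------------------------
    if "svs" in data:
        classified = classify_svs(
            data["svs"], tads_primary, bset_primary, p.boundary_len_bp, p.range_cutoff_bp
        )
        classified.to_csv(out / "svs_classified.tsv", sep="\t", index=False)
        counts = sv_counts_by_placement(classified)
        counts.to_csv(out / "sv_counts.tsv", sep="\t", index=False)
        placements = classified["placement"].value_counts().to_dict()
        summary["sv"] = {
            "n_svs": int(len(classified)),
            "n_within": int(placements.get("within", 0)),
            "n_span": int(placements.get("span", 0)),
            "n_other": int(placements.get("other", 0)),
        }

    # --- compartments and expression --------------------------------------
    oe_primary = observed_over_expected(bal_primary)
    corr_primary = {
        c: correlation_matrix(oe_primary[c], bal_primary.mask[c]) for c in genome.chrom_names
    }
    covariate = gene_density_covariate(data["genes"], genome)
    comp_primary = compartment_track(corr_primary, covariate, genome, "primary")
    summary["compartments"] = {"primary": count_compartments(comp_primary)}
    if have_ref:
        oe_ref = observed_over_expected(bal_ref)
        corr_ref = {
            c: correlation_matrix(oe_ref[c], bal_ref.mask[c]) for c in genome.chrom_names
        }
        comp_ref = compartment_track(corr_ref, covariate, genome, "reference")
        summary["compartments"]["reference"] = count_compartments(comp_ref)
        regions, fractions = detect_switches(comp_ref, comp_primary)
        switch_regions_to_frame(regions).to_csv(out / "switches.tsv", sep="\t", index=False)
        summary["switches"] = fractions
        if "expression" in data and len(regions):
            try:
                summary["switch_expression"] = switch_expression_fractions(
                    regions, data["expression"], data["genes"], genome
                )
            except ValueError as exc:
                log.warning("switch-expression stage skipped: %s", exc)

    # --- regulatory profiles ----------------------------------------------
    if "features" in data:
        d, edges, density = mark_distance_density(
            data["features"], bset_primary, p.profile_window_bp
        )
        pd.DataFrame({"edge_left": edges[:-1], "edge_right": edges[1:], "density": density}).to_csv(
            out / "feature_density.tsv", sep="\t", index=False
        )
        summary["profiles"] = {
            "n_features_in_window": int(d.size),
            "median_abs_distance": float(np.median(np.abs(d))) if d.size else None,
        }
        if records:
            mode_profiles = profile_by_change_mode(
                data["features"], records, genome, p.profile_window_bp
            )
            summary["profiles"]["mode_comparisons"] = {
                k: {kk: vv for kk, vv in v.items()}
                for k, v in mode_profiles["comparisons"].items()
            }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    log.info("pipeline finished; summary at %s", out / "summary.json")
    return summary
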