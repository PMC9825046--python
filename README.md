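# tadmut

Tools for asking how somatic variation in cancer genomes lines up with 3D
chromatin structure. Given binned intrachromosomal Hi-C contact matrices
alongside somatic SNVs, copy-number segments, structural variants, and a
differential-expression table, `tadmut` answers, per sample and between
samples:

- where TAD boundaries are, how strongly two samples share them, and how
  boundaries change between samples (de novo / loss / shifted / gain);
- whether co-mutated genes are spatially closer than chance ("CoMut"
  hotspot TADs, contact frequencies of co-mutated gene pairs against
  distance-matched backgrounds);
- whether CNV breakpoints cluster near TAD boundaries relative to a
  location-randomized null;
- how SVs place relative to domains (entirely within a TAD vs spanning a
  boundary region, short vs long range);
- which genomic regions switch A/B compartment between samples and how
  those switches couple to expression changes.

Because raw sequencing data of this kind is rarely shareable, the package
ships a first-class synthetic-data generator that plants all of this
structure with known ground truth, so every statistic can be validated by
parameter recovery.

## The model in brief

**Contact maps.** Counts on 50-kb bins follow
`E[i,j] = L (1+|i−j|)^−α · τ^[same TAD] · exp(κ e_i e_j)` with independent
Poisson draws on the upper triangle: power-law distance decay, a
within-domain enrichment factor τ, and a compartment plaid of strength κ
driven by per-bin labels `e ∈ {+1,−1}`. Matrices are balanced by
Knight–Ruiz symmetric scaling (`diag(w) M diag(w)` with unit row sums over
unmasked bins).

**Boundaries.** The insulation value of bin *i* is the mean balanced
contact between the *w* bins left and the *w* bins right of *i*
(default *w* = 10, i.e. 500 kb; capped at 2 Mb of flank). Boundaries sit
at local minima of the log2-normalized track, found where the left–right
delta crosses zero from + to −, filtered by a minimum strength. TADs are
the intervals between consecutive boundary midpoints.

**Compartments.** Per chromosome, the leading eigenvector of the Pearson
correlation matrix of the observed/expected map, sign-oriented against a
gene-density covariate: positive = A (open, gene-rich), negative = B.

**Statistics.** Two-sample Kolmogorov–Smirnov tests compare observed vs
background distributions throughout: co-mutated pair contact frequencies
vs distance-matched gene-level and overall backgrounds, CNV
breakpoint–boundary distances vs uniformly re-drawn breakpoints, and
regulatory-mark distance profiles between boundary classes. Boundary-set
overlap uses an add-one bootstrap p-value with per-chromosome counts
preserved.

## Worked example

```python
import numpy as np
from tadmut import BinnedGenome, SimParams, simulate_truth, simulate_contact_map
from tadmut.hic import mask_low_coverage_bins, kr_balance
from tadmut.tads import insulation_track, call_boundaries, boundaries_to_tads
from tadmut.simulate import simulate_mutations
from tadmut.comut import assign_mutations_to_genes, comut_per_tad

genome = BinnedGenome(("chr1", "chr2"), (20_000_000, 20_000_000), bin_size=50_000)
params = SimParams(seed=42)
truth = simulate_truth(genome, params)
cmap = simulate_contact_map(genome, truth, params)
balanced, report = kr_balance(mask_low_coverage_bins(cmap))
print(f"balanced in {report.iterations} outer iterations, "
      f"max row-sum deviation {report.max_rowsum_deviation:.2e}")

track = insulation_track(balanced, window_bins=10)
bset = call_boundaries(track, delta_bins=2, strength_min=0.1)
print(f"called {bset.n_boundaries()} boundaries "
      f"({sum(len(b) for b in truth.boundaries.values())} planted)")

tads = boundaries_to_tads(bset)
print(f"{tads.n_tads()} TADs, median length {np.median(tads.lengths())/1e3:.0f} kb")

muts = simulate_mutations(truth, params)
mutated = assign_mutations_to_genes(muts, truth.genes)
hot = [r for r in comut_per_tad(mutated, truth.genes, tads) if r.hotspot]
print(f"{len(mutated)} mutated genes; {len(hot)} CoMut hotspot TADs "
      f"(CoMut > 10): {[(r.chrom, r.comut) for r in hot]}")
```

prints

```
balanced in 3 outer iterations, max row-sum deviation 3.37e-07
called 66 boundaries (70 planted)
64 TADs, median length 500 kb
72 mutated genes; 4 CoMut hotspot TADs (CoMut > 10): [('chr1', 12), ('chr1', 14), ('chr1', 14), ('chr2', 13)]
```

Balancing reached unit row sums to 3×10⁻⁷; the insulation caller recovered
66 of the 70 planted boundaries; the resulting domains have the ~500-kb
median length the generator plants; and the four domains seeded with ≥12
mutated genes — and no others — exceed the strict CoMut > 10 hotspot
threshold.

The same analyses are available from the shell: `tadmut simulate`,
`tadmut balance`, `tadmut insulation`, `tadmut boundaries`,
`tadmut compare-boundaries`, `tadmut tad-changes`, `tadmut comut`,
`tadmut cnv-dist`, `tadmut sv-classify`, `tadmut compartments`,
`tadmut profiles`, and `tadmut run --config cfg.yaml` for the full
pipeline (see `tadmut --help`).

## Layout

```
src/tadmut/
  genome.py        fixed-width binned coordinate system
  simulate.py      synthetic data generators with planted ground truth
  hic.py           ContactMap, masking, KR balancing, O/E, correlation
  tads.py          insulation, boundary calling, matching, change modes
  comut.py         PASS-SNV aggregation, CoMut hotspots, pair frequencies, KS
  cnvsv.py         CNV breakpoint statistics, SV classification
  compartments.py  A/B calling, switches, expression integration
  profiles.py      regulatory-mark density around boundaries
  pipeline.py      config-driven end-to-end driver
  cli.py           the `tadmut` command
  io.py            COO/BED/VCF/SEG/BEDPE/TSV readers and writers
```

`docs/methods.md` documents the models, parameter choices, and known
limitations.
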