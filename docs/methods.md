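# Methods

This note records the models behind `tadmut`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions that matter when reading its output.

## Coordinate conventions

All analyses live on a fixed-width binning (default 50 kb). Bin *i* covers
the 0-based half-open interval `[i·b, (i+1)·b)`. A boundary's genomic
coordinate is its **bin midpoint** `(i + 0.5)·b`; TADs are half-open
intervals between consecutive boundary midpoints, so they tile the span
between the first and last boundary of a chromosome. SNV positions are
1-based (VCF convention) and are converted explicitly when intersected
with half-open gene intervals: position *p* hits `[start, end)` iff
`start ≤ p − 1 < end`.

## Contact-map model and balancing

The generator draws Poisson counts with expectation

    E[i,j] = L · (1+|i−j|)^(−α) · τ^[same planted TAD] · exp(κ·e_i·e_j)

on the upper triangle, mirrored. Defaults: `L = 100` (expected diagonal
count), `α = 1` (canonical contact-decay exponent at the sub-10-Mb scale),
`τ = 3` (within-TAD enrichment), `κ = 0.4` (plaid strength giving
compartment contrast comparable to mammalian O/E maps). Poisson rather
than negative-binomial noise is the simplest model consistent with every
analysis the package performs; overdispersion would only widen confidence
bands and can be layered on by scaling `L` per draw if needed.

Only intrachromosomal matrices are modeled and analyzed; interchromosomal
Hi-C signal is too sparse at these depths to support the statistics
computed here, and every downstream test (pair frequencies, insulation,
compartments) is defined per chromosome.

Balancing is Knight–Ruiz symmetric diagonal scaling: find `x > 0` with
`diag(x) M diag(x) 1 = 1` on the unmasked submatrix, via the inner–outer
Newton/conjugate-gradient iteration with box safeguards (step clipping at
0.1 and 3.0). The input is pre-scaled by its mean marginal for
conditioning; the returned weights absorb the rescaling, which also makes
the balanced matrix exactly invariant to multiplying the counts by any
constant. Convergence is declared when the 2-norm of the row-sum residual
is below `tol` (default 1e−6, so the max row-sum deviation is ≤ 1e−6);
`max_iter = 300` outer iterations; non-convergence raises or warns per
configuration. Bins with zero marginal are always masked before
balancing; additionally bins whose marginal falls below the 0.02 quantile
of nonzero marginals are dropped — the exact low-coverage cutoff is a free
parameter because no universal value exists.

Observed/expected divides each entry by the mean unmasked entry at the
same separation; a distance whose entries are all zero stays NaN rather
than dividing by zero. The compartment correlation matrix treats those
NaN bands as zero signal; constant rows yield NaN correlations and a NaN
diagonal (they carry no sign information).

## Boundaries and TADs

Insulation value of bin *i*: mean balanced contact over the `w × w` block
linking the `w` bins left of *i* to the `w` bins right (default `w` = 10
bins = 500 kb; windows are capped at 2 Mb of flank). The track is only
defined where the full window fits; the normalized track is
`log2(raw / chromosome mean)` and a per-chromosome z-score is also
emitted (the minima detector consumes the normalized track; the z-score
is informational).

Boundary calling follows the delta-vector convention of insulation
callers: `delta[i]` = mean normalized insulation over the `d` bins left
minus the `d` bins right (default `d` = 2). A boundary is a + → − zero
crossing whose swing (max delta over the positive run before, minus min
delta over the non-positive run after) reaches `strength_min` (default
0.1); of the two bins at the crossing the one with lower insulation wins,
and adjacent qualifying bins merge to the minimum. These defaults recover
planted boundaries with F1 ≈ 0.9–0.95 at ±1 bin on the generator's maps
(τ = 3) while calling essentially nothing on structureless matrices.

Cross-sample operations use bin tolerances: two boundaries match within
`tol_bins` = 2 (100 kb at the default binning — the "within two bins"
convention for common boundaries; set 1 to halve it). The bootstrap
overlap test redraws the second set's per-chromosome boundary counts
uniformly over eligible bins (without replacement) and reports the
add-one Monte-Carlo p-value `(1 + #{null ≥ obs}) / (n_boot + 1)`, which is
never smaller than `1/(n_boot+1)` and exactly matches enumeration on toy
genomes up to Monte-Carlo error.

Change modes between a query and a reference sample: **conserved**
(offset ≤ tol), **shifted** (tol < offset ≤ `shift_max_bins`, default 6),
**de novo** (query boundary with no reference boundary within shift_max),
**loss** (reference boundary with no query boundary within shift_max).
A de-novo boundary whose two query neighbors are both conserved subdivides
a reference TAD and is recorded as a **gain** — the distinction between
"gain" and plain "de novo" is not standardized anywhere, and this
definition was chosen because it is the unique local criterion that makes
a gain exactly "one reference TAD split in two". Fractions are reported
over non-conserved records and sum to 1 across the four change modes.

The short/long TAD ratio uses the same 2-Mb cutoff as the SV range split,
for comparability between the two summaries; with the generator's 541-kb
median spacing, most runs have no long TADs and the ratio is flagged
infinite rather than silently dropped.

## CoMut statistics

A gene is mutated iff at least one PASS-filtered SNV overlaps it; all
other filter values are ignored. CoMut of a TAD counts mutated genes by
the gene-midpoint rule, and hotspot status is the strict inequality
CoMut > 10. Pair contact frequency is the balanced matrix entry at the
two genes' TSS bins; pairs on different chromosomes are excluded, pairs
sharing a bin read the diagonal and carry a flag.

Backgrounds are **distance-matched by sampling**: for each observed pair,
`n_per_obs` = 10 background units on the same chromosome within ±10%
relative distance — pairs of annotated genes (gene-level) or pairs of
unmasked bins (overall). Matching removes the distance-decay confound
that would otherwise dominate any comparison of contact values; when no
candidate exists at ±10% the tolerance doubles (logged) up to six times.
Comparisons use the two-sided two-sample KS test (`scipy.stats.ks_2samp`),
which the suite checks against an exhaustive ECDF-scan oracle to 1e−12.

## CNV and SV

Breakpoints are the endpoints of non-neutral (CN ≠ 2) segments,
deduplicated per coordinate; neutral segments contribute nothing because
only gain and loss events have physical breaks. Distances are measured to
the nearest boundary midpoint; the proximity summary counts distances
≤ 120 kb inclusive. The null redraws per-chromosome breakpoint counts
uniformly and pools `n_rand` = 10 replicates; observed vs pooled null
goes through the same KS test. On synthetic data this test is calibrated
(type-I error ≈ 5% at α = 0.05 over 200 runs when breakpoints are truly
uniform) and has power ≥ 0.8 at 100 breakpoints when 60% of them sit an
exponential 40-kb offset from boundaries.

SVs carry a nine-class vocabulary (deletion, tandem-duplication,
duplication, inversion, amplified-inversion, foldback-inversion,
intrachromosomal, interchromosomal, complex); the vocabulary is
configuration, not logic — "amplified-inversion" is treated purely as a
label with no copy-number co-condition. An intrachromosomal SV's interval
runs between its break-end starts regardless of order. Range splits at
2 Mb (≥ 2 Mb is long). Placement: **span** when the interval fully covers
at least one boundary region (midpoint ± 37.5 kb, i.e. a 75-kb boundary
span), else **within** when it lies inside one TAD, else **other**.
Because boundary regions straddle TAD edges, a planted within-TAD SV can
never cover one and a planted spanning SV always does, so generator truth
is recovered exactly for those two modes.

## Compartments and expression

Per chromosome, the leading eigenvector of the O/E correlation matrix
over unmasked bins, oriented so its Pearson correlation with a covariate
is non-negative; gene density is the default covariate, and the generator
plants an A:B gene-density ratio of 3:1 precisely so that orientation is
identifiable (compartment A is gene-rich in real genomes; with uniform
genes the eigenvector sign would be arbitrary). Positive entries are A,
negative B; exact zeros go to B with a logged count — an arbitrary but
deterministic tie-break. Compartment "counts" are reported both as bins
and as maximal same-label runs, since either convention appears in the
literature.

Switches between two samples are maximal runs of jointly labeled bins
whose labels differ, with fractions over jointly labeled bins per
direction. Differential-expression calling itself is out of scope: the
pipeline consumes a table with `up`/`down`/`ns` status labels (the
generator produces one with known truth, coupling switch-region genes to
a ±`mu_de` log2FC shift and drawing negative-binomial counts consistent
with the fold change).

## Regulatory profiles

Features reduce to interval midpoints; each midpoint within ±500 kb of
its nearest boundary contributes a signed distance (negative upstream),
histogrammed over 50 bins and normalized to integrate to 1. Scores are
ignored by default — the profile is a density of sites, not of signal;
signal weighting is a flag away but changes the interpretation. Mode
profiles pool gain boundaries with de novo and compare the three
canonical mode pairs (de novo vs shifted, de novo vs loss, loss vs
shifted) by KS on absolute distances, reporting which side is more
boundary-enriched via median absolute distance.

## What the generator emulates — and what it does not

Planted structure: log-normal boundary spacing with median 541 kb
(σ = 0.4, spanning roughly 250 kb–1.2 Mb); geometric compartment runs of
mean 20 bins (1 Mb); genes at 20 per Mb, 10 kb long, TSS at the start,
A-biased 3:1; hotspot TADs seeded with `m_hot` = 12 mutated genes each
(topped up with extra genes when a TAD is gene-poor, so the CoMut > 10
criterion is satisfiable by construction); background mutation
probability 0.01 per gene plus a 10% non-PASS decoy fraction; CNV events
whose breakpoints sit near boundaries with probability `pi_near` = 0.6 at
exponential 40-kb offsets; SVs with log-normal lengths (median 150 kb)
and planted placement modes; expression shifts of ±1.5 log2FC in switch
regions. A paired "reference" sample is derived by dropping (20%),
shifting (12%, 2–3 bins), and adding (12%) boundaries and by flipping
compartment runs covering 0.6% (A→B) and 0.9% (B→A) of bins.

Not emulated: read-level noise and mappability artifacts, restriction-
fragment structure, translocations' trans contacts, aneuploid coverage
interactions with balancing, overdispersed counts, nested/hierarchical
TADs, and realistic gene-length or expression distributions. Passing
recovery tests therefore demonstrates correctness of the statistics under
the stated generative model — not robustness to every artifact of real
libraries.

One deliberate mismatch with real data scale: chromosomes default to
60 Mb (two of them) rather than full human size. All statistics here are
per-chromosome and length-normalized, so the problem size only sets the
number of boundaries/pairs entering each test; 60 Mb gives ~100 boundaries
per chromosome, enough for stable F1 and KS estimates.

## Numerical and degenerate-input conventions

- Balancing on a map with an unmasked zero-marginal row is an error (mask
  first); a single unmasked bin gets weight `1/√M₀₀`.
- Insulation and TAD-signal tracks are NaN wherever the full window does
  not fit, the bin is masked, or all window cells are masked.
- Chromosomes with fewer than two boundaries yield no TADs (warned).
- `proximity_fraction`, KS comparisons, and the overlap p-value reject
  empty inputs rather than returning NaN.
- All Monte-Carlo operations (bootstrap, randomized nulls, background
  sampling, every generator) take explicit seeds; the generators derive
  independent streams from one master seed by fixed offsets, so adding a
  generator never perturbs the draws of an existing one.

## Known limitations

- The insulation caller is single-scale; nested domain structure would be
  reported as whichever level dominates at the chosen window.
- The bootstrap null for boundary overlap ignores boundary clustering
  (uniform redraw); for strongly clustered boundary sets it is slightly
  anti-conservative.
- Gene-level backgrounds sample gene *pairs* by enumerating candidates at
  matched distance; on gene-dense chromosomes this is the slowest step of
  the pipeline.
- The "overall" background samples bin pairs, so it inherits any residual
  balancing bias at short distances.
- Interchromosomal SVs are carried through I/O and counting but excluded
  from range/placement analysis by design.
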