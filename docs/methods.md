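# Methods

## Probe model and scope

All operations assume the linear probe response

    y_i = c_i · (A_i x_i + B_i) + ε_i

with biological signal `x_i ∈ [0, 1]`, probe efficiency `A_i > 0`,
probe background `B_i`, apparent copy number `c_i` (1 outside repeats) and
noise `ε_i`. The goal of normalization is to recover `x_i` up to a global
affine scale without ever estimating `A_i` or `B_i` explicitly: both are
absorbed into empirical low/high signal levels of a reference set of
similarly responding probes. Intensities are used on the scale of the
input file; nothing in the algebra requires a log transform, and none is
applied implicitly (`read_probe_table(..., log2=True)` is available for
raw linear-scale inputs). Coordinates are 0-based half-open throughout,
matching BED/bedGraph; probe strand is ignored — tiling probes are
treated as unstranded genomic positions.

## Reference sets

For every probe, `Ref(p_i)` holds the N probes whose control-condition
behaviour is most similar (N = 1000 by default; the estimate of the rank
windows below degrades noticeably only when N drops well under a few
hundred). Three constructions:

* **single** — probes are sorted ascending by the control signal (stable,
  ties by probe index). An eligible probe at sorted position r takes the
  ideal window `[r − ⌈N/2⌉, r + ⌊N/2⌋]`, shifted (not truncated) into the
  valid rank range so that after removing the probe itself exactly N
  members remain. An ineligible probe (repeat regions) takes the N
  consecutive sorted eligible positions centred on its insertion point in
  the sorted eligible values — it borrows the window of its nearest
  eligible neighbourhood but never contributes to anyone's window.
* **sorted-average** — identical, applied to the per-probe mean over
  multiple control arrays; with one array it reduces exactly to *single*.
* **min-distance** — the N eligible probes nearest in the M-dimensional
  control space, computed exactly (chunked all-pairs distances), ties by
  probe index. Metrics: euclidean (default, the conventional reading of a
  distance), chebyshev and manhattan. With M = 1 this agrees with
  *single* except for window-clamping differences at the rank extremes,
  which we document rather than force away. Averages discard information
  about probe stability across controls; the min-distance construction
  keeps it, so two probes with equal averages but opposite responses are
  not conflated.

Self-exclusion is deliberate: with small N, letting a probe vote in its
own reference set feeds its own noise back into its dynamics estimate.
Probes overlapping a repeat-mask interval by ≥ 1 bp are ineligible; masking
is idempotent and monotone (adding intervals never frees a probe).

## Binary group normalization

Reference-set member values in the treatment condition are sorted
ascending; a fraction interval (a, b] over a size-N set selects 1-based
ranks `⌊aN⌋+1 … ⌊bN⌋` (so 0–30% and 70–100% give ranks 1–300 and 701–1000
at N = 1000). Defaults are the 10–40% window for `μ_low` and 60–90% for
`μ_high`. The normalized value is `(y_i − μ_low) / (μ_high − μ_low)`,
**not** clipped to [0, 1] — values outside mean "more extreme than the
reference set's low/high levels" and are information, not errors.

The exact choice of windows only shifts and rescales the output globally:
if the reference probes' biological signal is drawn from one distribution,
every window mean is an affine function of the same two unknowns, so any
two window choices differ by one global affine map. The test suite asserts
this to < 1e−8 residual on noise-free grouped-probe data for the four
window sets (.10–.40/.60–.90, .05–.50/.80–.95, .10–.50/.50–.90,
.10–.30/.70–.90).

Degenerate reference sets — `μ_high − μ_low ≤ δ·max(|μ_high|, |μ_low|, 1)`
with relative δ = 1e−9 — produce an undefined value (NaN in memory, no
bedGraph/wiggle line, `NA` in TSV); occurrences are counted and logged,
never silently zeroed.

## Quantile-based group normalization

Each probe's sorted reference-set distribution is averaged componentwise
over all probes; the probe's fractional rank in its own set (count of
members ≤ y, linearly interpolated between bracketing member values, so a
value tying a member lands exactly on that member's rank) indexes the
average distribution, clamped to its ends outside the support. Shrunken
sets (possible only when fewer than N+1 eligible probes exist) are
excluded from the average with a warning and mapped through their own
fractional position.

## Cross normalization

`cross_normalize(A, B)` builds single-reference sets from B to normalize
A, and from A to normalize B. Regions identical in both conditions land
near the centre of their reference-set dynamics; regions that changed are
pushed to the extremes in opposite directions in the two outputs. Both
asymmetric tracks are returned — their correspondence is the caller's
reliability measure, and no summary of it is imposed here.

## Signal quality

Given conditions A, B and a replicate of B (all normalized the same way):
changed probes are the top 2% by absolute difference of the two tracks
after spatial averaging over 147 bp (probe-centre windows of ± window/2,
truncated at chromosome ends; set size rounds up). When two approaches
are compared, the intersection of their changed sets is used so neither is
favoured. `S` is the mean square A−B difference over changed probes on the
*unsmoothed* tracks (smoothing enters only the selection — the metric
scores the signal itself, not a band-limited version of it); noise is the
mean square B−replicate difference over all probes;
`quality_db = 10·log10(S/noise)`. The measure is invariant under a common
affine transform of all three tracks, strictly increasing in S and
decreasing in noise. `signal_noise_combinations` enumerates every
(A-array, B-array, B-replicate) triple in both directions — three arrays
per condition give 36 — and evaluation averages the dB over them, which
also averages out array-level good or bad luck in the replicate pair.

The autocorrelation diagnostic pairs each probe with the probe nearest to
its centre plus the lag (tolerance step/2, per chromosome) and reports the
Pearson correlation per lag; lags with under 3 pairs are omitted, lag 0 is
1 by definition. On nucleosome occupancy tracks a recurrence near 170 bp
(footprint plus linker) indicates preserved periodic structure.

## Synthetic data

The generator emulates exactly the structure the method exploits, with
defaults fixed once as a realistic desk-scale study:

| parameter | default | why |
|---|---|---|
| probes | 10,000 × 25-mers, 4 bp step | high-density tiling at desk scale |
| gc | Uniform(0.2, 0.8) | latent covariate driving both A and B |
| A(gc) | (1 + 8·gc)·lognormal(σ=0.10) | ~3× efficiency range, GC-driven |
| B(gc) | (0.5 + 2·gc)·lognormal(σ=0.10) | background shares the covariate |
| occupancy | 147 bp footprints, exponential linkers, bound fraction 0.77 | ~75–80% of the genome is nucleosome bound; linker mean set to hit the fraction |
| noise | additive Gaussian, σ = 0.3 | moderate relative to the ~1–8 intensity range |
| per-array scale / offset | lognormal σ = 0.10 / Gaussian σ = 0.20 | global experimental biases between arrays |
| per-array response jitter | lognormal σ = 0.05 on A | arrays never reproduce probe response exactly |
| repeats | ~2% of bp, copy number 2–5, emitted as BED mask | elevated apparent copy number in repetitive regions |
| response regions | ~10% of bp re-drawn in condition B | differential occupancy between conditions |

Per-probe x is the fraction of the probe interval covered by bound bp, so
probe-level values interpolate smoothly across footprint edges. "GC" is a
latent uniform variate — no sequences are generated; the mechanism needs
only a shared covariate behind A and B. Noise is additive on the intensity
scale (the simplest reading of the linear model); real arrays are
heteroscedastic, which the multiplicative response jitter partially
captures. Every generator is a pure function of (config, seed); a full
experiment is reproducible to the byte.

What passing on this generator does **not** show: robustness to saturation
and other nonlinearities of real hybridization, to cross-hybridization
structure that correlates with the biological signal, or to spatial
artefacts (scratches, edge effects) — none of which are modelled.

## Numerical and design choices

* All ties (sorting probes, ranking differences, nearest neighbours) break
  by original probe index with stable sorts, making every output
  deterministic and permutation-equivariant.
* The normalizers operate on whatever scale the input is on; binary GN is
  exactly invariant under a global affine transform of the treatment
  array, which is why no separate global normalization pass is needed or
  performed. Global quantile normalization is included purely as the
  conventional baseline.
* TSV track values are written with shortest round-trip decimal formatting
  and parsed with exact float conversion, so write→read reproduces values
  bit-for-bit.
* `simulate_experiment`-based evaluations restrict correlation metrics to
  eligible probes: multi-copy repeat probes are excluded from reference
  sets by design, and their (deliberately unmodelled) normalized values
  would otherwise dominate Pearson correlations.
* Problem sizes in the test and acceptance runs (10,000-probe studies,
  N = 1000; 4,000-probe recovery runs at N = 500; 200-probe oracle
  instances) were chosen as the smallest at which the rank-window
  estimates are stable; results do not depend on these sizes beyond
  sampling noise.

## Known limitations

* Reference sets assume every eligible probe sees the same input DNA;
  copy-number variation outside the provided repeat mask violates this
  silently.
* The min-distance method is exact (no approximate nearest-neighbour
  index) and therefore quadratic in probe count per chunk; it is intended
  for up to a few hundred thousand probes, not read-level data.
* Cross normalization reuses the single-reference assignment on the
  opposite condition; with several replicates per condition a
  sorted-average variant may be preferable and can be composed manually
  from the library functions.
* Undefined values propagate as NaN; downstream consumers that cannot
  handle missing probes should use the TSV output and filter `NA` rows.
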