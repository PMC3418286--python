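# groupnorm

Nonparametric normalization and probe-effect correction for probe-level
genomic signals (tiling microarrays and analogous assays), built around
**Group Normalization**: instead of fitting a sequence-based model of probe
behaviour, each probe's response parameters are estimated from a *reference
set* of probes that demonstrably respond like it in one or more control
hybridizations.

## Who this is for

Anyone working with probe-level signal tables — nucleosome occupancy,
ChIP-chip, or any assay where readout efficiency varies strongly and
reproducibly along the genome. When randomly sheared genomic DNA is
hybridized to a tiling array, the signal should be flat; in practice it
varies severalfold, yet near-identically between replicates. That
reproducible *probe effect* is what this package removes.

## The model

The observed intensity of probe *i* is modelled as

```
y_i = A_i · x_i + B_i + ε_i
```

where `x_i ∈ [0, 1]` is the unitless biological signal (0 = unbound,
1 = fully bound), `A_i` a probe-specific efficiency, `B_i` a probe-specific
background (non-specific binding and other target-independent signal) and
`ε_i` random noise. For each probe, a reference set Ref(p_i) of N similarly
responding probes (N = 1000 by default) is found from control
hybridizations by one of three methods: nearest rank neighbours in a single
control (**single**), in the mean of several controls (**sorted-average**),
or nearest neighbours in the multi-dimensional control space
(**min-distance**; euclidean, chebyshev or manhattan metric). Probes inside
repeat regions are excluded from reference sets (their apparent copy number
is inflated) but are still themselves normalized.

Two normalizers are provided:

* **binary** — sort the reference set by its treatment values; the means of
  a low and a high rank window (default ranks in the 10–40% and 60–90%
  fractions) give `μ_low` and `μ_high`, and
  `x̂_i = (y_i − μ_low) / (μ_high − μ_low)`;
* **quantile** — map each probe's fractional rank within its reference set
  onto the average sorted reference-set distribution.

**Cross normalization** applies the same machinery to two experimental
conditions directly — each serves as the other's reference — which
amplifies the regions that actually differ between them. A **Signal
Quality** metric (`10·log10(S/N)` from two conditions plus a replicate)
quantifies what normalization buys, and a synthetic-data generator
reproduces the statistical structure (GC-driven probe effects, ~147 bp
occupancy footprints, replicate arrays, repeats) so the whole pipeline is
testable without any array downloads.

## Worked example

```python
import numpy as np
import groupnorm as gn

table, signals, truth = gn.simulate_experiment(seed=1)
control = signals.column("control_1")
treatment = signals.column("a_1")

ref = gn.assign_single_reference(control, table.eligible, N=1000)
track = gn.binary_group_normalize(treatment, ref)

el = table.eligible
print(f"raw corr with control: {np.corrcoef(treatment[el], control[el])[0,1]:.3f}")
print(f"GN  corr with control: {np.corrcoef(track.values[el], control[el])[0,1]:.3f}")
print(f"raw corr with truth x: {np.corrcoef(treatment[el], truth.x_a[el])[0,1]:.3f}")
print(f"GN  corr with truth x: {np.corrcoef(track.values[el], truth.x_a[el])[0,1]:.3f}")
```

prints

```
raw corr with control: 0.588
GN  corr with control: 0.012
raw corr with truth x: 0.757
GN  corr with truth x: 0.956
```

The raw treatment signal correlates strongly with the genomic control —
pure probe effect, not biology. After Group Normalization that correlation
is gone (0.012), and the agreement with the true simulated occupancy rises
from 0.757 to 0.956.

The same pipeline from the shell:

```sh
gn simulate --seed 1 --out sim/
gn normalize --input sim/probes.tsv --mask sim/mask.bed \
             --reference control_1 --method binary --out-dir tracks/
gn cross     --input sim/probes.tsv --cond-a a_1 --cond-b b_1 --out-dir tracks/
gn quality   --input sim/probes.tsv --cond-a a_1 --cond-b b_1 --replicate b_2
```

Outputs are bedGraph by default (`--format wiggle|tsv` also available);
probes with degenerate reference sets get no bedGraph line and `NA` in TSV.

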