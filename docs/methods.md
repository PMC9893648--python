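# Methods

## Quantification model

Droplet digital PCR partitions a reaction into n droplets of volume V_d.
Under ideal Poisson partitioning the per-droplet copy number of a target is
Poisson(λ) with λ = concentration × V_d, and a droplet is positive iff it
received at least one copy, so the positive fraction estimates
p = 1 − e^−λ.  The estimator chain is:

* λ̂ = −ln(1 − k/n) from the positive count k;
* SE(λ̂) = sqrt(p̂ / (n(1 − p̂))) by the delta method on the binomial count;
* concentration = λ̂ / V_d, 95% CI = (λ̂ ± 1.96·SE)/V_d floored at zero.

The delta-method interval was chosen for transparency; an exact
Clopper–Pearson interval mapped through −ln(1 − p) is available via
`exact_ci=True`.  At k = 0 the delta SE degenerates to zero, so the upper
bound falls back to the SE evaluated at one positive droplet (≈ 1.96/n on
the λ scale) — a conservative small-count floor.  A fully positive well
(k = n) raises a saturation error rather than returning infinity.

Replicate wells of one target are pooled by summing k and n across wells
*before* Poisson correction, the digital-PCR convention; pooling is not the
same as averaging per-well concentrations when droplet counts differ, and a
regression test pins that distinction.

In a duplex assay the two channels' occupancies are independent Poisson
draws, so each allele's λ is estimated from its own channel's total positive
count (single + double positives), and the total concentration of a well is
the sum of the two λ estimates with SEs combined in quadrature.

## Derived read-outs

All higher-level quantities are concentration ratios with first-order error
propagation (SE(R)/R = sqrt((SE_A/A)² + (SE_B/B)²)):

* **Allelic fraction** f_WT = λ_WT/(λ_WT + λ_MUT), SE(f) =
  f(1−f)·sqrt((SEλ_WT/λ_WT)² + (SEλ_MUT/λ_MUT)²), zero by convention when
  either λ is zero (the fraction is pinned to a boundary).  f_WT + f_MUT = 1
  holds exactly.  Replicate summaries report per-assay means and sample SDs;
  the cross-assay pooled value is the unweighted mean of per-assay means,
  since each SNP assay is an equally valid view of the same allele ratio.
* **Transcripts per diploid genome** = diploid_factor × scaling ×
  C_cDNA/C_gDNA from split-tube paired isolations measured with one SNP
  assay.  diploid_factor defaults to 2: a heterozygous SNP assay counts two
  genomic amplicons per diploid genome, so the cDNA/gDNA amplicon ratio must
  be doubled to be a per-cell transcript count.  The factor is a named
  parameter because the verbal definition of the estimator is ambiguous on
  this point; `scaling` (default 1) exposes a measured cDNA/gDNA recovery
  ratio for users who have one.
* **Copy number** = reference_copies × C_target/C_reference (reference gene
  at 2 copies per genome by default), reported both continuous and rounded
  to the nearest integer, ties away from zero.  Allele partitioning
  multiplies the total by the *genomic* WT/MUT fractions; continuous
  partitions sum to the total exactly.
* **Knockdown** = 100 × (1 − (C_treated/C_ref,treated)/(C_control/C_ref,control)),
  computed for total, WT and MUT.  Reference normalization cancels any
  global loading difference between the groups.

## Droplet classification

A droplet is positive on a channel iff its amplitude is strictly greater
than the channel threshold (ties count negative — a deterministic
tie-break).  Two threshold modes exist:

* **auto** — deterministic two-means on the 1-D amplitudes, centers
  initialised at the 5th/95th percentiles, ≤ 100 iterations, tolerance 1e-6;
  the threshold is the midpoint of the converged centers.  The split is
  rejected ("no cluster structure") when the separation of the centers is
  below twice the summed within-cluster SDs, which is the signature of a
  single cluster cut in half — so an all-negative well errors instead of
  inventing positives.  Auto mode needs both clusters populated (≥ 100
  droplets overall) and is intended for real wells of unknown scale.
* **fixed** — explicit per-channel cutoffs.  For simulated wells, where the
  amplitude model is known, the analyses use `rain_robust_thresholds()`:
  3 SD below the positive cluster mean.  A midpoint threshold scores half of
  the uniform rain band positive — an additive false-positive rate of
  rain_fraction/2 per channel that biases low-occupancy channels upward
  (for the 10% WT mixture it shifts the estimated fraction by more than a
  percentage point).  Sitting just under the positive cloud keeps 99.87% of
  true positives while only the top ~15% of the rain band crosses,
  mirroring the manual practice of thresholding tight beneath the positive
  cluster.

Wells with fewer than `min_droplets` (default 10,000) accepted droplets are
flagged, never dropped.

## The synthetic-data generator

The generator inverts the quantification model.  Per droplet and per
target: copies ~ Poisson(conc × V_d), independent across targets; occupancy
> 0 places the droplet in that channel's positive amplitude cluster;
amplitudes are normal (negative cluster 2,000 ± 300 a.u., positive
8,000 ± 300 a.u. by default — synthetic units chosen only to be well
separated, since real instrument scales vary by assay and dye).  A
`rain_fraction` (default 1%) of droplets lose their cluster amplitude and
draw uniformly between the cluster means on both channels; an optional
`crosstalk_shift` (default 0) adds spectral bleed-through to the off channel
of positive droplets.  Wells whose expected positive fraction exceeds 99.9%
carry a saturation flag.  Ground-truth occupancy labels and the rain mask
ride along on every simulated well, so tests can assert classification
against what each droplet actually contained.  V_d defaults to 0.85 nL (the
QX200 convention) and n to 20,000 accepted droplets; both are configurable.

Named experiment designs assemble study conditions: the seven-sample WT/MUT
mixture series (400 copies/µL total; fractions 100/90/75/50/25/10/0% WT),
the heterozygous-gDNA 50:50 control (100 copies/µL per allele, 3
replicates), paired cDNA/gDNA wells for the per-genome estimator, a
single-channel copy-number design (target + reference-gene wells), and a
control/treated silencing design (control 200/110 copies/µL, treated at
half, reference gene equal in both groups; 3 replicates throughout,
matching the replication level of the experiments being emulated).  Per-well
seeds are spawned deterministically from one design seed; there is no
global random state.

The **paired cDNA/gDNA design is rain-free by default**.  With any fixed
threshold a uniform rain band contributes a constant false-positive rate
(rain/2 at the midpoint, ≈ 0.15·rain at the rain-robust threshold).  A gDNA
well at 20 copies/µL has p ≈ 0.85%, so even the residual 0.15% false-positive
rate inflates its concentration by ~17% and destroys the cDNA/gDNA ratio;
the recovery experiments therefore characterize the Poisson-ratio estimator
on clean wells, and rain sensitivity is quantified separately by a dedicated
test of the low-concentration bias.

What the generator does *not* emulate: PCR efficiency and chemistry,
droplet-volume variability, probe cross-hybridization, or partition-size
effects.  Passing recovery tests therefore demonstrate the correctness of
the statistical chain under ideal partitioning, not robustness to those
instrument non-idealities.

## RNA-seq cross-check

Per-SNP allele read counts yield f = wt/(wt + mut) with a Wilson score
interval per (SNP, sample); zero-depth rows are excluded with a warning.
Per-sample aggregation defaults to the unweighted mean over SNP regions
(each SNP an independent view of the ratio), with pooled-count aggregation
available; the two differ whenever depths are unequal, and the across-SNP SD
is reported as the dispersion measure.  Read mapping, strand subsetting and
base-quality filtering are upstream of this module, which starts from a
validated count table.  The simulator draws per-SNP WT counts from
Binomial(depth, f_true), so the comparison of across-SNP scatter with
ddPCR's propagated SE at matched composition is itself testable.

## Numerical and serialization choices

Result tables are TSVs with a fixed column order, rows sorted on
(sample, assay, target) and floats at 6 significant digits, so identical
inputs produce byte-identical files.  Amplitude CSVs are written with
shortest-round-trip float repr, making write-then-read bit-exact.  Copy
numbers round half away from zero.  Readers reject malformed input (naming
the offending line) rather than coercing.

## Problem sizes

Simulated recovery experiments use 20,000 droplets per well and 3 replicate
wells per condition — the replication level of the emulated experiments.
Calibration sweeps use 200 replicate wells per λ on a grid spanning
0.05–1.5 copies/droplet, which brackets the occupancies of all study
designs (gDNA wells ≈ 0.017, the densest cDNA wells ≈ 0.46).

## Known limitations

* Rain is handled by threshold placement, not excluded or modeled; the
  residual false-positive rate biases very low-concentration wells (see
  above), which is why low-template quantification below ~20 copies/µL
  should pool replicate wells and use rain-robust thresholds.
* The delta-method CI undercovers slightly at very small k; the exact
  interval is available where that matters.
* Knockdown results report point ratios without a propagated interval;
  tests propagate the error externally when calibrating the recovery.
* Two fluorescence channels only; no 2-D cluster-shape classification.
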