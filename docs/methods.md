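# Methods

This note documents the models implemented in proteoqc, the defaults and
why, the numerical conventions, and what the simulator does and does not
capture about real LC–MS/MS data.

## The SNR statistic

For a balanced design of m biological groups with n technical replicates,
runs are embedded in the first two principal components. The signal is the
average variance-weighted squared distance over all C(m,2)·n² inter-group
replicate pairs; the noise is the average over the m·C(n,2) intra-group
pairs; SNR = 10·log10(signal/noise) in decibels. The weighted squared
distance between runs i and j is Σ_{p=1,2} W_p (PC_{p,i} − PC_{p,j})²,
where W_p is the fraction of total variance explained by component p taken
from the full decomposition, **not** renormalized to sum to one over the two
kept components (a renormalized option exists: `renormalize_weights=True`).
Since both numerator and denominator carry the same weights, the score is
invariant to a common weight rescaling, so this choice only matters when the
two components are combined with external quantities.

Preprocessing before PCA, each step switchable: missing values are filled
with the 10⁻⁵ sentinel, values are log10-transformed, and each protein is
centered and unit-scaled across runs. Sentinel filling before the log is
what lets stochastic detection contribute to the noise term — a protein
detected in one replicate and not another produces a large, real
displacement, exactly the behaviour that distinguishes a stable platform
from an unstable one. Proteins with zero range across runs are dropped
before scaling (peak-to-peak, not standard deviation, to be immune to
floating-point mean rounding on constant rows).

Numerical conventions:

- Category bins are left-closed/right-open: [0,2) ineligible, [2,10)
  average, [10,20) good, [20,∞) excellent; negative scores are ineligible.
  Boundary membership is fixed by convention since range labels like "2–10"
  are ambiguous.
- A noise term that is zero, or below 10⁻¹² of the signal (the level at
  which LAPACK round-off on coinciding replicates shows up), raises a
  distinct degenerate-replicates error rather than returning an infinite
  score; pipelines report it as category "degenerate".
- The batch threshold helper returns mean − sample (n−1) standard deviation
  of a collection of SNR scores.
- PCA sign/rotation indeterminacy is irrelevant: the statistic uses
  distances only, and tests assert at the distance level.

## Normalization

FOT_i = iBAQ_i / Σ_present iBAQ × 10⁵ per run; entries missing in the input
become the 10⁻⁵ sentinel, applied **only** at normalization (never at I/O,
so raw missingness stays recoverable on disk as "NA"). "Present" everywhere
downstream means non-missing and not equal to the sentinel; identification-
based metrics (IDF, occurrence bins, overlap, stability) treat sentinel
entries as absent, while profile-level comparisons (Pearson correlation of
log10 FOT, DEP fold-change means) include them so that dropout structure is
part of the comparison. A present-in-both correlation option exists.

Intensity tertiles: the ranking basis is the mean of present FOT values
across an experiment's runs (sentinels excluded so filled values can never
move the cuts); cut points are the 33.33rd and 66.67th percentiles with
linear interpolation; low < P33.33 < medium < P66.67 < high. If all basis
values coincide the split is undefined and everything is assigned "medium"
with a warning.

## Differential analysis

Fold change for an ordered pair (test, reference) is the ratio of
sentinel-filled replicate means, so a protein absent from one group gives a
large but finite ratio rather than being dropped — absence is evidence of
differential expression under this convention. Calls are strict: ratio > 2
(up) or < 1/2 (down); exactly 2 is not a call. No significance testing is
performed: the fold-change rule is the entire call, by design.

Reproducibility frequency across E experiments counts, per canonicalized
(protein, pair, direction) triple, the experiments containing the record.
The frequency axis [1, E] is divided in the ratio 3:3:2 — low gets the first
⌈3E/8⌉ frequencies, medium up to ⌈6E/8⌉, high the rest — which yields
1–9 / 10–18 / 19–24 at E = 24 (the axis is naturally divided into eight
width-3 intervals there; the three summary bins take 3, 3 and 2 of them).
Consistent-trend records have frequency exactly E and are never returned if
the same protein/pair was also called in the opposite direction anywhere.

## Absolute quantification

Gold-peptide anchoring: amount = gold amount × heavy/light signal ratio.
Copies/cell = moles × Avogadro / cell count; the cell count is an explicit
required parameter since no universal normalization exists. Dilution
linearity and anchor calibration are ordinary least squares in log10–log10
space — the standard choice for multi-decade abundance data; anchor
calibration is one global line per sample. Peptide-to-protein rollup uses
the mean ratio across a protein's anchor peptides. Degenerate cases:
constant dilution signal reports slope 0 with R² defined-as-0 and a
warning; two anchors give a saturated fit with R² = 1.

## The simulator

The generator emulates a quartet-style label-free campaign; its defaults
are the study conditions the rest of the package is validated under.

- **Base abundances**: log10 values drawn normal, then affinely rescaled so
  the realized span equals `dynamic_range_log10` (default 7 decades,
  centered at 10^2.5). The rescale makes the advertised dynamic range exact
  rather than approximate.
- **Group structure**: 4 groups × 3 replicates. `specific_fraction`
  (default 4%) of proteins per group are absent from all other groups, in
  pairwise-disjoint sets. `dep_fraction` (default 5%) of non-specific
  proteins get one group multiplied/divided by a fold change drawn
  log-uniform from `dep_fc_log2_range` (default FC ≈ 2.3–8, always strictly
  above the 2-fold threshold); the flag table enumerates the implied
  differential pairs. Optional lognormal per-group biological effects
  (`group_effect_sd`, default off) and a twin-similarity correlation between
  the first two groups (default off).
- **Technical noise**: multiplicative mean-one lognormal with
  σ = sqrt(ln(1+CV²)), so the realized CV equals the target exactly in
  expectation. Targets are per intensity stratum (tertiles of base log
  abundance): 80% low, 40% medium, 20% high — low-abundance proteins are
  noisier, as in real label-free data.
- **Detection**: each protein is observed with logistic probability in its
  *deterministic* log10 abundance (base × drift × degradation, technical
  noise excluded), midpoint 10^1.5 and slope 1.5/decade by default. This is
  the simplest monotone model of DDA's intensity-dependent sampling;
  midpoint −∞/+∞ force detection on/off for noise-free and degenerate
  scenarios.
- **Injection drift**: run intensities are multiplied by
  `drift_per_injection^((t−1)·s_p)` where t is the injection time and s_p a
  per-protein sensitivity ~ Normal(1, `drift_heterogeneity`, default 0.3).
  A strictly uniform drift would cancel exactly under FOT normalization (it
  is a per-run scale factor), whereas real LC–MS drift is analyte-specific;
  the heterogeneous component is what makes injection order recoverable
  downstream. Continuous modes (CI1 interleaved, CI2 group blocks) run
  back-to-back (t = slot); the random mode (RI) scatters the same runs over
  a `ri_time_spread`-fold longer window (default 10×), emulating random
  injection across idle instrument time. Injection indices remain a
  permutation of 1..m·n in every mode. Under drift this yields the mean-SNR
  ordering CI2 ≥ CI1 > RI, with RI collapsing toward 0 dB as drift grows.
- **Degradation**: a `degradation_fraction` of proteins decays as
  exp(−rate·(month − onset)) for months past the onset (default onset month
  12), lowering both measured values and detection probability, so
  longitudinal identification reproducibility drops after the onset.
- **Determinism**: all randomness flows from one integer seed through
  independent named streams (truth, injection order, per-run noise), so
  identical configurations give byte-identical outputs, and several
  experiments can share one ground truth while varying run-level noise
  (`experiment_seed`).

What the simulator does **not** capture: peptide-level identification and
roll-up (proteins are atomic), correlated noise between co-eluting analytes,
retention-time alignment artifacts, batch effects other than smooth
multiplicative drift, and missingness mechanisms beyond the
intensity-dependent logistic (no censoring at a hard limit of detection,
no run-level identification failures). Passing recovery tests therefore
demonstrates that the metrics respond correctly to these generative
mechanisms, not that they are robust to every failure mode of real data.

## Problem sizes and test design

The validation suites use desk-scale designs — hundreds to a few thousand
proteins, 10–100 seeds per stochastic check — chosen so the full test and
acceptance runs complete in seconds while keeping Monte-Carlo error well
inside the asserted margins (e.g. planted-DEP recall is asserted at ≥ 90%
where the measured mean is ≈ 99.9%; the RI-vs-CI2 ordering holds in 10 of
10 paired seeds against an asserted 9 of 10). The SNR implementation is
verified against an independent brute-force enumeration of all pairs (no
prefactor algebra) to 10⁻⁹ relative on random designs with m ∈ 2..5,
n ∈ 2..4.
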