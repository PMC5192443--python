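# Methods

This note documents the models, parameter choices, and numerical
conventions behind `isopick`, and what its synthetic data can and
cannot show about real measurements.

## Theoretical isotope patterns

A molecular formula's isotope distribution is computed by exact
convolution of per-element isotope distributions (binary
exponentiation over atom counts).  Intermediate terms below 1e-9 of
the running maximum probability are dropped, and terms more than
`max_isotopes + 1.5` nominal isotope spacings above the monoisotopic
mass are discarded early; both bounds keep the fifth isotope peak
accurate to well below the reported precision while bounding the term
count.  Fine-structure terms are aggregated at 1e-7 Da during
convolution.

Centroid merging emulates an instrument of resolving power R: sorted
fine-structure centroids are merged left to right whenever the gap to
the current group's intensity-weighted mean is below mass/R (the
implied FWHM), accumulating intensity-weighted means.  No peak-shape
model is applied; at R = 10,000 this reproduces reference centroid
patterns to < 1 mDa without simulating profiles.

Conventions that matter:

* **Monoisotopic = lightest.**  The monoisotopic peak is built from
  each element's lightest isotope.  For boron (¹⁰B at 19.9%) the
  monoisotopic peak is *not* the most intense one.
* **Pruning is relative to the monoisotopic peak**, not the base
  peak: a centroid is kept when its intensity is at least
  `prune_threshold` percent (default 0.01) of the monoisotopic
  centroid.  The two conventions coincide except when the mono peak
  is not the base peak (boron compounds), where the mono-relative
  rule is the one that reproduces the reference cluster sizes.
* **Cluster depth** is capped at `max_isotopes = 5` peaks beyond the
  monoisotopic one.  Without the cap, polychlorinated compounds have
  sixth-isotope centroids (e.g. ³⁷Cl₂¹³C₂) above the 0.01% threshold.
* Isotope numbers are assigned by rounding the mass shift from the
  monoisotopic centroid against Δm = 1.003355 Da, so combination
  peaks such as ³⁷Cl (+1.9973) land on the correct nominal slot.
* Electron mass is ignored; patterns are for neutral formulas.

**Isotope masses and abundances** are bundled (CIAAW/IUPAC values).
For chlorine, whose natural isotopic composition varies widely enough
that CIAAW quotes the interval ³⁷Cl ∈ [23.9%, 24.5%] around a
representative 24.24%, we adopt 24.36%: the value consistent with the
six-substance reference patterns used to calibrate the table, inside
the published interval.  With the representative value the ³⁷Cl-
dominated centroids of the chlorinated reference compounds deviate by
up to 0.4 percentage points; with 24.36% all 33 reference centroids
agree within 0.1 points and 0.1 mDa.

## Isotope ROI prediction and targeted picking

Predicted isotope ROIs take the source peak's retention-time interval
unchanged and shift its m/z interval by i·Δm/z (defaults Z = 3,
I = 5, giving 15 ROIs per peak).  Overlapping ROIs are not merged.
The relaxation grid for the signal-to-noise threshold is
r ∈ {5, 10, …, 100} percent with default r = 25 — the recommended
compromise between exhaustive isotope recovery and peak reliability —
so snthr′ = 6.25 for the default snthr = 25.

Noise ROIs are sampled one-for-one: centers uniform within the
bounding box of the predicted ROI centers; m/z widths from a 50-bin
histogram of detected relative widths (width/mz, rescaled by the
sampled m/z); rt widths from a 50-bin histogram of detected rt
widths.  Bin counts are a design choice (the histogram rule is
binning-agnostic in spirit); sampling is deterministic under a seed.

The ROI examination step is intentionally lightweight — the
contribution is *where to look*, not the wavelet machinery of a full
feature detector, and externally produced peak tables can be supplied
anywhere a peak list is accepted.  Per ROI: the extracted-ion trace
takes the most intense centroid inside the m/z window per scan; the
apex is the largest trace value inside the ROI's rt bounds; local
noise is the median positive centroid intensity within ±0.5 Da of the
ROI center over the ROI's rt window extended threefold on both sides,
excluding the chromatographic peak (the half-height span extended
outward while the trace keeps falling), floored at 1 count.  A peak
is emitted when apex/noise ≥ snthr, with the trapezoidal area of the
half-height span as intensity.  The ±0.5 Da noise band samples the
local noise floor robustly while excluding neighbouring isotopologues
(≥ 1 Da away at z = 1); in its noiseless limit (no background
centroids at all) the floor of 1 count makes every planted signal
recoverable at any threshold.

Merging of peak tables drops an added peak when any already retained
peak lies within max(mz·ppm_tol/10⁶, abs_tol) in m/z (defaults
10 ppm / 0.005 Da) and rt_tol (5 s) in retention time; this also
removes duplicates among targeted peaks themselves, which arise
because ROIs for (z = 2, i = 2) and (z = 3, i = 3) coincide with
(z = 1, i = 1).

## Cluster detection

For each charge state the spacing test compares a peak pair's m/z
difference with Δm/z at tolerance max(mono_mz·Δm_ppm/10⁶, Δm_abs);
defaults Δm_abs = 0.01 Da, Δm_ppm = 0 — the absolute error at which
both ordinary and S/Cl/B-containing substances are detectable.  The
ppm term is referenced to the chain's first (monoisotopic) m/z: this
is the reading that reproduces the reference per-substance relative
errors (e.g. 0.008946/121.019749·10⁶ = 73.9 ppm for cysteine).

All gap-free chains (consecutive isotope numbers only) are
enumerated per charge and start peak by depth-first search; the
retained cluster is the largest chain, with deterministic tie-breaks:
lower monoisotopic m/z, then smaller charge (widest spacing), then —
between equal-length chains from the same start — the successor
closest to the expected position, then higher intensity.  Retained
peaks are removed and the search repeats; clusters are therefore
peak-disjoint.  Exhaustive enumeration is exponential in
pathological inputs but negligible on coeluting groups of realistic
size; the test suite checks it against an independent brute force
over all peak subsequences.

Coeluting groups are formed by a simple retention-time gap rule
(5 s default) — plumbing that stands in for proper pseudospectrum
extraction, which is an upstream concern.

## Ratio quantile tables

For every database compound the theoretical pattern is computed at
full depth (no intensity pruning, 5 isotope peaks) and the ratios
monoisotopic/i-th recorded; compounds whose pattern genuinely lacks
the i-th centroid are skipped with a warning.  Pruning at 0.01% here
would cap all recorded ratios at 10⁴ and silently truncate the upper
quantiles that validation needs.

Compounds are grouped into half-open mass windows [k·w, (k+1)·w)
(supported w ∈ {10, 25, 50, 100, 250}, default 50 Da; a boundary mass
belongs to the upper window), and quantiles are computed on the
23-value grid {5·10⁻⁶ … 0.5 … 0.999995} by linear interpolation of
order statistics — any monotone estimator would do; on small windows
the extreme p-values degenerate to the window min/max, which is
documented behaviour, not an error.  Lookups beyond the last
populated window clamp to it; empty interior windows fall back to the
nearest populated window with a logged warning, because validation
must never fail on a lookup.  Tables serialize losslessly to JSON and
CSV.  Tables for arbitrary ordered peak-pair ratios (i-th vs j-th)
can be built the same way.

## Cluster validation

For each non-monoisotopic peak p′ of a putative cluster, the observed
ratio of monoisotopic to p′ abundance is bracketed assuming both
abundances carry noise n = a/sn: [max(a₁−n₁, 0)/(a₂+n₂),
(a₁+n₁)/max(a₂−n₂, ε)].  The linear noise model is a design choice —
what matters behaviourally is that the bracket contains the point
ratio and widens monotonically as S/N drops; peaks without an S/N
estimate get sn = ∞ (the strictest, point-ratio reading, logged).
The bracket is compared with the [p_low, p_high] = [0.005, 0.995]
quantile interval for the cluster's mass, taken as monoisotopic
m/z · charge (a neutral-mass approximation that ignores the proton
mass — well below the 50 Da window resolution).  On non-overlap the
cluster splits at p′: a prefix of ≥ 2 peaks is kept as validated
(yielding two clusters for overlapping-cluster deconvolution), a
1-peak prefix is released as an unannotated peak (the hydrogen-loss
case), and the suffix starting at p′ is revalidated as a new putative
cluster; suffixes that shrink below 2 peaks are released (the
underestimated-trailing-peak case).  The retained prefix is not
re-checked — its comparisons already passed against the correct
monoisotopic peak.  Only monoisotopic-to-p′ ratios are compared,
never consecutive-pair ratios.

## Performance measures

Isotope coverage is |cluster peaks| / |peaks| (0 with no peaks).  PPS
is reliable²/non-reliable with reliable = cluster members; when no
peak is non-reliable the score is reliable² (so perfect tables score
high instead of erroring).  The default expectation rule flags a
non-cluster peak when its intensity divided by the median mono/1st
ratio at its mass exceeds the weakest detected intensity — i.e. its
first isotope peak should have been detectable.  The rule is
pluggable, since "expected" is defined differently by different
optimization frameworks; the chosen rule is scale-invariant under
uniform intensity scaling.

## Synthetic data

**Reference spectrum.**  The six bundled clusters carry the printed
centroid masses and intensities digit for digit, share one retention
time, and default to sn = ∞ so that noise stays a controlled variable
in validation experiments.

**Raw maps.**  Planted compounds elute as Gaussians (default
σ = 5 s, 1 s scans); each isotopologue's apex is the compound apex
scaled by its theoretical relative intensity; centroid m/z jitter is
Gaussian (0.002 Da default); the noise floor is uniform on
[0, 2·noise_level] (median = noise_level = 100 counts), with a
configurable number of noise centroids per scan.  A ground-truth
ledger records every planted isotopologue with its apex and true
S/N = apex/noise_level.  Simulated conditions for the
recovery/specificity experiments use a 60 Da m/z band with ~100 noise
centroids per Da per scan so that the noise floor is actually sampled
inside ROI windows — the property that makes local S/N estimation
meaningful — and compound apexes chosen so first-isotope peaks fall
between the relaxed (6.25) and traditional (25) thresholds.  What the
maps do *not* emulate: chromatographic tailing, detector saturation,
correlated (chemical) noise, profile peak shapes, and mass-dependent
resolution; passing these tests therefore shows the targeting logic
is sound, not that a particular instrument will match the reported
recovery rates.

**Formula database.**  Random formulas are generated from a
compound-class mixture (generic metabolites 50%, sugar-like 15%,
nucleotide-like 10%, lipid-like 20%, sulfur-rich 5%), because
heteroatom content is *correlated* in real chemistry — nucleotides
combine high N, high O, and phosphate; lipids are carbon-rich and
oxygen-poor.  Each class fixes H/C and heteroatom/C ratio ranges and
a phosphorus count distribution; chlorine (8% of compounds,
geometric counts) and bromine (1%) occur across classes, mirroring
the halogenated fraction of real small-molecule databases — without
them, no lower ratio quantile could ever accommodate a ³⁷Cl₂-driven
second isotope peak, and validation would wrongly split chlorinated
compounds.  Boron is deliberately absent, as in common compound
databases.  An element profile rescales per-element presence (zero
removes an element).  The bundled default tables are prebuilt from
20,000 such formulas (50–1000 Da, seed 1, window 50 Da); rebuilding
them takes ~15 s with `scripts/build_default_quantiles.py`.

## Numerical choices and degenerate inputs

* Δm = 1.003355 Da is stored once and shared by ROI prediction,
  detection, and isotope-number assignment.
* Empty peak tables propagate to empty outputs and zero metrics, not
  errors; fewer than two peaks can never form a cluster.
* ROIs outside the raw map are skipped with a log entry; traces with
  fewer than 3 in-ROI scans are ignored.
* Validation intervals with ε = 10⁻¹² guard division when a peak's
  noise estimate reaches its abundance.
* All stochastic components (noise ROI sampling, simulations, formula
  generation) take explicit integer seeds and are reproducible
  bit-for-bit; CLI outputs for a fixed config and seed are
  byte-identical.

## Known limitations

* The chain search is exhaustive per start peak; extremely dense
  pseudospectra (hundreds of mutually compatible peaks at one
  retention time) would be slow.
* Quantile tables are only as representative as the formula list
  behind them; the bundled synthetic tables approximate a generic
  small-molecule database and should be rebuilt from a domain list
  (e.g. a lipid database for lipidomics) for specialised work.
* Validation assumes the monoisotopic abundance estimate is
  trustworthy; a saturated monoisotopic peak shifts every ratio and
  can cascade splits.
* The lightweight ROI examination is not a replacement for a full
  wavelet-based feature detector on real data; it exists to make the
  targeting stage testable end to end.
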