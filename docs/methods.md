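# Methods

This note records the models, parameter choices and numerical conventions
behind each stage of the pipeline, what the synthetic generators do and do
not emulate, and the known limitations.

## Coordinates and data containers

All transcript coordinates are 1-based with inclusive interval ends, the
convention of mutagenesis nomenclature (an interval (936, 1049) spans 114
nt). Splice variants are built by interval arithmetic over a base
transcript: deletions remove inclusive intervals, substitutions replace
single bases, and insertions of unknown sequence (such as a variable exon
whose sequence is not modelled) are stored as opaque segments that
contribute length but map to no base coordinate. The variant object retains
the full per-position map to base coordinates, so mutant positions can
always be reported in reference numbering.

Reactivity profiles hold one float per nucleotide with NaN as the in-memory
no-data marker, so missing values poison arithmetic instead of silently
entering statistics; on disk NODATA is written as −999, the common probing
convention. Secondary structures carry a nested pair layer (non-crossing,
enforced with a stack check) plus one pseudoknot layer used for kissing-loop
output; dot-bracket uses `()` and `[]` respectively.

## Reactivity processing

**Box-plot normalization.** Finite values above Q3 + 1.5·IQR are outliers,
but at most 10% of the finite values are removed; the normalization factor
is the mean of the top decile of the survivors and all finite values are
divided by it. This is the standard box-plot convention of SHAPE
normalization scripts; the alternative 2%/8% rule (exclude the top 2%,
average the next 8%) is available as `method="percentile_2_8"`. The rule is
scale-invariant and idempotent (a second normalization returns factor 1).

**Classification.** SHAPE boundaries 0.40 / 0.85, HRF boundaries
0.29 / 0.58 / 0.86. Intervals are closed on the left and the top class is
strictly open above its boundary, so 0.40 classifies as moderately reactive
and 0.85 also classifies as moderately reactive ("very reactive" requires
> 0.85). The literature leaves the membership of exactly 0.40 ambiguous;
assigning boundary values upward-closed at the bottom and downward-closed at
the top is this package's documented choice, and boundaries are configurable
per scheme.

**Merging, scaling, differencing.** Overlapping primer reads are averaged
arithmetically over finite contributions (order-invariant); cross-sample
scaling uses the slope-through-origin least-squares factor
Σtr/Σt² over positions finite in both profiles; reagent differencing
(e.g. NMIA − 1M6) is a centered window mean of the difference, default
window 3 nt.

**MaP rates.** Raw reactivity is the modified-channel mutation rate minus
the untreated rate; positions with depth below `min_depth` (default 1,000
reads — a conventional mutational-profiling depth filter, configurable)
become NODATA. Negative raw values are retained and only resolved at
normalization, preserving the information that background exceeded signal.

## Probing-directed folding

The energy model is a deliberately simplified nearest-neighbour scheme:
a stacking table keyed by adjacent pair types (derived from per-pair
strengths GC 2.2, AU 1.1, GU 0.7 kcal/mol; every canonical stack is
negative), affine hairpin/bulge/internal-loop penalties, and an affine
multiloop term (a + b·branches + c·unpaired). It is not the Turner 2004
rule set: the scientific surface here is internal consistency (dynamic
program versus exhaustive enumeration) and planted-structure recovery, not
replication of any specific folding server, and every term is replaceable
through `FoldingParams`.

The probing restraint is the Deigan-style pseudo-energy
m·ln(S+1) + b charged once per paired nucleotide (not per stack
participation — the simpler variant), with m = 2.6, b = −0.8 kcal/mol as
widely used defaults; NODATA positions contribute zero. Values below −0.3
are rejected as beyond plausible probing noise.

MFE folding is a Zuker-style dynamic program over V/WM/WM2 matrices with
minimum hairpin loop 3 and interior loops capped at 30 unpaired nucleotides
(the cap never binds at oracle-test sizes, so DP and enumeration agree
exactly there). The partition function is a McCaskill-style inside–outside
computation over the same model at kT = 0.6163 kcal/mol (37 °C); pair
probabilities are exact for the model, per-position normalization holds to
10⁻⁶, and Shannon entropies use log base 10, the convention of probing
pipelines that plot entropy alongside reactivity. The outside pass is
O(n⁴) in the worst case; the hard length cap is 2,000 nt but the intended
regime is the few-hundred-nucleotide scale used in the tests. Windowed
folding of very long RNAs is out of scope: every sequence is folded in one
window.

## Differential probing

The caller follows the published deltaSHAPE procedure with every constant
exposed: both profiles are smoothed (centered mean, default 3 nt), the
difference Δᵢ is screened by the Z-factor 1 − z·(σ_ex,i + σ_in,i)/|Δᵢ|
(z = 1.96) and by the standard score of Δ (cutoff 1.0), and a site rule
demands ≥ 3 passing positions within a 5-nt window. Standard errors default
to per-replicate SD/√n when replicates exist, else a configured constant.
Positive Δ (more reactive after protein removal) is reported as protection
in vivo. Calls are invariant to a common additive shift and swap direction
under input exchange. The published parameter choices for this procedure
are not printed anywhere authoritative, so the defaults replicate the
reference tool's and are all configurable.

## Kissing-loop discovery

Hairpin loops are the unpaired runs closed by innermost nested pairs. The
scanner slides a k-nt window (default k = 5, the motif length) over each
loop and tests antiparallel complementarity against every distal window
that is (i) at least `min_distance` = 100 nt away — the long-range
constraint — and (ii) single-stranded in the input structure (0 paired
positions tolerated by default, because a repeat engaged in the pseudoknot
must be free in the secondary structure; relaxable for noisy structures).
G·U wobble pairs are accepted by default: the wild-type interaction this
models contains a wobble, and its rescue (loop G→C answered by repeat U→G)
is only expressible with wobble awareness. Registers are reported 5′→3′ and
labelled TR1…TRn; registers sharing loop positions are merged into
mutual-exclusivity groups by union-find — the tool reports all alternative
registers and never chooses among them.

Compensatory design replaces the repeat base paired with a mutated loop
position by the Watson–Crick complement of the new loop base; enumerating a
group yields one double mutant per register, and re-scanning the doubly
mutated sequence restores each register's full pair count (a closure
property used as a test).

Repeat-count conservation degaps each alignment row and counts windows
complementary to the motif (wobble-aware), passing at a configurable
minimum (default 3). Counts are lower-bounded by the planted copies; the
evolved background can contribute extra complementary windows, as real
genomes do.

Covariation is scored per column pair as
fraction-canonical + 2·compensatory-fraction, where compensatory rows are
canonical but differ from the modal pair at both columns. Significance uses
a permutation null that shuffles each column independently (preserving
composition); the E-value is the per-pair permutation p-value times the
number of pairs tested. This is an explicit, simplified stand-in for
dedicated covariation statistics (R-scape-class methods are out of scope);
it is meant for ranking and sanity checks, not for publication-grade
significance claims, which for small alignments are debatable anyway.
Only structure-annotated pairs plus caller-supplied candidates are tested,
not all column pairs.

## AFM particle analytics

Square height-map crops (defaults 250 nm side, 0.98 nm/pixel → 255 px) are
reduced to a one-dimensional PSD row by row along the fast-scanning axis
(columns when `axis="y"`), with per-row mean detrending, no window function
(a Hann-windowed variant would only matter for strong low-frequency leakage,
absent here), and one-sided scaling such that the power over f > 0 sums to
the mean row variance (discrete Parseval). Spectra are averaged over rows
and particles.

The additive white-noise floor is estimated as the median power of the
top-quartile frequencies and subtracted before fitting; bins within 20% of
the floor are dropped. Auto-affine ranges default to: plateau = frequencies
within 10^−0.5 of the plateau level; flank = the band where corrected power
is 10⁻³–10⁻¹ of the plateau. Because the analysis is known to be sensitive
to these "arbitrarily selected" x-ranges, every fit records its range and
the auto-selection is overridable. The crossover of the two log–log lines
gives f\*; the characteristic length is reported as L = 1/f\* in the
cycles/nm convention, with the angular 2π/k convention selectable and the
convention string attached to every result (the two differ by 2π, so it
must always be reported).

Calibration: a compact particle is a Gaussian dome whose *diameter* is
defined as the 5σ apparent footprint (the dome has decayed to ~4% of its
peak, i.e. into the background). With the default flank band, the analytic
crossover for a Gaussian flank lands at f\* ≈ 0.19/σ, i.e. L ≈ 0.97·d —
the characteristic length estimates the footprint diameter essentially
unbiased, verified on simulated fields (within 15% at 30 nm; rank-correlated
ρ = 1.0 across 15–85 nm). Resolving the plateau requires the crop to exceed
the particle several-fold; the 85-nm regime needs a 500-nm crop.

## Mg²⁺ titration

The folding isotherm is the Hill form
R_h(c) = R_∞ + (R₀ − R_∞)/(1 + (c/C_half)ⁿ) — the standard cooperative
RNA-folding isotherm, which reduces to the midpoint definition of C_Mg1/2
(R_h(C_half) is exactly halfway). The two-state linear alternative was
rejected because it has no defined cooperativity and fits log-spaced
titrations poorly. Fitting is bounded nonlinear least squares
(scipy `curve_fit`) initialized from the data extremes and the concentration
nearest the midpoint; at zero noise all four parameters are recovered to
10⁻⁶ and bias is < 2% across random truths. A rising trend is flagged as
expansion but still fitted; a midpoint outside the measured range is
flagged. Construct comparison reports 100·(R_∞,b − R_∞,a)/R_∞,a (positive:
b compacts less); the denominator makes the swap antisymmetric only to
first order, which is documented on the function.

## Synthetic data: what it emulates, and what it does not

The generators plant exactly the statistical structure each analysis
assumes, with one seed controlling all draws:

* **Core transcripts** (default 320 nt; a 1,595-nt layout with the published
  domain/motif/repeat coordinates is provided): stems are perfect reverse
  complements, the loop motif (GUGAG) sits in a hairpin loop, and n tandem
  repeats (default 6, back-to-back, mirroring the dense natural repeat
  block) are the wobble-aware reverse complement of the motif. The random
  background is scrubbed so no accidental complementary window survives in
  any single-stranded region — the planted registers are provably the only
  ones, which is what makes the scanner's exact-recovery oracle meaningful.
* **Reactivities**: paired ~ Exponential(mean 0.15), unpaired ~ Gamma(2,
  0.5), clipped at 4.0, 5% NODATA. These reproduce the three-class occupancy
  pattern of normalized SHAPE data (> 70% of paired positions below 0.40)
  without claiming any experiment's actual noise, which the literature does
  not parameterize. MaP counts are Binomial(depth, 0.002 + 0.02·S) against a
  0.002 background — typical mutational-profiling magnitudes.
* **Protection pairs** add a planted reactivity gain to the ex vivo profile
  inside protection windows plus Gaussian noise (default sd 0.05).
* **Alignments** use a star phylogeny (independent descendants of one
  ancestor): the simplest model with tunable pairwise covariation. Paired
  columns co-substitute to a canonical pair differing at both positions
  with probability `covary_prob`; the motif is invariant (as in the real
  family) and each species keeps 3–6 repeat copies.
* **AFM fields**: Gaussian domes (compact), dome chains across an 85-nm
  envelope (intermediate; dome diameter 30 nm as in the multi-domain
  intermediate state), or a thin meandering filament (denatured), plus
  0.02-nm white pixel noise; dome amplitude 1.5 nm, a plausible RNA height —
  PSD length conclusions depend on lateral scales, not amplitude.
* **Titrations** follow the Hill form exactly, on a log grid over
  0.01–100 mM.

What they do **not** emulate: electropherogram traces and read-level
sequencing artifacts (primer dropoff, PCR bias), phylogenetic tree
structure and indels, AFM instrument artifacts (stripes, tip convolution,
plane tilt), and any correlation between probing noise and local sequence.
Tests passing on this synthetic data therefore demonstrate correctness of
the computations under the stated statistical assumptions, not robustness
to every artifact of real experiments.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately compact
instances — 320-nt cores (the published-coordinate 1,595-nt layout is
exercised once), folding oracles at ≤ 22 nt where exhaustive enumeration is
feasible, a 150-nt core for planted-structure recovery, 500-nt profile
pairs (1,000 null replicates), 15–20 particles per AFM condition, 100
titration replicates — sizes chosen so every stochastic claim is averaged
over enough replicates to be stable while the whole suite stays fast. All
randomness flows through explicit integer seeds; identical seeds give
identical outputs on any platform with the same numpy.

## Known limitations

* The folding model's absolute energies are not comparable to
  Turner-parameter software; only relative/structural conclusions are
  meaningful, and cross-algorithm reproducibility of real folds is left to
  the user.
* The covariation E-value is a permutation stand-in, not a calibrated
  phylogeny-aware statistic.
* The pair-probability outside pass scales as O(n⁴); probabilities and
  entropies are intended for sequences of a few hundred nucleotides.
* The scanner annotates pseudoknots post hoc on a fixed secondary
  structure; it performs no thermodynamic scoring of kissing-loop stability
  and no 3D modelling, and deliberately reports all mutually exclusive
  registers instead of choosing one.
* Characteristic-length extraction assumes an isolated particle population
  on a flat background; crops must exceed the particle size several-fold or
  the plateau is unresolvable.
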