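# Methods

## Background and scope

Free-flow electrophoresis (FFE) separates microsomal membrane vesicles in
a laminar buffer film by net surface charge; fractions collected along the
anode–cathode axis are enriched for different subcellular membranes. When
each fraction is quantified by data-independent-acquisition mass
spectrometry, every protein acquires an abundance profile across the
fraction axis — a "digital western" — and co-fractionation with curated
marker proteins localizes it. `ffeprof` implements the analysis half of
such an experiment: pooling and normalization of the raw fraction matrix,
marker-consensus profile construction, correlation-based compartment
assignment, bimodal-profile (dual-localization) detection, discordance
flagging against prior annotation, and transmembrane/category summaries.
Everything upstream of the quantification table (instrument processing,
spectral libraries, BLAST/database lookups, TM predictors) is consumed as
pre-parsed TSV input, never executed.

## Processing chain

1. **Pooling.** Adjacent fractions are physically combined in the wet
   protocol, so pooling is *summation*: pooled sample `s` aggregates
   fractions `k(s−1)+1 … ks` (default `k = 2`, 96 → 48). Total signal per
   protein × replicate is conserved exactly, which the tests assert
   integer-exactly.
2. **Analysis window.** The largest contiguous run of pooled samples with
   OD280 strictly greater than zero. With absorbance positive over
   fractions 15–70 this is pooled samples 8–35 (28 samples). Ties between
   equal-length runs go to the lower (anodic) run. Window selection is
   idempotent.
3. **OD280 normalization.** Each (protein, sample, replicate) peak area is
   divided by that pooled sample's OD280, correcting for per-sample protein
   load, *before* replicate averaging (quantification-level normalization).
   Whether normalization precedes or follows averaging is not observable
   from the final profiles when replicates share one OD trace; placing it
   first keeps replicate dispersion on the normalized scale.
4. **Replicate averaging.** Arithmetic mean over replicates per
   (protein, sample); dispersion is the per-sample SD. Zero (non-detected)
   cells are *included*: dropping them would bias bimodal profiles toward
   their better-covered population. Replicates in which a protein is
   entirely undetected are logged as low-coverage.
5. **Unit normalization.** Profiles are scaled to unit sum so that only
   shape is compared; all-zero profiles pass through flagged and are never
   assigned.

## Compartment consensus

The consensus profile of a compartment is the element-wise **median** of
its detected markers' unit-sum profiles, renormalized. Median rather than
mean: curated marker lists contain documented isoform-specific outliers
(e.g. V-ATPase subunits whose cathodic Golgi-region population dominates
their tonoplast signal), and the median ignores a minority of such
profiles. Markers absent from the run are skipped, not imputed. A
coherence report gives the median and minimum pairwise Pearson correlation
per compartment; markers whose median correlation to their peers falls
below 0.5 are listed as outliers. They are *not* excluded from the default
consensus (curated lists are used as-is); `build_consensus_robust`
excludes them on request.

## Assignment

Each profile is scored against every consensus by Pearson correlation
(scale-free on unit-sum profiles; the standard protein-correlation-
profiling choice). A protein is assigned to the argmax compartment iff
best r ≥ `r_min` (default 0.8) **and** the margin over the runner-up is
≥ `margin_min` (default 0.1); otherwise `unassigned`. Exact ties are never
broken arbitrarily: they yield `unassigned` with a tie flag. The two
thresholds are configurable defaults, not experimentally derived
constants.

## Population detection

A profile's populations are found on a 3-sample moving average
(zero-padded): local maxima with topographic prominence ≥ 10% of the
smoothed profile's global maximum are retained, basins between adjacent
peaks are cut at the smoothed minimum (the boundary sample's raw mass is
split evenly between neighbors, making the output exactly invariant under
profile reversal), each population's mass is the raw profile mass over its
basin, its peak is the raw argmax inside the basin (interior basin
boundaries excluded), and populations with mass < 15% are discarded. The
15% mass floor separates a genuine minor population from noise; it is a
design parameter chosen so the canonical minor tonoplast population
(~25% of tonoplast mass at sample 24) survives comfortably while
single-sample noise excursions do not.

## Dual localization and discordance

A compartment's *characteristic windows* are the contiguous sample runs
where its consensus exceeds half its own maximum (a bimodal consensus has
two windows). A population maps to its assigned compartment whenever that
compartment's windows contain the peak — a bimodal compartment's own
second population is not evidence of dual localization — otherwise to the
in-window compartment with the highest consensus value at the peak, or to
none. `dual_flag` is raised iff two populations map to different
compartments. `discordance_flag` is raised iff the profile assignment
differs from the prior annotation, preferring the experimentally verified
(high-confidence marker) compartment over the consensus prediction;
unassigned and unannotated proteins are never flagged.

## Synthetic data generator

The generator emulates the study conditions so every downstream stage is
testable without the deposited raw data:

- **Mobility templates.** Each of the eight compartments is a 1- or
  2-component Gaussian mixture on the pooled-sample axis, evaluated at
  integer samples and renormalized (delta limit handled for width → 0).
  Centers and windows transcribe the described marker behavior: tonoplast
  major 13–19 + minor at 24; ER 18–20 and 23–25; Golgi 23–24; TGN
  concentrated at 24; chloroplast envelope 23–25; thylakoid high at 20
  plus 23–24; mitochondria low at 20 plus a 23–25 population; PM 24–30
  peaking at 25. Widths and weights are not reported anywhere and were
  fixed once, at design time, under three requirements: every stated peak
  lies inside its compartment's half-max window, the number of modes of
  each noise-free profile equals its template's peak count at the default
  detection settings, and the worst pairwise Pearson correlation among
  the eight templates stays ≤ 0.83 so that marker-based assignment is
  well-posed. The mitochondrial sample-20 weight (0.25) is the smallest
  value that clears both the half-max and the 15% mass-floor constraints
  while honoring the qualitative "much lower than thylakoid" description.
- **Abundance and noise.** Per-protein abundance is log-uniform over two
  orders of magnitude (so normalization is non-trivially exercised); each
  protein × fraction × replicate cell gets independent multiplicative
  lognormal noise parameterized by its CV (mean-one:
  σ² = ln(1 + cv²), μ = −σ²/2). The default CV of 0.20 is a free
  parameter — the study reports no within-replicate dispersion — set to a
  typical DIA peak-area CV. Non-detections are zeros, not NA, matching
  DIA export semantics.
- **Geometry.** Profiles are emitted at fraction level by splitting each
  pooled sample's mass equally over its two member fractions, so pooling
  recovers the pooled template exactly and the noise-free chain is exact
  end to end. The OD280 trace is a smooth arch, strictly positive exactly
  inside fractions 15–70 and zero outside, with mild amplitude (≈1.5×
  across the window) — enough to exercise normalization without moving
  template modes. Raw peak areas do not include a per-sample loading
  factor, so OD division mildly reshapes profiles; targets and markers
  are reshaped identically, which keeps the comparison internally
  consistent, exactly as in the real pipeline.
- **Dual localization.** A configurable fraction of proteins receives a
  second, randomly chosen compartment mixed at weight 0.3. Ground truth
  records compartments, weights, and template peaks.

**What the generator does not emulate:** peptide-level roll-up, retention
times and spectral interference, batch effects between replicates,
correlated (structured) noise, partial marker contamination between
compartments, and electro-kinetic physics. Recovery results on synthetic
data therefore demonstrate the correctness and calibration of the
*analysis*, not the biological error rate on real runs, where marker
coherence and compartment separability are worse.

## Recovery evaluation

`evaluate` reports assignment accuracy and the false-dual rate over
singleton proteins, population-count accuracy against template peak
counts, and dual-detection sensitivity over **well-separated** planted
duals: those whose secondary compartment contributes a template peak at
least 5 samples from every peak of the primary *and* carrying mixture
mass ≥ the 15% detection floor. Duals outside this set (e.g. a Golgi
secondary under a tonoplast primary, whose peak coincides with the
tonoplast's own minor population) are geometrically unresolvable by peak
positions at these settings and are reported separately rather than
counted as misses. At the study conditions (8 compartments, 100
proteins/compartment, CV 0.2, 3 replicates) the resolvable pairings are
cathodic primaries with a tonoplast secondary, whose anodic 0.3 × 0.75
population is well above the floor.

## Problem sizes and numerical choices

Simulations used in the tests and the acceptance script run 8–100 proteins
per compartment (up to 800 proteins × 96 fractions × 3 replicates), sizes
at which every stage is exercised end to end while the full suite stays
interactive. Unit-sum checks use 1e-9 tolerance; Pearson scoring matches
the covariance formula to 1e-12; pooling conservation is exact. Degenerate
inputs (all-zero profiles, constant profiles, single-marker compartments,
empty windows) return flagged values or typed errors, never silent
coercion.

## Known limitations

- Assignment is single-label; the mixture weights of a dual-localized
  protein are summarized by population masses, not deconvolved (no
  probabilistic mixture modeling by design).
- Compartments whose templates are strongly collinear (Golgi vs TGN vs
  chloroplast envelope in the cathodic cluster) are distinguished by
  profile shape alone; with noisier real data the margin rule will leave
  more of these unassigned rather than guess.
- Profiles peaking outside all compartment windows (e.g. an unbound
  soluble protein released into anodic samples 8–14) map to no
  compartment; no dedicated "soluble" class is modeled.
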