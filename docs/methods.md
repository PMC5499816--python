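# Methods

This note records the models implemented in catackit, the defaults that
matter, and the design choices made where more than one reasonable option
existed.

## Motif model

The CATAC element is modelled as a 29-position probability matrix with an
explicit mononucleotide background. From `n` aligned sites, position
probabilities are estimated with background-weighted Laplace smoothing,

    p_i[b] = (c_i[b] + A·q[b]) / (n + A),

with total pseudocount weight `A = 0.5` by default — enough to keep every
log-odds finite without visibly distorting well-populated columns. The
background defaults to uniform; pass the empirical composition of the scanned
sequence set when scanning genomic DNA (`catackit.dna.empirical_background`).

Windows are scored by the log base-2 odds ("bit score") and a scan reports
every window strictly above 5 bits on either strand, with coordinates always
on the forward strand (0-based, half-open; BED score column = bits × 100).
Overlapping same-strand hits are resolved greedily by descending score with
leftmost tie-breaking. The 5-bit threshold is applied per window on each
strand; both-strand scanning is the default.

Matrix refinement against unaligned sequences uses a ZOOPS
(zero-or-one-occurrence-per-sequence) expectation–maximisation: each sequence
carries a motif occurrence with prior probability γ (estimated, initial 0.5)
placed uniformly, all other bases drawn from the background. The E-step is
exact enumeration over placements; the M-step re-estimates probabilities from
responsibility-weighted counts with the same smoothing. The data
log-likelihood is non-decreasing across iterations; iteration stops when the
improvement falls below `tol` (default 1e-6) or at `max_iter` (100), in which
case the returned matrix is flagged unconverged rather than rejected. This
single-motif EM stands in for single-motif hidden-Markov-model training; at a
fixed threshold the windowed log-odds scan is equivalent for site calling, so
the HMM machinery is used for training only.

Promoter-set enrichment treats a gene as motif-positive when at least one hit
overlaps its promoter window by ≥ 1 bp (a hit spanning two windows counts for
both genes), and reports the one-sided hypergeometric tail
P(X ≥ observed positives in the set) over the promoter universe, plus the
fold ratio of positive fractions. The exact test's p-values are discrete and
conservative near the null; the calibration test in the suite therefore
uniformises them with the standard randomized-tail transform before comparing
with U(0,1).

## Construct toolkit

Reporter enhancers multimerise four native CATAC elements. Their
oligonucleotide sets are assembled into the top strand by detecting maximal
complementary overlaps between consecutive oligos (trying both orientations).
Exact suffix–prefix overlaps are preferred; when none of at least 10 bp
exists, an overlap-alignment dynamic programme tolerating ~10% edits is used,
scoring candidates by overlap length minus three per edit — some published
oligo sets disagree with their partner strand by a residue, and annealing
tolerates such bulges.

Elements are located by the core consensus rather than fixed offsets, because
published oligos carry cloning flanks and do not mark element boundaries: any
29-base window (either strand) whose residues 8–17 carry at most 2 IUPAC
mismatches to `TRCGCATACG` is an element, reported in motif orientation with
its original strand recorded; overlaps resolve greedily by ascending
mismatch count. The cap of 2 recovers all eight wild-type elements in the
packaged *Pdp1*/*Slob* sets while rejecting every mutant element (which carry
four core transversions) — that separation is itself under test. Consensus
scores are plain per-residue IUPAC matching (R matches A or G) with no
position weighting; E-box tallies are reported against both `CRCGTG` and the
canonical `CACGTG`.

The mutation operator swaps A⇄T and C⇄G at 1-based motif residues
8, 10, 14, 16, 21, 23 — an involution that changes exactly six residues.
Published mutant oligo sets are treated as data (they contain flank
differences beyond the six element mutations), not as expected outputs of the
operator.

One printed tally could not be reproduced: with these rules the *Slob*
enhancer's four E-boxes carry 7/24 mismatches to `CRCGTG`, not the published
8/24, while the three companion tallies (9/24 and 4/24 canonical, 2/24 for
*Pdp1*) agree exactly; the `pdp1_pse` construct, designed to copy *Slob*'s
E-box fidelity, also computes 7/24. No uniform counting rule we tried
(strict R, shifted E-box window, alternative element registers) reproduces
all four published numbers simultaneously, so the implementation keeps the
stated rules and the discrepancy is surfaced by a deliberately failing
acceptance check.

## Rhythm analysis

Per-fly luciferase recordings are analysed in three stages.

**Preprocessing.** The first 24 h of each recording are discarded (freshly
fed luciferin produces an excess of active luciferase that settles over the
first day) along with any light-phase samples; fitting requires ≥ 48 h of
remaining darkness data.

**Detrending.** A centred running mean of width 24 h (edge-truncated window)
is subtracted. For a pure cosine on a uniform grid this scales the amplitude
by 1 − D, with D the normalised Dirichlet kernel of the window — ≈ 0.96 for a
24-h window on a 24-h cosine, so the circadian component passes essentially
unchanged. Within half a window of either end the truncated window biases the
trend estimate and injects low-frequency artifacts; the pipeline therefore
trims 12 h from each end before fitting (measured effect: noiseless 24-h
recovery is exact with trimming and ~0.4 h biased without).

**FFT-NLLS.** The model is a constant plus K cosines,
`y(t) = c + Σ A_k cos(2π(t − φ_k)/T_k)`. Components are added iteratively:
the residuals are linearly interpolated onto a uniform grid (the
least-squares refit itself always uses the native, possibly jittered
timestamps), the dominant spectral peak seeds the next component's period,
amplitude and phase, and all components plus the constant are refit jointly
by bounded nonlinear least squares. Parameter covariance comes from the
linearised Jacobian at the optimum; amplitude and period 95% confidence
half-widths use the t quantile at the residual degrees of freedom.

A new component is kept only if its amplitude is significant. Because a
free-phase cosine amplitude is a two-degree-of-freedom quantity (its null
distribution is Rayleigh, not half-normal) and the candidate is selected as
the best of ~n/2 spectral bins, the acceptance bound is
`Â > sqrt(2·F⁻¹(1 − 0.05/m; 2, dof))·se(Â)` with m the number of candidate
bins — a Bonferroni-corrected harmonic F test. A naive 1-df 95% bound
accepted a spurious component in ~35% of pure-noise traces; the corrected
rule restores a ~5% familywise rate, and with it ~96% of pure-noise flies are
classified not-rhythmic. Iteration stops at the first rejected component or
at 4 components.

The circadian component is the highest-amplitude accepted component with
period in 15–35 h. RAE is its 95% confidence half-width divided by the
amplitude estimate (the half-width reading of "ratio of the 95% confidence
interval to the amplitude"; using the full width would double every RAE).
Classification: RAE < 0.7 rhythmic; 0.7 ≤ RAE ≤ 1 weakly rhythmic; RAE > 1,
no circadian component, or optimiser failure → arrhythmic. Group summaries
report class percentages over all flies and mean ± SEM of RAE and circadian
period over rhythmic plus weakly rhythmic flies only.

Group comparisons: chi-square on the 3-class rhythmicity table (classes empty
in all groups are dropped), two-sided Mann–Whitney U on expression levels
(per-fly raw counts at the sample nearest 6 h after darkness onset, ± 1 h),
and Welch's heteroscedasticity-robust ANOVA with Tamhane's T2 post-hoc
(pairwise Welch t with Welch–Satterthwaite degrees of freedom and Šidák
adjustment). Welch/Tamhane are implemented in-package; no installed library
provides Tamhane T2, and the in-package Welch ANOVA is cross-checked against
an independent implementation in the test suite.

## Comparative-Ct analysis

Relative expression per matched (timepoint, replicate) pair is
`2^−(Ct_target − Ct_ref)`; replicate pairing follows the experimental design in
which each timepoint's replicates are independent fly groups sharing one RNA
sample across primer sets. Profiles are normalised so that the mean of
per-timepoint means equals one ("normalisation to the time course average");
SEMs scale by the same factor. Rhythmicity across timepoints is tested with
Kruskal–Wallis (standard tie correction) on normalised replicate values — the
rank test is invariant to the global normalisation — and the peak is the
timepoint with the highest mean (leftmost on ties). The last timepoint (CT24)
is a distinct sample, not wrapped onto CT0.

## Synthetic data

The generators produce the statistical structure the analyses assume, fully
determined by an integer seed.

**Traces.** Counts are a settling trend plus cosines plus Gaussian noise,
floored at zero:

    trend(t) = baseline·(f + (1 − f)·e^(−t/τ)),   f = plateau_fraction

with defaults baseline 200 counts, τ = 12 h, f = 0.5 — the trend settles from
the full baseline onto a persistent plateau of half of it, mimicking the
decay of previously synthesised luciferase onto a steady feeding level. (A
trend that decays all the way to zero would push the cosine into the zero
floor late in the recording and clip its amplitude; the plateau keeps
amplitude recovery well-posed while the degenerate case τ → ∞ still gives a
constant trace at baseline.) The circadian cosine has period 24 h, amplitude
50 counts and peak 4 h; a 12-h component of amplitude 10 is modelled as the
second harmonic phase-locked to the 24-h component, the simplest reading of a
two-peaks-per-day pattern. Sampling is hourly with uniform ±20% interval
jitter over 168 h, with a 12-h light head before darkness. Noise SD defaults
to 10 counts (20% of the circadian amplitude); neither noise magnitude nor
per-fly amplitude variability is constrained by published values, so these
are free, fixed defaults. Counts are truncated at zero rather than made
Poisson: amplitude recovery, not photon statistics, is the test target.

**Promoters.** Background bases are i.i.d. with a given GC fraction (default
0.43, fly-like); motif instances are drawn position-independently from the
matrix, planted without overlap on a uniformly random strand, and recorded in
a BED-style truth table with their bit scores.

**Ct tables.** The target's Ct follows
`Ct(t) = μ_target − a·cos(2π(t − peak)/24)` plus replicate noise; the
reference is flat. Defaults: timepoints CT0/6/12/18/24, 4 replicates,
amplitude 1 cycle (a 4-fold peak-to-trough expression range), peak CT6,
replicate SD 0.3 cycles.

What the generators deliberately do not emulate: luciferin pharmacokinetics,
plate-position effects, light-phase masking, photon-counting statistics,
per-fly parameter heterogeneity, amplification-efficiency differences between
primer pairs, and any sequence structure beyond mononucleotide composition.
Passing recovery tests on these inputs shows the estimators are correct under
the stated model, not that real recordings satisfy the model.

## Problem sizes and numerics

Simulation-based checks use desk-scale sizes: 100 flies for null
calibration, 15–26 flies per cohort for recovery and power checks, 100
synthetic promoters (1 kb) for planted-site recovery, 10⁵ random windows for
the empirical null score tail, 200 replicates for the Ct power check. Seeds
are fixed in tests; the acceptance script derives all randomness from its
`--seed` flag.

Numerical details worth knowing: EM clips probabilities away from zero before
taking logs and works in log space with log-sum-exp; the NLLS uses
`scipy.optimize.least_squares` (trust-region reflective) with period bounded
in [2 h, 4 × span] and non-negative amplitudes; covariance inversion failure
or optimiser failure maps the fly to arrhythmic; BED output follows the
0-based half-open convention with the integer score column capped at
bits × 100; motif serialisation is MEME minimal text, readable by standard
motif tools (frequencies are quantised to the `nsites` resolution by readers
that reconstruct counts).

## Known limitations

- The EM refinement models at most one occurrence per sequence; tandem
  elements (as in the 4xCATAC constructs) violate ZOOPS and should be scanned,
  not refined against.
- Confidence intervals are linearised (Wald-type); for very short or very
  noisy traces the amplitude CI, and hence RAE, is approximate.
- The spectral seeding assumes jitter small enough that linear interpolation
  onto a uniform grid does not alias; heavily gapped recordings would need a
  Lomb–Scargle seeding step instead.
- Enrichment treats genes as exchangeable; promoter length or GC confounds
  are not modelled.
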