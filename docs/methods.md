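# Methods

This note documents the models behind each analysis stage, the synthetic
data they are validated against, the defaults that matter, and the design
choices made where more than one reasonable convention exists.

## Scene model and chromocenter quantification

Synthetic scenes are 2D fields of disc-shaped nuclei (radius default
40 px at 0.1 µm/px, i.e. 4 µm — typical of cultured mouse fibroblast
nuclei in cross-section) containing disc-shaped DNA-dense foci (radius
6 px).  The DNA channel is piecewise constant: 0 outside nuclei, the
nucleoplasm level (1 a.u.) inside, and contrast × nucleoplasm (default 3)
within foci; the reporter channel either co-enriches at foci
("colocalized", with its own enrichment ratio) or is flat across the
nucleus ("diffuse").  Gaussian read noise is additive and clipped at zero.
Foci counts are Poisson per nucleus (mean 6, in the range typical of mouse
chromocenters) with an exact-count override for constructing fixtures;
focus positions are uniform in the nucleus with non-overlap enforced by
bounded rejection.  Flat-top (unsmoothed) focus profiles are the default so
that ground-truth means and ratios are exact by construction; an optional
Gaussian blur approximates optics when wanted.  The generator does not
model 3D acquisition, point-spread functions or photon (Poisson) noise, so
passing tests demonstrate correctness of the measurement logic, not
robustness to every artefact of real microscopy.

Nuclei are segmented on the DNA channel (max projection for stacks) by
global Otsu thresholding, hole filling and a minimum-area filter
(20 µm²).  A DNA channel with bright chromocenters has a three-mode
histogram (background / nucleoplasm / foci) on which binary Otsu is
bistable; when it locks onto the foci mode and leaves no nucleus-sized
object, the segmenter falls back to the lowest of the two three-class Otsu
thresholds.  An `external_mask` path accepts and relabels masks produced by
other segmenters (e.g. a trained deep-learning model) without recomputing
them.

Foci are detected by a threshold computed independently within each
nucleus — Otsu on the nucleus's own pixel values by default, or
mean + k·SD (k = 2) — which makes detection invariant to absolute nuclear
brightness.  A constant-intensity nucleus has no defined threshold and
contributes no foci.  No background subtraction is applied outside nuclei.
The nucleoplasm is defined as the nucleus minus its foci, and the per-
channel measurements satisfy the exact decomposition
total = mean_foci · foci_area + mean_nucleoplasm · (nucleus − foci) in
pixel units; areas are converted to µm² only at output.

Nuclei are classified spotty / mixed / diffuse from the reporter
enrichment ratio with thresholds t_spotty = 1.5 and t_diffuse = 1.1.
These defaults were calibrated on synthetic scenes (a diffuse reporter has
ratio 1 by construction; colocalized reporters sit well above 1.5) and are
exposed in the configuration; published datasets classified by eye will
need their own calibration.

## FRAP model

A trace carries four aligned series — bleached spot, non-bleached control
spot, background, and time — with the first `n_prebleach` frames (default
5) preceding the bleach; the frame at index `n_prebleach` is T0.  The
double normalization divides out acquisition photobleaching via the
control spot and rescales by pre-bleach levels so 1 is the pre-bleach
fluorescence.  "Pre-bleach value" means the mean over all pre-bleach
frames of each series.  Because the equation uses the ratio of pre-bleach
means, the normalized pre-bleach mean equals 1 exactly only for noise-free
traces; with noise it is close but not identical (mean of ratios vs ratio
of means), and the value is returned for inspection rather than asserted.

The simulator renders frap(t) = A·Y(t)·e^(−λt) + B and
control(t) = A·e^(−λt) + B with shared amplitude A, acquisition bleach
rate λ and background B — both spots see the same illumination, which is
exactly why the control-ratio normalization cancels λ and B; this
cancellation is grid-tested to 1e−6.

Recovery is fitted with the two-phase association model
Y(t) = y0 + a(1 − e^(−k_f t)) + b(1 − e^(−k_s t)) by bounded least squares
(spans and rates ≥ 0, y0 free).  Initialization: y0 = first post-bleach
value; total span = mean of the last 10 points − y0, split 70/30
fast/slow; k_f = 0.1 s⁻¹, k_s = 0.01 s⁻¹; up to five multiplicatively
jittered restarts on optimizer failure, after which the result is returned
with `converged=False` and diagnostics rather than silently.  The
identifiability convention k_fast ≥ k_slow is enforced by swapping the two
phases after convergence.

Summary quantities follow the plateau-at-last-time-point convention: the
mobile fraction is 100 × Y(t_end) with t_end the last observed time (not
the asymptote, which is ill-determined when recovery has not plateaued);
immobile = 100 − mobile, exact in floating point.  T50 is the smallest
t with Y(t) = 0.5 on the normalized scale — half of the *pre-bleach*
level, not half of the plateau — located by bisection (valid because Y is
non-decreasing) to 1e−6 relative tolerance, and flagged absent when the
curve never reaches 0.5 in the window.  Batch summaries report both SD and
SEM across cells, labeled, since either dispersion convention is common.

Two canonical acquisition regimes ship as constants, solved in closed form
(the two constraints Y(t_end) = mobile and Y(T50) = 0.5 are linear in the
spans at fixed rates): a slow regime with mobile 75.2% and T50 75.5 s —
a protein with a stably bound quarter of its pool — and a fast regime with
mobile 97.5% and T50 9.9 s, near-complete rapid exchange.  Validation uses
20 noisy replicates per regime (σ = 0.02, 1 Hz, 400 s with 5 pre-bleach
frames); accuracy is assessed on the replicate means (the bias of the
estimator), and the fitted T50s of the two regimes must not overlap.

## Buffering diagnostic

Populations draw total expression E log-uniformly over two decades
(expression spans orders of magnitude in transient transfections).
Concentrations are anchored at the geometric-mean expression: a mid-
expression cell has focus concentration c_sat (100 a.u.) and nucleoplasm
concentration 20 a.u., summed focus area 20 µm², and 15 foci.  Under
concentration buffering, focus and nucleoplasm concentrations stay pinned
while focus area scales with E; under size buffering, area and count stay
fixed while both concentrations scale with E (stable foci/nucleoplasm
ratio).  Multiplicative lognormal noise with unit mean and a given CV
(default 0.1) perturbs each quantity independently; at CV = 0 the
populations are exact.

The test regresses log10 focus concentration, focus area and focus count
on log10 E (area and count untransformed — only the fluorescence axes are
logarithmic).  R² is the squared Pearson correlation.  The regime call
uses two thresholds, r2_high = 0.5 and r2_low = 0.2: concentration
buffering requires a low concentration-R² together with a high area-R²;
size buffering requires the reverse with both area and count R² low;
anything between is reported as indeterminate rather than forced.  The
thresholds are a deliberate decision rule on top of the regression — the
regression itself reports R² without judgment — and raising r2_high can
only move calls toward indeterminate, never flip one regime to the other.
"Total expression" is integrated nuclear intensity (mean × area), which is
what scales with protein copy number; cells without foci have no focus
concentration and are excluded with an explicit count.

## Satellite-sequence analyses

GC content is 100 × (G+C)/length with strict ACGT validation (an
ambiguous-skipping mode exists).  Restriction enzymes are defined by an
IUPAC site, a top-strand cut offset and a CpG-methylation-sensitivity
flag; built-ins are HpyCH4IV (ACGT, blocked), ApoI (RAATTY, not blocked),
and the isoschizomers HpaII/MspI (CCGG, blocked/not).  Sites are scanned
on the top strand with overlapping matches (all built-in sites are
palindromic, so one strand suffices); a blocked enzyme skips any matched
window containing a methylated CpG cytosine — blocking is all-or-nothing,
partial enzymatic activity is out of scope.  Digestion is linear; fragment
lengths always sum to the sequence length.  Methylation is modeled on the
forward-strand cytosine of each CpG only; the assays this simulates cannot
distinguish hemimethylation.

Probe matching is a sliding-window Hamming comparison on the forward
strand and, optionally, against the reverse complement of the probe, with
overlapping matches counted; it is property-tested against an exhaustive
scan.

Tandem-repeat structure: the period p maximizes the mean per-base identity
between seq[i] and seq[i+p] over the overlap, taking the smallest p within
5% of the maximum because multiples of the fundamental period score
essentially the same identity.  Copy counting is alignment-based rather
than fixed-phase windowing: a representative unit (each putative copy
along the tiling from the 5′ edge of the high-identity region, plus the
most self-similar window, best result kept) is aligned semi-globally and
greedily without overlap at identity ≥ 0.8.  The indel tolerance matters
on real satellite DNA, whose monomers accumulate insertions and deletions:
on the packaged 804 bp mouse major-satellite probe, fixed-phase windows
find only two complete 234 nt monomers, while alignment correctly
recovers the three diverged copies the probe contains (the probe also
carries vector-derived flanks, which is why the repeat span rather than
the full printed length is reported).  A sequence with no period reaching
the identity threshold is flagged non-repetitive with a single copy — the
behaviour on the 725 bp red deer satellite I probe, which is a single
consensus unit.

## Statistics

Welch's t (with Satterthwaite degrees of freedom), Welch's one-way ANOVA
(the inferential test driving the post-hoc) and the Games-Howell procedure
are computed from their standard formulas; scipy supplies only the t, F
and studentized-range distribution functions (the latter evaluated by
scipy's numerical integration, as no closed form exists).
Brown-Forsythe's F is available as a labeled companion statistic.
Games-Howell uses q = |Δmean| / √((s²ᵢ/nᵢ + s²ⱼ/nⱼ)/2) with per-pair Welch
degrees of freedom and k = number of groups; for k = 2 it reduces to the
Welch t test (q = t√2), a consistency chain the tests verify together with
agreement with an independent implementation.  Small-sample Games-Howell
conventions differ slightly across references; this formulation is pinned
by oracle tests, not claimed to match any particular software bit-for-bit.
Quartiles use linear interpolation between order statistics; Tukey fences
are Q1 − 1.5·IQR and Q3 + 1.5·IQR, with strictly-outside flagging (a value
exactly on a fence is an inlier).

Type-I calibration of the Welch t test is checked by simulation: 20 000
null replicates with unequal variances (n = 15 vs 10, σ = 1 vs 2), where
the rejection rate at α = 0.05 must fall within [0.045, 0.055].

## Problem sizes and determinism

All generators take explicit integer seeds and are bit-reproducible; no
global random state is used.  The validation suite uses scenes of 4–5
nuclei at ~800×800 px, 20 FRAP replicates per regime at 400 frames, 20
populations of 100 cells per regime, and 20 000 statistical null
simulations — sizes chosen so the full suite and the acceptance script
each run in seconds on a single core while keeping Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

- 2D scenes only; no PSF, no photon noise, no z-stacks, no time-lapse
  tracking.
- The classifier thresholds (1.5/1.1) and buffering decision thresholds
  (0.5/0.2) are package conventions, not community standards.
- FRAP fitting assumes the two-phase association form; reaction–diffusion
  models and bleach-geometry corrections are out of scope.
- Digest simulation is binary per site and linear-topology only; no gel
  mobility or band-intensity modeling.
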