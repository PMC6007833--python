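# Methods

## The measurement model

The pipeline starts from 1-D axial fluorescence profiles: for each cell and
frame, the mean intensity across the cell width projected onto the long
axis, in two channels (ParA, ParB). Cell geometry arrives separately as a
per-frame table (cell id, parent id, length, new-pole side). Segmentation
itself — turning 2-D images into meshes and axial profiles — is out of
scope; the package consumes its output. All axial positions are reported in
micrometres from the cell's *new* pole (the end created at the most recent
division), pixel indices are 0-based, and pixel i of a profile samples
position i × `pixel_size` from the cell's left end.

## Pipeline stages

**Smoothing.** Profiles are smoothed with a 1-D Gaussian kernel,
σ = 2 px, reflective boundaries. Microscopy workflows usually smooth the
2-D image before projection; projecting an isotropically blurred image
across the width is well approximated by blurring the projection along the
axis with the same σ, and this package only ever sees profiles. Reflection
avoids edge dimming that would push pole-proximal maxima inward.

**ParA maximum and heatmaps.** The per-frame ParA maximum is the argmax of
the smoothed trace, ties broken toward the new pole (deterministic, and
consistent with the new-pole bias of the gradient). Flat frames have no
defined maximum and are excluded from distance-based analyses. Heatmaps
divide every pixel of every frame by the single maximum over the cell's
birth-to-division lifetime, so each cell's kymograph contains exactly one
value of 1.

**ParB peak detection.** Candidate foci are local maxima of the smoothed
trace (first derivative crossing from positive to negative; derivative
peak finders are sometimes described in terms of negative-to-positive
crossings, which literally describes minima — maxima detection is what is
implemented here). Candidates must exceed
`min + threshold_rel × (max − min)` of their own trace
(`threshold_rel` = 0.3 by default; the relative, scale-free form is robust
to baseline offsets, and an absolute threshold remains configurable) and
survive greedy highest-first
suppression so that retained peaks are more than 5 px apart.

**Noise-perturbation validation.** Each of 20 trials adds i.i.d. Gaussian
noise with σ = sd(trace)/2 to the smoothed trace, re-smooths (same 2-px σ
as the primary smoothing) and re-detects. A candidate scores
a trial when a trial peak lies within 2 px of it (half the separation
floor, preventing double matching); candidates with ≥ 10 of 20 matching
trials survive. A zero-variance trace admits no perturbation: candidates
pass trivially, with a warning.

**Tracking.** Foci in consecutive frames are linked when their
pole-relative positions differ by ≤ 5 px; matching is greedy
closest-pair-first (ties to the lower position), unlinked foci seed new
tracks, and no gap closing across missing frames is attempted. Across a
division, the parent's position is remapped into the daughter whose
segment contains it, both daughters being re-anchored at the division
plane (their shared new pole). A track ending at frame t with exactly two
tracks starting at t + 1 within 10 px (2× the link step — split siblings
separate beyond the link radius but stay near the parent) is proposed as a
focus split; more than two candidates suppresses the proposal for manual
override. The override file (merge/split/unsplit commands) reproduces the
manual curation workflow in a reviewable, replayable form.

**Diffusion analysis.** For each track the unsigned distance d(t) to the
ParA maximum is followed; the landmark itself moves, so displacements
conflate focus and landmark motion — deliberately, as this is the quantity
of interest. Displacements Δx = d(t+Δt) − d(t) are taken over *all*
ordered time-window pairs within a series, and every pair goes to the
single distance bin chosen by the series' *initial* distance (0–1.5,
1.5–3, 3–4.5 μm, half-open; series starting beyond 4.5 μm are discarded as
too sparse). Overlapping windows induce autocorrelation in the mean; the
95% CI is the naive Student-t interval of the per-bin mean, consistent
with how such curves are conventionally reported. The lag grid stops at
half the longest series so single-pair tails cannot dominate.

Each bin's curve is fitted to ⟨Δx²⟩ = 2D·(Δt)^β by OLS on
ln⟨Δx²⟩ vs ln Δt (non-positive means excluded; ≥ 3 distinct lags
required). Log-log OLS is standard, reproducible, and exact on exact
power-law inputs; the exponent's standard error comes from the regression,
and D's from the delta method on exp(intercept)/2. β classifies the
regime: sub-diffusive below 1, active above 1, free within a ±0.1 band
(the band is a labelling convenience only; numeric β and its SE are always
reported). Velocity classification fits d(t) by OLS and thresholds the
slope at ±0.15 μm h⁻¹ into toward / with / away.

**Inheritance.** At each observed division the two newborn sisters'
total ParA (pixel sum), maximum ParA (pixel max), birth length/area
(length × 0.5 μm nominal width) and growth rate are compared. The sister
whose axial segment contains the parent's last pre-division ParA maximum
is the maximum inheritor (a maximum exactly at the plane goes to the
larger sister, flagged). Under random placement the probability a daughter
inherits the maximum equals her share of the parent size; "parent size" is
operationalised as the *sum of the two daughters' birth sizes* so the two
shares sum to exactly 1 and septum geometry drops out. Summing the larger
sister's share over divisions predicts the expected larger-sister
inheritance count, reported with the Poisson-binomial standard error
√(Σ pᵢ(1−pᵢ)). Group comparisons always report both the paired Wilcoxon
signed-rank test and Welch's t-test (the two conventions in use for such
data). Population size comparisons use tie-corrected Kruskal-Wallis H plus
Dunn's rank-sum pairwise z tests; no post-hoc package is available in the
dependency set, so Dunn's statistic is implemented directly, with
Bonferroni adjustment over all pairs (the adjustment used is recorded in
the output metadata).
Mutually non-different groups share a compact-display letter, assigned
greedily in descending-median order.

## The synthetic-data generator

The simulator emulates the study conditions the analysis assumes rather
than any mechanistic ParA/ParB reaction-diffusion model. Cells elongate
exponentially (default 0.23 h⁻¹, ≈ 3 h doubling), are imaged every 0.25 h,
and divide on reaching 5 μm at a plane placed a `division_asymmetry`
fraction (default 0.6, jittered with a truncated Gaussian of sd 0.03 so
sibling sizes vary) of the length from the new pole; each daughter's new
pole is the plane side. The ParA maximum sits at 0.2 of the length from
the new pole (a Gaussian bump of sd 0.4 μm on a baseline — the true
gradient shape is unknown; this is an emulation choice) and relocates next
to the incipient septum on the final pre-division frame, on the
larger-daughter side. The single ParB focus splits when the cell reaches
0.68 of the division length: the two children start ±0.7 μm from the
parent position, one governed by near-regime motion, the other by the far
regime. Both regimes are distance-switched: within 1.5 μm of the ParA
maximum, motion is fractional-Gaussian noise (Hurst 0.2, step scale
0.05 μm — MSD exponent 2H = 0.4, matching the sub-diffusive regime the
analysis expects near ParA); beyond it, motion is directed at 0.5 μm h⁻¹ —
toward the old pole for the far sibling, back toward the maximum for
everything else. Positions advect with growth (uniform stretching) and are
clipped to the cell. fGn increments are sampled exactly by Cholesky
factorisation of the closed-form autocovariance
γ(k) = (s²/2)(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}); tracks are short
(≤ a few hundred steps), so the O(n³) factorisation — computed once and
shared — is cheap and avoids spectral approximation error.

Rendering places Gaussian spots (sd 0.15 μm) at focus positions on the
ParB channel and the gradient bump on the ParA channel, adds i.i.d.
Gaussian pixel noise (sd 6 on amplitudes of 250–300) on a 0.1 μm/px grid
(a plausible scale for a 63× EM-CCD set-up, and configurable — all
pixel-denominated thresholds are applied in pixel space after conversion),
and clips at zero. Cells shorter than 3 px are
rejected.

What the generator does *not* emulate: photobleaching, background drift,
segmentation error, focus loss/blinking, anuclear cells, or mechanistic
ParA-ParB coupling. Passing tests therefore demonstrate that the
*analysis* is correct on data with the assumed statistical structure, not
that real microscopy meets those assumptions.

## Numerical and design choices

- Split-offset (0.7 μm) and elongation-rate defaults are chosen together
  so that at a focus split both children displace beyond the 5-px link
  radius (ending the parent track) yet stay within the 10-px split radius,
  the geometry the auto-proposal rule is designed for.
- Determinism: a single master seed feeds a `SeedSequence` hierarchy — one
  child stream per (cell, frame) for validation noise — so results are
  independent of execution order; identical (inputs, config, seed) give
  byte-identical outputs.
- Simulated motion-class series are wrapped as distance series by shifting
  each trajectory by its own minimum; a per-track constant shift leaves
  every displacement, and hence the MSD and fitted exponent, unchanged.
- Degenerate inputs: flat profiles yield no peaks and no ParA maximum;
  all-zero ParA lifetimes yield a flagged all-zero heatmap; growth rate
  needs ≥ 3 frames (one more than an OLS line strictly needs, guarding
  degenerate fits); doubling time is undefined for roots (birth
  unobserved) and for cells that never divide; all-tied sibling pairs make
  the signed-rank test undefined and are reported as such.
- Problem sizes: the bundled analyses use a 3-generation movie
  (15 cells, ~55 frames, ~380 foci) and 200–300 simulated tracks of 30
  steps per motion class, sizes at which every recovery statistic reported
  here is stable across seeds.

## Known limitations

- Distance series on the simulated movie mix focus motion, ParA-maximum
  motion and growth-driven advection, so whole-movie MSD exponents sit
  above the pure near-regime value; regime recovery is therefore
  benchmarked on isolated motion-class simulations where the exponent is
  known exactly.
- The tracker is the deliberately simple frame-pair rule of the original
  workflow: no global assignment, no motion model, no gap closing. The
  override file exists precisely because such rules need curation.
- Letter classes use a greedy compact-letter display; it is valid (no two
  significantly different groups share a letter) but not guaranteed
  minimal in letter count.
- Dunn p-values use Bonferroni adjustment; with many groups this is
  conservative relative to sequential variants.
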