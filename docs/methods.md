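# Methods

This note records the models the package implements, the defaults that
matter, what the synthetic-data generators do and do not emulate, and the
choices made where the underlying measurement descriptions leave the
design open.

## SAIM axial nanometry

**Model.** A fluorophore at height *h* (nm) above the oxide surface of a
silicon substrate is excited by the interference of the direct beam and
its reflection. The excitation intensity at incidence angle θ (measured
in the sample medium) is

    F(θ; h) = |1 + r(θ) · exp(i φ)|²,   φ = 4π n_m h cos θ / λ,

with `r(θ)` the complex amplitude reflection coefficient of the
medium / SiO₂ / silicon stack, computed by the single-film Airy summation
(equivalent to the 2×2 transfer matrix). Emission-side interference,
fluorophore dipole orientation, and objective-side angle conversion are
out of scope; the measured pixel intensity is modeled as
`I_j = A·F_j(h) + B` with scale A ≥ 0 and background B.

**Optical constants.** Defaults (all overridable): n_medium = 1.33,
n_oxide = 1.463, n_silicon = 4.37 − 0.08i at 488 nm and 4.05 − 0.04i at
561 nm; oxide 500 nm. These are textbook values — per-chip ellipsometry
would replace them in a real deployment, and absolute z-centers at the
sub-nm level depend on them, so recovery is demonstrated in simulation
rather than against instrument data. The silicon index is accepted in the
absorbing `n − iκ` engineering convention and conjugated internally to
the physics convention the transfer-matrix formulas use; either input
sign gives identical results. Polarization defaults to TE (s), with TM
and amplitude-average available; the TE/TM reflection coefficients follow
the E-field (Verdet) sign convention.

**Inversion.** The fit is a variable-projection least squares: at any
height the optimal (A, B) solve a 2×2 linear system, leaving a 1-D
profiled objective S(h). `fit_pixel` multi-starts over a 10-nm restart
grid on h ∈ [0, 200] nm (covering the 40–140 nm display range with
margin), refines each start by bounded scalar minimization, breaks ties
toward the lowest height, and polishes the winner with
Levenberg–Marquardt-class least squares over (h, A, B). `fit_stack`
evaluates the same objective vectorised over all masked pixels (coarse
0.5-nm grid, then four 9-point grid-zoom rounds, final precision
< 0.01 nm). A fit with negative optimal amplitude is clipped to A = 0 and
flagged unconverged; constant pixels are unidentifiable and flagged. The
ROI summary is the median of finite fitted heights (`z_center`), with the
even-count median defined as the mean of the two central values.

## Worm-like-chain step prediction and event analysis

**Polymer model.** Released polypeptide is a Marko–Siggia worm-like
chain, `f = (kT/Lp)·[1/4(1−x/L)⁻² − 1/4 + x/L]`, inverted numerically
(Brent) to extension-at-force; valid down to the ~5 pN regime, unlike the
high-force asymptote. Defaults: persistence Lp = 0.8 nm (unfolded
polypeptide), contour 0.38 nm per residue, kT = 4.28 pN·nm (37 °C).

**Construct accounting.** On VBS–VD1 dissociation the stretched chain
gains the 182-residue FH1 spacer plus 40 further residues: the two GGGSG
linkers flanking FH1 (10 aa) and the 30-residue β-catenin VBS peptide
that leaves its docked helical conformation. Each VD1 subunit unfolding
releases 120 residues (two subunits; the exact count sits in prior
single-molecule work on vinculin D1 and is configuration, not a
constant). Each release is credited `folded_span_nm` = 4 nm of
pre-existing extension, subtracted from its WLC extension; concurrent
releases add. These defaults place the scenario predictions inside the
theoretical bands (unloop ≈ 39–54 nm over 7–16 pN, unloop + one subunit
≤ 90 nm at 16 pN, unloop + full unfolding > 100 nm). Reported theoretical
unloop bands appear as both 40–50 nm and 50–60 nm in the source
literature; the 40–50 nm band is adopted here and the discrepancy is
surfaced rather than resolved. Bead/handle geometry, DNA-spacer elasticity, and titin I27
unfolding (a > 60 pN phenomenon) are excluded.

**Detection.** Steps are found by a three-window sliding statistic: the
difference between the mean heights of the windows after and before a
candidate point, minus the same difference one window earlier. The second
difference cancels the linear drift of the tether's smooth force-dependent
stretching during the ramp, so the statistic is ≈ 0 on drift and ≈ ΔH at
a genuine step. The threshold is `significance` (default 8) times the
statistic's standard error under the trace noise (robust MAD of first
differences), floored at `min_step_nm` = 10 nm; runs above threshold
merge into one event at the maximal statistic. ΔH is the drift-corrected
statistic at the change point; the mirror lobe the second difference
produces one window downstream is discarded because its raw plateau jump
is near zero. Events closer than one window are not resolvable (the
generator refuses to plant them).

**Classification.** ΔH ≤ 35 nm → consistent with VD1 subunit unfolding
alone (`below_threshold`, not dissociation). Larger steps match the
scenario whose prediction at the event force lies within
`band_tolerance_nm` (default 10 nm); steps above the full-unfold
prediction classify as full unfolding; overlapping bands resolve by
parsimony (fewest released segments), and a step in no band takes the
nearest prediction. Force uncertainty is reported as 20% of the measured
force (bead-size and attachment-geometry variation).

## FRAP

Double normalization divides the background-subtracted bleached-ROI
signal by the background-subtracted reference ROI, each normalized by its
pre-bleach average (all frames strictly before `bleach_index`, default 4),
cancelling acquisition photobleaching exactly for a shared bleach rate.
Full-scale calibration then anchors the pre-bleach average at 1 and the
single bleach frame at 0, so the fitted plateau of `I(t) = p(1−e^{−kt})`
(t from the bleach frame) is the mobile fraction relative to total and
ln2/k is the half-life. Whether recovery fits should target the
double-normalized or the full-scale curve is genuinely open; the
full-scale curve is used (it makes p the mobile fraction by construction)
and the alternative is a one-line switch.

The fit profiles the linearly-entering plateau out (closed-form p per
candidate k), minimises the profiled objective over k on a log grid with
bounded refinement, then polishes (p, k) by Levenberg–Marquardt-class
least squares whose covariance supplies standard errors. The profiling
matters: on noisy traces a naive joint bounded fit can wander into the
flat large-p/small-k valley and rail at the p bound even when the true
basin is deeper. Bounds p ∈ [0, 1.5] (flagged above 1), k ∈ (0, 10] s⁻¹.
Group summaries compare mobile fractions by ordinary one-way ANOVA
without multiple-comparison correction, as these conditions are compared.

## Ablation recoil

The inter-edge distance is the Euclidean norm in the image plane (no
arc-length along the junction); whether the original analyses summed the
two edge speeds or used the inter-edge rate is unstated — they coincide
for symmetric recoil, and the inter-edge rate is used. The initial recoil
rate is the one-sided secant over the first 2 s after ablation (one frame
interval), not a multi-frame linear fit, matching the stated first-2-s
measurement; the follow-up frame must exist within half that interval.
Group comparison: one-way ANOVA with Sidak-adjusted pairwise Welch
t-tests.

## Migration angular statistics

Vectors slower than 10 µm/h are removed ("below" read strictly: exactly
10 survives). Angles are `atan2(v, u)` with 0° the outward wound normal
(+x); callers orient fields accordingly. Bins are 12 half-open 30° bins,
by default offset half a bin so one bin spans [−15°, 15°) — rose plots of
cohesive migration peak on the front normal, and this keeps that peak in
a single bin. Frequencies are counts over total retained vectors, pooled
across all frames and positions of an experiment (per-frame averaging is
available as a switch); relative angular speed is frequency × mean bin
speed, so the bin sums equal 1 and the overall mean retained speed
respectively. The major angle is a least-squares Gaussian on (bin center,
frequency) after circularly shifting the modal bin to the centre (the
Gaussian is not periodic), with the mean mapped back to [−180°, 180°);
conditions are compared by one-way ANOVA with Tukey correction. The
block-matching velocimetry operator (FFT cross-correlation per window,
32 px windows, 50% overlap, integer-pixel peaks) exists to exercise the
pipeline on synthetic movies; it is not a full multi-pass PIV.

## Synthetic-data generators

Each generator emulates the acquisition geometry its analysis assumes —
14-angle SAIM stacks; 1 pN/s load / −0.1 pN/s release ramps sampled at
0.01 s; 90 FRAP frames at 1 s with bleach after the fourth; ablation
frames every 2 s from −6 s to +30 s; gridded velocity fields — and
returns a machine-readable truth record; recovery tests read truth only
from it. All randomness flows from explicit seeds (`split_seed` derives
independent per-generator streams below 2³¹).

Noise models are design choices, set once so the analyses' published
operating points are recoverable: multiplicative Gaussian noise on SAIM
images (fractional σ per pixel); Gaussian height noise on tweezer traces
(σ = 5 nm default) over a WLC tether baseline; Gaussian positional noise
on ablation edges; von Mises angles with truncated-Gaussian speeds and a
configurable static (sub-threshold) fraction for velocity fields. FRAP
channels carry Gaussian noise proportional to the instantaneous clean
signal (shot-noise-like) with bleach depth 0.9 (near-complete bleaching):
noise whose absolute scale ignores the post-bleach signal drop makes the
single-frame bleach anchor of the full-scale calibration meaningless at
realistic noise, producing a heavy-tailed fit the real measurement does
not show.

What the generators do **not** emulate — and hence what passing recovery
tests do not demonstrate about real data: camera-specific noise
(read/EMCCD excess noise, saturation), drift and stage instability,
fluorophore photophysics (blinking, orientation effects), per-chip
optical-constant variation, asymmetric or curved junction recoil,
cell-shape-dependent PIV artifacts, and any biology (the generators plant
the effect sizes; they cannot confirm them).

## Problem sizes

Default test and reproduction sizes are chosen to exercise every code
path at full fidelity while staying lightweight: 64×64-pixel SAIM stacks
(4096 independent per-pixel fits), 50 FRAP traces, 20 ablation tracks,
single-cycle tweezer ramps of ~2×10⁴ samples (three-cycle where the
protocol matters), and ~3×10³ velocity vectors per angular fit.

## Known limitations

* Absolute SAIM z-centers depend on optical constants and the polarization
  treatment of the original instrument, which are not fully specified;
  only simulated recovery, not first-principles reproduction of absolute
  offsets at the 0.5-nm level, is claimed.
* VD1 subunit released-residue counts and the folded-state span are
  configuration with literature-scale defaults, not measured quantities.
* The step detector assumes locally linear baseline drift; strongly
  curved baselines within three windows bias ΔH slightly.
* The Gaussian major-angle fit treats the histogram as non-periodic after
  recentring; distributions broader than ~half the circle are poorly
  summarized by it.
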