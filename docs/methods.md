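# Methods

## Two-state thermodynamics

The hairpin is modeled as a two-state folder with a first-order (linear)
expansion of the unfolding free energy around the melting temperature,
ΔG_u(T) = g¹·(T − T_m). No heat-capacity (ΔCp) curvature term is carried:
only the first-order cooperativity is identifiable from the narrow in-cell
temperature window, and the quantities of interest (ΔG₃₇, K₃₇, populations)
are evaluated close to T_m relative to the expansion's validity range. The
reference temperature is 310 K exactly (not 310.15 K), matching the
convention of the ΔG₃₇ = (310 K − T_m)·g¹ formula; R = 8.314 J·mol⁻¹·K⁻¹,
energies are carried in kJ/mol with the J↔kJ conversion explicit. K is the
*unfolding* constant K_u = [U]/[F] = exp(−ΔG_u/RT); this convention is what
makes a positive ΔG₃₇ correspond to a mostly folded hairpin (6.8 kJ/mol →
6.7% unfolded at 310 K). Populations are evaluated in logistic form
(`expit`), which is exact and overflow-free for any |ΔG|.

A note on g¹: dimensional consistency requires g¹ = dΔG_u/dT at T_m
(kJ·mol⁻¹·K⁻¹), not the slope of the melting curve itself; under this model
the slope of f_u(T) at T_m is −g¹·10³/(4·R·T_m).

## Kinetic melting fit

Amplitude model: the slow-phase relaxation amplitude of jump k reports the
change in unfolded population between the equilibria before and after the
jump, a_k = c·[f_u(T_k) − f_u(T_{k−1})] + m·ΔT_k. The finite-difference
form is the minimal model with exactly the degrees of freedom of interest
(T_m, g¹) plus a scale c and a linear drift m for dye/baseline trends; the
literature kinetic method it follows is not reproduced verbatim here, so
this form is a documented modeling choice. Consequences asserted in tests:
with m = 0 the model amplitudes telescope to c·[f_u(T_N) − f_u(T_0)], the
fit is exactly invariant to rescaling all amplitudes, and on noiseless data
the generator parameters are recovered to optimizer tolerance anywhere
inside the scanned ladder for g¹ ∈ [−2, −0.1].

Fitting: `scipy.optimize.least_squares` with multi-start initialization —
T_m started at the temperature of the largest |amplitude| and at the ladder
midpoint, g¹ at {−0.2, −0.5, −1.0} kJ·mol⁻¹·K⁻¹, best SSE wins with ties
broken toward smaller |g¹|. Tolerances 1e−12 (xtol/ftol/gtol), ≤ 2000
function evaluations per start. Parameter covariance is the
residual-variance-scaled inverse Gauss–Newton Hessian of the winning start;
σ(ΔG₃₇) follows by first-order (Gaussian) propagation, including the
(T_m, g¹) covariance with the cross term −2·g¹·(310 − T_m)·cov. Degenerate
outcomes are flagged rather than raised: |c| ≈ 0 (no folding signal, T_m
unidentifiable), g¹ ≥ 0 (no melting signature), unphysical T_m ≤ 0.

Per-jump relaxations are fit as offset + a·(1 − e^(−k·(t−t₀))) by
`curve_fit`, with the onset t₀ taken from the first sample whose calibrated
temperature crosses the midpoint of the pre/post targets (or sample 0 when
no temperature series is attached). The signed amplitude carries the
direction of the equilibrium shift; D/A ratio is the default observable
with the donor channel as a configurable alternative. Flat traces return
amplitude 0 with an "unidentifiable rate" flag and are *kept* in the
amplitude curve (a zero amplitude is informative); non-converged fits are
flagged and excluded with a log record.

Temperature calibration inverts F(T) = F_ref·e^(−s·(T−T_ref)) fitted by
linear regression on log F of the reference pairs; readings more than 10%
of the calibrated span outside it raise an extrapolation warning.

An identifiability caveat observed on the synthetic ladders: for weakly
stable hairpins (ΔG₃₇ ≈ 6 kJ/mol) with noise, T_m and g¹ are individually
soft (the fit can trade a higher T_m against a shallower g¹) while their
product ΔG₃₇ stays well determined — the drivers therefore report ΔG₃₇
with its propagated σ as the primary quantity.

## FRAP

Traces are normalized to a unit pre-bleach mean, optionally after dividing
by an unbleached reference region (double normalization, cancelling
acquisition bleaching). Recovery is a single exponential
I(t) = I₀ + (I_plateau − I₀)(1 − e^(−(t−t_bleach)/τ)); no diffusion model
is attached to τ. I₀ is the first post-bleach sample by default
(optionally a fitted parameter), the plateau is always fitted rather than
taken from the last samples, so truncated acquisitions extrapolate
correctly. f_mobile = (I_plateau − I₀)/(1 − I₀), clipped to [0, 1.05] with
values > 1 flagged as over-recovery. Bleach depths below 0.05 are rejected
as unfittable. Group summaries are mean ± SD across cells.

## Imaging

Segmentation is a deliberately minimal, deterministic stand-in for an
interactive CellProfiler pipeline: median-filter background subtraction
(radius 15 px default), Otsu threshold, 8-connected components, minimum
area 4 px, every knob exposed in `SegmentationConfig`. Blank images yield
an empty segmentation, not an error. Colocalization is object-based and
reported with two metrics, because the exact overlap definition used by
interactive pipelines varies: the primary metric is area-weighted (percent
of total RNA-focus area on the speckle mask), the secondary is the percent
of RNA objects touching a speckle by ≥ 1 px. The partition coefficient is
the ratio of mean intensities over the speckle and nucleoplasm
(nucleus − speckles) masks; the nucleus mask is an input, never segmented
here. Coordinates are 0-based row-major pixels.

## Trajectory contacts

Hydrogen bonds use the geometric criterion d(donor, acceptor) < 0.4 nm AND
angle(donor, H, acceptor) > 120°; the distance is donor–acceptor (not
hydrogen–acceptor). Explicit hydrogens are required — a donor without its
polar hydrogen is an input error, since the angle cannot be evaluated.
Donor/acceptor tables (module constants, override-able per call): RNA
donors are the base N–H groups and O2′–H; RNA acceptors the base lone-pair
N/O atoms plus backbone oxygens; ATP donates via N6–H and its ribose
hydroxyls and accepts at N1/N3/N7, ribose and phosphate oxygens. Counts
are bucketed by the RNA-side moiety (phosphate = {P, OP1, OP2, O5′, O3′};
ribose = {C1′–C5′, O4′, O2′}; base = remaining heavy atoms) and, within
base, by nucleobase identity; each donor–acceptor pair counts once per
frame; frames are equally weighted and tables report mean counts per
frame. The WC-edge flag marks the standard Watson–Crick edge atoms
(A: N1, N6; C: N3, N4, O2; G: N1, N2, O6; U: N3, O2, O4).

χ torsions: dihedral(O4′, C1′, N9, C4) for purines, (O4′, C1′, N1, C2) for
pyrimidines, signed, in (−180°, 180°]. RMSD-to-average superposes all
frames on frame 0 (Kabsch), averages, then runs two refinement iterations
of re-superposing on the average and re-averaging; (near-)collinear
selections trigger a warning since the rotation is then ill-conditioned.
Internal unit is nm; PDB ångströms are converted on read/write (multi-model
PDB via biotite).

## Synthetic data

The generators define the study conditions and are bit-exact functions of
(parameters, seed):

* **T-jump ladders** — 19 jumps, 303–358 K, 25 s dwell (total 475 s),
  start 300 K; amplitudes from the same finite-difference model the fit
  assumes, rates from an Arrhenius-like schedule k(T) = k₀·e^(0.02·(T−310)),
  channel noise multiplicative Gaussian. Amplitude-level curves for the
  Monte-Carlo suites use σ = 5% of the largest amplitude.
* **FRAP** — single-exponential truth with f_mobile = 0.46 and τ = 8 s as
  the reference condition (the measured value for the pure CAG hairpin in
  speckles), bleach depth 0.8, noise σ = 1% of the pre-bleach level.
* **Focus fields** — 20 RNA foci / 12 speckles on 256² px; a
  round(f·n) subset of identical RNA disks is planted fully inside
  speckles (one per host), the rest fully outside, making the planted
  area-overlap equal the request up to disk-rounding; channels are
  PSF-blurred disks with Poisson + Gaussian noise.
* **Hairpin topology** — (CAG)ₙ with repeats i and n+1−i paired for
  i ≤ ⌊(n−2)/2⌋, a two-repeat (6-nt) terminal loop, C·G/G·C canonical pairs
  and A·A mismatches per repeat pair, hence 2·⌊(n−2)/2⌋ canonical pairs
  (18 at n = 20). This register is the minimal scheme consistent with that
  count; the 3D coordinates are a regular helix (rise 0.28 nm, twist 32.7°
  per step) carrying chemically named atoms — geometric scaffolding for
  contact/torsion/RMSD tests, with no energetic meaning. `plant_atp`
  searches approach directions and spins for a placement where the planted
  N6–H61⋯acceptor bond is the only pair satisfying the criteria; at
  crowded stem sites perfect isolation can be geometrically impossible, so
  tests plant at exposed sites. The lm4U* control hairpin ships as a
  *synthetic* pairing-table fixture: only its canonical-pair count (14) is
  meaningful, the register is illustrative.

What the generators do **not** emulate: photophysics (bleaching,
blinking, detector offsets) beyond Gaussian/Poisson noise, spatially
varying background, focus-size heterogeneity, multi-exponential or
diffusion-limited kinetics, real RNA/ATP geometry or energetics, and
correlated per-cell variability. Passing round trips therefore demonstrate
correctness of the estimators under their own model assumptions, not
robustness to every real-data pathology.

## Group statistics

One-way ANOVA is the standard decomposition (implemented directly; the
scipy implementation serves as an independent cross-check in the tests).
The post-hoc test is Tukey–Kramer via the studentized-range distribution,
chosen because group sizes differ between cells/conditions; degenerate
zero-variance groups are reported as F = ∞, p = 0 (distinct means) or
F = 0, p = 1 (identical). Within-cell fit uncertainty (from the parameter
covariance) and between-cell scatter (group SD) are reported separately,
never merged.

## Problem sizes

The shipped suites use desk-scale sizes chosen to exercise every code
path with stable statistics: 100-seed Monte-Carlo repeats for parameter
recovery, 19-point ladders, 3–5 synthetic image fields of 256² px, 10–20
frame toy trajectories. The cell-derived group values of a real study
(e.g. a 45 ± 13% colocalization share) arise from biological scatter that
no desk-scale synthetic run reproduces; they are covered by the recovery
suites, not by re-deriving the printed group means.
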