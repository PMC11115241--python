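# Methods

This note documents the models, numerical choices and limitations behind
`hybridct`. It is written for users who need to know what the simulator does
and does not emulate, and why the solvers are configured the way they are.

## System model

The scanner is modeled as a **stacked parallel-beam geometry**: detector
columns span the transaxial direction, detector rows the rotation axis, and
each row images one axial plane. `circular` mode maps rows to fixed slices;
`helical` mode translates the subject vertically across views and is
exercised on small grids only. This desk-scale abstraction keeps every stage
(corrections, reconstruction, decomposition, metrology) faithful while
avoiding cone-beam ray geometry; the physical system it emulates acquires
1200 views over 1070° with 18 mm translation on a 1024×256 detector with
100 µm pixels and 8 ASIC tiles. Default study conditions are 360 views over
180°, a 256-column 8-tile detector at 50 µm pitch, and 128² axial slices at
0.1 mm — chosen so a full corrected study reconstructs in about a minute.

The projector is Joseph's method (one-voxel steps along the dominant ray
axis, linear interpolation across it), assembled once per geometry as a
sparse matrix. The backprojector is the exact transpose, so the adjoint
identity ⟨Rx, y⟩ = ⟨x, Rᵀy⟩ holds to floating precision — the property the
conjugate-gradient data step requires. Path lengths are in cm; attenuation
volumes are in cm⁻¹.

## Spectra and materials

The source is a Kramers bremsstrahlung spectrum truncated at the 60 kVp tube
potential and sampled at 1 keV from 10 keV (the beryllium exit window is
spectrally negligible above 10 keV). Mass-attenuation coefficients are
log-log interpolated from a compact embedded table of standard published
values, with the iodine K-edge represented by an explicit below/above pair
at 33.169 keV so the discontinuity survives interpolation. Water-like
materials are parameterized in g/mL, iodine in mg/mL. PBS is modeled as
water.

The counting detector weights photons w(E) = 1 above each threshold (15 and
34 keV by default); the energy integrator uses w(E) = E. Tile spectral
mismatch is modeled as per-tile **threshold offsets** (default ±0.6 keV,
drawn once per study seed) plus small multiplicative gains (±3 %): pure
gains cancel under flat-field normalization, so the offsets carry the
object-dependent residual that produces real band/ring artifacts. Poisson
noise samples nested PCD bins jointly (the high bin first, then an
independent increment), preserving the physical ordering
counts(15 keV) ≥ counts(34 keV) pixel-by-pixel. EID noise uses the Gaussian
compound-Poisson approximation with variance N₀·Σ s(E)E²T(E). Flat-field
fluence defaults to 2.5×10⁵ (PCD) and 1.2×10⁵ (EID) photons per pixel — the
scale implied by heavy frame averaging (100×80 ms and 10×100 ms) at ~130 µA.
Detector blur is a Gaussian PSF across columns: σ = 1.6 px for the
scintillator-coupled EID, σ = 0.5 px for the PCD (residual charge sharing).

**Not modeled:** pulse pileup, K-escape, explicit charge-sharing physics,
scatter, focal-spot blur, detector lag, and absolute count rates. Frame
averaging is collapsed into a single equivalent exposure.

## The brain-vial phantom

The seeded generator builds an outer water cylinder (the PBS-filled vial,
radius 0.42 × field of view) containing an ellipsoidal "brain" split into
equal-area concentric shells. Per-region iodine concentrations are drawn
from N(6, 1.5²) mg/mL (clipped at 0.5) — the contrast scale of a
Lugol-stained, partially cleared brain. Brain water density carries a
smooth ±2 % texture emulating tissue heterogeneity; this matters for CNR
comparisons because channel images see water texture that an iodine material
map removes. The generator does not emulate real anatomy, asymmetric
structures (unless mirrored), skull fragments, or staining gradients — so
passing tests demonstrate correctness of the pipeline's operations, not
anatomical realism.

## Tile-gain (ring) correction

The correction follows the water-phantom gain-ratio scheme: reconstruct the
PBS-only scan, idealize it (per channel: threshold at half the bright level,
center of mass + equivalent-area radius, median interior attenuation),
forward-project the ideal cylinder, divide ideal by real intensities,
median-filter 4×4, and replace columns outside the PBS with their nearest
in-PBS neighbor. The ratio multiplies sample projections in the count
domain, where gains are physically multiplicative.

One implementation detail is deliberate: the median filter runs **within
each tile's column band** (reflect padding) rather than across the whole
detector. The spectral steps at tile boundaries are exactly the signal the
ratio must preserve; a boundary-crossing median smears them over ±2 columns,
and because the central tile boundary sits at the detector center, that
smeared error backprojects into a strong spike at the rotation axis. Tile
boundaries are known hardware positions, so restricting the filter is free.

The correction is calibrated on PBS paths, so a residual object-dependent
mismatch remains over the stained brain (strongest in the 34 keV channel) —
the same residual rings the hybrid reconstruction is designed to suppress.
The band-artifact score used in tests measures the view/row-averaged column
profile's step at each tile boundary against quadratic extrapolations from
both sides, which removes the smooth chord-length trend; an image-domain
analogue scores ring steps on the azimuthally averaged radial profile.

## Beam-hardening correction

EID projections are corrected by a per-detector-row 2nd-degree polynomial
mapping the log-normalized value p to acrylic-equivalent thickness,
least-squares fit on simulated plate scans of {0, 2, 5, 10, 20} mm acrylic ×
{0, 0.5} mm aluminum (aluminum enters as its acrylic-equivalent at the
effective energy; a thickness-0 scan pins the polynomial near the origin).
Corrected projections are thickness × the attenuation of 1 mm acrylic at the
detected spectrum's mean energy, restoring a dimensionless line integral.
The PCD channels receive no beam-hardening correction; the 15 keV channel
keeps a small residual cupping, as expected for a wide counting bin.

## Reconstruction

`wfbp_reconstruct` is filtered backprojection with the band-limited
spatial-domain Ram-Lak kernel (h[0] = 1/(4Δt²), odd taps −1/(πnΔt)²), which
handles the DC term correctly: a uniform disk reconstructs to its true
attenuation within 0.1 %. Helical scans are rebinned: filtered rows are
spread to their axial planes with linear weights and averaged over the views
that illuminate each plane — a simplified weighting adequate at desk scale.

`iterative_reconstruct` solves
argmin_X ½Σₑ‖RX(e)−Y(e)‖² + λ‖X‖_BTV by split Bregman with
add-residual-back:

1. per-channel CG (20 iterations, matrix-free on RᵀR + λI) pulled toward
   the current denoised estimate D,
2. joint BTV denoising of all channels,
3. Bregman update b ← b + (Y − RX),

for 4 outer iterations, initialized from the analytical reconstruction. The
solver is deterministic. A fidelity term that rises twice in a row raises an
error carrying the iterate.

The joint denoiser normalizes each channel by its robust scale (1.4826×MAD),
takes the leading singular component across channels as a rank-1 composite,
and computes bilateral range weights from the composite once, applying them
to every channel (window radius 1, weights exp(−Δ²/2h²)/distance, h
defaulting to 1.4826 × the median absolute first difference of the
composite). In addition, the higher-order singular components of the channel
stack are shrunk by a factor (default 0.5) toward the rank-1 composite.
This rank shrinkage is what couples channel *content*: channel-specific
structure — residual PCD tile rings, uncorrelated noise — is attenuated by
the clean EID channel, at the cost of a small transfer of EID blur into the
PCD channels (hybrid resolution lands between PCD-only and EID-only, as it
should) and a mild loss of spectral separation. It diverges from a full
rank-sparse kernel regression (no patchwise kernel, no rank-threshold
schedule); the contract kept is joint edge weights from a cross-channel
low-rank composite plus first-order BTV.

λ is never reported for the physical studies, so the default is automatic:
λ = mean diag(RᵀR) × (relative projection noise / 5×10⁻⁴), capped at 100×.
The relative noise is estimated from second differences along detector
columns. The rule is a discrepancy-principle surrogate calibrated so the
prior carries data-term-comparable weight at ~1 % noise; noiseless data is
reconstructed essentially unregularized (the λ→0 limit reproduces the
least-squares solution). Too-small λ demonstrably amplifies noise beyond
filtered backprojection because the Bregman residual re-injects it.

## Material decomposition

Image-domain water/iodine decomposition uses all three hybrid channels: the
per-voxel system X = MC is overdetermined, solved by pseudo-inverse; with
two channels it reduces to exact inversion. M is calibrated from a vials
reconstruction — water-vial means per channel, iodine sensitivity as the
through-origin LSQ slope against known concentrations. Non-negativity is
exact active-set NNLS on the two-material cone: an infeasible voxel is
re-fit on whichever single-material edge has the smaller residual. The water
map is density relative to 1 g/mL.

## Metrology choices

- Line profiles are linearly interpolated; a zero-variance profile gets
  r² = 1 by convention (a constant fits it perfectly).
- The uniformity profile runs across the central 85 % of the vial radius
  through the vial center (air outside the vial would dominate PIU
  otherwise).
- Bar-group contrast uses peaks/troughs located from the known bar period
  (phase-recovered by correlating with the fundamental), averaged over the
  central third of each half-period — robust to noise. Contrasts are
  normalized to the lowest-frequency group and fit with A·exp(−f²/2s²); the
  amplitude absorbs the square-wave (CTF) excess so the width, and hence
  f10 = s√(2 ln 10), matches the sine-wave MTF — for a Gaussian PSF of width
  σ, f10 = √(2 ln 10)/(2πσ) to within a few percent in the fit range.
  Patterns the grid cannot attenuate report the Nyquist bound rather than an
  extrapolated number.
- ROIs are circles in 0-based voxel coordinates, recorded in reports.

## Morphometry statistics

Pooled-variance (Student) t-tests are used rather than Welch: recomputing a
published comparison row (n = 10 vs 16, means/SDs in percent of total
volume) under pooled variance reproduces the printed t, Cohen's d and both
CI bounds within rounding, while Welch's CI does not match; the choice is
pinned by a regression test. Cohen's d uses the pooled SD with (n−1)
weights. Percent difference is relative to the second group's mean. The FDR
family is all regions of a comparison. The synthetic cohort generator draws
per-region percent volumes from log-uniform means (0.008–2.5 % of total)
with SDs of 15 % of the mean and injects effects as mean shifts — matching
the scale of real atlas tables; over 200 replicate cohorts the
BH-at-5 % discovery set keeps its false-discovery proportion at the nominal
level.

## Known limitations

- The parallel-beam desk geometry does not model cone-angle or helical
  weighting artifacts; the helical mode is a rebinning approximation.
- Simulation and reconstruction share the ray model (the classic "inverse
  crime"); polychromatic physics, detector blur, tile distortions and noise
  break the triviality, but projector-model mismatch with real hardware is
  not represented.
- The attenuation table is a compact interpolation of standard values, not a
  full cross-section database; absolute attenuations are approximate though
  self-consistent across simulation, calibration and reconstruction.
- The gain-ratio correction assumes the vial is at the same position in
  sample and PBS scans (same trajectory), as the protocol guarantees.
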