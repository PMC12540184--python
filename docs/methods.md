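# Methods

`sonolens` designs phase-only acoustic hologram lenses for single-element
therapeutic ultrasound transducers by time reversal, verifies them by
forward simulation, and maps the focusing limits (focal size, bifocal
separation, focal depth, F-number dependence, transcranial correction)
with RMSE- and focus-distinctness-based evaluation.  This note records
the model, the numerical choices, and what the synthetic conditions do
and do not show about laboratory practice.

## Wave model and conventions

All fields are monochromatic complex pressure amplitudes at the working
frequency f0, with the time convention `p(t) = Re{P exp(+i w t)}`; a wave
travelling towards +z therefore carries `exp(-i k z)`.  Propagation is
linear, lossless in water, longitudinal-only (fluid model of bone), with
no nonlinearity or heating.

Two engines share this convention:

* **Angular spectrum (ASM)** for homogeneous media: plane-to-plane
  transfer `exp(-i kz d)` with `kz = sqrt(k0^2 - kt^2)` and a hard cutoff
  of evanescent components (`kt >= k0` zeroed).  The cutoff is applied
  identically for both propagation directions, so a +z/-z round trip is
  the identity on the propagating band — a property the test suite
  asserts to 1e-10.  ASM windows are periodic; sweeps size the lateral
  window at 2.2x the aperture (more for wide bifocal separations) to
  keep wrap-around energy negligible where the metrics are read.
* **k-space pseudospectral time domain (2-D x–z)** for heterogeneous
  media: first-order coupled pressure/velocity updates with staggered
  spectral derivatives and the k-space correction
  `sinc(c_ref |k| dt / 2)`, `c_ref = c_max`, which makes homogeneous
  propagation exact at any CFL.  A split-field PML (quartic profile,
  ~1.5 wavelengths, ~2 Np per cell peak) absorbs the boundaries.
  Sound-speed and density maps are smoothed by a 0.7-cell Gaussian to
  tame interface ringing, standard for spectral schemes.  Runs are
  single precision by default (the scipy.fft single-precision kernels
  halve the cost; the steady-state extraction averages rounding noise
  orders of magnitude below the solver's own tolerance).

Time-harmonic sources ramp up over 4 cycles; the run lasts 1.3 diagonal
transits plus ramp plus extraction window, and the complex amplitude is
the temporal Fourier coefficient at f0 over the final 8 cycles.  The two
halves of that window are compared; a >2% disagreement sets
`meta["converged"] = False`.  The CFL number defaults to 0.2 and the
time step is snapped to an integer number of steps per period so the
extraction window holds whole cycles.

Medium absorption (`alpha`, dB/cm/MHz, linear in frequency) is applied
as an amplitude decay rate folded into the same half-step factors as the
PML.  Water is lossless; the bone shell of the skull phantom absorbs.

## Time-reversal lens design

Targets are amplitude patterns on the grid: a binary disc (focal
enlargement), two unit monopole voxels at ±s/2 (bifocal), or the fixed
15 mm bifocal at a caller-chosen depth (depth series).  Design proceeds
by placing monochromatic sources at the target voxels, recording the
complex field at the holographic plane, and conjugating it.  Radiation
away from a source accumulates the same delay for either direction, so
the homogeneous-medium recording propagates by the separation distance
|z_target − z_plane|; heterogeneous recordings run the time-domain
solver so scattering is encoded in the phase map.

The holographic plane is the emitting surface of the planar transducer.
For a bowl it is the flat exit plane of the housing; the bowl field is
first projected onto it by summing the outgoing Green's function
(Hankel `H0^(2)` in 2-D; `exp(-ikr)/r` over the spherical cap in 3-D,
computed by axisymmetric radial quadrature) over a uniformly driven
discretisation of the bowl surface.  Depth is measured from the bowl
apex, so the geometric focus sits at z = roc (verified within half a
millimetre for the 63.2 mm bowl).  The lens phase is the difference
between the conjugated recording and the incident aperture phase; for
the planar piston the incident phase is zero and one simulation
suffices, for the bowl the two simulations are combined.

The amplitude of the recording is discarded: the lens is phase-only,
single-pass (no iterative amplitude shaping).

## Transmission equation and height lookup

A lens pixel of height h transmits

    T(h) = 2 Z exp(-i k0 (d - h)) / [ 2 Z cos(kL h) + i (Z^2 + 1) sin(kL h) ]

with Z the lens impedance normalised by water, k0/kL the water/lens
wavenumbers, and d the total thickness from the bottom of the lens (the
remaining d − h is water path).  `|T| <= 1` always (the denominator
magnitude is bounded below by 2Z), asserted over an impedance sweep.
Multiple reflections beyond this single-layer model are ignored.

The default material is a stereolithography clear resin surrogate
(c = 2580 m/s, rho = 1171 kg/m^3; overridable) in water at c0 = 1482 m/s,
rho0 = 994 kg/m^3 (degassed, ~22 °C; the spacing 0.426 mm at 7 points
per wavelength implies the design water speed was within ~1% of this).
For these constants the transmitted phase is strictly monotone in h, and
a cubic spline of height against unwrapped phase inverts it.  The height
range starts at a 1 mm base and spans exactly one 2π cycle (≈7 mm at
0.5 MHz); d defaults to base + 1.2 cycles.  Ties break toward thinner
pixels (the modulo maps phase 0 to the base height).  The inversion
round-trips 100 random phases to <0.01 rad.  Forward verification
multiplies the incident aperture by the full complex T(h) — amplitude
ripple included — and propagates with the appropriate engine.

Lenses export as watertight STL meshes (height samples as surface
vertices on the pixel pitch; mesh volume equals the trapezoidal
thickness integral) or as 16-bit height images with a text sidecar.

## Evaluation protocol

Forward-simulated volumes are normalised to their peak magnitude;
values strictly above 0.5 of the normalised range count as focusing and
everything at or below 0.5 is discarded (the boundary is resolved as
strict).  Two full-grid RMSE variants are reported against the target
map (binary/monopole targets dilated by one cell so a point target
admits a finite spot):

* `rmse_full_grid` — raw normalised maps; sensitive to sidelobe and
  background energy.  Used for the sweep curves and the F-number
  comparison, where it lands in the 1e-2..1e-1 range for sparse targets.
* `rmse_thresholded` — maps after the 0.5 cutoff; sensitive only to
  focal shape.  Used as the transcranial headline number, where the
  quantity of interest is how much above-half-maximum focusing falls
  outside the target.

Foci are local maxima >= 0.5 on the focal-plane profile (y = 0); two
foci are *distinct* when the field along the line between the two
strongest drops below half the lower peak.  Detection agrees with an
exhaustive neighbour scan on small grids.  Focal width is the linearly
interpolated full width at half maximum of the profile.

Disc sweeps declare *clear focusing* when the above-threshold region
covers at least half the target disc, and flag a requested diameter as
below resolution when the achieved width exceeds 1.5x the request.
Sweep limits are the extreme passing values; a non-contiguous passing
set flags the sweep as non-monotone instead of being silently reported.

The hydrophone comparator resamples the simulated plane onto the scan
lattice (bilinear, no extrapolation), normalises the simulation to its
peak, and fits the scan with a least-squares scale factor before taking
the RMSE.  The scale fit, rather than peak normalisation, reflects that
hydrophone voltages are uncalibrated and avoids the upward bias a noisy
maximum injects; with 5% synthetic amplitude noise the comparator
recovers an RMSE of ~0.05, and a noiseless closed loop returns 0.

## Synthetic data: what it emulates and what it does not

* **Targets** are exact binary discs and two-voxel monopole pairs —
  the idealised design inputs, not measured pressure distributions.
* **The skull phantom** is an elliptical bone shell at human-head scale
  (outer semi-axes 70 x 85 mm, 6 mm thick, crown 10 mm above the
  transducer) with cortical-typical properties c = 2800 m/s,
  rho = 1850 kg/m^3, alpha = 6.9 dB/cm/MHz.  An asymmetry factor
  (default 1.4) thickens the +x side, emulating a focus placed under a
  thicker part of the skull; transmission under the thicker crown is
  measurably weaker (an absorption-dominated effect — on the oblique
  flanks of the shell, refraction dominates and the ordering can
  invert).  The asymmetric default matters: a perfectly symmetric
  smooth shell applies so little aberration that the free-field control
  lens performs on par with the corrected one and the aberration-
  correction experiment degenerates.  The phantom
  has none of a real skull's surface roughness, diploë porosity,
  CT-derived property gradients, or shear conversion, so transcranial
  results here demonstrate the *mechanism* of time-reversal correction,
  not clinical targeting accuracy.
* **Synthetic raster scans** sample a simulated plane with Gaussian
  amplitude noise (fraction of peak), Gaussian position jitter, and
  clamping at zero — a stand-in for needle-hydrophone scans that has no
  spatial averaging over the hydrophone aperture and no drift.

All generators are deterministic given their parameters and seed.

## Study conditions and problem sizes

Free-field sweeps run in 2-D (x–z) — the limits under study are set by
in-plane diffraction — at the hardware presets: planar 44 mm at 0.5 MHz
with 7 points per wavelength (dh = 0.423 mm), focused 82 mm / 63.2 mm
radius of curvature at 1.645 MHz with 9 points per wavelength
(dh = 0.100 mm).  Grids span 2.2x the aperture laterally (wider for
large separations) and the design depth plus margin axially; bifocal
and disc designs default to 50 mm depth.

The F-number comparison runs in 3-D at the same spacing (257^2
transverse, 25 mm bifocal separation at depth F x 44 mm): its metric —
volume-normalised RMSE — is focal-gain-sensitive, and only spherical
focusing carries the gain the comparison is about.  In 2-D the low
cylindrical gain lets near-field speckle dominate the normalisation and
the high-F comparison degenerates.  In 3-D the focused transducer wins
clearly at F = 0.52, the advantage shrinks through F ≈ 1, and the gap is
near zero at F = 2.

The transcranial experiment runs the 2-D heterogeneous solver over the
whole head slice (~390 x 460 cells, ~8,500 time steps per solve, about
two minutes each in single precision).  Normalisation and the RMSE
averages are restricted to the head interior: in continuous-wave steady
state the standing-wave pressure inside the bone shell exceeds the
focal pressure, and letting it set the normalisation would silently
rescale every metric.  Each corrected lens is accompanied by a control
lens designed in free field and pushed through the same phantom.

### Scale caveat for the transcranial RMSE

The head-interior thresholded RMSE of a 2-D slice is not comparable in
magnitude to the same metric over a 3-D head volume: the above-threshold
focal tails occupy a far larger fraction of a slice than of a volume
(the off-focus voxel count scales with the square of the transverse
extent in 3-D but linearly in 2-D), and a monochromatic steady state
superposes multipath arrivals (post-focal beam crossings, far-shell
refocusing) at full amplitude, where a transient peak-pressure map would
not accumulate them.  At this package's desk scale the corrected lens
lands near 0.07; the meaningful desk-scale statements are the
*relative* ones — the corrected lens recovers both foci on target
(with the focus under the thicker side slightly weaker, as expected),
and strictly beats the free-field control through the same phantom by
more than a factor of two on the same metric.

## Known limitations

* The heterogeneous solver is 2-D; 3-D work is ASM-only (homogeneous).
* Longitudinal-only bone model; no shear conversion, no porosity.
* CW steady state throughout; no transient or peak-negative-pressure
  maps.
* Phase-only, single-pass design; no amplitude shaping, no iterative
  refinement.
* The printed pairing of points-per-wavelength with the two transducers
  is internally inconsistent with the printed grid spacings; the package
  exposes ppw per run (presets: 7 planar, 9 focused) and does not
  resolve the pairing.
* Real-CT import is supported only as precomputed property maps; no
  Hounsfield-to-acoustic-property conversion is provided.
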