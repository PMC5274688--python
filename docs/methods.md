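# Methods

`boneguide` models low-frequency axial-transmission ultrasound in a
fractured long bone and quantifies the fracture through the amplitude
ratio of the two fundamental guided modes. This note records the models,
the numerical choices, and what the package's tests do and do not
establish.

## Physical model

The bone is a 2D three-layer waveguide: 2 mm of soft tissue over a 4 mm
cortical plate over 10 mm of marrow, all isotropic elastic solids (the
soft tissue and marrow are near-fluids with shear velocities of 0.10 and
0.07 mm/µs). Material parameters (density g/cm³, V_L, V_T mm/µs,
attenuation dB·cm⁻¹·MHz⁻¹):

| tissue | ρ | V_L | V_T | attenuation |
|---|---|---|---|---|
| cortical bone | 2.00 | 4.20 | 2.00 | 5.09 |
| soft tissue | 0.92 | 1.47 | 0.10 | 1.20 |
| marrow | 1.00 | 1.40 | 0.07 | 0.80 |

The marrow density is set to 1.00 g/cm³: published tables for this model
print 0.10 with inconsistent units, which is an order of magnitude below
any soft tissue and is treated as a typo. It is overridable in the
configuration (a warning is logged).

The fracture is a parallelogram band through the full cortical thickness:
at every depth the axial gap width is w (0–1 mm), and the band's mid-line
is tilted by the fracture angle θ from the vertical (θ = 0 is a
transverse fracture; the representable sweep angles are
0/14/18/26/37/45/53/63/76/83°). The gap is filled with soft tissue (an
unhealed fracture). Whether w should be measured axially or perpendicular
to the tilted faces is ambiguous in the source protocol; the axial
convention is used so w is comparable across angles, and the fill
material is configurable.

A 5-cycle Gaussian-modulated 100 kHz toneburst (support exactly
cycles/f0 = 50 µs, Gaussian σ = T/6) drives a 10 mm-wide vertical
traction strip on the free tissue surface at z = −z1 (z1 = 60 mm);
receivers of the same aperture record the surface vertical particle
velocity at z2 = 30–90 mm on the far side of the crack. At
f·h = 0.1 MHz × 4 mm = 0.4 MHz·mm only the fundamental S0 and A0 Lamb
modes propagate, so the received record is two packets separable by
arrival time.

## Dispersion solver

Free-plate Rayleigh–Lamb dispersion is solved in the pole-free product
form of the characteristic equations, with the evanescent
through-thickness wavenumbers (p² = ω²/V_L² − k², q² = ω²/V_T² − k²)
continued through zero by cosh/sinh and the common exponential growth
factored out, so the residual is real, bounded and continuous in phase
velocity and every sign change brackets a root. Branches are traced by
continuation (local re-bracketing around the previous root, full dense
scan as fallback), and group velocity is dω/dk by central differences on
the traced (ω, k) samples (default f·h step 0.005 MHz·mm; one-sided at
the ends). Internal units are mm, µs and g/cm³ throughout, so velocities
are mm/µs ≡ km/s and no conversion factors appear.

For the bone parameters above the solver gives, at 0.4 MHz·mm,
v_g(S0) = 3.445 and v_g(A0) = 1.938 mm/µs. These disagree with the
widely quoted windowing pair 3.95/1.51 km/s for this configuration; the
solver is validated against the closed-form thin-plate S0 limit
2·V_T·√(1 − V_T²/V_L²) = 3.5174 mm/µs (matched to 0.1%), the A0
low-frequency behaviour, and the Rayleigh-velocity asymptote
(c_R = 1.871 mm/µs; both branches within 1% by f·h = 5 MHz·mm — note S0
approaches the asymptote slowly and is still 23% away at 2 MHz·mm). No
isotropic free plate can produce 3.95 and 1.51 simultaneously at
0.4 MHz·mm, since the S0 group velocity is bounded by the plate velocity
3.52. The package therefore uses its computed velocities for window
planning; in the simulated layered model the measured packet velocities
are ≈3.44 (S0) and ≈1.6 (A0; tissue/marrow mass-loading slows the
flexural mode below the free-plate value).

Mode counting uses the standard cutoff ladder: the fundamentals always
propagate, and each higher mode cuts on at f·h = n·V_T/2 or n·V_L/2.

## FDTD solver

Elastodynamics is integrated with the standard second-order velocity–
stress staggered-grid (P-SV) scheme: normal stresses on integer nodes,
shear stress on (½,½) nodes, velocities on the half-staggered nodes.
Square cells; the time step is 0.8× the CFL bound dx/(v_max·√2) by
default. The often-quoted discretization pair (0.025 mm, 0.015 µs)
violates this bound by 3.6× and is rejected by construction; the solver
always derives a stable step.

* **Free surface** (top): stress-image condition — τyy ≡ 0 on the
  surface row (which leaves the effective plane-stress modulus in the
  τzz update) and the antisymmetric τzy image for the surface vz update.
  The source enters as a prescribed τyy traction on the aperture columns.
* **Absorbing boundaries** (both axial ends and below the marrow):
  convolutional PML, 20 cells, quadratic σ profile sized for a 10⁻⁸
  theoretical reflection, linear α frequency shift (max π·f0) and
  polynomial κ grid stretching (max 8). Measured normal-incidence P
  reflection at 100 kHz is ≈ −100 dB against a double-length reference.
  CPML is known to amplify slowly creeping interface-guided
  (Stoneley/Scholte-type) modes in layered media; these hug the layer
  boundaries, so a strong quadratic-depth sponge confined to within
  0.75 mm of each material interface (and the free surface) inside the
  PML strips suppresses the growth without affecting bulk-wave
  absorption. With this the layered model is stable well beyond the
  longest runs used anywhere in the package (≥3× margin at dx = 0.1 mm,
  verified also at dx = 0.05 mm).
* **Attenuation**: the tabulated coefficients are linear in frequency,
  which has no exact counterpart in a second-order time-domain scheme; a
  frequency-independent decay rate γ = att·f_ref·V_L·ln10/200 (1/µs) is
  matched at the 100 kHz center frequency (adequate for the narrowband
  excitation) and applied as a per-step exp(−γ·dt) factor on the whole
  state (velocities and stresses), so a plane wave decays at exactly γ
  in time. Per-distance decay therefore depends on the actual propagation
  speed of a packet; the quoted dB/cm figures assume travel at V_L.
* **Material sampling**: cell-centered properties coincide with the
  normal-stress nodes; densities are arithmetically averaged onto
  velocity nodes and the shear modulus harmonically averaged onto shear
  nodes (zero if any neighbour is fluid), the standard treatment for
  fluid–solid contrasts.
* Fields are single precision (the scheme is memory-bound; the measured
  quantities are amplitude ratios far above the float32 noise floor).
  Runs are bit-deterministic for a given configuration. An instability
  detector aborts a run if any field exceeds 10⁶× the source amplitude.

## Mode measurement

Packet amplitudes are peaks of the Hilbert-transform envelope — not raw
waveform extrema — inside temporal windows derived from the predicted
group arrivals z/v_S0 and z/v_A0: the shared boundary sits at the
midpoint of the two arrivals, the S0 window opens half a pulse before
its arrival, the A0 window closes one pulse duration after its arrival
(admitting the slower spectral tail of A0), and both windows are shifted
by the source group delay T/2 = 25 µs, since the toneburst peaks at
mid-support. Windows whose arrival gap is smaller than the pulse length
are flagged (`separation_ok = False`) but still measured; at z = 120 mm
the packets are resolved. The statistic is 20·log10(S0/A0), invariant to
source amplitude and coupling. Converted-mode packets (mixed-path delays
z1/v_a + z2/v_b) are predicted for annotation but not measured — they
overlap the direct modes for most geometries.

The synthetic trace generator used as the no-simulation fixture places
tonebursts at the direct delays (packet centers at z/v, no source
delay), optionally adds the two converted packets and seeded white
noise. It emulates packet timing and amplitude structure only — no
dispersion-induced packet spreading, no multi-mode tails, no coherent
reverberation — so tests built on it establish the correctness of the
measurement chain, not the realism of the waveforms.

## Sweeps and statistics

One simulation per (w, θ) cell records all receiver distances at once;
results are cached on disk keyed by a content hash of the grid and
configuration, so interrupted sweeps resume and repeats are free.
Cell failures are isolated and reported in a manifest rather than
aborting the sweep. Amplitudes are normalized to the intact model at the
same distance. Amplitude and ratio surfaces over (w, θ) use bicubic
smoothing splines (zero smoothing interpolates exactly). Sensitivities
are least-squares slopes of ratio_db over the full w grid (dB/mm) and a
continuous two-segment piecewise-linear fit over θ with the breakpoint
chosen by exhaustive search (dB/10°); distance stability is the RMS
deviation of ratio_db about its mean over z.

## Problem sizes

The package's standard ("desk") profile uses dx = 0.1 mm on a
240 mm × 16 mm domain (~10⁴ steps per run, under a minute each), which
resolves the operating wavelengths by >80 cells and the finest studied
crack by a few cells. The test suite and the acceptance script run a
reduced design at this profile: the intact benchmark with a five-receiver
scan plus single-receiver fractured cells covering the corners of the
(w, θ) grid. These reduced runs are lossless: intact-normalized
amplitudes cancel absorption to first order, while with absorption on
the slow direct A0 (75 µs of travel at z = 120 mm, ≈6× decay) competes
inside its window with faster converted/multipath arrivals that decay
far less, which blurs packet attribution at this grid scale. Full sweeps
through `run_sweep` keep attenuation on by default. The full-resolution profile (dx = 0.025 mm, 300 mm domain,
7.7M cells) is available behind a configuration flag; its per-run cost is
roughly two orders of magnitude higher and it is exercised in the tests
only up to construction and stability validation. Desk-scale grid
sensitivity: the transverse-crack A0 transmission changes by ~4% between
dx = 0.2 and 0.1 mm, the S0 packet arrival by ~1%, and the A0 packet
arrival by ~0.1% between dx = 0.1 and 0.05 mm.

## Known limitations

* 2D plane-strain plate model: no tubular geometry, no 3D spreading.
* Planar, full-thickness, constant-width cracks only.
* Free-plate dispersion for windowing; the loaded waveguide's A0 is
  measurably slower (≈1.6 vs 1.94 mm/µs), which the window margins
  absorb at the studied distances.
* Narrowband center-frequency attenuation matching; no viscoelastic
  memory variables.
* The measured desk-scale fracture contrasts are weaker than some
  published figures for nominally similar models (the transmitted A0
  across a 1 mm soft-filled transverse gap is ≈37% here, consistent with
  the closed-form thin-fluid-layer tunneling coefficient ≈0.6 for the
  accompanying S0 normal-stress transmission); see the acceptance script
  output for the measured values. The qualitative signatures — both
  amplitudes fall with w, A0 recovers with θ, S0 dips at mid angles, the
  ratio shift changes sign between transverse and steep-oblique cracks —
  are robust.
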