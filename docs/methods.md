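# Methods

This note records the models behind each stage of the package, the
defaults and why they were chosen, the numerical schemes, and what the
synthetic data does and does not emulate.  Units are SI throughout unless
stated; optical attenuation is quoted in mm⁻¹ (the field's convention)
and converted once at the registry boundary.

## Materials registry

Water at 1 atm / 20 °C: ρ = 998.2 kg m⁻³, c = 1480 m s⁻¹,
p_stat = 101 325 Pa, p_v = 2339 Pa, μ_a = 2.42 mm⁻¹ at 2080 nm (vapor:
0.001 mm⁻¹).  Fused quartz: ρ = 2200 kg m⁻³, c_L = 5970, c_T = 3760 m s⁻¹
(literature values).  Hard BegoStone (gypsum-based stone phantom):
ρ = 1995 kg m⁻³, c_L = 4159, c_T = 2319 m s⁻¹ from published phantom
characterization.  The BegoStone *optical* scattering/absorption and the
photoelastic (PSM-4) constants are stand-in values chosen to be
physically plausible; they are marked as substitutes in the data file and
are overridable by a user-supplied registry.  Every record is validated
against its physical invariants (e.g. c_L > c_T√(4/3)) at load time.

## Synthetic experimental inputs (`synth`)

The generators define the study conditions; their defaults are fixed once
and are not fitting knobs.

* **Power profile.**  0.2 J pulse, 70 µs FWHM.  The measured profile is
  not tabulated anywhere, so the default is a trapezoid: 10 µs linear
  ramp, flat top of 0.43·FWHM, linear tail whose end point follows from
  the requested FWHM (half-power points sit mid-ramp and mid-tail), all
  on a 150 µs support matching the total pulse duration used for
  segmentation.  Energy normalization is exact by construction; the flat
  shape uses half-value edge samples so its trapezoidal integral equals
  peak × FWHM exactly.
* **Bubble geometry sequence.**  30 segments of 5 µs.  Vapor masks are
  pear-shaped solids of revolution on a cell-centered (r, z) grid
  (z = 0 at the stone, z toward the fiber): widest near the fiber,
  tapered toward the advancing apex.  No vapor exists before an
  inception segment (default 0.7 × contact segment ≈ 17 µs, the
  superheating delay); the apex advances linearly and reaches the stone
  at segment 5 for SD = 0.5 mm, after which a virtual apex keeps sinking
  so the contact disc widens.  Per-segment volume-equivalent radii follow
  a sin^(2/3) ramp to R_e,max (volume grows as sin²); a fixed-point
  rescale of the radial profile makes each segment's voxel volume match
  its target to ≲0.1 %, and the final segment reproduces R_e,max within
  1 %.
* **Radius–time curve.**  Growth ∝ sin^(2/5)(πt/2t_max) to R_e,max at
  t_max, collapse ∝ (t_c−t)^(2/5) (the Rayleigh end-stage exponent) with
  t_c = k₁·2T_c, a rebound to (rebound fraction)^{1/3}·R_e,max — the
  volume-fraction convention, so the analyzer's ΔE_B/E_B equals
  1 − rebound fraction — and a mirrored secondary collapse.  Parameter
  sets whose collapse would precede the maximum (k₁·2T_c ≤ t_max) are
  rejected: with water defaults that rules out k₁ = 1 for R_e,max below
  ≈1.4 mm, which is the physics, not a limitation of the generator.
* **Hydrophone traces.**  Each requested (time, amplitude-at-1 mm) peak
  becomes a bipolar derivative-of-Gaussian transient (0.5 µs lobe
  half-width — shock-like but resolvable at the 5 MHz-equivalent
  sampling used in tests), shifted so the compressive maximum lands at
  the requested time, scaled by (1 mm)/d for a sensor at distance d, with
  optional seeded Gaussian noise.
* **Silhouettes.**  Axisymmetric projection of a half-width profile,
  optional Gaussian blur and seeded noise, ≥20 px across the bubble
  enforced.

What the synthetic data does **not** emulate: real shadowgraph intensity
structure (interference fringes, the cone bubble at the fiber tip),
asymmetric/fingered toroidal break-up, hydrophone calibration drift, and
the measured fine structure of the fiber power profile.  Closure tests
therefore demonstrate the *analyzers* are correct and self-consistent,
not that the generators reproduce any particular laboratory record.

## Photon Monte Carlo (`photon_mc`)

Packet transport with 3-D positions/directions over an axisymmetric
labeled voxel map (water / vapor / stone; medium looked up through
r = √(x²+y²)).  Launch: uniform over the 365 µm fiber core, directions
uniform in solid angle inside the NA cone (sin θ_max = NA/n_water,
NA = 0.26); NA = 0 gives a collimated beam.  Absorption is continuous
weight attenuation per step (step = half the smallest voxel edge), so the
energy ledger — absorbed + transmitted + escaped = launched — closes to
round-off by construction; zero-scattering transport is therefore *exactly*
Beer–Lambert on straight paths.  Scattering is drawn per step with
probability 1 − exp(−μ_s ds) and redirected by Henyey–Greenstein
inversion (stone default g = 0.9).  Packets below 10⁻⁴ of their launch
weight deposit the residual locally.  An optional absorbing target plane
tallies transmitted energy with the attenuation integrated exactly up to
the crossing point.  The bubble interior defaults to the vapor
coefficient 0.001 mm⁻¹; a `vacuum_bubble` switch zeroes it.  Refraction
and Fresnel reflection at the water/vapor and water/stone interfaces are
off by default (no reliable indices for the phantom at 2080 nm) — this is
the main reason the dynamic-geometry energy partition is
transmission-dominant (~18 % fluid / 82 % solid at SD = 0.5 mm) compared
with laboratory observations where roughly the opposite split occurs; the
imaged bubble's narrow channel and interface optics gate the real
transmission.  The Moses-limit bound (vapor channel wider than the beam →
>80 % transmission) is insensitive to this choice.

## Thermal ablation (`thermal`)

Cell-centered axisymmetric finite volumes, θ-scheme (Crank–Nicolson by
default; θ < 0.5 enforces the explicit stability bound and suggests a
step).  Homogeneous Neumann on all boundaries, so enthalpy is conserved
exactly on the insulated domain; the solver verifies against the 3-D
point-release heat kernel to <3 %.  Ablated cells become insulating voids
(zeroed face conductances) and never revert; their enthalpy is charged to
an ablation debit so the energy ledger still closes.

Ablation rule: a cell is removed when (i) its temperature reaches the
ablation temperature and (ii) the energy density deposited *during the
current pulse* exceeds the material's thermal resistance.  The per-pulse
reading of the dose condition is deliberate: a cumulative reading lets
deep cells stockpile dose over hundreds of pulses and the crater never
saturates (it burns through any finite domain), which contradicts the
observed saturation of crater growth.

Multi-pulse model (0.5 × 0.5 mm solid domain, 48² cells): each pulse
deposits absorbed_fraction × E_p (default 1 %) on the current crater
front with Beer–Lambert decay into the solid, the beam radius growing
with the fiber-to-front distance via the NA cone
(a(d) = a₀ + d·tan θ_div); four conduction steps during the pulse, four
during the inter-pulse interval at the 20 Hz repetition rate.
Calibrated defaults for the gypsum phantom: μ_a = 30 mm⁻¹ (strong
O–H-related absorption at 2.08 µm), ablation temperature 423 K (gypsum
dehydration onset), per-pulse threshold 1.5 × 10⁸ J m⁻³.  With these, the
SD = 0.5 mm run grows quickly and saturates at ≈0.07 mm³ — the observed
order of magnitude — though saturation completes by pulse ~50 rather
than 200–250: the smooth tail of the real process (burn-mark optics,
debris, irregular fronts) is outside this model.  Surface irradiance uses
the in-pulse average power convention; divide by the duty factor for a
pulse-rate-averaged figure.

## Inception and Rayleigh dynamics (`inception`)

The fully coupled compressible two-phase laser–fluid problem is replaced
by two desk-scale components; this replacement is the package's central
simplification and is stated prominently here.

* **Heat-to-nucleation.**  Collimated Beer–Lambert deposition in the
  water column under the fiber feeds either the conduction solver or an
  adiabatic balance (closed form
  t_nuc = ρC_pΔT/(μ_a I₀) for a flat top, matched to 2 %).  Nucleation is
  declared when the peak temperature reaches the chosen superheat T_vap
  (homogeneous-nucleation window 373.15–533.15 K, accepted up to
  673.15 K); the nucleus is the connected region at/above T_vap.  With
  the default trapezoid the model absorbs ~15 mJ by nucleation at
  ~10 µs — the right tens-of-mJ scale, profile-dependent.
* **Latent heat.**  mass × L with saturated-vapor density at T_vap
  (0.598 kg m⁻³ at 373 K, L = 2.257 MJ kg⁻¹).
* **Initial bubble pressure.**  Two models ship because the published
  GPa-scale figure cannot come from the saturation curve (4.7 MPa at
  533 K): `saturation` interpolates an embedded steam table
  (273–647 K, log-linear); `isochoric_stiffened_gas` gives the pressure
  of liquid heated at constant density, with its two EOS constants fitted
  so the window endpoints span 0.15–0.22 GPa.  Neither is asserted as
  "the" physical answer.
* **Rayleigh collapse.**  R R̈ + (3/2)Ṙ² = (p_in − p_stat)/ρ integrated
  with an implicit Radau method; the empty-cavity run stops at
  R = 10⁻⁴R₀ and adds the analytic end-stage tail
  t_c − t = (2/5)R/|Ṙ| (an O(ε^{5/2}) correction).  The collapse
  coefficient t_c/(R₀√(ρ/Δp)) evaluates to 0.91468, i.e. 0.915 at the
  printed precision, independent of R₀ and Δp over two decades.

## Emission analysis (`emission`)

Equivalent radius by solid-of-revolution row integration of binary
silhouettes; R_e = (3V/4π)^{1/3}.  Peak detection uses local maxima with
a prominence floor of 3× the trace noise RMS (so noise cannot enter the
significance rule); a peak is significant iff it exceeds 30 % of the
trace maximum *strictly*.  Peak pressures are referred to 1 mm by the 1/r
spherical-spreading law.  Pressure impulse is the trapezoidal integral
over a window; note it is a *signed* integral, near zero for a bipolar
transient.  The acoustic emission energy uses the far-field spherical-wave
form E_s = 4πr²/(ρc)·∫p²dt — the published analysis never prints its
formula, and this standard choice is consistent with the 1/r convention
(it makes E_s sensor-distance-invariant).  Primary and secondary burst
windows split at the rebound-maximum time.  Torus volume is
V = 2π²r_c r_t²; the compression ratio is a plain volume ratio.

## Wave solver (`waves`)

Axisymmetric velocity–stress staggered grid with *no field on a singular
1/r point*: normal stresses (and λ, μ) at (i+½, j), v_r at (i, j) with
v_r = 0 on the axis, σ_rz at (i, j+½) with σ_rz = 0 on the axis, v_z at
(i+½, j+½).  The fluid is the μ = 0 limit of the same isotropic update;
the harmonic-mean shear modulus at σ_rz points vanishes at the interface
row, giving the correct free-slip inviscid contact.  CFL number 0.45 on
the fastest wave speed; Cerjan exponential sponges (30 cells, α = 0.01)
on the outer boundaries.  Verified against: the 1/r free-field law
(≲1 %), normal-incidence reflection at a water/quartz interface
(R = (Z₂−Z₁)/(Z₂+Z₁) ≈ 0.80, matched to ~2 %), rigid-limit pressure
doubling (0.6 %), and monotone decay of the discrete energy (compliance-
form strain energy + kinetic) after source switch-off.

**Source.**  A monopole stress-rate injection in a ~1-cell Gaussian blob
of fluid at height h_c.  Because the radiated pressure of a point
monopole is the time derivative of the injection rate, a Gaussian rate
radiates a clean single-cycle bipolar pulse and a smooth-step rate
radiates a purely *compressive* Gaussian pulse; a plane (sheet) source
radiates the integral instead, so plane-wave tests inject the bipolar
rate.  Amplitudes are calibrated by a free-field run so the radiated peak
at 1 mm matches the request (linear, cached per grid spacing).  For
boundary-damage runs the compressive shape is the default: with a bipolar
source the rarefaction lobe itself puts large tension on the axis,
masking the off-axis leaky-Rayleigh tension that is the actual damage
mechanism; the measured boundary-stress structure (unipolar compression
on axis, leading-tension bipolar off axis) selects the compressive model.

**Head-wave angle.**  Ahead of the direct water arrival — bounded below
by hypot(r, z−h_c)/c — the only signal on a horizontal probe line in the
fluid is the Schmidt head wave radiated by the leaky Rayleigh wave
running along the interface at c_LRW > c.  Its pulse-peak arrival time
advances at dt/dr = 1/c_LRW, so a linear fit of (sub-sample-refined) peak
times along the line yields the interface speed and
θ = arcsin(c/c_LRW).  This front-trajectory fit replaces iso-amplitude
contouring of a snapshot, which is biased by the leaky wave's amplitude
decay along the front; on the default grid (6 µm, 0.08 µs pulse,
probe line at z = 0.35 mm, r = 1.3–1.9 mm) it reproduces the analytic
cross-check (free-surface Rayleigh root of
(2−x²)² = 4√(1−x²c_T²/c_L²)√(1−x²), Viktorov ≈ (0.87+1.12ν)/(1+ν)·c_T)
to better than 0.1°, giving 25.6° for quartz-like parameters
(c_T = 3780 m s⁻¹, ν = 0.17) against the measured 25.1°.

## Damage assessment (`damage`)

σ₁/σ₃ at boundary stations are principal stresses of the axisymmetric
tensor (the hoop component decouples; the in-plane 2×2 block is solved in
closed form).  SI = ∫(σ₁−σ₀)²dt over strict exceedances, trapezoidal,
σ₀ = 7.1 MPa for hard BegoStone; the damage band 6.7–8.8 × 10⁸ Pa²·s is
the comparison threshold.  Radial profiles of max σ₁ / min σ₃ use
parabolic sub-station peak interpolation and −6 dB (half-extremum)
widths; an extremum at the station-range edge is flagged unresolved (the
compression peak at R = 0 always is, by geometry).  Station spacing
40 µm out to 1.2 mm; grid 8 µm; source pulse width 0.1 µs (short enough
to behave shock-like — tension conversion weakens markedly for longer
pulses — while staying resolvable).

Source amplitude per standoff follows the measured primary-collapse peak
pressures: 30 bar at 1 mm for SD = 0.5 mm, 0.25 bar at SD = 1.5 mm,
16.4 bar at SD = 3.0 mm, log-linearly interpolated between anchors.
Collapse heights default to the observed ranges (30–60 µm at SD = 0.5 mm
up to 80–110 µm at SD = 1.0 mm).  With these conditions SI decreases
monotonically (≈linearly) over h_c = 30–110 µm, the compression peak
stays pinned at the axis while dropping ~50 % over 30–60 µm, and the
dusting configuration (SD = 0.5 mm, low h_c) exceeds the SD = 1.0 mm /
high-h_c configuration by far more than one order of magnitude in SI.
Absolute SI and peak-stress values depend on the unpublished fitted
source waveform and are *not* asserted — with the 30 bar / 0.1 µs
compressive default the model yields σ₁,max ≈ 11 MPa at R ≈ 0.57 mm and
SI_max ≈ 7.6 × 10⁵ Pa²·s, the right structure and ordering but a weaker
absolute loading than the published fitted-source simulation.

## Pipeline (`pipeline`, `cli`)

One JSON-serializable configuration, one global seed fanned out through
`numpy.random.SeedSequence` to the photon transport and trace synthesis;
reports embed the config hash, package version and seed, and identical
configurations produce byte-identical reports.  Stage failures are
recorded per stage without aborting independent stages.  The `lithocav`
command exposes each stage thinly (`synth`, `mc`, `ablate`, `incept`,
`emit`, `waves`, `damage`, `run`).

## Problem sizes

Defaults were chosen so the whole test suite and the acceptance script
run on a single CPU in minutes: Monte Carlo 10⁴–10⁵ packets on
125×125-voxel maps, conduction on ≤100×200 cells, wave runs on grids of
order 300×300–500×300 cells with 2–4 × 10³ steps.  All are plain
parameters; scale them up for production accuracy.

## Known limitations

* No refraction/Fresnel optics at phase boundaries; no fluid scattering.
* The full compressible two-phase Euler treatment of bubble expansion
  (and hence pear-bubble *dynamics*, as opposed to imaged geometry) is
  out of scope; the Rayleigh sphere stands in for collapse timing only.
* Thermal model omits burn-mark optical changes, pore micro-explosions
  and debris redeposition; its saturation is sharper than observed.
* Linear acoustics/elastodynamics only (the near-source Mach 1.23
  nonlinearity is ignored); homogeneous half-space by default, the
  two-layer (BegoStone on photoelastic block) option is geometric only.
* Absolute boundary-stress magnitudes await a measured source waveform;
  only shapes, locations, ratios and trends are meaningful.
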