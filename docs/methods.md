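# Methods

## Phantom data model

A voxel phantom is a 3D integer lattice indexed `(z, y, x)` with x the
anterior–posterior depth, y lateral, z the body axis.  The linear fill
order is x-fastest, then y, then z ("filled from the bottom"): element
`(z, y, x)` of the grid is `linear[z·ny·nx + y·nx + x]`.  This makes
`populate_lattice` a bijection between linear arrays and grids for fixed
dims, enforced by round-trip property tests.  The physical frame is
centred on the origin: voxel index `i` along an axis of `n` voxels has
its centre at `(i − n/2 + 0.5)·pitch` cm.  ID 255 is reserved for the
surrounding air and is forbidden in registries; ID 0 is accepted in fill
cards as a void label.  Fill cards are whitespace-separated integers
with an optional `<value>r<count>` run-length token and a
`# dims nx ny nz pitch` header; the writer emits run-length tokens for
runs of four or more.

Organ mass is `voxel count · pitch³ · density`, so total body mass is
exactly the sum of per-organ masses (air excluded) — a conservation
identity the tests assert.

## Photon interaction data

The bundled element table (`data/photon_coefficients_synthetic.csv`,
13 elements × 20 energies, 0.01–1.25 MeV) is **synthetic**: evaluated
photoatomic libraries are deliberately not a dependency.  It is
generated from

* exact Klein–Nishina incoherent cross sections (total and
  energy-transfer closed forms, unit-tested against numerical
  integration of the differential cross section),
* a photoelectric power law τ/ρ = C·Z^4.15/A·(0.01/E)^3.3, and
* a coherent power law σ/ρ = C'·Z^2.5/A·(0.01/E)^2,

with the two constants calibrated so that liquid water reproduces its
canonical attenuation coefficient at 10 keV.  Against standard water
values the table agrees to within roughly 10% over the full range, and
it preserves the Z- and E-trends (photoelectric dominance at low
energy and high Z) that the package's qualitative results rest on.
Limitations: no absorption edges (the iodine K edge at 33 keV is
smoothed over; iodine appears only as a 0.1% thyroid constituent), no
fluorescence escape (photoelectric events absorb fully), free-electron
incoherent scattering (binding corrections of a few percent at 10–30 keV
are ignored), no pair production (the table stops at 1.25 MeV).

Mixtures use Bragg additivity; interpolation is log–log linear, exact at
grid nodes and monotone between them; energies outside table coverage
raise rather than extrapolate.

## Synthetic body

`synthetic.generate_body()` paints 30 organs from geometric primitives
(ellipsoids, elliptical cylinders, shells, boxes) in priority order onto
a `(64, 64, 160)` lattice at 0.4 cm pitch (25.6 × 25.6 × 64 cm): an
elliptical trunk ~18 cm deep by ~22 cm wide, a head with skull shell and
brain, a spine column split into bone-surface annulus, cortical bone and
red marrow, thoracic and abdominal organs, and a one-voxel skin shell
obtained by binary erosion of the body mask so the shell is closed at
any resolution.  The organ inventory is the ICRP-103 effective-dose
inventory: the 14 weighted organs (colon segmented as upper + lower),
the 13 male remainder tissues, plus eye lenses and cortical skeleton
(unscored) — chosen so every effective-dose code path, including
remainder averaging and organ grouping, is exercised.  Compositions and
densities are ICRU-44-style tissue recipes stored in
`data/organ_registry_synthetic.csv`; the registry is a labelled stand-in,
not survey-derived anthropometric data, and is fully user-replaceable.

The only randomness is a seeded Gaussian jitter (σ = 0.15 cm) of
internal-organ centres; geometry is otherwise deterministic, so fixed
seeds give identical phantoms.  The trunk depth matters: with ~18 cm of
tissue the AP beam attenuation is of the order of a real abdomen, which
is what makes the energy trends below physically representative.  What
the synthetic body does **not** emulate: anatomical shape fidelity,
realistic organ masses (the body is ~16 kg), age/sex variation, limbs.
Tests passing on it demonstrate correctness of the transport and
dosimetry machinery, not agreement with any real phantom's dose values.

## Transport

Voxels are traversed with Amanatides–Woo stepping (`siddon_traverse`);
chords sum to the exact ray–box intersection length (checked to 1e-9
against an independent slab-clipping oracle on 1000 rays).  Primary
transmission is Beer–Lambert over the traversal and matches the
homogeneous-slab closed form to 1e-12.

**Radiography** casts one parallel +x ray per mesh cell centre (no
source sampling noise) and reports transmitted primary fluence per unit
incident fluence; grayscale export applies logarithmic normalisation.
Scatter is excluded from the image by construction, so the images are
idealised primary radiographs; the Monte Carlo engine exists for scatter
studies.

**Deterministic collision kerma**: per voxel along each column,
deposited energy is `E·φ_in·(1 − e^(−μΔ))·(μ_en/μ)`; the collided
non-absorbed share is booked as scattered escape, and the per-ray energy
balance (deposited + scattered + transmitted = incident) closes to 1e-9.

**Analog Monte Carlo**: primaries are sampled on the source plane and
their first interaction site is found by exact inversion of the
per-column cumulative optical depth (no majorant needed for the
monodirectional beam); scattered photons are tracked with Woodcock
delta-tracking using a per-energy majorant over all materials.  At a
collision the channel is chosen from (photoelectric, incoherent,
coherent) partial coefficients: incoherent from the mixture's electron
density and the Klein–Nishina total; coherent from the synthetic model's
power law clipped into the available total; photoelectric as the
remainder.  Photoelectric absorbs fully; Compton deposits the
transferred energy locally (kerma approximation) and continues the
photon with Kahn-sampled energy and angle; coherent events leave the
photon unchanged (a forward-scatter approximation — with the default
`rayleigh=False` this is statistically identical to removing the
coherent cross section from sampling).  Photons falling below the table
cutoff (10 keV) deposit their residual energy on the spot.  With
`scatter=False` every first collision scores the expected local kerma
`E·μ_en/μ` and terminates, which makes the estimator's mean exactly the
deterministic engine — the cross-validation the tests perform at 3
standard errors.  Uncertainties are standard deviations of the mean over
batches (default 10); the 1/√n scaling is asserted at ±20%.

The kerma approximation (no secondary-electron transport) is adequate at
diagnostic energies where electron ranges are sub-voxel; above roughly
1 MeV it progressively overestimates local deposition in small organs.

## Fluence normalisation and dose

The normalisation plane defaults to the source plane: fluence per source
particle is 1/A for a monodirectional plane source of area A.  Dose
conversion coefficients DCC = D_T/φ are then independent of the source
area for beams fully covering the phantom (asserted deterministically to
1e-9 and statistically for the MC engine).  Absorbed dose uses
C1 = 1.602176634×10⁻¹⁹ J/eV and C2 = 10¹² pGy/Gy.

Effective dose uses the ICRP-103 factors: 0.12 for red marrow, colon,
lungs, stomach, breast and the remainder; 0.08 gonads; 0.04 bladder,
oesophagus, liver, thyroid; 0.01 bone surface, brain, salivary glands,
skin — summing to exactly 1.  The remainder is the arithmetic mean of
the 13 remainder-tissue equivalent doses times 0.12.  The colon weight
applies to the mass-weighted mean dose of the upper and lower colon
segments (physically, the dose averaged over the merged tissue).
Uncertainties propagate in quadrature treating organ tallies as
independent.  All weights, remainder membership and organ groupings are
configuration, not constants.

## Comparison statistics

Missing-value policy is pairwise-complete-case throughout: RMSE between
two series uses only energies where both are defined (the count is
reported alongside every RMSE), and the multi-model average at an energy
is the arithmetic mean over the models defining it.  This policy is
itself validated: applied to the packaged published AP effective-dose
table it reproduces every published pairwise RMSE to 5×10⁻⁶, including
the 7-point MCNPX comparisons, and the published average column
including the energy where MCNPX is absent.  Display rounding follows
published-table conventions (4 significant figures for ED, 2 decimals
for percent differences); internal arithmetic is full precision.  RMSEs
involving the model average are computed from full-precision averages,
not re-rounded ones; the difference is below 1e-3.

## Deck export

The XML exports target the four-card family (materials, geometry,
settings, tallies) structurally: organ-ID-numbered materials plus air as
255, a rectangular lattice with centred lower-left corner and 750/800 cm
bounding spheres (outer boundary vacuum), a fixed-source monodirectional
+x plane source with a single discrete energy line, and
universe-filtered heating plus 1×1000×1000 mesh flux tallies.
Validation is by round-trip through the module's own parsers; byte-level
fidelity to any particular external code version is not claimed, and the
external code is never executed.

## Problem sizes and defaults

Defaults are chosen as the package's study conditions: the 20-energy
grid 0.01–1 MeV for dose tables; radiography demo energies 0.07 and
0.12 MeV; 10 batches; MC history counts of 10⁵ for engine
cross-validation (giving per-organ relative errors of ~1%); the
`(64, 64, 160)` body for imaging and dose trends.  The deterministic
kerma engine (exact expectation of the scatter-off MC estimator) is used
for the monotonic ED(E) measurement, since monotonicity is a property of
the attenuation physics rather than of Monte Carlo noise; MC appears
wherever the statistical estimator itself is the object under test.

## Known limitations

* Synthetic coefficient table (~10% absolute accuracy; no edges): dose
  *magnitudes* are approximate even though unit conversions, geometry
  and statistical machinery are exact.
* Kerma approximation; no electron, neutron or proton transport; no
  variance reduction.
* Primary-only radiography (no scatter fog in images).
* Coherent scattering is a no-op by default rather than sampled from a
  form factor.
* The synthetic body is stylized; its absolute organ doses are not
  comparable to reference-phantom tabulations and are not presented as
  such.
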