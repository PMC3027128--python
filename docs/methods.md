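# Methods

`scatterdose` estimates the dose scattered to internal organs (contralateral
breast, spleen, posterior ipsilateral lung, anterior heart at the LAD
position) by five adjuvant breast-radiotherapy techniques, and converts the
organ doses into lifetime fatal secondary-cancer risks.  This note records
the model, its assumptions, the parameters that matter, and what the
desk-scale simulations can and cannot show.

## Photon interaction model

Component mass-attenuation tables (photoelectric, incoherent, coherent,
pair) are *computed* from a compact analytic model rather than shipped as
data files:

| channel | per-atom cross-section | anchor |
|---|---|---|
| incoherent | exact Klein–Nishina total, free electron, × Z | closed form |
| photoelectric | `1.0e-32 · Z^4.5 / E^3` cm² (E in MeV) | water ≈ 0.485 cm²/g at 20 keV |
| coherent | `6.5e-30 · Z^2.5 / E^2` cm² | water ≈ 0.10 cm²/g at 20 keV |
| pair | `9.9e-28 · Z² · ln(E/1.022)` cm², above threshold | water ≈ 0.005 cm²/g at 10 MeV |

Tables are sampled on a 96-point log grid over 5 keV–8 MeV and interpolated
log–log, so the power-law channels round-trip essentially exactly.  The
Compton-dominated mid range (100 keV–5 MeV) that controls the scattered-dose
comparison is therefore accurate to better than ~1% for light materials
(water at 1 MeV: 0.0707 cm⁻¹); the approximate photoelectric/coherent
channels control only the low-energy (Pd-103) regime, where the model is
qualitatively correct but not benchmark-grade (no absorption edges; iron's
K-edge is smoothed over).  Materials: water-equivalent soft tissue
(ρ = 1.0), lung (water at ρ = 0.26), air, steel (pure-iron surrogate at the
quoted ρ = 7.81 g/cm³), vacuum.

Source spectra: Ir-192 and Pd-103 as embedded decay-scheme line tables
(normalised on load; table means 0.372 MeV and 0.021 MeV — the Ir-192
average is the quoted ~367 keV), and a 6 MV bremsstrahlung stand-in as a
Gamma(2, 0.9 MeV) distribution truncated to 0.25–6 MeV (mean ≈ 1.8 MeV,
scale configurable).  The accelerator phase space itself is not modelled;
only relative scatter behaviour is needed.

## Phantom

A constructive-geometry chest phantom honouring the printed anatomy
constraints: overall bounding box 26 × 12.2 × 70 cm (within 5% of the
nominal 12 × 26 × 70), breast volumes exactly 520 cc, a 150 cc spherical
spleen tally 5 cm inferior to the field edge, and 0.65 cc tally spheres in
both breasts, the anterior heart and the posterior ipsilateral lung.
Coordinates: origin at the phantom centre, +x patient-left, +y anterior,
+z superior; the treated breast is the left one.

Realisation (the reference gives no surface equations): a water-equivalent
slab torso, thicker in the abdomen (inferior to the field) so the 150 cc
spleen tally fits inside tissue; breasts as half-ellipsoid domes on the
chest-wall plane with a midline gap (lateral semi-axis 4.8 cm, height
6.1 cm, superior–inferior semi-axis solved for 520 cc); half-ellipsoid
lungs, an ellipsoidal heart left of midline, a spherical spleen.  Overlaps
resolve by integer priority (heart > lungs > breasts > spleen > chest wall >
body > world).  Tally centres are configuration, not constants.

The treated-breast tally sits on the brachytherapy prescription surface
(target centre + 3 cm along (1,1,1)/√3): the HDR dose is prescribed to the
85% isodose surface and the seed-implant dose to the minimal peripheral
dose, so anchoring the normalisation at the target *centre* would
under-state every brachytherapy organ dose by the centre-to-surface dose
ratio.  For the tangential beams the point is mid-field, so external-beam
normalisation is unaffected.  The point is chosen off the dwell/seed
lattice so no source can sit inside the tally sphere.

## Beams and modifiers

External beams are opposed point sources at 100 cm SAD collimated to a
rectangular aperture at the isocentre plane.  Tangents are realised as
half-beam-blocked fields (effective transverse width = half the nominal
16 × 20 / 8 × 20 cm² collimator setting, the same half-beam arrangement as
the out-of-field measurements), tilted 45° anterior–posterior in the axial
plane, with the deep field edge at ~1 cm lung margin and the anterior jaw
clipped so neither the contralateral-breast nor the posterior-lung tally
lies in a primary cone.  On a flat-slab phantom this tilt is the geometric
condition for a "tangent": a purely lateral beam would irradiate the
contralateral dome directly.  A consequence of the slab geometry is that
the anterior-heart (LAD) tally *is* inside the tangent fields, so external
heart doses are primary-dominated and much larger than published values;
the heart is therefore excluded from the scatter-ordering checks.

The physical wedge is a 30° steel prism spanning the diverged aperture,
placed 75 cm from the source (a compensator tray ~25 cm above the
isocentre plane), thickness growing anterior-medially.  It participates in
transport as a geometry region, so wedge-scattered photons reach the
phantom and the out-of-field tallies — the mechanism behind the
compensator-dominated scatter budget.  Field-in-field "IMRT" delivers 80%
of histories through the open aperture and 20% through the posterior half
(segment weights configurable).  HDR: 123 dwells on a 1 cm grid in the
3 cm target sphere, uniform loading, Ir-192 lines, isotropic emission.
PBSI: 100 seeds on a jittered ~1.04 cm lattice, Pd-103 lines.

Dwell times use a point-source dose model, inverse-square × exp(−μ_eff r)
with μ_eff = 0.03 cm⁻¹, a dose-rate constant of 1.11 cGy h⁻¹ U⁻¹ and
4037 U/Ci for Ir-192.  The prescription is met at the *median* surface dose
(lattice dwells can lie exactly on the prescription sphere, which makes the
surface mean of 1/r² ill-defined; the median is the robust peripheral-dose
statistic).  The vendor inverse-planning optimiser is out of scope; dwell
times only set treatment-time scale, since organ doses are normalised
through the treated-breast tally.

## Transport

Vectorised photon random walk under the kerma approximation: photoelectric
events absorb locally; Compton events (Kahn's Klein–Nishina sampler)
deposit the electron energy locally and continue the scattered photon;
coherent scattering (Thomson-shaped, simulated below 100 keV only)
redirects without deposition; pair production deposits E − 1.022 MeV and
emits two back-to-back 511 keV photons; photons below the 5 keV cutoff
deposit locally.  Energy is conserved exactly per history (deposited +
escaped = emitted, asserted to 1e-9 relative).  No electron transport — the
main physics simplification relative to a coupled pulse-height tally; for
small tallies in charged-particle equilibrium the collision-kerma score is
a reasonable surrogate.  No variance reduction by default (an optional
weight roulette exists but is off).

Runs are split into batches (default 20) with independent substreams
spawned deterministically from the master seed; the relative error is
R = (s/√n)/mean over batch means, with R < 5% the conventional reliability
threshold.  Desk-scale runs use 10⁶–4×10⁶ histories — far below the 10⁹ of
a production study — so out-of-field tally errors are reported, not hidden:
the 150 cc spleen tally reaches R ≈ 1–3% at 10⁶ histories, while the
0.65 cc contralateral-breast and lung tallies sit at R ≈ 20–50% and are
only meaningful pooled across seeds.

Photons that have left the anatomy (and any beam-line region) into the
enclosing air region are retired as escaped without simulating the
remaining air path; air scatter outside the beam corridor is part of what
the measured leakage term represents.

## Hybrid out-of-field model

Head leakage and room back-scatter cannot be reached by desk-scale Monte
Carlo, so they are measured quantities: relative dose at 5 cm depth,
2.5/7/10/19/28 cm from the axis, two field sizes, fitted per field size
with a power law a·d^b in log–log space and interpolated linearly in field
area for unseen sizes.  The packaged measurement table is synthetic
(generating laws a = 0.036/0.030 for 16×20/8×20 cm², b = −1.2, 5%
log-normal noise), chosen once to honour the two qualitative anchors — the
fraction drops below 1% of the central-axis dose away from the field, and
the large field runs 20% hotter — and never claimed as the original data.
The hybrid organ total is MC scatter + fraction(distance) × prescription,
with per-organ distances from the field edge carried as configuration
(spleen 5 cm as described anatomically; contralateral breast 3, lung 4,
heart 3 as phantom-geometry estimates).

## Dose and risk accounting

Organ doses are normalised so the treated-breast tally equals the
prescription exactly (50 Gy/25 fx wedge and IMRT, 38.5 Gy/10 3D-CRT PBI,
34 Gy/10 HDR, 90 Gy PBSI); mSv ≡ mGy for photons (radiation weighting
factor 1).  Report rounding matches the printed convention: integers for
mSv rows, one decimal for Gy rows.  The balloon-applicator variant is
reproduced via the stated +44% relation on the catheter-HDR column, not by
geometric modelling.

Lifetime fatal secondary-cancer risk = NCRP Report 116 coefficient
(breast 0.20 %/Sv on the contralateral-breast dose, lung 0.85 %/Sv on the
ipsilateral-lung dose) × dose in Sv, rounded half-up to two decimals —
this rounding reproduces every published cell, including 0.00% for the
seed implant's 2.2 mSv.  The 17%/Gy excess-relative-risk slope for
ischaemic heart disease is exposed as a literature-cited constant only.

The compensator/internal/leakage decomposition attributes the compensator
share by paired-run subtraction (same seed, with and without the wedge),
clamping negative differences to zero with a warning.  This is unbiased in
expectation but ignores that the wedge also attenuates internal scatter,
so the compensator share is, if anything, under-estimated.

## What the tests show — and what they do not

Exact stages (risk table, balloon arithmetic, plan arithmetic, batch
statistics, leakage fitting) reproduce the published worked numbers to
printed precision.  The transport engine is validated against closed-form
oracles: exp(−μt) transmission, attenuated inverse-square dose ratios
(numerical-quadrature oracle), exact energy conservation, 1/√N error
scaling, and Klein–Nishina angular quadrature.

The absolute published organ-dose table and percentage splits are *not*
reproducible at desk scale: they came from 10⁹-history runs with the
authors' exact phantom and accelerator phase space.  The simulator is held
instead to the published qualitative orderings, asserted on tally means
pooled across five seeds at 1–2 × 10⁶ histories per run: physical wedge >
field-in-field for contralateral-breast and spleen dose; HDR lung dose
above every external-beam technique; the Pd-103 implant lowest for the
contralateral breast; and the compensator the leading contributor to the
wedge technique's scatter budget (summed over contralateral breast, spleen
and lung — the heart is excluded because it is primary-lit in this
geometry).  The synthetic leakage fixture, slab anatomy and analytic
spectra mean that agreement here demonstrates correct mechanism and
direction, not clinical dosimetry accuracy.

## Numerical choices and degenerate inputs

Log–log interpolation with zero-component guards; surfaces are crossed
with a 10⁻⁶ cm push and candidate crossings below 10⁻⁷ cm are ignored
(grazing/tangent rays count as non-entering); ray–geometry queries batch
all ellipsoids/boxes/half-spaces per step; a flight-step limit of 2×10⁵
guards against infinite loops.  Zero-mean tallies return R = ∞ rather than
raising; a zero treated-breast tally is a hard normalisation error.
Single-seed plans place the seed at the target centre; jittered seeds are
re-projected inside the target sphere.

## Known limitations

Kerma approximation (no electron transport) near tally boundaries; slab
anatomy puts the LAD tally in-field and exaggerates heart dose;
half-beam/45° tangent realisation is a geometric idealisation; analytic
photoelectric/coherent cross-sections are edge-free approximations;
Pd-103's weak 357 keV gamma line is included, which makes the PBSI
contralateral dose larger (tens of mSv at desk scale) than a fully
encapsulated seed model would give; the leakage fixture is synthetic; the
balloon column is an arithmetic relation, not a simulated applicator.
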