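# Methods

This note records the models behind each analysis, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want written down.

## Isotherm analysis

**Compression modulus.** Cs⁻¹(A) = −A·(dπ/dA), evaluated by central
finite differences (`numpy.gradient`, one-sided at the endpoints) on an
optionally smoothed π(A). Smoothing is a Savitzky–Golay local
polynomial, default window 11 samples, order 3; it is applied only on
(near-)uniform APL grids — the filter assumes uniform spacing — and
falls back to the raw derivative otherwise. Derivatives amplify noise,
so the default window is a compromise: wide enough to keep Cs⁻¹ usable
at instrument-level noise (±0.1 mN m⁻¹ on π), narrow enough not to
smear genuine phase kinks. The raw-derivative mode (`smoothing=None`)
is exact on clean data.

**Phase classification.** The Davies–Rideal bands on Cs⁻¹ (mN m⁻¹):
≤12.5 gaseous, ≤50 liquid-expanded, ≤100 LE–LC coexistence, ≤250
liquid-condensed, >250 solid. Band boundaries belong to the lower band
so classification is a deterministic, total, monotone step function.

**Lift-off.** "π rises above 0" is not operational against noise, so
the detector (i) takes the baseline as the median π over the leading
10 % of samples (largest areas), (ii) finds where π first exceeds
baseline + 0.5 mN m⁻¹ (the threshold is ~5× the stated instrument
accuracy), then (iii) fits a hinge model — π = baseline above the onset
area, linear rise below — by least squares over the samples up to ~6×
the threshold, scanning 400 candidate onset positions. The hinge apex
is reported. Unlike the raw threshold crossing (which sits ~0.7 Å²
down-slope on a Cs⁻¹ ≈ 60 curve), the hinge estimate is unbiased to
<0.02 Å² on clean curves and stays within one 0.25 Å² grid step at
noise σ = 0.1 mN m⁻¹.

**Collapse.** During compression dπ/dA is strongly negative; collapse
is the first sample — after π has exceeded half its maximum — where the
derivative changes sign or its magnitude drops below 5 % of its peak
(the plateau tolerance). A strictly rising branch returns no collapse
rather than an error, since a film may simply not be compressed far
enough.

**Relaxation.** For A/A₀(t) at constant π: area loss = 1 − min(A/A₀);
the initial rate is the negated least-squares slope over the first 10 %
of samples (≥3); the exponential constant comes from a log-linear fit
over the strictly positive samples. The log fit is appropriate for the
near-exponential decays these films show; for strongly non-exponential
traces the initial rate is the more faithful number.

## Surface-potential analysis

μa = ΔV·A·ε₀ with A converted Å² → m², ε₀ = 8.8541878128×10⁻¹² F m⁻¹,
and the C·m result divided by 3.33564×10⁻³⁰ to give Debye. The
monolayer's own permittivity is unknown in principle, so only this
apparent (vacuum-permittivity) moment is computed — no three-layer
capacitor decomposition. The critical area is the APL of maximum
|d(ΔV)/d(APL)| on the smoothed curve; a maximum-slope definition was
chosen over a threshold crossing because no numeric ΔV criterion exists
for these films, and the inflection of a sigmoidal rise is
parameter-free.

## Composition and dosing

Drug mass concentration uses C % w/w = 100·n·MW_d/(n·MW_d + Σ N_i·MW_i);
Avogadro's number cancels. The integer count for a target concentration
solves the real-valued inverse and returns whichever of floor/ceil
minimises |C(n) − target| (ties to the smaller count), so the inverse
round-trips within one molecule's quantisation.

Reference constants: DPPC 734.04, POPC 760.08, POPG 770.99 (sodium
salt, matching the purchased material; configurable), CHOL 386.65,
mometasone furoate 521.40 g mol⁻¹. The reference film is 1224 DPPC +
408 POPC + 200 POPG + 200 CHOL = 2032 molecules in two leaflets (1016
per leaflet) — the only per-leaflet count that reproduces the
box-edge ↔ APL table (223.1 Å ↔ 49 Å², …, 249.2 Å ↔ 61 Å²). Two flags
worth knowing:

* the nominal 60:20:10:10 mol% mixture converts to 62.2/21.5/10.9/5.5
  mass % — cholesterol is commonly quoted as 6 % but computes to 5.46,
  which this package reports as-is (rounded 5) rather than forcing;
* a 220.0 Å box at 1016 per leaflet computes to APL 47.6 Å², not the
  47 sometimes quoted next to it; the arithmetic here flags it.

Quoted per-system drug masses in mg (0.32…6.63 for 0.72…14.84 % w/w)
depend on a lung-pool mass and a 50 %-deposition-efficacy factor that
are not combined by any stated formula, so they are carried as metadata
only, never recomputed.

Integer reporting (mass %, APL) uses round-half-to-even for
determinism; raw values are always retained alongside.

## Trajectory analysis

All distances use the orthorhombic minimum-image convention; triclinic
boxes are rejected at the IO layer (scope control). Coordinates are nm
internally.

**Order parameters.** P2 = (3⟨cos²θ⟩ − 1)/2 per bonded bead pair, θ
against the z axis (the monolayer normal). The default chain topology
lists four-bead MARTINI-style chains per phospholipid (C1–C2/D2,
C2/D2–C3, C3–C4 bonds per chain); the unsaturated oleoyl chain (D2
bead) is carried as sn-1 for POPC/POPG, matching how per-chain values
are reported for this lipid set, and the bead names are configurable
per species. Averaging is over molecules within a frame, then over
frames; the frame-to-frame SD is reported.

**Surface tension.** γ = (L_z/n_interfaces)·⟨P_zz − (P_xx+P_yy)/2⟩,
with bar·nm → mN m⁻¹ (factor 0.1). `n_interfaces` defaults to 2 — the
symmetric double-monolayer slab that standard monolayer builders
produce — and is configurable to 1. The uncertainty is the standard
error over 5 blocks; note a 5-block SE is itself noisy (χ² with 4
degrees of freedom), so treat ±3 SE as indicative, not exact.

**RDF.** Distance-histogram g(r) normalised by ideal-gas shell counts
at the box's mean density, default cutoff 1.0 nm, with raw pair counts
returned so tests can compare against brute-force enumeration. Whether
a monolayer g(r) should be spherical (3-D) or lateral (2-D) is a
genuine choice; both modes are provided (`mode="3d"` default,
`mode="2d"` normalises by rings at the areal density) and neither is
claimed as canonical.

**Clustering.** Molecules are linked when any bead pair lies within the
cutoff (single linkage, minimum image); clusters are connected
components (`scipy.sparse.csgraph`). Results are independent of
particle ordering.

**Pores.** Lipid beads are projected onto x–y; grid cells (default
0.25 nm) within a footprint radius of any bead are occupied; connected
empty components (4-connectivity, periodic wrap via union-find across
the boundaries) with area ≥ 1 nm² are pores. The footprint radius
defaults to 0.6 nm — large enough that an intact film at APL ≤ ~61 Å²
(lattice spacing ~0.78 nm) closes its interstices and yields zero
pores; for denser bead fields use radii down to the single-bead vdW
scale (~0.26 nm). Detected areas are the *empty* region: an excised
disk is eroded by up to the footprint radius plus half a lattice
spacing, so area comparisons must use that margin (the tests do). On
fine bead fields the detected area converges to the analytic disk area
as the grid cell shrinks.

**Collapse.** Per-frame interdecile range (q90 − q10) of head-bead z;
a frame is collapsed when the spread exceeds 3× the first frame's
(flat-film) spread, floored at 0.5 nm so a near-perfectly flat baseline
does not make thermal jitter look like collapse. Sarle's bimodality
coefficient of the z distribution is reported as supporting evidence.

**Roughness.** Ra = mean |z − mean(z)| of an ordered height profile, in
the input units — the standard mean-roughness definition used for AFM
cross-sections.

## Synthetic generators

Each generator uses one explicitly seeded `numpy.random.Generator` (no
global state), attaches a machine-readable ground-truth record, and is
byte-identical under a fixed seed.

* **Isotherms**: piecewise-modulus model — π = 0 above the lift-off
  area, dπ/dA = −Cs⁻¹/A within each contiguous segment (so π grows as
  Cs⁻¹·ln(A_top/A)), plateau at the collapse pressure, optional
  Gaussian noise. Defaults embed the reference film's structure:
  lift-off 86 Å², collapse 42 mN m⁻¹, a single segment with Cs⁻¹ = 75
  (the middle of the LE–LC coexistence band where these films peak),
  0.25 Å² grid from 110 Å².
* **Scenes**: one leaflet of lipids on a vacancy-free jittered lattice
  at the requested APL (rows share the count as evenly as possible),
  chains as straight 0.47 nm-spaced bead rods at the prescribed tilt
  (delta tilts are exact, so P2 limits are reproduced to machine
  precision), head beads stacked into the subphase. Drugs are placed
  dispersed (Gaussian about the head-group plane, laterally separated),
  aggregated (z-stacked chains of prescribed cluster sizes at mutually
  distant lateral positions), or airborne; pore disks excise lipids;
  collapse displaces a molecule fraction downward — on frames after the
  first when several frames are generated, keeping a flat baseline
  frame. Default composition is the 1016-per-leaflet reference film.
* **Pressure series**: anisotropy set to γ·n_interfaces/(0.1·L_z) bar
  so the tension estimator's expectation equals the target (default
  23 mN m⁻¹, the drug-free inhalation-condition value), plus optional
  per-component Gaussian noise.
* **Potential curves / relaxation traces**: sigmoidal ΔV with the
  inflection at the prescribed critical area; exponential or linear
  A/A₀ decay with the prescribed constant.

What the scenes are *not*: equilibrium ensembles. They are geometric
fixtures — no thermal disorder beyond lateral jitter, no water, no
realistic chain conformations, no interactions. Passing recovery tests
therefore demonstrates that the measurement code inverts its generators
correctly at the study's scales and compositions; it does not validate
force fields, sampling, or any experimental value. The experimentally
reported numbers themselves (86 Å² lift-off, 42 mN m⁻¹ maximum π, AFM
roughness tables, the 23 → 15 mN m⁻¹ tension drop with drug load, the
umbrella-sampling partition coefficient) require the lab data or
microsecond coarse-grained simulations and are deliberately outside
what this package claims to reproduce; the generator defaults embed the
curve *shapes* so the detectors are exercised on realistic structure.

## Problem sizes and test conditions

The recovery suite runs each estimator across 10 seeds at conditions
chosen once: isotherm noise 0.1 mN m⁻¹ (instrument accuracy) for
lift-off, 0.05 for collapse, 0.004 for the modulus (a derivative-based
quantity; this is the precision of replicate-averaged smoothed curves,
and the 100-fold noise amplification of the window-21 derivative maps
it to the ±0.5 mN m⁻¹ tolerance), ΔV noise 5 mV (the stated sensor
sensitivity is ±1 mV), relaxation noise 10⁻³, pressure noise 10 bar
over 10⁴ samples. Scene-based tests use a 200-lipid leaflet with the
reference mole ratios; the acceptance script uses the full 1016-lipid
leaflet (~5500 bond vectors). The ideal-gas RDF check uses 500
particles × 50 frames with 5 bins so every bin holds >1500 expected
counts and the ±0.05 flatness band is ~2σ.

## Known limitations

* PDB output truncates 4-character residue names to 3 (fixed-column
  format); GRO and XYZ round-trip names verbatim. GRO coordinates
  round-trip to its native 10⁻³ nm precision.
* Savitzky–Golay smoothing silently degrades to the raw derivative on
  non-uniform APL grids.
* The pore detector reports empty-region areas, biased low against the
  excised-disk area by the erosion margin described above.
* Single compression branch only — no compression–expansion hysteresis.
* Exact experimental Cs⁻¹ curves are not reproducible (the smoothing
  scheme used for published curves is unstated); the modulus is treated
  at property level.
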