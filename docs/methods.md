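# Methods

## Model

Dynamic quadrupole selection narrows the selection window symmetrically and
linearly from a starting width *w* (Th) to an end width (default 0) over the
ion accumulation period, holding the center *c* fixed. The relative
accumulation of an ion at *m/z* is the transfer function
T(m/z, c, w) = 1 − 2|m/z − c|/w inside the window and 0 outside; the
boundary |m/z − c| = w/2 maps to 0. A positive end width generalises T to a
trapezoid with a flat top (end width equal to the start width recovers a
static window; this is how MS1 scans are modelled). Averaged over the
window, T is exactly 1/2 for any width: dynamic selection halves the
effective accumulation relative to a static window of the same width.

Observed intensities are A·t·T, with A the extrinsic abundance rate (signal
per ms at full transmission; it absorbs concentration, ionisation and
transfer efficiencies) and t the accumulation time. Product ions inherit
their precursor's transmission scaled by a per-product yield. Inference
treats (m/z, A) as the two unknowns.

### Inverse method

- **Two-point solver.** Two scans at centers c₁ < c₂ give
  Iᵢ = A·T(x, cᵢ, w). The sign of x − cᵢ is unknown, so three branch
  hypotheses are enumerated (x below both centers, between, above both);
  each candidate must reproduce both observations and respect its branch
  geometry. More than one consistent branch sets an `ambiguous` flag (the
  between branch is preferred); none raises an error. A zero observation
  only brackets the precursor at the silent window's edge; the solver then
  returns the nearest consistent point (exact when the precursor sits at a
  selection center and both neighbours are silent).
- **Profile regression.** Dense profiles are split at the maximum-intensity
  center (ties toward the lower center) and an ordinary least-squares line
  is fitted per flank. The maximum point itself generally samples only one
  of the two flank lines, so it is excluded from both fits whenever each
  flank retains ≥ 2 other points — this keeps noiseless fits exact whether
  or not the grid hits the apex. The estimate is the line intersection
  (abscissa: m/z; ordinate: static-window-equivalent intensity); the flank
  zero crossings are the x-intercepts, whose span equals w for a clean
  profile. Leading/trailing zero-intensity points are trimmed (they lie
  beyond the intercepts); interior zeros are kept. A flank with < 2 points
  falls back to the two-point solver on the two most intense points, or on
  a single positive point paired with an adjacent zero.
- **Association.** Product peaks are matched across scans by
  single-linkage grouping at 25 ppm, keyed by intensity-weighted mean m/z,
  and flux-normalised by each scan's actual accumulation time, which makes
  estimates invariant to AGC-chosen accumulation times. Each group is padded
  with explicit zeros at the scanned centers immediately adjacent to its
  observed centers: absence from an overlapping neighbouring window is
  physically informative and lets a precursor lying exactly on one
  selection center still be located. Groups with fewer than two points
  after padding are dropped and counted.
- **Clustering.** Products are grouped into pseudo-spectra by sorting the
  per-product precursor estimates and splitting where consecutive estimates
  differ by more than 0.6 Th (twice the demonstrated 0.3 Th accuracy; no
  clustering rule is implied by the accuracy figure itself). The reported
  precursor m/z of a pseudo-spectrum is the apex-intensity-weighted mean of
  its members' estimates.
- Association is geometric throughout; no statistical scoring or FDR
  machinery is applied, and isotopolog-bearing estimates are interpreted as
  the contribution-weighted mean m/z without a monoisotopic correction.

### Quadrupole physics

Voltages (U DC, V RF) map to Mathieu coordinates a = 2CU/(m/z),
q = CV/(m/z) with C = 4e/(u·Ω²·r0²) (CODATA constants; the ion charge
cancels in the m/z formulation). Stability in the first region requires
a < b₁(q) (x motion) and a < −a₀(q) (y motion); the characteristic curves
are evaluated with scipy's Mathieu routines, and their intersection — the
apex q ≈ 0.70600, a ≈ 0.23699 — is resolved at run time. The test suite
cross-checks the curves against an independent tridiagonal-eigenvalue
formulation. `voltages_for_window` reduces the two-edge condition to a
one-dimensional root problem in V (the operating-line slopes demanded by
the two edges must agree) and is solved with Brent's method to 1e-11 V;
bands round-trip to well under 0.05 Th over 150–1750 Th.

At 1.1 MHz and r0 = 4 mm, a 10 Th window at 200 Th requires 274.9 V RF with
a 4.69 V slew to the apex (the printed instrument-simulation values are
277 V and ~4.7 V; the ~0.8 % offset is within the spread expected between
boundary-curve and trajectory-integration conventions), 9.52 V for a 20 Th
window, and 2092.6 V at 1500 Th (printed: 2109 V).

**Slew convention.** The default slew narrows the *window width* linearly in
time (the defining behaviour of the method); the voltages then follow the
calibration curve and stay within ~0.4 % of the straight chord between the
endpoints — "a nearly constant change" in voltage. A strictly
voltage-linear mode is also provided: because the −a₀ boundary is curved,
it bows the high-mass band edge and distorts the realised profile by about
1.5 % (sup-norm, 10 Th at 200 Th), which is measurable but has little
effect on inferred m/z. Band integration uses midpoint time slices
(default 1000; halving the step changes results by < 0.1 %).

**Loss model.** Real quadrupoles lose transmission at small widths, which
rounds and depresses the profile apex. No functional form is
experimentally constrained; the default is efficiency =
clamp(width / w_crit, 0, 1) with w_crit = 2 Th, configurable.

### Isotopolog model

Peptides are modelled as averagine chains (C 4.9384, H 7.7583, N 1.3577,
O 1.4773 per residue, sulfur excluded, counts rounded to the nearest
integer per element, plus one water). Only ¹³C is modelled (abundance
p = 0.011 by default); ²H/¹⁵N/¹⁸O are neglected — a documented limitation
that slightly understates the heavy envelope. Heavy-atom counts are
binomial in the carbon count; a product inheriting a fixed number of
exchangeable carbons retains heavy atoms hypergeometrically. The
monoisotopic product channel therefore mixes precursor isotopologs with
weights (binomial abundance) × (probability of retaining zero heavy atoms),
each transmitted at its own m/z (spacing 1.003355/z Th). Flank
extrapolation of the composite profile returns the weight-averaged m/z;
`mass_residual` computes it by sampling strict flanks (all isotopologs on
one side, inside window support) and agrees with the closed-form weighted
mean to 1e-9. Isotopologs offset by more than 0.45 × width are outside the
shared support and excluded (relative weight ≲ 1e-7 at tryptic lengths).
For a 3-mer product at charge 2 the residual grows from ~0.08 Th (5-mer
precursor) to 0.46 Th (20-mer); (n−2)-mer products stay below 0.06 Th.

## Simulator

The generator emulates a trapping instrument running overlapping
dynamic-selection DIA:

- **Acquisition defaults**: 30 ms maximum accumulation, AGC pre-scan
  through a static window at the starting width (accumulation time =
  target/flux capped at the maximum; AGC target 3e4 charges so
  mid-intensity species exercise sub-maximal times), 10 Th windows with
  5 Th overlap, 25 ppm matching, 1.1 MHz / 4 mm quadrupole, 0.011 ¹³C.
- **Noise**: multiplicative log-normal per peak with configurable relative
  RMS (1 % default, the stability of an internal calibrant source;
  electrospray instability is emulated by raising it), optional Poisson
  shot noise; microscans are averaged as independent draws. All draws
  derive from (seed, scan index), so runs are reproducible and
  individual scans independent.
- **Scenarios**: a fluoranthene-like calibrant at 202.07 Th for center
  sweeps (centers from anchor − w/2 − 2 to anchor + w/2 + 2 in 0.1 Th
  steps, five replicate spectra averaged per condition); a two-peptide
  direct-infusion pair 1 Th apart with five synthetic products each
  (product m/z values are arbitrary placeholders, not predicted fragment
  masses); a 20-species synthetic calibration ladder spanning
  150–1750 Th; LC runs with Gaussian elution interleaving MS1 and MS2
  cycles, with a fixed 10 ms per-scan overhead on top of the accumulation
  time (≈ 25 Hz at full accumulation).

What the generator does **not** emulate: real fragmentation chemistry and
fragment m/z values, mass-analyser resolution and centroiding, space
charge, calibration drift of the quadrupole, and correlated (drifting) ESI
instability — noise is independent per peak and scan. Passing tests
therefore demonstrate the internal consistency and noise robustness of the
inversion, not its performance against instrument-specific distortions
(the lossy-quadrupole mode probes one such distortion qualitatively).

## Numerical choices and degenerate inputs

- Boundary point of T maps to zero; zero-width windows are invalid except
  as the slew endpoint (the stability apex).
- Two-point branch consistency uses a 1e-9 relative tolerance; duplicate
  branch solutions (boundary cases) are deduplicated before the ambiguity
  flag is set.
- Scan tables serialise m/z to 6 decimals and intensities to 6 significant
  figures — ample for 25 ppm matching at 2000 Th — with fixed column order
  and locale-independent formatting; identical seeds give byte-identical
  files.
- Empty scans are preserved through the TSV round trip (one blank-peak
  row); profile-mode mzML spectra are centroided by local-maximum picking.
- mzML ingestion uses a minimal namespace-agnostic reader (index, ms
  level, scan start time, m/z and intensity arrays, optional zlib); the
  dynamic-window metadata mzML cannot carry comes from a JSON sidecar, and
  unmapped scans are skipped with a warning.

## Known limitations

- Only ¹³C isotopologs; elemental compositions come from averagine, not
  sequences.
- The inverse method assumes extrinsic intensity is constant across the
  scans being combined (quasi-static approximation); on LC timescales this
  holds within a cycle but the package does not model within-cycle drift.
- Single-peak-per-product association: co-isobaric products from different
  precursors (within 25 ppm) merge into one profile and will fit poorly or
  ambiguously rather than being deconvolved.
- No fringe fields, ion optics, resolution ramps or trajectory integration
  in the quadrupole layer; the stability band is the idealised
  boundary-curve band.
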