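# dynaquad

Dynamic quadrupole selection for data-independent acquisition (DIA) mass
spectrometry: a forward simulator and an inverse method that recovers each
product ion's **precursor m/z** from its intensity profile across
overlapping selection windows.

## The problem

Wide-window DIA co-selects many precursors per scan, superimposing their
fragments into chimeric MS/MS spectra with no record of which product came
from which precursor. Dynamic quadrupole selection narrows the selection
window linearly from a starting width *w* to a point during ion
accumulation, so the relative accumulation time of an ion at *m/z* is the
triangular transfer function

```
T(m/z, c, w) = 1 − 2|m/z − c| / w    if |m/z − c| < w/2
             = 0                      otherwise
```

where *c* is the selection center. The observed intensity of a precursor —
and of every product it yields — is then *A·t·T(m/z, c, w)*, with *A* the
unknown extrinsic abundance rate and *t* the accumulation time. Two scans at
different centers give two equations in the two unknowns (*m/z*, *A*);
a dense center sweep gives a redundant system solved by least-squares flank
regression. The extrapolated flank intersection returns the precursor m/z
and the intensity a *static* window would have observed, and the two flank
x-intercepts are separated by exactly *w* — a built-in consistency check.
With 10 Th windows and 5 Th overlap, products of two precursors only 1 Th
apart are assigned to the right precursor within 0.3 Th, a precursor
resolving power of ~33 per selection window.

The package covers the full method:

- `dynaquad.transfer` — the triangular/trapezoidal transfer function.
- `dynaquad.quadsim` — Mathieu first-stability-region physics: the (U, V)
  voltages realising a selection band at a given drive frequency and field
  radius, the narrowing voltage slew, band integration, and a lossy
  small-width transmission model.
- `dynaquad.isotopes` — averagine ¹³C isotopolog model: binomial precursor
  distributions, hypergeometric heavy-atom retention in products, composite
  selection-center profiles, and the mass residual they induce.
- `dynaquad.simulate` — scan-series generator (calibrant center sweeps,
  overlapping-window DIA cycles, LC runs) with static-window AGC pre-scans,
  microscan averaging and multiplicative noise.
- `dynaquad.infer` — two-point solver, profile regression, product
  association across scans (25 ppm), flux normalisation, and pseudo-spectrum
  demultiplexing.
- `dynaquad.io` — TSV scan tables with JSON sidecars, mzML ingestion, MGF
  export, YAML/JSON run configuration.

## Worked example

`examples/demultiplex_two_precursors.py` simulates a direct-infusion DIA
cycle over two precursors at 500.0 and 501.0 Th (five products each, 10 Th
dynamic windows, 5 Th overlap, 1 % RMS noise, AGC-controlled accumulation)
and demultiplexes it:

```
Simulated 7 overlapping MS2 scans (AGC accumulation times [16.7, 30.0] ms)

pseudo-spectrum 0: inferred precursor 500.0000 Th, 5 products
    product  211.100 Th -> precursor 500.0000 Th (two_point_fallback)
    ...
pseudo-spectrum 1: inferred precursor 500.9916 Th, 5 products
    product  252.870 Th -> precursor 500.9970 Th (two_point_fallback)
    ...

max |inferred - true| = 0.0224 Th over 10 products (claim: within 0.3 Th)
precursor resolving power of the spectra: 33 (= window width / accuracy)
```

All ten products land in the correct pseudo-spectrum; the inferred precursor
m/z values deviate from the truth by at most 0.022 Th. The other examples
show the quadrupole voltage solutions (a 10 Th window at 200 Th needs
274.9 V RF and a 4.69 V slew to the stability apex at q ≈ 0.706),
the isotopolog mass residuals (worst case 0.46 Th for a 3-mer product of a
20-mer peptide at charge 2), and an LC run in which product-ion
chromatograms preserve their precursor's elution apex.

A thin CLI wraps the same functions:

```bash
dynaquad quad-voltages --center 200 --width 10
dynaquad simulate-dia --seed 7 --out scans.tsv
dynaquad demux --scans scans.tsv --width 10 --out pseudo.tsv
dynaquad isotope-scan --lengths 3:20 --product 3 --charge 2
```

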