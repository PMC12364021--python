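"""Isotopolog effects on inferred precursor m/z.

A monoisotopic product ion inherits intensity from every precursor
isotopolog that avoided handing it a heavy carbon, so its selection-center
profile is a superposition of shifted triangles.  The flank extrapolation
therefore lands on a contribution-weighted mean m/z.  This script prints the
residual (extrapolated minus monoisotopic) for short and near-full-length
products across tryptic peptide lengths.
"""

from dynaquad.isotopes import AveraginePeptide, mass_residual, precursor_contributions

print("Averagine peptides, charge 2, 1.1 % 13C, 10 Th windows\n")
print("length   3-mer residual (Th)   (n-2)-mer residual (Th)")
for n in range(3, 21):
    pep = AveraginePeptide(length=n, charge=2)
    small = mass_residual(pep, 3)
    large = mass_residual(pep, max(n - 2, 1)) if n >= 3 else float("nan")
    print(f"  {n:2d}        {small:8.4f}              {large:8.4f}")

pep20 = AveraginePeptide(length=20, charge=2)
contrib = precursor_contributions(pep20, 18)
print(f"\nFor a 20-mer, the monoisotopic (n-2)-mer product gets "
      f"{contrib[0]:.0%} of its intensity from the monoisotopic precursor,")
print("so large products track the monoisotopic mass, while 3-mer products")
print("mirror the isotopolog abundances and drift toward the average mass.")
print("Worst case over these lengths stays below 0.5 Th.")
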