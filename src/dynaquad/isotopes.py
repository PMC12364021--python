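"""Isotopolog effects on precursor m/z inference from product-ion profiles.

Peptide precursors are modelled as chains of "averagine" residues (the
hypothetical average amino acid, C4.9384 H7.7583 N1.3577 O1.4773, sulfur
excluded) plus one water.  Only carbon isotopes are considered: each carbon
is 13C with probability ``p13c`` (natural abundance 1.1 %), so the number of
heavy atoms k in a precursor is binomial in its carbon count.

When a precursor carrying k heavy carbons fragments, the probability that a
product inheriting ``product_C`` of the precursor's carbons keeps exactly j
of them is hypergeometric: large products usually retain the heavy atoms,
small products usually stay monoisotopic.  A monoisotopic product peak
therefore mixes contributions from several precursor isotopologs, each
transmitted according to its own (shifted) m/z, producing a composite
selection-center profile whose flank extrapolation lands on the
contribution-weighted mean isotopolog m/z rather than the monoisotopic one.
``mass_residual`` quantifies that deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .containers import IntensityProfile
from .errors import IllConditionedFitError, InvalidParameterError
from .transfer import transmission

__all__ = [
    "AVERAGINE_RESIDUE",
    "C13_MASS_SHIFT",
    "AveraginePeptide",
    "IsotopologDistribution",
    "averagine_composition",
    "averagine_carbon_count",
    "isotopolog_distribution",
    "retention_probability",
    "precursor_contributions",
    "composite_profile",
    "mass_residual",
]

# averagine residue stoichiometry (sulfur's 0.0417 omitted)
AVERAGINE_RESIDUE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773}

# monoisotopic element masses (u) and the proton mass for charging
_ELEMENT_MASS = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221}
_PROTON = 1.00727646688

# 13C - 12C mass difference (u); isotopolog m/z spacing is this over charge
C13_MASS_SHIFT = 1.003355

# largest isotopolog offset, as a fraction of the window width, kept in the
# mass-residual extrapolation: leaves >= 5 % of the half-window as a strict
# flank sampling range on each side
SUPPORT_FRACTION = 0.45


def averagine_composition(length: int) -> dict[str, int]:
    """Integer CHNO composition of an averagine peptide of ``length`` residues.

    Per-residue stoichiometry times length, rounded to the nearest integer
    per element, plus one water for the intact peptide.
    """
    if length < 1:
        raise InvalidParameterError(f"length must be >= 1, got {length}")
    comp = {el: int(round(n * length)) for el, n in AVERAGINE_RESIDUE.items()}
    comp["H"] += 2
    comp["O"] += 1
    return comp


def averagine_carbon_count(length: int) -> int:
    """Carbon atoms in an averagine peptide: round(4.9384 * length)."""
    if length < 1:
        raise InvalidParameterError(f"length must be >= 1, got {length}")
    return int(round(AVERAGINE_RESIDUE["C"] * length))


def _monoisotopic_mz(composition: dict[str, int], charge: int) -> float:
    mass = sum(_ELEMENT_MASS[el] * n for el, n in composition.items())
    return (mass + charge * _PROTON) / charge


@dataclass(frozen=True)
class AveraginePeptide:
    """An averagine model peptide: length, charge, and derived composition."""

    length: int
    charge: int = 2
    mz: Optional[float] = None  # monoisotopic m/z; computed when omitted

    def __post_init__(self) -> None:
        if self.length < 1:
            raise InvalidParameterError(f"length must be >= 1, got {self.length}")
        if self.charge < 1:
            raise InvalidParameterError(f"charge must be >= 1, got {self.charge}")
        if self.mz is None:
            object.__setattr__(
                self, "mz", _monoisotopic_mz(averagine_composition(self.length), self.charge)
            )

    @property
    def carbon_count(self) -> int:
        return averagine_carbon_count(self.length)

    def isotopolog_mzs(self, n_heavy: Sequence[int]) -> np.ndarray:
        """m/z of the k-heavy isotopologs: mz + k * 1.003355 / z."""
        return self.mz + np.asarray(n_heavy, dtype=float) * C13_MASS_SHIFT / self.charge


@dataclass
class IsotopologDistribution:
    """Binomial distribution of heavy-carbon counts for a carbon skeleton."""

    carbon_count: int
    p13c: float = 0.011
    probabilities: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.carbon_count < 1:
            raise InvalidParameterError(f"carbon_count must be >= 1, got {self.carbon_count}")
        if not (0.0 < self.p13c < 1.0):
            raise InvalidParameterError(f"p13c must be in (0, 1), got {self.p13c}")
        k = np.arange(self.carbon_count + 1)
        self.probabilities = stats.binom.pmf(k, self.carbon_count, self.p13c)

    @property
    def heavy_counts(self) -> np.ndarray:
        return np.arange(self.carbon_count + 1)


def isotopolog_distribution(carbon_count: int, p13c: float = 0.011) -> IsotopologDistribution:
    """Distribution of the number of 13C atoms in a ``carbon_count`` skeleton."""
    return IsotopologDistribution(carbon_count=carbon_count, p13c=p13c)


def retention_probability(precursor_c: int, product_c: int, k: int, j: int) -> float:
    """P(product carries j of the precursor's k heavy carbons).

    The product inherits ``product_c`` of the precursor's ``precursor_c``
    carbons; treating carbons as exchangeable, the heavy atoms it receives
    follow a hypergeometric draw without replacement.
    """
    if not (0 <= k <= precursor_c):
        raise InvalidParameterError(f"need 0 <= k <= precursor_c, got k={k}")
    if not (0 <= j <= k):
        raise InvalidParameterError(f"need 0 <= j <= k, got j={j}")
    if not (0 <= product_c <= precursor_c):
        raise InvalidParameterError(
            f"need 0 <= product_c <= precursor_c, got product_c={product_c}"
        )
    return float(stats.hypergeom.pmf(j, precursor_c, k, product_c))


def _monoisotopic_retention(precursor_c: int, product_c: int, kmax: int) -> np.ndarray:
    """P(j = 0 | k) for k = 0..kmax, vectorised."""
    k = np.arange(kmax + 1)
    return stats.hypergeom.pmf(0, precursor_c, k, product_c)


def precursor_contributions(
    precursor: AveraginePeptide, product_length: int, p13c: float = 0.011
) -> np.ndarray:
    """Fraction of a monoisotopic product's intensity owed to each precursor isotopolog.

    contribution_k is proportional to (binomial abundance of the k-heavy
    precursor) x (probability the product received none of the k heavy
    atoms), normalised to sum to 1.  For a near-full-length product only
    k = 0 survives; for a short product the contributions track the
    precursor's isotopolog abundances.
    """
    if not (1 <= product_length <= precursor.length):
        raise InvalidParameterError(
            f"product_length must be in [1, precursor length], got {product_length}"
        )
    dist = isotopolog_distribution(precursor.carbon_count, p13c)
    product_c = averagine_carbon_count(product_length)
    retain0 = _monoisotopic_retention(precursor.carbon_count, product_c, precursor.carbon_count)
    weights = dist.probabilities * retain0
    return weights / weights.sum()


def _composite_weights(
    precursor: AveraginePeptide, product_length: int, p13c: float
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised isotopolog weights and their m/z for the monoisotopic product."""
    dist = isotopolog_distribution(precursor.carbon_count, p13c)
    product_c = averagine_carbon_count(product_length)
    retain0 = _monoisotopic_retention(precursor.carbon_count, product_c, precursor.carbon_count)
    weights = dist.probabilities * retain0
    # drop the numerically irrelevant tail
    keep = weights > weights.sum() * 1e-15
    kmax = int(np.max(np.nonzero(keep)))
    weights = weights[: kmax + 1]
    mzs = precursor.isotopolog_mzs(np.arange(kmax + 1))
    return weights, mzs


def composite_profile(
    precursor: AveraginePeptide,
    product_length: int,
    centers: Sequence[float],
    width: float,
    p13c: float = 0.011,
) -> IntensityProfile:
    """Monoisotopic-product intensity versus selection center.

    Each precursor isotopolog is transmitted according to its own m/z
    (spaced 1.003355/z Th), weighted by abundance times monoisotopic
    retention; the product profile is their superposition, which is no
    longer a single triangle for carbon-rich precursors.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise InvalidParameterError("centers must be non-empty")
    weights, mzs = _composite_weights(precursor, product_length, p13c)
    intensity = np.array(
        [float(np.sum(weights * transmission(mzs, c, width))) for c in centers]
    )
    return IntensityProfile(mz=float(precursor.mz), centers=centers, intensities=intensity, width=width)


def mass_residual(
    precursor: AveraginePeptide,
    product_length: int,
    width: float = 10.0,
    p13c: float = 0.011,
    n_flank_points: int = 25,
) -> float:
    """Deviation of the extrapolated precursor m/z from the monoisotopic m/z.

    Samples the composite monoisotopic-product profile only at selection
    centers where every contributing isotopolog sits on the same flank
    (below the lowest isotopolog m/z on the left, above the highest on the
    right, all within window support), fits a line per flank, and returns
    the abscissa of their intersection minus the monoisotopic m/z.  On
    strict flanks the composite is an exact line, so this equals the
    contribution-weighted mean isotopolog offset sum_k c_k * k * 1.003355/z
    over the isotopologs the window can hold.

    Isotopologs offset by more than ``SUPPORT_FRACTION * width`` from the
    monoisotopic m/z fall outside the shared window support and are excluded
    (their relative weight is ~1e-7 or less for tryptic peptide lengths, so
    the exclusion is physically negligible but keeps the flanks exact lines).
    """
    if width <= 0:
        raise InvalidParameterError(f"width must be > 0, got {width}")
    weights, mzs = _composite_weights(precursor, product_length, p13c)
    usable = mzs - precursor.mz <= SUPPORT_FRACTION * width
    if not np.any(usable):
        raise IllConditionedFitError("no isotopolog fits the window support")
    weights, mzs = weights[usable], mzs[usable]
    mz_lo, mz_hi = float(mzs[0]), float(mzs[-1])
    half = width / 2.0
    # strict-flank center ranges with margin; all kept isotopologs inside support
    left_lo, left_hi = mz_hi - half, mz_lo
    right_lo, right_hi = mz_hi, mz_lo + half
    pad_l = 0.02 * (left_hi - left_lo)
    pad_r = 0.02 * (right_hi - right_lo)
    if left_hi - left_lo <= 0 or right_hi - right_lo <= 0:
        raise IllConditionedFitError(
            "isotopolog envelope spans more than half the window; no strict flank exists"
        )
    left = np.linspace(left_lo + pad_l, left_hi - pad_l, n_flank_points)
    right = np.linspace(right_lo + pad_r, right_hi - pad_r, n_flank_points)

    def line(centers: np.ndarray) -> tuple[float, float]:
        y = np.array([float(np.sum(weights * transmission(mzs, c, width))) for c in centers])
        slope, intercept = np.polyfit(centers, y, 1)
        return slope, intercept

    m1, b1 = line(left)
    m2, b2 = line(right)
    if m1 == m2:
        raise IllConditionedFitError("flank lines are parallel")
    x_star = (b2 - b1) / (m1 - m2)
    return float(x_star - precursor.mz)
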