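"""Core data containers shared across the simulation and inference layers.

All m/z values are in thomson (Th), accumulation times in milliseconds,
retention times in seconds.  Extrinsic intensity ``A`` is an abundance rate
(signal per millisecond of accumulation at full transmission); observed peak
intensities are accumulated signal on the ``A * t`` scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class SelectionWindow:
    """A dynamic quadrupole selection event.

    The window starts ``start_width`` Th wide, centred at ``center``, and
    narrows symmetrically to ``end_width`` (default 0, a point) over the
    accumulation period.  An ion's relative accumulation is the triangular
    (or, for ``end_width > 0``, trapezoidal) transfer function.
    """

    center: float
    start_width: float
    accumulation_time: float = 30.0
    end_width: float = 0.0

    def __post_init__(self) -> None:
        if self.start_width <= 0:
            raise InvalidParameterError(f"start_width must be > 0, got {self.start_width}")
        if not (0 <= self.end_width <= self.start_width):
            raise InvalidParameterError(
                f"end_width must lie in [0, start_width], got {self.end_width}"
            )
        if self.center <= 0:
            raise InvalidParameterError(f"center must be > 0, got {self.center}")
        if self.accumulation_time <= 0:
            raise InvalidParameterError(
                f"accumulation_time must be > 0, got {self.accumulation_time}"
            )

    @property
    def low_edge(self) -> float:
        return self.center - self.start_width / 2.0

    @property
    def high_edge(self) -> float:
        return self.center + self.start_width / 2.0


@dataclass(frozen=True)
class ProductIon:
    """A product ion of a precursor.

    ``yield_`` is the fraction of the transmitted precursor signal that ends
    up in this product's monoisotopic peak.  ``carbon_count`` (optional)
    enables isotopolog-aware simulation: the probability that the product
    stays monoisotopic when its precursor carries heavy carbons depends on
    how many of the precursor's carbons it inherits.
    """

    mz: float
    yield_: float = 1.0
    carbon_count: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.yield_ <= 1.0):
            raise InvalidParameterError(f"yield must be in [0, 1], got {self.yield_}")


@dataclass(frozen=True)
class PrecursorSpecies:
    """A precursor ion population presented to the instrument.

    ``intensity`` is the extrinsic abundance rate A (per ms): the signal the
    species would accumulate per millisecond through a fully transmitting
    quadrupole.  It folds together concentration, ionisation and transfer
    efficiencies and is one of the two unknowns the inverse method solves for.
    """

    mz: float
    charge: int = 1
    intensity: float = 1.0
    peptide_length: Optional[int] = None
    elution: Optional[tuple[float, float]] = None  # (apex rt s, sigma s)
    products: tuple[ProductIon, ...] = ()

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise InvalidParameterError(f"mz must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise InvalidParameterError(f"intensity must be >= 0, got {self.intensity}")
        if self.charge < 1:
            raise InvalidParameterError(f"charge must be >= 1, got {self.charge}")
        object.__setattr__(self, "products", tuple(self.products))


@dataclass
class ScanRecord:
    """One acquired or simulated spectrum with its selection metadata."""

    scan_index: int
    window: SelectionWindow
    accumulation_time: float  # actual ms (AGC outcome), <= configured max
    ms_level: int = 2
    retention_time: float = 0.0
    microscans: int = 1
    mzs: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensities: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mzs = np.asarray(self.mzs, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mzs.shape != self.intensities.shape:
            raise InvalidParameterError("mzs and intensities must have equal length")
        if np.any(self.intensities < 0):
            raise InvalidParameterError("peak intensities must be >= 0")
        order = np.argsort(self.mzs, kind="stable")
        self.mzs = self.mzs[order]
        self.intensities = self.intensities[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mzs.size)


@dataclass(frozen=True)
class NoiseModel:
    """Scan-to-scan intensity noise.

    ``rms`` is the relative RMS of multiplicative log-normal noise applied
    per peak per microscan (a stable calibrant source sits below 1 %;
    electrospray instability is emulated by raising it).  ``shot_noise``
    additionally Poisson-resamples each peak's accumulated counts.
    """

    rms: float = 0.01
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if self.rms < 0:
            raise InvalidParameterError(f"rms must be >= 0, got {self.rms}")


@dataclass
class IntensityProfile:
    """Flux-normalised intensity of one product across selection centers.

    ``intensities`` are peak intensities divided by each scan's actual
    accumulation time, which removes the AGC-chosen accumulation time from
    the profile and leaves pure transmission shape times extrinsic rate.
    """

    mz: float
    centers: np.ndarray
    intensities: np.ndarray
    width: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.centers.size < 2:
            raise InvalidParameterError("a profile needs at least 2 points")
        if np.any(np.diff(self.centers) <= 0):
            raise InvalidParameterError("profile centers must be strictly increasing")
        if np.any(self.intensities < 0):
            raise InvalidParameterError("profile intensities must be >= 0")
        if self.width <= 0:
            raise InvalidParameterError(f"width must be > 0, got {self.width}")

    @property
    def n_points(self) -> int:
        return int(self.centers.size)


@dataclass
class PrecursorEstimate:
    """Result of inverting an intensity profile.

    ``mz`` is the inferred precursor m/z (the selection center that would
    maximise transmission); ``apex_intensity`` is the flux-normalised
    intensity that a static window of the same width would have observed.
    ``x_low``/``x_high`` are the zero crossings of the fitted flank lines;
    their separation recovers the starting window width for a clean profile.
    """

    mz: float
    apex_intensity: float
    x_low: Optional[float] = None
    x_high: Optional[float] = None
    phase: Optional[float] = None
    residual: float = 0.0
    method: str = "profile_fit"
    ambiguous: bool = False
    n_points: int = 0

    @property
    def intercept_span(self) -> Optional[float]:
        if self.x_low is None or self.x_high is None:
            return None
        return self.x_high - self.x_low


def as_peak_arrays(peaks: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    """Split an iterable of (mz, intensity) pairs into sorted arrays."""
    if not peaks:
        return np.empty(0), np.empty(0)
    arr = np.asarray(peaks, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    return arr[order, 0], arr[order, 1]
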