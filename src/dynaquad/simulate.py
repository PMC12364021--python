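"""Forward simulator for dynamic quadrupole selection acquisitions.

Produces the scan series the inverse method consumes: calibrant
selection-center sweeps, overlapping-window DIA cycles over an m/z range,
and LC runs with Gaussian elution.  The simulator applies the ideal
triangular transfer function (optionally the lossy quadrupole model),
automatic gain control with a static pre-scan window, isotopolog-aware
product intensities, multiplicative log-normal noise, and microscan
averaging.  All randomness flows from an explicit seed; every scan's draws
are reproducible from (seed, scan index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import isotopes
from .containers import (
    NoiseModel,
    PrecursorSpecies,
    ProductIon,
    ScanRecord,
    SelectionWindow,
)
from .errors import InvalidParameterError
from .quadsim import LossModel, QuadrupoleGeometry, dynamic_transmission
from .transfer import transmission

__all__ = [
    "AcquisitionSettings",
    "agc_accumulation_time",
    "simulate_scan",
    "simulate_calibrant_sweep",
    "simulate_dia_cycle",
    "simulate_lc_run",
    "fluoranthene_calibrant",
    "two_peptide_infusion",
    "flexmix_ladder",
]

FLUORANTHENE_MZ = 202.07  # internal calibrant cation


@dataclass(frozen=True)
class AcquisitionSettings:
    """Instrument-level acquisition parameters.

    Defaults mirror a fast Q-Orbitrap style method: 30 ms maximum
    accumulation, AGC target expressed directly in accumulated charges,
    one microscan, ideal quadrupole.
    """

    max_accumulation_time: float = 30.0  # ms
    agc_target: float = 3.0e4  # charges (100 % AGC target)
    microscans: int = 1
    scan_overhead: float = 10.0  # ms added to accumulation for cycle time
    loss: Optional[LossModel] = None
    geometry: QuadrupoleGeometry = QuadrupoleGeometry()


def agc_accumulation_time(prescan_flux: float, target: float, max_it: float) -> float:
    """Accumulation time chosen by automatic gain control.

    The AGC pre-scan measures the total charge flux through a *static*
    window at the starting width; the accumulation time is the time needed
    to reach the target charge, capped at the maximum.  Zero flux returns
    the maximum.
    """
    if prescan_flux < 0:
        raise InvalidParameterError(f"prescan_flux must be >= 0, got {prescan_flux}")
    if target <= 0:
        raise InvalidParameterError(f"target must be > 0, got {target}")
    if max_it <= 0:
        raise InvalidParameterError(f"max_it must be > 0, got {max_it}")
    if prescan_flux == 0:
        return max_it
    return min(target / prescan_flux, max_it)


def _static_prescan_flux(precursors: Sequence[PrecursorSpecies], window: SelectionWindow) -> float:
    """Total charge flux inside the static (full starting width) window."""
    flux = 0.0
    for p in precursors:
        if window.low_edge < p.mz < window.high_edge:
            flux += p.intensity
    return flux


def _precursor_transmission(
    precursor: PrecursorSpecies,
    window: SelectionWindow,
    settings: AcquisitionSettings,
    p13c: float = 0.011,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-isotopolog (mz, abundance, transmission) for one precursor.

    Without a declared peptide length the precursor is purely monoisotopic.
    """
    if precursor.peptide_length is None:
        mzs = np.array([precursor.mz])
        abund = np.array([1.0])
    else:
        dist = isotopes.isotopolog_distribution(
            isotopes.averagine_carbon_count(precursor.peptide_length), p13c
        )
        keep = dist.probabilities > 1e-12
        kmax = int(np.max(np.nonzero(keep)))
        abund = dist.probabilities[: kmax + 1]
        mzs = precursor.mz + np.arange(kmax + 1) * isotopes.C13_MASS_SHIFT / precursor.charge
    if settings.loss is None:
        trans = transmission(mzs, window.center, window.start_width, window.end_width)
    else:
        trans = dynamic_transmission(
            mzs, window, settings.geometry, loss=settings.loss, n_steps=400
        )
    return mzs, abund, np.atleast_1d(trans)


def _apply_noise(
    intensities: np.ndarray,
    noise: Optional[NoiseModel],
    microscans: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-peak multiplicative noise, averaged over independent microscans."""
    if noise is None or (noise.rms == 0 and not noise.shot_noise):
        return intensities
    out = np.zeros_like(intensities)
    sigma = math.sqrt(math.log1p(noise.rms**2)) if noise.rms > 0 else 0.0
    for _ in range(max(1, microscans)):
        draw = intensities.copy()
        if sigma > 0:
            factors = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=draw.shape)
            draw = draw * factors
        if noise.shot_noise:
            draw = rng.poisson(np.clip(draw, 0, None)).astype(float)
        out += draw
    return out / max(1, microscans)


def simulate_scan(
    precursors: Sequence[PrecursorSpecies],
    window: SelectionWindow,
    ms_level: int = 2,
    noise: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
    settings: Optional[AcquisitionSettings] = None,
    scan_index: int = 0,
    retention_time: float = 0.0,
    p13c: float = 0.011,
) -> ScanRecord:
    """Simulate one spectrum under a dynamic selection window.

    MS2: each precursor's transmitted signal A * t * T (summed over
    isotopologs when a peptide length is declared) is distributed over its
    products by yield; products of co-selected precursors superimpose into
    one chimeric peak list.  Products with a declared carbon count keep only
    the monoisotopic channel, weighting each precursor isotopolog by the
    hypergeometric probability of retaining zero heavy atoms.

    MS1: the peaks are the precursor isotopologs themselves.
    """
    settings = settings or AcquisitionSettings()
    rng = rng or np.random.default_rng(0)
    t = window.accumulation_time
    peak_map: dict[float, float] = {}

    for prec in precursors:
        mzs, abund, trans = _precursor_transmission(prec, window, settings, p13c)
        if ms_level == 1:
            for mz_k, ab_k, t_k in zip(mzs, abund, trans):
                signal = prec.intensity * t * ab_k * t_k
                if signal > 0:
                    peak_map[mz_k] = peak_map.get(mz_k, 0.0) + signal
            continue
        weighted = abund * trans  # per-isotopolog transmitted fraction of A
        total_transmitted = prec.intensity * t * float(weighted.sum())
        if total_transmitted <= 0 and not np.any(weighted > 0):
            continue
        prec_c = (
            isotopes.averagine_carbon_count(prec.peptide_length)
            if prec.peptide_length is not None
            else None
        )
        for prod in prec.products:
            if prec_c is not None and prod.carbon_count is not None:
                ks = np.arange(weighted.size)
                retain0 = stats.hypergeom.pmf(0, prec_c, ks, prod.carbon_count)
                signal = prec.intensity * t * prod.yield_ * float(np.sum(weighted * retain0))
            else:
                signal = prod.yield_ * total_transmitted
            if signal > 0:
                peak_map[prod.mz] = peak_map.get(prod.mz, 0.0) + signal

    mz_arr = np.array(sorted(peak_map))
    int_arr = np.array([peak_map[m] for m in mz_arr]) if mz_arr.size else np.empty(0)
    int_arr = _apply_noise(int_arr, noise, settings.microscans, rng)
    keep = int_arr > 0
    return ScanRecord(
        scan_index=scan_index,
        window=window,
        accumulation_time=t,
        ms_level=ms_level,
        retention_time=retention_time,
        microscans=settings.microscans,
        mzs=mz_arr[keep] if mz_arr.size else mz_arr,
        intensities=int_arr[keep] if mz_arr.size else int_arr,
    )


def sweep_centers(anchor_mz: float, width: float, step: float = 0.1) -> np.ndarray:
    """Selection centers of a calibrant sweep.

    Centers run from ``anchor - width/2 - 2`` to ``anchor + width/2 + 2`` Th
    in increments of ``step``, covering the full profile plus a 2 Th margin
    on each side.
    """
    if step <= 0:
        raise InvalidParameterError(f"step must be > 0, got {step}")
    first = anchor_mz - width / 2.0 - 2.0
    last = anchor_mz + width / 2.0 + 2.0
    n = int(round((last - first) / step))
    return first + step * np.arange(n + 1)


def simulate_calibrant_sweep(
    anchor_mz: float = FLUORANTHENE_MZ,
    widths: Sequence[float] = (10.0,),
    accumulation_times: Sequence[float] = (10.0,),
    step: float = 0.1,
    replicates: int = 5,
    intensity: float = 1000.0,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    settings: Optional[AcquisitionSettings] = None,
) -> list[ScanRecord]:
    """Step the selection center across a single calibrant species.

    For every (width, accumulation time) condition the center is stepped by
    ``step`` Th across the profile; ``replicates`` independent spectra per
    condition are averaged into one reported scan.
    """
    settings = settings or AcquisitionSettings()
    calibrant = PrecursorSpecies(mz=anchor_mz, intensity=intensity)
    scans: list[ScanRecord] = []
    idx = 0
    for w in widths:
        for it in accumulation_times:
            for c in sweep_centers(anchor_mz, w, step):
                window = SelectionWindow(center=float(c), start_width=w, accumulation_time=it)
                rng = np.random.default_rng((seed, idx))
                reps = [
                    simulate_scan(
                        [calibrant], window, ms_level=1, noise=noise, rng=rng,
                        settings=settings, scan_index=idx,
                    )
                    for _ in range(replicates)
                ]
                scans.append(_average_scans(reps))
                idx += 1
    return scans


def _average_scans(reps: list[ScanRecord]) -> ScanRecord:
    """Average replicate spectra peak-by-peak (peaks matched by exact m/z)."""
    base = reps[0]
    if len(reps) == 1:
        return base
    acc: dict[float, float] = {}
    for r in reps:
        for mz, inten in zip(r.mzs, r.intensities):
            acc[mz] = acc.get(mz, 0.0) + inten / len(reps)
    mzs = np.array(sorted(acc))
    return replace(
        base,
        mzs=mzs,
        intensities=np.array([acc[m] for m in mzs]) if mzs.size else np.empty(0),
    )


def dia_window_centers(mz_range: tuple[float, float], width: float, overlap: float) -> np.ndarray:
    """Window centers tiling ``mz_range`` with the given width and overlap.

    Centers are spaced ``width - overlap``; every interior m/z is covered by
    at least width / (width - overlap) windows.
    """
    if not (0 <= overlap < width):
        raise InvalidParameterError(f"need 0 <= overlap < width, got overlap={overlap}")
    lo, hi = mz_range
    if hi <= lo:
        raise InvalidParameterError(f"empty mz_range {mz_range}")
    spacing = width - overlap
    first = lo + width / 2.0
    n = int(math.ceil((hi - width / 2.0 - first) / spacing - 1e-9))
    return first + spacing * np.arange(max(n, 0) + 1)


def simulate_dia_cycle(
    precursors: Sequence[PrecursorSpecies],
    mz_range: tuple[float, float],
    width: float = 10.0,
    overlap: float = 5.0,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    settings: Optional[AcquisitionSettings] = None,
    start_index: int = 0,
    retention_time: float = 0.0,
    agc: bool = True,
) -> list[ScanRecord]:
    """One cycle of overlapping dynamic-selection MS2 windows over a range.

    Each window is preceded by a static-window AGC pre-scan that sets its
    accumulation time; with ``agc=False`` every scan uses the maximum.
    """
    settings = settings or AcquisitionSettings()
    scans = []
    for i, c in enumerate(dia_window_centers(mz_range, width, overlap)):
        idx = start_index + i
        probe = SelectionWindow(center=float(c), start_width=width, accumulation_time=1.0)
        if agc:
            flux = _static_prescan_flux(precursors, probe)
            it = agc_accumulation_time(flux, settings.agc_target, settings.max_accumulation_time)
        else:
            it = settings.max_accumulation_time
        window = SelectionWindow(center=float(c), start_width=width, accumulation_time=it)
        rng = np.random.default_rng((seed, idx))
        scans.append(
            simulate_scan(
                precursors, window, ms_level=2, noise=noise, rng=rng,
                settings=settings, scan_index=idx, retention_time=retention_time,
            )
        )
    return scans


def simulate_lc_run(
    precursors: Sequence[PrecursorSpecies],
    mz_range: tuple[float, float],
    gradient_length: float = 120.0,
    width: float = 10.0,
    overlap: float = 5.0,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    settings: Optional[AcquisitionSettings] = None,
) -> list[ScanRecord]:
    """Interleaved MS1 + dynamic-selection MS2 cycles over a gradient.

    Every precursor must declare an elution profile; its extrinsic intensity
    follows a Gaussian of the declared apex and sigma.  Each cycle is one
    MS1 scan (static full-range window) followed by the overlapping MS2
    windows; the cycle time emerges from the AGC-chosen accumulation times
    plus a fixed per-scan overhead.
    """
    settings = settings or AcquisitionSettings()
    for p in precursors:
        if p.elution is None:
            raise InvalidParameterError(f"precursor at {p.mz} Th lacks an elution profile")

    def eluting(rt: float) -> list[PrecursorSpecies]:
        out = []
        for p in precursors:
            apex, sig = p.elution
            amp = p.intensity * math.exp(-0.5 * ((rt - apex) / sig) ** 2)
            out.append(replace(p, intensity=amp, elution=None))
        return out

    scans: list[ScanRecord] = []
    rt = 0.0
    idx = 0
    ms1_width = mz_range[1] - mz_range[0]
    ms1_center = 0.5 * (mz_range[0] + mz_range[1])
    while rt < gradient_length:
        current = eluting(rt)
        flux = sum(p.intensity for p in current if mz_range[0] < p.mz < mz_range[1])
        it1 = agc_accumulation_time(flux, settings.agc_target, settings.max_accumulation_time)
        ms1_window = SelectionWindow(
            center=ms1_center, start_width=ms1_width, end_width=ms1_width,
            accumulation_time=it1,
        )
        rng = np.random.default_rng((seed, idx))
        scans.append(
            simulate_scan(
                current, ms1_window, ms_level=1, noise=noise, rng=rng,
                settings=settings, scan_index=idx, retention_time=rt,
            )
        )
        rt += (it1 + settings.scan_overhead) / 1000.0
        idx += 1
        ms2 = simulate_dia_cycle(
            current, mz_range, width=width, overlap=overlap, noise=noise,
            seed=seed, settings=settings, start_index=idx, retention_time=rt,
        )
        for s in ms2:
            s.retention_time = rt
            rt += (s.accumulation_time + settings.scan_overhead) / 1000.0
        idx += len(ms2)
        scans.extend(ms2)
    return scans


# ---------------------------------------------------------------------------
# Built-in synthetic scenarios
# ---------------------------------------------------------------------------


def fluoranthene_calibrant(intensity: float = 1000.0) -> PrecursorSpecies:
    """A fluoranthene-like internal calibrant cation at 202.07 Th."""
    return PrecursorSpecies(mz=FLUORANTHENE_MZ, charge=1, intensity=intensity)


def two_peptide_infusion(
    mz1: float = 500.0,
    mz2: float = 501.0,
    intensity1: float = 1000.0,
    intensity2: float = 800.0,
    n_products: int = 5,
) -> list[PrecursorSpecies]:
    """Two co-infused precursors 1 Th apart, each with distinct synthetic products.

    Product m/z values are synthetic (arbitrary, well separated); yields
    decay geometrically from the base peak.
    """
    def products(base: float, offset: float) -> tuple[ProductIon, ...]:
        # products spread across 200-700 Th, distinct between the two species
        # and mutually separated by far more than the 25 ppm matching tolerance
        return tuple(
            ProductIon(mz=base + offset + 97.3 * i, yield_=0.8 * 0.85**i)
            for i in range(n_products)
        )

    return [
        PrecursorSpecies(mz=mz1, charge=2, intensity=intensity1, products=products(211.1, 0.0)),
        PrecursorSpecies(mz=mz2, charge=2, intensity=intensity2, products=products(211.1, 41.77)),
    ]


def flexmix_ladder(
    n_species: int = 20,
    mz_range: tuple[float, float] = (150.0, 1750.0),
    seed: int = 0,
) -> list[PrecursorSpecies]:
    """A synthetic calibration ladder spanning the mass range.

    Emulates a multi-component calibration mixture: species spread across
    ``mz_range`` at varied intensities, no fragmentation (products observed
    at the precursor m/z, as acquired with zero collision energy).
    """
    rng = np.random.default_rng(seed)
    lo, hi = mz_range
    base = np.linspace(lo + 20.0, hi - 20.0, n_species)
    jitter = rng.uniform(-5.0, 5.0, n_species)
    mzs = np.sort(base + jitter)
    intensities = rng.uniform(200.0, 5000.0, n_species)
    return [
        PrecursorSpecies(
            mz=float(m), charge=1, intensity=float(a),
            products=(ProductIon(mz=float(m), yield_=1.0),),
        )
        for m, a in zip(mzs, intensities)
    ]
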