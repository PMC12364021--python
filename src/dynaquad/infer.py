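"""Recovering precursor m/z from product-ion intensity profiles.

Under dynamic selection the observed intensity of an ion (or of its
products) is A * t * T(x, c, w): two unknowns, the precursor m/z ``x`` and
the extrinsic rate ``A``.  Two scans at different selection centers give two
equations; a dense center sweep gives a redundant system solved by flank
regression.  Both yield the precursor m/z as the abscissa where the two
flank lines intersect, the extrapolated apex intensity (what a static
window would have observed), and the flank x-intercepts, whose separation
recovers the starting window width — a built-in consistency diagnostic.

The full demultiplexing pipeline matches product peaks across overlapping
scans into profiles (25 ppm tolerance), flux-normalises by each scan's
actual accumulation time, estimates a precursor m/z per product, and
clusters products into pseudo-spectra, one per inferred precursor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import IntensityProfile, PrecursorEstimate, ScanRecord
from .errors import (
    IllConditionedFitError,
    InvalidParameterError,
    UnsolvableGeometryError,
)

__all__ = [
    "two_point_solve",
    "profile_fit",
    "phase",
    "associate_products",
    "demultiplex",
    "evaluate_estimates",
    "resolving_power",
    "PseudoSpectrum",
    "DemuxResult",
]

logger = logging.getLogger(__name__)

# relative tolerance for accepting a branch hypothesis in two_point_solve
_BRANCH_RTOL = 1e-9


def _branch_solutions(
    c1: float, i1: float, c2: float, i2: float, width: float
) -> list[tuple[str, float, float]]:
    """Candidate (branch, x, A) solutions of the two-point system.

    The sign of |x - c| is unknown, so three branch hypotheses are
    enumerated: x below both centers, between them, or above both.  Each
    candidate is kept only if it reproduces the observations and respects
    its own branch geometry.
    """
    s = c2 - c1
    out: list[tuple[str, float, float]] = []

    def consistent(x: float, amp: float) -> bool:
        if amp <= 0:
            return False
        scale = max(i1, i2, amp)
        for c, i_obs in ((c1, i1), (c2, i2)):
            t = 1.0 - 2.0 * abs(x - c) / width
            pred = amp * max(t, 0.0)
            if abs(pred - i_obs) > _BRANCH_RTOL * scale + 1e-300:
                return False
        return True

    # between: I1 = A(1 - 2(x-c1)/w), I2 = A(1 - 2(c2-x)/w)
    if 2.0 - 2.0 * s / width > 0:
        amp = (i1 + i2) / (2.0 - 2.0 * s / width)
        if amp > 0:
            x = c1 + (width / 2.0) * (1.0 - i1 / amp)
            if c1 - _BRANCH_RTOL <= x <= c2 + _BRANCH_RTOL and consistent(x, amp):
                out.append(("between", x, amp))
    # below both: I1 = A(1 - 2(c1-x)/w), I2 = A(1 - 2(c2-x)/w); needs I1 > I2
    if i1 > i2:
        amp = (i1 - i2) * width / (2.0 * s)
        x = c1 - (width / 2.0) * (1.0 - i1 / amp)
        if x <= c1 + _BRANCH_RTOL and consistent(x, amp):
            out.append(("below", x, amp))
    # above both: mirror image; needs I2 > I1
    if i2 > i1:
        amp = (i2 - i1) * width / (2.0 * s)
        x = c2 + (width / 2.0) * (1.0 - i2 / amp)
        if x >= c2 - _BRANCH_RTOL and consistent(x, amp):
            out.append(("above", x, amp))
    return out


def two_point_solve(
    p1: tuple[float, float], p2: tuple[float, float], width: float
) -> PrecursorEstimate:
    """Solve I_i = A * T(x, c_i, w) for (x, A) from two scans.

    Branch ambiguity (more than one geometric hypothesis consistent with
    the data) is flagged on the estimate, with the between-centers branch
    preferred; no consistent branch raises ``UnsolvableGeometryError``.
    """
    if width <= 0:
        raise InvalidParameterError(f"width must be > 0, got {width}")
    (c1, i1), (c2, i2) = p1, p2
    if c1 == c2:
        raise InvalidParameterError("the two selection centers must differ")
    if c1 > c2:
        (c1, i1), (c2, i2) = (c2, i2), (c1, i1)
    if i1 < 0 or i2 < 0:
        raise InvalidParameterError("intensities must be >= 0")
    if i1 == 0 and i2 == 0:
        raise InvalidParameterError("at least one intensity must be positive")

    candidates = _branch_solutions(c1, i1, c2, i2, width)
    if not candidates:
        raise UnsolvableGeometryError(
            f"no flank-branch hypothesis fits points ({c1}, {i1}), ({c2}, {i2}) "
            f"with width {width}"
        )
    # distinct solutions only (branch boundaries can duplicate)
    distinct: list[tuple[str, float, float]] = []
    for cand in candidates:
        if not any(abs(cand[1] - d[1]) < 1e-9 * max(1.0, abs(cand[1])) for d in distinct):
            distinct.append(cand)
    ambiguous = len(distinct) > 1
    chosen = next((c for c in distinct if c[0] == "between"), distinct[0])
    _, x, amp = chosen
    return PrecursorEstimate(
        mz=x,
        apex_intensity=amp,
        x_low=x - width / 2.0,
        x_high=x + width / 2.0,
        phase=phase(c1, c2, x),
        method="two_point",
        ambiguous=ambiguous,
        n_points=2,
    )


def _trim_profile(centers: np.ndarray, intensities: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep positive points and interior zeros; drop zero runs outside support."""
    pos = np.nonzero(intensities > 0)[0]
    if pos.size == 0:
        return centers[:0], intensities[:0]
    lo, hi = pos[0], pos[-1]
    return centers[lo : hi + 1], intensities[lo : hi + 1]


def profile_fit(profile: IntensityProfile) -> PrecursorEstimate:
    """Least-squares flank regression of a dense intensity profile.

    Points are split at the maximum-intensity center (ties toward the lower
    center); an ordinary least-squares line is fitted to each flank, and the
    estimate is the abscissa of the line intersection, with the apex
    intensity as its ordinate and the x-intercepts from each line's zero
    crossing.  The maximum point itself generally belongs to only one flank
    line (whichever side of the true apex it samples), so it is left out of
    both fits whenever each flank keeps at least two other points; a starved
    flank reclaims it.  With fewer than two points on a flank the method
    falls back to ``two_point_solve`` on the two most intense points
    (flagged in ``method``).
    """
    centers, intens = _trim_profile(profile.centers, profile.intensities)
    if centers.size == 0:
        raise IllConditionedFitError("profile has no positive intensities")

    imax = int(np.argmax(intens))  # argmax takes the first (lower-center) tie
    if imax >= 2 and centers.size - imax >= 3:
        left_c, left_i = centers[:imax], intens[:imax]
        right_c, right_i = centers[imax + 1 :], intens[imax + 1 :]
    else:
        left_c, left_i = centers[: imax + 1], intens[: imax + 1]
        right_c, right_i = centers[imax:], intens[imax:]

    if left_c.size < 2 or right_c.size < 2:
        # untrimmed arrays: an adjacent zero point can pin a window edge
        return _two_point_fallback(profile.centers, profile.intensities, profile.width)

    m1, b1 = np.polyfit(left_c, left_i, 1)
    m2, b2 = np.polyfit(right_c, right_i, 1)
    if m1 == m2:
        raise UnsolvableGeometryError("flank lines are parallel")
    x = (b2 - b1) / (m1 - m2)
    amp = m1 * x + b1
    if amp <= 0:
        raise UnsolvableGeometryError("flank lines intersect at non-positive intensity")
    pred = np.concatenate([m1 * left_c + b1, m2 * right_c + b2])
    obs = np.concatenate([left_i, right_i])
    residual = float(np.sqrt(np.mean((pred - obs) ** 2)))
    x_low = -b1 / m1 if m1 != 0 else None
    x_high = -b2 / m2 if m2 != 0 else None
    return PrecursorEstimate(
        mz=float(x),
        apex_intensity=float(amp),
        x_low=None if x_low is None else float(x_low),
        x_high=None if x_high is None else float(x_high),
        residual=residual,
        method="profile_fit",
        n_points=int(centers.size),
    )


def _two_point_fallback(
    centers: np.ndarray, intens: np.ndarray, width: float
) -> PrecursorEstimate:
    """Two-point solve on the best available pair when a flank is starved.

    Uses the two most intense points with distinct centers; a single
    positive point is paired with an adjacent zero point, which pins the
    window edge.
    """
    pos = np.nonzero(intens > 0)[0]
    if pos.size >= 2:
        order = pos[np.argsort(intens[pos])[::-1]]
        i, j = sorted((order[0], order[1]))
    elif pos.size == 1 and intens.size >= 2:
        k = pos[0]
        j_adj = k + 1 if k + 1 < intens.size else k - 1
        i, j = sorted((k, j_adj))
    else:
        raise IllConditionedFitError("not enough points for a two-point fallback")
    est = two_point_solve(
        (float(centers[i]), float(intens[i])), (float(centers[j]), float(intens[j])), width
    )
    est.method = "two_point_fallback"
    est.n_points = int(intens.size)
    return est


def phase(c1: float, c2: float, true_mz: float) -> float:
    """Position of a two-scan pair relative to the precursor m/z, in degrees.

    0 deg when the precursor bisects the two selection centers; +180 deg
    when it coincides with the first (lower) center, -180 deg with the
    second.  Linear in between and clipped to [-180, 180].
    """
    if not c1 < c2:
        raise InvalidParameterError("need c1 < c2")
    midpoint = 0.5 * (c1 + c2)
    return float(np.clip(360.0 * (midpoint - true_mz) / (c2 - c1), -180.0, 180.0))


def associate_products(
    scans: Sequence[ScanRecord], ppm_tol: float = 25.0, pad_zeros: bool = True
) -> list[IntensityProfile]:
    """Match product peaks across scans into per-product intensity profiles.

    Peaks are grouped across scans within ``ppm_tol`` parts per million
    (single-linkage on the sorted m/z list) and keyed by their
    intensity-weighted mean m/z.  Intensities are divided by each scan's
    actual accumulation time (flux normalisation), so AGC-varying
    accumulation times cancel.

    With ``pad_zeros`` (default), a zero-intensity point is added at every
    scanned center immediately adjacent to the centers where the product was
    observed: a product absent from an overlapping neighbouring window
    brackets its precursor at that window's edge, which is what lets a
    precursor sitting exactly on one selection center still be located.
    Groups that remain at fewer than two distinct centers are dropped (their
    count is logged).
    """
    ms2 = [s for s in scans if s.ms_level == 2]
    if not ms2:
        return []
    widths = {round(s.window.start_width, 9) for s in ms2}
    if len(widths) != 1:
        raise InvalidParameterError(f"scans mix starting widths: {sorted(widths)}")
    width = ms2[0].window.start_width
    if len({s.window.center for s in ms2}) < 2:
        raise InvalidParameterError("need scans at >= 2 distinct selection centers")

    rows = []  # (mz, center, flux_normalised_intensity)
    for s in ms2:
        for mz, inten in zip(s.mzs, s.intensities):
            rows.append((mz, s.window.center, inten / s.accumulation_time))
    if not rows:
        return []
    rows.sort()
    mzs = np.array([r[0] for r in rows])
    breaks = np.nonzero(np.diff(mzs) > ppm_tol * 1e-6 * mzs[:-1])[0] + 1
    groups = np.split(np.arange(len(rows)), breaks)

    all_centers = np.array(sorted({s.window.center for s in ms2}))
    profiles: list[IntensityProfile] = []
    n_singletons = 0
    for g in groups:
        by_center: dict[float, float] = {}
        wsum = isum = 0.0
        for idx in g:
            mz, center, inten = rows[idx]
            by_center[center] = by_center.get(center, 0.0) + inten
            wsum += mz * inten
            isum += inten
        if pad_zeros:
            observed = sorted(by_center)
            for c in observed:
                k = int(np.searchsorted(all_centers, c))
                for adj in (k - 1, k + 1):
                    if 0 <= adj < all_centers.size:
                        by_center.setdefault(float(all_centers[adj]), 0.0)
        if len(by_center) < 2:
            n_singletons += 1
            continue
        key_mz = wsum / isum if isum > 0 else float(np.mean([rows[i][0] for i in g]))
        centers = np.array(sorted(by_center))
        profiles.append(
            IntensityProfile(
                mz=key_mz,
                centers=centers,
                intensities=np.array([by_center[c] for c in centers]),
                width=width,
            )
        )
    if n_singletons:
        logger.info("dropped %d singleton peak groups (seen at one center only)", n_singletons)
    return profiles


@dataclass
class PseudoSpectrum:
    """A demultiplexed product-ion spectrum under one inferred precursor."""

    precursor_mz: float
    apex_intensity: float
    product_mzs: np.ndarray
    product_intensities: np.ndarray
    estimates: list[PrecursorEstimate] = field(default_factory=list)


@dataclass
class DemuxResult:
    """Outcome of demultiplexing one overlapping scan series."""

    pseudo_spectra: list[PseudoSpectrum]
    unassigned: list[IntensityProfile] = field(default_factory=list)


def demultiplex(
    scans: Sequence[ScanRecord],
    width: Optional[float] = None,
    ppm_tol: float = 25.0,
    grouping_tol: float = 0.6,
) -> DemuxResult:
    """Full pipeline: associate, estimate, and cluster into pseudo-spectra.

    Each product profile yields a precursor estimate (flank regression,
    or the two-point solver when a flank is starved); products are then
    clustered by estimated precursor m/z — consecutive sorted estimates
    closer than ``grouping_tol`` Th join the same cluster — into one
    pseudo-spectrum per inferred precursor.  Profiles whose fit fails are
    returned unassigned.
    """
    profiles = associate_products(scans, ppm_tol=ppm_tol)
    if width is not None:
        for p in profiles:
            if abs(p.width - width) > 1e-9:
                raise InvalidParameterError(
                    f"scan width {p.width} does not match requested {width}"
                )
    fitted: list[tuple[IntensityProfile, PrecursorEstimate]] = []
    unassigned: list[IntensityProfile] = []
    for prof in profiles:
        try:
            fitted.append((prof, profile_fit(prof)))
        except (UnsolvableGeometryError, IllConditionedFitError) as exc:
            logger.debug("profile at %.4f Th unassigned: %s", prof.mz, exc)
            unassigned.append(prof)

    fitted.sort(key=lambda pe: pe[1].mz)
    clusters: list[list[tuple[IntensityProfile, PrecursorEstimate]]] = []
    for item in fitted:
        if clusters and item[1].mz - clusters[-1][-1][1].mz <= grouping_tol:
            clusters[-1].append(item)
        else:
            clusters.append([item])

    spectra = []
    for members in clusters:
        amps = np.array([e.apex_intensity for _, e in members])
        mzs_est = np.array([e.mz for _, e in members])
        weight = amps / amps.sum()
        order = np.argsort([p.mz for p, _ in members])
        spectra.append(
            PseudoSpectrum(
                precursor_mz=float(np.sum(weight * mzs_est)),
                apex_intensity=float(amps.sum()),
                product_mzs=np.array([members[i][0].mz for i in order]),
                product_intensities=np.array(
                    [members[i][1].apex_intensity for i in order]
                ),
                estimates=[members[i][1] for i in order],
            )
        )
    return DemuxResult(pseudo_spectra=spectra, unassigned=unassigned)


def evaluate_estimates(
    estimates: Sequence[PrecursorEstimate],
    true_mzs: Sequence[float],
    width: Optional[float] = None,
):
    """Per-estimate deviation report against a truth table.

    Each estimate is matched to the nearest true precursor m/z.  Returns a
    pandas DataFrame with the signed m/z deviation, the x-intercept
    deviations from (true -/+ width/2) when a width is given, and the
    phase; summary statistics live in ``df.attrs['summary']``.
    """
    import pandas as pd

    true_arr = np.asarray(true_mzs, dtype=float)
    if true_arr.size == 0:
        raise InvalidParameterError("truth table is empty")
    recs = []
    for est in estimates:
        j = int(np.argmin(np.abs(true_arr - est.mz)))
        true = true_arr[j]
        rec = {
            "estimated_mz": est.mz,
            "true_mz": true,
            "delta_mz": est.mz - true,
            "apex_intensity": est.apex_intensity,
            "phase_deg": est.phase,
            "method": est.method,
        }
        if width is not None and est.x_low is not None and est.x_high is not None:
            rec["x_low_dev"] = est.x_low - (true - width / 2.0)
            rec["x_high_dev"] = est.x_high - (true + width / 2.0)
            rec["span_dev"] = (est.x_high - est.x_low) - width
        recs.append(rec)
    df = pd.DataFrame.from_records(recs)
    d = df["delta_mz"].to_numpy()
    df.attrs["summary"] = {
        "n": len(df),
        "max_abs_delta_mz": float(np.max(np.abs(d))),
        "mean_delta_mz": float(np.mean(d)),
        "rms_delta_mz": float(np.sqrt(np.mean(d**2))),
    }
    return df


def resolving_power(width: float, accuracy: float) -> int:
    """Precursor-association resolving power: window width over accuracy.

    A 10 Th window demultiplexed to 0.3 Th precursor accuracy resolves
    precursors at width/accuracy ~ 33 distinct positions per window.
    Rounded to the nearest integer for reporting.
    """
    if accuracy <= 0:
        raise InvalidParameterError(f"accuracy must be > 0, got {accuracy}")
    if width <= 0:
        raise InvalidParameterError(f"width must be > 0, got {width}")
    return int(round(width / accuracy))
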