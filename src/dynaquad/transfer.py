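"""The triangular transmission transfer function of dynamic quadrupole selection.

When the quadrupole selection window narrows linearly from a starting width
``w`` to a point over the ion accumulation period, an ion at ``mz`` is
transmitted only while it remains inside the instantaneous window.  The
fraction of the accumulation period during which it is transmitted is

    T(mz, c, w) = 1 - 2|mz - c| / w   if |mz - c| <  w/2
                = 0                    if |mz - c| >= w/2

where ``c`` is the selection center.  T ramps linearly from 0 at the window
edges to 1 at the center; the boundary point |mz - c| = w/2 maps to 0.

These are pure functions; everything else in the package composes with them.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .containers import SelectionWindow
from .errors import InvalidParameterError

ArrayLike = Union[float, np.ndarray]

__all__ = ["transmission", "mean_transmission", "effective_signal"]


def transmission(mz: ArrayLike, center: float, width: float, end_width: float = 0.0) -> ArrayLike:
    """Fraction of the accumulation period during which ``mz`` is transmitted.

    Parameters
    ----------
    mz : float or array
        Ion mass-to-charge in Th.
    center : float
        Selection window center in Th.
    width : float
        Starting selection width in Th (must be positive).
    end_width : float, optional
        Final window width.  The default 0 gives the triangular profile; a
        positive value gives a trapezoid with a flat top of width
        ``end_width`` (the ion is transmitted for the whole period anywhere
        inside the final window).

    Returns
    -------
    float or array in [0, 1], zero outside ``center ± width/2``.
    """
    if width <= 0:
        raise InvalidParameterError(f"width must be > 0, got {width}")
    if not (0 <= end_width <= width):
        raise InvalidParameterError(f"end_width must be in [0, width], got {end_width}")
    d = np.abs(np.asarray(mz, dtype=float) - center)
    if end_width == width:
        t = np.where(d < width / 2.0, 1.0, 0.0)
    else:
        # linear ramp from the flat top (d <= end_width/2) to the start edge
        t = (width - 2.0 * d) / (width - end_width)
        t = np.clip(t, 0.0, 1.0)
        t = np.where(d < width / 2.0, t, 0.0)
    if np.isscalar(mz):
        return float(t)
    return t


def mean_transmission(width: float, end_width: float = 0.0) -> float:
    """Mean of the transfer function over the starting window support.

    For the triangular profile this is exactly 1/2 for any width (similar
    triangles): relative to a static window of the same width, dynamic
    selection halves the average effective accumulation time.  For the
    trapezoidal generalisation the mean is (1 + end_width/width) / 2.
    """
    if width <= 0:
        raise InvalidParameterError(f"width must be > 0, got {width}")
    if not (0 <= end_width <= width):
        raise InvalidParameterError(f"end_width must be in [0, width], got {end_width}")
    return 0.5 * (1.0 + end_width / width)


def effective_signal(intensity_rate: float, mz: ArrayLike, window: SelectionWindow) -> ArrayLike:
    """Accumulated signal for an ion under a dynamic selection window.

    The observed spectral intensity is the product of the extrinsic
    abundance rate ``A`` (signal per ms at full transmission), the
    accumulation time, and the transfer function:

        I = A * t * T(mz, c, w)
    """
    if intensity_rate < 0:
        raise InvalidParameterError(f"intensity rate must be >= 0, got {intensity_rate}")
    t = transmission(mz, window.center, window.start_width, window.end_width)
    return intensity_rate * window.accumulation_time * t
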