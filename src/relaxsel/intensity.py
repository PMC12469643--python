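"""Relaxation rates from peak-intensity decay series.

R1 comes from a two-parameter monoexponential fit of intensities over the
relaxation-delay series; η_xy from the constant-time series in which a
variable delay ζ ∈ [−T/4, +T/4] modulates the transverse relaxation
between the TROSY and anti-TROSY components, giving
I(ζ) = A·exp(−c·η_xy·ζ) with modulation factor c = 4 by default; the NOE
is the ratio of saturated to reference peak intensities with first-order
error propagation. Reported relative errors are floored at 5% throughout,
matching the conservative error convention used for such fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IntensitySeries",
    "R1_DELAYS_S",
    "ETA_ZETA_DELAYS_S",
    "fit_exp_decay",
    "eta_from_ct_series",
    "noe_from_ratio",
]

#: relaxation-delay grid for R1 series (s)
R1_DELAYS_S: tuple[float, ...] = (
    0.010, 0.090, 0.192, 0.260, 0.380, 0.480, 0.690, 0.980, 1.220, 1.444,
)
#: constant-time ζ grid for the η_xy series (s)
ETA_ZETA_DELAYS_S: tuple[float, ...] = (
    -0.05, -0.0375, -0.025, -0.0125, 0.0, 0.0125, 0.025, 0.0375, 0.05,
)

ERROR_FLOOR = 0.05   # minimum reported relative error


@dataclass
class IntensitySeries:
    """Peak intensities over a delay grid for one residue.

    ``delays`` may be negative in constant-time η_xy mode (the ζ grid);
    ``constant_time`` carries T for that mode.
    """

    delays: np.ndarray
    intensities: np.ndarray
    noise: float | None = None
    constant_time: float | None = None
    residue: int | None = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.size < 3:
            raise ValueError("need at least 3 delay points")
        if self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must match in length")
        order = np.argsort(self.delays)
        self.delays = self.delays[order]
        self.intensities = self.intensities[order]
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly monotone after sorting")


def _floor_error(rate: float, err: float) -> float:
    return max(err, ERROR_FLOOR * abs(rate))


def fit_exp_decay(series: IntensitySeries, *,
                  with_offset: bool = False) -> tuple[float, float]:
    """Rate from I(t) = I0·exp(−R·t); returns (R in s⁻¹, error).

    The error is the covariance-derived standard error of R, floored at 5%
    of the rate. ``with_offset`` adds a constant baseline parameter.
    """
    t, y = series.delays, series.intensities
    if np.any(y <= 0) and not with_offset:
        raise ValueError("intensities must be positive for a log-decay fit")
    span = t[-1] - t[0]
    # log-linear slope as initial guess
    r0 = 0.0
    if np.all(y > 0):
        slope = np.polyfit(t, np.log(y), 1)[0]
        r0 = max(-slope, 0.0)
    sigma = np.full_like(y, series.noise) if series.noise else None
    if with_offset:
        model = lambda t, i0, r, c: i0 * np.exp(-r * t) + c  # noqa: E731
        p0 = (y[0] - y[-1], r0 if r0 > 0 else 1.0 / max(span, 1e-9), y[-1])
    else:
        model = lambda t, i0, r: i0 * np.exp(-r * t)  # noqa: E731
        p0 = (y[0], r0)
    popt, pcov = curve_fit(model, t, y, p0=p0, sigma=sigma, maxfev=10000)
    rate = float(popt[1])
    err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else 0.0
    return rate, _floor_error(rate, err)


def eta_from_ct_series(series: IntensitySeries, *,
                       exponent_factor: float = 4.0) -> tuple[float, float]:
    """η_xy from a constant-time series I(ζ) = A·exp(−c·η_xy·ζ).

    The fit is log-linear in ζ: −slope/c with c = ``exponent_factor``
    (default 4). A series symmetric in ζ yields η_xy = 0; negating ζ
    negates the rate. Returns (η_xy in s⁻¹, error floored at 5%).
    """
    z, y = series.delays, series.intensities
    if np.any(y <= 0):
        raise ValueError("constant-time intensities must be positive")
    if series.constant_time is not None:
        if np.abs(z).max() > series.constant_time / 2 + 1e-12:
            raise ValueError("|zeta| exceeds T/2 for the stated constant time")
    w = None
    if series.noise:
        w = y / series.noise            # d(log I) error = noise / I
    coeffs, cov = np.polyfit(z, np.log(y), 1, w=w, cov=True)
    eta = float(-coeffs[0] / exponent_factor)
    err = float(math.sqrt(cov[0, 0]) / exponent_factor)
    return eta, _floor_error(eta, err)


def noe_from_ratio(i_sat: float, i_ref: float,
                   noise_sat: float = 0.0,
                   noise_ref: float = 0.0) -> tuple[float, float]:
    """Heteronuclear NOE as I_sat/I_ref with propagated error.

    Negative saturated intensities (highly flexible residues) pass through
    with their sign. The relative error is the quadrature sum of the two
    intensity S/N terms, floored at 5%.
    """
    if i_ref == 0:
        raise ValueError("reference intensity must be non-zero")
    noe = i_sat / i_ref
    rel = math.hypot(
        noise_sat / i_sat if i_sat != 0 else 0.0,
        noise_ref / i_ref,
    )
    err = abs(noe) * rel
    return noe, max(err, ERROR_FLOOR * abs(noe))
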