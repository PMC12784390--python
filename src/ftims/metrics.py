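"""Peak fitting and spectral figures of merit.

Two quantities score a mobility spectrum:

* resolving power  Rp = td / w_1/2  — drift time over full width at half
  maximum, and
* signal-to-noise  S/N = peak height / mu_RMS, with the RMS noise

      mu_RMS = sqrt( sum_i (H_i - Hbar)^2 / n )

  taken over a signal-free region of the spectrum.

Peaks are detected as local maxima above a prominence threshold and refined
with a Gaussian fit; the reported width ``w_half`` is measured directly from
interpolated half-maximum crossings, so it stays meaningful for line shapes
(window main lobes) that a Gaussian only approximates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths

if TYPE_CHECKING:  # pragma: no cover
    from .reconstruct import MobilitySpectrum

__all__ = [
    "GAUSSIAN_FWHM_FACTOR",
    "Peak",
    "NoiseEstimate",
    "fit_peaks",
    "resolving_power",
    "rms_noise",
    "default_noise_region",
    "snr",
]

#: FWHM of a unit-sigma Gaussian: 2 sqrt(2 ln 2).
GAUSSIAN_FWHM_FACTOR = 2.3548200450309493


@dataclass(frozen=True)
class Peak:
    """A fitted spectral peak: centre ``td`` (ms), FWHM ``w_half`` (ms),
    ``height`` and ``area`` (height * ms)."""

    td: float
    w_half: float
    height: float
    area: float
    note: str | None = None


@dataclass(frozen=True)
class NoiseEstimate:
    """Population RMS deviation of a spectral region of ``n`` points."""

    mu_rms: float
    region: tuple[float, float] | None
    n: int


def _gauss(t, a, mu, s):
    return a * np.exp(-0.5 * ((t - mu) / s) ** 2)


def _fwhm_by_crossings(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """FWHM around local maximum index ``i`` from linearly interpolated
    half-height crossings; NaN if a flank never drops below half."""
    half = y[i] / 2.0

    def crossing(direction: int) -> float:
        j = i
        while True:
            k = j + direction
            if k < 0 or k >= len(y):
                return np.nan
            if y[k] <= half:
                # interpolate between j and k
                frac = (y[j] - half) / (y[j] - y[k])
                return x[j] + frac * (x[k] - x[j])
            j = k

    left = crossing(-1)
    right = crossing(+1)
    return right - left


def fit_peaks(spectrum: "MobilitySpectrum",
              min_prominence: float = 0.2) -> list[Peak]:
    """Detect and fit peaks in a mobility spectrum.

    Local maxima with prominence above ``min_prominence`` times the global
    maximum are kept; each is fitted with a Gaussian over a window of +/- 2
    preliminary half-widths for centre and height, while ``w_half`` comes
    from direct half-maximum crossings.  Returns peaks sorted by drift time
    (so equal-prominence ties resolve leftmost-first); an empty list if
    nothing clears the threshold.
    """
    x = spectrum.drift_times
    y = spectrum.intensity
    if len(y) == 0:
        raise ValueError("empty spectrum")
    ymax = float(y.max())
    if ymax <= 0:
        return []
    idx, _ = find_peaks(y, prominence=min_prominence * ymax)
    peaks: list[Peak] = []
    for i in idx:
        w = _fwhm_by_crossings(x, y, i)
        if not np.isfinite(w) or w <= 0:
            widths, *_ = peak_widths(y, [i], rel_height=0.5)
            w = float(widths[0]) * spectrum.bin_width
            if w <= 0:
                continue
        half_width = w / 2.0
        sel = (x >= x[i] - 2.0 * half_width) & (x <= x[i] + 2.0 * half_width)
        p0 = (y[i], x[i], w / GAUSSIAN_FWHM_FACTOR)
        try:
            popt, _ = curve_fit(_gauss, x[sel], y[sel], p0=p0, maxfev=2000)
            a, mu, s = float(popt[0]), float(popt[1]), abs(float(popt[2]))
            if not (x[i] - w <= mu <= x[i] + w) or a <= 0:
                raise RuntimeError("fit wandered off the peak")
        except RuntimeError:
            a, mu, s = float(y[i]), float(x[i]), w / GAUSSIAN_FWHM_FACTOR
        peaks.append(Peak(td=mu, w_half=float(w), height=a,
                          area=a * s * np.sqrt(2.0 * np.pi)))
    peaks.sort(key=lambda p: p.td)
    return peaks


def resolving_power(peak: Peak) -> float:
    """Rp = td / w_half (dimensionless)."""
    if peak.w_half <= 0:
        raise ValueError("resolving power undefined for zero peak width")
    return peak.td / peak.w_half


def rms_noise(H, region: tuple[float, float] | None = None,
              ddof: int = 0) -> NoiseEstimate:
    """Population RMS deviation of an intensity series.

    ``mu_rms = sqrt(sum_i (H_i - Hbar)^2 / (n - ddof))`` with ``Hbar`` the
    arithmetic mean.  ``ddof=0`` (the default) is the population RMS;
    ``ddof=1`` gives the sample standard deviation for users who prefer it.
    ``region`` is carried through for reporting only.
    """
    H = np.asarray(H, dtype=float)
    n = len(H)
    if n < 2:
        raise ValueError("rms_noise needs at least 2 points")
    mu = float(np.sqrt(np.sum((H - H.mean()) ** 2) / (n - ddof)))
    return NoiseEstimate(mu_rms=mu, region=region, n=n)


def default_noise_region(spectrum: "MobilitySpectrum",
                         peaks: list[Peak]) -> tuple[float, float]:
    """A signal-free region: the final 20% of the drift axis, shifted left
    in whole region-lengths until it clears every peak by 3 half-widths."""
    x = spectrum.drift_times
    span = x[-1] - x[0]
    length = 0.2 * span
    start = x[-1] - length
    while start >= x[0]:
        stop = start + length
        clear = all(
            stop <= p.td - 3.0 * p.w_half or start >= p.td + 3.0 * p.w_half
            for p in peaks
        )
        if clear:
            return (float(start), float(stop))
        start -= length
    raise ValueError("no peak-free noise region found on the drift axis")


def snr(spectrum: "MobilitySpectrum", peak: Peak,
        noise_region: tuple[float, float] | None = None,
        peaks: list[Peak] | None = None) -> float:
    """Signal-to-noise: maximum peak height over the RMS noise of a
    signal-free region.

    A user-supplied ``noise_region`` must stay at least 3 half-widths away
    from every fitted peak (those in ``peaks``, or at least the scored peak);
    otherwise it is refused.  With no region given, the default region from
    :func:`default_noise_region` is used.  A noiseless spectrum returns
    ``inf``.
    """
    all_peaks = peaks if peaks is not None else [peak]
    if noise_region is None:
        noise_region = default_noise_region(spectrum, all_peaks)
    else:
        start, stop = noise_region
        for p in all_peaks:
            if not (stop <= p.td - 3.0 * p.w_half
                    or start >= p.td + 3.0 * p.w_half):
                raise ValueError(
                    f"noise region {noise_region} overlaps the peak at "
                    f"{p.td:.2f} ms (+/- 3 w_half)"
                )
    x = spectrum.drift_times
    sel = (x >= noise_region[0]) & (x <= noise_region[1])
    est = rms_noise(spectrum.intensity[sel], region=noise_region)
    if est.mu_rms == 0.0:
        return np.inf
    return peak.height / est.mu_rms
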