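"""Pigment quantification, spectral peak detection, stability and dose-response.

Covers the spectrophotometric side of the pigment workflow:

* Beer--Lambert quantification, ``c = A / (a * b)``;
* peak detection in UV--Vis or FTIR spectra (local maxima above a
  prominence threshold, positions refined by 3-point parabolic
  interpolation; regions at the instrument ceiling can be masked);
* residual-intensity (percent retention) series for pH/thermal stability
  and a stable/degrading classification against a retention threshold;
* phosphomolybdenum-style antioxidant activity,
  ``100 * (As - Ablank) / (Acontrol - Ablank)``;
* EC50 by linear interpolation on the concentration axis between the two
  measured points bracketing 50% activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Spectrum",
    "Peak",
    "StabilitySeries",
    "DoseResponse",
    "EC50Result",
    "beer_lambert_concentration",
    "beer_lambert_absorbance",
    "detect_peaks",
    "residual_intensity",
    "classify_stability",
    "antioxidant_activity",
    "ec50_interpolate",
]


@dataclass
class Spectrum:
    """Ordered (abscissa, absorbance) pairs.

    ``kind`` is ``"uvvis"`` (abscissa in nm) or ``"ftir"`` (cm^-1).
    A descending abscissa (common in FTIR exports) is re-sorted ascending.
    """

    x: np.ndarray
    y: np.ndarray
    kind: str = "uvvis"
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("abscissa and absorbance must be equal-length 1-D arrays")
        if self.x.size >= 2:
            d = np.diff(self.x)
            if np.all(d < 0):
                self.x, self.y = self.x[::-1].copy(), self.y[::-1].copy()
            elif not np.all(d > 0):
                raise ValueError("abscissa must be strictly monotone")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("absorbance contains non-finite values")
        if self.kind not in {"uvvis", "ftir"}:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class Peak:
    position: float
    height: float


def beer_lambert_concentration(absorbance: float, a: float, b: float) -> float:
    """Concentration from Beer--Lambert, ``c = A / (a * b)``.

    ``a`` is the absorptivity in per-(concentration * cm), ``b`` the path
    length in cm; the concentration unit is whatever ``a`` is quoted in.
    """
    if a <= 0 or b <= 0:
        raise ValueError("absorptivity and path length must be positive")
    return absorbance / (a * b)


def beer_lambert_absorbance(c: float, a: float, b: float) -> float:
    """Inverse of :func:`beer_lambert_concentration`: ``A = a * b * c``."""
    if a <= 0 or b <= 0:
        raise ValueError("absorptivity and path length must be positive")
    return a * b * c


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabola through (i-1, i, i+1); falls back to the grid point."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1, 1))
    step = 0.5 * (x[i + 1] - x[i - 1])
    return float(x[i] + delta * step), float(y1 - 0.25 * (y0 - y2) * delta)


def detect_peaks(
    spectrum: Spectrum,
    prominence: float | None = None,
    ceiling: float | None = None,
    min_points: int = 5,
) -> list[Peak]:
    """Local maxima of a spectrum above a prominence threshold.

    ``prominence`` defaults to 2% of the spectrum's absorbance range.
    Points at or above ``ceiling`` (the instrument's saturation level, if
    given) are excluded from candidate peaks before parabolic refinement,
    since a clipped plateau has no meaningful apex.
    """
    if len(spectrum) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(spectrum)}")
    x, y = spectrum.x, spectrum.y
    rng = float(y.max() - y.min())
    if rng == 0:
        return []
    if prominence is None:
        prominence = 0.02 * rng
    idx, _props = find_peaks(y, prominence=prominence)
    peaks = []
    for i in idx:
        if ceiling is not None and y[i] >= ceiling:
            continue
        pos, height = _parabolic_refine(x, y, int(i))
        peaks.append(Peak(position=pos, height=height))
    return peaks


@dataclass
class StabilitySeries:
    """Pigment intensity over time under one pH or temperature condition."""

    condition: str
    times_min: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_min.shape != self.intensities.shape:
            raise ValueError("times and intensities must align")
        if self.times_min.size == 0:
            raise ValueError("empty stability series")
        if self.times_min[0] != 0:
            raise ValueError("stability series must start at t = 0")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")


def residual_intensity(series: StabilitySeries) -> np.ndarray:
    """Percent retention 100 * I(t) / I(0) at every time point."""
    i0 = series.intensities[0]
    if i0 <= 0:
        raise ValueError("reference intensity I(0) must be > 0")
    return 100.0 * series.intensities / i0


def classify_stability(series: StabilitySeries, threshold: float = 90.0) -> str:
    """``"stable"`` iff retention at the final time point >= threshold (%)."""
    final = residual_intensity(series)[-1]
    return "stable" if final >= threshold else "degrading"


def antioxidant_activity(a_sample: float, a_blank: float, a_control: float) -> float:
    """Percent scavenging: 100 * (Asample - Ablank) / (Acontrol - Ablank)."""
    denom = a_control - a_blank
    if denom == 0:
        raise ValueError("control and blank absorbances coincide; activity undefined")
    return 100.0 * (a_sample - a_blank) / denom


@dataclass
class DoseResponse:
    """Paired concentration (ug/mL) / activity (%) series."""

    concentrations: np.ndarray
    activities: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.concentrations.shape != self.activities.shape:
            raise ValueError("concentrations and activities must align")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be > 0")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.activities)):
            raise ValueError("activities must be finite")


@dataclass
class EC50Result:
    value: float  # ug/mL
    bracket: tuple[float, float] | None = None
    warnings: list[str] = field(default_factory=list)


def ec50_interpolate(
    dr: DoseResponse, level: float = 50.0, log_scale: bool = False
) -> EC50Result:
    """Half-maximal concentration by linear interpolation at the 50% crossing.

    The first adjacent pair whose activities bracket ``level`` is
    interpolated linearly on the concentration axis (or on log-concentration
    with ``log_scale=True``). An exact hit returns that concentration.
    Raises if the series never crosses the level; later crossings beyond the
    first are recorded as a warning.
    """
    c, a = dr.concentrations, dr.activities
    notes: list[str] = []
    hits = np.flatnonzero(a == level)
    crossings = [
        i for i in range(len(a) - 1)
        if (a[i] - level) * (a[i + 1] - level) < 0
    ]
    if hits.size:
        first_hit = int(hits[0])
        if crossings and crossings[0] < first_hit:
            pass  # interpolated crossing comes first
        else:
            if hits.size > 1 or crossings:
                notes.append("response crosses the level more than once; first hit used")
            return EC50Result(value=float(c[first_hit]), bracket=None, warnings=notes)
    if not crossings:
        raise ValueError(
            f"EC{level:g} outside measured range: activities never cross {level}%"
        )
    if len(crossings) > 1 or (hits.size and crossings):
        notes.append("response crosses the level more than once; first crossing used")
    i = crossings[0]
    frac = (level - a[i]) / (a[i + 1] - a[i])
    if log_scale:
        value = float(np.exp(np.log(c[i]) + frac * (np.log(c[i + 1]) - np.log(c[i]))))
    else:
        value = float(c[i] + frac * (c[i + 1] - c[i]))
    return EC50Result(value=value, bracket=(float(c[i]), float(c[i + 1])), warnings=notes)
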