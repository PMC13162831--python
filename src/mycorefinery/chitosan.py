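"""Fungal chitosan characterization: yield, deacetylation degree, composites.

Chitosan recovered from de-oiled fungal biomass is characterized by

* gravimetric yield, ``100 * obtained / sample`` (% of dry biomass);
* degree of deacetylation (DD) from an FTIR spectrum by the two-point
  baseline method: within each band window a straight baseline is drawn
  between the window endpoints, the peak absorbance above it is read, and

      DD = 100 - (A1655 / A3450) * (100 / 1.33),

  where 1.33 is the amide-I/hydroxyl absorbance ratio of fully acetylated
  chitin (overridable);
* encapsulation efficiency and loading capacity of a chitosan--pigment
  composite, ``EE = 100*(total - free)/total`` and
  ``LC = 100*(total - free)/chitosan weight``;
* band-shift tables between two FTIR spectra (or band lists): greedy
  nearest-neighbor matching within a wavenumber window, reporting shifts
  and bands that appear or disappear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pigment import Spectrum, detect_peaks

__all__ = [
    "DDResult",
    "CompositeMetrics",
    "BandMatch",
    "BandShiftTable",
    "FULLY_ACETYLATED_RATIO",
    "chitosan_yield",
    "baseline_corrected_band",
    "degree_of_deacetylation",
    "encapsulation_efficiency",
    "loading_capacity",
    "composite_metrics",
    "compare_band_positions",
]

#: Baseline-method constant: A(amide I)/A(hydroxyl) of fully acetylated chitin.
FULLY_ACETYLATED_RATIO = 1.33

#: Default band windows (center, half-width) in cm^-1.
AMIDE_I_WINDOW = (1655.0, 40.0)
HYDROXYL_WINDOW = (3450.0, 40.0)


def chitosan_yield(obtained_dry_weight: float, sample_dry_weight: float) -> float:
    """Gravimetric chitosan yield: 100 * obtained / sample (%)."""
    if sample_dry_weight <= 0:
        raise ValueError("sample dry weight must be > 0")
    if obtained_dry_weight < 0:
        raise ValueError("obtained dry weight must be >= 0")
    if obtained_dry_weight > sample_dry_weight:
        raise ValueError(
            f"obtained mass {obtained_dry_weight} exceeds sample mass "
            f"{sample_dry_weight}: impossible yield"
        )
    return 100.0 * obtained_dry_weight / sample_dry_weight


def baseline_corrected_band(
    spectrum: Spectrum, center: float, half_width: float
) -> float:
    """Peak absorbance above a two-point linear baseline across a band window.

    The baseline runs between the spectrum's values at the window edges
    (linearly interpolated); the returned height is the apex of
    (absorbance - baseline) inside the window, refined by a 3-point
    parabola so band centers off the sampling grid are not underread.
    """
    lo, hi = center - half_width, center + half_width
    x, y = spectrum.x, spectrum.y
    if lo < x[0] or hi > x[-1]:
        raise ValueError(
            f"spectrum [{x[0]:.1f}, {x[-1]:.1f}] does not cover the band window "
            f"[{lo:.1f}, {hi:.1f}] cm^-1"
        )
    y_lo = float(np.interp(lo, x, y))
    y_hi = float(np.interp(hi, x, y))
    sel = (x >= lo) & (x <= hi)
    xs, ys = x[sel], y[sel]
    baseline = y_lo + (xs - lo) * (y_hi - y_lo) / (hi - lo)
    corrected = ys - baseline
    i = int(np.argmax(corrected))
    height = float(corrected[i])
    if 0 < i < len(corrected) - 1:
        y0, y1, y2 = corrected[i - 1], corrected[i], corrected[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # true local maximum
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1:
                height = float(y1 - 0.25 * (y0 - y2) * delta)
    if height <= 0:
        raise ValueError(
            f"no band above baseline in window [{lo:.1f}, {hi:.1f}] cm^-1"
        )
    return height


@dataclass
class DDResult:
    """Degree-of-deacetylation readout from one FTIR spectrum."""

    a_amide: float  # baseline-corrected amide I absorbance (~1655 cm^-1)
    a_hydroxyl: float  # baseline-corrected O-H/N-H absorbance (~3450 cm^-1)
    dd: float  # percent deacetylation

    @property
    def ratio(self) -> float:
        return self.a_amide / self.a_hydroxyl


def degree_of_deacetylation(
    spectrum: Spectrum,
    amide_window: tuple[float, float] = AMIDE_I_WINDOW,
    hydroxyl_window: tuple[float, float] = HYDROXYL_WINDOW,
    acetylated_ratio: float = FULLY_ACETYLATED_RATIO,
) -> DDResult:
    """DD (%) from the baseline-corrected amide-I / hydroxyl band ratio.

    Windows are ``(center, half_width)`` in cm^-1; defaults sit on the
    1655 and 3450 cm^-1 bands. DD is clipped to [0, 100] only if baseline
    noise pushes the ratio marginally outside the physical range.
    """
    a_amide = baseline_corrected_band(spectrum, *amide_window)
    a_hydroxyl = baseline_corrected_band(spectrum, *hydroxyl_window)
    if a_hydroxyl <= 0:
        raise ValueError("hydroxyl band absorbance must be positive after correction")
    dd = 100.0 - (a_amide / a_hydroxyl) * (100.0 / acetylated_ratio)
    dd = float(np.clip(dd, 0.0, 100.0))
    return DDResult(a_amide=a_amide, a_hydroxyl=a_hydroxyl, dd=dd)


def encapsulation_efficiency(total_pigment: float, free_pigment: float) -> float:
    """EE (%) = 100 * (total - free) / total."""
    if total_pigment <= 0:
        raise ValueError("total pigment must be > 0")
    if free_pigment < 0:
        raise ValueError("free pigment must be >= 0")
    if free_pigment > total_pigment:
        raise ValueError(f"free pigment {free_pigment} exceeds total {total_pigment}")
    return 100.0 * (total_pigment - free_pigment) / total_pigment


def loading_capacity(
    total_pigment: float, free_pigment: float, chitosan_weight: float
) -> float:
    """LC (%) = 100 * (total - free) / chitosan weight."""
    if chitosan_weight <= 0:
        raise ValueError("chitosan weight must be > 0")
    if free_pigment > total_pigment:
        raise ValueError(f"free pigment {free_pigment} exceeds total {total_pigment}")
    return 100.0 * (total_pigment - free_pigment) / chitosan_weight


@dataclass
class CompositeMetrics:
    """Encapsulation metrics of a chitosan--pigment composite (masses in mg)."""

    total_pigment: float
    free_pigment: float
    chitosan_weight: float
    ee: float = field(init=False)
    lc: float = field(init=False)

    def __post_init__(self) -> None:
        self.ee = encapsulation_efficiency(self.total_pigment, self.free_pigment)
        self.lc = loading_capacity(
            self.total_pigment, self.free_pigment, self.chitosan_weight
        )


def composite_metrics(
    total_pigment: float, free_pigment: float, chitosan_weight: float
) -> CompositeMetrics:
    return CompositeMetrics(total_pigment, free_pigment, chitosan_weight)


@dataclass
class BandMatch:
    reference: float
    sample: float
    shift: float  # sample - reference, cm^-1
    assignment: str = ""


@dataclass
class BandShiftTable:
    """Nearest-neighbor band correspondence between two FTIR spectra."""

    matches: list[BandMatch]
    only_reference: list[float]  # bands that disappear in the sample
    only_sample: list[float]  # bands that appear in the sample


def _band_positions(obj) -> list[float]:
    if isinstance(obj, Spectrum):
        return [p.position for p in detect_peaks(obj)]
    return [float(v) for v in obj]


def compare_band_positions(
    reference, sample, window: float = 60.0
) -> BandShiftTable:
    """Match band positions between two spectra (or band lists).

    Greedy nearest-neighbor matching: candidate pairs within ``window``
    cm^-1 are taken in order of increasing absolute shift (ties to the
    lower reference wavenumber), each band used at most once. Unmatched
    bands are reported as disappearing (reference only) or appearing
    (sample only).
    """
    ref = _band_positions(reference)
    sam = _band_positions(sample)
    pairs = [
        (abs(s - r), r, s)
        for r in ref
        for s in sam
        if abs(s - r) <= window
    ]
    pairs.sort(key=lambda t: (t[0], t[1]))
    used_r: set[float] = set()
    used_s: set[float] = set()
    matches: list[BandMatch] = []
    for _d, r, s in pairs:
        if r in used_r or s in used_s:
            continue
        used_r.add(r)
        used_s.add(s)
        matches.append(BandMatch(reference=r, sample=s, shift=s - r))
    matches.sort(key=lambda m: -m.reference)
    return BandShiftTable(
        matches=matches,
        only_reference=sorted((r for r in ref if r not in used_r), reverse=True),
        only_sample=sorted((s for s in sam if s not in used_s), reverse=True),
    )
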