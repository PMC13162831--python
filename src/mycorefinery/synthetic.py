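"""Seeded synthetic-data generators with known ground truth.

Every pipeline stage has a generator that emulates the shape of the real
measurements and returns the exact quantity the analysis is supposed to
recover, so recovery can be asserted without external data:

* :func:`make_fame_profile` — GC-MS-style FAME tables, Dirichlet mass
  allocation concentrated on C16--C18 esters, with the exactly computed
  fuel-property vector;
* :func:`make_spectrum` — sums of Gaussian bands on an optional sloped
  baseline (UV--Vis or FTIR), with the true peak list; the FTIR helper
  :func:`make_ftir_dd_spectrum` also returns the true baseline-corrected
  amide/hydroxyl ratio;
* :func:`make_decay_series` — first-order intensity decay
  ``I(t) = I0 * exp(-k t)`` sampled at 0..150 min;
* :func:`make_dose_response` — logistic activity curves with known
  midpoint on the standard 10--100 ug/mL grid;
* :func:`make_fermentation_table` — bell-shaped (quadratic in log
  substrate) dose series with mass-balance-consistent sugar columns.

All randomness flows from the spec's single integer seed; an identical
spec reproduces identical data bit for bit. Additive Gaussian noise is
clipped at zero where the measured quantity cannot be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _refdata
from .fame import FAMEComponent, FAMEProfile, FuelProperties, normalize
from .fermentation import CultureObservation
from .pigment import DoseResponse, Spectrum, StabilitySeries

__all__ = [
    "FameProfileSpec",
    "SpectrumSpec",
    "DecaySpec",
    "DoseResponseSpec",
    "FermentationSpec",
    "make_fame_profile",
    "make_spectrum",
    "make_ftir_dd_spectrum",
    "make_decay_series",
    "make_dose_response",
    "make_fermentation_table",
]


# ---------------------------------------------------------------------------
# FAME profiles


@dataclass
class FameProfileSpec:
    """Controls the synthetic FAME composition.

    ``c16_c18_weight`` multiplies the Dirichlet concentration of C16--C18
    species so the dominant esters mirror a typical oleaginous fungal oil.
    """

    seed: int = 0
    n_components: int = 8
    c16_c18_weight: float = 6.0
    sn_constant: float = 560.0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("need at least one component")


def make_fame_profile(spec: FameProfileSpec) -> tuple[FAMEProfile, FuelProperties]:
    """Draw a FAME profile and its exactly computed fuel-property truth.

    The truth vector is computed by direct summation over the drawn
    fractions and the embedded reference constants — independent of the
    mixture-property code paths under test.
    """
    rng = np.random.default_rng(spec.seed)
    table = _refdata.reference_table().reset_index()
    k = min(spec.n_components, len(table))
    rows = table.iloc[
        np.sort(rng.choice(len(table), size=k, replace=False))
    ]
    alpha = np.where(
        (rows["carbons"] >= 16) & (rows["carbons"] <= 18),
        spec.c16_c18_weight,
        1.0,
    )
    fractions = rng.dirichlet(alpha) * 100.0
    comps = [
        FAMEComponent(
            name=f"synthetic {r.shorthand}",
            shorthand=r.shorthand,
            mass_fraction=float(f),
            molecular_weight=float(r.molecular_weight),
            double_bonds=int(r.double_bonds),
            density_ref=float(r.density_15c),
            viscosity_ref=float(r.viscosity_40c),
            cetane_ref=float(r.cetane),
            ref_source="table",
        )
        for r, f in zip(rows.itertuples(), fractions)
    ]
    profile = normalize(FAMEProfile(components=comps))
    # ground truth by plain sums
    w = np.array([c.mass_fraction for c in profile]) / 100.0
    rho = float(np.sum(w * [c.density_ref for c in profile]))
    nu = float(np.sum(w * [c.viscosity_ref for c in profile]))
    sn = float(np.sum(spec.sn_constant * w * 100.0 / np.array([c.molecular_weight for c in profile])))
    iv = float(
        np.sum(254.0 * np.array([c.double_bonds for c in profile]) * w * 100.0
               / np.array([c.molecular_weight for c in profile]))
    )
    cn = 1.068 * float(np.sum(w * [c.cetane_ref for c in profile])) - 6.747
    truth = FuelProperties(
        density=rho,
        kinematic_viscosity=nu,
        saponification_number=sn,
        iodine_value=iv,
        higher_heating_value=49.43 - (0.041 * sn + 0.015 * iv),
        cetane_number=cn,
        constants_record={"generator_seed": spec.seed, "sn_constant": spec.sn_constant},
    )
    return profile, truth


# ---------------------------------------------------------------------------
# spectra


@dataclass
class SpectrumSpec:
    """Gaussian-band spectrum: peaks are (center, height, sigma) triples."""

    seed: int = 0
    kind: str = "uvvis"
    x_start: float = 200.0
    x_stop: float = 800.0
    n_points: int = 601
    peaks: Sequence[tuple[float, float, float]] = field(
        default_factory=lambda: [(280.0, 1.0, 12.0), (420.0, 0.5, 15.0), (520.0, 0.4, 15.0)]
    )
    baseline_intercept: float = 0.0
    baseline_slope: float = 0.0
    noise_sd: float = 0.0


def make_spectrum(spec: SpectrumSpec) -> tuple[Spectrum, list[tuple[float, float]]]:
    """Sum of Gaussian bands + sloped baseline + clipped Gaussian noise.

    Returns the spectrum and the true ``(center, height)`` list. Peak
    centers must lie inside the abscissa range; zero/negative widths are
    rejected.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(spec.x_start, spec.x_stop, spec.n_points)
    y = spec.baseline_intercept + spec.baseline_slope * (x - spec.x_start)
    truth = []
    for center, height, sigma in spec.peaks:
        if sigma <= 0:
            raise ValueError(f"peak at {center}: width must be > 0")
        if not (spec.x_start <= center <= spec.x_stop):
            raise ValueError(f"peak center {center} outside abscissa range")
        y = y + height * np.exp(-0.5 * ((x - center) / sigma) ** 2)
        truth.append((float(center), float(height)))
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=x.size)
    y = np.clip(y, 0.0, None)
    return Spectrum(x=x, y=y, kind=spec.kind), truth


def make_ftir_dd_spectrum(
    seed: int = 0,
    ratio: float = 0.5,
    hydroxyl_height: float = 1.0,
    noise_sd: float = 5e-4,
    baseline_slope: float = 0.0,
) -> tuple[Spectrum, float]:
    """FTIR spectrum whose baseline-corrected amide/hydroxyl ratio is known.

    Places narrow Gaussian bands at 1655 and 3450 cm^-1 with heights
    ``ratio * hydroxyl_height`` and ``hydroxyl_height`` on a linear
    background, so a two-point baseline across the default +-40 cm^-1
    windows recovers the heights (and hence the ratio) almost exactly.
    Returns the spectrum and the true ratio.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    peaks = [(3450.0, hydroxyl_height, 9.0)]
    if ratio > 0:
        peaks.append((1655.0, ratio * hydroxyl_height, 9.0))
    spec = SpectrumSpec(
        seed=seed,
        kind="ftir",
        x_start=500.0,
        x_stop=4000.0,
        n_points=1751,
        peaks=peaks,
        baseline_intercept=0.05,
        baseline_slope=baseline_slope,
        noise_sd=noise_sd,
    )
    spectrum, _truth = make_spectrum(spec)
    return spectrum, ratio


# ---------------------------------------------------------------------------
# decay series


@dataclass
class DecaySpec:
    """First-order intensity decay at fixed sampling times (min)."""

    seed: int = 0
    i0: float = 1.0
    rate_per_min: float = 0.002
    times_min: Sequence[float] = (0, 30, 60, 90, 120, 150)
    noise_sd: float = 0.0
    condition: str = "synthetic"


def make_decay_series(spec: DecaySpec) -> tuple[StabilitySeries, float]:
    """``I(t) = I0 exp(-k t)`` plus clipped noise; returns the true rate k.

    The t = 0 point is left noise-free so percent retention has an exact
    reference.
    """
    if spec.i0 < 0:
        raise ValueError("initial intensity must be >= 0")
    if spec.rate_per_min < 0:
        raise ValueError("decay rate must be >= 0")
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times_min, dtype=float)
    y = spec.i0 * np.exp(-spec.rate_per_min * t)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=t.size)
        noise[0] = 0.0
        y = np.clip(y + noise, 0.0, None)
    return (
        StabilitySeries(condition=spec.condition, times_min=t, intensities=y),
        spec.rate_per_min,
    )


# ---------------------------------------------------------------------------
# dose-response


@dataclass
class DoseResponseSpec:
    """Logistic scavenging curve on the standard assay grid."""

    seed: int = 0
    midpoint: float = 23.6
    slope: float = 0.08  # per (ug/mL)
    floor: float = 0.0
    ceiling: float = 100.0
    concentrations: Sequence[float] = (10, 20, 40, 60, 80, 100)
    noise_sd: float = 0.0


def make_dose_response(spec: DoseResponseSpec) -> tuple[DoseResponse, float]:
    """Sampled logistic curve + noise; returns the true midpoint.

    ``activity(c) = floor + (ceiling - floor) / (1 + exp(-slope (c - m)))``
    so with floor 0 / ceiling 100 the true 50% point is exactly ``m``.
    """
    if spec.slope <= 0:
        raise ValueError("slope must be > 0")
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.concentrations, dtype=float)
    a = spec.floor + (spec.ceiling - spec.floor) / (
        1.0 + np.exp(-spec.slope * (c - spec.midpoint))
    )
    if spec.noise_sd > 0:
        a = a + rng.normal(0.0, spec.noise_sd, size=c.size)
    return DoseResponse(concentrations=c, activities=a), spec.midpoint


# ---------------------------------------------------------------------------
# fermentation tables


@dataclass
class FermentationSpec:
    """Bell-shaped substrate response over a screening grid."""

    seed: int = 0
    grid: Sequence[float] = (25, 50, 75, 100, 150, 200)
    optimum: float = 100.0
    peak_lipid: float = 3.9  # g/L at the optimum
    log_width: float = 0.6  # bell width in ln(substrate)
    sugar_fraction: float = 0.55  # total sugar per g substrate
    noise_sd: float = 0.0


def make_fermentation_table(
    spec: FermentationSpec,
) -> tuple[list[CultureObservation], float]:
    """Generate culture observations with a known grid optimum.

    The lipid response is a log-normal-shaped bell around ``optimum``;
    biomass tracks lipid; sugar columns respect the mass balance
    (0 <= residual <= total, consumption efficiency falling off above the
    optimum, mirroring substrate inhibition).
    """
    if not any(g == spec.optimum for g in spec.grid):
        raise ValueError("optimum must be a point of the substrate grid")
    rng = np.random.default_rng(spec.seed)
    obs: list[CultureObservation] = []
    for s in spec.grid:
        bell = np.exp(-0.5 * ((np.log(s) - np.log(spec.optimum)) / spec.log_width) ** 2)
        lipid = spec.peak_lipid * bell
        if spec.noise_sd > 0 and s != spec.optimum:
            # noise never promotes a non-optimal point above the optimum
            lipid = float(
                np.clip(lipid + rng.normal(0.0, spec.noise_sd), 0.0, 0.95 * spec.peak_lipid)
            )
        total = spec.sugar_fraction * s
        consumed_frac = 0.35 + 0.45 * bell
        residual = float(np.clip(total * (1.0 - consumed_frac), 0.0, total))
        dry_weight = max(2.0, 3.6 * lipid + 0.4)
        obs.append(
            CultureObservation(
                substrate_conc=float(s),
                total_sugar=float(total),
                residual_sugar=residual,
                dry_weight=float(dry_weight),
                lipid_conc=float(lipid),
                pigment_conc=float(1.2 * lipid + 0.3),
                treatment_label=f"SDF {s:g} g/L",
            )
        )
    return obs, spec.optimum
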