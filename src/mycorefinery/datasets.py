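"""Packaged study datasets: the transcribed measurement tables.

These small delimited fixtures carry the published measurements of the
*Talaromyces atroroseus* biorefinery workflow — the GC-MS FAME composition,
the substrate-loading and pretreatment screens, the pigment dose-response
points and the FTIR band assignments — so every analysis stage runs and is
demonstrable offline. ``± `` columns are split into mean/sd on load.
"""

from __future__ import annotations

from functools import lru_cache

import pandas as pd

from ._refdata import data_path
from .fame import FAMEProfile, parse_fame_table
from .fermentation import CultureObservation
from .io import read_table
from .pigment import DoseResponse

__all__ = [
    "load_fame_profile",
    "load_substrate_series",
    "load_pretreatment_screen",
    "load_pretreatment_observations",
    "load_pigment_dose_response",
    "load_pigment_substrate_series",
    "load_chitosan_bands",
    "substrate_composition",
    "load_pigment_gcms",
    "composite_antioxidant_assay",
    "printed_fuel_properties",
]


def load_fame_profile() -> FAMEProfile:
    """The strain's GC-MS FAME composition (15 esters, percent of total)."""
    with data_path("fame_profile_talaromyces.csv").open() as fh:
        return parse_fame_table(fh)


def load_substrate_series() -> pd.DataFrame:
    """Lipid production across substrate loadings 25--200 g/L SDF.

    Columns ending ``_printed`` are the published derived values kept for
    cross-checks; the raw columns are means with ``*_sd`` uncertainties.
    """
    with data_path("substrate_lipid_series.csv").open() as fh:
        return read_table(fh)


def load_pretreatment_screen() -> pd.DataFrame:
    """Thermal / acid / alkali pretreatment screen (sugars, biomass, lipid, pigment)."""
    with data_path("pretreatment_screen.csv").open() as fh:
        return read_table(fh)


def load_pretreatment_observations() -> list[CultureObservation]:
    """Pretreatment screen as observation records for ranking.

    The treatment label combines chemistry and temperature, e.g.
    ``"H2SO4 0.2 M, 121 degC"``. Substrate loading was fixed in this
    screen, so it is recorded as 100 g/L for all rows.
    """
    df = load_pretreatment_screen()
    obs = []
    for _, row in df.iterrows():
        if isinstance(row.get("chemical"), str) and row["chemical"]:
            label = f"{row['chemical']} {row['chemical_conc']} M, {row['temperature_c']:g} degC"
        else:
            label = f"Thermal, {row['temperature_c']:g} degC"
        obs.append(
            CultureObservation(
                substrate_conc=100.0,
                total_sugar=row["total_sugar"],
                dry_weight=row["dry_weight"],
                lipid_conc=row["lipid_conc"],
                pigment_conc=row["pigment_conc"],
                treatment_label=label,
                sd={
                    k: row[f"{k}_sd"]
                    for k in ("total_sugar", "dry_weight", "lipid_conc", "pigment_conc")
                    if f"{k}_sd" in row and pd.notna(row[f"{k}_sd"])
                },
            )
        )
    return obs


def load_pigment_dose_response() -> DoseResponse:
    """Published antioxidant dose-response points (ug/mL vs % scavenging)."""
    with data_path("pigment_dose_response.csv").open() as fh:
        df = read_table(fh)
    return DoseResponse(
        concentrations=df["concentration_ug_ml"].to_numpy(),
        activities=df["activity_percent"].to_numpy(),
    )


def load_pigment_substrate_series() -> list[tuple[float, float]]:
    """Pigment titer (g/L) vs substrate loading; peak at 100 g/L SDF."""
    return [(25.0, 2.31), (100.0, 4.80), (150.0, 2.90), (200.0, 2.10)]


def load_chitosan_bands() -> pd.DataFrame:
    """FTIR band assignments of fungal chitosan vs the pigment composite."""
    with data_path("chitosan_ftir_bands.csv").open() as fh:
        return pd.read_csv(fh)


def load_pigment_gcms() -> pd.DataFrame:
    """GC-MS compound profile of the pigment extract (stored as data only)."""
    with data_path("pigment_gcms_profile.csv").open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=1)
def substrate_composition() -> dict:
    """Proximate/mineral composition of the spoiled date fruit substrate (%).

    Total sugar is reported twice in the source material (62 in the
    composition table, 58 in the narrative); both are kept, unadjudicated.
    """
    return {
        "total_sugar": {"table": 62.0, "narrative": 58.0},
        "reducing_sugars": {"table": 21.0, "narrative": 24.0},
        "total_soluble_proteins": 3.1,
        "total_lipids": 0.21,
        "free_amino_acids": 1.01,
        "sodium": 0.005,
        "potassium": 0.042,
        "calcium": 0.035,
        "magnesium": 0.08,
        "phosphorus": 0.079,
        "zinc": 0.003,
        "cobalt": 0.006,
        "copper": 0.004,
        "fiber": 2.9,
    }


def composite_antioxidant_assay() -> dict:
    """Measured scavenging activities (%): pigment, chitosan, composite.

    Stored assay data; the package summarizes but does not model these.
    """
    return {
        "pigment": {"mean": 87.2, "sd": 4.2},
        "chitosan": {"mean": 56.4, "sd": 2.8},
        "composite": {"mean": 92.6, "sd": 4.6},
    }


def printed_fuel_properties() -> dict:
    """The published bulk fuel-property vector of the fungal biodiesel."""
    return {
        "density": 873.8,
        "kinematic_viscosity": 4.11,
        "saponification_number": 203.65,
        "iodine_value": 61.18,
        "higher_heating_value": 40.16,
        "cetane_number": 60.3,
    }
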