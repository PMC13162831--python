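"""Derived yields and optimum/ranking summaries for fungal batch cultures.

A culture observation couples the substrate loading (g/L spoiled date fruit,
SDF) with what was measured at harvest: total and residual sugar, biomass
dry weight, lipid titer and optionally pigment titer. From those raw
columns this module derives

* lipid content  = 100 * lipid / dry weight          (% of dry biomass),
* lipid yield    = 1000 * lipid / substrate          (mg lipid per g SDF),
* consumed sugar = total sugar - residual sugar      (g/L),

locates the grid optimum of a dose series (pure argmax — the screening
designs tested discrete substrate grids, so no curve is fitted), and ranks
pretreatment conditions by any response column.

Replicate standard deviations, when present, are carried through the
derived ratios by first-order (relative-variance) propagation; they are
reported but never used for decisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = [
    "CultureObservation",
    "DerivedYields",
    "OptimumResult",
    "lipid_content",
    "lipid_yield_per_substrate",
    "consumed_sugar",
    "derive_yields",
    "derive_table",
    "find_optimum",
    "rank_treatments",
]


@dataclass
class CultureObservation:
    """One fermentation condition with its measured responses (all g/L)."""

    substrate_conc: float
    total_sugar: float | None = None
    residual_sugar: float | None = None
    dry_weight: float | None = None
    lipid_conc: float | None = None
    pigment_conc: float | None = None
    treatment_label: str = ""
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for attr in ("substrate_conc", "total_sugar", "residual_sugar",
                     "dry_weight", "lipid_conc", "pigment_conc"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValueError(f"{attr} must be >= 0, got {v}")
        if (
            self.total_sugar is not None
            and self.residual_sugar is not None
            and self.residual_sugar > self.total_sugar
        ):
            raise ValueError(
                f"residual sugar {self.residual_sugar} exceeds total {self.total_sugar}"
            )


@dataclass
class DerivedYields:
    """Ratios computed from one observation, with propagated uncertainties."""

    lipid_content: float | None  # percent of dry weight
    lipid_yield: float | None  # mg lipid per g substrate
    consumed_sugar: float | None  # g/L
    sd: dict[str, float] = field(default_factory=dict)


def lipid_content(lipid_conc: float, dry_weight: float) -> float:
    """Lipid as percent of dry biomass: 100 * lipid / dry weight."""
    if dry_weight <= 0:
        raise ValueError("dry_weight must be > 0")
    if lipid_conc < 0:
        raise ValueError("lipid_conc must be >= 0")
    return 100.0 * lipid_conc / dry_weight


def lipid_yield_per_substrate(lipid_conc: float, substrate_conc: float) -> float:
    """Lipid yield on substrate: 1000 * lipid / substrate, mg/g."""
    if substrate_conc <= 0:
        raise ValueError("substrate_conc must be > 0")
    if lipid_conc < 0:
        raise ValueError("lipid_conc must be >= 0")
    return 1000.0 * lipid_conc / substrate_conc


def consumed_sugar(total: float, residual: float) -> float:
    """Sugar consumed over the run: total - residual (mass balance)."""
    if residual < 0 or total < 0:
        raise ValueError("sugar concentrations must be >= 0")
    if residual > total:
        raise ValueError(f"residual sugar {residual} exceeds total {total}")
    return total - residual


def _ratio_sd(value: float, num: float, num_sd: float, den: float, den_sd: float) -> float:
    # first-order propagation for a ratio
    if num == 0:
        return abs(value) * (den_sd / den) if den else 0.0
    return abs(value) * math.sqrt((num_sd / num) ** 2 + (den_sd / den) ** 2)


def derive_yields(obs: CultureObservation) -> DerivedYields:
    """Compute every derivable ratio of one observation; missing inputs -> None."""
    lc = ly = cs = None
    sd: dict[str, float] = {}
    if obs.lipid_conc is not None and obs.dry_weight:
        lc = lipid_content(obs.lipid_conc, obs.dry_weight)
        if "lipid_conc" in obs.sd or "dry_weight" in obs.sd:
            sd["lipid_content"] = _ratio_sd(
                lc, obs.lipid_conc, obs.sd.get("lipid_conc", 0.0),
                obs.dry_weight, obs.sd.get("dry_weight", 0.0),
            )
    if obs.lipid_conc is not None and obs.substrate_conc:
        ly = lipid_yield_per_substrate(obs.lipid_conc, obs.substrate_conc)
        if "lipid_conc" in obs.sd:
            sd["lipid_yield"] = _ratio_sd(
                ly, obs.lipid_conc, obs.sd.get("lipid_conc", 0.0), obs.substrate_conc, 0.0
            )
    if obs.total_sugar is not None and obs.residual_sugar is not None:
        cs = consumed_sugar(obs.total_sugar, obs.residual_sugar)
        if "total_sugar" in obs.sd or "residual_sugar" in obs.sd:
            sd["consumed_sugar"] = math.hypot(
                obs.sd.get("total_sugar", 0.0), obs.sd.get("residual_sugar", 0.0)
            )
    return DerivedYields(lipid_content=lc, lipid_yield=ly, consumed_sugar=cs, sd=sd)


def derive_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns to a raw observation table.

    Expects ``substrate_conc``, ``total_sugar``, ``dry_weight``,
    ``lipid_conc`` and optionally ``residual_sugar`` columns; adds
    ``lipid_content``, ``lipid_yield_mg_g`` and ``consumed_sugar``.
    """
    out = df.copy()
    out["lipid_content"] = [
        lipid_content(l, w) if pd.notna(l) and pd.notna(w) and w > 0 else float("nan")
        for l, w in zip(df["lipid_conc"], df["dry_weight"])
    ]
    out["lipid_yield_mg_g"] = [
        lipid_yield_per_substrate(l, s) if pd.notna(l) and pd.notna(s) and s > 0 else float("nan")
        for l, s in zip(df["lipid_conc"], df["substrate_conc"])
    ]
    if "residual_sugar" in df.columns:
        out["consumed_sugar"] = [
            consumed_sugar(t, r) if pd.notna(t) and pd.notna(r) else float("nan")
            for t, r in zip(df["total_sugar"], df["residual_sugar"])
        ]
    return out


@dataclass
class OptimumResult:
    """Grid argmax of a dose series."""

    substrate_conc: float
    response: float
    tie: bool = False


def find_optimum(
    observations: Sequence[CultureObservation] | Sequence[tuple[float, float]],
    response: str = "lipid_conc",
) -> OptimumResult:
    """Locate the substrate concentration with the maximal response.

    Accepts either :class:`CultureObservation` records (``response`` selects
    the field) or plain ``(substrate_conc, response)`` pairs. Ties resolve
    to the lowest substrate concentration and are flagged.
    """
    pairs: list[tuple[float, float]] = []
    for obs in observations:
        if isinstance(obs, CultureObservation):
            y = getattr(obs, response)
            if y is None:
                continue
            pairs.append((obs.substrate_conc, y))
        else:
            pairs.append((float(obs[0]), float(obs[1])))
    if not pairs:
        raise ValueError("empty dose series")
    best_y = max(y for _, y in pairs)
    winners = [x for x, y in pairs if y == best_y]
    return OptimumResult(
        substrate_conc=min(winners), response=best_y, tie=len(winners) > 1
    )


def rank_treatments(
    observations: Sequence[CultureObservation],
    response: str = "lipid_conc",
) -> list[tuple[CultureObservation, float]]:
    """Order treatments by descending response mean.

    The sort is stable, so equal responses keep their input order.
    Observations lacking the response are dropped.
    """
    if len(observations) == 0:
        raise ValueError("need at least one observation")
    scored = [
        (obs, getattr(obs, response))
        for obs in observations
        if getattr(obs, response) is not None
    ]
    return sorted(scored, key=lambda t: -t[1])
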