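"""Biodiesel fuel-property prediction from a FAME composition.

A gas-chromatographic FAME (fatty acid methyl ester) profile — component
identities and their mass percentages — is converted into the six standard
fuel-quality indicators of a B100 biodiesel:

* density (mass-fraction-weighted pure-ester densities at 15 degC, kg/m3),
* kinematic viscosity (abundance-weighted pure-ester viscosities at 40 degC,
  mm2/s; a log-linear mixing rule is available as an alternative),
* saponification number SN = sum(K * Ai / MWi) with K the KOH constant
  (default 560 mg KOH/g; see :data:`SN_CONSTANT_DEFAULT`),
* iodine value IV = sum(254 * D * Ai / MWi),
* higher heating value HHV = 49.43 - 0.041*SN - 0.015*IV,
* cetane number CN = 1.068 * sum(CNi * Wi) - 6.747.

Ai/Wi are mass percentages/fractions, MWi the ester molecular weight, D the
number of C=C double bonds, and the per-ester reference constants
(density, viscosity, cetane) come from an embedded table of published
pure-ester values (see ``data/fame_reference.csv``).

Components without published constants — hydroxy-, branched- or otherwise
substituted esters — are handled by a configurable inclusion policy:
``"homolog"`` (default) maps them onto the nearest straight-chain homolog
and records the mapping, ``"exclude"`` drops them and renormalizes, and
``"strict"`` raises.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
import pandas as pd

from . import _refdata

__all__ = [
    "FAMEComponent",
    "FAMEProfile",
    "FuelProperties",
    "StandardSpec",
    "ComplianceReport",
    "parse_fame_table",
    "parse_shorthand",
    "methyl_ester_weight",
    "normalize",
    "attach_reference_constants",
    "mixture_density",
    "mixture_viscosity",
    "saponification_number",
    "iodine_value",
    "higher_heating_value",
    "cetane_number",
    "compute_fuel_properties",
    "get_standard",
    "check_compliance",
    "SN_CONSTANT_DEFAULT",
    "IV_CONSTANT",
]

#: Default KOH-based saponification constant (mg KOH/g basis). The classical
#: summation uses 3*56.1 ~ 560; 254 (the iodine constant) is selectable for
#: strict formula fidelity but does not give SN on the mg KOH/g scale.
SN_CONSTANT_DEFAULT = 560.0

#: Iodine value constant: 2 * 126.9 g I2 per double bond, rounded as 254.
IV_CONSTANT = 254.0

_ATOMIC = {"C": 12.011, "H": 1.008, "O": 15.999}

_SHORTHAND_RE = re.compile(r"^(?P<prefix>[A-Za-z]{1,6}-)?[Cc](?P<c>\d{1,2}):(?P<d>\d{1,2})$")


def methyl_ester_weight(carbons: int, double_bonds: int = 0) -> float:
    """Formula weight (g/mol) of the methyl ester of a straight-chain acid.

    A fatty acid with ``carbons`` carbon atoms and ``double_bonds`` C=C bonds
    esterifies to C(n+1) H(2n+2-2d) O2.
    """
    if carbons < 2:
        raise ValueError(f"unphysical carbon count {carbons}")
    n_c = carbons + 1
    n_h = 2 * carbons + 2 - 2 * double_bonds
    if n_h <= 0:
        raise ValueError(f"C{carbons}:{double_bonds} has no valid formula")
    return n_c * _ATOMIC["C"] + n_h * _ATOMIC["H"] + 2 * _ATOMIC["O"]


def parse_shorthand(code: str) -> tuple[int, int, str]:
    """Parse a carbon:double-bond code like ``"C18:1"`` or ``"OH-C16:0"``.

    Returns ``(carbons, double_bonds, prefix)`` where a non-empty prefix
    (``"br-"``, ``"OH-"``, ``"ts-"``, ...) marks a substituted/branched ester
    that has no published pure-ester fuel constants.
    """
    m = _SHORTHAND_RE.match(code.strip())
    if m is None:
        raise ValueError(f"cannot parse FAME shorthand {code!r}")
    return int(m.group("c")), int(m.group("d")), (m.group("prefix") or "")


def _canonical(code: str) -> str:
    c, d, prefix = parse_shorthand(code)
    return f"{prefix}C{c}:{d}"


@dataclass
class FAMEComponent:
    """One ester of a FAME profile with its share and reference constants."""

    name: str
    shorthand: str
    mass_fraction: float  # percent of total FAMEs
    molecular_weight: float | None = None  # g/mol
    double_bonds: int | None = None
    density_ref: float | None = None  # kg/m3 at 15 degC
    viscosity_ref: float | None = None  # mm2/s at 40 degC
    cetane_ref: float | None = None
    ref_source: str = "unset"

    def __post_init__(self) -> None:
        if self.mass_fraction < 0:
            raise ValueError(
                f"component {self.shorthand or self.name!r}: "
                f"negative mass fraction {self.mass_fraction}"
            )
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise ValueError(f"component {self.shorthand}: molecular_weight must be > 0")
        if self.double_bonds is not None and self.double_bonds < 0:
            raise ValueError(f"component {self.shorthand}: double_bonds must be >= 0")
        for attr in ("density_ref", "viscosity_ref", "cetane_ref"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValueError(f"component {self.shorthand}: {attr} must be positive")

    @property
    def is_standard(self) -> bool:
        """True for plain straight-chain esters (no substituent prefix)."""
        try:
            _, _, prefix = parse_shorthand(self.shorthand)
        except ValueError:
            return False
        return prefix == ""


@dataclass
class FAMEProfile:
    """Ordered FAME composition; fractions are percentages of the total."""

    components: list[FAMEComponent] = field(default_factory=list)
    normalized: bool = False
    original_sum: float | None = None
    exclusion_policy: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for i, comp in enumerate(self.components):
            key = _canonical(comp.shorthand)
            if key in seen:
                raise ValueError(
                    f"duplicate shorthand {key!r} in rows {seen[key]} and {i}"
                )
            seen[key] = i

    def total(self) -> float:
        return sum(c.mass_fraction for c in self.components)

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)


@dataclass
class FuelProperties:
    """The six predicted bulk fuel properties of a FAME mixture."""

    density: float  # kg/m3
    kinematic_viscosity: float  # mm2/s
    saponification_number: float  # mg KOH/g
    iodine_value: float  # g I2 / 100 g
    higher_heating_value: float  # MJ/kg
    cetane_number: float
    constants_record: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "density": self.density,
            "kinematic_viscosity": self.kinematic_viscosity,
            "saponification_number": self.saponification_number,
            "iodine_value": self.iodine_value,
            "higher_heating_value": self.higher_heating_value,
            "cetane_number": self.cetane_number,
        }


# ---------------------------------------------------------------------------
# parsing and normalization


_COLUMN_ALIASES = {
    "name": {"name", "fatty_acid_methyl_ester", "compound"},
    "shorthand": {"shorthand", "code", "carbon_double_bond", "cd"},
    "percent": {"percent", "pct", "mass_fraction", "percent_of_total", "area_percent"},
    "mw": {"mw", "molecular_weight"},
    "double_bonds": {"double_bonds", "d", "unsaturation"},
    "density": {"density", "density_ref", "density_15c"},
    "viscosity": {"viscosity", "viscosity_ref", "viscosity_40c"},
    "cetane": {"cetane", "cetane_ref", "cn"},
}


def _find_column(df: pd.DataFrame, key: str) -> str | None:
    aliases = _COLUMN_ALIASES[key]
    for col in df.columns:
        if str(col).strip().lower().replace(" ", "_") in aliases:
            return col
    return None


def parse_fame_table(source) -> FAMEProfile:
    """Read a delimited FAME composition table into a :class:`FAMEProfile`.

    ``source`` may be a path, an open text buffer, a CSV/TSV string, or a
    ``pandas.DataFrame``. The table needs a ``shorthand`` (or ``name``)
    column and a ``percent`` column; ``mw``, ``double_bonds``, ``density``,
    ``viscosity`` and ``cetane`` columns are optional overrides.

    Missing molecular weights and double-bond counts are filled from the
    shorthand: the formula weight of the straight-chain methyl ester.
    Substituted esters (prefixes like ``OH-``, ``br-``, ``ts-``) keep the
    homolog formula weight but are flagged (``ref_source="needs-mapping"``)
    for the inclusion policy to resolve.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        if isinstance(source, str) and ("\n" in source or "," in source or "\t" in source) \
                and not Path(source.split("\n")[0]).exists():
            source = io.StringIO(source)
        df = pd.read_csv(source, sep=None, engine="python", skip_blank_lines=True)

    if df.empty:
        return FAMEProfile(components=[], normalized=False)

    col_short = _find_column(df, "shorthand")
    col_name = _find_column(df, "name")
    col_pct = _find_column(df, "percent")
    if col_pct is None:
        raise ValueError(f"no percent column found among {list(df.columns)}")
    if col_short is None and col_name is None:
        raise ValueError("table needs a 'shorthand' or 'name' column")

    col_mw = _find_column(df, "mw")
    col_d = _find_column(df, "double_bonds")
    col_rho = _find_column(df, "density")
    col_nu = _find_column(df, "viscosity")
    col_cn = _find_column(df, "cetane")

    components: list[FAMEComponent] = []
    for idx, row in df.iterrows():
        pct = float(row[col_pct])
        if pct < 0:
            raise ValueError(f"row {idx}: negative mass fraction {pct}")
        shorthand = str(row[col_short]).strip() if col_short is not None else ""
        name = str(row[col_name]).strip() if col_name is not None else shorthand
        if not shorthand or shorthand.lower() in {"nan", "-", "—"}:
            raise ValueError(
                f"row {idx} ({name!r}): no carbon:double-bond shorthand; "
                "supply one (optionally prefixed, e.g. 'ts-C12:0') so the "
                "inclusion policy can act on it"
            )
        carbons, d, prefix = parse_shorthand(shorthand)
        mw = float(row[col_mw]) if col_mw is not None and pd.notna(row[col_mw]) else None
        if col_d is not None and pd.notna(row[col_d]):
            d = int(row[col_d])
        if mw is None:
            mw = methyl_ester_weight(carbons, d)
        rho = float(row[col_rho]) if col_rho is not None and pd.notna(row[col_rho]) else None
        nu = float(row[col_nu]) if col_nu is not None and pd.notna(row[col_nu]) else None
        cn = float(row[col_cn]) if col_cn is not None and pd.notna(row[col_cn]) else None
        if rho is not None or nu is not None or cn is not None:
            source = "user"
        elif prefix:
            source = "needs-mapping"
        else:
            source = "unset"
        components.append(
            FAMEComponent(
                name=name,
                shorthand=f"{prefix}C{carbons}:{d}",
                mass_fraction=pct,
                molecular_weight=mw,
                double_bonds=d,
                density_ref=rho,
                viscosity_ref=nu,
                cetane_ref=cn,
                ref_source=source,
            )
        )

    return FAMEProfile(components=components, normalized=False)


def normalize(profile: FAMEProfile) -> FAMEProfile:
    """Rescale mass fractions so they sum to exactly 100.

    The pre-normalization sum is recorded in ``original_sum``. Idempotent.
    """
    total = profile.total()
    if total <= 0:
        raise ValueError("cannot normalize: mass fractions sum to zero")
    if profile.normalized and abs(total - 100.0) <= 1e-9:
        return replace(profile, components=list(profile.components))
    scale = 100.0 / total
    comps = [replace(c, mass_fraction=c.mass_fraction * scale) for c in profile.components]
    return FAMEProfile(
        components=comps,
        normalized=True,
        original_sum=profile.original_sum if profile.normalized else total,
        exclusion_policy=list(profile.exclusion_policy),
    )


# ---------------------------------------------------------------------------
# reference-constant attachment and inclusion policy


def attach_reference_constants(profile: FAMEProfile, policy: str = "homolog") -> FAMEProfile:
    """Fill per-component reference constants from the embedded pure-ester table.

    policy:
        ``"homolog"``  — substituted esters take the constants of their
                         straight-chain homolog (same carbons and double
                         bonds; nearest chain length otherwise); mapping
                         recorded in ``ref_source`` and ``exclusion_policy``.
        ``"exclude"``  — components without a table entry are dropped and the
                         rest renormalized; drops are recorded.
        ``"strict"``   — any component without direct constants raises.

    User-supplied constants (from the input table) always win.
    """
    if policy not in {"homolog", "exclude", "strict"}:
        raise ValueError(f"unknown policy {policy!r}; use homolog, exclude or strict")
    table = _refdata.reference_table()
    notes = list(profile.exclusion_policy)
    comps: list[FAMEComponent] = []
    for comp in profile.components:
        carbons, d, prefix = parse_shorthand(comp.shorthand)
        if comp.molecular_weight is None:
            comp = replace(comp, molecular_weight=methyl_ester_weight(carbons, comp.double_bonds or d))
        if comp.double_bonds is None:
            comp = replace(comp, double_bonds=d)
        has_user = all(
            v is not None for v in (comp.density_ref, comp.viscosity_ref, comp.cetane_ref)
        )
        if has_user:
            comps.append(comp)
            continue
        direct = prefix == "" and (carbons, d) in table.index
        if direct:
            ref = table.loc[(carbons, d)]
            comps.append(
                replace(
                    comp,
                    density_ref=comp.density_ref or float(ref["density_15c"]),
                    viscosity_ref=comp.viscosity_ref or float(ref["viscosity_40c"]),
                    cetane_ref=comp.cetane_ref or float(ref["cetane"]),
                    ref_source=f"table:{ref['provenance']}",
                )
            )
            continue
        if policy == "strict":
            raise ValueError(
                f"component {comp.shorthand} ({comp.name!r}) has no reference "
                "constants under strict policy"
            )
        if policy == "exclude":
            notes.append(f"excluded {comp.shorthand} ({comp.name}): no reference entry")
            continue
        # homolog mapping: same double-bond count, nearest carbon number
        candidates = [(c, dd) for (c, dd) in table.index if dd == d]
        if not candidates:
            candidates = list(table.index)
        target = min(candidates, key=lambda cd: (abs(cd[0] - carbons), abs(cd[1] - d)))
        ref = table.loc[target]
        notes.append(
            f"homolog-mapped {comp.shorthand} ({comp.name}) -> C{target[0]}:{target[1]}"
        )
        comps.append(
            replace(
                comp,
                density_ref=comp.density_ref or float(ref["density_15c"]),
                viscosity_ref=comp.viscosity_ref or float(ref["viscosity_40c"]),
                cetane_ref=comp.cetane_ref or float(ref["cetane"]),
                ref_source=f"homolog:C{target[0]}:{target[1]}",
            )
        )
    out = FAMEProfile(
        components=comps,
        normalized=False,
        original_sum=profile.original_sum,
        exclusion_policy=notes,
    )
    return normalize(out)


def _prepared(profile: FAMEProfile, policy: str, need: str) -> FAMEProfile:
    """Normalize and, if any component lacks the needed constant, attach refs."""
    missing = any(getattr(c, need) is None for c in profile.components)
    if missing:
        profile = attach_reference_constants(profile, policy=policy)
        still = [c.shorthand for c in profile.components if getattr(c, need) is None]
        if still:
            raise ValueError(f"no {need} available for components {still}")
    if not profile.normalized or abs(profile.total() - 100.0) > 1e-9:
        profile = normalize(profile)
    return profile


# ---------------------------------------------------------------------------
# the six mixture properties


def mixture_density(profile: FAMEProfile, policy: str = "homolog") -> float:
    """Mass-fraction-weighted mixture density, kg/m3 at 15 degC."""
    p = _prepared(profile, policy, "density_ref")
    return sum(c.mass_fraction / 100.0 * c.density_ref for c in p)


def mixture_viscosity(
    profile: FAMEProfile, policy: str = "homolog", rule: str = "linear"
) -> float:
    """Mixture kinematic viscosity, mm2/s at 40 degC.

    ``rule="linear"`` is the plain abundance-weighted sum; ``rule="log"``
    weights log-viscosities (Grunberg--Nissan-style), which is the more
    common physical mixing rule for viscosity.
    """
    if rule not in {"linear", "log"}:
        raise ValueError(f"unknown mixing rule {rule!r}; use linear or log")
    p = _prepared(profile, policy, "viscosity_ref")
    if rule == "linear":
        return sum(c.mass_fraction / 100.0 * c.viscosity_ref for c in p)
    return math.exp(sum(c.mass_fraction / 100.0 * math.log(c.viscosity_ref) for c in p))


def saponification_number(
    profile: FAMEProfile, constant: float = SN_CONSTANT_DEFAULT, policy: str = "homolog"
) -> float:
    """SN = sum(constant * Ai / MWi), Ai in percent -> mg KOH/g for K=560."""
    p = _prepared(profile, policy, "molecular_weight")
    return sum(constant * c.mass_fraction / c.molecular_weight for c in p)


def iodine_value(profile: FAMEProfile, policy: str = "homolog") -> float:
    """IV = sum(254 * D * Ai / MWi) in g I2 / 100 g; saturated esters add zero."""
    p = _prepared(profile, policy, "molecular_weight")
    for c in p:
        if c.double_bonds is None:
            raise ValueError(f"component {c.shorthand} has no double-bond count")
    return sum(
        IV_CONSTANT * c.double_bonds * c.mass_fraction / c.molecular_weight for c in p
    )


def higher_heating_value(sn: float, iv: float) -> float:
    """HHV = 49.43 - (0.041*SN + 0.015*IV), MJ/kg."""
    if sn < 0 or iv < 0:
        raise ValueError("SN and IV must be non-negative")
    return 49.43 - (0.041 * sn + 0.015 * iv)


def cetane_number(profile: FAMEProfile, policy: str = "homolog") -> float:
    """CN = 1.068 * sum(CNi * Wi) - 6.747, Wi as fraction of 1."""
    p = _prepared(profile, policy, "cetane_ref")
    s = sum(c.mass_fraction / 100.0 * c.cetane_ref for c in p)
    return 1.068 * s - 6.747


def compute_fuel_properties(
    profile: FAMEProfile,
    sn_constant: float = SN_CONSTANT_DEFAULT,
    mixing: str = "linear",
    policy: str = "homolog",
) -> FuelProperties:
    """Evaluate all six fuel properties of a FAME profile in one pass."""
    prepared = attach_reference_constants(profile, policy=policy)
    sn = saponification_number(prepared, constant=sn_constant, policy=policy)
    iv = iodine_value(prepared, policy=policy)
    return FuelProperties(
        density=mixture_density(prepared, policy=policy),
        kinematic_viscosity=mixture_viscosity(prepared, policy=policy, rule=mixing),
        saponification_number=sn,
        iodine_value=iv,
        higher_heating_value=higher_heating_value(sn, iv),
        cetane_number=cetane_number(prepared, policy=policy),
        constants_record={
            "sn_constant": sn_constant,
            "viscosity_mixing_rule": mixing,
            "inclusion_policy": policy,
            "exclusions_and_mappings": list(prepared.exclusion_policy),
            "original_percent_sum": prepared.original_sum,
        },
    )


# ---------------------------------------------------------------------------
# standards compliance


@dataclass
class StandardSpec:
    """Per-property limit intervals of a biodiesel quality standard."""

    standard_name: str
    limits: dict[str, tuple[float | None, float | None]]

    def __post_init__(self) -> None:
        for prop, (lo, hi) in self.limits.items():
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"{self.standard_name}/{prop}: lower {lo} > upper {hi}")


_STANDARDS = {
    "EN14214": StandardSpec(
        "EN 14214",
        {
            "density": (860.0, 900.0),
            "kinematic_viscosity": (3.5, 5.0),
            "cetane_number": (51.0, None),
            "iodine_value": (None, 120.0),
        },
    ),
    "ASTMD6751": StandardSpec(
        "ASTM D6751",
        {
            "kinematic_viscosity": (1.9, 6.0),
            "cetane_number": (47.0, None),
        },
    ),
}


def get_standard(name: str) -> StandardSpec:
    """Look up a built-in standard by name (punctuation/space-insensitive)."""
    key = re.sub(r"[\s\-_.]", "", name).upper()
    if key not in _STANDARDS:
        raise ValueError(
            f"unknown standard {name!r}; supported: "
            + ", ".join(s.standard_name for s in _STANDARDS.values())
        )
    return _STANDARDS[key]


@dataclass
class ComplianceReport:
    """Pass/fail verdicts of a property vector against one standard."""

    standard_name: str
    verdicts: dict[str, str]  # pass | fail | not-limited
    margins: dict[str, float | None]  # signed distance to the nearest limit
    overall_pass: bool

    def as_dict(self) -> dict:
        return {
            "standard": self.standard_name,
            "verdicts": dict(self.verdicts),
            "margins": dict(self.margins),
            "overall_pass": self.overall_pass,
        }


def check_compliance(props: FuelProperties, spec: StandardSpec | str) -> ComplianceReport:
    """Compare each fuel property against a standard's limit intervals.

    Properties the standard does not limit are marked ``"not-limited"``.
    The margin is the signed distance to the nearest limit: positive inside
    the allowed interval, negative outside. Overall pass holds iff every
    limited property passes.
    """
    if isinstance(spec, str):
        spec = get_standard(spec)
    values = props.as_dict()
    verdicts: dict[str, str] = {}
    margins: dict[str, float | None] = {}
    for prop, value in values.items():
        if prop not in spec.limits:
            verdicts[prop] = "not-limited"
            margins[prop] = None
            continue
        lo, hi = spec.limits[prop]
        dists = []
        if lo is not None:
            dists.append(value - lo)
        if hi is not None:
            dists.append(hi - value)
        margin = min(dists)
        verdicts[prop] = "pass" if margin >= 0 else "fail"
        margins[prop] = margin
    overall = all(v != "fail" for v in verdicts.values())
    return ComplianceReport(
        standard_name=spec.standard_name,
        verdicts=verdicts,
        margins=margins,
        overall_pass=overall,
    )
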