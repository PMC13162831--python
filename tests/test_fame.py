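"""FAME parsing, normalization, mixture fuel properties and compliance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycorefinery.fame import (
    FAMEComponent,
    FAMEProfile,
    FuelProperties,
    attach_reference_constants,
    cetane_number,
    check_compliance,
    compute_fuel_properties,
    get_standard,
    higher_heating_value,
    iodine_value,
    methyl_ester_weight,
    mixture_density,
    mixture_viscosity,
    normalize,
    parse_fame_table,
    parse_shorthand,
    saponification_number,
)

# ---------------------------------------------------------------------------
# parsing


def test_parse_row_with_name_shorthand_percent():
    profile = parse_fame_table(
        "name,shorthand,percent\nMethyl palmitate,C16:0,20.156\n"
    )
    (comp,) = profile.components
    assert comp.double_bonds == 0
    assert comp.mass_fraction == 20.156
    assert comp.molecular_weight == pytest.approx(270.45, abs=0.02)


def test_parse_empty_table_gives_empty_unnormalized_profile():
    profile = parse_fame_table("name,shorthand,percent\n")
    assert len(profile) == 0
    assert profile.normalized is False


def test_parse_fills_molecular_weight_from_formula():
    profile = parse_fame_table("shorthand,percent\nC18:2,18.107\n")
    (comp,) = profile.components
    # methyl linoleate C19H34O2
    assert comp.molecular_weight == pytest.approx(294.47, abs=0.02)
    assert comp.double_bonds == 2


def test_parse_rejects_negative_fraction_with_row_diagnostic():
    with pytest.raises(ValueError, match="row.*negative"):
        parse_fame_table("shorthand,percent\nC16:0,-1.0\n")


def test_parse_rejects_duplicate_shorthand_naming_both_rows():
    with pytest.raises(ValueError, match="duplicate.*C16:0.*0.*1"):
        parse_fame_table("shorthand,percent\nC16:0,10\nc16:0,20\n")


def test_substituted_esters_flagged_for_mapping():
    profile = parse_fame_table("shorthand,percent\nOH-C16:0,4.645\n")
    (comp,) = profile.components
    assert not comp.is_standard
    assert comp.ref_source == "needs-mapping"


@pytest.mark.parametrize(
    "code,expected",
    [("C18:1", (18, 1, "")), ("br-C17:0", (17, 0, "br-")), ("OH-C16:0", (16, 0, "OH-"))],
)
def test_shorthand_parsing(code, expected):
    assert parse_shorthand(code) == expected


# ---------------------------------------------------------------------------
# normalization


def _profile(fractions, **kw):
    comps = [
        FAMEComponent(
            name=f"c{i}", shorthand=f"C{12 + 2 * i}:0", mass_fraction=f,
            molecular_weight=methyl_ester_weight(12 + 2 * i), double_bonds=0, **kw
        )
        for i, f in enumerate(fractions)
    ]
    return FAMEProfile(components=comps)


def test_normalize_leaves_already_normalized_unchanged():
    p = normalize(_profile([50, 50]))
    assert [c.mass_fraction for c in p] == [50, 50]


def test_normalize_uniform_rescale():
    p = normalize(_profile([2, 2]))
    assert [c.mass_fraction for c in p] == [50, 50]


def test_normalize_study_table_scales_by_measured_sum(study_profile):
    assert study_profile.total() == pytest.approx(100.007, abs=1e-9)
    p = normalize(study_profile)
    assert p.total() == pytest.approx(100.0, abs=1e-9)
    scale = 100.0 / 100.007
    assert p.components[0].mass_fraction == pytest.approx(8.497 * scale, rel=1e-12)
    assert p.original_sum == pytest.approx(100.007)


def test_normalize_idempotent():
    p = _profile([3, 7, 11])
    once = normalize(p)
    twice = normalize(once)
    assert [c.mass_fraction for c in twice] == [c.mass_fraction for c in once]
    assert twice.original_sum == once.original_sum


def test_normalize_rejects_all_zero():
    with pytest.raises(ValueError, match="zero"):
        normalize(_profile([0, 0]))


# ---------------------------------------------------------------------------
# single-component closed forms


def _single(rho=864.0, nu=4.38, cn=85.9, mw=270.457, d=0, pct=100.0):
    return FAMEProfile(
        components=[
            FAMEComponent(
                name="x", shorthand="C16:0" if d == 0 else "C18:1",
                mass_fraction=pct, molecular_weight=mw, double_bonds=d,
                density_ref=rho, viscosity_ref=nu, cetane_ref=cn,
            )
        ]
    )


def test_single_component_density_is_pure_value():
    assert mixture_density(_single(rho=864.0)) == pytest.approx(864.0)


def test_two_component_density_midpoint():
    p = FAMEProfile(
        components=[
            FAMEComponent("a", "C16:0", 50, 270.457, 0, density_ref=860.0),
            FAMEComponent("b", "C18:0", 50, 298.511, 0, density_ref=880.0),
        ]
    )
    assert mixture_density(p) == pytest.approx(870.0)


def test_single_component_viscosity_is_pure_value():
    assert mixture_viscosity(_single(nu=4.38)) == pytest.approx(4.38)


def test_two_component_viscosity_linear_midpoint():
    p = FAMEProfile(
        components=[
            FAMEComponent("a", "C16:0", 50, 270.457, 0, viscosity_ref=3.0),
            FAMEComponent("b", "C18:0", 50, 298.511, 0, viscosity_ref=5.0),
        ]
    )
    assert mixture_viscosity(p, rule="linear") == pytest.approx(4.0)
    # log rule gives the geometric mean instead
    assert mixture_viscosity(p, rule="log") == pytest.approx(math.sqrt(15.0))


def test_saponification_number_single_term_both_constants():
    pure_palmitate = _single(mw=270.45)
    assert saponification_number(pure_palmitate, constant=560) == pytest.approx(
        560 * 100 / 270.45, abs=1e-9
    )
    assert saponification_number(pure_palmitate, constant=560) == pytest.approx(207.06, abs=0.01)
    assert saponification_number(pure_palmitate, constant=254) == pytest.approx(93.92, abs=0.01)


def test_iodine_value_zero_for_saturated():
    assert iodine_value(_single(d=0)) == 0.0


def test_iodine_value_pure_methyl_oleate():
    assert iodine_value(_single(mw=296.49, d=1)) == pytest.approx(85.67, abs=0.01)


@pytest.mark.parametrize(
    "sn,iv,expected",
    [(0, 0, 49.43), (203.65, 61.18, 40.16), (100, 100, 43.83)],
)
def test_higher_heating_value(sn, iv, expected):
    assert higher_heating_value(sn, iv) == pytest.approx(expected, abs=0.005)


def test_cetane_number_affine_in_single_component():
    assert cetane_number(_single(cn=100.0)) == pytest.approx(1.068 * 100 - 6.747)
    assert cetane_number(_single(cn=100.0)) == pytest.approx(100.05, abs=0.005)
    # the root of the affine form
    assert cetane_number(_single(cn=6.318)) == pytest.approx(0.0, abs=1e-3)


# ---------------------------------------------------------------------------
# inclusion policy


def test_strict_policy_raises_on_substituted_component():
    profile = parse_fame_table("shorthand,percent\nC16:0,90\nOH-C16:0,10\n")
    with pytest.raises(ValueError, match="OH-C16:0"):
        mixture_density(profile, policy="strict")


def test_exclude_policy_drops_and_renormalizes():
    profile = parse_fame_table("shorthand,percent\nC16:0,90\nOH-C16:0,10\n")
    out = attach_reference_constants(profile, policy="exclude")
    assert len(out) == 1
    assert out.components[0].mass_fraction == pytest.approx(100.0)
    assert any("excluded" in note for note in out.exclusion_policy)


def test_homolog_policy_maps_and_records():
    profile = parse_fame_table("shorthand,percent\nC16:0,90\nOH-C16:0,10\n")
    out = attach_reference_constants(profile, policy="homolog")
    assert len(out) == 2
    mapped = [c for c in out if c.ref_source.startswith("homolog")][0]
    direct = [c for c in out if c.ref_source.startswith("table")][0]
    assert mapped.density_ref == direct.density_ref


# ---------------------------------------------------------------------------
# oracle equivalence / invariance properties


def _random_profile(rng, n=None):
    table_rows = [
        ("C12:0", 214.349, 0, 873.0, 2.43, 66.7),
        ("C14:0", 242.403, 0, 870.0, 3.30, 66.2),
        ("C16:0", 270.457, 0, 867.0, 4.38, 85.9),
        ("C16:1", 268.441, 1, 876.4, 3.67, 51.0),
        ("C18:0", 298.511, 0, 864.0, 5.85, 101.0),
        ("C18:1", 296.495, 1, 873.9, 4.51, 59.3),
        ("C18:2", 294.479, 2, 888.5, 3.65, 38.2),
        ("C18:3", 292.463, 3, 900.5, 3.14, 22.7),
    ]
    n = n or rng.integers(3, 9)
    picks = rng.choice(len(table_rows), size=n, replace=False)
    fracs = rng.dirichlet(np.ones(n)) * 100
    comps = [
        FAMEComponent(
            name=sh, shorthand=sh, mass_fraction=float(f), molecular_weight=mw,
            double_bonds=d, density_ref=rho, viscosity_ref=nu, cetane_ref=cn,
        )
        for (sh, mw, d, rho, nu, cn), f in
        ((table_rows[i], fracs[j]) for j, i in enumerate(picks))
    ]
    return FAMEProfile(components=comps)


def _brute_force(profile):
    """Independent re-summation of all six properties with plain loops."""
    total = sum(c.mass_fraction for c in profile.components)
    rho = nu = cns = sn = iv = 0.0
    for c in profile.components:
        w = c.mass_fraction / total
        rho += w * c.density_ref
        nu += w * c.viscosity_ref
        cns += w * c.cetane_ref
        sn += 560.0 * (100.0 * w) / c.molecular_weight
        iv += 254.0 * c.double_bonds * (100.0 * w) / c.molecular_weight
    return {
        "density": rho,
        "kinematic_viscosity": nu,
        "saponification_number": sn,
        "iodine_value": iv,
        "higher_heating_value": 49.43 - 0.041 * sn - 0.015 * iv,
        "cetane_number": 1.068 * cns - 6.747,
    }


def test_mixture_properties_match_brute_force_resummation():
    rng = np.random.default_rng(20260927)
    for _ in range(200):
        profile = _random_profile(rng)
        expected = _brute_force(profile)
        got = compute_fuel_properties(profile).as_dict()
        for key, val in expected.items():
            assert got[key] == pytest.approx(val, rel=1e-12), key


def test_properties_invariant_under_component_permutation():
    rng = np.random.default_rng(42)
    for _ in range(50):
        profile = _random_profile(rng)
        shuffled = FAMEProfile(
            components=[profile.components[i]
                        for i in rng.permutation(len(profile.components))]
        )
        a = compute_fuel_properties(profile).as_dict()
        b = compute_fuel_properties(shuffled).as_dict()
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-12)


def test_hhv_strictly_decreasing_in_sn_and_iv():
    base = higher_heating_value(200, 60)
    assert higher_heating_value(201, 60) < base
    assert higher_heating_value(200, 61) < base


def test_iv_strictly_increases_with_double_bonds():
    lo = iodine_value(_single(mw=296.49, d=1))
    hi = iodine_value(
        FAMEProfile(components=[
            FAMEComponent("x", "C18:2", 100, 296.49, 2,
                          density_ref=888.5, viscosity_ref=3.65, cetane_ref=38.2)
        ])
    )
    assert hi > lo


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    fracs=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=8),
)
def test_normalize_idempotence_property(fracs):
    p = _profile(fracs[:8])
    once = normalize(p)
    twice = normalize(once)
    assert once.total() == pytest.approx(100.0, abs=1e-9)
    for a, b in zip(once.components, twice.components):
        assert a.mass_fraction == pytest.approx(b.mass_fraction, rel=1e-15)


# ---------------------------------------------------------------------------
# compliance


def _printed_props():
    return FuelProperties(
        density=873.8, kinematic_viscosity=4.11, saponification_number=203.65,
        iodine_value=61.18, higher_heating_value=40.16, cetane_number=60.3,
    )


def test_printed_vector_meets_en14214_on_limited_properties():
    report = check_compliance(_printed_props(), "EN 14214")
    for prop in ("density", "kinematic_viscosity", "cetane_number", "iodine_value"):
        assert report.verdicts[prop] == "pass"
    assert report.overall_pass


def test_printed_vector_astm_viscosity_cn_pass_density_not_limited():
    report = check_compliance(_printed_props(), "ASTM D6751")
    assert report.verdicts["kinematic_viscosity"] == "pass"
    assert report.verdicts["cetane_number"] == "pass"
    assert report.verdicts["density"] == "not-limited"


def test_density_just_below_limit_fails_with_margin():
    props = _printed_props()
    props.density = 859.9
    report = check_compliance(props, "EN14214")
    assert report.verdicts["density"] == "fail"
    assert report.margins["density"] == pytest.approx(-0.1)


def test_unknown_standard_lists_supported_names():
    with pytest.raises(ValueError, match="EN 14214.*ASTM D6751"):
        get_standard("EN 590")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    rho=st.floats(800, 950), nu=st.floats(1, 8), cn=st.floats(30, 110),
    iv=st.floats(0, 200),
)
def test_overall_pass_iff_every_limited_property_passes(rho, nu, cn, iv):
    props = FuelProperties(
        density=rho, kinematic_viscosity=nu, saponification_number=200.0,
        iodine_value=iv, higher_heating_value=40.0, cetane_number=cn,
    )
    report = check_compliance(props, "EN 14214")
    expected = all(v == "pass" for v in report.verdicts.values() if v != "not-limited")
    assert report.overall_pass == expected
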