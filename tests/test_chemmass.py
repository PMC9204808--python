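"""Exact-mass chemistry: formula algebra, adduct/fragment m/z, isotope
patterns and formula enumeration, each checked against an independent
oracle (published atomic masses, brute-force isotopologue expansion,
naive nested-loop enumeration, and rdkit's periodic table)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coformscreen.chemmass import (
    ADDUCTS,
    DEFAULT_ELEMENT_BOUNDS,
    ELECTRON_MASS,
    ISOTOPES,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    ElementalFormula,
    FormulaError,
    TheoreticalFragment,
    adduct_mz,
    enumerate_formulas,
    fragment_cation_mz,
    isotope_pattern_bruteforce,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    rdbe,
    simulate_isotope_pattern,
)

# -- formula parsing --------------------------------------------------------


@pytest.mark.parametrize("text,counts", [
    ("C4H4ClNOS", {"C": 4, "H": 4, "Cl": 1, "N": 1, "O": 1, "S": 1}),
    ("H2O", {"H": 2, "O": 1}),
    ("C21H42O4", {"C": 21, "H": 42, "O": 4}),
    ("CH4", {"C": 1, "H": 4}),
    ("C2H4OC2H4O", {"C": 4, "H": 8, "O": 2}),  # repeated tokens accumulate
])
def test_parse_formula(text, counts):
    assert parse_formula(text).counts == counts


def test_parse_roundtrip_and_equality():
    f = parse_formula("C4H4ClNOS")
    assert parse_formula(f.hill()) == f
    assert parse_formula("ClSNOC4H4") == f  # order-independent equality


@pytest.mark.parametrize("bad", ["", "C4Xx2", "4CH", "c4h4"])
def test_parse_errors(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.dictionaries(
    st.sampled_from(["C", "H", "N", "O", "P", "S", "Cl", "Na"]),
    st.integers(min_value=1, max_value=60), min_size=1, max_size=6))
def test_parse_serialize_roundtrip_property(counts):
    f = ElementalFormula(counts)
    assert parse_formula(f.hill()) == f


# -- masses -----------------------------------------------------------------


def test_monoisotopic_mass_water_independent_sum():
    # independent sum of published atomic masses
    assert monoisotopic_mass(parse_formula("H2O")) == pytest.approx(
        2 * 1.00782503 + 15.99491462, abs=1e-5)


def test_monoisotopic_mass_empty_formula():
    assert monoisotopic_mass(ElementalFormula({})) == 0.0


def test_monoisotopic_mass_mci():
    assert monoisotopic_mass(parse_formula("C4H4ClNOS")) == pytest.approx(
        148.97021, abs=1e-5)


def test_atomic_masses_against_rdkit():
    """Our shipped table must agree with rdkit's periodic table to 1e-5 Da."""
    rdchem = pytest.importorskip("rdkit.Chem")
    pt = rdchem.GetPeriodicTable()
    for el, mass in MONOISOTOPIC_MASS.items():
        assert mass == pytest.approx(pt.GetMostCommonIsotopeMass(el), abs=1e-5), el


# -- adducts and fragments --------------------------------------------------

#: every theoretical m/z printed for the validated compounds, +-1e-4 Da
PRINTED_MZ = {
    ("C4H4ClNOS", "[M+H]+"): 149.97749,
    ("C16H33NO3", "[M+H]+"): 288.25332,
}
PRINTED_FRAGMENTS = {
    "C14H28NO": 226.21654,
    "C4H12NO2": 106.08626,
    "C21H41O3": 341.30502,   # [M+H-H2O]+ of glyceryl monostearate
    "C18H37O2": 285.27881,   # protonated stearic acid
    "C18H35O": 267.26824,
    "C18H33": 249.25768,
    "C12H21": 165.16378,
    "C6H13": 85.10118,
}


@pytest.mark.parametrize("formula,adduct", sorted(PRINTED_MZ))
def test_adduct_mz_anchors(formula, adduct):
    assert adduct_mz(parse_formula(formula), adduct) == pytest.approx(
        PRINTED_MZ[(formula, adduct)], abs=1e-4)


@pytest.mark.parametrize("cation", sorted(PRINTED_FRAGMENTS))
def test_fragment_cation_mz_anchors(cation):
    assert fragment_cation_mz(parse_formula(cation)) == pytest.approx(
        PRINTED_FRAGMENTS[cation], abs=1e-4)


def test_adduct_shift_symmetry(mci_formula):
    delta = adduct_mz(mci_formula, "[M+H]+") - adduct_mz(mci_formula, "[M-H]-")
    assert delta == pytest.approx(2 * PROTON_MASS, abs=2e-5)  # 5-decimal reporting
    assert ADDUCTS["[M+H]+"].mass_shift == -ADDUCTS["[M-H]-"].mass_shift


def test_fragment_consistent_with_protonated_adduct(mci_formula):
    # cation of atoms M+H equals [M+H]+: the proton convention nets the electron
    mh = mci_formula + parse_formula("H")
    assert fragment_cation_mz(mh) == adduct_mz(mci_formula, "[M+H]+")


def test_sodium_adduct_shift():
    # Na minus one electron: 22.98976928 - 0.00054858
    assert ADDUCTS["[M+Na]+"].mass_shift == pytest.approx(22.98922070, abs=1e-7)


def test_unknown_adduct_rejected(mci_formula):
    with pytest.raises(KeyError):
        adduct_mz(mci_formula, "[M+K]+")


def test_theoretical_fragment_invariant():
    frag = TheoreticalFragment.from_formula("C18H35O")
    assert frag.expected_mz == pytest.approx(
        monoisotopic_mass(frag.cation_formula) - ELECTRON_MASS, abs=1e-5)
    with pytest.raises(ValueError):
        TheoreticalFragment(parse_formula("C18H35O"), 267.3)


# -- ppm error --------------------------------------------------------------


def test_ppm_error_rounded_and_unrounded_conventions(mci_formula):
    theo_unrounded = monoisotopic_mass(mci_formula) + PROTON_MASS
    assert round(ppm_error(149.97716, theo_unrounded, rounded=True), 2) == -2.20
    assert round(ppm_error(149.97716, theo_unrounded, rounded=False), 2) == -2.19


def test_ppm_error_zero_and_sign():
    assert ppm_error(200.0, 200.0) == 0.0
    with pytest.raises(ValueError):
        ppm_error(100.0, 0.0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.floats(50, 750), st.floats(50, 750))
def test_ppm_error_antisymmetry_identity(a, b):
    # ppm(a,b) = -ppm(b,a) * a/b, exact algebraic identity
    lhs = ppm_error(a, b, rounded=False)
    rhs = -ppm_error(b, a, rounded=False) * a / b
    assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


# -- isotope patterns -------------------------------------------------------


def test_mci_m2_ratio_matches_chlorine_plus_sulfur(mci_formula):
    pat = simulate_isotope_pattern(mci_formula, "[M+H]+", min_rel=5.0)
    m2 = pat.relative_at(pat.base_mz + 1.99705, tol_da=0.05)
    assert 33.0 <= m2 <= 39.0


def test_single_carbon_m1_abundance():
    pat = simulate_isotope_pattern(parse_formula("C"), "[M+H]+", min_rel=0.1)
    m1 = pat.relative_at(pat.base_mz + 1.00336, tol_da=0.05)
    assert m1 == pytest.approx(100 * 0.0107 / 0.9893, rel=0.02)


@pytest.mark.parametrize("formula", ["C10H22O3", "C12H24O2", "C8H11N"])
def test_no_halogen_no_m2(formula):
    # without Cl/Br/S, M+2 stays tiny for small CHNO formulas
    pat = simulate_isotope_pattern(parse_formula(formula), "[M+H]+", min_rel=0.01)
    m2 = pat.relative_at(pat.base_mz + 2.0, tol_da=0.1)
    assert m2 < 2.0


@pytest.mark.parametrize("formula", ["C4H4ClNOS", "C6H5N", "C2H4OS2", "C7H5NOS"])
def test_fast_pattern_matches_bruteforce(formula):
    """Aggregated convolution vs explicit multinomial enumeration, 0.5% abs."""
    f = parse_formula(formula)
    assert f.n_atoms <= 30
    fast = simulate_isotope_pattern(f, "[M+H]+", min_rel=0.5)
    slow = isotope_pattern_bruteforce(f, "[M+H]+", min_rel=0.5)
    for mz, rel in slow.peaks:
        assert fast.relative_at(mz, 0.02) == pytest.approx(rel, abs=0.5)
    for mz, rel in fast.peaks:
        assert slow.relative_at(mz, 0.02) == pytest.approx(rel, abs=0.5)


def test_pattern_invariants(mci_formula):
    pat = simulate_isotope_pattern(mci_formula, "[M+H]+", min_rel=1.0)
    mzs = [p[0] for p in pat.peaks]
    rels = [p[1] for p in pat.peaks]
    assert mzs == sorted(mzs)
    assert sum(1 for r in rels if r == 100.0) == 1
    assert all(0 < r <= 100 for r in rels)


# -- formula enumeration ----------------------------------------------------


def _naive_enumeration(mz, adduct, tol_ppm, bounds):
    """Nested-loop oracle over explicit count ranges."""
    target = mz - ADDUCTS[adduct].mass_shift
    tol_da = mz * tol_ppm * 1e-6
    elements = sorted(bounds)
    out = set()
    ranges = [range(bounds[el][0], bounds[el][1] + 1) for el in elements]
    for combo in itertools.product(*ranges):
        counts = {el: n for el, n in zip(elements, combo) if n}
        if not counts:
            continue
        mass = sum(n * MONOISOTOPIC_MASS[el] for el, n in counts.items())
        if abs(mass - target) > tol_da:
            continue
        f = ElementalFormula(counts)
        if rdbe(f) < -1e-9:
            continue
        c = f["C"]
        if c > 0 and not (0.1 <= f["H"] / c <= 4.0):
            continue
        out.add(f)
    return out


SMALL_BOUNDS = {"C": (0, 8), "H": (0, 16), "N": (0, 2), "O": (0, 3),
                "S": (0, 1), "Cl": (0, 1)}


@pytest.mark.parametrize("mz", [149.97749, 119.10666, 101.0597])
def test_enumeration_equals_naive_oracle(mz):
    fast = set(enumerate_formulas(mz, "[M+H]+", 5.0, SMALL_BOUNDS))
    slow = _naive_enumeration(mz, "[M+H]+", 5.0, SMALL_BOUNDS)
    assert fast == slow


def test_enumeration_contains_planted_formula():
    bounds = dict(DEFAULT_ELEMENT_BOUNDS, Cl=(0, 3))
    cands = enumerate_formulas(149.97749, "[M+H]+", 5.0, bounds)
    assert parse_formula("C4H4ClNOS") in cands
    # sorted by |ppm error|: the exact-match formula comes first
    assert cands[0] == parse_formula("C4H4ClNOS")


def test_enumeration_monotone_in_tolerance():
    prev = set()
    for tol in (0.5, 2.0, 5.0, 10.0):
        cur = set(enumerate_formulas(288.25332, "[M+H]+", tol, SMALL_BOUNDS))
        assert prev <= cur
        prev = cur


def test_enumeration_zero_tolerance_and_empty_bounds():
    assert enumerate_formulas(288.25332, "[M+H]+", 0.0, SMALL_BOUNDS) in ([],
        [parse_formula("C16H33NO3")])
    with pytest.raises(ValueError):
        enumerate_formulas(288.25332, "[M+H]+", 5.0, {})
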