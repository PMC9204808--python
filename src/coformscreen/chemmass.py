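"""Exact-mass chemistry core.

Formula algebra, adduct and fragment-cation m/z, ppm mass error,
isotope-pattern simulation and accurate-mass formula enumeration for
small-molecule electrospray work (singly charged ions only).

All masses are monoisotopic and in Da. m/z values are conventionally
reported to five decimals, which matches the precision of a Q-Orbitrap
operated at R = 70,000.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "ISOTOPES",
    "ADDUCTS",
    "ElementalFormula",
    "AdductSpec",
    "IsotopePattern",
    "TheoreticalFragment",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "fragment_cation_mz",
    "ppm_error",
    "simulate_isotope_pattern",
    "isotope_pattern_bruteforce",
    "enumerate_formulas",
    "DEFAULT_ELEMENT_BOUNDS",
]

# ---------------------------------------------------------------------------
# Physical constants and atomic data (CODATA 2018 / IUPAC 2021)
# ---------------------------------------------------------------------------

#: Mass of the proton in Da — the shift of an [M+H]+ adduct (electron already
#: netted out: m(H) - m(e) = 1.00782503 - 0.00054858).
PROTON_MASS = 1.00727646

#: Electron rest mass in Da, subtracted for even-electron fragment cations.
ELECTRON_MASS = 0.00054858

#: Isotope table: element -> tuple of (isotope mass / Da, fractional abundance),
#: lightest first. Abundances are IUPAC representative values.
ISOTOPES: Dict[str, Tuple[Tuple[float, float], ...]] = {
    "H": ((1.0078250319, 0.999885), (2.0141017781, 0.000115)),
    "C": ((12.0, 0.9893), (13.0033548351, 0.0107)),
    "N": ((14.0030740052, 0.99636), (15.0001088989, 0.00364)),
    "O": ((15.9949146221, 0.99757), (16.9991315650, 0.00038), (17.9991604, 0.00205)),
    "P": ((30.97376151, 1.0),),
    "S": (
        (31.97207069, 0.9499),
        (32.97145850, 0.0075),
        (33.96786683, 0.0425),
        (35.96708088, 0.0001),
    ),
    "Cl": ((34.96885271, 0.7576), (36.96590260, 0.2424)),
    "Br": ((78.9183376, 0.5069), (80.9162906, 0.4931)),
    "Na": ((22.98976928, 1.0),),
    "K": ((38.9637064864, 0.932581), (39.963998166, 0.000117), (40.9618252579, 0.067302)),
    "F": ((18.9984031627, 1.0),),
    "Si": ((27.9769265347, 0.92223), (28.9764946649, 0.04685), (29.9737701, 0.03092)),
    "I": ((126.9044719, 1.0),),
}

#: Monoisotopic (lightest-isotope) masses derived from :data:`ISOTOPES`.
MONOISOTOPIC_MASS: Dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


# ---------------------------------------------------------------------------
# ElementalFormula
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map; the unit of all mass arithmetic.

    Equality is count-map equality, independent of textual element order.
    Zero counts are dropped on construction so C1H4O0 == CH4.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", dict(clean))

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __iter__(self):
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementalFormula):
            return self.counts == other.counts
        return NotImplemented

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(f"subtraction yields negative count for {el}")
        return ElementalFormula(merged)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def hill(self) -> str:
        """Serialize in Hill order (C, H, then alphabetical)."""
        parts = []
        rest = dict(self.counts)
        for el in ("C", "H"):
            if el in rest:
                n = rest.pop(el)
                parts.append(el + (str(n) if n != 1 else ""))
        for el in sorted(rest):
            n = rest[el]
            parts.append(el + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string like ``"C4H4ClNOS"``.

    Multi-letter element symbols and repeated element tokens
    (counts accumulate) are supported.

    Raises
    ------
    FormulaError
        On unknown element symbols or malformed tokens, naming the offender.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula at {text[pos:]!r} in {text!r}")
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            # try splitting a greedy two-letter match such as "Nb" -> "N" + "b"?
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Sum of count x lightest-isotope mass over all elements, in Da."""
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in f.counts.items())


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged ESI adduct: name, signed charge and mass shift in Da."""

    name: str
    charge: int
    mass_shift: float

    def __post_init__(self) -> None:
        if abs(self.charge) != 1:
            raise ValueError("only singly charged adducts are supported")


_NA_MINUS_ELECTRON = MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS  # 22.98922070

#: Adduct registry. Extensible: callers may register additional entries.
ADDUCTS: Dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", +1, PROTON_MASS),
    "[M-H]-": AdductSpec("[M-H]-", -1, -PROTON_MASS),
    "[M+Na]+": AdductSpec("[M+Na]+", +1, _NA_MINUS_ELECTRON),
}
# unicode-minus alias, as printed in some sources
ADDUCTS["[M−H]-"] = ADDUCTS["[M-H]-"]


def _resolve_adduct(a) -> AdductSpec:
    if isinstance(a, AdductSpec):
        return a
    try:
        return ADDUCTS[a]
    except KeyError:
        raise KeyError(f"unsupported adduct name: {a!r}; known: {sorted(set(ADDUCTS))}")


def adduct_mz(f: ElementalFormula, adduct="[M+H]+", *, ndigits: int = 5) -> float:
    """Theoretical m/z of a singly charged adduct ion, reported to 5 decimals."""
    a = _resolve_adduct(adduct)
    return round(monoisotopic_mass(f) + a.mass_shift, ndigits)


def fragment_cation_mz(cation: ElementalFormula, *, ndigits: int = 5) -> float:
    """m/z of an even-electron fragment cation: atoms minus one electron mass.

    For a cation whose atoms are M+H this equals ``adduct_mz(M, "[M+H]+")``,
    because the proton-mass convention already nets out the electron.
    """
    return round(monoisotopic_mass(cation) - ELECTRON_MASS, ndigits)


def ppm_error(observed: float, theoretical: float, *, rounded: bool = True) -> float:
    """Signed mass error in ppm: (observed - theoretical) / theoretical x 1e6.

    With ``rounded=True`` (default) the theoretical m/z is first rounded to
    five decimals, the convention used when errors are quoted against
    5-decimal printed reference values; ``rounded=False`` uses it as given.
    """
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    t = round(theoretical, 5) if rounded else theoretical
    return (observed - t) / t * 1e6


# ---------------------------------------------------------------------------
# Isotope patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotopologue pattern: (m/z, relative abundance %) peaks.

    The base peak has abundance 100; peaks are sorted by increasing m/z.
    """

    peaks: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        mzs = [p[0] for p in self.peaks]
        if mzs != sorted(mzs) or len(set(mzs)) != len(mzs):
            raise ValueError("isotope pattern m/z must be strictly increasing")
        rels = [p[1] for p in self.peaks]
        if any(r <= 0 or r > 100 for r in rels):
            raise ValueError("relative abundances must lie in (0, 100]")
        if sum(1 for r in rels if abs(r - 100.0) < 1e-9) != 1:
            raise ValueError("exactly one base peak at 100%")

    @property
    def base_mz(self) -> float:
        return max(self.peaks, key=lambda p: p[1])[0]

    def relative_at(self, mz: float, tol_da: float = 0.02) -> float:
        """Relative abundance of the peak nearest ``mz`` within ``tol_da``, or 0."""
        best = 0.0
        for pmz, rel in self.peaks:
            if abs(pmz - mz) <= tol_da:
                best = max(best, rel)
        return best


def _element_distribution(el: str, n: int, prune: float) -> List[Tuple[float, float]]:
    """Isotopologue distribution of n atoms of one element by repeated convolution."""
    base = list(ISOTOPES[el])
    dist: List[Tuple[float, float]] = [(0.0, 1.0)]
    for _ in range(n):
        nxt: Dict[float, float] = {}
        for m0, p0 in dist:
            for mi, pi in base:
                key = round(m0 + mi, 6)
                nxt[key] = nxt.get(key, 0.0) + p0 * pi
        dist = [(m, p) for m, p in nxt.items() if p >= prune]
    return dist


def _merge_peaks(
    peaks: Iterable[Tuple[float, float]], merge_da: float
) -> List[Tuple[float, float]]:
    """Merge peaks closer than ``merge_da``; merged m/z is abundance-weighted."""
    out: List[List[float]] = []
    for mz, ab in sorted(peaks):
        if out and mz - out[-1][0] <= merge_da:
            m0, a0 = out[-1]
            tot = a0 + ab
            out[-1] = [(m0 * a0 + mz * ab) / tot, tot]
        else:
            out.append([mz, ab])
    return [(m, a) for m, a in out]


def simulate_isotope_pattern(
    f: ElementalFormula,
    adduct="[M+H]+",
    min_rel: float = 1.0,
    *,
    merge_da: float = 0.01,
    _prune: float = 1e-10,
) -> IsotopePattern:
    """Simulate the isotopologue pattern of an adduct ion.

    Per-element multinomial distributions are convolved across elements,
    isotopologues within ``merge_da`` (default 0.01 Da, unresolvable on an
    Orbitrap at R = 70,000 in this mass range) are merged, abundances are
    normalized to base = 100 and peaks below ``min_rel`` % are pruned.
    """
    if not (0 < min_rel < 100):
        raise ValueError("min_rel must lie strictly between 0 and 100")
    a = _resolve_adduct(adduct)
    dist: List[Tuple[float, float]] = [(0.0, 1.0)]
    for el, n in f.counts.items():
        eldist = _element_distribution(el, n, _prune)
        nxt: Dict[float, float] = {}
        for m0, p0 in dist:
            for mi, pi in eldist:
                key = round(m0 + mi, 6)
                nxt[key] = nxt.get(key, 0.0) + p0 * pi
        dist = [(m, p) for m, p in nxt.items() if p >= _prune]
    merged = _merge_peaks(dist, merge_da)
    top = max(p for _, p in merged)
    peaks = tuple(
        (round(m + a.mass_shift, 5), min(100.0, 100.0 * p / top))
        for m, p in merged
        if 100.0 * p / top >= min_rel
    )
    return IsotopePattern(peaks)


def isotope_pattern_bruteforce(
    f: ElementalFormula, adduct="[M+H]+", min_rel: float = 1.0, *, merge_da: float = 0.01
) -> IsotopePattern:
    """Reference isotope pattern by explicit multinomial isotopologue enumeration.

    Exponential in isotope choices; intended for formulas with few tens of
    atoms as an independent cross-check of :func:`simulate_isotope_pattern`.
    """
    a = _resolve_adduct(adduct)
    peaks: Dict[float, float] = {}

    def compositions(n: int, k: int):
        if k == 1:
            yield (n,)
            return
        for i in range(n + 1):
            for rest in compositions(n - i, k - 1):
                yield (i,) + rest

    per_element: List[List[Tuple[float, float]]] = []
    for el, n in f.counts.items():
        isos = ISOTOPES[el]
        options: List[Tuple[float, float]] = []
        for comp in compositions(n, len(isos)):
            mass = sum(c * iso[0] for c, iso in zip(comp, isos))
            prob = math.factorial(n)
            for c, iso in zip(comp, isos):
                prob = prob // math.factorial(c)
            p = float(prob)
            for c, iso in zip(comp, isos):
                p *= iso[1] ** c
            options.append((mass, p))
        per_element.append(options)

    for combo in itertools.product(*per_element) if per_element else [()]:
        mass = sum(m for m, _ in combo)
        prob = math.prod(p for _, p in combo) if combo else 1.0
        key = round(mass, 6)
        peaks[key] = peaks.get(key, 0.0) + prob

    merged = _merge_peaks(peaks.items(), merge_da)
    top = max(p for _, p in merged)
    out = tuple(
        (round(m + a.mass_shift, 5), min(100.0, 100.0 * p / top))
        for m, p in merged
        if 100.0 * p / top >= min_rel
    )
    return IsotopePattern(out)


# ---------------------------------------------------------------------------
# Accurate-mass formula enumeration
# ---------------------------------------------------------------------------

#: Default element bounds for CHNOPS(+Cl) enumeration of ions below ~750 Da.
DEFAULT_ELEMENT_BOUNDS: Dict[str, Tuple[int, int]] = {
    "C": (0, 50),
    "H": (0, 100),
    "N": (0, 6),
    "O": (0, 20),
    "P": (0, 4),
    "S": (0, 4),
}

# ring-plus-double-bond valence contributions (monovalent: -1/2, trivalent: +1/2,
# tetravalent: +1); divalent atoms contribute zero
_RDBE_WEIGHT = {"C": 1.0, "Si": 1.0, "N": 0.5, "P": 0.5,
                "H": -0.5, "Cl": -0.5, "Br": -0.5, "F": -0.5, "I": -0.5, "Na": -0.5,
                "O": 0.0, "S": 0.0}


def rdbe(f: ElementalFormula) -> float:
    """Ring-plus-double-bond equivalents of a neutral formula."""
    return 1.0 + sum(_RDBE_WEIGHT.get(el, 0.0) * n for el, n in f.counts.items())


def enumerate_formulas(
    mz: float,
    adduct="[M+H]+",
    tol_ppm: float = 5.0,
    bounds: Optional[Mapping[str, Tuple[int, int]]] = None,
) -> List[ElementalFormula]:
    """Exhaustively enumerate neutral formulas whose adduct m/z matches ``mz``.

    Candidates satisfy the element bounds, have RDBE >= 0 and, when carbon is
    present, H/C within [0.1, 4]. The result is sorted by absolute ppm error
    (computed against the unrounded theoretical m/z).

    Parameters
    ----------
    bounds:
        element -> (min, max) count bounds. Defaults to CHNOPS bounds; add a
        "Cl" entry to allow chlorinated candidates.
    """
    if tol_ppm < 0:
        raise ValueError("tolerance must be >= 0")
    if bounds is not None and len(bounds) == 0:
        raise ValueError("empty element bounds")
    b = dict(DEFAULT_ELEMENT_BOUNDS if bounds is None else bounds)
    a = _resolve_adduct(adduct)
    target = mz - a.mass_shift
    tol_da = mz * tol_ppm * 1e-6

    h_bounds = b.pop("H", (0, 0))
    elements = sorted(b, key=lambda el: -MONOISOTOPIC_MASS[el])
    results: List[Tuple[float, ElementalFormula]] = []
    m_h = MONOISOTOPIC_MASS["H"]

    def recurse(idx: int, counts: Dict[str, int], mass: float) -> None:
        if mass > target + tol_da:
            return
        if idx == len(elements):
            # solve the hydrogen count from the residual mass
            resid = target - mass
            h_lo = max(h_bounds[0], math.ceil((resid - tol_da) / m_h))
            h_hi = min(h_bounds[1], math.floor((resid + tol_da) / m_h))
            for h in range(h_lo, h_hi + 1):
                total = mass + h * m_h
                if abs(total - target) > tol_da:
                    continue
                cand = dict(counts)
                if h:
                    cand["H"] = h
                formula = ElementalFormula(cand)
                if not formula:
                    continue
                if rdbe(formula) < -1e-9:
                    continue
                c = formula["C"]
                if c > 0 and not (0.1 <= formula["H"] / c <= 4.0):
                    continue
                err = abs((total - target) / target) * 1e6 if target > 0 else 0.0
                results.append((err, formula))
            return
        el = elements[idx]
        lo, hi = b[el]
        for n in range(lo, hi + 1):
            new_mass = mass + n * MONOISOTOPIC_MASS[el]
            if new_mass > target + tol_da:
                break
            if n:
                counts[el] = n
            recurse(idx + 1, counts, new_mass)
            counts.pop(el, None)

    recurse(0, {}, 0.0)
    results.sort(key=lambda t: (t[0], t[1].hill()))
    return [f for _, f in results]


# ---------------------------------------------------------------------------
# Theoretical fragments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TheoreticalFragment:
    """An even-electron fragment cation and its expected m/z."""

    cation_formula: ElementalFormula
    expected_mz: float

    def __post_init__(self) -> None:
        theo = monoisotopic_mass(self.cation_formula) - ELECTRON_MASS
        if abs(theo - self.expected_mz) > 1e-5 + 5e-6:
            raise ValueError(
                f"expected_mz {self.expected_mz} inconsistent with formula "
                f"{self.cation_formula} (computed {theo:.5f})"
            )

    @classmethod
    def from_formula(cls, formula) -> "TheoreticalFragment":
        f = parse_formula(formula) if isinstance(formula, str) else formula
        return cls(f, fragment_cation_mz(f))
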