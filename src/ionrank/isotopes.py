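"""Theoretical isotope patterns for formula+adduct ions, and decoy generation.

An ion candidate is a molecular formula combined with an adduct at the
dataset polarity.  Target ions use plausible adducts (+H, +Na, +K in
positive mode; -H, +Cl in negative mode); decoy ions combine the same
formula with chemically implausible single-element adducts and estimate the
false-match score distribution in target-decoy FDR estimation.

Patterns are computed by element-wise convolution of natural isotope
abundances (pyteomics ``nist_mass`` element table) over nominal-mass-shift
bins, keeping the first ``T`` isotopic peaks (default 4) and normalizing
intensities to the most intense kept peak.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
from pyteomics import mass as _pmass

from .io import MoleculeRecord, parse_formula

__all__ = [
    "IsotopePattern",
    "IonCandidate",
    "InvalidIonError",
    "parse_adduct",
    "ion_formula",
    "theoretical_pattern",
    "default_decoy_universe",
    "sample_decoy_adducts",
    "build_candidates",
    "ELECTRON_MASS",
]

ELECTRON_MASS = 0.000548579909  # Da

DEFAULT_TARGET_ADDUCTS = {"positive": ("+H", "+Na", "+K"), "negative": ("-H", "+Cl")}


class InvalidIonError(ValueError):
    """Adduct arithmetic produced a negative element count."""


@dataclass(frozen=True)
class IsotopePattern:
    """First ``T`` theoretical isotopic peaks of an ion.

    ``mzs`` ascending; ``rel_intensities`` normalized so the most intense
    kept peak equals 1.
    """

    mzs: tuple[float, ...]
    rel_intensities: tuple[float, ...]

    @property
    def T(self) -> int:
        return len(self.mzs)


@dataclass(frozen=True)
class IonCandidate:
    formula: str
    adduct: str
    polarity: str
    is_decoy: bool
    pattern: IsotopePattern


import re as _re

_ADDUCT_TOKEN = _re.compile(r"([+-])(\d*)([A-Z][A-Za-z0-9]*)")


def parse_adduct(adduct: str) -> dict[str, int]:
    """Parse an adduct string (``+H``, ``-H``, ``+Na-2H``) into signed counts."""
    pos = 0
    delta: dict[str, int] = {}
    for m in _ADDUCT_TOKEN.finditer(adduct):
        if m.start() != pos:
            raise ValueError(f"invalid adduct: {adduct!r}")
        pos = m.end()
        sign = 1 if m.group(1) == "+" else -1
        mult = int(m.group(2) or 1)
        for el, n in parse_formula(m.group(3)).items():
            delta[el] = delta.get(el, 0) + sign * mult * n
    if pos != len(adduct) or not delta:
        raise ValueError(f"invalid adduct: {adduct!r}")
    return delta


def ion_formula(
    formula: str, adduct: str, polarity: str = "positive"
) -> tuple[dict[str, int], int]:
    """Elemental composition and charge of a formula+adduct ion.

    Charge is +1 in positive mode and -1 in negative mode (singly charged
    ions only).  Raises :class:`InvalidIonError` when the adduct subtracts
    more atoms of an element than the molecule has.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError(f"unknown polarity: {polarity!r}")
    comp = parse_formula(formula)
    for el, n in parse_adduct(adduct).items():
        comp[el] = comp.get(el, 0) + n
        if comp[el] < 0:
            raise InvalidIonError(f"{adduct} removes more {el} than {formula} has")
        if comp[el] == 0:
            del comp[el]
    if not comp:
        raise InvalidIonError(f"{formula}{adduct} leaves an empty composition")
    charge = 1 if polarity == "positive" else -1
    return comp, charge


def _element_shift_distribution(element: str) -> tuple[np.ndarray, np.ndarray]:
    """Single-atom (probability, mass) arrays over nominal-mass-shift bins."""
    try:
        table = _pmass.nist_mass[element]
    except KeyError as exc:
        raise ValueError(f"unknown element: {element!r}") from exc
    isotopes = [
        (num, m, ab) for num, (m, ab) in table.items() if num != 0 and ab > 0
    ]
    if not isotopes:
        raise ValueError(f"element {element!r} has no natural isotopes")
    isotopes.sort()
    base = isotopes[0][0]
    max_shift = isotopes[-1][0] - base
    prob = np.zeros(max_shift + 1)
    mass_arr = np.zeros(max_shift + 1)
    for num, m, ab in isotopes:
        prob[num - base] += ab
        mass_arr[num - base] = m
    prob /= prob.sum()
    return prob, mass_arr


def _convolve(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray], nmax: int
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two (prob, expected-mass) bin distributions, truncated at nmax bins."""
    pa, ma = a
    pb, mb = b
    n = min(len(pa) + len(pb) - 1, nmax)
    prob = np.zeros(n)
    wmass = np.zeros(n)
    for i in range(min(len(pa), n)):
        if pa[i] == 0:
            continue
        jmax = min(len(pb), n - i)
        contrib = pa[i] * pb[:jmax]
        prob[i : i + jmax] += contrib
        wmass[i : i + jmax] += contrib * (ma[i] + mb[:jmax])
    mass_out = np.where(prob > 0, wmass / np.where(prob > 0, prob, 1.0), 0.0)
    return prob, mass_out


def _composition_distribution(
    comp: dict[str, int], nmax: int
) -> tuple[np.ndarray, np.ndarray]:
    """Isotopologue distribution of a composition over nominal-shift bins.

    Per-bin probabilities are exact; per-bin masses are probability-weighted
    centroids (exact expected values under aggregation).
    """
    acc: tuple[np.ndarray, np.ndarray] | None = None
    for el, count in sorted(comp.items()):
        single = _element_shift_distribution(el)
        # exponentiation by squaring over the atom count
        powed: tuple[np.ndarray, np.ndarray] | None = None
        sq = single
        k = count
        while k:
            if k & 1:
                powed = sq if powed is None else _convolve(powed, sq, nmax)
            k >>= 1
            if k:
                sq = _convolve(sq, sq, nmax)
        assert powed is not None
        acc = powed if acc is None else _convolve(acc, powed, nmax)
    if acc is None:
        raise ValueError("empty composition")
    return acc


def theoretical_pattern(
    comp: dict[str, int], charge: int, T: int = 4
) -> IsotopePattern:
    """Theoretical T-peak isotope pattern of an ion composition.

    Peaks are nominal-mass-shift aggregates of the full isotopologue
    distribution, sorted ascending in m/z; intensities are normalized to the
    most intense kept peak.  m/z accounts for the electron mass at the given
    charge (restricted to +-1).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if charge not in (1, -1):
        raise ValueError("only singly charged ions are supported")
    prob, mass_arr = _composition_distribution(comp, T)
    keep = min(T, len(prob))
    prob = prob[:keep]
    mass_arr = mass_arr[:keep]
    # drop trailing zero-probability bins (tiny molecules may have < T peaks)
    nz = np.nonzero(prob)[0]
    last = nz[-1] + 1
    prob = prob[:last]
    mass_arr = mass_arr[:last]
    mzs = (mass_arr - charge * ELECTRON_MASS) / abs(charge)
    rel = prob / prob.max()
    return IsotopePattern(mzs=tuple(float(x) for x in mzs), rel_intensities=tuple(float(x) for x in rel))


def pattern_for(
    formula: str, adduct: str, polarity: str = "positive", T: int = 4
) -> IsotopePattern:
    comp, charge = ion_formula(formula, adduct, polarity)
    return theoretical_pattern(comp, charge, T=T)


# ---------------------------------------------------------------------------
# decoys


def default_decoy_universe() -> list[str]:
    """The bundled implausible-adduct list (user-overridable)."""
    text = (
        resources.files("ionrank")
        .joinpath("data/decoy_adducts.txt")
        .read_text(encoding="utf-8")
    )
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def _formula_rng(seed: int, formula: str, purpose: str = "decoys") -> np.random.Generator:
    """Named RNG stream per (purpose, formula), derived from a master seed.

    Keeps a formula's decoy set stable when other formulas are added or
    removed from the database.
    """
    key = zlib.crc32(f"{purpose}:{formula}".encode())
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, key])


def sample_decoy_adducts(
    formula: str,
    S_D: int = 20,
    universe: list[str] | None = None,
    seed: int = 0,
) -> list[str]:
    """Sample ``S_D`` distinct implausible adducts for a target formula.

    The same set is returned for a formula regardless of which target adduct
    is being ranked (the decoy-sharing contract), and the draw is a function
    of (formula, seed, universe) only.
    """
    if universe is None:
        universe = default_decoy_universe()
    if S_D > len(universe):
        raise ValueError(f"S_D={S_D} exceeds universe size {len(universe)}")
    rng = _formula_rng(seed, formula)
    idx = rng.choice(len(universe), size=S_D, replace=False)
    return [universe[i] for i in idx]


def build_candidates(
    db: list[MoleculeRecord],
    target_adducts: tuple[str, ...] | list[str] | None = None,
    polarity: str = "positive",
    S_D: int = 20,
    seed: int = 0,
    universe: list[str] | None = None,
    T: int = 4,
) -> tuple[list[IonCandidate], list[str]]:
    """Build target and shared decoy candidates for every database formula.

    Returns (candidates, skipped) where ``skipped`` logs formula+adduct
    combinations whose adduct arithmetic was invalid.
    """
    if not db:
        raise ValueError("empty molecule database")
    if target_adducts is None:
        target_adducts = DEFAULT_TARGET_ADDUCTS[polarity]
    if not target_adducts:
        raise ValueError("empty target adduct list")
    candidates: list[IonCandidate] = []
    skipped: list[str] = []
    for rec in db:
        for adduct in target_adducts:
            try:
                pat = pattern_for(rec.formula, adduct, polarity, T=T)
            except (InvalidIonError, ValueError) as exc:
                skipped.append(f"{rec.formula}{adduct}: {exc}")
                continue
            candidates.append(
                IonCandidate(rec.formula, adduct, polarity, False, pat)
            )
        if S_D == 0:
            continue
        for adduct in sample_decoy_adducts(rec.formula, S_D, universe, seed):
            try:
                pat = pattern_for(rec.formula, adduct, polarity, T=T)
            except (InvalidIonError, ValueError) as exc:  # pragma: no cover
                skipped.append(f"{rec.formula}{adduct}: {exc}")
                continue
            candidates.append(IonCandidate(rec.formula, adduct, polarity, True, pat))
    return candidates, skipped
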