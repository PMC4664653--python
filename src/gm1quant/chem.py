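"""Molecular-formula arithmetic and isotope-envelope computation.

The two analytes of this package are GM1 ganglioside species differing in
their sphingosine long-chain base (d18:1 vs d20:1, two CH2 groups = 28.06 Da
apart), both carrying a stearoyl (18:0) fatty acid:

* GM1 d18:1  C73H131N3O31, [M-H]- at m/z 1544.87
* GM1 d20:1  C75H135N3O31, [M-H]- at m/z 1572.90

Masses are computed from a bundled static table of IUPAC isotope masses and
natural abundances; envelopes are aggregated by nucleon number (unit-mass
resolution), which is the resolution regime of reflectron TOF data at
m/z ~1500.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Adduct",
    "MolecularFormula",
    "IsotopeEnvelope",
    "SpeciesTarget",
    "monoisotopic_mz",
    "isotope_envelope",
    "default_targets",
    "PROTON_MASS",
]

#: Mass of a proton in Da. [M-H]- m/z is computed as neutral monoisotopic
#: mass minus one proton; the electron mass (~0.00055 Da) is deliberately
#: ignored — the error is far below the 0.01 Da reporting precision used
#: for these targets.
PROTON_MASS = 1.007276466621

# (mass Da, natural abundance), lightest isotope first. IUPAC 2021 values.
_ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.00307400443, 0.99636), (15.00010889888, 0.00364)],
    "O": [
        (15.99491461957, 0.99757),
        (16.99913175650, 0.00038),
        (17.99915961286, 0.00205),
    ],
    "S": [
        (31.9720711744, 0.9499),
        (32.9714589098, 0.0075),
        (33.9678670040, 0.0425),
        (35.9670807100, 0.0001),
    ],
    "P": [(30.97376199842, 1.0)],
    "Na": [(22.98976928200, 1.0)],
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Adduct(str, Enum):
    """Supported ionization adducts. Only deprotonation is needed here."""

    M_MINUS_H = "[M-H]-"


class UnknownElementError(ValueError):
    def __init__(self, symbol: str):
        super().__init__(
            f"element {symbol!r} is not in the bundled isotope table "
            f"(known: {sorted(_ISOTOPES)})"
        )
        self.symbol = symbol


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map for a neutral molecule.

    Construct from Hill notation with :meth:`parse`, e.g.
    ``MolecularFormula.parse("C73H131N3O31")``.
    """

    element_counts: Mapping[str, int]

    def __post_init__(self):
        if not self.element_counts:
            raise ValueError("empty molecular formula")
        for sym, n in self.element_counts.items():
            if sym not in _ISOTOPES:
                raise UnknownElementError(sym)
            if not isinstance(n, (int, np.integer)) or n < 1:
                raise ValueError(f"count for {sym} must be a positive integer, got {n!r}")
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    @classmethod
    def parse(cls, hill: str) -> "MolecularFormula":
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(hill):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {hill!r} at position {pos}")
            pos = m.end()
            sym = m.group(1)
            n = int(m.group(2)) if m.group(2) else 1
            counts[sym] = counts.get(sym, 0) + n
        if pos != len(hill) or not counts:
            raise ValueError(f"cannot parse formula {hill!r}")
        return cls(counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for sym, n in other.element_counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return MolecularFormula(counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        syms = sorted(
            self.element_counts,
            key=lambda s: (s != "C", s != "H", s),
        )
        return "".join(
            f"{s}{self.element_counts[s] if self.element_counts[s] > 1 else ''}"
            for s in syms
        )

    @property
    def n_atoms(self) -> int:
        return sum(self.element_counts.values())

    def monoisotopic_mass(self) -> float:
        """Neutral mass using the lightest isotope of every element."""
        return sum(_ISOTOPES[s][0][0] * n for s, n in self.element_counts.items())


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Unit-mass-aggregated isotope pattern.

    ``peaks`` is an ordered list of (mass, relative_abundance); masses are
    abundance-weighted means within each nucleon-number bin, so consecutive
    peaks are ~1.0034 Da apart. ``normalization`` is ``"sum"``
    (abundances sum to 1) or ``"base_peak"`` (largest peak = 1).
    """

    peaks: tuple[tuple[float, float], ...]
    normalization: str = "sum"

    def __post_init__(self):
        masses = [m for m, _ in self.peaks]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("envelope masses must be strictly increasing")
        if any(a < 0 for _, a in self.peaks):
            raise ValueError("envelope abundances must be nonnegative")
        if self.normalization not in ("sum", "base_peak"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def abundances(self) -> np.ndarray:
        return np.array([a for _, a in self.peaks])

    def normalized(self, mode: str) -> "IsotopeEnvelope":
        ab = self.abundances
        if mode == "sum":
            ab = ab / ab.sum()
        elif mode == "base_peak":
            ab = ab / ab.max()
        else:
            raise ValueError(f"unknown normalization {mode!r}")
        return IsotopeEnvelope(tuple(zip(self.masses, ab)), normalization=mode)

    @property
    def base_peak_index(self) -> int:
        return int(np.argmax(self.abundances))

    def monoisotopic_fraction(self) -> float:
        """Fraction of total envelope abundance carried by the first peak."""
        ab = self.abundances
        return float(ab[0] / ab.sum())


def monoisotopic_mz(formula: MolecularFormula | str, adduct: Adduct | str = Adduct.M_MINUS_H) -> float:
    """Predicted m/z of the adduct ion from lowest-isotope atomic masses.

    For [M-H]- this is the neutral monoisotopic mass minus one proton.
    """
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula)
    adduct = Adduct(adduct)
    if adduct is Adduct.M_MINUS_H:
        if formula.element_counts.get("H", 0) < 1:
            raise ValueError(
                f"[M-H]- requires at least one hydrogen; formula {formula} has none"
            )
        return formula.monoisotopic_mass() - PROTON_MASS
    raise ValueError(f"unsupported adduct {adduct}")  # pragma: no cover


def _element_envelope(symbol: str, count: int, max_peaks: int) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated envelope of ``count`` atoms of one element.

    Returns (a, s): a[k] = probability of k extra nucleons, s[k] = sum of
    probability-weighted masses, both truncated to ``max_peaks`` bins.
    Computed by exponentiation-by-squaring of the single-atom distribution.
    """
    isos = _ISOTOPES[symbol]
    base_nucleon = round(isos[0][0])
    # single-atom distribution over nucleon offsets
    max_off = max(round(m) - base_nucleon for m, _ in isos)
    a1 = np.zeros(min(max_off, max_peaks - 1) + 1)
    s1 = np.zeros_like(a1)
    for m, p in isos:
        k = round(m) - base_nucleon
        if k >= len(a1):
            continue
        a1[k] += p
        s1[k] += p * m
    # renormalize in case an isotope was truncated (never for CHNOPS here)
    tot = sum(p for _, p in isos)
    a1, s1 = a1 / tot, s1 / tot

    def mul(x, y):
        ax, sx = x
        ay, sy = y
        n = min(len(ax) + len(ay) - 1, max_peaks)
        a = np.zeros(n)
        s = np.zeros(n)
        for i in range(len(ax)):
            if ax[i] == 0 and sx[i] == 0:
                continue
            j_hi = min(len(ay), n - i)
            a[i : i + j_hi] += ax[i] * ay[:j_hi]
            s[i : i + j_hi] += sx[i] * ay[:j_hi] + ax[i] * sy[:j_hi]
        return a, s

    result = (np.array([1.0]), np.array([0.0]))
    square = (a1, s1)
    n = count
    while n:
        if n & 1:
            result = mul(result, square)
        n >>= 1
        if n:
            square = mul(square, square)
    return result


def isotope_envelope(
    formula: MolecularFormula | str,
    max_peaks: int = 8,
    normalization: str = "sum",
) -> IsotopeEnvelope:
    """Nucleon-number-aggregated isotope envelope of a neutral formula.

    Abundances come from per-element multinomial convolution; peak masses
    are abundance-weighted means within each nucleon bin. The envelope is
    truncated to ``max_peaks`` peaks, then normalized. Results are cached
    per (formula, max_peaks, normalization).
    """
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula)
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    key = (str(formula), max_peaks, normalization)
    cached = _ENVELOPE_CACHE.get(key)
    if cached is not None:
        return cached
    a = np.array([1.0])
    s = np.array([0.0])
    for sym, count in formula.element_counts.items():
        ea, es = _element_envelope(sym, count, max_peaks)
        n = min(len(a) + len(ea) - 1, max_peaks)
        na = np.zeros(n)
        ns = np.zeros(n)
        for i in range(len(a)):
            j_hi = min(len(ea), n - i)
            na[i : i + j_hi] += a[i] * ea[:j_hi]
            ns[i : i + j_hi] += s[i] * ea[:j_hi] + a[i] * es[:j_hi]
        a, s = na, ns
    keep = a > 0
    masses = s[keep] / a[keep]
    env = IsotopeEnvelope(tuple(zip(masses, a[keep])), normalization="sum")
    env = env.normalized(normalization)
    _ENVELOPE_CACHE[key] = env
    return env


_ENVELOPE_CACHE: dict[tuple, IsotopeEnvelope] = {}


@dataclass(frozen=True)
class SpeciesTarget:
    """A named species to quantify: formula, adduct, predicted m/z, windows.

    ``search_halfwidth`` bounds where the apex may sit around the predicted
    m/z (default 0.5 Da, half an isotope spacing, so only the monoisotopic
    peak can be selected); ``integration_halfwidth`` bounds the AUC window
    around the located apex (default 0.4 Da, within one isotope spacing so
    only the highest peak is integrated).
    """

    name: str
    formula: MolecularFormula
    adduct: Adduct = Adduct.M_MINUS_H
    predicted_mz: float = field(default=0.0)
    search_halfwidth: float = 0.5
    integration_halfwidth: float = 0.4

    def __post_init__(self):
        if self.predicted_mz == 0.0:
            object.__setattr__(
                self, "predicted_mz", monoisotopic_mz(self.formula, self.adduct)
            )
        if self.predicted_mz <= 0:
            raise ValueError("predicted_mz must be > 0")
        if self.search_halfwidth <= 0 or self.integration_halfwidth <= 0:
            raise ValueError("halfwidths must be > 0")

    def window_bounds(self) -> tuple[float, float]:
        """m/z bounds of the full correction window (search + integration)."""
        hw = self.search_halfwidth + self.integration_halfwidth
        return self.predicted_mz - hw, self.predicted_mz + hw

    def envelope(self, max_peaks: int = 8) -> IsotopeEnvelope:
        return isotope_envelope(self.formula, max_peaks=max_peaks)

    def ion_peak_masses(self, max_peaks: int = 8) -> np.ndarray:
        """Envelope peak m/z values for the adduct ion."""
        env = self.envelope(max_peaks)
        if self.adduct is Adduct.M_MINUS_H:
            return env.masses - PROTON_MASS
        raise ValueError(f"unsupported adduct {self.adduct}")  # pragma: no cover


def default_targets() -> tuple[SpeciesTarget, SpeciesTarget]:
    """The (numerator, denominator) GM1 species pair: d18:1 then d20:1.

    The stearoyl (18:0) fatty acid is assumed for both species; the
    resulting formulas reproduce the predicted [M-H]- anchors 1544.87 and
    1572.90 used for quantification.
    """
    d18 = SpeciesTarget("GM1d18:1", MolecularFormula.parse("C73H131N3O31"))
    d20 = SpeciesTarget("GM1d20:1", MolecularFormula.parse("C75H135N3O31"))
    return d18, d20
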