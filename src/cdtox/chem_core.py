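"""Deterministic chemical and physical arithmetic shared across the pipeline.

Formula parsing and monoisotopic masses, ring-and-double-bond equivalents,
polyethylene-glycol (PEG) homologue masses, Bragg lattice spacings and
dilution-series construction.  Everything here is closed-form and exact to
the precision of the hard-coded isotope mass table.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "Formula",
    "parse_formula",
    "monoisotopic_mass",
    "rdbe",
    "peg_mass",
    "bragg_spacing",
    "dilution_series",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PEG_REPEAT_MASS",
    "WATER_MASS",
    "CU_KALPHA_NM",
]

# IUPAC 2021 most-abundant-isotope masses (Da), 6 decimals.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
    "Si": 27.976927,
}

ELECTRON_MASS = 0.000549  # Da per elementary charge

#: Monoisotopic mass of the PEG repeat unit C2H4O.
PEG_REPEAT_MASS = 44.026215
#: Monoisotopic mass of H2O (the HO–…–H end groups of a PEG chain).
WATER_MASS = 18.010565

#: Cu Kalpha X-ray wavelength in nm (default anode for the Bragg utility).
CU_KALPHA_NM = 0.15406

# Hill order: C first, H second, all else alphabetical.
_HILL_TAIL = sorted(e for e in MONOISOTOPIC_MASS if e not in ("C", "H"))

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
# charge: trailing run of signs ("+", "--") or caret notation ("^2+");
# a bare digit before a sign is always an element count, never a magnitude
_CHARGE_RE = re.compile(r"(?:\^(\d+)([+-])|([+-]+))$")


@dataclass(frozen=True)
class Formula:
    """An elemental composition over C, H, N, O, S, Si with an optional charge.

    ``element_counts`` maps element symbols to non-negative integer counts;
    ``charge`` is in elementary charges (positive for cations).
    """

    element_counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        for sym, n in self.element_counts.items():
            if sym not in MONOISOTOPIC_MASS:
                raise ValueError(f"unsupported element symbol: {sym!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {sym} must be a non-negative integer")
        if not any(n > 0 for n in self.element_counts.values()):
            raise ValueError("formula must contain at least one atom")

    def __getitem__(self, sym: str) -> int:
        return self.element_counts.get(sym, 0)

    def hill(self) -> str:
        """Serialize in Hill notation, with a trailing charge sign if charged."""
        parts: list[str] = []
        order = ["C", "H"] + _HILL_TAIL if self["C"] else sorted(MONOISOTOPIC_MASS)
        for sym in order:
            n = self[sym]
            if n == 0:
                continue
            parts.append(sym if n == 1 else f"{sym}{n}")
        s = "".join(parts)
        if self.charge:
            mag = abs(self.charge)
            sign = "+" if self.charge > 0 else "-"
            # caret notation for multi-charges: a bare digit before the sign
            # would be ambiguous with an element count
            s += sign if mag == 1 else f"^{mag}{sign}"
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation formula string, e.g. ``"C6H14O4"`` or ``"C7H7+"``.

    An optional trailing charge (``+``, ``-``, ``2+`` ...) is accepted.
    Unknown element symbols and malformed strings raise ``ValueError``.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula string")
    body = text.strip()
    charge = 0
    m = _CHARGE_RE.search(body)
    if m:
        if m.group(3) is not None:
            signs = set(m.group(3))
            if len(signs) != 1:
                raise ValueError(f"mixed charge signs in {text!r}")
            charge = len(m.group(3)) * (1 if "+" in signs else -1)
        else:
            mag = int(m.group(1))
            charge = mag if m.group(2) == "+" else -mag
        body = body[: m.start()]
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(body):
        m = _TOKEN_RE.match(body, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula string: {text!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise ValueError(f"unsupported element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Formula(counts, charge)


def monoisotopic_mass(f: Formula) -> float:
    """Monoisotopic mass in Da, or m/z for a charged species.

    Neutral: sum of most-abundant-isotope masses.  For charge ±z the electron
    mass is subtracted (cations) or added (anions) per charge and the result
    divided by |z|.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    mass = sum(MONOISOTOPIC_MASS[sym] * n for sym, n in f.element_counts.items())
    if f.charge:
        mass -= f.charge * ELECTRON_MASS
        mass /= abs(f.charge)
    return mass


def rdbe(f: Formula) -> float:
    """Ring-and-double-bond equivalents: C + Si − H/2 + N/2 + 1.

    O and S contribute nothing.  May be half-integer for odd-electron species.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    return f["C"] + f["Si"] - f["H"] / 2.0 + f["N"] / 2.0 + 1.0


def peg_mass(n: int) -> float:
    """Monoisotopic mass of the PEG oligomer HO–[C2H4O]n–H in Da."""
    if not isinstance(n, int) or n < 1:
        raise ValueError("PEG repeat count n must be an integer >= 1")
    return n * PEG_REPEAT_MASS + WATER_MASS


def bragg_spacing(two_theta: float, wavelength: float = CU_KALPHA_NM, order: int = 1) -> float:
    """Lattice spacing d = n·λ / (2 sin θ) from a diffraction angle 2θ.

    Parameters
    ----------
    two_theta : diffraction angle in degrees, 0 < 2θ < 180 (≤ 180 at the limit).
    wavelength : X-ray wavelength in the output length unit (default Cu Kα, nm).
    order : diffraction order n ≥ 1.
    """
    if not 0.0 < two_theta <= 180.0:
        raise ValueError("two_theta must be in (0, 180] degrees")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if order < 1:
        raise ValueError("order must be >= 1")
    theta = math.radians(two_theta / 2.0)
    return order * wavelength / (2.0 * math.sin(theta))


def dilution_series(top: float, factor: float, n_points: int) -> list[float]:
    """Descending serial-dilution concentrations [top, top/f, …, top/f^(n−1)]."""
    if top <= 0:
        raise ValueError("top concentration must be positive")
    if factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    return [top / factor**i for i in range(n_points)]
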