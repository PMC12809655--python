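"""Nuclide masses and exact m/z computation for isotopologue ions.

Masses are atomic masses in u from the 2020 atomic mass evaluation
(rounded to 1e-8 u, far below the 1e-3 tolerance used for checking
printed m/z values). The m/z of an ion corrects the neutral-sum mass
by one electron mass according to polarity (singly charged ions).
"""

from __future__ import annotations

ELECTRON_MASS_U = 0.00054858

#: atomic masses of the nuclides occurring in small-molecule fragments
NUCLIDE_MASS_U: dict[str, float] = {
    "1H": 1.00782503,
    "2H": 2.01410178,
    "12C": 12.0,
    "13C": 13.00335484,
    "14N": 14.00307400,
    "15N": 15.00010890,
    "16O": 15.99491462,
    "17O": 16.99913176,
    "18O": 17.99915961,
    "32S": 31.97207117,
    "33S": 32.97145891,
    "34S": 33.96786700,
    "36S": 35.96708071,
}


class UnknownNuclideError(KeyError):
    """A formula references a nuclide not in the mass table."""


def formula_mass(formula: tuple[tuple[str, int], ...] | list[tuple[str, int]]) -> float:
    """Neutral mass (u) of an isotopic formula given as (nuclide, count) pairs."""
    total = 0.0
    for nuclide, count in formula:
        try:
            mass = NUCLIDE_MASS_U[nuclide]
        except KeyError:
            raise UnknownNuclideError(
                f"nuclide {nuclide!r} not in mass table"
            ) from None
        total += mass * count
    return total


def ion_mz(formula, polarity: str, charge: int = 1) -> float:
    """m/z of a |z|-charged ion: neutral mass minus (positive) or plus
    (negative) ``charge`` electron masses, divided by ``charge``."""
    mass = formula_mass(formula)
    if polarity == "positive":
        mass -= charge * ELECTRON_MASS_U
    elif polarity == "negative":
        mass += charge * ELECTRON_MASS_U
    else:
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    return mass / charge
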