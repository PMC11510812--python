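"""Packaged X-ray mass-attenuation tables and compound lookup.

The tables below give total mass-attenuation coefficients mu/rho (cm^2/g,
with coherent scattering) for the handful of elements needed by the phantom
and spectrum models, on a coarse energy grid with log-log interpolation in
between.  Values follow the standard XCOM-style element compilations to a
few percent; absorption-edge discontinuities are represented by a pair of
almost-coincident energies.  Sub-6 keV L/M-shell fine structure of the heavy
elements is smoothed or omitted (it is irrelevant above the ~20 keV lower
bound of the simulated spectra).  These synthetic packaged tables stand in
for an online attenuation database so that everything runs offline.

Compounds are resolved from their chemical formula; the mixture rule
(mu/rho)_compound = sum_i w_i (mu/rho)_i with mass fractions w_i applies.
"""

from __future__ import annotations

import re

import numpy as np

__all__ = [
    "UnknownMaterialError",
    "EnergyRangeError",
    "element_mass_attenuation",
    "compound_mass_attenuation",
    "parse_formula",
    "ATOMIC_MASS",
]


class UnknownMaterialError(KeyError):
    """Raised for a chemical symbol/formula not in the packaged tables."""


class EnergyRangeError(ValueError):
    """Raised when an energy falls outside the tabulated range."""


ATOMIC_MASS = {
    "H": 1.008,
    "Be": 9.0122,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Al": 26.982,
    "Ar": 39.948,
    "I": 126.904,
    "W": 183.84,
}

# (energy keV, mu/rho cm^2/g); strictly increasing energies, edge = duplicated
# energy with a tiny offset.
_MU_RHO: dict[str, list[tuple[float, float]]] = {
    "H": [
        (1.0, 7.217), (1.5, 2.148), (2.0, 1.059), (3.0, 0.5612),
        (4.0, 0.4546), (5.0, 0.4193), (6.0, 0.4042), (8.0, 0.3914),
        (10.0, 0.3854), (15.0, 0.3764), (20.0, 0.3695), (30.0, 0.3570),
        (40.0, 0.3458), (50.0, 0.3355), (60.0, 0.3260), (80.0, 0.3091),
        (100.0, 0.2944), (150.0, 0.2651), (200.0, 0.2429), (300.0, 0.2112),
        (400.0, 0.1893), (500.0, 0.1729),
    ],
    "Be": [
        (1.0, 604.1), (1.5, 179.7), (2.0, 74.69), (3.0, 21.27),
        (4.0, 8.685), (5.0, 4.369), (6.0, 2.527), (8.0, 1.124),
        (10.0, 0.6466), (15.0, 0.3070), (20.0, 0.2251), (30.0, 0.1792),
        (40.0, 0.1640), (50.0, 0.1554), (60.0, 0.1493), (80.0, 0.1401),
        (100.0, 0.1328), (150.0, 0.1190), (200.0, 0.1089), (300.0, 0.0945),
        (400.0, 0.0847), (500.0, 0.0773),
    ],
    "C": [
        (1.0, 2211.0), (1.5, 700.2), (2.0, 302.6), (3.0, 94.33),
        (4.0, 40.49), (5.0, 21.07), (6.0, 12.46), (8.0, 5.437),
        (10.0, 2.373), (15.0, 0.8071), (20.0, 0.4420), (30.0, 0.2562),
        (40.0, 0.2076), (50.0, 0.1871), (60.0, 0.1753), (80.0, 0.1610),
        (100.0, 0.1514), (150.0, 0.1347), (200.0, 0.1229), (300.0, 0.1066),
        (400.0, 0.09546), (500.0, 0.08715),
    ],
    "N": [
        (1.0, 3311.0), (1.5, 1083.0), (2.0, 476.1), (3.0, 145.6),
        (4.0, 61.66), (5.0, 31.69), (6.0, 18.06), (8.0, 7.562),
        (10.0, 3.879), (15.0, 1.236), (20.0, 0.6178), (30.0, 0.3066),
        (40.0, 0.2288), (50.0, 0.1980), (60.0, 0.1817), (80.0, 0.1639),
        (100.0, 0.1529), (150.0, 0.1353), (200.0, 0.1233), (300.0, 0.1068),
        (400.0, 0.0955), (500.0, 0.0872),
    ],
    "O": [
        (1.0, 4590.0), (1.5, 1549.0), (2.0, 694.9), (3.0, 217.1),
        (4.0, 93.15), (5.0, 47.90), (6.0, 27.70), (8.0, 11.63),
        (10.0, 5.952), (15.0, 1.836), (20.0, 0.8651), (30.0, 0.3779),
        (40.0, 0.2585), (50.0, 0.2132), (60.0, 0.1907), (80.0, 0.1678),
        (100.0, 0.1551), (150.0, 0.1361), (200.0, 0.1237), (300.0, 0.1070),
        (400.0, 0.0957), (500.0, 0.0871),
    ],
    "Al": [
        (1.0, 1185.0), (1.5, 402.2), (1.5596, 362.1), (1.55961, 3957.0),
        (2.0, 2263.0), (3.0, 788.0), (4.0, 360.5), (5.0, 193.4),
        (6.0, 115.3), (8.0, 50.33), (10.0, 26.23), (15.0, 7.955),
        (20.0, 3.441), (30.0, 1.128), (40.0, 0.5685), (50.0, 0.3681),
        (60.0, 0.2778), (80.0, 0.2018), (100.0, 0.1704), (150.0, 0.1378),
        (200.0, 0.1223), (300.0, 0.1042), (400.0, 0.0927), (500.0, 0.0844),
    ],
    "Ar": [
        (1.0, 3184.0), (1.5, 1105.0), (2.0, 516.9), (3.0, 169.7),
        (3.2029, 142.3), (3.20291, 1275.0), (4.0, 979.0), (5.0, 501.0),
        (6.0, 290.0), (8.0, 122.4), (10.0, 62.66), (15.0, 19.55),
        (20.0, 8.630), (30.0, 2.697), (40.0, 1.228), (50.0, 0.7012),
        (60.0, 0.4664), (80.0, 0.2760), (100.0, 0.2043), (150.0, 0.1427),
        (200.0, 0.1205), (300.0, 0.0995), (400.0, 0.0878), (500.0, 0.0796),
    ],
    # Iodine: K edge at 33.1694 keV; L-shell structure below 6 keV omitted.
    "I": [
        (6.0, 941.0), (8.0, 397.0), (10.0, 203.0), (15.0, 60.2),
        (20.0, 25.42), (25.0, 13.50), (30.0, 8.561),
        (33.1694, 6.553), (33.16941, 36.33),
        (35.0, 31.20), (40.0, 22.10), (50.0, 12.32), (60.0, 7.579),
        (69.525, 5.050), (80.0, 3.510), (100.0, 1.942), (150.0, 0.6573),
        (200.0, 0.3415), (300.0, 0.1658), (400.0, 0.1145), (500.0, 0.0901),
    ],
    # Tungsten: L edges (10.2-12.1 keV) coarsened, K edge at 69.525 keV.
    "W": [
        (1.0, 3683.0), (2.0, 2500.0), (3.0, 1100.0), (4.0, 580.0),
        (5.0, 330.0), (6.0, 210.0), (8.0, 105.0), (10.0, 96.91),
        (10.5, 223.0), (11.0, 205.0), (12.0, 184.0), (13.0, 170.0),
        (15.0, 139.3), (20.0, 65.73), (30.0, 22.73), (40.0, 10.67),
        (50.0, 5.949), (60.0, 3.713),
        (69.525, 2.552), (69.5251, 11.23),
        (80.0, 7.810), (100.0, 4.438), (150.0, 1.581), (200.0, 0.7844),
        (300.0, 0.3238), (400.0, 0.1925), (500.0, 0.1378),
    ],
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a simple chemical formula ("C6H5NO2") into element counts."""
    pos = 0
    counts: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise UnknownMaterialError(f"cannot parse formula {formula!r}")
        pos = match.end()
        sym, num = match.group(1), match.group(2)
        if sym not in ATOMIC_MASS:
            raise UnknownMaterialError(f"element {sym!r} not in packaged tables")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise UnknownMaterialError(f"cannot parse formula {formula!r}")
    return counts


def mass_fractions(formula: str) -> dict[str, float]:
    counts = parse_formula(formula)
    masses = {sym: n * ATOMIC_MASS[sym] for sym, n in counts.items()}
    total = sum(masses.values())
    return {sym: m / total for sym, m in masses.items()}


def element_mass_attenuation(symbol: str, energy_kev) -> np.ndarray | float:
    """mu/rho (cm^2/g) of an element, log-log interpolated from the tables."""
    if symbol not in _MU_RHO:
        raise UnknownMaterialError(f"element {symbol!r} not in packaged tables")
    table = _MU_RHO[symbol]
    e_tab = np.array([row[0] for row in table])
    mu_tab = np.array([row[1] for row in table])
    energy = np.asarray(energy_kev, dtype=float)
    if np.any(energy < e_tab[0]) or np.any(energy > e_tab[-1]):
        raise EnergyRangeError(
            f"energy outside tabulated range [{e_tab[0]}, {e_tab[-1]}] keV "
            f"for {symbol}"
        )
    out = np.exp(np.interp(np.log(energy), np.log(e_tab), np.log(mu_tab)))
    return float(out) if np.isscalar(energy_kev) else out


def compound_mass_attenuation(fractions: dict[str, float], energy_kev):
    """mu/rho of a mixture from element mass fractions (mixture rule)."""
    energy = np.asarray(energy_kev, dtype=float)
    out = np.zeros_like(energy)
    for sym, w in fractions.items():
        out = out + w * element_mass_attenuation(sym, energy)
    return float(out) if np.isscalar(energy_kev) else out
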