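"""Physical constants and isotope abundance data.

Constants are CODATA 2018 exact SI values. The gas constant is also kept in
cal mol^-1 K^-1 because activation parameters are conventionally reported in
kcal/cal units in coordination chemistry.

Isotope abundances are the IUPAC 2021 representative values, aggregated at
nominal (unit) mass resolution: each entry maps an element symbol to a list
of (nominal mass offset from the lightest isotope, abundance). ``D`` is an
explicit element for site-specific deuteration (no H/D scrambling).
"""

from __future__ import annotations

# CODATA 2018 (exact by SI definition)
BOLTZMANN_J_PER_K = 1.380649e-23
PLANCK_J_S = 6.62607015e-34
GAS_CONSTANT_CAL = 1.98720425864083  # cal mol^-1 K^-1
STANDARD_TEMPERATURE_K = 298.15  # 25 degC

KELVIN_OFFSET = 273.15

# element -> [(nominal offset, abundance), ...]; offsets increasing, abundances sum to 1
ISOTOPE_ABUNDANCES: dict[str, list[tuple[int, float]]] = {
    "H": [(0, 0.999885), (1, 0.000115)],
    "D": [(0, 1.0)],  # enriched label, treated as pure
    "C": [(0, 0.9893), (1, 0.0107)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "F": [(0, 1.0)],
    "P": [(0, 1.0)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)],
    "Cl": [(0, 0.7576), (2, 0.2424)],
    "Co": [(0, 1.0)],
    "Mn": [(0, 1.0)],
}
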