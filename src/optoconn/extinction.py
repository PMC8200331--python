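"""Hemoglobin extinction coefficients for dual-wavelength spectroscopy.

Values are molar extinction coefficients in cm^-1 / (mol/L) at the two
acquisition wavelengths, taken from the compiled tabulation of W. B. Gratzer
and N. Kollias as distributed by S. Prahl (Oregon Medical Laser Center,
"Optical absorption of hemoglobin", https://omlc.org/spectra/hemoglobin/).
The table is configurable: any mapping wavelength -> (eps_HbO, eps_HbR) with
an invertible 2x2 system can be passed wherever a default is used.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError

# wavelength (nm) -> (epsilon_HbO, epsilon_HbR) in cm^-1 M^-1
EXTINCTION_CM_PER_M = {
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}


def extinction_matrix(wavelengths_nm=(760.0, 850.0), table=None) -> np.ndarray:
    """2x2 matrix E with rows = wavelengths, columns = (HbO, HbR).

    Raises ConfigError if a wavelength is missing from the table or the pair
    is singular (the two wavelengths carry no independent information).
    """
    table = EXTINCTION_CM_PER_M if table is None else table
    rows = []
    for wl in wavelengths_nm:
        key = float(wl)
        if key not in table:
            raise ConfigError(f"no extinction coefficients tabulated at {wl} nm")
        rows.append(table[key])
    E = np.asarray(rows, dtype=float)
    if abs(np.linalg.det(E)) < 1e-9 * np.abs(E).max() ** 2:
        raise ConfigError(f"singular extinction pair for wavelengths {wavelengths_nm}")
    return E
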