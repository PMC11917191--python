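"""Modified Beer-Lambert conversion between optical density and hemoglobin.

The change in optical density at wavelength λ over a channel of geometric
source-detector separation d and differential pathlength factor DPF is

    ΔOD_λ = (ε_HbO,λ · ΔHbO + ε_HbR,λ · ΔHbR) · d · DPF

with ε the molar extinction coefficients.  Two wavelengths give a 2×2
linear system per channel, inverted to recover ΔHbO/ΔHbR.  Concentrations
are handled in µmol/L, distances in mm, extinction coefficients in
cm⁻¹/(mol/L).

The shipped extinction values are the widely used compiled hemoglobin
spectra (Gratzer/Kollias compilation as distributed with Homer); they are
swappable via the ``extinction`` argument.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EXTINCTION_CM_PER_M", "extinction_matrix", "conc_to_od", "od_to_conc"]

#: wavelength (nm) -> (ε_HbO, ε_HbR) in cm^-1 / (mol/L)
EXTINCTION_CM_PER_M: dict[float, tuple[float, float]] = {
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}


def extinction_matrix(
    wavelengths: tuple[float, float],
    extinction: dict[float, tuple[float, float]] | None = None,
) -> np.ndarray:
    """2×2 matrix E with E[i] = (ε_HbO, ε_HbR) at wavelengths[i]."""
    table = EXTINCTION_CM_PER_M if extinction is None else extinction
    try:
        e = np.array([table[float(w)] for w in wavelengths], dtype=float)
    except KeyError as err:
        raise KeyError(f"no extinction coefficients for wavelength {err}") from None
    if abs(np.linalg.det(e)) < 1e-9:
        raise ValueError("extinction matrix is singular; check coefficient table")
    return e


def _pathlength_cm(distance_mm: float, dpf: float) -> float:
    return (distance_mm / 10.0) * dpf


def conc_to_od(
    hbo_um: np.ndarray,
    hbr_um: np.ndarray,
    distance_mm: float,
    dpf: float = 5.1,
    wavelengths: tuple[float, float] = (760.0, 850.0),
    extinction: dict[float, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Forward-project ΔHbO/ΔHbR (µM) to ΔOD, shape (2, n_times)."""
    e = extinction_matrix(wavelengths, extinction)
    conc_molar = np.vstack([hbo_um, hbr_um]) * 1e-6
    return e @ conc_molar * _pathlength_cm(distance_mm, dpf)


def od_to_conc(
    od: np.ndarray,
    distance_mm: float,
    dpf: float = 5.1,
    wavelengths: tuple[float, float] = (760.0, 850.0),
    extinction: dict[float, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert ΔOD (2, n_times) to (ΔHbO, ΔHbR) in µM."""
    od = np.asarray(od, dtype=float)
    if od.ndim != 2 or od.shape[0] != 2:
        raise ValueError("od must have shape (2, n_times)")
    e = extinction_matrix(wavelengths, extinction)
    conc_molar = np.linalg.solve(e, od) / _pathlength_cm(distance_mm, dpf)
    hbo_um, hbr_um = conc_molar * 1e6
    return hbo_um, hbr_um
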