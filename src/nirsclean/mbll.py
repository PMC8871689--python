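"""Modified Beer–Lambert law: dual-wavelength ΔOD to Δ[HbO2]/Δ[Hb].

The conversion is the linear map

    Δ[HbO2] = (a1·ΔOD_λ1 + a2·ΔOD_λ2) / L
    Δ[Hb]   = (b1·ΔOD_λ1 + b2·ΔOD_λ2) / L

where L is the measuring depth of the probes and the mixing coefficients
(a1, a2, b1, b2) depend on the wavelength pair. The package ships the
numeric coefficients for 735/850 nm as its default; for other wavelength
pairs the coefficients can be derived from extinction coefficients and
differential path factors by inverting the forward absorption model
(:func:`coefficients_from_extinction`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MBLLCoefficients:
    """Mixing coefficients of the ΔOD → hemoglobin conversion.

    ``L`` is the path/depth term (any length unit, used consistently);
    the conversion must be invertible, i.e. ``a1*b2 - a2*b1 != 0``.
    """

    a1: float
    a2: float
    b1: float
    b2: float
    L: float = 1.0
    lambda1: float | None = None
    lambda2: float | None = None

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"path term L must be positive, got {self.L}")
        if self.a1 * self.b2 - self.a2 * self.b1 == 0:
            raise ValueError("singular coefficient matrix: conversion not invertible")


#: coefficients for the 735 nm / 850 nm wavelength pair
DEFAULT_COEFFICIENTS = MBLLCoefficients(
    a1=330.1717,
    a2=-131.3958,
    b1=-127.6967,
    b2=184.5598,
    L=1.0,
    lambda1=735.0,
    lambda2=850.0,
)


@dataclass(frozen=True)
class ExtinctionParams:
    """Extinction coefficients and differential path factors at two wavelengths.

    ``eps_*_l1``/``eps_*_l2`` are molar extinction coefficients of Hb and
    HbO2 at wavelengths λ1 and λ2; ``dpf1``/``dpf2`` the differential path
    factors (>0). The 2×2 extinction matrix must be nonsingular.
    """

    eps_hb_l1: float
    eps_hb_l2: float
    eps_hbo2_l1: float
    eps_hbo2_l2: float
    dpf1: float
    dpf2: float

    def __post_init__(self) -> None:
        if self.dpf1 <= 0 or self.dpf2 <= 0:
            raise ValueError("differential path factors must be positive")
        det = self.eps_hbo2_l1 * self.eps_hb_l2 - self.eps_hbo2_l2 * self.eps_hb_l1
        if det == 0:
            raise ValueError("singular extinction matrix")


def od_to_hemo(
    dod1,
    dod2,
    coeffs: MBLLCoefficients = DEFAULT_COEFFICIENTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert ΔOD at the two wavelengths to (Δ[HbO2], Δ[Hb]) in µmol/L.

    Accepts scalars or arrays (applied elementwise). The map is linear:
    superposition and scaling hold exactly.
    """
    dod1 = np.asarray(dod1, dtype=float)
    dod2 = np.asarray(dod2, dtype=float)
    if not (np.all(np.isfinite(dod1)) and np.all(np.isfinite(dod2))):
        raise ValueError("optical-density inputs must be finite")
    hbo2 = (coeffs.a1 * dod1 + coeffs.a2 * dod2) / coeffs.L
    hb = (coeffs.b1 * dod1 + coeffs.b2 * dod2) / coeffs.L
    if hbo2.ndim == 0:
        return float(hbo2), float(hb)
    return hbo2, hb


def forward_od(
    hbo2,
    hb,
    ext: ExtinctionParams,
    L: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward absorption model: concentrations to ΔOD at both wavelengths.

    ΔOD_λi = DPF_λi · (ε_HbO2,λi · Δ[HbO2] + ε_Hb,λi · Δ[Hb]) · L
    """
    hbo2 = np.asarray(hbo2, dtype=float)
    hb = np.asarray(hb, dtype=float)
    dod1 = ext.dpf1 * (ext.eps_hbo2_l1 * hbo2 + ext.eps_hb_l1 * hb) * L
    dod2 = ext.dpf2 * (ext.eps_hbo2_l2 * hbo2 + ext.eps_hb_l2 * hb) * L
    return dod1, dod2


def coefficients_from_extinction(
    ext: ExtinctionParams,
    L: float = 1.0,
    lambda1: float | None = None,
    lambda2: float | None = None,
) -> MBLLCoefficients:
    """Derive mixing coefficients by inverting the forward absorption model.

    Solves the 2×2 linear system rather than using any closed-form
    fraction; the resulting coefficients satisfy
    ``od_to_hemo(forward_od(c, ext)) == c`` up to rounding.
    """
    m = np.array(
        [
            [ext.dpf1 * ext.eps_hbo2_l1, ext.dpf1 * ext.eps_hb_l1],
            [ext.dpf2 * ext.eps_hbo2_l2, ext.dpf2 * ext.eps_hb_l2],
        ]
    )
    try:
        inv = np.linalg.inv(m)
    except np.linalg.LinAlgError:
        raise ValueError("singular extinction matrix") from None
    return MBLLCoefficients(
        a1=float(inv[0, 0]),
        a2=float(inv[0, 1]),
        b1=float(inv[1, 0]),
        b2=float(inv[1, 1]),
        L=L,
        lambda1=lambda1,
        lambda2=lambda2,
    )
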