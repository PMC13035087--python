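"""Optical constants and the modified Beer-Lambert law (MBLL).

The MBLL relates optical-density change at wavelength lambda to hemoglobin
concentration changes::

    dOD(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] * L * DPF(lambda)

with extinction coefficients ``eps`` in cm^-1 mM^-1, source-detector
separation ``L`` in cm, concentrations in mM (the API uses uM and carries
the 1e-3 factor internally), and the dimensionless differential pathlength
factor DPF accounting for photon scattering. The 2x2 system over the two
wavelengths is inverted per channel and sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidParameterError

WAVELENGTHS_NM = (760.0, 850.0)

# Specific extinction coefficients, cm^-1 mM^-1 (units as tabulated for
# continuous-wave NIRS processing; a single pinned tabulation so forward
# simulation and inversion always agree).
DEFAULT_EXTINCTION = {
    760.0: {"hbo": 1.4866, "hbr": 3.8437},
    850.0: {"hbo": 2.5264, "hbr": 1.7986},
}

# General age- and wavelength-dependent DPF (Scholkmann-Wolf form):
# DPF(age, lambda) = a + b*age^c + d*lambda^3 + e*lambda^2 + f*lambda
DPF_COEFFS = {
    "a": 223.3,
    "b": 0.05624,
    "c": 0.8493,
    "d": -5.723e-7,
    "e": 0.001245,
    "f": -0.9025,
}

DEFAULT_PATHLENGTH_CM = 3.5  # standard octode-template source-detector separation


def dpf_for_age(age: float, wavelength: float, coeffs: dict | None = None) -> float:
    """Differential pathlength factor for an adult of ``age`` years.

    Monotonically increasing in age at fixed wavelength. Supported
    wavelengths are the instrument's 760 and 850 nm.
    """
    if not (18.0 <= age <= 100.0):
        raise InvalidParameterError(f"age {age} outside supported range [18, 100]")
    if wavelength not in WAVELENGTHS_NM:
        raise InvalidParameterError(
            f"wavelength {wavelength} nm unsupported; expected one of {WAVELENGTHS_NM}"
        )
    c = coeffs or DPF_COEFFS
    lam = float(wavelength)
    return (
        c["a"]
        + c["b"] * age ** c["c"]
        + c["d"] * lam**3
        + c["e"] * lam**2
        + c["f"] * lam
    )


@dataclass(frozen=True)
class ExtinctionTable:
    """eps_HbO / eps_HbR at both wavelengths, cm^-1 mM^-1."""

    table: dict = field(default_factory=lambda: DEFAULT_EXTINCTION)

    def matrix(self, wavelengths=WAVELENGTHS_NM) -> np.ndarray:
        """Rows = wavelengths, columns = (HbO, HbR)."""
        try:
            E = np.array(
                [[self.table[w]["hbo"], self.table[w]["hbr"]] for w in wavelengths]
            )
        except KeyError as exc:
            raise ConfigurationError(f"extinction table missing entry: {exc}") from exc
        if abs(np.linalg.det(E)) < 1e-12:
            raise ConfigurationError("extinction matrix is singular")
        return E


def mbll_forward(
    hbo_uM: np.ndarray,
    hbr_uM: np.ndarray,
    age: float,
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM,
    extinction: ExtinctionTable | None = None,
    wavelengths=WAVELENGTHS_NM,
) -> np.ndarray:
    """Map (channels x time) concentration changes in uM to OD, shape
    (channels, wavelengths, time)."""
    ext = extinction or ExtinctionTable()
    E = ext.matrix(wavelengths)
    dpf = np.array([dpf_for_age(age, w) for w in wavelengths])
    conc_mM = np.stack([hbo_uM, hbr_uM], axis=0) * 1e-3  # (2, ch, t)
    # od[ch, iw, t] = sum_k E[iw, k] * conc[k, ch, t] * L * dpf[iw]
    od = np.einsum("wk,kct->cwt", E, conc_mM) * pathlength_cm
    od *= dpf[None, :, None]
    return od


def mbll_inverse(
    od: np.ndarray,
    age: float,
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM,
    extinction: ExtinctionTable | None = None,
    wavelengths=WAVELENGTHS_NM,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert OD (channels x wavelengths x time) to (hbo_uM, hbr_uM, dpf)."""
    ext = extinction or ExtinctionTable()
    E = ext.matrix(wavelengths)
    dpf = np.array([dpf_for_age(age, w) for w in wavelengths])
    Einv = np.linalg.inv(E)
    scaled = od / (pathlength_cm * dpf[None, :, None])  # eps * conc_mM
    conc_mM = np.einsum("kw,cwt->kct", Einv, scaled)
    hbo = conc_mM[0] * 1e3
    hbr = conc_mM[1] * 1e3
    return hbo, hbr, dpf
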