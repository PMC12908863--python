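"""Modified Beer-Lambert inversion of reflectance to haemoglobin changes.

Reflectance changes at a wavelength report changes in the tissue
absorption coefficient through the modified Beer-Lambert law,

    delta_mu_a(lambda) = -(1 / X(lambda)) * ln(I / I0),

with X(lambda) the effective photon pathlength.  With two wavelengths the
absorption changes are a linear mix of the oxy- and deoxy-haemoglobin
concentration changes through the natural-log extinction coefficients
zeta = ln(10) * eps:

    [dmu_a(l1)]   [zeta_HbO(l1)  zeta_HHb(l1)] [d_HbO]
    [dmu_a(l2)] = [zeta_HbO(l2)  zeta_HHb(l2)] [d_HHb]

This module applies the closed-form 2x2 inversion pixel-wise and reports
concentration changes in micromolar; d[HbT] = d[HbO] + d[HHb] exactly.
With a single isosbestic wavelength (HbO and HHb coefficients equal),
the percentage reflectance change serves as a total-haemoglobin proxy.

Unit convention: eps and zeta in cm^-1 M^-1, X in cm, delta_mu_a in
cm^-1, concentrations in uM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, NearSingularMatrixError
from .spectra import ExtinctionMatrix, find_isosbestic
from .stack_io import RelativeStack

__all__ = [
    "AbsorptionChange",
    "HaemoglobinChange",
    "absorption_change",
    "solve_haemoglobin",
    "isosbestic_proxy",
    "NonIsosbesticWarning",
]

M_TO_UM = 1e6


class NonIsosbesticWarning(UserWarning):
    """The single-wavelength proxy is used away from an isosbestic point."""


@dataclass
class AbsorptionChange:
    """Per-pixel absorption-coefficient change series, cm^-1."""

    delta_mua: np.ndarray  # (t, h, w)
    wavelength_nm: float
    timestamps: np.ndarray | None = None
    invalid_mask: np.ndarray | None = None  # (h, w) pixels with bad ratios


@dataclass
class HaemoglobinChange:
    """Per-pixel concentration-change series, uM relative to baseline."""

    d_hbo: np.ndarray
    d_hhb: np.ndarray
    d_hbt: np.ndarray
    wavelengths_nm: tuple[float, float]
    timestamps: np.ndarray | None = None
    invalid_mask: np.ndarray | None = None


def absorption_change(ratios: RelativeStack, x_cm: float) -> AbsorptionChange:
    """Absorption-coefficient change from relative intensity.

    ``delta_mu_a = -(1/X) * ln(I/I0)`` per pixel and frame.  Non-positive
    ratios cannot be log-transformed; those pixels are NaN in the output
    and reported in ``invalid_mask``.
    """
    if not (x_cm > 0):
        raise InvalidArgumentError("pathlength must be > 0")
    r = np.asarray(ratios.ratios, dtype=float)
    bad = ~(r > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dmua = -np.log(np.where(bad, np.nan, r)) / float(x_cm)
    invalid = bad.any(axis=0)
    lam = ratios.channel.wavelength_nm if ratios.channel is not None else np.nan
    return AbsorptionChange(dmua, lam, timestamps=ratios.timestamps,
                            invalid_mask=invalid if invalid.any() else None)


def solve_haemoglobin(dmua1: AbsorptionChange, dmua2: AbsorptionChange,
                      zmat: ExtinctionMatrix) -> HaemoglobinChange:
    """Closed-form two-wavelength inversion to d[HbO], d[HHb], d[HbT].

    ``zmat`` rows must correspond to the wavelengths of ``dmua1`` and
    ``dmua2`` in that order.  The explicit 2x2 solution is

        d_HHb = (z_HbO(l1)*dmu(l2) - z_HbO(l2)*dmu(l1))
                / (z_HbO(l1)*z_HHb(l2) - z_HbO(l2)*z_HHb(l1))
        d_HbO = (z_HHb(l1)*dmu(l2) - z_HHb(l2)*dmu(l1))
                / (z_HHb(l1)*z_HbO(l2) - z_HHb(l2)*z_HbO(l1))

    applied pixel-wise, with molar results scaled to uM and
    d_HbT = d_HbO + d_HHb pointwise.
    """
    a1 = np.asarray(dmua1.delta_mua, dtype=float)
    a2 = np.asarray(dmua2.delta_mua, dtype=float)
    if a1.shape != a2.shape:
        raise InvalidArgumentError(
            f"absorption stacks must share a shape, got {a1.shape} vs {a2.shape}")
    (z_hbo1, z_hhb1), (z_hbo2, z_hhb2) = zmat.matrix
    det = z_hbo1 * z_hhb2 - z_hbo2 * z_hhb1
    if det == 0 or not np.isfinite(det):
        raise NearSingularMatrixError("extinction matrix is singular")
    d_hhb = (z_hbo1 * a2 - z_hbo2 * a1) / det
    d_hbo = (z_hhb1 * a2 - z_hhb2 * a1) / (-det)
    d_hbo = d_hbo * M_TO_UM
    d_hhb = d_hhb * M_TO_UM
    invalid = None
    masks = [m for m in (dmua1.invalid_mask, dmua2.invalid_mask) if m is not None]
    if masks:
        invalid = np.logical_or.reduce(masks)
    return HaemoglobinChange(d_hbo, d_hhb, d_hbo + d_hhb,
                             zmat.wavelengths_nm,
                             timestamps=dmua1.timestamps,
                             invalid_mask=invalid)


def isosbestic_proxy(ratios: RelativeStack, extinction_table=None,
                     tolerance_nm: float = 5.0) -> np.ndarray:
    """Single-wavelength total-haemoglobin proxy, percent reflectance change.

    Returns ``100 * (I/I0 - 1)``.  At an isosbestic wavelength HbO and
    HHb absorb equally, so an increase in total haemoglobin darkens the
    image and drives the proxy negative.  If an extinction table is
    supplied, the channel wavelength is checked against detected
    isosbestic points and a :class:`NonIsosbesticWarning` is raised (not
    an error) when none lies within ``tolerance_nm``.
    """
    lam = ratios.channel.wavelength_nm if ratios.channel is not None else None
    if extinction_table is not None and lam is not None:
        lo, hi = extinction_table.range_nm
        points = find_isosbestic(extinction_table, lo + 1e-9, hi - 1e-9)
        if not points or min(abs(lam - p) for p in points) > tolerance_nm:
            warnings.warn(
                f"{lam} nm is more than {tolerance_nm} nm from any isosbestic "
                "point; the reflectance proxy mixes HbO and HHb contributions",
                NonIsosbesticWarning,
            )
    return 100.0 * (np.asarray(ratios.ratios, dtype=float) - 1.0)
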