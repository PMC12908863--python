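"""Haemoglobin extinction spectra and photon pathlengths.

Dual-wavelength haemoglobin spectroscopy rests on two tabulated inputs: the
decadic molar extinction coefficients of oxy- (HbO) and deoxy-haemoglobin
(HHb) as a function of wavelength, and the effective photon pathlength
X(lambda) through cortical tissue.  This module loads and queries both,
converts decadic coefficients to their natural-log form (zeta = ln(10)*eps),
locates isosbestic points (wavelengths where the HbO and HHb coefficients
are equal, so absorption reports total haemoglobin only), and assembles the
2x2 coefficient matrix inverted by :mod:`wfoi.hemodynamics`.

The packaged default table (``data/hb_extinction_synthetic.csv``) is a
synthetic compilation: a smooth curve through literature-standard band
parameters of human haemoglobin in water (tetramer molar extinction,
cm^-1 M^-1; HbO Q-bands at 542/577 nm, HHb band at 555 nm, green-red
isosbestic points near 500, 529, 545, 570 and 584 nm, standard red-region
magnitudes).  For quantitative work users should supply their preferred
published table via :meth:`ExtinctionTable.from_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import (
    DegenerateSpectraError,
    InvalidArgumentError,
    NearSingularMatrixError,
    OutOfRangeError,
)

LN10 = float(np.log(10.0))

__all__ = [
    "LN10",
    "ExtinctionTable",
    "PathlengthTable",
    "ExtinctionMatrix",
    "to_natural_log_coefficient",
    "interpolate_extinction",
    "find_isosbestic",
    "extinction_matrix",
    "load_default_extinction",
    "load_default_pathlengths",
]


def to_natural_log_coefficient(eps):
    """Convert a decadic extinction coefficient to natural-log form.

    The Beer-Lambert law can be written with base-10 (``10**(-eps*c*X)``)
    or base-e (``exp(-zeta*c*X)``) attenuation; the coefficients differ by
    a factor ln(10), i.e. ``zeta = ln(10) * eps``.

    Parameters
    ----------
    eps : float or array_like
        Decadic molar extinction coefficient(s), cm^-1 M^-1.  Must be
        finite and non-negative.

    Returns
    -------
    float or ndarray
        ``ln(10) * eps`` in the same units.
    """
    arr = np.asarray(eps, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError("extinction coefficient must be finite")
    if np.any(arr < 0):
        raise InvalidArgumentError("extinction coefficient must be >= 0")
    out = LN10 * arr
    return float(out) if np.isscalar(eps) or arr.ndim == 0 else out


@dataclass(frozen=True)
class ExtinctionTable:
    """Tabulated decadic molar extinction of HbO and HHb vs wavelength.

    Attributes
    ----------
    wavelength_nm : ndarray
        Strictly increasing wavelength grid, nm.
    eps_hbo, eps_hhb : ndarray
        Decadic molar extinction coefficients, cm^-1 M^-1 (tetramer).
    """

    wavelength_nm: np.ndarray
    eps_hbo: np.ndarray
    eps_hhb: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.wavelength_nm, dtype=float)
        hbo = np.asarray(self.eps_hbo, dtype=float)
        hhb = np.asarray(self.eps_hhb, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise InvalidArgumentError("wavelength grid must be 1-D with >= 2 points")
        if not (lam.shape == hbo.shape == hhb.shape):
            raise InvalidArgumentError("columns must have matching length")
        if np.any(np.diff(lam) <= 0):
            raise InvalidArgumentError("wavelengths must be strictly increasing")
        if np.any(hbo < 0) or np.any(hhb < 0):
            raise InvalidArgumentError("extinction coefficients must be >= 0")
        object.__setattr__(self, "wavelength_nm", lam)
        object.__setattr__(self, "eps_hbo", hbo)
        object.__setattr__(self, "eps_hhb", hhb)

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        """Load from a CSV with header ``wavelength_nm,eps_hbo,eps_hhb``."""
        import pandas as pd

        df = pd.read_csv(path)
        required = {"wavelength_nm", "eps_hbo", "eps_hhb"}
        if not required.issubset(df.columns):
            raise InvalidArgumentError(
                f"extinction CSV needs columns {sorted(required)}, got {list(df.columns)}"
            )
        return cls(df["wavelength_nm"].to_numpy(),
                   df["eps_hbo"].to_numpy(), df["eps_hhb"].to_numpy())


@dataclass(frozen=True)
class PathlengthTable:
    """Effective photon pathlength X(lambda) per wavelength, cm."""

    x_cm: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for lam, x in dict(self.x_cm).items():
            x = float(x)
            if not np.isfinite(x) or x <= 0:
                raise InvalidArgumentError(f"pathlength at {lam} nm must be > 0, got {x}")
            clean[float(lam)] = x
        object.__setattr__(self, "x_cm", clean)

    def get(self, wavelength_nm: float, tol_nm: float = 1.0) -> float:
        """Pathlength at the given wavelength (nearest entry within tol)."""
        lam = float(wavelength_nm)
        if lam in self.x_cm:
            return self.x_cm[lam]
        keys = np.array(sorted(self.x_cm))
        i = int(np.argmin(np.abs(keys - lam)))
        if abs(keys[i] - lam) > tol_nm:
            raise OutOfRangeError(
                f"no pathlength entry within {tol_nm} nm of {lam} nm "
                f"(available: {sorted(self.x_cm)})"
            )
        return self.x_cm[float(keys[i])]

    @classmethod
    def from_yaml(cls, path) -> "PathlengthTable":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def interpolate_extinction(table: ExtinctionTable, lam: float,
                           mode: str = "linear") -> tuple[float, float]:
    """Extinction pair (eps_hbo, eps_hhb) at an arbitrary wavelength.

    ``mode='linear'`` interpolates between the bracketing grid points;
    ``mode='nearest'`` returns the closest grid entry.  No extrapolation:
    wavelengths outside the table raise :class:`OutOfRangeError`.
    """
    lam = float(lam)
    lo, hi = table.range_nm
    if not (lo <= lam <= hi):
        raise OutOfRangeError(f"{lam} nm outside table range [{lo}, {hi}] nm")
    if mode == "nearest":
        i = int(np.argmin(np.abs(table.wavelength_nm - lam)))
        return float(table.eps_hbo[i]), float(table.eps_hhb[i])
    if mode != "linear":
        raise InvalidArgumentError(f"unknown interpolation mode {mode!r}")
    return (float(np.interp(lam, table.wavelength_nm, table.eps_hbo)),
            float(np.interp(lam, table.wavelength_nm, table.eps_hhb)))


def find_isosbestic(table: ExtinctionTable, lo: float, hi: float) -> list[float]:
    """Wavelengths in [lo, hi] where the HbO and HHb curves cross.

    Scans the sign of ``eps_hbo - eps_hhb`` along the tabulated grid
    restricted to the window and refines each sign change by linear
    interpolation within its bracketing segment.  A plateau of exact
    equality flanked by opposite signs reports its midpoint.  Returns
    crossings sorted ascending.
    """
    lo, hi = float(lo), float(hi)
    tlo, thi = table.range_nm
    if not (lo < hi):
        raise InvalidArgumentError("require lo < hi")
    if lo < tlo or hi > thi:
        raise OutOfRangeError(f"[{lo}, {hi}] nm outside table range [{tlo}, {thi}] nm")

    inside = (table.wavelength_nm > lo) & (table.wavelength_nm < hi)
    lam = np.concatenate(([lo], table.wavelength_nm[inside], [hi]))
    d = (np.interp(lam, table.wavelength_nm, table.eps_hbo)
         - np.interp(lam, table.wavelength_nm, table.eps_hhb))
    if np.all(d == 0):
        raise DegenerateSpectraError(
            f"HbO and HHb spectra identical over [{lo}, {hi}] nm")

    crossings: list[float] = []
    n = len(lam)
    i = 0
    while i < n - 1:
        a, b = d[i], d[i + 1]
        if a == 0.0:
            # plateau (possibly length 1): find its end, report the midpoint
            # if the flanking signs differ
            j = i
            while j < n and d[j] == 0.0:
                j += 1
            left = d[i - 1] if i > 0 else 0.0
            right = d[j] if j < n else 0.0
            if left * right < 0 or (i == 0 and right != 0) or (j == n and left != 0):
                crossings.append(float(0.5 * (lam[i] + lam[j - 1])))
            i = j
            continue
        if a * b < 0:
            # linear zero crossing inside the segment
            crossings.append(float(lam[i] + (lam[i + 1] - lam[i]) * a / (a - b)))
        i += 1
    return sorted(crossings)


@dataclass(frozen=True)
class ExtinctionMatrix:
    """2x2 natural-log coefficient matrix for a wavelength pair.

    ``matrix[i, j]`` is ``zeta`` for wavelength i (rows: lam1, lam2) and
    species j (columns: HbO, HHb), in cm^-1 M^-1.
    """

    matrix: np.ndarray
    wavelengths_nm: tuple[float, float]
    condition_number: float

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))


def extinction_matrix(table: ExtinctionTable, lam1: float, lam2: float,
                      mode: str = "linear",
                      cond_threshold: float = 1e5) -> ExtinctionMatrix:
    """Build the natural-log extinction matrix for a wavelength pair.

    Entries are ``ln(10) * eps`` interpolated from the table; rows are
    indexed by wavelength (lam1, lam2) and columns by species (HbO, HHb).
    Raises :class:`NearSingularMatrixError` if the condition number
    exceeds ``cond_threshold`` — an ill-conditioned pair (e.g. two nearby
    or two isosbestic wavelengths) cannot separate HbO from HHb.
    """
    z1 = to_natural_log_coefficient(np.array(interpolate_extinction(table, lam1, mode)))
    z2 = to_natural_log_coefficient(np.array(interpolate_extinction(table, lam2, mode)))
    m = np.vstack([z1, z2])
    cond = float(np.linalg.cond(m))
    if not np.isfinite(cond) or cond > cond_threshold:
        raise NearSingularMatrixError(
            f"extinction matrix for ({lam1} nm, {lam2} nm) is near-singular "
            f"(condition number {cond:.3g} > {cond_threshold:g}); choose "
            "wavelengths with more distinct HbO/HHb contrast"
        )
    return ExtinctionMatrix(m, (float(lam1), float(lam2)), cond)


def load_default_extinction() -> ExtinctionTable:
    """The packaged synthetic haemoglobin extinction compilation."""
    with resources.as_file(
        resources.files("wfoi").joinpath("data/hb_extinction_synthetic.csv")
    ) as p:
        return ExtinctionTable.from_csv(p)


def load_default_pathlengths() -> PathlengthTable:
    """Packaged default pathlengths; experiment-specific, confirm per setup."""
    with resources.as_file(
        resources.files("wfoi").joinpath("data/pathlengths_default.yaml")
    ) as p:
        return PathlengthTable.from_yaml(p)
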