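"""Fluorescence spectra and Förster-theory calculations.

A :class:`Spectrum` is a wavelength-indexed curve — either an emission
spectrum in arbitrary units or an absorption spectrum scaled to molar
extinction (M⁻¹cm⁻¹).  From a donor emission spectrum and an acceptor
extinction spectrum the spectral overlap integral

    J = ∫ f̄_D(λ) ε_A(λ) λ⁴ dλ        [M⁻¹cm⁻¹nm⁴]

is computed by trapezoidal quadrature on the intersection of the two
wavelength supports, with f̄_D area-normalized over its tabulated range
(∫ f̄_D dλ = 1).  The Förster radius follows as

    R₀ = (8.79×10⁻⁵ · κ² · n⁻⁴ · QY_D · J)^(1/6)   [Å]

with κ² the dipole orientation factor (2/3 for freely rotating dyes),
n the refractive index of the medium, and QY_D the donor quantum yield.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "ForsterContext",
    "read_spectrum",
    "write_spectrum",
    "area_normalize",
    "overlap_integral",
    "forster_radius",
]

#: Valid spectrum kinds.
EMISSION = "emission_au"
ABSORPTION = "absorption_extinction"

# Förster prefactor for J in M^-1 cm^-1 nm^4 and R0 in Å, bundling
# 9000 ln(10) / (128 π^5 N_A) and the unit conversions.
FORSTER_PREFACTOR = 8.79e-5


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed curve on a strictly increasing nm grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelength grid, nm.  At least two points.
    values
        Non-negative spectral values.  Arbitrary units for emission;
        M⁻¹cm⁻¹ for extinction-scaled absorption.
    kind
        ``"emission_au"`` or ``"absorption_extinction"``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = EMISSION

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or v.ndim != 1 or wl.shape != v.shape:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(v)):
            raise ValueError("non-finite entries in spectrum")
        if np.any(v < 0):
            raise ValueError("spectral values must be non-negative")
        if self.kind not in (EMISSION, ABSORPTION):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")

    @property
    def peak_wavelength_nm(self) -> float:
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    def integral(self) -> float:
        """Trapezoidal integral over the tabulated range (per nm)."""
        return float(np.trapezoid(self.values, self.wavelengths_nm))

    def interpolate(self, grid_nm: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid_nm``; zero outside the support."""
        return np.interp(grid_nm, self.wavelengths_nm, self.values, left=0.0, right=0.0)

    def shifted(self, shift_nm: float) -> "Spectrum":
        """Return a copy translated along the wavelength axis."""
        return replace(self, wavelengths_nm=self.wavelengths_nm + shift_nm)

    def scaled_to_peak(self, peak_value: float) -> "Spectrum":
        """Rescale so the maximum equals ``peak_value`` (e.g. an EC)."""
        m = float(np.max(self.values))
        if m <= 0:
            raise ValueError("cannot scale an all-zero spectrum")
        return replace(self, values=self.values * (peak_value / m))


@dataclass(frozen=True)
class ForsterContext:
    """Photophysical environment entering R₀: κ² and refractive index."""

    kappa_squared: float = 0.6667
    refractive_index: float = 1.33

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa_squared <= 4.0:
            raise ValueError("kappa_squared must lie in [0, 4]")
        if self.refractive_index < 1.0:
            raise ValueError("refractive_index must be >= 1")


def read_spectrum(path: str | Path, kind: str = EMISSION) -> Spectrum:
    """Read a two-column CSV (``wavelength_nm,value``) into a Spectrum."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    wl = pd.to_numeric(df["wavelength_nm"], errors="raise").to_numpy(dtype=float)
    v = pd.to_numeric(df["value"], errors="raise").to_numpy(dtype=float)
    if np.any(np.diff(wl) == 0):
        raise ValueError(f"{path}: duplicated wavelength rows")
    return Spectrum(wl, v, kind=kind)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a Spectrum as a ``wavelength_nm,value`` CSV."""
    pd.DataFrame({"wavelength_nm": s.wavelengths_nm, "value": s.values}).to_csv(
        path, index=False
    )


def area_normalize(s: Spectrum) -> Spectrum:
    """Scale an emission spectrum so its trapezoidal integral over nm is 1.

    Only the tabulated range is used; no extrapolation.
    """
    if s.kind != EMISSION:
        raise ValueError("area normalization applies to emission spectra only")
    area = s.integral()
    if area <= 0:
        raise ValueError("cannot normalize a spectrum with zero area")
    return replace(s, values=s.values / area)


def _union_grid(a: Spectrum, b: Spectrum) -> np.ndarray:
    lo = max(a.wavelengths_nm[0], b.wavelengths_nm[0])
    hi = min(a.wavelengths_nm[-1], b.wavelengths_nm[-1])
    if lo >= hi:
        return np.empty(0)
    pts = np.union1d(a.wavelengths_nm, b.wavelengths_nm)
    pts = pts[(pts >= lo) & (pts <= hi)]
    # guarantee both endpoints of the overlap window are present
    pts = np.union1d(pts, [lo, hi])
    return pts


def overlap_integral(donor_em: Spectrum, acceptor_abs: Spectrum) -> float:
    """Spectral overlap integral J = ∫ f̄_D(λ) ε_A(λ) λ⁴ dλ.

    ``donor_em`` should be area-normalized (f̄_D, nm⁻¹) and
    ``acceptor_abs`` scaled so its peak equals the acceptor extinction
    coefficient (M⁻¹cm⁻¹).  Units of J: M⁻¹cm⁻¹nm⁴.  Both curves are
    linearly interpolated onto the union of their grids restricted to the
    overlapping wavelength range; the integral is trapezoidal.  Disjoint
    supports yield 0 with a warning.
    """
    grid = _union_grid(donor_em, acceptor_abs)
    if grid.size == 0:
        warnings.warn(
            "donor emission and acceptor absorption do not overlap; J = 0",
            stacklevel=2,
        )
        return 0.0
    fd = donor_em.interpolate(grid)
    ea = acceptor_abs.interpolate(grid)
    return float(np.trapezoid(fd * ea * grid**4, grid))


def forster_radius(
    J: float,
    quantum_yield_donor: float,
    ctx: ForsterContext | None = None,
) -> float:
    """Förster radius R₀ in Å from an overlap integral in M⁻¹cm⁻¹nm⁴.

    R₀⁶ = 8.79×10⁻⁵ · κ² · n⁻⁴ · QY_D · J  (Å⁶).
    """
    if J < 0:
        raise ValueError("overlap integral must be non-negative")
    if not 0.0 < quantum_yield_donor <= 1.0:
        raise ValueError("donor quantum yield must lie in (0, 1]")
    ctx = ctx or ForsterContext()
    r6 = (
        FORSTER_PREFACTOR
        * ctx.kappa_squared
        * ctx.refractive_index**-4
        * quantum_yield_donor
        * J
    )
    return float(r6 ** (1.0 / 6.0))
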