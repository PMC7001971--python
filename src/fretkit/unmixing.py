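"""Linear spectral unmixing and intensiometric FRET efficiency.

A mixed emission scan collected at donor excitation is decomposed into
weighted donor-only and acceptor-only reference components by
non-negative least squares.  With component weights W_D and W_A and the
two quantum yields, the sensitized-emission FRET efficiency is

    E = 100 · W_A / (W_A + W_D · QY_A / QY_D)
      = 100 · (W_A/QY_A) / (W_A/QY_A + W_D/QY_D)

i.e. the fraction of donor excitations emitted through the acceptor,
after converting each emission weight back to excitation events via the
corresponding quantum yield.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear, nnls

from .spectra import Spectrum

__all__ = [
    "EmissionScan",
    "UnmixResult",
    "linear_unmix",
    "spectral_fret_efficiency",
]

# Condition number of the reference design matrix above which the two
# references are treated as collinear and unmixing refuses to proceed.
COLLINEARITY_LIMIT = 1e8


@dataclass(frozen=True)
class EmissionScan:
    """An emission scan at fixed excitation (e.g. 490–750 nm at 470 nm)."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    excitation_nm: float = 470.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or wl.shape != it.shape or wl.size < 2:
            raise ValueError("scan must be 1-D with >= 2 matching points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("scan intensities must be non-negative")
        if self.excitation_nm >= wl[0]:
            raise ValueError("excitation wavelength must lie below the emission range")


@dataclass(frozen=True)
class UnmixResult:
    """Outcome of a two-component linear unmixing."""

    W_D: float
    W_A: float
    baseline: float
    fitted: np.ndarray
    rss: float
    r_squared: float


def linear_unmix(
    scan: EmissionScan,
    donor_ref: Spectrum,
    acceptor_ref: Spectrum,
    fit_baseline: bool = False,
) -> UnmixResult:
    """Decompose a scan into donor and acceptor reference components.

    References are linearly interpolated onto the scan grid and should be
    area-normalized on their own grids.  Weights are constrained
    non-negative (component weights are photon counts); the optional
    constant baseline is unconstrained.

    Raises
    ------
    ValueError
        If the interpolated references are collinear (condition number
        above ``COLLINEARITY_LIMIT``) or vanish on the scan grid.
    """
    grid = scan.wavelengths_nm
    d = donor_ref.interpolate(grid)
    a = acceptor_ref.interpolate(grid)
    if not d.any() or not a.any():
        raise ValueError("a reference spectrum vanishes on the scan grid")

    A = np.column_stack([d, a])
    # condition number on unit-scaled columns so it reflects shape, not scale
    cond = np.linalg.cond(A / np.linalg.norm(A, axis=0))
    if cond > COLLINEARITY_LIMIT:
        raise ValueError(
            f"donor and acceptor references are collinear on the scan grid "
            f"(condition number {cond:.3g} > {COLLINEARITY_LIMIT:.3g})"
        )

    y = scan.intensities
    if fit_baseline:
        Ab = np.column_stack([d, a, np.ones_like(y)])
        res = lsq_linear(Ab, y, bounds=([0, 0, -np.inf], [np.inf] * 3))
        wd, wa, b0 = res.x
        fitted = Ab @ res.x
    else:
        (wd, wa), _ = nnls(A, y)
        b0 = 0.0
        fitted = A @ np.array([wd, wa])

    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    return UnmixResult(
        W_D=float(wd), W_A=float(wa), baseline=float(b0),
        fitted=fitted, rss=rss, r_squared=r2,
    )


def spectral_fret_efficiency(
    res: UnmixResult,
    quantum_yield_donor: float,
    quantum_yield_acceptor: float,
    convention: str = "sensitized",
) -> float:
    """FRET efficiency (percent) from unmixing weights and quantum yields.

    ``convention="sensitized"`` (default) uses
    E = 100·W_A/(W_A + W_D·QY_A/QY_D); ``"literal"`` uses the alternative
    reading E = 100·W_A·(QY_A/QY_D)/(W_D + W_A), retained for comparison.
    """
    for qy in (quantum_yield_donor, quantum_yield_acceptor):
        if not 0.0 < qy <= 1.0:
            raise ValueError("quantum yields must lie in (0, 1]")
    wd, wa = res.W_D, res.W_A
    if wd + wa <= 0:
        raise ValueError("both component weights are zero")
    ratio = quantum_yield_acceptor / quantum_yield_donor
    if convention == "sensitized":
        return 100.0 * wa / (wa + wd * ratio)
    if convention == "literal":
        return 100.0 * wa * ratio / (wd + wa)
    raise ValueError(f"unknown convention {convention!r}")
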