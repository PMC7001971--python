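"""TCSPC decay fitting and FLIM-FRET efficiency.

Time-correlated single photon counting histograms are fit in tail mode:
only bins after the decay peak enter the fit, so no instrument-response
deconvolution is attempted.  The model is a sum of exponentials plus a
constant offset,

    m(t) = Σᵢ aᵢ · exp(−t/τᵢ) + c,

minimized by weighted least squares with Poisson (Neyman) weights
σ² = max(counts, 1).  FRET efficiency follows from the donor lifetime
shortening,

    E = 100 · (1 − τ_DA / τ_D),

where τ_DA is the donor lifetime in the presence of acceptor and τ_D the
donor-only lifetime.  Negative efficiencies (τ_DA > τ_D) are reported
as-is so donor-reference variability stays visible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "DecayCurve",
    "FlimStack",
    "LifetimeFitResult",
    "PhotobleachComparison",
    "read_decay",
    "write_decay",
    "read_flim_stack",
    "write_flim_stack",
    "sum_roi_decay",
    "tail_fit",
    "model_select",
    "flim_fret_efficiency",
    "lifetime_map",
    "photobleach_compare",
    "framewise_lifetimes",
]

#: Default minimum photons in a decay before tail fitting is attempted.
DEFAULT_MIN_TOTAL_COUNTS = 1000

#: Reduced chi-squared at or below which a fit counts as "well described".
CHI2_GOOD_FIT = 1.5


@dataclass(frozen=True)
class DecayCurve:
    """A time-binned photon-count histogram on a uniform grid.

    ``bin_times_ns`` are bin centers.  ``require_integer`` may be set to
    False for noiseless expected-count curves (real-valued); measured or
    simulated photon data must be integer-valued.
    """

    bin_times_ns: np.ndarray
    counts: np.ndarray
    n_frames: int = 1
    meta: dict = field(default_factory=dict)
    require_integer: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.bin_times_ns, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "bin_times_ns", t)
        object.__setattr__(self, "counts", c)
        if t.ndim != 1 or t.shape != c.shape or t.size < 2:
            raise ValueError("decay must be 1-D with >= 2 matching bins")
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise ValueError("bin times must be increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9:
            raise ValueError("bin width must be uniform")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if self.require_integer and np.any(np.abs(c - np.round(c)) > 1e-9):
            raise ValueError("counts must be integer-valued")

    @property
    def bin_width_ns(self) -> float:
        return float(self.bin_times_ns[1] - self.bin_times_ns[0])

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class FlimStack:
    """A photon-count cube indexed (y, x, time_bin)."""

    cube: np.ndarray
    bin_times_ns: np.ndarray

    def __post_init__(self) -> None:
        cube = np.asarray(self.cube)
        t = np.asarray(self.bin_times_ns, dtype=float)
        object.__setattr__(self, "cube", cube)
        object.__setattr__(self, "bin_times_ns", t)
        if cube.ndim != 3:
            raise ValueError("cube must be (y, x, time_bin)")
        if cube.shape[2] != t.size:
            raise ValueError("time axis length must match bin_times_ns")
        if np.any(cube < 0):
            raise ValueError("photon counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    @property
    def intensity_image(self) -> np.ndarray:
        """Per-pixel photon totals (marginal sum over time)."""
        return self.cube.sum(axis=2)


@dataclass(frozen=True)
class LifetimeFitResult:
    """Outcome of an exponential tail fit."""

    n_components: int
    lifetimes_ns: tuple[float, ...]  # descending: tau1 > tau2
    amplitudes: tuple[float, ...]
    offset: float
    fit_window: tuple[int, int]  # [start_bin, end_bin] inclusive
    chi2_reduced: float
    success: bool
    message: str = ""

    @property
    def tau_ns(self) -> float:
        """Principal (longest) lifetime."""
        return self.lifetimes_ns[0]

    @property
    def good_fit(self) -> bool:
        return self.success and self.chi2_reduced <= CHI2_GOOD_FIT


# ---------------------------------------------------------------------------
# I/O

def read_decay(path: str | Path) -> DecayCurve:
    """Read a ``time_ns,counts`` CSV into a DecayCurve."""
    df = pd.read_csv(path)
    if not {"time_ns", "counts"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns time_ns,counts")
    return DecayCurve(df["time_ns"].to_numpy(float), df["counts"].to_numpy(float))


def write_decay(decay: DecayCurve, path: str | Path) -> None:
    pd.DataFrame({"time_ns": decay.bin_times_ns, "counts": decay.counts}).to_csv(
        path, index=False
    )


def write_flim_stack(stack: FlimStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF (one page per time bin) plus a
    JSON sidecar ``<path>.json`` holding the bin times."""
    path = Path(path)
    pages = np.moveaxis(stack.cube.astype(np.uint32), 2, 0)
    tifffile.imwrite(path, pages)
    Path(str(path) + ".json").write_text(
        json.dumps({"bin_times_ns": stack.bin_times_ns.tolist()})
    )


def read_flim_stack(path: str | Path) -> FlimStack:
    path = Path(path)
    pages = tifffile.imread(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    cube = np.moveaxis(np.atleast_3d(pages), 0, 2)
    return FlimStack(cube, np.asarray(sidecar["bin_times_ns"], dtype=float))


# ---------------------------------------------------------------------------
# ROI aggregation

def sum_roi_decay(
    stack: FlimStack,
    roi_mask: np.ndarray,
    intensity_threshold: float = 0.0,
) -> DecayCurve:
    """Sum per-pixel histograms over a mask, keeping only pixels whose
    total photon count exceeds ``intensity_threshold``."""
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != stack.shape:
        raise ValueError("mask shape must match stack")
    if intensity_threshold < 0:
        raise ValueError("intensity threshold must be >= 0")
    qualifying = mask & (stack.intensity_image > intensity_threshold)
    if not qualifying.any():
        raise ValueError("no pixels qualify after thresholding")
    counts = stack.cube[qualifying].sum(axis=0)
    return DecayCurve(stack.bin_times_ns, counts.astype(float))


# ---------------------------------------------------------------------------
# Tail fitting

def _default_window(counts: np.ndarray) -> tuple[int, int]:
    """Tail window: two bins past the peak through the last occupied bin."""
    start = int(np.argmax(counts)) + 2
    nz = np.nonzero(counts > 0)[0]
    end = int(nz[-1]) if nz.size else counts.size - 1
    return start, end


def _log_linear_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Initial (amplitude, tau) via weighted regression of log counts."""
    pos = y > 0
    if pos.sum() < 2:
        return max(float(y.max()), 1.0), max(float(t[-1] - t[0]), 1.0)
    coef = np.polyfit(t[pos], np.log(y[pos]), 1, w=np.sqrt(y[pos]))
    slope, intercept = coef
    tau = -1.0 / slope if slope < 0 else float(t[-1] - t[0])
    return float(np.exp(intercept)), float(max(tau, 1e-3))


def _fit_decay_arrays(
    t: np.ndarray,
    y: np.ndarray,
    n_components: int,
    window: tuple[int, int],
) -> LifetimeFitResult:
    i0, i1 = window
    tw = t[i0 : i1 + 1]
    yw = y[i0 : i1 + 1]
    n_params = 2 * n_components + 1
    if tw.size < 3 * n_params:
        raise ValueError(
            f"fit window of {tw.size} bins is shorter than 3x the "
            f"{n_params} free parameters"
        )
    sigma = np.sqrt(np.maximum(yw, 1.0))

    offset0 = float(np.mean(yw[-max(1, yw.size // 20):]))
    a0, tau0 = _log_linear_guess(tw, np.clip(yw - offset0, 0, None))

    params = lmfit.Parameters()
    params.add("offset", value=max(offset0, 0.0), min=0.0)
    if n_components == 1:
        params.add("a1", value=max(a0, 1e-6), min=0.0)
        params.add("tau1", value=tau0, min=1e-6)
    else:
        # slow component from the late half, fast from the early half
        mid = tw.size // 2
        a_slow, tau_slow = _log_linear_guess(
            tw[mid:], np.clip(yw[mid:] - offset0, 0, None)
        )
        a_fast, tau_fast = _log_linear_guess(
            tw[:mid], np.clip(yw[:mid] - offset0, 0, None)
        )
        if tau_fast >= tau_slow:
            tau_fast = tau_slow / 3.0
        params.add("a1", value=max(a_slow, 1e-6), min=0.0)
        params.add("tau1", value=tau_slow, min=1e-6)
        params.add("a2", value=max(a_fast - a_slow, a_slow * 0.5), min=0.0)
        params.add("tau2", value=tau_fast, min=1e-6)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = np.full_like(tw, p["offset"].value)
        for i in range(1, n_components + 1):
            model = model + p[f"a{i}"].value * np.exp(-tw / p[f"tau{i}"].value)
        return (yw - model) / sigma

    minres = lmfit.minimize(
        residual, params, method="leastsq", xtol=1e-12, ftol=1e-12, max_nfev=20000
    )
    p = minres.params
    comps = sorted(
        ((p[f"tau{i}"].value, p[f"a{i}"].value) for i in range(1, n_components + 1)),
        reverse=True,
    )
    dof = max(tw.size - n_params, 1)
    chi2_red = float(np.sum(residual(p) ** 2)) / dof
    success = bool(minres.success)
    if not success:
        logger.warning("tail fit did not converge: %s", minres.message)
    return LifetimeFitResult(
        n_components=n_components,
        lifetimes_ns=tuple(float(tau) for tau, _ in comps),
        amplitudes=tuple(float(a) for _, a in comps),
        offset=float(p["offset"].value),
        fit_window=(i0, i1),
        chi2_reduced=chi2_red,
        success=success,
        message=str(minres.message),
    )


def tail_fit(
    decay: DecayCurve,
    n_components: int = 1,
    fit_window: tuple[int, int] | None = None,
    min_total_counts: float = DEFAULT_MIN_TOTAL_COUNTS,
) -> LifetimeFitResult:
    """Fit Σ aᵢ·exp(−t/τᵢ) + offset to the decay tail.

    Poisson-weighted least squares over the window (default: from two
    bins past the peak to the last occupied bin).  Non-convergence is
    flagged on the result, not raised.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if decay.total_counts < min_total_counts:
        raise ValueError(
            f"decay has {decay.total_counts:.0f} counts; "
            f"minimum for fitting is {min_total_counts:.0f}"
        )
    window = fit_window or _default_window(decay.counts)
    if window[0] < int(np.argmax(decay.counts)):
        raise ValueError("fit window must start at or after the peak bin")
    return _fit_decay_arrays(decay.bin_times_ns, decay.counts, n_components, window)


def model_select(
    decay: DecayCurve,
    chi2_improvement_threshold: float = 0.20,
    **fit_kwargs,
) -> int:
    """Choose 1 vs 2 exponential components.

    Returns 2 only when the biexponential fit lowers reduced χ² by more
    than the given relative threshold; otherwise the decay is considered
    well described by a single exponential.
    """
    fit1 = tail_fit(decay, n_components=1, **fit_kwargs)
    fit2 = tail_fit(decay, n_components=2, **fit_kwargs)
    if fit1.chi2_reduced <= 0:
        return 1
    improvement = (fit1.chi2_reduced - fit2.chi2_reduced) / fit1.chi2_reduced
    return 2 if improvement > chi2_improvement_threshold else 1


# ---------------------------------------------------------------------------
# Efficiency

def flim_fret_efficiency(tau_DA_ns: float, tau_D_ns: float) -> float:
    """E = 100·(1 − τ_DA/τ_D), percent.  Negative values are reported."""
    if tau_DA_ns <= 0 or tau_D_ns <= 0:
        raise ValueError("lifetimes must be positive")
    e = 100.0 * (1.0 - tau_DA_ns / tau_D_ns)
    if e < 0:
        logger.info("negative FRET efficiency %.2f%% (tau_DA > tau_D)", e)
    return e


@dataclass(frozen=True)
class PhotobleachComparison:
    """Paired donor-lifetime efficiencies before/after acceptor bleaching."""

    E_pre: float
    E_post: float

    @property
    def delta_E(self) -> float:
        return self.E_post - self.E_pre


def photobleach_compare(
    pre_fit: LifetimeFitResult,
    post_fit: LifetimeFitResult,
    tau_D_ns: float,
) -> PhotobleachComparison:
    """FRET efficiency before vs after acceptor photobleaching."""
    if not (pre_fit.success and post_fit.success):
        raise ValueError("both fits must have converged")
    return PhotobleachComparison(
        E_pre=flim_fret_efficiency(pre_fit.tau_ns, tau_D_ns),
        E_post=flim_fret_efficiency(post_fit.tau_ns, tau_D_ns),
    )


# ---------------------------------------------------------------------------
# Maps and time series

def lifetime_map(
    stack: FlimStack,
    min_photons_per_pixel: int = 100,
) -> np.ndarray:
    """Per-pixel monoexponential tail-fit lifetime image.

    Pixels below ``min_photons_per_pixel`` total photons, or whose fit
    fails, are NaN.
    """
    if min_photons_per_pixel < 1:
        raise ValueError("min_photons_per_pixel must be >= 1")
    out = np.full(stack.shape, np.nan)
    intensity = stack.intensity_image
    t = stack.bin_times_ns
    for y, x in zip(*np.nonzero(intensity >= min_photons_per_pixel)):
        counts = stack.cube[y, x].astype(float)
        try:
            window = _default_window(counts)
            fit = _fit_decay_arrays(t, counts, 1, window)
        except ValueError:
            continue
        if fit.success:
            out[y, x] = fit.tau_ns
    return out


def framewise_lifetimes(
    blocks: Sequence[DecayCurve],
    **fit_kwargs,
) -> pd.DataFrame:
    """Per-frame-block tail fits for acquisition-stability analysis.

    Returns a table of (block, tau_ns, total_counts, chi2_reduced,
    success), one row per decay block in acquisition order.
    """
    if len(blocks) == 0:
        raise ValueError("at least one frame block is required")
    rows = []
    for i, decay in enumerate(blocks):
        fit = tail_fit(decay, n_components=1, **fit_kwargs)
        rows.append(
            {
                "block": i,
                "tau_ns": fit.tau_ns,
                "total_counts": decay.total_counts,
                "chi2_reduced": fit.chi2_reduced,
                "success": fit.success,
            }
        )
    return pd.DataFrame(rows)
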