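"""Ground-truth generators emulating the microscope and spectrometer.

Every analysis stage in this package has a matching forward model here:
skew-normal protein spectra, mixed emission scans built from the
sensitized-emission model, multinomial TCSPC photon histograms, FLIM
photon cubes of elliptical "cells" with per-cell mature-acceptor
fractions, two-channel confocal images with per-cell red/green slopes,
and multi-day cohorts following first-order maturation kinetics.  Each
generator is bit-reproducible under a fixed seed and returns a truth
table sufficient to score the downstream estimate; the noiseless limits
are exactly invertible by the corresponding analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .fluorophores import FLUOROPHORES, FluorophoreRecord
from .flim import DecayCurve, FlimStack
from .heterogeneity import TwoChannelImage
from .maturation import MaturationScenario, mature_fraction, mixture_decay_params
from .spectra import ABSORPTION, EMISSION, Spectrum, area_normalize
from .unmixing import EmissionScan

__all__ = [
    "GeneratorConfig",
    "FlimCellSpec",
    "ImageCellSpec",
    "tandem_scenario",
    "gen_spectrum",
    "gen_emission_scan",
    "expected_decay_counts",
    "gen_tcspc_decay",
    "gen_flim_stack",
    "gen_two_channel_image",
    "gen_cohort_timeseries",
]

#: FLIM-plateau efficiency adopted for fully mature tandem constructs —
#: the level the fast-maturing acceptors reach (donor lifetime 3.05 ns
#: dropping to ~2.22 ns).
DEFAULT_E_TRUE = 0.27

#: Donor-only (mNeonGreen) lifetime, ns.
DEFAULT_TAU_D_NS = 3.05

#: Default TCSPC histogram geometry: 256 bins over one 80 MHz period.
DEFAULT_BINS = 256
DEFAULT_RANGE_NS = 12.5


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared defaults for the synthetic cohort generators."""

    seed: int = 0
    fluorophores: dict[str, FluorophoreRecord] = field(
        default_factory=lambda: dict(FLUOROPHORES)
    )
    scan_noise_sigma: float = 0.0
    per_pixel_photons: float = 400.0
    image_shape: tuple[int, int] = (48, 48)
    cells_per_image: int = 8
    f_concentration: float = 30.0  # Beta concentration of per-cell jitter


def tandem_scenario(
    acceptor: str,
    E_true: float = DEFAULT_E_TRUE,
    tau_D_ns: float = DEFAULT_TAU_D_NS,
) -> MaturationScenario:
    """Maturation scenario for an mNeonGreen–acceptor tandem construct."""
    rec = FLUOROPHORES[acceptor]
    return MaturationScenario(
        t_half_min=rec.maturation_half_time_min, E_true=E_true, tau_D_ns=tau_D_ns
    )


# ---------------------------------------------------------------------------
# Spectra and emission scans

def gen_spectrum(
    peak_nm: float,
    width_nm: float,
    skew: float = 0.0,
    kind: str = EMISSION,
) -> Spectrum:
    """Smooth unimodal skew-normal spectrum on a 1 nm grid.

    The grid spans peak ± 5 widths and the curve's mode lands on
    ``peak_nm`` (within the 1 nm grid) for any skew.
    """
    if width_nm <= 0:
        raise ValueError("width must be positive")
    # locate the skew-normal mode numerically, then translate it onto the peak
    probe = np.linspace(-3 * width_nm, 3 * width_nm, 2001)
    mode = probe[np.argmax(sstats.skewnorm.pdf(probe, a=skew, loc=0, scale=width_nm))]
    grid = np.arange(peak_nm - 5 * width_nm, peak_nm + 5 * width_nm + 0.5)
    values = sstats.skewnorm.pdf(grid, a=skew, loc=peak_nm - mode, scale=width_nm)
    return Spectrum(grid, values, kind=kind)


def gen_emission_scan(
    E_true: float,
    donor_ref: Spectrum,
    acceptor_ref: Spectrum,
    quantum_yield_donor: float,
    quantum_yield_acceptor: float,
    direct_excitation_fraction: float = 0.0,
    amplitude: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    wavelengths_nm: np.ndarray | None = None,
    excitation_nm: float = 470.0,
) -> EmissionScan:
    """Forward model of a mixed donor+acceptor emission scan.

    scan = A·[(1−E)·QY_D·f̄_D + (E + direct)·QY_A·f̄_A] + N(0, σ²),
    with f̄ the area-normalized references.  With zero direct acceptor
    excitation and no noise, unmixing followed by the sensitized-emission
    formula recovers ``E_true`` exactly.
    """
    if not 0.0 <= E_true < 1.0:
        raise ValueError("E_true must lie in [0, 1)")
    if not 0.0 <= direct_excitation_fraction < 1.0:
        raise ValueError("direct excitation fraction must lie in [0, 1)")
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(490.0, 751.0)
    fd = area_normalize(donor_ref).interpolate(wavelengths_nm)
    fa = area_normalize(acceptor_ref).interpolate(wavelengths_nm)
    signal = amplitude * (
        (1.0 - E_true) * quantum_yield_donor * fd
        + (E_true + direct_excitation_fraction) * quantum_yield_acceptor * fa
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sigma, signal.shape)
    return EmissionScan(
        wavelengths_nm, np.clip(signal, 0, None), excitation_nm=excitation_nm
    )


# ---------------------------------------------------------------------------
# TCSPC decays

def _bin_probabilities(
    lifetimes: tuple[float, ...] | list[float],
    amplitudes: tuple[float, ...] | list[float],
    bins: int,
    range_ns: float,
    background_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin centers and per-bin photon probabilities for a mixture decay.

    Per-component bin content is the closed-form integral of
    exp(−t/τ) over each bin, normalized over the acquisition window.
    """
    amps = np.asarray(amplitudes, dtype=float)
    taus = np.asarray(lifetimes, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    if abs(amps.sum() - 1.0) > 1e-9 or np.any(amps < 0):
        raise ValueError("amplitudes must be a simplex (non-negative, sum 1)")
    if not 0.0 <= background_fraction < 1.0:
        raise ValueError("background fraction must lie in [0, 1)")
    edges = np.linspace(0.0, range_ns, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    prob = np.zeros(bins)
    for a, tau in zip(amps, taus):
        content = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
        prob += a * content / (1.0 - np.exp(-range_ns / tau))
    prob = (1.0 - background_fraction) * prob + background_fraction / bins
    return centers, prob


def expected_decay_counts(
    lifetimes,
    amplitudes,
    total_photons: float,
    bins: int = DEFAULT_BINS,
    range_ns: float = DEFAULT_RANGE_NS,
    background_fraction: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless expected bin contents (bin centers, real-valued counts)."""
    centers, prob = _bin_probabilities(
        lifetimes, amplitudes, bins, range_ns, background_fraction
    )
    return centers, total_photons * prob


def gen_tcspc_decay(
    lifetimes,
    amplitudes,
    total_photons: float,
    background_fraction: float = 0.0,
    bins: int = DEFAULT_BINS,
    range_ns: float = DEFAULT_RANGE_NS,
    seed: int | None = None,
) -> DecayCurve:
    """Simulated photon-counting histogram of a mixture decay.

    ``total_photons`` are placed multinomially over the bins with
    probabilities proportional to the closed-form bin integrals (plus a
    uniform background component).
    """
    if total_photons < 1:
        raise ValueError("total_photons must be >= 1")
    centers, prob = _bin_probabilities(
        lifetimes, amplitudes, bins, range_ns, background_fraction
    )
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(round(total_photons)), prob)
    return DecayCurve(centers, counts.astype(float))


# ---------------------------------------------------------------------------
# FLIM stacks

@dataclass(frozen=True)
class FlimCellSpec:
    """An elliptical cell in a synthetic FLIM field."""

    center: tuple[float, float]  # (y, x)
    radius: tuple[float, float]  # (ry, rx)
    f: float  # mature acceptor fraction
    scenario: MaturationScenario
    brightness: float = 1.0


def _ellipse_mask(shape: tuple[int, int], center, radius) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cy, cx = center
    ry, rx = radius
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def gen_flim_stack(
    shape: tuple[int, int],
    cell_specs: list[FlimCellSpec],
    per_pixel_photons: float = 400.0,
    bins: int = DEFAULT_BINS,
    range_ns: float = DEFAULT_RANGE_NS,
    seed: int | None = None,
) -> tuple[FlimStack, pd.DataFrame]:
    """Photon cube of non-overlapping elliptical cells plus a truth table.

    Each cell's pixels draw Poisson counts around the expected mixture
    decay from its mature fraction; background pixels are dark.  The
    truth table records per-cell (f, amplitudes, lifetimes, expected
    apparent efficiency from a noiseless monoexponential tail fit).
    """
    from .maturation import FitProtocol, apparent_efficiency

    rng = np.random.default_rng(seed)
    cube = np.zeros((*shape, bins), dtype=np.int64)
    occupied = np.zeros(shape, dtype=bool)
    centers = None
    rows = []
    for cid, spec in enumerate(cell_specs, start=1):
        mask = _ellipse_mask(shape, spec.center, spec.radius)
        if not mask.any():
            raise ValueError(f"cell {cid} lies outside the image")
        if (mask & occupied).any():
            raise ValueError(f"cell {cid} overlaps a previous cell")
        occupied |= mask
        amps, taus = mixture_decay_params(spec.f, spec.scenario)
        centers, expected = expected_decay_counts(
            taus, amps, per_pixel_photons * spec.brightness, bins, range_ns
        )
        npix = int(mask.sum())
        cube[mask] = rng.poisson(expected, size=(npix, bins))
        e_app = apparent_efficiency(
            spec.f, spec.scenario, FitProtocol(noiseless=True, bins=bins, range_ns=range_ns)
        )
        rows.append(
            {
                "cell_id": cid,
                "f": spec.f,
                "lifetimes_ns": taus,
                "amplitudes": amps,
                "tau_D_ns": spec.scenario.tau_D_ns,
                "E_true_percent": 100.0 * spec.scenario.E_true,
                "E_app_expected_percent": e_app,
                "n_pixels": npix,
            }
        )
    if centers is None:
        centers, _ = expected_decay_counts((1.0,), (1.0,), 1.0, bins, range_ns)
    truth = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "f", "lifetimes_ns", "amplitudes", "tau_D_ns",
            "E_true_percent", "E_app_expected_percent", "n_pixels",
        ],
    )
    return FlimStack(cube, centers), truth


# ---------------------------------------------------------------------------
# Two-channel confocal images

@dataclass(frozen=True)
class ImageCellSpec:
    """An elliptical cell in a synthetic two-channel confocal field."""

    center: tuple[float, float]
    radius: tuple[float, float]
    expression: float  # mean photons per pixel at unit gain
    f: float  # mature acceptor fraction
    E_true: float
    quantum_yield_donor: float = 0.80
    quantum_yield_acceptor: float = 0.54


def gen_two_channel_image(
    shape: tuple[int, int],
    cell_specs: list[ImageCellSpec],
    gain_green: float = 1.0,
    gain_red: float = 1.0,
    direct_excitation_fraction: float = 0.0,
    background: float = 0.0,
    shot_noise: bool = True,
    expression_texture_sigma: float = 0.4,
    seed: int | None = None,
) -> tuple[TwoChannelImage, pd.DataFrame]:
    """Green/red image of tandem-expressing cells plus a truth table.

    Per-pixel expected intensities follow the tandem photophysics:
    green ∝ N·[(1−f) + f·(1−E)]·QY_D·g_G and
    red ∝ N·f·(E + direct)·QY_A·g_R, with a shared log-normal expression
    texture N per pixel (so the red/green ratio — the true slope — is
    constant within a cell), an optional constant background, and Poisson
    shot noise.  The truth table records each cell's true slope.
    """
    rng = np.random.default_rng(seed)
    green = np.zeros(shape)
    red = np.zeros(shape)
    occupied = np.zeros(shape, dtype=bool)
    rows = []
    for cid, spec in enumerate(cell_specs, start=1):
        if gain_green <= 0 or gain_red <= 0:
            raise ValueError("channel gains must be positive")
        mask = _ellipse_mask(shape, spec.center, spec.radius)
        if not mask.any():
            raise ValueError(f"cell {cid} lies outside the image")
        if (mask & occupied).any():
            raise ValueError(f"cell {cid} overlaps a previous cell")
        occupied |= mask
        npix = int(mask.sum())
        texture = np.exp(rng.normal(0.0, expression_texture_sigma, npix))
        n_px = spec.expression * texture
        g_factor = (
            ((1.0 - spec.f) + spec.f * (1.0 - spec.E_true))
            * spec.quantum_yield_donor * gain_green
        )
        r_factor = (
            spec.f * (spec.E_true + direct_excitation_fraction)
            * spec.quantum_yield_acceptor * gain_red
        )
        green[mask] = n_px * g_factor
        red[mask] = n_px * r_factor
        rows.append(
            {
                "cell_id": cid,
                "f": spec.f,
                "E_true": spec.E_true,
                "true_slope": r_factor / g_factor if g_factor > 0 else np.nan,
                "n_pixels": npix,
            }
        )
    green = green + background
    red = red + background
    if shot_noise:
        green = rng.poisson(green).astype(float)
        red = rng.poisson(red).astype(float)
    truth = pd.DataFrame(
        rows, columns=["cell_id", "f", "E_true", "true_slope", "n_pixels"]
    )
    return TwoChannelImage(green, red), truth


# ---------------------------------------------------------------------------
# Multi-day cohorts

def _grid_cells(
    shape: tuple[int, int], n_cells: int, radius: tuple[float, float]
) -> list[tuple[float, float]]:
    """Non-overlapping cell centers on a regular grid."""
    ry, rx = radius
    step_y, step_x = int(2 * ry + 3), int(2 * rx + 3)
    centers = [
        (float(y), float(x))
        for y in range(int(ry) + 1, shape[0] - int(ry), step_y)
        for x in range(int(rx) + 1, shape[1] - int(rx), step_x)
    ]
    if len(centers) < n_cells:
        raise ValueError(
            f"image of shape {shape} fits only {len(centers)} cells; "
            f"{n_cells} requested"
        )
    return centers[:n_cells]


def _jittered_fraction(f_mean: float, concentration: float, rng) -> float:
    """Beta-distributed per-cell mature fraction around the kinetic mean."""
    if f_mean <= 0.0:
        return 0.0
    if f_mean >= 1.0:
        return 1.0
    return float(rng.beta(f_mean * concentration, (1.0 - f_mean) * concentration))


def gen_cohort_timeseries(
    days,
    scenario: MaturationScenario,
    cells_per_day: int = 8,
    shape: tuple[int, int] = (48, 48),
    cell_radius: tuple[float, float] = (4.0, 4.0),
    per_pixel_photons: float = 400.0,
    bins: int = DEFAULT_BINS,
    range_ns: float = DEFAULT_RANGE_NS,
    f_concentration: float = 30.0,
    seed: int | None = None,
) -> list[tuple[float, FlimStack, pd.DataFrame]]:
    """Days-post-transfection FLIM cohorts under first-order maturation.

    For each day, the population-mean mature fraction follows
    f = 1 − 2^(−t/t_half) and each cell draws a Beta-jittered fraction
    around that mean; a FLIM stack and truth table are generated per day.
    """
    days = list(days)
    if not days:
        raise ValueError("at least one day is required")
    rng = np.random.default_rng(seed)
    out = []
    for day in days:
        f_mean = float(mature_fraction(day * 24.0 * 60.0, scenario.t_half_min))
        centers = _grid_cells(shape, cells_per_day, cell_radius)
        specs = [
            FlimCellSpec(
                center=c,
                radius=cell_radius,
                f=_jittered_fraction(f_mean, f_concentration, rng),
                scenario=scenario,
            )
            for c in centers
        ]
        stack, truth = gen_flim_stack(
            shape, specs, per_pixel_photons, bins, range_ns,
            seed=int(rng.integers(2**31 - 1)),
        )
        truth = truth.assign(day=day, f_mean=f_mean)
        out.append((day, stack, truth))
    return out
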