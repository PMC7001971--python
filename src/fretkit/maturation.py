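"""Chromophore-maturation mixture model for apparent FRET efficiency.

Red fluorescent proteins form their chromophore slowly (half-times of
tens to hundreds of minutes); until it forms, the acceptor is dark and
the tandem's donor decays with the unquenched lifetime τ_D.  Modelling
maturation as first-order kinetics, the mature fraction at time t is

    f(t) = 1 − 2^(−t / t_half).

A cell population at mature fraction f emits a two-component donor decay
with amplitudes (1−f, f) on lifetimes (τ_D, τ_DA), τ_DA = τ_D·(1−E_true)
— amplitude weighting, since each tandem molecule carries one donor.
Fitting that mixture with a single exponential (the standard FLIM
protocol) and applying E = 1 − τ̂/τ_D yields the *apparent* efficiency,
which rises from 0 at f = 0 to E_true at f = 1 and is what a days-post-
transfection FLIM time course actually measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flim import LifetimeFitResult, _default_window, _fit_decay_arrays, flim_fret_efficiency

__all__ = [
    "MaturationScenario",
    "FitProtocol",
    "mature_fraction",
    "mixture_decay_params",
    "apparent_efficiency",
]


@dataclass(frozen=True)
class MaturationScenario:
    """A tandem construct's maturation kinetics and FRET endpoint."""

    t_half_min: float
    E_true: float
    tau_D_ns: float = 3.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.E_true < 1.0:
            raise ValueError("E_true must lie in [0, 1)")
        if self.t_half_min <= 0:
            raise ValueError("maturation half-time must be positive")
        if self.tau_D_ns <= 0:
            raise ValueError("donor lifetime must be positive")

    @property
    def tau_DA_ns(self) -> float:
        """Donor lifetime in a fully mature tandem."""
        return self.tau_D_ns * (1.0 - self.E_true)


@dataclass(frozen=True)
class FitProtocol:
    """Photon budget and histogram geometry for apparent-efficiency fits."""

    total_photons: float = 1e6
    bins: int = 256
    range_ns: float = 12.5
    noiseless: bool = True
    seed: int | None = None


def mature_fraction(t_min: float | np.ndarray, t_half_min: float) -> float | np.ndarray:
    """Mature acceptor fraction after t minutes: f = 1 − 2^(−t/t_half)."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if t_half_min <= 0:
        raise ValueError("half-time must be positive")
    f = 1.0 - np.exp2(-t / t_half_min)
    return float(f) if np.isscalar(t_min) else f


def mixture_decay_params(
    f: float, scenario: MaturationScenario
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Amplitudes and lifetimes of the dark/mature donor-decay mixture.

    Returns ``(amplitudes, lifetimes_ns)``; degenerate f ∈ {0, 1} gives a
    single component.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("mature fraction must lie in [0, 1]")
    if f == 0.0:
        return (1.0,), (scenario.tau_D_ns,)
    if f == 1.0:
        return (1.0,), (scenario.tau_DA_ns,)
    return (1.0 - f, f), (scenario.tau_D_ns, scenario.tau_DA_ns)


def apparent_efficiency(
    f: float,
    scenario: MaturationScenario,
    protocol: FitProtocol | None = None,
) -> float:
    """Apparent FLIM-FRET efficiency (percent) at mature fraction f.

    Builds the mixture decay (noiseless expectation by default, or a
    Poisson realization with the protocol's photon budget and seed),
    fits a single exponential in tail mode, and applies the lifetime-
    ratio formula against the scenario's τ_D.
    """
    protocol = protocol or FitProtocol()
    amps, taus = mixture_decay_params(f, scenario)
    # imported here to avoid a circular module dependency
    from .synthetic import expected_decay_counts, gen_tcspc_decay

    if protocol.noiseless:
        t, counts = expected_decay_counts(
            lifetimes=taus,
            amplitudes=amps,
            total_photons=protocol.total_photons,
            bins=protocol.bins,
            range_ns=protocol.range_ns,
        )
    else:
        decay = gen_tcspc_decay(
            lifetimes=taus,
            amplitudes=amps,
            total_photons=protocol.total_photons,
            bins=protocol.bins,
            range_ns=protocol.range_ns,
            seed=protocol.seed,
        )
        t, counts = decay.bin_times_ns, decay.counts
    fit: LifetimeFitResult = _fit_decay_arrays(t, counts, 1, _default_window(counts))
    if not fit.success:
        raise RuntimeError(f"apparent-efficiency fit failed: {fit.message}")
    return flim_fret_efficiency(fit.tau_ns, scenario.tau_D_ns)
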