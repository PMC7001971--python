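"""Batch pipelines: spectral FRET, FLIM-FRET, and slope heterogeneity.

Each runner takes a serializable configuration, processes every input it
can resolve, logs and skips per-file failures, and writes CSV tables
whose rows trace back to the input file (and cell id) they came from.
Re-running with the same configuration and seed reproduces the outputs.
"""

from __future__ import annotations

import glob as globmod
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import flim as flim_mod
from . import heterogeneity as het_mod
from .permutation import permutation_test
from .spectra import read_spectrum
from .unmixing import EmissionScan, linear_unmix, spectral_fret_efficiency

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralConfig",
    "FlimConfig",
    "HeterogeneityConfig",
    "RunConfig",
    "run_spectral_pipeline",
    "run_flim_pipeline",
    "run_heterogeneity_pipeline",
    "run_all",
]


@dataclass
class SpectralConfig:
    scan_glob: str = ""
    donor_ref: str = ""
    acceptor_ref: str = ""
    quantum_yield_donor: float = 0.80
    quantum_yield_acceptor: float = 0.54
    fit_baseline: bool = False
    excitation_nm: float = 470.0


@dataclass
class FlimConfig:
    #: group name -> glob of FLIM stack TIFFs (each with a .json sidecar;
    #: an optional `<stem>.mask.tif` label image marks the cells)
    groups: dict[str, str] = field(default_factory=dict)
    tau_D_ns: float = 3.05
    intensity_threshold: float = 0.0
    min_total_counts: float = 1000.0
    n_perm: int = 100_000


@dataclass
class HeterogeneityConfig:
    green_glob: str = ""
    red_glob: str = ""
    segmentation_threshold: float = 10.0
    min_area: int = 50


@dataclass
class RunConfig:
    """Serializable configuration driving all pipeline stages."""

    output_dir: str = "results"
    seed: int = 0
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    flim: FlimConfig = field(default_factory=FlimConfig)
    heterogeneity: HeterogeneityConfig = field(default_factory=HeterogeneityConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            output_dir=raw.get("output_dir", "results"),
            seed=raw.get("seed", 0),
            spectral=SpectralConfig(**raw.get("spectral", {})),
            flim=FlimConfig(**raw.get("flim", {})),
            heterogeneity=HeterogeneityConfig(**raw.get("heterogeneity", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_spectral_pipeline(config: RunConfig) -> pd.DataFrame:
    """Unmix every emission scan and tabulate per-scan FRET efficiencies.

    Output columns: scan, W_D, W_A, E_percent, r_squared.  Failures are
    logged and skipped; an empty glob yields an empty table.
    """
    cfg = config.spectral
    out = _outdir(config)
    donor = read_spectrum(cfg.donor_ref) if cfg.donor_ref else None
    acceptor = read_spectrum(cfg.acceptor_ref) if cfg.acceptor_ref else None
    rows = []
    for path in sorted(globmod.glob(cfg.scan_glob)):
        try:
            df = pd.read_csv(path)
            scan = EmissionScan(
                df["wavelength_nm"].to_numpy(float),
                df["value"].to_numpy(float),
                excitation_nm=cfg.excitation_nm,
            )
            res = linear_unmix(scan, donor, acceptor, fit_baseline=cfg.fit_baseline)
            e = spectral_fret_efficiency(
                res, cfg.quantum_yield_donor, cfg.quantum_yield_acceptor
            )
            rows.append(
                {
                    "scan": path,
                    "W_D": res.W_D,
                    "W_A": res.W_A,
                    "E_percent": e,
                    "r_squared": res.r_squared,
                }
            )
        except Exception as exc:  # per-file robustness
            logger.warning("skipping scan %s: %s", path, exc)
    table = pd.DataFrame(rows, columns=["scan", "W_D", "W_A", "E_percent", "r_squared"])
    table.to_csv(out / "spectral_efficiencies.csv", index=False)
    return table


def _cell_masks_for(stack_path: Path, shape: tuple[int, int]) -> np.ndarray:
    mask_file = Path(str(stack_path).replace(".tif", ".mask.tif"))
    if mask_file.exists():
        return tifffile.imread(mask_file)
    return np.ones(shape, dtype=np.int32)  # whole field as one cell


def run_flim_pipeline(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell lifetimes and FRET efficiencies plus group comparisons.

    For each group's stacks, every labeled cell is aggregated above the
    intensity threshold, tail-fit with one exponential, and converted to
    efficiency against the configured donor-only lifetime.  Group pairs
    are compared with a seeded permutation test on the lifetimes.
    Returns (cells, comparisons).
    """
    cfg = config.flim
    out = _outdir(config)
    rows = []
    for group, pattern in cfg.groups.items():
        for path in sorted(globmod.glob(pattern)):
            path = Path(path)
            if path.name.endswith(".mask.tif"):
                continue
            try:
                stack = flim_mod.read_flim_stack(path)
                labels = _cell_masks_for(path, stack.shape)
                for cell_id in np.unique(labels[labels > 0]):
                    decay = flim_mod.sum_roi_decay(
                        stack, labels == cell_id, cfg.intensity_threshold
                    )
                    fit = flim_mod.tail_fit(
                        decay, n_components=1, min_total_counts=cfg.min_total_counts
                    )
                    rows.append(
                        {
                            "group": group,
                            "stack": str(path),
                            "cell_id": int(cell_id),
                            "tau_ns": fit.tau_ns,
                            "E_percent": flim_mod.flim_fret_efficiency(
                                fit.tau_ns, cfg.tau_D_ns
                            ),
                            "chi2_reduced": fit.chi2_reduced,
                            "success": fit.success,
                        }
                    )
            except Exception as exc:
                logger.warning("skipping stack %s: %s", path, exc)
    cells = pd.DataFrame(
        rows,
        columns=[
            "group", "stack", "cell_id", "tau_ns", "E_percent",
            "chi2_reduced", "success",
        ],
    )
    comps = []
    for ga, gb in combinations(sorted(cells["group"].unique()), 2) if len(cells) else []:
        ta = cells.loc[cells["group"] == ga, "tau_ns"].to_numpy()
        tb = cells.loc[cells["group"] == gb, "tau_ns"].to_numpy()
        res = permutation_test(ta, tb, n_perm=cfg.n_perm, seed=config.seed)
        comps.append(
            {
                "group_a": ga,
                "group_b": gb,
                "p_value": res.p_value,
                "observed_difference_ns": res.observed_statistic,
                "method": res.method,
            }
        )
    comparisons = pd.DataFrame(
        comps,
        columns=["group_a", "group_b", "p_value", "observed_difference_ns", "method"],
    )
    cells.to_csv(out / "flim_cells.csv", index=False)
    comparisons.to_csv(out / "flim_comparisons.csv", index=False)
    return cells, comparisons


def run_heterogeneity_pipeline(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell red/green slopes across image pairs plus a pooled histogram.

    Green and red globs are paired in sorted order.  Cells are segmented
    on the summed channels, the background (median outside all masks) is
    subtracted, and each cell's pixels are regressed red-on-green.
    Returns (slopes, histogram).
    """
    cfg = config.heterogeneity
    out = _outdir(config)
    greens = sorted(globmod.glob(cfg.green_glob))
    reds = sorted(globmod.glob(cfg.red_glob))
    if len(greens) != len(reds):
        raise ValueError(
            f"{len(greens)} green vs {len(reds)} red images; globs must pair up"
        )
    rows = []
    for gpath, rpath in zip(greens, reds):
        try:
            img = het_mod.TwoChannelImage(
                tifffile.imread(gpath).astype(float),
                tifffile.imread(rpath).astype(float),
            )
            labels = het_mod.segment_cells(
                img, cfg.segmentation_threshold, cfg.min_area
            )
            img_bg = het_mod.background_subtract(img, masks=labels)
            for cell_id in np.unique(labels[labels > 0]):
                try:
                    rec = het_mod.cell_intensity_slope(
                        img_bg, labels == cell_id, cell_id=int(cell_id),
                        min_pixels=cfg.min_area,
                    )
                except ValueError as exc:
                    logger.info("skipping cell %d in %s: %s", cell_id, gpath, exc)
                    continue
                rows.append(
                    {
                        "image": gpath,
                        "cell_id": rec.cell_id,
                        "slope": rec.slope,
                        "intercept": rec.intercept,
                        "r_squared": rec.r_squared,
                        "n_pixels": rec.n_pixels,
                    }
                )
        except Exception as exc:
            logger.warning("skipping image pair (%s, %s): %s", gpath, rpath, exc)
    slopes = pd.DataFrame(
        rows,
        columns=["image", "cell_id", "slope", "intercept", "r_squared", "n_pixels"],
    )
    hist = (
        het_mod.slope_histogram(slopes)
        if len(slopes)
        else pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    )
    slopes.to_csv(out / "slopes.csv", index=False)
    hist.to_csv(out / "slope_histogram.csv", index=False)
    return slopes, hist


def run_all(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every configured stage; stages with empty configs yield empty tables."""
    results: dict[str, pd.DataFrame] = {}
    if config.spectral.scan_glob:
        results["spectral"] = run_spectral_pipeline(config)
    if config.flim.groups:
        cells, comps = run_flim_pipeline(config)
        results["flim_cells"] = cells
        results["flim_comparisons"] = comps
    if config.heterogeneity.green_glob:
        slopes, hist = run_heterogeneity_pipeline(config)
        results["slopes"] = slopes
        results["slope_histogram"] = hist
    return results
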