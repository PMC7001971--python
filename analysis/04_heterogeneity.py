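"""Per-cell red/green slope histograms for dark vs mature cohorts.

Simulates confocal fields of tandem-expressing cells where each cell has
a mature-acceptor fraction drawn from a cohort distribution: a
dark-acceptor cohort (Beta(0.5, 4), most cells near f = 0, the
slow-maturing phenotype) and a mature cohort (Beta(8, 1), most cells
near f = 1).  Runs segmentation, background subtraction and red-on-green
regression per cell and histograms the slopes.
Writes results/slopes_{dark,mature}.csv and results/slope_histograms.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fretkit import (
    ImageCellSpec,
    background_subtract,
    cell_intensity_slope,
    gen_two_channel_image,
    segment_cells,
    slope_histogram,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 3
N_CELLS = 40
E_TRUE = 0.27

rng = np.random.default_rng(SEED)
hist_tables = []
for cohort, (alpha, beta) in {"dark": (0.5, 4.0), "mature": (8.0, 1.0)}.items():
    records = []
    for chunk in range(5):  # 8 cells per simulated field
        fs = rng.beta(alpha, beta, 8)
        specs = [
            ImageCellSpec(
                (10.0, 10.0 + 14 * i), (5.0, 5.0),
                float(rng.uniform(200, 400)), float(f), E_TRUE,
            )
            for i, f in enumerate(fs)
        ]
        img, truth = gen_two_channel_image(
            (20, 14 * 8 + 10), specs, background=5.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        labels = segment_cells(img, threshold=15, min_area=30)
        bg = background_subtract(img, labels)
        for cell_id in np.unique(labels[labels > 0]):
            rec = cell_intensity_slope(bg, labels == cell_id, int(cell_id), 30)
            records.append(
                {"field": chunk, "cell_id": rec.cell_id, "slope": rec.slope,
                 "r_squared": rec.r_squared, "n_pixels": rec.n_pixels}
            )
    slopes = pd.DataFrame(records)
    slopes.to_csv(OUT / f"slopes_{cohort}.csv", index=False)
    hist = slope_histogram(slopes, bins=np.arange(-0.055, 0.36, 0.01))
    hist["cohort"] = cohort
    hist_tables.append(hist)
    mode_center = 0.5 * (
        hist.loc[hist["count"].idxmax(), "bin_left"]
        + hist.loc[hist["count"].idxmax(), "bin_right"]
    )
    print(
        f"{cohort} cohort: {len(slopes)} cells, median slope "
        f"{slopes['slope'].median():.3f}, histogram mode at {mode_center:.3f}"
    )

pd.concat(hist_tables).to_csv(OUT / "slope_histograms.csv", index=False)
print(
    "\nThe dark-acceptor cohort piles up at slope 0 — cells with clear green "
    "signal but no red — while the mature cohort peaks at the tandem's "
    "characteristic red/green ratio.  The two histograms reproduce the "
    "qualitative contrast between a slow-maturing and a fast-maturing "
    "acceptor under identical imaging conditions."
)
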