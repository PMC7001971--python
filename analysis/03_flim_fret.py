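"""FLIM-FRET on synthetic cell fields: lifetimes, efficiencies, statistics.

Simulates one field per construct — donor-only cells at 3.05 ns and
tandem cells whose mature-acceptor fraction reflects each acceptor's
maturation speed after ~1 day of expression — then runs the full
analysis: ROI decay aggregation, monoexponential tail fits, the
lifetime-ratio efficiency, and permutation tests between groups.
Writes results/flim_cells.csv and results/flim_comparisons.csv.
"""

from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from fretkit import (
    FlimCellSpec,
    MaturationScenario,
    flim_fret_efficiency,
    gen_flim_stack,
    permutation_test,
    sum_roi_decay,
    tail_fit,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 2
TAU_D = 3.05
E_TRUE = 0.27  # plateau efficiency of a fully mature tandem

# mature fraction after ~1 day at each acceptor's effective in-cell rate:
# fast maturers are essentially complete, mRuby3-like cells mostly dark
GROUPS = {
    "NG-Stop": 0.0,
    "NG-mRuby3": 0.15,
    "NG-mScarlet-I": 1.0,
    "NG-mCherry": 1.0,
}

rng = np.random.default_rng(SEED)
rows = []
for group, f_mean in GROUPS.items():
    scenario = MaturationScenario(t_half_min=136.5, E_true=E_TRUE, tau_D_ns=TAU_D)
    specs = []
    for i in range(8):
        f = (
            0.0 if f_mean == 0.0
            else 1.0 if f_mean == 1.0
            else float(rng.beta(f_mean * 30, (1 - f_mean) * 30))
        )
        specs.append(FlimCellSpec((8.0, 8.0 + 18 * i), (4.0, 4.0), f, scenario))
    stack, truth = gen_flim_stack(
        (16, 18 * 8 + 8), specs, per_pixel_photons=2000,
        seed=int(rng.integers(2**31 - 1)),
    )
    labels = measure.label(stack.intensity_image > 0)
    for cell_id in np.unique(labels[labels > 0]):
        decay = sum_roi_decay(stack, labels == cell_id, 0)
        fit = tail_fit(decay)
        rows.append(
            {
                "group": group,
                "cell_id": int(cell_id),
                "f_true": truth.set_index("cell_id")["f"].get(int(cell_id), np.nan),
                "tau_ns": fit.tau_ns,
                "E_percent": flim_fret_efficiency(fit.tau_ns, TAU_D),
                "chi2_reduced": fit.chi2_reduced,
            }
        )

cells = pd.DataFrame(rows)
cells.to_csv(OUT / "flim_cells.csv", index=False)
summary = cells.groupby("group")[["tau_ns", "E_percent"]].agg(["mean", "std"])
print(summary.round(3).to_string())

comps = []
for ga, gb in combinations(GROUPS, 2):
    res = permutation_test(
        cells.loc[cells.group == ga, "tau_ns"],
        cells.loc[cells.group == gb, "tau_ns"],
        n_perm=100_000, seed=SEED,
    )
    comps.append({"group_a": ga, "group_b": gb, "p_value": res.p_value,
                  "delta_tau_ns": res.observed_statistic, "method": res.method})
comparisons = pd.DataFrame(comps)
comparisons.to_csv(OUT / "flim_comparisons.csv", index=False)
print()
print(comparisons.round(5).to_string(index=False))

ms = cells.groupby("group")["E_percent"].mean()
print(
    f"\nDonor-only cells fit to ~{ms['NG-Stop']:.1f}% efficiency (zero within "
    f"noise); the fast-maturing tandems reach ~{ms['NG-mScarlet-I']:.0f}% "
    f"and ~{ms['NG-mCherry']:.0f}%, while the mostly-dark mRuby3-like group "
    f"shows only ~{ms['NG-mRuby3']:.0f}% — the characteristic failure of a "
    "slow-maturing acceptor despite favourable spectral overlap.  Group "
    "differences are assessed with seeded permutation tests."
)
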