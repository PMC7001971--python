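"""Apparent FLIM efficiency of a slow-maturing tandem over days.

Two curves from the maturation mixture model, both with a fully-mature
efficiency of 27% and donor lifetime 3.05 ns:

1. the published in-vitro half-time (136.5 min), under which a single
   synthesis cohort would be >99.9% mature within one day — so the
   in-vitro rate cannot by itself explain a FRET rise that continues for
   days in cells;
2. an effective in-cell half-time of 2 days, which reproduces a
   multi-day rise of the kind observed (a few percent at day 1 to ~20%
   by day 5), consistent with maturation being strongly retarded in
   cells and with dark states beyond slow maturation.

Writes results/maturation_timecourse.csv.
"""

from pathlib import Path

import pandas as pd

from fretkit import MaturationScenario, apparent_efficiency, mature_fraction

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

DAYS = [0, 1, 2, 3, 4, 5]
rows = []
for label, t_half_min in {"in_vitro_136.5min": 136.5, "effective_2day": 2880.0}.items():
    scenario = MaturationScenario(t_half_min=t_half_min, E_true=0.27, tau_D_ns=3.05)
    for day in DAYS:
        f = mature_fraction(day * 24 * 60.0, t_half_min)
        rows.append(
            {
                "kinetics": label,
                "day": day,
                "mature_fraction": f,
                "E_app_percent": apparent_efficiency(f, scenario),
            }
        )

table = pd.DataFrame(rows)
table.to_csv(OUT / "maturation_timecourse.csv", index=False)
print(table.round(4).to_string(index=False))

eff = table[table.kinetics == "effective_2day"].set_index("day")["E_app_percent"]
print(
    f"\nWith the published 136.5 min half-time the tandem is fully mature by "
    "day 1 and the apparent efficiency is flat at 27% — ruling out in-vitro "
    "kinetics as the whole story.  An effective in-cell half-time of 2 days "
    f"gives {eff[1]:.0f}% at 1 day rising to {eff[5]:.0f}% at 5 days, the "
    "shape of a days-long maturation-limited FRET recovery.  Note the "
    "apparent efficiency always lies below the mature fraction times 27%: "
    "a monoexponential fit of the dark/mature lifetime mixture is pulled "
    "toward the long donor-only component."
)
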