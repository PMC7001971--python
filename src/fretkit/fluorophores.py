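"""Photophysical constants for the fluorescent proteins under study.

The bundled records cover the green-yellow donors mNeonGreen and mClover3
and the red acceptors mRuby3, mScarlet-I, mCherry and mScarlet, with
excitation/emission maxima, molar extinction coefficients, quantum
yields, pKa, and chromophore maturation half-times.  These constants
parameterize the synthetic-data generators and the Förster-radius
calculations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["FluorophoreRecord", "FLUOROPHORES", "read_fluorophore_table"]


@dataclass(frozen=True)
class FluorophoreRecord:
    """Photophysical constants for one fluorescent protein."""

    name: str
    lambda_ex_max_nm: float
    lambda_em_max_nm: float
    extinction_coefficient_M1cm1: float
    quantum_yield: float
    pKa: float
    maturation_half_time_min: float

    def __post_init__(self) -> None:
        if not 0.0 < self.quantum_yield <= 1.0:
            raise ValueError("quantum_yield must lie in (0, 1]")
        if self.extinction_coefficient_M1cm1 <= 0:
            raise ValueError("extinction coefficient must be positive")
        if self.maturation_half_time_min <= 0:
            raise ValueError("maturation half-time must be positive")


#: Reference constants for the proteins characterized in this package.
FLUOROPHORES: dict[str, FluorophoreRecord] = {
    r.name: r
    for r in [
        FluorophoreRecord("mNeonGreen", 506, 517, 116_000, 0.80, 5.7, 10.0),
        FluorophoreRecord("mClover3", 506, 518, 109_000, 0.78, 6.5, 43.5),
        FluorophoreRecord("mRuby3", 558, 592, 128_000, 0.45, 4.8, 136.5),
        FluorophoreRecord("mScarlet-I", 569, 593, 104_000, 0.54, 5.4, 36.0),
        FluorophoreRecord("mCherry", 587, 610, 72_000, 0.22, 4.5, 15.0),
        FluorophoreRecord("mScarlet", 569, 594, 100_000, 0.70, 5.3, 174.0),
    ]
}

_COLUMNS = [
    "name",
    "lambda_ex_max_nm",
    "lambda_em_max_nm",
    "extinction_coefficient_M1cm1",
    "quantum_yield",
    "pKa",
    "maturation_half_time_min",
]


def read_fluorophore_table(path: str | Path) -> dict[str, FluorophoreRecord]:
    """Read a CSV of fluorophore constants (columns as in ``FLUOROPHORES``)."""
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, FluorophoreRecord] = {}
    for _, row in df.iterrows():
        rec = FluorophoreRecord(
            name=str(row["name"]),
            lambda_ex_max_nm=float(row["lambda_ex_max_nm"]),
            lambda_em_max_nm=float(row["lambda_em_max_nm"]),
            extinction_coefficient_M1cm1=float(row["extinction_coefficient_M1cm1"]),
            quantum_yield=float(row["quantum_yield"]),
            pKa=float(row["pKa"]),
            maturation_half_time_min=float(row["maturation_half_time_min"]),
        )
        out[rec.name] = rec
    return out
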