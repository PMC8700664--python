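"""Reference chemistry: titratable acidity and the BrimA taste index."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "TitrationRecord",
    "ChemistryRecord",
    "titratable_acidity",
    "brima",
    "read_chemistry_table",
    "write_chemistry_table",
    "DEFAULT_K",
]

#: Tongue acid-sensitivity constant; the conventional value.
DEFAULT_K = 5.0

#: Milliequivalent factor of malic acid (g/meq), the apple convention.
MALIC_ACID_MEQ = 0.067


@dataclass(frozen=True)
class TitrationRecord:
    """Inputs of the NaOH titration formula."""

    naoh_volume: float       # mL
    naoh_normality: float    # eq/L
    acid_meq_factor: float   # g/meq, acid-species specific (malic: 0.067)
    juice_volume: float      # mL

    def __post_init__(self) -> None:
        for name in ("naoh_volume", "naoh_normality", "acid_meq_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.juice_volume <= 0:
            raise ValueError("juice_volume must be > 0")


def titratable_acidity(t: TitrationRecord) -> float:
    """Titratable acidity in percent: V_NaOH * N_NaOH * meq * 100 / V_juice."""
    return (t.naoh_volume * t.naoh_normality * t.acid_meq_factor * 100.0
            / t.juice_volume)


def brima(tss: float, ta: float, k: float = DEFAULT_K) -> float:
    """BrimA taste index: TSS - k * TA (k defaults to 5)."""
    return tss - k * ta


@dataclass(frozen=True)
class ChemistryRecord:
    """Per-sample destructive chemistry (TSS in degrees Brix, TA in %)."""

    sample_id: str
    tss: float
    ta: float
    brima: float
    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.ta < 0:
            raise ValueError("ta must be >= 0")
        expected = self.tss - self.k * self.ta
        if abs(self.brima - expected) > 1e-9:
            raise ValueError(
                f"inconsistent BrimA for {self.sample_id!r}: stored "
                f"{self.brima}, recomputed {expected}"
            )

    @classmethod
    def from_measurements(cls, sample_id: str, tss: float, ta: float,
                          k: float = DEFAULT_K) -> "ChemistryRecord":
        return cls(sample_id, tss, ta, brima(tss, ta, k), k)


def read_chemistry_table(path: str | Path,
                         k: float = DEFAULT_K) -> list[ChemistryRecord]:
    """Read a chemistry CSV (sample_id, tss, ta[, brima]).

    A missing brima column is recomputed from TSS and TA.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in ("sample_id", "tss", "ta"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        b = getattr(row, "brima", None)
        if b is None or pd.isna(b):
            b = brima(row.tss, row.ta, k)
        records.append(ChemistryRecord(row.sample_id, float(row.tss),
                                       float(row.ta), float(b), k))
    return records


def write_chemistry_table(records: list[ChemistryRecord],
                          path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "tss": [r.tss for r in records],
            "ta": [r.ta for r in records],
            "brima": [r.brima for r in records],
        }
    ).to_csv(path, index=False, float_format="%.17g")
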