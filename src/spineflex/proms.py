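"""Patient-reported outcome measures (PROMs) for low back pain profiling.

Seven questionnaire totals enter the classifier as numeric features, in a
fixed order that downstream subset masks rely on:

    VAS   pain intensity, 0–100 mm visual analogue scale
    ODI   Oswestry Disability Index, 0–100
    TSK   Tampa Scale of Kinesiophobia, 17–68
    PCS   Pain Catastrophising Scale, 0–52
    PSEQ  Pain Self-Efficacy Questionnaire, 0–60
    CSQ   Coping Strategies Questionnaire total, 0–70 (14 items × 0–5)
    SBT   STarT Back screening tool total, 0–9

Values outside the declared closed range are rejected; there is no
imputation. SBT additionally carries a derived chronicity risk band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PROM_FEATURE_NAMES = ("vas", "odi", "tsk", "pcs", "pseq", "csq", "sbt")
N_PROM_FEATURES = len(PROM_FEATURE_NAMES)

#: closed [lo, hi] bounds per measure
PROM_RANGES: dict[str, tuple[float, float]] = {
    "vas": (0, 100),
    "odi": (0, 100),
    "tsk": (17, 68),
    "pcs": (0, 52),
    "pseq": (0, 60),
    "csq": (0, 70),
    "sbt": (0, 9),
}


class PromsValidationError(ValueError):
    """A PROM value falls outside its instrument's score range."""


class PromsSchemaError(ValueError):
    """The PROMs table is missing required columns or has duplicate ids."""


@dataclass
class PROMS:
    """One participant's seven validated questionnaire totals."""

    participant_id: str
    vas: float
    odi: float
    tsk: float
    pcs: float
    pseq: float
    csq: float
    sbt: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in PROM_RANGES.items():
            v = float(getattr(self, name))
            if not np.isfinite(v) or not (lo <= v <= hi):
                raise PromsValidationError(
                    f"participant {self.participant_id!r}: {name}={v} outside "
                    f"allowed range [{lo}, {hi}]"
                )
            setattr(self, name, v)

    @property
    def sbt_risk_band(self) -> str:
        """STarT Back risk stratum derived from the total score."""
        if self.sbt <= 3:
            return "low"
        return "medium" if self.sbt <= 6 else "high"

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PROM_FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PROM_FEATURE_NAMES}


def load_proms(path: str | Path) -> dict[str, PROMS]:
    """Load and validate a PROMs CSV, keyed by participant id.

    Expected columns: participant_id, vas, odi, tsk, pcs, pseq, csq, sbt.
    Out-of-range values raise :class:`PromsValidationError`; missing columns
    or duplicated ids raise :class:`PromsSchemaError`.
    """
    df = pd.read_csv(path)
    required = ("participant_id",) + PROM_FEATURE_NAMES
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PromsSchemaError(f"PROMs file {path}: missing columns {missing}")
    ids = df["participant_id"].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise PromsSchemaError(f"PROMs file {path}: duplicate participant ids {dupes}")
    records: dict[str, PROMS] = {}
    for _, row in df.iterrows():
        pid = str(row["participant_id"])
        records[pid] = PROMS(
            participant_id=pid,
            **{k: float(row[k]) for k in PROM_FEATURE_NAMES},
        )
    return records


def proms_to_frame(records: dict[str, PROMS]) -> pd.DataFrame:
    """Tidy DataFrame of PROMs records (one row per participant)."""
    rows = [{"participant_id": pid, **rec.as_dict()} for pid, rec in records.items()]
    return pd.DataFrame(rows, columns=["participant_id", *PROM_FEATURE_NAMES])
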