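"""Method validation statistics: spiked recovery and repeatability (RSD).

Recovery is the percentage of a spiked (added) analyte amount that the
method measures back, reported to the nearest integer percent as analytical
tables conventionally print it. RSD is the sample standard deviation
(n−1 denominator) divided by the mean, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RecoveryRecord",
    "recovery",
    "rsd",
    "recovery_table",
]


@dataclass
class RecoveryRecord:
    """One spiked-recovery measurement: amounts in μmol, recovery in %."""

    sample_id: str
    analyte: str
    added: float
    measured: float

    def __post_init__(self) -> None:
        if self.added < 0 or self.measured < 0:
            raise ValueError("added and measured amounts must be >= 0")

    @property
    def recovery_percent(self) -> int:
        return round(recovery(self.added, self.measured))


def recovery(added: float, measured: float) -> float:
    """Recovery 100 × measured / added, in percent (full precision).

    Round to the nearest integer for table display. Raises ``ValueError``
    when nothing was added.
    """
    if added <= 0:
        raise ValueError("added amount must be > 0 to compute a recovery")
    return 100.0 * measured / added


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, 100 × sd / mean, in percent.

    Uses the sample (n−1) standard deviation. Requires at least two values
    and a nonzero mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ZeroDivisionError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def recovery_table(
    records: Iterable[RecoveryRecord | Mapping[str, object]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-record recoveries plus a per-analyte min/max summary.

    ``records`` may be :class:`RecoveryRecord` objects or mappings with keys
    ``sample_id, analyte, added, measured``. Returns ``(table, summary)``
    DataFrames; the summary carries min/max of the rounded integer
    recoveries per analyte, matching how validation tables are reported.
    """
    recs = [
        r if isinstance(r, RecoveryRecord) else RecoveryRecord(**r)  # type: ignore[arg-type]
        for r in records
    ]
    if not recs:
        raise ValueError("no recovery records provided")
    table = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in recs],
            "analyte": [r.analyte for r in recs],
            "added_umol": [r.added for r in recs],
            "measured_umol": [r.measured for r in recs],
            "recovery_percent_exact": [recovery(r.added, r.measured) for r in recs],
            "recovery_percent": [r.recovery_percent for r in recs],
        }
    )
    summary = (
        table.groupby("analyte")["recovery_percent"]
        .agg(["min", "max", "count"])
        .rename(columns={"min": "recovery_min", "max": "recovery_max", "count": "n"})
        .reset_index()
    )
    return table, summary
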