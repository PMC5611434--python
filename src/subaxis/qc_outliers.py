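"""Quality control: per-segment +/-3 SD outlier exclusion.

Visual inspection of individual axis segments is not feasible (segment
boundaries have no visible anatomical correlate), so quality control is
statistical: within each (hemisphere, segment) cell, a volume further than
``z_threshold`` standard deviations from the cell mean is excluded from
analysis.  Excluded measurements are set missing, never imputed; downstream
models apply listwise deletion.

The mean and SD are computed in a single pass over the whole sample (no
iteration on the filtered table), pooled across diagnostic groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("subaxis")

DEFAULT_Z_THRESHOLD = 3.0


@dataclass(frozen=True)
class QCReport:
    n_measurements: int
    n_excluded: int
    excluded_records: tuple = field(default_factory=tuple)

    @property
    def excluded_fraction(self) -> float:
        if self.n_measurements == 0:
            return 0.0
        return self.n_excluded / self.n_measurements

    def to_dict(self) -> dict:
        return {
            "n_measurements": self.n_measurements,
            "n_excluded": self.n_excluded,
            "excluded_fraction": self.excluded_fraction,
            "excluded_records": [list(r) for r in self.excluded_records],
        }


def flag_outlier_segments(
    cohort: pd.DataFrame,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    value_column: str = "volume_mm3",
) -> tuple[pd.DataFrame, QCReport]:
    """Flag segment volumes more than ``z_threshold`` SD from the cell mean.

    ``cohort`` is a long table with one row per participant x hemisphere x
    segment and at least the columns ``participant_id``, ``hemisphere``,
    ``segment`` and ``value_column``.  Returns a copy with an ``excluded``
    flag set and the excluded volumes replaced by NaN, plus a QCReport.

    Cells with SD = 0 produce no exclusions (warning logged); every cell must
    contain at least 3 participants.
    """
    if z_threshold <= 0:
        raise ValueError(f"z_threshold must be positive, got {z_threshold}")
    out = cohort.copy()
    grouped = out.groupby(["hemisphere", "segment"], sort=False)[value_column]
    counts = grouped.transform("count")
    if (counts < 3).any():
        bad = (
            out.loc[counts < 3, ["hemisphere", "segment"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        raise ValueError(
            "fewer than 3 participants in cell(s): "
            + ", ".join(f"({h}, {s})" for h, s in bad)
        )
    mean = grouped.transform("mean")
    sd = grouped.transform("std")  # ddof=1, one pass over the whole sample
    if (sd == 0).any():
        logger.warning(
            "degenerate SD=0 in %d cell(s); no exclusions applied there",
            out.loc[sd == 0, ["hemisphere", "segment"]].drop_duplicates().shape[0],
        )
    with np.errstate(invalid="ignore"):
        flag = (np.abs(out[value_column] - mean) > z_threshold * sd) & (sd > 0)
    flag &= out[value_column].notna()
    if "excluded" in out.columns:
        out["excluded"] = out["excluded"].astype(bool) | flag
    else:
        out["excluded"] = flag
    excluded_records = tuple(
        (str(r.participant_id), str(r.hemisphere), int(r.segment))
        for r in out.loc[flag, ["participant_id", "hemisphere", "segment"]]
        .itertuples(index=False)
    )
    out.loc[flag, value_column] = np.nan
    n_meas = int(out[value_column].notna().sum() + flag.sum())
    report = QCReport(
        n_measurements=n_meas,
        n_excluded=int(flag.sum()),
        excluded_records=excluded_records,
    )
    logger.info(
        "QC: excluded %d of %d measurements (%.2f%%) at |z| > %g",
        report.n_excluded, report.n_measurements,
        100 * report.excluded_fraction, z_threshold,
    )
    return out, report
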