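"""Per-subject relative-change statistics between postural phases.

For every metric the tilt response is expressed as a percent change
relative to the preceding phase:

    delta1 = 100 * (tilt - supine) / supine
    delta2 = 100 * (resupine - tilt) / tilt

Deltas are computed per subject and only then summarized (group medians
with IQR), never as the change of group medians.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .hrv_metrics import METRIC_NAMES

log = logging.getLogger(__name__)

DELTA_COLUMNS = ["subject_id", "metric", "delta1_pct", "delta2_pct"]


def relative_change(later_value: float, earlier_value: float) -> float:
    """Percent change from ``earlier_value`` to ``later_value``.

    Undefined (NaN) when the reference value is zero or not finite.
    """
    if not np.isfinite(earlier_value) or earlier_value == 0 or not np.isfinite(later_value):
        return np.nan
    return 100.0 * (later_value - earlier_value) / earlier_value


def delta_panels(panel_df: pd.DataFrame,
                 phases: Sequence[str] = ("supine", "tilt", "resupine"),
                 metrics: Sequence[str] | None = None) -> pd.DataFrame:
    """Long table of per-subject, per-metric %Δ1 and %Δ2.

    ``panel_df`` is the stacked panel frame (one row per subject × phase).
    Subjects missing any of the three phases are skipped with a logged
    reason; metrics undefined in either phase of a ratio yield NaN deltas.
    The returned frame carries a completeness report in
    ``df.attrs["n_skipped_subjects"]`` and ``df.attrs["n_undefined"]``.
    """
    if len(phases) != 3:
        raise ValueError("phases must name (baseline, challenge, recovery)")
    metrics = list(metrics) if metrics is not None else [
        m for m in METRIC_NAMES if m in panel_df.columns]
    p0, p1, p2 = phases

    rows = []
    n_skipped = 0
    n_undefined = 0
    for sid, sub in panel_df.groupby("subject_id", sort=True):
        by_phase = sub.set_index("phase_name")
        if not all(p in by_phase.index for p in phases):
            missing = [p for p in phases if p not in by_phase.index]
            log.warning("subject %s skipped: missing phase(s) %s", sid, missing)
            n_skipped += 1
            continue
        for metric in metrics:
            d1 = relative_change(by_phase.at[p1, metric], by_phase.at[p0, metric])
            d2 = relative_change(by_phase.at[p2, metric], by_phase.at[p1, metric])
            n_undefined += int(np.isnan(d1)) + int(np.isnan(d2))
            rows.append((sid, metric, d1, d2))

    out = pd.DataFrame(rows, columns=DELTA_COLUMNS)
    out.attrs["n_skipped_subjects"] = n_skipped
    out.attrs["n_undefined"] = n_undefined
    return out


def delta_wide(delta_df: pd.DataFrame, which: str = "delta1_pct") -> pd.DataFrame:
    """Pivot the long delta table to subjects × metrics for one delta."""
    return delta_df.pivot(index="subject_id", columns="metric", values=which)
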