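"""Output surfaces: fitted-sensitivity tables and trial yield series as CSV.

All exports are loss-free round-trips at the rendered precision
(percentages to one decimal), so write -> read -> write is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .natural_history import HISTOLOGIES, STAGES
from .screening import SensitivityParams, TrialResult, all_screen_average_sensitivity

__all__ = [
    "write_sensitivity_table",
    "read_sensitivity_table",
    "export_yield_series",
]


def write_sensitivity_table(
    params: SensitivityParams,
    path,
    averages: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write the fitted sensitivity table (percent, one decimal) to CSV.

    Columns: histology, stage, all_screen_average, baseline, repeat.  The
    all-screen average column is filled from ``averages`` (the output of
    :func:`all_screen_average_sensitivity`) when given, else left blank.
    Returns the frame that was written.
    """
    rows = []
    avg_lookup = {}
    if averages is not None:
        avg_lookup = {
            (r.stage, r.histology): r.all_screen_average
            for r in averages.itertuples(index=False)
        }
    for h in HISTOLOGIES:
        for s in STAGES:
            try:
                b = params.value(s, h, False)
                rp = params.value(s, h, True)
            except Exception:
                continue
            avg = avg_lookup.get((s, h), np.nan)
            rows.append(dict(
                histology=h, stage=s,
                all_screen_average=("" if avg is None or (isinstance(avg, float) and np.isnan(avg))
                                    else f"{avg:.1f}"),
                baseline=f"{100.0 * b:.1f}",
                repeat=f"{100.0 * rp:.1f}",
            ))
    df = pd.DataFrame(rows, columns=["histology", "stage", "all_screen_average",
                                     "baseline", "repeat"])
    df.to_csv(path, index=False)
    return df


def read_sensitivity_table(path) -> SensitivityParams:
    """Load a table written by :func:`write_sensitivity_table`."""
    df = pd.read_csv(path, keep_default_na=False)
    df = df.assign(baseline=df.baseline.astype(float),
                   repeat=df["repeat"].astype(float))
    return SensitivityParams.from_percent_frame(df)


def export_yield_series(result: TrialResult, out_dir) -> dict[str, Path]:
    """Write tidy trial-outcome series; returns the written paths.

    ``yield_by_round_stage.csv`` — screen detections by round, stage,
    histology; ``incidence_by_year.csv`` — clinical incidence by year and
    arm; ``mortality_after_detection.csv`` — deaths and person-years by stage
    at detection.  Row sums equal the aggregate counts in ``result``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "yield": out_dir / "yield_by_round_stage.csv",
        "incidence": out_dir / "incidence_by_year.csv",
        "mortality": out_dir / "mortality_after_detection.csv",
    }
    result.yield_frame().to_csv(paths["yield"], index=False)
    result.incidence_frame().to_csv(paths["incidence"], index=False)
    result.mortality_frame().to_csv(paths["mortality"], index=False)
    return paths
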