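"""Human-readable reports and plot-ready exports."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import Dataset


def profile_plot_data(dataset: Dataset, bandwidth: float = 2.0,
                      grid_step: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject raw trajectories plus a kernel-smoothed mean trend.

    Returns ``(profiles, trend)``: the raw (unscaled, ng/mL) measurements and
    a table of (time, smoothed mean) computed by a Gaussian-kernel weighted
    mean with SD ``bandwidth`` months on a regular time grid.  The trend at
    every grid point is a convex combination of observed values, so it lies
    within [min y, max y].
    """
    if dataset.n_obs == 0:
        raise ValueError("profile plot requires at least one measurement")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    mdf = dataset.measurement_frame()
    mdf["y_raw"] = mdf["y"] * dataset.scale_factor
    t = mdf["time"].to_numpy(float)
    y = mdf["y_raw"].to_numpy(float)
    grid = np.arange(t.min(), t.max() + grid_step / 2, grid_step)
    w = np.exp(-0.5 * ((grid[:, None] - t[None, :]) / bandwidth) ** 2)
    trend = (w @ y) / np.sum(w, axis=1)
    profiles = mdf[["subject_id", "time", "y_raw"]].copy()
    return profiles, pd.DataFrame({"time": grid, "trend_mean": trend})


def format_cohort_summary(summary: dict) -> str:
    """Baseline-characteristics table as plain text."""
    d = summary
    lines = [
        "Cohort summary",
        f"  Subjects                     {d['n_subjects']}",
        f"  Measurements                 {d['n_measurements']}"
        f"  (per subject {d['measurements_per_subject_min']}"
        f"-{d['measurements_per_subject_max']})",
        f"  Deaths observed              {d['n_events']}",
        f"  Follow-up, months (mean+/-SD) {d['follow_up_mean_months']:.1f}"
        f" +/- {d['follow_up_sd_months']:.1f}",
        f"  Age, years (mean+/-SD)       {d['age_mean']:.1f} +/- {d['age_sd']:.1f}",
        f"  Male                         {d['male_pct']:.0f}%",
        f"  BMI, kg/m2 (mean+/-SD)       {d['bmi_mean']:.1f} +/- {d['bmi_sd']:.1f}",
        f"  Acute rejection (>=1)        {d['ar_pct']:.0f}%",
        f"  CMV Ag+ (>=1)                {d['cmv_pct']:.0f}%",
        "  Underlying disease",
    ]
    for level, pct in d["disease_pct"].items():
        lines.append(f"    {level:<26} {pct:.0f}%")
    return "\n".join(lines)
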