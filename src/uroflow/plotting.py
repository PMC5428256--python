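"""Plot helpers for trajectories, validation bands and workflow histograms.

Matplotlib is imported lazily so headless/pipeline use never touches a
display backend unless a plot is actually requested.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_trajectory_fit(traj, fit, ax=None):
    """Scan series with its fitted line; returns the axes."""
    plt = _plt()
    ax = ax or plt.subplots()[1]
    t, v = traj.t, traj.volume
    sigma = [m.sigma_v or 0.0 for m in traj.measurements]
    ax.errorbar(t, v, yerr=sigma, fmt="o", label="US scans")
    grid = np.linspace(t.min(), t.max(), 50)
    ax.plot(grid, fit.intercept + fit.vtot * grid,
            label=f"fit: {fit.vtot:.2f} ± {fit.vtot_se:.2f} ml/min")
    ax.set_xlabel("time since void (min)")
    ax.set_ylabel("bladder volume (ml)")
    ax.legend()
    return ax


def plot_validation(records, tolerance=0.42, ax=None):
    """Measured vs. predicted inflow rates with the consistency band."""
    plt = _plt()
    ax = ax or plt.subplots()[1]
    measured = np.array([r.measured_vtot for r in records])
    predicted = np.array([r.predicted_vtot for r in records])
    ax.scatter(measured, predicted, marker="*", c="crimson", label="patients")
    grid = np.linspace(0, max(measured.max(), predicted.max()) * 1.05, 50)
    ax.plot(grid, grid, "k--", lw=0.8)
    ax.fill_between(grid, grid * (1 - tolerance), grid * (1 + tolerance),
                    alpha=0.2, label=f"±{tolerance} band")
    ax.set_xlabel("measured v_tot (ml/min)")
    ax.set_ylabel("predicted v_tot (ml/min)")
    ax.legend()
    return ax


def plot_schedule_histograms(summary, axes=None):
    """Scan-count and waiting-time histograms of a schedule summary."""
    plt = _plt()
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    ax0, ax1 = axes
    sh = summary.scan_histogram
    ax0.bar(sh["n_scans"], sh["fraction"])
    ax0.set_xlabel("US scans per fraction")
    ax0.set_ylabel("fraction of sessions")
    wh = summary.wait_histogram
    ax1.bar(wh["wait_lo_min"], wh["fraction"],
            width=(wh["wait_hi_min"] - wh["wait_lo_min"]).iloc[0] * 0.9,
            align="edge")
    ax1.set_xlabel("waiting time (min)")
    ax1.set_ylabel("fraction of sessions")
    return axes
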