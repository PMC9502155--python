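"""Diagnostic figures: regression lines, calibration curves, metadata.

All plotting is best-effort decoration around the numeric results — figure
generation failures must never fail a workflow, so callers wrap these in
try/except and degrade to warnings.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .singlefield import LinearCalibration
from .stepped import SteppedFieldResults
from .twims import PolynomialCalibration, PowerCalibration

__all__ = [
    "plot_stepped_fit",
    "plot_single_field_calibration",
    "plot_twims_calibration",
]


def plot_stepped_fit(results: SteppedFieldResults, path: str | Path) -> None:
    """Regressor lines with the chosen per-field points, one per conformer."""
    fig, ax = plt.subplots(figsize=(6, 4))
    model = results.model
    for i, conf in enumerate(results.conformers):
        idx = [model.field_ids.index(fid) for fid in conf.field_ids]
        xs = model.x_axis[idx]
        ts = [m.feature.arrival_time for m in conf.features]
        ax.scatter(xs, ts, s=25, label=f"conformer {i + 1} (r²={conf.r_squared:.4f})")
        grid = np.linspace(0, float(model.x_axis.max()) * 1.05, 50)
        ax.plot(grid, conf.slope * grid + conf.intercept_t0, lw=1)
    t = model.target
    ax.set_xlabel("x = 1000·L²·(273.15/760)·P/(T·V)  [ms·cm²/(V·s)]")
    ax.set_ylabel("arrival time [ms]")
    ax.set_title(f"{t.name} {t.adduct.label} (m/z {t.expected_mz:.4f})")
    if results.conformers:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_single_field_calibration(cal: LinearCalibration, path: str | Path) -> None:
    """Calibrant points and fitted line for a single-field calibration."""
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = np.array([p.x_value for p in cal.calibrant_points])
    ts = np.array([p.feature.arrival_time for p in cal.calibrant_points])
    ax.scatter(xs, ts, s=30, zorder=3)
    grid = np.linspace(xs.min() * 0.95, xs.max() * 1.05, 50)
    ax.plot(grid, cal.slope * grid + cal.intercept_t0, lw=1)
    xlabel = "Ω'' = (P/T)·Ω'" if cal.mode == "enhanced" else "Ω' (reduced CCS)"
    ax.set_xlabel(xlabel)
    ax.set_ylabel("scan number" if cal.mode == "tims_scan" else "arrival time [ms]")
    ax.set_title(f"{cal.mode} calibration, run {cal.source_run} (r²={cal.r_squared:.6f})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_twims_calibration(
    cal: PolynomialCalibration | PowerCalibration,
    path: str | Path,
    sample_t_primes: Sequence[float] = (),
) -> None:
    """TWIMS calibration curve with interpolation (solid) and extrapolation
    (dashed) segments; optional sample corrected times as vertical marks."""
    fig, ax = plt.subplots(figsize=(6, 4))
    lo, hi = cal.tA_range
    span = hi - lo
    grid_in = np.linspace(lo, hi, 100)
    grid_lo = np.linspace(max(lo - 0.3 * span, 1e-6), lo, 30)
    grid_hi = np.linspace(hi, hi + 0.3 * span, 30)

    if isinstance(cal, PolynomialCalibration):
        def curve(t):
            return np.polynomial.polynomial.polyval(t, cal.coefficients)
        ylabel = "Ω' (reduced CCS)"
        title = f"polynomial (degree {cal.degree_D})"
    else:
        def curve(t):
            return np.exp(cal.lnY) * np.asarray(t) ** cal.exponent_X
        ylabel = "Ω' (reduced CCS)"
        title = f"power (X={cal.exponent_X:.4f})"

    ax.plot(grid_in, curve(grid_in), "-", lw=1.5, label="interpolation")
    ax.plot(grid_lo, curve(grid_lo), "--", lw=1, color="C0", label="extrapolation")
    ax.plot(grid_hi, curve(grid_hi), "--", lw=1, color="C0")
    for t in sample_t_primes:
        ax.axvline(t, color="C3", lw=0.6, alpha=0.6)
    ax.set_xlabel("corrected arrival time t' [ms]")
    ax.set_ylabel(ylabel)
    ax.set_title(f"TWIMS calibration: {title}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
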