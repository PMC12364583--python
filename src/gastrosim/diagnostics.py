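"""Analysis of gastric trituration runs.

Works on the tidy long-format series written by the runner:

* particle series: one row per (output time, particle) with position, arc
  coordinate s (distance to the pylorus along the centreline, mm),
  surface-mean pressure p_bar (Pa, gauge = duodenal outlet), surface-mean
  shear tau_bar (Pa) and the peak contact-force magnitude in the interval.
* flux series: one row per step with the transpyloric flow rate (mm^2/s).

The ensemble statistics follow the standard definition: <tau> is the mean
over particles of the per-particle surface means tau_bar_n, and likewise
<p>; envelopes are the min/max over particles at each time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ensemble_means",
    "ensemble_series",
    "min_distance_report",
    "percent_excess",
    "emptying_rate",
    "force_statistics",
    "histogram",
    "shuttling_period",
    "descent_time",
    "MinDistanceReport",
]

#: default start of the analysis window (s): descent is complete by then
ANALYSIS_START = 20.0


def ensemble_means(loads) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """(<tau>, <p>, (tau_min, tau_max), (p_min, p_max)) over a list of loads.

    ``loads`` is a sequence of ParticleLoads (or any objects with
    ``tau_mean``/``p_mean``).
    """
    if len(loads) == 0:
        raise ValueError("ensemble statistics need at least one particle")
    taus = np.array([ld.tau_mean for ld in loads])
    ps = np.array([ld.p_mean for ld in loads])
    return (
        float(taus.mean()),
        float(ps.mean()),
        (float(taus.min()), float(taus.max())),
        (float(ps.min()), float(ps.max())),
    )


def ensemble_series(particles_df: pd.DataFrame) -> pd.DataFrame:
    """Per-time ensemble mean and min/max envelope of tau_bar and p_bar."""
    grp = particles_df.groupby("t")
    out = grp.agg(
        tau_mean=("tau_bar", "mean"),
        tau_min=("tau_bar", "min"),
        tau_max=("tau_bar", "max"),
        p_mean=("p_bar", "mean"),
        p_min=("p_bar", "min"),
        p_max=("p_bar", "max"),
        n=("particle", "size"),
    ).reset_index()
    return out


@dataclass(frozen=True)
class MinDistanceReport:
    """Per-particle minimum distance to the pylorus, plus the average."""

    minima: np.ndarray       # sorted ascending (mm)
    by_particle: dict
    average: float           # mm


def min_distance_report(particles_df: pd.DataFrame, t_start: float = ANALYSIS_START) -> MinDistanceReport:
    """Minimum of s_n(t) per particle, restricted to t >= t_start (post-descent)."""
    df = particles_df[particles_df["t"] >= t_start]
    if df.empty:
        warnings.warn("run shorter than the descent phase; no samples after t_start")
        df = particles_df
    mins = df.groupby("particle")["s"].min()
    return MinDistanceReport(
        minima=np.sort(mins.to_numpy()),
        by_particle=mins.to_dict(),
        average=float(mins.mean()),
    )


def percent_excess(value: float, reference: float) -> float:
    """How much larger ``value`` is than ``reference``, in percent."""
    return 100.0 * (value - reference) / reference


def emptying_rate(
    flux_df: pd.DataFrame,
    window: tuple[float, float],
    period: float = 20.0,
    depth_mm: float = 4.0,
) -> float:
    """Time-averaged transpyloric volume flow over ``window``, in ml/min.

    The window should span an integer number of wave periods; otherwise the
    pulsatile component aliases into the mean and a warning is issued.  The
    2D flux (mm^2/s) is converted with the nominal depth.
    """
    t0, t1 = window
    span = t1 - t0
    if abs(span / period - round(span / period)) > 1e-6:
        warnings.warn(
            f"averaging window {span:.3f}s is not an integer number of "
            f"wave periods ({period}s): the mean aliases the pulsatile flux"
        )
    df = flux_df[(flux_df["t"] > t0) & (flux_df["t"] <= t1)]
    if df.empty:
        raise ValueError("empty averaging window")
    q_mean = float(np.average(df["q"], weights=df["dt"]))      # mm^2/s
    return q_mean * depth_mm * 60.0 / 1000.0                    # ml/min


def force_statistics(
    particles_df: pd.DataFrame,
    t_start: float = ANALYSIS_START,
    t_end: float | None = None,
) -> pd.DataFrame:
    """Mean, population s.d. and max of surface pressure and shear.

    Statistics are pooled over all particles and output times in the window,
    the convention used for the summary tables.  Shear is reported in mPa,
    pressure in Pa (gauge = duodenal outlet).
    """
    df = particles_df[particles_df["t"] >= t_start]
    if t_end is not None:
        df = df[df["t"] <= t_end]
    rows = []
    for name, col, scale in (("p - p_duo (Pa)", "p_bar", 1.0), ("tau (mPa)", "tau_bar", 1e3)):
        x = df[col].to_numpy() * scale
        rows.append(
            {"quantity": name, "mean": x.mean(), "sd": x.std(ddof=0), "max": x.max()}
        )
    return pd.DataFrame(rows)


def histogram(values, bins="fd") -> tuple[np.ndarray, np.ndarray]:
    """Binned counts over all particle-time samples (Freedman-Diaconis default)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty series")
    counts, edges = np.histogram(values, bins=bins)
    return counts, edges


def shuttling_period(
    particles_df: pd.DataFrame,
    t_start: float = ANALYSIS_START,
    period_range: tuple[float, float] = (5.0, 60.0),
) -> float:
    """Dominant oscillation period (s) of the distance-to-pylorus signal.

    Uses a Lomb-Scargle periodogram of the demeaned per-particle s_n(t),
    summed over particles, on a dense period grid; robust for the few cycles
    a 1-2 minute run contains.
    """
    from scipy.signal import lombscargle

    df = particles_df[particles_df["t"] >= t_start]
    if df.empty:
        raise ValueError("no samples after t_start")
    periods = np.linspace(period_range[0], period_range[1], 2000)
    omega = 2.0 * np.pi / periods
    power = np.zeros_like(omega)
    for _, sub in df.groupby("particle"):
        t = sub["t"].to_numpy()
        y = sub["s"].to_numpy()
        y = y - y.mean()
        tr = t - t.mean()
        # subtract the linear trend so slow drift does not mask the oscillation
        y = y - np.polyval(np.polyfit(tr, y, 1), tr)
        power += lombscargle(t, y, omega)
    return float(periods[np.argmax(power)])


def descent_time(particles_df: pd.DataFrame, s_antrum: float) -> float:
    """Time at which the last particle first enters the antral band s < s_antrum."""
    entries = []
    for pid, sub in particles_df.groupby("particle"):
        inside = sub[sub["s"] < s_antrum]
        if inside.empty:
            raise ValueError(f"particle {pid} never entered the antral band")
        entries.append(float(inside["t"].iloc[0]))
    return max(entries)
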