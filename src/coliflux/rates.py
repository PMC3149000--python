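"""Specific rates from continuous-cultivation time series.

Converts measured culture time series (dilution rate D, biomass X, feed and
broth concentrations, volumetric CO2 evolution) into biomass-specific rates
(mmol / g DCW / h) under three regimes:

* chemostat: true steady state, mu = D, algebraic balances;
* A-stat: D rises at a slow constant acceleration (default 0.01 1/h^2), the
  culture tracks a quasi steady state; accumulation terms are kept
  (mu = D + X'/X, q_P = (P' + D (P - P_feed)) / X) with derivatives from a
  centred local linear regression;
* D-stat: constant D while the feed changes (here acetate co-feeding); the
  same A-stat balances apply with D' = 0.

Sign conventions: glucose uptake positive; product excretion positive,
consumption negative (acetate is negative under D-stat co-utilisation).

Units: time h, concentrations mM, biomass g DCW/L, volumetric CO2 rate
mmol/L/h, specific rates mmol/gDCW/h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GLUCOSE_MOLAR_MASS = 0.18016  # g/mmol

__all__ = [
    "CultureTimeSeries",
    "SteadyStateSnapshot",
    "NonStationaryError",
    "specific_rates_chemostat",
    "specific_rates_astat",
    "detect_overflow_onset",
    "read_timeseries",
    "write_timeseries",
    "NO_OVERFLOW",
]

log = logging.getLogger(__name__)

#: sentinel returned by detect_overflow_onset when acetate never overflows
NO_OVERFLOW = None


class NonStationaryError(ValueError):
    """A chemostat window violates the stationarity precondition."""


@dataclass
class CultureTimeSeries:
    time: np.ndarray                       # h, strictly increasing
    dilution_rate: np.ndarray              # 1/h
    biomass: np.ndarray                    # g DCW / L
    feed_concentrations: dict[str, np.ndarray]   # mM in feed
    broth_concentrations: dict[str, np.ndarray]  # mM in broth
    co2_rate: np.ndarray                   # mmol / L / h (volumetric CER)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        n = len(self.time)
        for name in ("dilution_rate", "biomass", "co2_rate"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)
        if np.any(self.dilution_rate < 0):
            raise ValueError("dilution_rate must be >= 0")
        for d in (self.feed_concentrations, self.broth_concentrations):
            for k, v in d.items():
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise ValueError(f"concentration series {k} length mismatch")
                d[k] = v

    @property
    def species(self) -> list[str]:
        return sorted(self.broth_concentrations)

    def index_at(self, t: float) -> int:
        if t < self.time[0] or t > self.time[-1]:
            raise ValueError(f"t={t} outside series range")
        return int(np.argmin(np.abs(self.time - t)))


@dataclass
class SteadyStateSnapshot:
    """One physiological state: mu plus biomass-specific exchange rates."""

    mu: float                      # 1/h
    q_glc: float                   # glucose uptake, positive
    q_products: dict[str, float]   # excretion positive, consumption negative
    r_co2: float                   # specific CO2 evolution
    biomass_yield: float = float("nan")  # g DCW per g glucose

    def __post_init__(self) -> None:
        if self.q_glc < -1e-12:
            raise ValueError("q_glc must be non-negative (uptake positive)")

    @property
    def q_acetate(self) -> float:
        return self.q_products.get("acetate", 0.0)

    def per_biomass(self) -> dict[str, float]:
        """Per-biomass product amounts O_x = q_x / mu (mmol / g DCW), the
        alternative reading of steady-state production tables."""
        if self.mu <= 0:
            raise ValueError("per-biomass view requires mu > 0")
        return {k: v / self.mu for k, v in self.q_products.items()}


def _window_slice(series: CultureTimeSeries, window: tuple[float, float]) -> slice:
    t0, t1 = window
    i0 = int(np.searchsorted(series.time, t0, side="left"))
    i1 = int(np.searchsorted(series.time, t1, side="right"))
    if i1 - i0 < 2:
        raise ValueError("window contains fewer than two samples")
    return slice(i0, i1)


def specific_rates_chemostat(
    series: CultureTimeSeries,
    window: tuple[float, float],
    drift_threshold: float = 0.05,
) -> SteadyStateSnapshot:
    """Steady-state balances averaged over a stationary window.

    mu = D; q_S = D (S_feed - S) / X; q_P = D (P - P_feed) / X;
    r_CO2 = CER / X.  Raises NonStationaryError if D varies or any
    concentration drifts by more than ``drift_threshold`` (relative, over the
    window) for species with non-negligible levels.
    """
    sl = _window_slice(series, window)
    D = series.dilution_rate[sl]
    if np.ptp(D) > 1e-9 + 1e-6 * np.abs(D).max():
        raise NonStationaryError("dilution rate is not constant over the window")
    X = series.biomass[sl]
    if np.any(X <= 0):
        raise ValueError("biomass must be positive over the window")
    tw = series.time[sl]
    for name, arr in {"biomass": X, **{
        k: v[sl] for k, v in series.broth_concentrations.items()
    }}.items():
        scale = np.abs(arr).mean()
        if scale <= 1e-6:
            continue
        # drift = fitted linear trend over the window (robust to noise)
        slope = np.polyfit(tw, arr, 1)[0]
        drift = abs(slope) * (tw[-1] - tw[0]) / scale
        if drift > drift_threshold:
            raise NonStationaryError(
                f"{name} drifts by {drift:.1%} over the window "
                f"(threshold {drift_threshold:.0%})"
            )
    Dm, Xm = D.mean(), X.mean()
    mu = Dm
    feed = {k: v[sl].mean() for k, v in series.feed_concentrations.items()}
    broth = {k: v[sl].mean() for k, v in series.broth_concentrations.items()}
    q_glc = Dm * (feed.get("glucose", 0.0) - broth.get("glucose", 0.0)) / Xm
    q_products = {
        k: Dm * (broth[k] - feed.get(k, 0.0)) / Xm
        for k in broth
        if k != "glucose"
    }
    r_co2 = series.co2_rate[sl].mean() / Xm
    yield_xs = mu / (q_glc * GLUCOSE_MOLAR_MASS) if q_glc > 0 else float("nan")
    return SteadyStateSnapshot(mu, q_glc, q_products, r_co2, yield_xs)


def _local_derivative(
    t: np.ndarray, y: np.ndarray, i: int, window_points: int
) -> tuple[float, float]:
    """Centred local linear regression; returns (value, slope) at index i."""
    half = window_points // 2
    lo = max(0, i - half)
    hi = min(len(t), i + half + 1)
    tw, yw = t[lo:hi], y[lo:hi]
    slope, intercept = np.polyfit(tw - t[i], yw, 1)
    return float(intercept), float(slope)


def specific_rates_astat(
    series: CultureTimeSeries,
    t: float,
    window_points: int = 11,
    acceleration_bound: float = 0.01,
) -> SteadyStateSnapshot:
    """Quasi-steady-state rates at time t of an A-stat (or D-stat) ramp.

    mu = D + X'/X; q_S = (D (S_feed - S) - S') / X;
    q_P = (P' + D (P - P_feed)) / X.  Derivatives come from a centred local
    linear regression over ``window_points`` samples.  The acceleration
    dD/dt must not exceed ``acceleration_bound`` (default the standard
    A-stat acceleration 0.01 1/h^2).
    """
    i = series.index_at(t)
    _, dDdt = _local_derivative(series.time, series.dilution_rate, i, window_points)
    if dDdt > acceleration_bound * (1 + 1e-6) + 1e-12:
        raise ValueError(
            f"dD/dt = {dDdt:.4f} 1/h^2 exceeds the quasi-steady-state bound "
            f"{acceleration_bound} 1/h^2"
        )
    D = series.dilution_rate[i]
    X, _ = _local_derivative(series.time, series.biomass, i, window_points)
    # biomass is the slowest channel; estimate its trend over a wider window
    # so measurement noise does not leak into mu = D + X'/X
    _, dXdt = _local_derivative(series.time, series.biomass, i, 3 * window_points)
    if X <= 0:
        raise ValueError("biomass must be positive")
    mu = D + dXdt / X
    feed = {k: v[i] for k, v in series.feed_concentrations.items()}
    qssa_log: dict[str, float] = {}
    q_products = {}
    q_glc = 0.0
    for k in series.broth_concentrations:
        C, dCdt = _local_derivative(
            series.time, series.broth_concentrations[k], i, window_points
        )
        dilution_term = D * (C - feed.get(k, 0.0))
        if k == "glucose":
            q_glc = (-dilution_term - dCdt) / X
        else:
            q_products[k] = (dCdt + dilution_term) / X
        denom = max(abs(dilution_term), 1e-12)
        qssa_log[k] = abs(dCdt) / denom
    log.debug("quasi-steady-state derivative/dilution ratios at t=%.2f: %s",
              t, qssa_log)
    cer, _ = _local_derivative(series.time, series.co2_rate, i, window_points)
    r_co2 = cer / X
    yield_xs = mu / (q_glc * GLUCOSE_MOLAR_MASS) if q_glc > 0 else float("nan")
    return SteadyStateSnapshot(mu, q_glc, q_products, r_co2, yield_xs)


def detect_overflow_onset(
    snapshots: list[SteadyStateSnapshot],
    threshold: float = 0.05,
    refine: bool = True,
) -> float | None:
    """Specific growth rate at which acetate overflow starts.

    The detection gate is the smallest mu at which acetate excretion exceeds
    ``threshold`` (mmol/gDCW/h) and stays above it for all later snapshots.
    With ``refine`` (default), the early above-threshold segment is fitted
    with a line in mu and the onset is back-extrapolated to the zero
    crossing, which removes the lag introduced by the finite threshold on a
    ramping profile; the refinement falls back to the gate mu whenever the
    fit is unusable (flat or decreasing profile, or a crossing outside the
    bracketing snapshots).

    Returns :data:`NO_OVERFLOW` (None) when no sustained onset exists.
    Snapshots are sorted by mu internally; at least 5 are required.
    """
    if len(snapshots) < 5:
        raise ValueError("need at least 5 snapshots spanning the onset")
    snaps = sorted(snapshots, key=lambda s: s.mu)
    above = np.array([s.q_acetate > threshold for s in snaps])
    gate = None
    for i in range(len(snaps)):
        if above[i] and above[i:].all():
            gate = i
            break
    if gate is None:
        return NO_OVERFLOW
    mu_gate = snaps[gate].mu
    if not refine:
        return mu_gate
    seg = snaps[gate : gate + 10]
    if len(seg) < 3:
        return mu_gate
    mus = np.array([s.mu for s in seg])
    # per-biomass production q/mu is linear in mu for a ramping onset, so its
    # zero crossing locates the start of accumulation without curvature bias
    qs = np.array([s.q_acetate / s.mu for s in seg])
    slope, intercept = np.polyfit(mus, qs, 1)
    if slope <= 0:
        return mu_gate
    mu_zero = -intercept / slope
    lower = mu_gate - (mus[-1] - mus[0])
    if lower <= mu_zero <= mu_gate:
        return float(mu_zero)
    return mu_gate


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_timeseries(series: CultureTimeSeries, path: str | Path) -> None:
    """Delimited text, one row per time point.  Columns: time (h),
    dilution_rate (1/h), biomass (gDCW/L), co2_rate (mmol/L/h),
    feed_<species> and broth_<species> (mM)."""
    df = pd.DataFrame(
        {
            "time": series.time,
            "dilution_rate": series.dilution_rate,
            "biomass": series.biomass,
            "co2_rate": series.co2_rate,
        }
    )
    for k, v in sorted(series.feed_concentrations.items()):
        df[f"feed_{k}"] = v
    for k, v in sorted(series.broth_concentrations.items()):
        df[f"broth_{k}"] = v
    df.to_csv(path, index=False, float_format="%.8g")


def read_timeseries(path: str | Path) -> CultureTimeSeries:
    """Read a time-series file; missing values are linearly interpolated
    (count logged)."""
    df = pd.read_csv(path)
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        log.info("interpolating %d missing values in %s", n_missing, path)
        df = df.interpolate(limit_direction="both")
    feed = {
        c[len("feed_"):]: df[c].to_numpy()
        for c in df.columns
        if c.startswith("feed_")
    }
    broth = {
        c[len("broth_"):]: df[c].to_numpy()
        for c in df.columns
        if c.startswith("broth_")
    }
    return CultureTimeSeries(
        time=df["time"].to_numpy(),
        dilution_rate=df["dilution_rate"].to_numpy(),
        biomass=df["biomass"].to_numpy(),
        feed_concentrations=feed,
        broth_concentrations=broth,
        co2_rate=df["co2_rate"].to_numpy(),
    )
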