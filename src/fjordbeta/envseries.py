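"""Environmental sensor time series: containers, preprocessing and exposure metrics.

The measurements this module handles come from a fixed seafloor sensor package:
dissolved oxygen (ml l-1), temperature (deg C), salinity (PSU), pressure (dbar)
and acoustic backscatter (counts), sampled at minute-scale intervals over months
to years.  Operations cover the standard preprocessing chain for such records —
constant sensor-offset correction, conversion of oxygen concentration to partial
pressure (the physiologically relevant quantity for water breathers), windowed
summary statistics aligned to biological sampling times, gap interpolation,
running means — and the long-term hypoxia-exposure metrics (decadal trend,
annual duration below ecological oxygen thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "EnvSeries",
    "WindowSummary",
    "ExposureReport",
    "correct_offset",
    "oxygen_solubility",
    "water_vapor_pressure_kpa",
    "compute_po2",
    "add_po2",
    "summarize_window",
    "interpolate_gaps",
    "running_mean",
    "decadal_trend",
    "threshold_durations",
]

#: mole fraction of O2 in dry air
X_O2 = 0.20946
#: standard atmospheric pressure, kPa
P_ATM_KPA = 101.325

SECONDS_PER_DAY = 86400.0


class EnvSeries:
    """Timestamped multichannel environmental series with a per-channel missing mask.

    Values and the missing mask are stored separately: masking a sample marks it
    unavailable without destroying the stored number, so downstream stages can
    choose their own gap-handling strategy (interpolation, supplementary basis
    points, exclusion).

    Parameters
    ----------
    values : pandas.DataFrame
        Float columns on a strictly increasing :class:`~pandas.DatetimeIndex`.
    mask : pandas.DataFrame or None
        Boolean frame aligned with *values*; ``True`` marks a missing sample.
        NaNs in *values* are always treated as missing in addition to the mask.
    """

    def __init__(self, values: pd.DataFrame, mask: pd.DataFrame | None = None):
        if not isinstance(values.index, pd.DatetimeIndex):
            raise TypeError("EnvSeries requires a DatetimeIndex")
        if len(values) > 1 and not values.index.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if values.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing (duplicates found)")
        self.values = values.astype(float)
        if mask is None:
            mask = pd.DataFrame(False, index=values.index, columns=values.columns)
        else:
            mask = mask.reindex(index=values.index, columns=values.columns).fillna(False)
        self.mask = mask.astype(bool) | values.isna()

    # -- basic protocol ------------------------------------------------
    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.values.index

    @property
    def channels(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def copy(self) -> "EnvSeries":
        return EnvSeries(self.values.copy(), self.mask.copy())

    def observed(self) -> pd.DataFrame:
        """Values with missing samples replaced by NaN."""
        return self.values.mask(self.mask)

    def subset(self, start=None, end=None) -> "EnvSeries":
        sl = self.values.loc[start:end]
        return EnvSeries(sl, self.mask.loc[sl.index])

    def channel(self, name: str) -> pd.Series:
        """One channel with missing samples as NaN."""
        return self.values[name].mask(self.mask[name])

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write with ISO-8601 timestamps; missing cells are left empty."""
        out = self.observed()
        out.index.name = "timestamp"
        out.to_csv(path, date_format="%Y-%m-%dT%H:%M:%SZ")

    @classmethod
    def from_csv(cls, path) -> "EnvSeries":
        df = pd.read_csv(path, index_col="timestamp", parse_dates=["timestamp"])
        df.index = pd.DatetimeIndex(df.index).tz_localize(None)
        return cls(df, df.isna())


@dataclass
class WindowSummary:
    """Per-channel mean/s.d./max/min over a trailing window before each target time.

    ``stats`` holds one DataFrame per statistic keyed ``mean``, ``sd``, ``max``,
    ``min``; rows are target timestamps, columns channels.  ``coverage`` is the
    fraction of the window's nominal samples that were observed.  Windows are
    half-open ``(t - window, t]`` so a sample taken exactly at a target belongs
    to that target's window only.
    """

    targets: pd.DatetimeIndex
    window: pd.Timedelta
    stats: dict[str, pd.DataFrame]
    coverage: pd.DataFrame

    def table(self) -> pd.DataFrame:
        """Wide table with ``channel_stat`` columns (e.g. ``o2_conc_mean``)."""
        parts = {}
        for stat, df in self.stats.items():
            for ch in df.columns:
                parts[f"{ch}_{stat}"] = df[ch]
        return pd.DataFrame(parts, index=self.targets)


@dataclass
class ExposureReport:
    """Annual cumulative days below oxygen thresholds, with linear trends.

    ``durations``: rows = year starts, one column per threshold, values in days
    (NaN for years with no usable record).  ``trends``: per threshold, the OLS
    slope of duration on year (days per year), its p-value and adjusted R².
    """

    durations: pd.DataFrame
    thresholds: tuple[float, ...]
    trends: dict[float, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.durations.copy()

    def to_json_dict(self) -> dict:
        return {
            "thresholds": list(self.thresholds),
            "durations_days": {
                str(th): [None if np.isnan(v) else float(v) for v in self.durations[th]]
                for th in self.thresholds
            },
            "year_starts": [str(t.date()) for t in self.durations.index],
            "trends": {str(th): tr for th, tr in self.trends.items()},
        }


# ---------------------------------------------------------------------------
# offset correction and oxygen partial pressure
# ---------------------------------------------------------------------------

def correct_offset(series: EnvSeries, offset: float, channel: str = "o2_conc") -> EnvSeries:
    """Subtract a constant sensor offset from the oxygen channel, clamping at zero.

    Optode records in persistently anoxic water commonly show a small positive
    offset that manifests as the minimum of the measurement histogram; the
    minimum is interpreted as true anoxia, so the offset is removed and any
    resulting negative concentrations are clamped to zero.
    """
    if not np.isfinite(offset) or offset < 0:
        raise ValueError(f"offset must be finite and >= 0, got {offset}")
    out = series.copy()
    out.values[channel] = np.clip(out.values[channel] - offset, 0.0, None)
    return out


def oxygen_solubility(temperature, salinity):
    """Oxygen solubility at air saturation, ml(STP) l-1 (Garcia & Gordon 1992 fit).

    Valid for T in roughly [-2, 40] degC and S in [0, 42]; pressure is taken as
    1 atm total (the convention of the fit).
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    ts = np.log((298.15 - t) / (273.15 + t))
    a = (2.00907, 3.22014, 4.05010, 4.94457, -0.256847, 3.88767)
    b = (-0.00624523, -0.00737614, -0.0103410, -0.00817083)
    c0 = -4.88682e-7
    lnc = np.polyval(a[::-1], ts) + s * np.polyval(b[::-1], ts) + c0 * s * s
    return np.exp(lnc)


def water_vapor_pressure_kpa(temperature, salinity):
    """Saturation water vapour pressure over seawater, kPa (Weiss & Price 1980)."""
    tk = np.asarray(temperature, dtype=float) + 273.15
    s = np.asarray(salinity, dtype=float)
    ln_atm = 24.4543 - 67.4509 * (100.0 / tk) - 4.8489 * np.log(tk / 100.0) - 0.000544 * s
    return np.exp(ln_atm) * P_ATM_KPA


def compute_po2(o2_conc, temperature, salinity, pressure=None, p_atm_kpa: float = P_ATM_KPA):
    """Oxygen partial pressure (kPa) from concentration and in-situ T and S.

    pO2 = (C / Csat(T, S)) * xO2 * (Patm - pH2O(T, S)),

    i.e. the fractional air saturation times the partial pressure of oxygen in
    water-saturated air at one atmosphere.  The relation is linear in C, zero
    iff C is zero, and strictly increasing in C at fixed T, S.  Hydrostatic
    pressure does not enter: partial pressure at depth is set by the gas
    content relative to surface equilibration, and *pressure* is accepted only
    so callers can pass the full CTD record through one signature.
    """
    c = np.asarray(o2_conc, dtype=float)
    if np.any(c[np.isfinite(c)] < 0):
        raise ValueError("negative oxygen concentration; apply offset correction first")
    csat = oxygen_solubility(temperature, salinity)
    pv = water_vapor_pressure_kpa(temperature, salinity)
    return (c / csat) * X_O2 * (p_atm_kpa - pv)


def add_po2(series: EnvSeries, channel_out: str = "po2") -> EnvSeries:
    """Attach a pO2 channel (kPa) computed from o2_conc, temperature, salinity."""
    needed = ("o2_conc", "temperature", "salinity")
    for ch in needed:
        if ch not in series.channels:
            raise ValueError(f"missing channel {ch!r} required for pO2")
    out = series.copy()
    po2 = compute_po2(
        series.values["o2_conc"].to_numpy(),
        series.values["temperature"].to_numpy(),
        series.values["salinity"].to_numpy(),
    )
    out.values[channel_out] = po2
    out.mask[channel_out] = series.mask[needed[0]] | series.mask[needed[1]] | series.mask[needed[2]]
    return out


# ---------------------------------------------------------------------------
# window summaries
# ---------------------------------------------------------------------------

def summarize_window(
    series: EnvSeries,
    targets,
    window: pd.Timedelta | str = "12h",
) -> WindowSummary:
    """Mean, s.d., max and min of each channel over the window preceding each target.

    Windows are half-open ``(t - window, t]`` and use only non-missing samples;
    the sample standard deviation (n-1 denominator) is reported, 0 for a
    single-sample window.  A target whose window holds no observations yields
    NaN for every statistic.  Coverage is the observed-sample count divided by
    the window's nominal capacity at the series' median sampling interval.
    """
    window = pd.Timedelta(window)
    if window <= pd.Timedelta(0):
        raise ValueError("window must be positive")
    targets = pd.DatetimeIndex(targets)
    ts = series.timestamps.asi8
    lo = np.searchsorted(ts, (targets - window).asi8, side="right")
    hi = np.searchsorted(ts, targets.asi8, side="right")

    if len(series) > 1:
        dt_ns = float(np.median(np.diff(ts)))
    else:
        dt_ns = float(window.value)
    capacity = max(1.0, window.value / dt_ns)

    stats = {s: {} for s in ("mean", "sd", "max", "min")}
    cov = {}
    for ch in series.channels:
        x = series.values[ch].to_numpy(dtype=float)
        miss = series.mask[ch].to_numpy()
        mean = np.full(len(targets), np.nan)
        sd = np.full(len(targets), np.nan)
        mx = np.full(len(targets), np.nan)
        mn = np.full(len(targets), np.nan)
        n_obs = np.zeros(len(targets))
        for k in range(len(targets)):
            seg = x[lo[k]:hi[k]]
            ok = ~miss[lo[k]:hi[k]] & np.isfinite(seg)
            seg = seg[ok]
            n_obs[k] = seg.size
            if seg.size:
                mean[k] = seg.mean()
                sd[k] = seg.std(ddof=1) if seg.size > 1 else 0.0
                mx[k] = seg.max()
                mn[k] = seg.min()
        stats["mean"][ch] = mean
        stats["sd"][ch] = sd
        stats["max"][ch] = mx
        stats["min"][ch] = mn
        cov[ch] = np.minimum(1.0, n_obs / capacity)

    return WindowSummary(
        targets=targets,
        window=window,
        stats={s: pd.DataFrame(d, index=targets) for s, d in stats.items()},
        coverage=pd.DataFrame(cov, index=targets),
    )


# ---------------------------------------------------------------------------
# gap interpolation and running mean
# ---------------------------------------------------------------------------

def interpolate_gaps(series: EnvSeries, max_gap: pd.Timedelta | str | None = None) -> EnvSeries:
    """Linearly interpolate missing runs in time; never extrapolate at the ends.

    If *max_gap* is given, only missing runs whose anchor-to-anchor span is at
    most that duration are filled; longer gaps stay missing.
    """
    out = series.copy()
    max_gap = pd.Timedelta(max_gap) if max_gap is not None else None
    t = series.timestamps
    tnum = t.asi8.astype(float)
    for ch in series.channels:
        vals = series.channel(ch)
        miss = vals.isna().to_numpy()
        if miss.all():
            raise ValueError(f"channel {ch!r} has no observed samples to interpolate from")
        if not miss.any():
            continue
        filled = vals.to_numpy(dtype=float).copy()
        obs_idx = np.flatnonzero(~miss)
        interior = (np.arange(len(t)) >= obs_idx[0]) & (np.arange(len(t)) <= obs_idx[-1])
        fill = miss & interior
        if max_gap is not None:
            prev_obs = np.searchsorted(obs_idx, np.flatnonzero(fill), side="left") - 1
            lo = obs_idx[prev_obs]
            hi = obs_idx[np.minimum(prev_obs + 1, len(obs_idx) - 1)]
            span_ok = (tnum[hi] - tnum[lo]) <= max_gap.value
            sel = np.flatnonzero(fill)
            fill = np.zeros_like(miss)
            fill[sel[span_ok]] = True
        filled[fill] = np.interp(tnum[fill], tnum[obs_idx], vals.to_numpy(dtype=float)[obs_idx])
        new_mask = miss & ~fill
        out.values[ch] = filled
        out.mask[ch] = new_mask
    return out


def running_mean(
    series: EnvSeries,
    window: pd.Timedelta | str = "365D",
    trim: pd.Timedelta | str = "182D",
) -> EnvSeries:
    """Centred moving average with the boundary-affected ends trimmed off.

    The window is time-based (so irregular sampling is handled) and *trim* is
    removed from both ends of the output to drop the partially covered edges.
    """
    window = pd.Timedelta(window)
    trim = pd.Timedelta(trim)
    span = series.timestamps[-1] - series.timestamps[0]
    if window > span:
        raise ValueError("running-mean window exceeds the record span")
    # closed='both' keeps the window symmetric, so a linear signal is unchanged
    sm_vals = series.observed().rolling(window, center=True, min_periods=1,
                                        closed="both").mean()
    t0 = series.timestamps[0] + trim
    t1 = series.timestamps[-1] - trim
    sel = sm_vals.loc[t0:t1]
    return EnvSeries(sel, sel.isna())


# ---------------------------------------------------------------------------
# long-term trends and threshold durations
# ---------------------------------------------------------------------------

def _ols_on_time(t_years: np.ndarray, y: np.ndarray):
    X = sm.add_constant(t_years)
    return sm.OLS(y, X).fit()


def decadal_trend(
    series: EnvSeries,
    channel: str = "o2_conc",
    truncate_at_maxima: bool = True,
    smooth: pd.Timedelta | str = "30D",
    edge: pd.Timedelta | str = "548D",
):
    """Long-term linear trend of a channel (units per year) on the interpolated record.

    A multi-year record with a strong seasonal cycle biases an OLS slope when
    the record starts and ends at different phases of the cycle.  With
    *truncate_at_maxima* the record is cut at the first and the last seasonal
    maximum — located on a lightly smoothed copy (window *smooth*) within
    *edge* of each end — so both endpoints sit at the same phase of the annual
    cycle before fitting.

    Returns ``(slope, p_value, fit)`` with *fit* the statsmodels OLS results.
    """
    filled = interpolate_gaps(series)
    vals = filled.channel(channel).dropna()
    if vals.index[-1] - vals.index[0] <= pd.Timedelta(0) or len(vals) < 2:
        raise ValueError("record too short for a trend")
    if truncate_at_maxima:
        r = vals.rolling(pd.Timedelta(smooth), center=True, min_periods=1).mean()
        edge = pd.Timedelta(edge)
        head = r.loc[: r.index[0] + edge]
        tail = r.loc[r.index[-1] - edge:]
        vals = vals.loc[head.idxmax(): tail.idxmax()]
        if len(vals) < 2:
            raise ValueError("truncation left a degenerate record")
    t_years = (vals.index - vals.index[0]).total_seconds() / (365.25 * SECONDS_PER_DAY)
    fit = _ols_on_time(np.asarray(t_years), vals.to_numpy())
    return float(fit.params[1]), float(fit.pvalues[1]), fit


def _year_boundaries(index: pd.DatetimeIndex, month: int, day: int) -> list[pd.Timestamp]:
    first = pd.Timestamp(year=index[0].year, month=month, day=day)
    if first > index[0]:
        first = pd.Timestamp(year=index[0].year - 1, month=month, day=day)
    bounds = [first]
    while bounds[-1] < index[-1]:
        bounds.append(pd.Timestamp(year=bounds[-1].year + 1, month=month, day=day))
    return bounds


def threshold_durations(
    series: EnvSeries,
    thresholds: tuple[float, ...] = (0.5, 0.88),
    channel: str = "o2_conc",
    year_start: tuple[int, int] = (3, 16),
    min_coverage: float = 0.5,
) -> ExposureReport:
    """Cumulative days per year below each threshold, plus the linear trend in time.

    Time below threshold is integrated on the sampling grid (each observed
    sample contributes one sampling interval).  Years start on the *year_start*
    anniversary (month, day); a year covering less than *min_coverage* of its
    span is reported as missing rather than zero.  For each threshold an OLS
    regression of duration on year index gives the trend (days per year), its
    p-value and adjusted R².
    """
    if any(th <= 0 for th in thresholds):
        raise ValueError("thresholds must be positive")
    vals = series.channel(channel)
    t = vals.index
    if len(t) < 2:
        raise ValueError("record too short")
    dt_days = np.median(np.diff(t.asi8)) / 1e9 / SECONDS_PER_DAY
    bounds = _year_boundaries(t, *year_start)

    rows = {}
    for start, stop in zip(bounds[:-1], bounds[1:]):
        seg = vals.loc[start: stop - pd.Timedelta(1, "ns")]
        span_days = (min(stop, t[-1] + pd.Timedelta(dt_days, "D")) - max(start, t[0])).total_seconds() / SECONDS_PER_DAY
        obs = seg.dropna()
        coverage = len(obs) * dt_days / span_days if span_days > 0 else 0.0
        if span_days <= 0 or coverage < min_coverage:
            rows[start] = {th: np.nan for th in thresholds}
            continue
        rows[start] = {th: float((obs < th).sum() * dt_days) for th in thresholds}

    durations = pd.DataFrame.from_dict(rows, orient="index")[list(thresholds)]
    report = ExposureReport(durations=durations, thresholds=tuple(thresholds))
    year_idx = np.array([(d - durations.index[0]).days / 365.25 for d in durations.index])
    for th in thresholds:
        y = durations[th].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() >= 3:
            fit = _ols_on_time(year_idx[ok], y[ok])
            report.trends[th] = {
                "slope_days_per_year": float(fit.params[1]),
                "p_value": float(fit.pvalues[1]),
                "adj_r2": float(fit.rsquared_adj),
            }
        else:
            report.trends[th] = {"slope_days_per_year": np.nan, "p_value": np.nan, "adj_r2": np.nan}
    return report
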