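"""Deriving analysis traits from field records and soil-temperature series.

Soil temperature 5 cm below the surface, logged at 2-h intervals, shows
a characteristic snow-cover signature: a long near-zero plateau (snow
insulation) ending in a sharp rise at snowmelt.  The snowmelt day is
detected as the first day whose daily mean exceeds a rise threshold
after a sufficiently long run of days inside a flat band around 0 deg C.

Derived traits per patch:

* ``leaf_size`` — ellipse area ``pi * (length/2) * (width/2)`` in mm^2,
  averaged over the measured leaves;
* ``snowmelt_to_leaf_expansion`` — days from site snowmelt to first leaf
  expansion;
* ``gdd_to_leaf_expansion`` / ``gdd_to_flowering`` — growing-degree days
  above 5 deg C accumulated from the snowmelt day to the phenophase day
  (inclusive endpoints, daily-mean basis);
* ``change_in_stem_number`` — stems 2012 / stems 2011 (clonal
  reproduction);
* ``proportion_flowering_stems`` — flowering stems 2012 / stems 2012
  (sexual reproduction).

Patches missing any component get a missing trait value, never a
fabricated one, and are only dropped per model downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TRAIT_COLUMNS = [
    "leaf_size",
    "change_in_stem_number",
    "proportion_flowering_stems",
    "snowmelt_to_leaf_expansion",
    "gdd_to_leaf_expansion",
    "gdd_to_flowering",
]

FACTOR_COLUMNS = ["site", "microhabitat", "elevation", "transect"]


@dataclass
class TemperatureSeries:
    """A soil-temperature logger series at (nominally) 2-h resolution."""

    site: str
    timestamps: pd.DatetimeIndex
    temp_c: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if len(self.timestamps) != len(self.temp_c):
            raise ValueError("timestamps and temperatures differ in length")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if len(self.timestamps) < 12:
            raise ValueError("series must span at least one full day")

    def daily_means(self, max_missing_frac: float = 0.25) -> pd.Series:
        """Daily mean temperature indexed by day-of-year.

        Days missing more than ``max_missing_frac`` of the expected
        twelve 2-h readings are excluded (and reported via a warning).
        """
        df = pd.DataFrame(
            {"doy": self.timestamps.dayofyear, "temp": self.temp_c}
        ).dropna()
        grouped = df.groupby("doy")["temp"]
        counts = grouped.count()
        means = grouped.mean()
        ok = counts >= np.ceil(12 * (1.0 - max_missing_frac))
        if (~ok).any():
            warnings.warn(
                f"site {self.site}: excluded {int((~ok).sum())} days with "
                f">{max_missing_frac:.0%} missing readings"
            )
        return means[ok]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, site: str) -> "TemperatureSeries":
        """Build from a long table with columns site, timestamp, temp_c."""
        sub = df[df["site"].astype(str) == str(site)]
        if sub.empty:
            raise KeyError(f"no temperature rows for site {site!r}")
        ts = pd.to_datetime(sub["timestamp"])
        order = np.argsort(ts.to_numpy())
        return cls(str(site), pd.DatetimeIndex(ts.iloc[order]),
                   sub["temp_c"].to_numpy()[order])


def detect_snowmelt_day(
    t: TemperatureSeries,
    flat_band: float = 0.5,
    min_flat_days: int = 5,
    rise_threshold: float = 1.5,
) -> int:
    """Day-of-year when soil temperature rises sharply from near zero.

    Scans daily means for the first day exceeding ``rise_threshold``
    that follows a run of at least ``min_flat_days`` consecutive days
    with mean inside ``[-flat_band, +flat_band]`` (the snow-insulation
    plateau).
    """
    means = t.daily_means()
    flat_run = 0
    armed = False  # a qualifying plateau has been seen
    for doy, v in zip(means.index.to_numpy(), means.to_numpy()):
        if armed and v > rise_threshold:
            return int(doy)
        if abs(v) <= flat_band:
            flat_run += 1
            if flat_run >= min_flat_days:
                armed = True
        else:
            # a day outside the band interrupts the plateau; intermediate
            # ramp days after a full plateau do not disarm the detector
            flat_run = 0
    raise ValueError(
        f"site {t.site}: no snow-cover signature "
        f"(no {min_flat_days}-day flat period followed by a rise above "
        f"{rise_threshold} degC)"
    )


def gdd(
    t: TemperatureSeries,
    start_day: int,
    end_day: int,
    base: float = 5.0,
    sub_daily: bool = False,
) -> float:
    """Growing-degree days: sum of max(0, daily mean - base) over a window.

    The window ``[start_day, end_day]`` is inclusive on both ends and is
    expressed in day-of-year.  With ``sub_daily=True`` the truncation is
    applied per 2-h reading (each weighted 1/12 of a day) instead of to
    daily means, which accumulates more under fluctuating temperatures.
    """
    if start_day > end_day:
        raise ValueError(f"start_day {start_day} > end_day {end_day}")
    if sub_daily:
        doy = t.timestamps.dayofyear
        sel = (doy >= start_day) & (doy <= end_day)
        if not sel.any():
            raise ValueError(
                f"site {t.site}: temperature series does not cover days "
                f"[{start_day}, {end_day}]"
            )
        return float(np.clip(t.temp_c[sel] - base, 0.0, None).sum() / 12.0)
    means = t.daily_means()
    window = means[(means.index >= start_day) & (means.index <= end_day)]
    if window.empty:
        raise ValueError(
            f"site {t.site}: temperature series does not cover days "
            f"[{start_day}, {end_day}]"
        )
    return float(np.clip(window.to_numpy() - base, 0.0, None).sum())


def leaf_area(length_mm: float, width_mm: float) -> float:
    """Ellipse leaf area ``pi * (L/2) * (W/2)`` in mm^2."""
    if length_mm < 0 or width_mm < 0:
        raise ValueError("leaf dimensions must be non-negative")
    return float(np.pi * (length_mm / 2.0) * (width_mm / 2.0))


def site_snowmelt_days(
    series_by_site: dict[str, list[TemperatureSeries]],
    **detect_kwargs,
) -> dict[str, int]:
    """Site-level snowmelt day: median over the site's loggers."""
    out = {}
    for site, series_list in series_by_site.items():
        days = [detect_snowmelt_day(s, **detect_kwargs) for s in series_list]
        out[site] = int(np.median(days))
    return out


def derive_traits(
    records: pd.DataFrame,
    snowmelt_day: dict[str, int],
    series: dict[str, TemperatureSeries],
    gdd_base: float = 5.0,
) -> pd.DataFrame:
    """Derive the six analysis traits for each patch.

    ``records`` needs columns: ``patch``, ``site``, ``microhabitat``,
    ``elevation``, ``transect``, ``leaf_expansion_day``,
    ``flowering_day``, ``stems_2011``, ``stems_2012``,
    ``flowering_stems_2012``, ``leaf_length_mm``, ``leaf_width_mm`` (the
    leaf columns may hold the mean of the measured leaves).  Any missing
    component leaves that trait missing for the patch.  A phenophase
    preceding the site's snowmelt day is flagged (``negative_interval``)
    rather than silently used.
    """
    rows = []
    for _, rec in records.iterrows():
        site = str(rec["site"])
        melt = snowmelt_day.get(site)
        out = {
            "patch": rec["patch"],
            "site": site,
            "microhabitat": rec["microhabitat"],
            "elevation": rec["elevation"],
            "transect": rec["transect"],
            "negative_interval": False,
        }
        length, width = rec.get("leaf_length_mm"), rec.get("leaf_width_mm")
        out["leaf_size"] = (
            leaf_area(length, width)
            if pd.notna(length) and pd.notna(width)
            else np.nan
        )
        s11, s12 = rec.get("stems_2011"), rec.get("stems_2012")
        fl12 = rec.get("flowering_stems_2012")
        out["change_in_stem_number"] = (
            s12 / s11 if pd.notna(s11) and pd.notna(s12) and s11 > 0 else np.nan
        )
        out["proportion_flowering_stems"] = (
            fl12 / s12 if pd.notna(fl12) and pd.notna(s12) and s12 > 0 else np.nan
        )
        leaf_day = rec.get("leaf_expansion_day")
        flower_day = rec.get("flowering_day")
        ts = series.get(site)
        for phen_day, interval_col, gdd_col in (
            (leaf_day, "snowmelt_to_leaf_expansion", "gdd_to_leaf_expansion"),
            (flower_day, None, "gdd_to_flowering"),
        ):
            if melt is None or pd.isna(phen_day):
                if interval_col:
                    out[interval_col] = np.nan
                out[gdd_col] = np.nan
                continue
            interval = float(phen_day) - melt
            if interval < 0:
                out["negative_interval"] = True
                if interval_col:
                    out[interval_col] = np.nan
                out[gdd_col] = np.nan
                continue
            if interval_col:
                out[interval_col] = interval
            out[gdd_col] = (
                gdd(ts, melt, int(phen_day), base=gdd_base)
                if ts is not None
                else np.nan
            )
        rows.append(out)
    df = pd.DataFrame(rows).set_index("patch")
    n_neg = int(df["negative_interval"].sum())
    if n_neg:
        warnings.warn(f"{n_neg} patches had a phenophase before snowmelt; flagged")
    return df


def standardize(values: np.ndarray | pd.Series) -> np.ndarray:
    """Z-scores over non-missing values (sample sd, n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    distinct = np.unique(x[ok])
    if distinct.size < 2:
        raise ValueError("cannot standardize a constant (or empty) vector")
    mean = x[ok].mean()
    sd = x[ok].std(ddof=1)
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - mean) / sd
    return out


def standardize_traits(
    table: pd.DataFrame, columns: list[str] | None = None, suffix: str = "_z"
) -> pd.DataFrame:
    """Append standardized copies of trait columns (``<name>_z``)."""
    cols = columns if columns is not None else TRAIT_COLUMNS
    out = table.copy()
    for c in cols:
        out[c + suffix] = standardize(out[c])
    return out
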