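"""Diel (day/night) classification and time-of-day activity densities.

Camera-trap observations are classified as DAY or NIGHT against computed
sunrise and sunset, and per-species activity curves are estimated with a
circular (wrapped) Gaussian kernel density on the 24 h clock.

Sunrise and sunset come from the standard NOAA solar-position equations
(fractional year, equation of time, solar declination, hour angle at a
zenith of 90.833 degrees, i.e. including standard atmospheric refraction
and the solar semi-diameter).  A user-supplied sunrise/sunset table can be
passed instead wherever sun times are consumed, for exact replication of
analyses performed against published almanac figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as date_type
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

__all__ = [
    "SunTimes",
    "ActivityDensity",
    "sun_times",
    "classify_diel",
    "diel_fraction",
    "activity_density",
    "UnsupportedLatitudeError",
    "InsufficientDataError",
]

#: Solar zenith angle (degrees) defining sunrise/sunset: 90° geometric
#: horizon + 34' refraction + 16' solar semi-diameter.
SUNRISE_SUNSET_ZENITH_DEG = 90.833

DAY = "DAY"
NIGHT = "NIGHT"


class UnsupportedLatitudeError(ValueError):
    """Latitude poleward of the polar circles is not handled."""


class InsufficientDataError(ValueError):
    """Too few data points for the requested estimate."""


@dataclass(frozen=True)
class SunTimes:
    """Sunrise/sunset for one site and calendar date, in UTC."""

    date: date_type
    latitude: float
    longitude: float
    sunrise: datetime
    sunset: datetime

    @property
    def day_length_h(self) -> float:
        return (self.sunset - self.sunrise).total_seconds() / 3600.0


@dataclass(frozen=True)
class ActivityDensity:
    """Kernel density of activity time over the 24 h clock.

    ``density`` integrates to one over [0, 24) hours (trapezoid rule on
    ``grid``, closing the circle at midnight).
    """

    species: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        # close the circle: append grid[0] + 24 with density[0]
        x = np.append(self.grid, self.grid[0] + 24.0)
        y = np.append(self.density, self.density[0])
        return float(np.trapezoid(y, x))


def _julian_day(d: date_type, hour_utc: float) -> float:
    y, m = d.year, d.month
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    jd0 = math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d.day + b - 1524.5
    return jd0 + hour_utc / 24.0


def _solar_coefficients(d: date_type, hour: float = 12.0) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians).

    NOAA solar-calculator formulation: geometric mean longitude and anomaly,
    equation of center, apparent longitude and corrected obliquity as
    polynomials in the Julian century.
    """
    jc = (_julian_day(d, hour) - 2451545.0) / 36525.0
    gml = math.radians((280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0)
    gma = math.radians(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eq_center = (
        math.sin(gma) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * gma) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * gma) * 0.000289
    )
    true_long_deg = math.degrees(gml) + eq_center
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = math.radians(true_long_deg - 0.00569 - 0.00478 * math.sin(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = math.radians(mean_obliq + 0.00256 * math.cos(omega))
    decl = math.asin(math.sin(obliq) * math.sin(app_long))
    y = math.tan(obliq / 2.0) ** 2
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * gml)
        - 2.0 * ecc * math.sin(gma)
        + 4.0 * ecc * y * math.sin(gma) * math.cos(2 * gml)
        - 0.5 * y * y * math.sin(4 * gml)
        - 1.25 * ecc * ecc * math.sin(2 * gma)
    )
    return eqtime, decl


def sun_times(latitude: float, longitude: float, date: date_type) -> SunTimes:
    """Compute UTC sunrise and sunset for a site and date.

    Parameters
    ----------
    latitude, longitude
        Site position in decimal degrees; longitude positive east.
    date
        Calendar (UTC) date.

    Raises
    ------
    UnsupportedLatitudeError
        For ``|latitude| >= 66.5`` degrees, where the sun may not rise or
        set, or when the hour-angle equation has no solution on ``date``.
    """
    if abs(latitude) >= 66.5:
        raise UnsupportedLatitudeError(
            f"latitude {latitude:.2f} is poleward of the polar circles; "
            "polar day/night is not supported"
        )
    if isinstance(date, datetime):  # accept datetimes for convenience
        date = date.date()
    lat_r = math.radians(latitude)
    cos_zen = math.cos(math.radians(SUNRISE_SUNSET_ZENITH_DEG))

    def _event_minutes(rising: bool, hour: float) -> float:
        eqtime, decl = _solar_coefficients(date, hour)
        cos_ha = (
            cos_zen / (math.cos(lat_r) * math.cos(decl)) - math.tan(lat_r) * math.tan(decl)
        )
        if not -1.0 <= cos_ha <= 1.0:
            raise UnsupportedLatitudeError(
                f"sun does not cross the horizon at latitude {latitude:.2f} on {date}"
            )
        ha_deg = math.degrees(math.acos(cos_ha))
        sign = 1.0 if rising else -1.0
        return 720.0 - 4.0 * (longitude + sign * ha_deg) - eqtime

    # second pass re-evaluates the equation of time and declination at the
    # event itself (they drift enough within a day to matter at shallow
    # high-latitude horizon crossings)
    sunrise_min = _event_minutes(True, 12.0)
    sunrise_min = _event_minutes(True, sunrise_min / 60.0)
    sunset_min = _event_minutes(False, 12.0)
    sunset_min = _event_minutes(False, sunset_min / 60.0)
    midnight = datetime(date.year, date.month, date.day, tzinfo=timezone.utc)
    return SunTimes(
        date=date,
        latitude=latitude,
        longitude=longitude,
        sunrise=midnight + timedelta(minutes=sunrise_min),
        sunset=midnight + timedelta(minutes=sunset_min),
    )


def classify_diel(start, sun: SunTimes) -> str:
    """Classify an observation start time as ``DAY`` or ``NIGHT``.

    The day interval is half-open, ``[sunrise, sunset)``: a bout starting
    exactly at sunrise is DAY, one starting exactly at sunset is NIGHT.
    Observations spanning sunset keep the class of their start time.
    """
    ts = pd.Timestamp(start)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return DAY if pd.Timestamp(sun.sunrise) <= ts < pd.Timestamp(sun.sunset) else NIGHT


def _sun_lookup(latitude: float, longitude: float, override: pd.DataFrame | None,
                site_id=None):
    """Return a memoised date -> SunTimes resolver, honouring an override table.

    ``override`` columns: site_id, date, sunrise_utc, sunset_utc.
    """
    cache: dict[date_type, SunTimes] = {}
    if override is not None and len(override):
        ov = override.copy()
        ov["date"] = pd.to_datetime(ov["date"]).dt.date
        for _, row in ov.iterrows():
            if site_id is not None and row["site_id"] != site_id:
                continue
            cache[row["date"]] = SunTimes(
                date=row["date"],
                latitude=latitude,
                longitude=longitude,
                sunrise=pd.Timestamp(row["sunrise_utc"], tz="UTC").to_pydatetime(),
                sunset=pd.Timestamp(row["sunset_utc"], tz="UTC").to_pydatetime(),
            )

    def lookup(d: date_type) -> SunTimes:
        if d not in cache:
            cache[d] = sun_times(latitude, longitude, d)
        return cache[d]

    return lookup


def classify_observations(
    observations: pd.DataFrame,
    deployments: pd.DataFrame,
    sun_override: pd.DataFrame | None = None,
) -> pd.Series:
    """DAY/NIGHT class for every observation row (totality guaranteed).

    Site coordinates come from the deployment table; sun times are computed
    per (site, date) unless ``sun_override`` supplies them.
    """
    dep = deployments.set_index("carcass_id")
    classes = []
    lookups: dict = {}
    for _, obs in observations.iterrows():
        d = dep.loc[obs["carcass_id"]]
        key = d["site_id"]
        if key not in lookups:
            lookups[key] = _sun_lookup(
                float(d["latitude"]), float(d["longitude"]), sun_override, site_id=key
            )
        start = pd.Timestamp(obs["start_utc"])
        if start.tzinfo is None:
            start = start.tz_localize("UTC")
        sun = lookups[key](start.date())
        classes.append(classify_diel(start, sun))
    return pd.Series(classes, index=observations.index, name="diel")


def diel_fraction(
    observations: pd.DataFrame,
    deployments: pd.DataFrame,
    sun_override: pd.DataFrame | None = None,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Per-species percentage of observations made during the day.

    Returns a frame indexed by species with columns ``n_day``, ``n_total``
    and ``day_pct`` (0–100).  A species listed in ``species`` but never
    observed gets ``n_total = 0`` and ``day_pct = NaN`` — an empty
    denominator is reported as missing, not as zero.
    """
    if len(observations):
        cls = classify_observations(observations, deployments, sun_override)
        tab = pd.DataFrame({"species": observations["species"].values, "diel": cls.values})
        grouped = tab.groupby("species", sort=True)
        out = pd.DataFrame(
            {
                "n_day": grouped["diel"].apply(lambda s: int((s == DAY).sum())),
                "n_total": grouped["diel"].size(),
            }
        )
    else:
        out = pd.DataFrame(columns=["n_day", "n_total"], dtype=int)
    if species is not None:
        out = out.reindex(species, fill_value=0)
    out["day_pct"] = np.where(
        out["n_total"] > 0, 100.0 * out["n_day"] / out["n_total"].replace(0, np.nan), np.nan
    )
    out.index.name = "species"
    return out


def _normal_reference_bandwidth(times: np.ndarray) -> float:
    """Silverman's rule on the linearised sample, floored at 0.25 h."""
    sd = float(np.std(times, ddof=1)) if times.size > 1 else 0.0
    h = 1.06 * sd * times.size ** (-1.0 / 5.0)
    return max(h, 0.25)


def activity_density(
    times_of_day,
    bandwidth="auto",
    species: str = "",
    grid_size: int | None = None,
    circular: bool = True,
) -> ActivityDensity:
    """Kernel density of activity times on the 24 h clock.

    Parameters
    ----------
    times_of_day
        Sample of times in decimal hours, each in [0, 24).
    bandwidth
        Kernel standard deviation in hours, or ``"auto"`` for the normal
        reference rule on the linearised sample.
    circular
        Wrap kernel contributions modulo 24 h (default).  ``False`` gives a
        plain linear Gaussian KDE evaluated on the same grid, for
        replication of analyses that ignored the midnight boundary.

    Raises
    ------
    InsufficientDataError
        Fewer than two time points.
    """
    t = np.asarray(list(times_of_day), dtype=float) % 24.0
    if t.size < 2:
        raise InsufficientDataError(
            f"activity density needs at least 2 time points, got {t.size}"
        )
    if bandwidth == "auto":
        h = _normal_reference_bandwidth(t)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    if grid_size is None:
        # keep the grid fine relative to the kernel so the trapezoid
        # integral holds to 1e-3 even for narrow bandwidths
        grid_size = max(256, int(math.ceil(24.0 / (h / 4.0))))
    grid = np.linspace(0.0, 24.0, grid_size, endpoint=False)
    diff = grid[:, None] - t[None, :]
    if circular:
        k_wrap = max(1, int(math.ceil(5.0 * h / 24.0)))
        dens = np.zeros(grid_size)
        for k in range(-k_wrap, k_wrap + 1):
            dens += np.exp(-0.5 * ((diff + 24.0 * k) / h) ** 2).sum(axis=1)
        dens /= t.size * h * math.sqrt(2.0 * math.pi)
    else:
        dens = np.exp(-0.5 * (diff / h) ** 2).sum(axis=1)
        dens /= t.size * h * math.sqrt(2.0 * math.pi)
    return ActivityDensity(species=species, grid=grid, density=dens, bandwidth=h)
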