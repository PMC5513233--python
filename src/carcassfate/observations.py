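"""Turn per-image detection records into behavioural observations.

An *observation* — the unit of replication in carcass-fate studies — is a
contiguous interval during which one species displays one behaviour at one
carcass.  Consecutive frames of the same species at the same carcass whose
inter-frame gaps do not exceed ``gap_threshold_s`` form a presence run; the
run is split wherever the behaviour label changes, so a bird that switches
from examining to eating produces two observations.

Frames with no animal (``species`` empty/NONE) separate nothing: presence
runs are keyed by (carcass, species), so two species photographed in
alternation at one carcass yield independent, possibly overlapping runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "BEHAVIORS",
    "SCAVENGING_BEHAVIORS",
    "extract_observations",
    "eating_time_by_species",
    "first_arrival_latency",
    "FrameOrderError",
    "BehaviorError",
]

#: The five behaviour codes scored from camera-trap images.
BEHAVIORS = ("NONE", "LOOKING", "EXAMINING", "EATING", "REMOVING")

#: Behaviours that constitute scavenging (consumption or whole-carcass removal).
SCAVENGING_BEHAVIORS = ("EATING", "REMOVING")

NO_SPECIES = "NONE"


class FrameOrderError(ValueError):
    """Detection frames are not sorted by (carcass_id, timestamp)."""


class BehaviorError(ValueError):
    """A frame carries an unknown behaviour code."""


def _as_utc(series: pd.Series) -> pd.Series:
    ts = pd.to_datetime(series)
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize("UTC")
    else:
        ts = ts.dt.tz_convert("UTC")
    return ts


def extract_observations(frames: pd.DataFrame, gap_threshold_s: float = 60.0) -> pd.DataFrame:
    """Group detection frames into observations.

    Parameters
    ----------
    frames
        Columns ``carcass_id``, ``timestamp_utc``, ``species``, ``behavior``,
        sorted by (carcass_id, timestamp_utc).  Rows with species
        ``NONE``/empty are empty triggers and are ignored.
    gap_threshold_s
        Maximum silence, in seconds, between frames of one species at one
        carcass before the next frame opens a new presence run.  The default
        of 60 s is far above a rapid-fire camera's reset time (~0.5 s) yet
        short enough to separate genuine revisits.

    Returns
    -------
    DataFrame with columns ``carcass_id, species, behavior, start_utc,
    end_utc, duration_min``, one row per observation, ordered by
    (carcass_id, start_utc, species).  A single-frame observation has
    duration 0.

    Raises
    ------
    FrameOrderError
        If frames are not sorted within each carcass.
    BehaviorError
        On a behaviour code outside the five-code vocabulary.
    """
    if gap_threshold_s <= 0:
        raise ValueError("gap_threshold_s must be positive")
    cols = ["carcass_id", "species", "behavior", "start_utc", "end_utc", "duration_min"]
    if frames is None or len(frames) == 0:
        return pd.DataFrame(columns=cols)

    f = frames.copy()
    f["timestamp_utc"] = _as_utc(f["timestamp_utc"])

    bad = set(f["behavior"].dropna().unique()) - set(BEHAVIORS)
    if bad:
        raise BehaviorError(f"unknown behavior code(s): {sorted(bad)}")

    same_carcass = f["carcass_id"].values[1:] == f["carcass_id"].values[:-1]
    dt = np.diff(f["timestamp_utc"].values.astype("datetime64[ns]").astype("int64"))
    if np.any(same_carcass & (dt < 0)):
        raise FrameOrderError("frames must be sorted by (carcass_id, timestamp)")

    f = f[(f["species"].notna()) & (f["species"] != NO_SPECIES) & (f["species"] != "")]
    if len(f) == 0:
        return pd.DataFrame(columns=cols)

    f = f.sort_values(["carcass_id", "species", "timestamp_utc"], kind="mergesort")
    t_ns = f["timestamp_utc"].values.astype("datetime64[ns]").astype("int64")
    gap_s = np.empty(len(f))
    gap_s[0] = np.inf
    gap_s[1:] = np.diff(t_ns) / 1e9
    new_key = np.zeros(len(f), dtype=bool)
    new_key[0] = True
    for col in ("carcass_id", "species"):
        v = f[col].values
        new_key[1:] |= v[1:] != v[:-1]
    new_run = new_key | (gap_s > gap_threshold_s)
    beh = f["behavior"].values
    new_obs = new_run.copy()
    new_obs[1:] |= beh[1:] != beh[:-1]
    obs_id = np.cumsum(new_obs)

    g = f.assign(_obs=obs_id).groupby("_obs", sort=True)
    out = g.agg(
        carcass_id=("carcass_id", "first"),
        species=("species", "first"),
        behavior=("behavior", "first"),
        start_utc=("timestamp_utc", "first"),
        end_utc=("timestamp_utc", "last"),
    ).reset_index(drop=True)
    out["duration_min"] = (out["end_utc"] - out["start_utc"]).dt.total_seconds() / 60.0
    return out.sort_values(["carcass_id", "start_utc", "species"], kind="mergesort").reset_index(
        drop=True
    )


def eating_time_by_species(
    observations: pd.DataFrame, species: list[str] | None = None
) -> pd.DataFrame:
    """Total EATING minutes per (carcass, species).

    With ``species`` given, every (carcass, species) pair is present and
    zero-filled; otherwise only pairs with eating time appear.
    """
    cols = ["carcass_id", "species", "eating_min"]
    if len(observations) == 0:
        return pd.DataFrame(columns=cols)
    eating = observations[observations["behavior"] == "EATING"]
    tab = (
        eating.groupby(["carcass_id", "species"], sort=True)["duration_min"]
        .sum()
        .rename("eating_min")
        .reset_index()
    )
    if species is not None:
        carcasses = observations["carcass_id"].unique()
        full = pd.MultiIndex.from_product(
            [sorted(carcasses), sorted(species)], names=["carcass_id", "species"]
        )
        tab = (
            tab.set_index(["carcass_id", "species"])
            .reindex(full, fill_value=0.0)
            .reset_index()
        )
    return tab


def first_arrival_latency(
    deployments: pd.DataFrame, observations: pd.DataFrame
) -> pd.DataFrame:
    """Minutes from carcass deployment to each species' first observation.

    One row per (carcass, species) actually observed; species that never
    visited a carcass contribute no row.  Latencies are nonnegative by the
    deployment-window invariant of the detection stream.
    """
    cols = ["carcass_id", "species", "latency_min"]
    if len(observations) == 0:
        return pd.DataFrame(columns=cols)
    unknown = set(observations["carcass_id"]) - set(deployments["carcass_id"])
    if unknown:
        raise KeyError(f"observations reference unknown carcass id(s): {sorted(unknown)}")
    dep_start = deployments.set_index("carcass_id")["start_utc"]
    dep_start = _as_utc(dep_start)
    firsts = (
        observations.assign(start_utc=_as_utc(observations["start_utc"]))
        .groupby(["carcass_id", "species"], sort=True)["start_utc"]
        .min()
        .reset_index()
    )
    firsts["latency_min"] = (
        firsts["start_utc"] - firsts["carcass_id"].map(dep_start)
    ).dt.total_seconds() / 60.0
    return firsts[cols]
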