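"""Descriptive result ledgers for a carcass-fate study.

Three blocks, mirroring the standard presentation of scavenging studies:
per-species attendance / observation / scavenging / removal counts with
time budgets; study-level detection rates (how many carcasses saw any
vertebrate, how many were scavenged); and a mass-loss comparison between
carcasses with and without scavenger activity.  Percent shares are rounded
to integers for display; machine columns keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observations import SCAVENGING_BEHAVIORS

__all__ = [
    "attendance_summary",
    "scavenging_detection_summary",
    "detection_summary_from_counts",
    "mass_loss_comparison",
    "EmptyStudyError",
]


class EmptyStudyError(ValueError):
    pass


def _experimental(deployments: pd.DataFrame) -> pd.DataFrame:
    return deployments[deployments["is_control"].astype(int) == 0]


def attendance_summary(
    deployments: pd.DataFrame,
    observations: pd.DataFrame,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Per-species block: attendance, observation shares, time budgets.

    *Attendance* counts any observation of the species at a carcass,
    whatever the behaviour (an animal merely looking is still attending);
    *scavenging* requires EATING or REMOVING.  Observation shares are
    computed across the listed species only, so they sum to 100 up to
    rounding.

    Columns: carcasses_attended, attended_pct (of experimental carcasses),
    n_observations, obs_share_pct, n_scavenging_obs, scavenging_share_pct,
    hours_observed, hours_eating, carcasses_removed.
    """
    exp = _experimental(deployments)
    n_carc = len(exp)
    if n_carc == 0:
        raise EmptyStudyError("no experimental carcasses")
    if species is None:
        species = sorted(observations["species"].unique()) if len(observations) else []
    obs = (
        observations[observations["species"].isin(species)]
        if len(observations)
        else observations
    )
    rows = []
    total_obs = len(obs)
    scav = obs[obs["behavior"].isin(SCAVENGING_BEHAVIORS)] if len(obs) else obs
    total_scav = len(scav)
    for sp in species:
        o = obs[obs["species"] == sp] if len(obs) else obs
        s = scav[scav["species"] == sp] if len(scav) else scav
        removed = o[o["behavior"] == "REMOVING"]["carcass_id"].nunique() if len(o) else 0
        rows.append(
            {
                "species": sp,
                "carcasses_attended": o["carcass_id"].nunique() if len(o) else 0,
                "attended_pct": 100.0 * (o["carcass_id"].nunique() if len(o) else 0) / n_carc,
                "n_observations": len(o),
                "obs_share_pct": 100.0 * len(o) / total_obs if total_obs else np.nan,
                "n_scavenging_obs": len(s),
                "scavenging_share_pct": 100.0 * len(s) / total_scav if total_scav else np.nan,
                "hours_observed": float(o["duration_min"].sum()) / 60.0 if len(o) else 0.0,
                "hours_eating": float(
                    o.loc[o["behavior"] == "EATING", "duration_min"].sum()
                )
                / 60.0
                if len(o)
                else 0.0,
                "carcasses_removed": removed,
            }
        )
    columns = [
        "species",
        "carcasses_attended",
        "attended_pct",
        "n_observations",
        "obs_share_pct",
        "n_scavenging_obs",
        "scavenging_share_pct",
        "hours_observed",
        "hours_eating",
        "carcasses_removed",
    ]
    return pd.DataFrame(rows, columns=columns).set_index("species")


def detection_summary_from_counts(
    n_carcasses: int,
    n_with_vertebrate: int,
    n_scavenged: int,
    n_observations: int | None = None,
    n_scavenging_obs: int | None = None,
) -> dict:
    """Study-level detection rates from raw counts.

    Returns a dict with the counts and the derived percentages
    (``vertebrate_pct``, ``scavenged_pct``, ``scavenging_obs_pct``), each
    both raw and rounded for display.
    """
    if n_carcasses <= 0:
        raise EmptyStudyError("empty study: no experimental carcasses")
    out = {
        "n_carcasses": n_carcasses,
        "n_with_vertebrate": n_with_vertebrate,
        "n_scavenged": n_scavenged,
        "vertebrate_pct": 100.0 * n_with_vertebrate / n_carcasses,
        "scavenged_pct": 100.0 * n_scavenged / n_carcasses,
        "vertebrate_pct_display": int(round(100.0 * n_with_vertebrate / n_carcasses)),
        "scavenged_pct_display": int(round(100.0 * n_scavenged / n_carcasses)),
    }
    if n_observations is not None and n_scavenging_obs is not None:
        pct = 100.0 * n_scavenging_obs / n_observations if n_observations else np.nan
        out.update(
            {
                "n_observations": n_observations,
                "n_scavenging_obs": n_scavenging_obs,
                "scavenging_obs_pct": pct,
                "scavenging_obs_pct_display": int(round(pct)) if n_observations else None,
            }
        )
    return out


def scavenging_detection_summary(
    deployments: pd.DataFrame, observations: pd.DataFrame
) -> dict:
    """Counts and percentages of carcasses with vertebrate / scavenging
    activity, over experimental carcasses only."""
    exp = _experimental(deployments)
    n = len(exp)
    if n == 0:
        raise EmptyStudyError("empty study: no experimental carcasses")
    if len(observations):
        obs = observations[observations["carcass_id"].isin(set(exp["carcass_id"]))]
        with_vert = obs["carcass_id"].nunique()
        scavd = obs.loc[
            obs["behavior"].isin(SCAVENGING_BEHAVIORS), "carcass_id"
        ].nunique()
        n_obs = len(obs)
        n_scav_obs = int(obs["behavior"].isin(SCAVENGING_BEHAVIORS).sum())
    else:
        with_vert = scavd = n_obs = n_scav_obs = 0
    return detection_summary_from_counts(n, with_vert, scavd, n_obs, n_scav_obs)


def mass_loss_comparison(
    deployments: pd.DataFrame, observations: pd.DataFrame
) -> pd.DataFrame:
    """Mean/SD mass loss by scavenger presence, in grams and % of initial.

    Groups experimental carcasses by whether any scavenging behaviour
    (EATING/REMOVING) was recorded; removed carcasses count their whole
    initial mass as lost.  Purely descriptive — no inference.
    """
    exp = _experimental(deployments).copy()
    if len(exp) == 0:
        raise EmptyStudyError("no experimental carcasses")
    if len(observations):
        scavd = set(
            observations.loc[
                observations["behavior"].isin(SCAVENGING_BEHAVIORS), "carcass_id"
            ].unique()
        )
    else:
        scavd = set()
    exp["scavenged"] = exp["carcass_id"].isin(scavd)
    loss = np.where(
        exp["removed"].astype(int) == 1,
        exp["initial_mass_g"],
        exp["initial_mass_g"] - exp["final_mass_g"],
    )
    exp["loss_g"] = loss
    exp["loss_pct"] = 100.0 * exp["loss_g"] / exp["initial_mass_g"]
    g = exp.groupby("scavenged")
    out = pd.DataFrame(
        {
            "n": g.size(),
            "mean_loss_g": g["loss_g"].mean(),
            "sd_loss_g": g["loss_g"].std(ddof=1),
            "mean_loss_pct": g["loss_pct"].mean(),
            "sd_loss_pct": g["loss_pct"].std(ddof=1),
        }
    )
    out.index.name = "scavenged"
    return out
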