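"""File formats, validation, and the end-to-end pipeline.

CSV schemas (comma-separated, UTF-8, header row mandatory, timestamps
ISO-8601 UTC):

* ``deployments.csv`` — carcass_id, site_id, town, latitude, longitude,
  start_utc, end_utc, initial_mass_g, final_mass_g, removed (0/1),
  access_class (ALL|AVIAN_ONLY), is_control (0/1)
* ``detections.csv`` — carcass_id, timestamp_utc, species, behavior
* ``observations.csv`` — carcass_id, species, behavior, start_utc,
  end_utc, duration_min
* ``suntimes.csv`` (optional override) — site_id, date, sunrise_utc,
  sunset_utc
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .attribution import AttributionConfig, AttributionResult, attribute_study
from .diel import diel_fraction
from .observations import BEHAVIORS, extract_observations, first_arrival_latency
from .summaries import (
    attendance_summary,
    mass_loss_comparison,
    scavenging_detection_summary,
)

__all__ = [
    "StudyBundle",
    "SchemaError",
    "IntegrityError",
    "read_study",
    "write_study",
    "run_pipeline",
]

DEPLOYMENT_COLUMNS = [
    "carcass_id",
    "site_id",
    "town",
    "latitude",
    "longitude",
    "start_utc",
    "end_utc",
    "initial_mass_g",
    "final_mass_g",
    "removed",
    "access_class",
    "is_control",
]
DETECTION_COLUMNS = ["carcass_id", "timestamp_utc", "species", "behavior"]
OBSERVATION_COLUMNS = [
    "carcass_id",
    "species",
    "behavior",
    "start_utc",
    "end_utc",
    "duration_min",
]
SUNTIMES_COLUMNS = ["site_id", "date", "sunrise_utc", "sunset_utc"]


class SchemaError(ValueError):
    """A table is missing required columns."""


class IntegrityError(ValueError):
    """A table violates a row-level or cross-table invariant."""


@dataclass
class StudyBundle:
    """Validated in-memory study: tables plus run metadata."""

    deployments: pd.DataFrame
    detections: pd.DataFrame | None = None
    observations: pd.DataFrame | None = None
    sun_override: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _parse_utc(df: pd.DataFrame, cols: list[str], name: str) -> None:
    for c in cols:
        try:
            df[c] = pd.to_datetime(df[c], utc=True, format="ISO8601")
        except (ValueError, TypeError) as e:
            raise SchemaError(f"{name}.{c}: unparseable ISO-8601 timestamp ({e})") from e


def validate_deployments(dep: pd.DataFrame) -> pd.DataFrame:
    _require_columns(dep, DEPLOYMENT_COLUMNS, "deployments")
    dep = dep.copy()
    _parse_utc(dep, ["start_utc", "end_utc"], "deployments")
    dup = dep.loc[dep["carcass_id"].duplicated(), "carcass_id"]
    if len(dup):
        raise IntegrityError(f"duplicate carcass id(s): {sorted(dup.unique())}")
    for i, row in dep.iterrows():
        cid = row["carcass_id"]
        if row["final_mass_g"] < 0 or row["initial_mass_g"] <= 0:
            raise IntegrityError(f"row {i} (carcass {cid}): nonpositive mass")
        if row["final_mass_g"] > row["initial_mass_g"]:
            raise IntegrityError(
                f"row {i} (carcass {cid}): final_mass_g exceeds initial_mass_g"
            )
        if int(row["removed"]) and row["final_mass_g"] != 0:
            raise IntegrityError(
                f"row {i} (carcass {cid}): removed carcass must have final mass 0"
            )
        if row["end_utc"] <= row["start_utc"]:
            raise IntegrityError(f"row {i} (carcass {cid}): end_utc not after start_utc")
        if row["access_class"] not in ("ALL", "AVIAN_ONLY"):
            raise IntegrityError(
                f"row {i} (carcass {cid}): bad access_class {row['access_class']!r}"
            )
    return dep


def _check_carcass_refs(df: pd.DataFrame, dep: pd.DataFrame, name: str) -> None:
    unknown = set(df["carcass_id"]) - set(dep["carcass_id"])
    if unknown:
        raise IntegrityError(f"{name}: unknown carcass id(s) {sorted(unknown)}")


def read_study(
    deployments_path,
    detections_path=None,
    observations_path=None,
    suntimes_path=None,
    metadata: dict | None = None,
) -> StudyBundle:
    """Load and validate a study from CSV files.

    Either a detections file (raw frames, observations extracted later) or
    a pre-extracted observations file must be supplied; both is fine.
    """
    dep = validate_deployments(pd.read_csv(deployments_path))
    det = obs = sun = None
    if detections_path is not None:
        det = pd.read_csv(detections_path)
        _require_columns(det, DETECTION_COLUMNS, "detections")
        _parse_utc(det, ["timestamp_utc"], "detections")
        bad = set(det["behavior"].dropna()) - set(BEHAVIORS)
        if bad:
            raise IntegrityError(f"detections: unknown behavior code(s) {sorted(bad)}")
        _check_carcass_refs(det, dep, "detections")
    if observations_path is not None:
        obs = pd.read_csv(observations_path)
        _require_columns(obs, OBSERVATION_COLUMNS, "observations")
        _parse_utc(obs, ["start_utc", "end_utc"], "observations")
        _check_carcass_refs(obs, dep, "observations")
    if det is None and obs is None:
        raise SchemaError("a detections or observations table is required")
    if suntimes_path is not None:
        sun = pd.read_csv(suntimes_path)
        _require_columns(sun, SUNTIMES_COLUMNS, "suntimes")
    return StudyBundle(
        deployments=dep,
        detections=det,
        observations=obs,
        sun_override=sun,
        metadata=dict(metadata or {}, package_version=__version__),
    )


def write_study(outdir, deployments=None, detections=None, observations=None,
                metadata: dict | None = None) -> None:
    """Write study tables as CSV with canonical column order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if deployments is not None:
        deployments.to_csv(outdir / "deployments.csv", index=False)
    if detections is not None:
        detections.to_csv(outdir / "detections.csv", index=False)
    if observations is not None:
        observations.to_csv(outdir / "observations.csv", index=False)
    if metadata is not None:
        (outdir / "metadata.json").write_text(json.dumps(metadata, indent=2, default=str))


def _fmt_pct(x) -> str:
    return "n/a" if pd.isna(x) else f"{x:.0f}%"


def _render_report(
    detection: dict,
    attendance: pd.DataFrame,
    diel: pd.DataFrame,
    massloss: pd.DataFrame,
    attribution: AttributionResult,
) -> str:
    lines = []
    lines.append("CARCASS-FATE REPORT")
    lines.append("===================")
    lines.append("")
    lines.append(
        f"Experimental carcasses: {detection['n_carcasses']}; "
        f"with any vertebrate: {detection['n_with_vertebrate']} "
        f"({_fmt_pct(detection['vertebrate_pct'])}); "
        f"scavenged: {detection['n_scavenged']} "
        f"({_fmt_pct(detection['scavenged_pct'])})"
    )
    if detection.get("n_observations"):
        lines.append(
            f"Observations: {detection['n_observations']}; scavenging behaviour: "
            f"{detection['n_scavenging_obs']} "
            f"({_fmt_pct(detection['scavenging_obs_pct'])})"
        )
    lines.append("")
    lines.append("Per-species ledger (attendance / observations / scavenging / removals):")
    for sp, row in attendance.iterrows():
        day_pct = diel["day_pct"].get(sp, float("nan")) if len(diel) else float("nan")
        lines.append(
            f"  {sp:<10s} attended {int(row['carcasses_attended'])} carcasses "
            f"({_fmt_pct(row['attended_pct'])}); {int(row['n_observations'])} obs "
            f"({_fmt_pct(row['obs_share_pct'])} share); "
            f"{int(row['n_scavenging_obs'])} scavenging "
            f"({_fmt_pct(row['scavenging_share_pct'])} share); "
            f"{row['hours_observed']:.1f} h observed, {row['hours_eating']:.1f} h eating; "
            f"{int(row['carcasses_removed'])} carcasses removed; "
            f"day share {_fmt_pct(day_pct)}"
        )
    lines.append("")
    lines.append("Mass loss by scavenger presence:")
    for scav, row in massloss.iterrows():
        label = "scavenged" if scav else "unscavenged"
        sd_g = row["sd_loss_g"]
        sd_p = row["sd_loss_pct"]
        lines.append(
            f"  {label:<12s} n={int(row['n'])}: "
            f"{row['mean_loss_g']:.1f} g (SD {0.0 if pd.isna(sd_g) else sd_g:.1f}), "
            f"{row['mean_loss_pct']:.0f}% of initial "
            f"(SD {0.0 if pd.isna(sd_p) else sd_p:.0f}%)"
        )
    lines.append("")
    lines.append(
        f"Non-vertebrate loss fraction: {100.0 * attribution.fraction:.1f}% of initial mass"
    )
    if attribution.kappa is not None:
        lines.append(f"Calibrated in-situ rate kappa: {attribution.kappa:.3f} g/(kg·min)")
    lines.append("")
    lines.append("Biomass attribution (scope: species grams, % of scope biomass):")
    for scope, block in attribution.study_totals.groupby("scope", sort=False):
        parts = [
            f"{r['species']} {r['grams']:.0f} g ({int(r['pct_display'])}%)"
            for _, r in block.iterrows()
        ]
        lines.append(f"  {scope}: " + "; ".join(parts))
    lines.append("")
    pc = attribution.per_carcass
    if len(pc):
        max_err = (
            (pc["allocated_g"] + pc["unattributed_g"] - pc["adjusted_loss_g"]).abs().max()
        )
        lines.append(
            f"Conservation check: max |allocated + unattributed - adjusted| = "
            f"{max_err:.2e} g over {len(pc)} carcasses "
            f"({'PASS' if max_err < 1e-9 else 'FAIL'})"
        )
    else:
        lines.append("Conservation check: no experimental carcasses")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(
    bundle: StudyBundle,
    outdir,
    gap_threshold_s: float = 60.0,
    body_masses: dict[str, float] | None = None,
    attribution_config: AttributionConfig | None = None,
) -> dict:
    """Execute extract → classify → attribute → summarize and write outputs.

    Writes ``observations.csv``, ``latency.csv``, ``diel.csv``,
    ``attribution_per_carcass.csv``, ``attribution_allocations.csv``,
    ``study_summary.csv``, ``metadata.json`` and a human-readable
    ``report.txt`` into ``outdir``.  Deterministic given inputs: rerunning
    on identical files produces byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs = bundle.observations
    if obs is None:
        obs = extract_observations(bundle.detections, gap_threshold_s=gap_threshold_s)
    detection = scavenging_detection_summary(bundle.deployments, obs)
    attendance = attendance_summary(bundle.deployments, obs)
    diel = diel_fraction(obs, bundle.deployments, sun_override=bundle.sun_override)
    massloss = mass_loss_comparison(bundle.deployments, obs)
    latency = first_arrival_latency(bundle.deployments, obs)
    attribution = attribute_study(
        bundle.deployments, obs, body_masses=body_masses, config=attribution_config
    )

    obs_out = obs.copy()
    obs_out.to_csv(outdir / "observations.csv", index=False)
    latency.to_csv(outdir / "latency.csv", index=False)
    diel.to_csv(outdir / "diel.csv")
    attendance.to_csv(outdir / "attendance.csv")
    massloss.to_csv(outdir / "mass_loss.csv")
    attribution.per_carcass.to_csv(outdir / "attribution_per_carcass.csv", index=False)
    attribution.allocations.to_csv(outdir / "attribution_allocations.csv", index=False)
    attribution.study_totals.to_csv(outdir / "study_summary.csv", index=False)
    report = _render_report(detection, attendance, diel, massloss, attribution)
    (outdir / "report.txt").write_text(report)
    meta = dict(bundle.metadata)
    meta.setdefault("package_version", __version__)
    meta["gap_threshold_s"] = gap_threshold_s
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2, default=str, sort_keys=True))
    return {
        "observations": obs,
        "detection": detection,
        "attendance": attendance,
        "diel": diel,
        "mass_loss": massloss,
        "latency": latency,
        "attribution": attribution,
        "report": report,
    }
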