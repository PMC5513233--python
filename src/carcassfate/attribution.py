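"""Partition carcass biomass loss among scavenger species.

The estimator works from two measurements per carcass — mass lost over the
deployment, and per-species eating time from the camera record — plus the
caged controls:

1. **Non-vertebrate adjustment.**  Controls and experimental carcasses with
   no scavenging behaviour estimate the pooled fraction of initial mass
   lost to invertebrates, microbes and desiccation.  Each carcass's loss is
   reduced by that fraction of its initial mass (floored at zero) before
   anything is credited to vertebrates.  A carcass removed whole from
   camera view is treated as fully consumed elsewhere: its measured loss is
   its entire initial mass.
2. **Proportional allocation.**  For a carcass not removed, the adjusted
   loss is split across species in proportion to body mass × eating time
   (the two standard proportionality assumptions: biomass removed scales
   with time spent feeding and with scavenger body mass).
3. **Removed carcasses.**  The species that carried the carcass off gets
   the remainder after in-situ eaters are credited at a calibrated rate
   κ (grams per kg of scavenger per minute of eating), fitted by least
   squares through the origin on the non-removed scavenged carcasses.
   A pure-proportional alternative (remover credited with the whole
   adjusted loss) is available via :class:`AttributionConfig`.

Study totals are reported under three scopes: all experimental carcasses,
carcasses with scavenging activity only, and scavenged carcasses at sites
accessible to non-avian scavengers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observations import SCAVENGING_BEHAVIORS, eating_time_by_species

__all__ = [
    "AttributionConfig",
    "AttributionResult",
    "DEFAULT_BODY_MASS_G",
    "nonvertebrate_loss_fraction",
    "adjust_loss",
    "calibrate_kappa",
    "allocate_carcass",
    "attribute_study",
    "scope_ledger",
    "InsufficientDataError",
    "CalibrationError",
]

#: Stand-in adult body masses (g); override with study-specific values.
DEFAULT_BODY_MASS_G = {"crow": 570.0, "magpie": 230.0, "fox": 6500.0}

SCOPES = ("ALL", "SCAVENGED_ONLY", "FOX_ACCESSIBLE_ONLY")


class InsufficientDataError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


@dataclass
class AttributionConfig:
    """Estimator options.

    removal_rule
        ``"kappa"`` (default): in-situ eaters on removed carcasses credited
        at the calibrated rate, remover takes the rest.  ``"proportional"``:
        the remover is treated as sole consumer of the adjusted loss.
    adjustment_scope
        ``"per_carcass"`` (default): subtract fraction × initial mass from
        each carcass's loss.  ``"study_wide"``: subtract the fraction from
        the pooled deployed biomass when building study ledgers (per-carcass
        adjusted losses are still computed for allocation weights).
    """

    removal_rule: str = "kappa"
    adjustment_scope: str = "per_carcass"
    fraction: float | None = None  # override the control-based estimate
    scavenging_behaviors: tuple[str, ...] = SCAVENGING_BEHAVIORS

    def validate(self) -> None:
        if self.removal_rule not in ("kappa", "proportional"):
            raise ValueError(f"unknown removal_rule: {self.removal_rule}")
        if self.adjustment_scope not in ("per_carcass", "study_wide"):
            raise ValueError(f"unknown adjustment_scope: {self.adjustment_scope}")
        if self.fraction is not None and not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


@dataclass
class AttributionResult:
    """Per-carcass and study-level biomass attribution.

    per_carcass
        One row per experimental carcass: measured and adjusted loss,
        non-vertebrate grams, per-species grams (long companion table
        ``allocations``), unattributed grams.
    allocations
        One row per (carcass, species) with grams credited.
    study_totals
        One row per (scope, species) with grams, raw percentage of the
        scope's deployed biomass, and the integer display percentage; plus
        a ``total`` species row per scope summing the display percentages
        the way published ledgers do.
    """

    per_carcass: pd.DataFrame
    allocations: pd.DataFrame
    study_totals: pd.DataFrame
    fraction: float
    kappa: float | None


def nonvertebrate_loss_fraction(
    controls: pd.DataFrame, unscavenged: pd.DataFrame
) -> float:
    """Pooled fraction of initial mass lost to non-vertebrate causes.

    ``Σ(initial − final) / Σ initial`` over caged controls plus
    experimental carcasses at which no scavenging behaviour was recorded.
    Removed carcasses are inadmissible here (their loss is vertebrate by
    definition).
    """
    pool = pd.concat([controls, unscavenged], ignore_index=True) if len(controls) or len(
        unscavenged
    ) else pd.DataFrame()
    if len(pool) == 0:
        raise InsufficientDataError(
            "no control or unscavenged carcasses to estimate non-vertebrate loss"
        )
    if pool.get("removed") is not None and (pool["removed"].astype(int) != 0).any():
        raise ValueError("removed carcasses cannot enter the non-vertebrate pool")
    total_initial = float(pool["initial_mass_g"].sum())
    total_loss = float((pool["initial_mass_g"] - pool["final_mass_g"]).sum())
    frac = total_loss / total_initial
    return float(min(max(frac, 0.0), 1.0))


def measured_loss(deployment) -> float:
    """Grams lost: initial − final, or the whole initial mass if removed."""
    if int(deployment["removed"]):
        return float(deployment["initial_mass_g"])
    return float(deployment["initial_mass_g"] - deployment["final_mass_g"])


def adjust_loss(deployment, fraction: float) -> float:
    """Vertebrate-attributable loss: measured loss minus the non-vertebrate
    share of initial mass, floored at zero."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    loss = measured_loss(deployment)
    return max(0.0, loss - fraction * float(deployment["initial_mass_g"]))


def calibrate_kappa(pairs: list[tuple[float, float]]) -> float:
    """In-situ consumption rate κ (g per kg·min) by OLS through the origin.

    ``pairs`` holds (adjusted loss L in grams, Σ body-mass-kg × eating-min
    S) for non-removed scavenged carcasses; κ = Σ L·S / Σ S², floored at 0.
    """
    usable = [(L, S) for L, S in pairs if S > 0]
    if not usable:
        raise CalibrationError(
            "no non-removed scavenged carcasses with eating time; "
            "cannot calibrate the in-situ rate"
        )
    L = np.array([p[0] for p in usable])
    S = np.array([p[1] for p in usable])
    return float(max(0.0, (L * S).sum() / (S * S).sum()))


def allocate_carcass(
    deployment,
    eating_minutes_by_species: dict[str, float],
    remover: str | None,
    body_masses: dict[str, float],
    fraction: float,
    kappa: float | None = None,
    removal_rule: str = "kappa",
) -> dict[str, float]:
    """Grams credited to each species for one carcass.

    Non-removed carcass: species *i* receives
    ``adjusted_loss × m_i t_i / Σ_j m_j t_j``; with no eating time recorded
    the loss stays unattributed.  Removed carcass: under the ``"kappa"``
    rule each in-situ eater receives ``κ m_i t_i`` (rescaled down if the
    sum would exceed the adjusted loss) and the remover the remainder;
    under ``"proportional"`` the remover is sole consumer.
    """
    removed = bool(int(deployment["removed"]))
    if remover is not None and not removed:
        raise ValueError("a remover can only be credited on a removed carcass")
    for sp in list(eating_minutes_by_species) + ([remover] if remover else []):
        if sp not in body_masses:
            raise KeyError(f"species {sp!r} missing from body-mass table")
    adjusted = adjust_loss(deployment, fraction)
    weights = {
        sp: body_masses[sp] * t
        for sp, t in eating_minutes_by_species.items()
        if t > 0
    }
    alloc: dict[str, float] = {}
    if not removed or remover is None:
        wsum = sum(weights.values())
        if wsum > 0:
            for sp, w in weights.items():
                alloc[sp] = adjusted * w / wsum
        return alloc
    if removal_rule == "proportional":
        alloc[remover] = adjusted
        return alloc
    if kappa is None:
        raise CalibrationError("kappa removal rule requires a calibrated kappa")
    insitu = {
        sp: kappa * (body_masses[sp] / 1000.0) * t
        for sp, t in eating_minutes_by_species.items()
        if t > 0
    }
    total_insitu = sum(insitu.values())
    if total_insitu > adjusted > 0:
        scale = adjusted / total_insitu
        insitu = {sp: g * scale for sp, g in insitu.items()}
        total_insitu = adjusted
    elif adjusted == 0:
        insitu = {}
        total_insitu = 0.0
    alloc.update(insitu)
    alloc[remover] = alloc.get(remover, 0.0) + (adjusted - total_insitu)
    return alloc


def scope_ledger(
    deployed_g: float,
    species_grams: dict[str, float],
    scope: str = "ALL",
) -> pd.DataFrame:
    """Percentage ledger for one denominator scope.

    Raw percentages are grams / deployed biomass × 100; display percentages
    are rounded to the nearest integer and the ``total`` row's display value
    is the sum of the species' display values, matching the convention of
    published biomass ledgers.
    """
    if deployed_g <= 0:
        raise InsufficientDataError(f"scope {scope}: no deployed biomass")
    rows = []
    for sp in species_grams:
        g = species_grams[sp]
        pct = 100.0 * g / deployed_g
        rows.append(
            {
                "scope": scope,
                "species": sp,
                "grams": g,
                "pct_raw": pct,
                "pct_display": int(round(pct)),
            }
        )
    total_g = sum(species_grams.values())
    rows.append(
        {
            "scope": scope,
            "species": "total",
            "grams": total_g,
            "pct_raw": 100.0 * total_g / deployed_g,
            "pct_display": int(sum(r["pct_display"] for r in rows)),
        }
    )
    return pd.DataFrame(rows)


def _scavenged_carcasses(observations: pd.DataFrame, behaviors) -> set:
    if len(observations) == 0:
        return set()
    mask = observations["behavior"].isin(behaviors)
    return set(observations.loc[mask, "carcass_id"].unique())


def attribute_study(
    deployments: pd.DataFrame,
    observations: pd.DataFrame,
    body_masses: dict[str, float] | None = None,
    config: AttributionConfig | None = None,
) -> AttributionResult:
    """Run the full attribution over one study.

    Estimates the non-vertebrate fraction, calibrates κ, allocates every
    experimental carcass, and aggregates grams and percentages under the
    three reporting scopes.  Per carcass, allocated + unattributed equals
    the adjusted loss exactly, and species grams + unattributed +
    non-vertebrate grams reconstruct the measured loss.
    """
    config = config or AttributionConfig()
    config.validate()
    body_masses = dict(DEFAULT_BODY_MASS_G if body_masses is None else body_masses)

    dep = deployments.copy()
    exp = dep[dep["is_control"].astype(int) == 0]
    controls = dep[dep["is_control"].astype(int) == 1]
    scavenged = _scavenged_carcasses(observations, config.scavenging_behaviors)

    unscavenged = exp[
        ~exp["carcass_id"].isin(scavenged) & (exp["removed"].astype(int) == 0)
    ]
    if config.fraction is not None:
        fraction = config.fraction
    else:
        fraction = nonvertebrate_loss_fraction(controls, unscavenged)

    species_list = sorted(body_masses)
    eating = eating_time_by_species(observations, species=None)
    eating_map: dict = {}
    for _, row in eating.iterrows():
        eating_map.setdefault(row["carcass_id"], {})[row["species"]] = float(
            row["eating_min"]
        )

    removers: dict = {}
    if len(observations):
        rem_obs = observations[observations["behavior"] == "REMOVING"].sort_values(
            "start_utc"
        )
        for _, row in rem_obs.iterrows():
            removers.setdefault(row["carcass_id"], row["species"])

    # κ calibration over non-removed scavenged carcasses
    kappa: float | None = None
    if config.removal_rule == "kappa":
        pairs = []
        for _, d in exp.iterrows():
            cid = d["carcass_id"]
            if cid not in scavenged or int(d["removed"]):
                continue
            S = sum(
                (body_masses[sp] / 1000.0) * t
                for sp, t in eating_map.get(cid, {}).items()
            )
            pairs.append((adjust_loss(d, fraction), S))
        try:
            kappa = calibrate_kappa(pairs)
        except CalibrationError:
            kappa = None  # no usable carcasses: fall back per carcass

    pc_rows = []
    alloc_rows = []
    for _, d in exp.iterrows():
        cid = d["carcass_id"]
        etimes = eating_map.get(cid, {})
        remover = removers.get(cid) if int(d["removed"]) else None
        rule = config.removal_rule
        if rule == "kappa" and kappa is None:
            rule = "proportional"
        alloc = allocate_carcass(
            d, etimes, remover, body_masses, fraction, kappa=kappa, removal_rule=rule
        )
        loss = measured_loss(d)
        adjusted = adjust_loss(d, fraction)
        nonvert = min(loss, fraction * float(d["initial_mass_g"]))
        allocated = sum(alloc.values())
        pc_rows.append(
            {
                "carcass_id": cid,
                "initial_mass_g": float(d["initial_mass_g"]),
                "measured_loss_g": loss,
                "nonvertebrate_g": nonvert,
                "adjusted_loss_g": adjusted,
                "allocated_g": allocated,
                "unattributed_g": adjusted - allocated,
                "scavenged": cid in scavenged,
                "removed": int(d["removed"]),
                "remover": remover or "",
            }
        )
        for sp, g in sorted(alloc.items()):
            alloc_rows.append({"carcass_id": cid, "species": sp, "grams": g})

    per_carcass = pd.DataFrame(pc_rows)
    allocations = pd.DataFrame(alloc_rows, columns=["carcass_id", "species", "grams"])

    # study ledgers under the three scopes
    fox_ok_sites = set(exp.loc[exp["access_class"] == "ALL", "carcass_id"])
    scope_sets = {
        "ALL": set(exp["carcass_id"]),
        "SCAVENGED_ONLY": scavenged & set(exp["carcass_id"]),
        "FOX_ACCESSIBLE_ONLY": scavenged & fox_ok_sites,
    }
    ledgers = []
    dep_mass = exp.set_index("carcass_id")["initial_mass_g"]
    observed_species = sorted(set(allocations["species"])) or species_list
    for scope, cids in scope_sets.items():
        if not cids:
            continue
        deployed = float(dep_mass.loc[list(cids)].sum())
        in_scope = allocations[allocations["carcass_id"].isin(cids)]
        grams = {
            sp: float(in_scope.loc[in_scope["species"] == sp, "grams"].sum())
            for sp in observed_species
        }
        if config.adjustment_scope == "study_wide":
            # re-derive from the pooled adjusted biomass instead of the
            # per-carcass floors (allocation shares kept)
            pool = deployed * (1.0 - fraction)
            total = sum(grams.values())
            if total > pool and total > 0:
                grams = {sp: g * pool / total for sp, g in grams.items()}
        ledgers.append(scope_ledger(deployed, grams, scope=scope))
    study_totals = (
        pd.concat(ledgers, ignore_index=True)
        if ledgers
        else pd.DataFrame(columns=["scope", "species", "grams", "pct_raw", "pct_display"])
    )

    return AttributionResult(
        per_carcass=per_carcass,
        allocations=allocations,
        study_totals=study_totals,
        fraction=fraction,
        kappa=kappa,
    )
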