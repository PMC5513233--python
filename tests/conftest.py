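from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from carcassfate import default_paperlike_config, extract_observations, simulate_study


def small_config(seed: int = 7, n_carcasses: int = 16, n_controls: int = 4):
    """Reduced copy of the study design for fast unit tests."""
    cfg = default_paperlike_config(seed=seed)
    cfg.n_carcasses = n_carcasses
    cfg.n_controls = n_controls
    return cfg


@pytest.fixture(scope="session")
def small_study():
    cfg = small_config()
    deployments, frames, truth = simulate_study(cfg)
    return cfg, deployments, frames, truth


@pytest.fixture(scope="session")
def paperlike_study():
    cfg = default_paperlike_config(seed=11)
    deployments, frames, truth = simulate_study(cfg)
    return cfg, deployments, frames, truth


@pytest.fixture(scope="session")
def paperlike_observations(paperlike_study):
    _, _, frames, _ = paperlike_study
    return extract_observations(frames)


def make_frames(rows):
    """Detection frames from (carcass, seconds-offset, species, behavior)."""
    base = pd.Timestamp("2014-06-10 09:00:00", tz="UTC")
    return pd.DataFrame(
        {
            "carcass_id": [r[0] for r in rows],
            "timestamp_utc": [base + pd.Timedelta(seconds=r[1]) for r in rows],
            "species": [r[2] for r in rows],
            "behavior": [r[3] for r in rows],
        }
    )


def naive_extract(frames: pd.DataFrame, gap_threshold_s: float = 60.0) -> pd.DataFrame:
    """Quadratic reference grouping: per (carcass, species), walk frames in
    time order and split on gap > threshold or behaviour change."""
    recs = [
        r
        for _, r in frames.iterrows()
        if pd.notna(r["species"]) and r["species"] not in ("", "NONE")
    ]
    out = []
    keys = sorted({(r["carcass_id"], r["species"]) for r in recs})
    for cid, sp in keys:
        sub = sorted(
            (r for r in recs if r["carcass_id"] == cid and r["species"] == sp),
            key=lambda r: r["timestamp_utc"],
        )
        groups = [[sub[0]]]
        for prev, nxt in zip(sub, sub[1:]):
            gap = (nxt["timestamp_utc"] - prev["timestamp_utc"]).total_seconds()
            if gap > gap_threshold_s or nxt["behavior"] != prev["behavior"]:
                groups.append([nxt])
            else:
                groups[-1].append(nxt)
        for g in groups:
            start, end = g[0]["timestamp_utc"], g[-1]["timestamp_utc"]
            out.append(
                {
                    "carcass_id": cid,
                    "species": sp,
                    "behavior": g[0]["behavior"],
                    "start_utc": start,
                    "end_utc": end,
                    "duration_min": (end - start).total_seconds() / 60.0,
                }
            )
    cols = ["carcass_id", "species", "behavior", "start_utc", "end_utc", "duration_min"]
    return (
        pd.DataFrame(out, columns=cols)
        .sort_values(["carcass_id", "start_utc", "species"], kind="mergesort")
        .reset_index(drop=True)
    )


def random_frames(rng: np.random.Generator, n: int, n_species: int = 2) -> pd.DataFrame:
    """Random single-carcass detection stream with bursts and long gaps."""
    rows = []
    t = 0.0
    for _ in range(n):
        # mostly rapid-fire, occasionally a long silence
        t += float(rng.choice([1.0, 2.0, 30.0, 120.0, 900.0], p=[0.6, 0.2, 0.1, 0.05, 0.05]))
        sp = f"sp{rng.integers(n_species)}"
        behavior = str(rng.choice(["LOOKING", "EXAMINING", "EATING"], p=[0.2, 0.4, 0.4]))
        rows.append(("C001", t, sp, behavior))
    return make_frames(rows)
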