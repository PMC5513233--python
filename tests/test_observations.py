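"""Observation extraction: grouping semantics, oracles, latency tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from pandas.testing import assert_frame_equal

from carcassfate import (
    eating_time_by_species,
    extract_observations,
    first_arrival_latency,
)
from carcassfate.observations import BehaviorError, FrameOrderError

from conftest import make_frames, naive_extract, random_frames


class TestExtraction:
    def test_empty_input_gives_empty_table(self):
        out = extract_observations(pd.DataFrame(
            columns=["carcass_id", "timestamp_utc", "species", "behavior"]))
        assert len(out) == 0
        assert list(out.columns) == [
            "carcass_id", "species", "behavior", "start_utc", "end_utc", "duration_min",
        ]

    def test_behavior_change_splits_run(self):
        # 5 eating frames at 1 s spacing then 3 examining frames: two
        # observations of 4 s and 2 s
        rows = [("C1", t, "crow", "EATING") for t in range(5)]
        rows += [("C1", 5 + t, "crow", "EXAMINING") for t in range(3)]
        out = extract_observations(make_frames(rows))
        assert len(out) == 2
        eat, exam = out.iloc[0], out.iloc[1]
        assert eat["behavior"] == "EATING"
        assert eat["duration_min"] == pytest.approx(4 / 60)
        assert exam["behavior"] == "EXAMINING"
        assert exam["duration_min"] == pytest.approx(2 / 60)

    def test_long_gap_splits_run(self):
        rows = [("C1", t, "crow", "EXAMINING") for t in range(5)]
        rows += [("C1", 604 + t, "crow", "EXAMINING") for t in range(5)]
        out = extract_observations(make_frames(rows), gap_threshold_s=60)
        assert len(out) == 2
        assert out["duration_min"].tolist() == pytest.approx([4 / 60, 4 / 60])

    def test_gap_at_threshold_merges(self):
        rows = [("C1", 0, "crow", "EXAMINING"), ("C1", 60, "crow", "EXAMINING")]
        out = extract_observations(make_frames(rows), gap_threshold_s=60)
        assert len(out) == 1

    def test_species_key_separates_interleaved_animals(self):
        rows = []
        for t in range(0, 20, 2):
            rows.append(("C1", t, "crow", "EATING"))
            rows.append(("C1", t + 1, "magpie", "EXAMINING"))
        out = extract_observations(make_frames(rows))
        assert len(out) == 2
        assert set(out["species"]) == {"crow", "magpie"}

    def test_single_frame_observation_has_zero_duration(self):
        out = extract_observations(make_frames([("C1", 0, "fox", "LOOKING")]))
        assert len(out) == 1
        assert out.loc[0, "duration_min"] == 0.0

    def test_unsorted_frames_rejected(self):
        rows = [("C1", 10, "crow", "EATING"), ("C1", 0, "crow", "EATING")]
        with pytest.raises(FrameOrderError):
            extract_observations(make_frames(rows))

    def test_unknown_behavior_rejected(self):
        with pytest.raises(BehaviorError, match="FLYING"):
            extract_observations(make_frames([("C1", 0, "crow", "FLYING")]))

    def test_matches_naive_oracle_on_random_stream(self):
        rng = np.random.default_rng(42)
        frames = random_frames(rng, 1000, n_species=3)
        fast = extract_observations(frames)
        slow = naive_extract(frames)
        assert_frame_equal(fast, slow, check_dtype=False)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=1, max_value=80), st.integers(min_value=0, max_value=10_000))
    def test_matches_naive_oracle_property(self, n, seed):
        frames = random_frames(np.random.default_rng(seed), n)
        assert_frame_equal(
            extract_observations(frames), naive_extract(frames), check_dtype=False
        )

    def test_idempotent_through_reencoding(self, paperlike_observations):
        """Re-encoding observations as a 1 s frame stream and re-extracting
        reproduces every duration within one frame interval."""
        obs = paperlike_observations.head(300)
        rows = []
        for _, o in obs.iterrows():
            n = int(round(o["duration_min"] * 60.0)) + 1
            for k in range(n):
                rows.append(
                    {
                        "carcass_id": o["carcass_id"],
                        "timestamp_utc": o["start_utc"] + pd.Timedelta(seconds=k),
                        "species": o["species"],
                        "behavior": o["behavior"],
                    }
                )
        frames = (
            pd.DataFrame(rows)
            .sort_values(["carcass_id", "timestamp_utc"], kind="mergesort")
            .reset_index(drop=True)
        )
        redone = extract_observations(frames)
        merged = obs.merge(
            redone,
            on=["carcass_id", "species", "behavior", "start_utc"],
            suffixes=("", "_re"),
        )
        assert len(merged) == len(obs)
        assert (merged["duration_min"] - merged["duration_min_re"]).abs().max() <= 1 / 60


class TestEatingTime:
    def test_no_eating_gives_zeros(self):
        obs = extract_observations(
            make_frames([("C1", 0, "crow", "EXAMINING"), ("C1", 1, "crow", "EXAMINING")])
        )
        tab = eating_time_by_species(obs, species=["crow", "magpie"])
        assert (tab["eating_min"] == 0).all()
        assert set(tab["species"]) == {"crow", "magpie"}

    def test_additivity(self):
        obs = pd.DataFrame(
            {
                "carcass_id": ["C1", "C1"],
                "species": ["crow", "crow"],
                "behavior": ["EATING", "EATING"],
                "start_utc": pd.to_datetime(["2014-06-01 10:00", "2014-06-01 12:00"], utc=True),
                "end_utc": pd.to_datetime(["2014-06-01 10:10", "2014-06-01 12:05"], utc=True),
                "duration_min": [10.0, 5.0],
            }
        )
        tab = eating_time_by_species(obs)
        assert tab.loc[0, "eating_min"] == pytest.approx(15.0)

    def test_matches_independent_groupby(self, paperlike_observations):
        obs = paperlike_observations
        tab = eating_time_by_species(obs).set_index(["carcass_id", "species"])["eating_min"]
        oracle = (
            obs[obs["behavior"] == "EATING"]
            .groupby(["carcass_id", "species"])["duration_min"]
            .sum()
        )
        assert tab.sort_index().round(9).equals(oracle.sort_index().round(9))


class TestFirstArrival:
    def test_unobserved_pair_has_no_row(self, small_study):
        _, dep, frames, _ = small_study
        obs = extract_observations(frames)
        lat = first_arrival_latency(dep, obs)
        observed_pairs = set(map(tuple, obs[["carcass_id", "species"]].drop_duplicates().values))
        assert set(map(tuple, lat[["carcass_id", "species"]].values)) == observed_pairs

    def test_single_case_arithmetic(self):
        dep = pd.DataFrame(
            {
                "carcass_id": ["C1"],
                "start_utc": pd.to_datetime(["2014-06-01 12:00"], utc=True),
            }
        )
        obs = pd.DataFrame(
            {
                "carcass_id": ["C1"],
                "species": ["magpie"],
                "behavior": ["EXAMINING"],
                "start_utc": pd.to_datetime(["2014-06-01 20:24"], utc=True),
                "end_utc": pd.to_datetime(["2014-06-01 20:30"], utc=True),
                "duration_min": [6.0],
            }
        )
        lat = first_arrival_latency(dep, obs)
        assert lat.loc[0, "latency_min"] == pytest.approx(504.0)

    def test_matches_simulator_arrival_draws(self, paperlike_study):
        _, dep, frames, truth = paperlike_study
        obs = extract_observations(frames)
        lat = first_arrival_latency(dep, obs).set_index(["carcass_id", "species"])
        arr = truth.arrivals.set_index(["carcass_id", "species"])
        joined = lat.join(arr, how="inner", lsuffix="_obs")
        assert len(joined) == len(arr)
        assert (joined["latency_min_obs"] - joined["latency_min"]).abs().max() < 1e-6

    def test_unknown_carcass_rejected(self):
        dep = pd.DataFrame(
            {"carcass_id": ["C1"], "start_utc": pd.to_datetime(["2014-06-01"], utc=True)}
        )
        obs = pd.DataFrame(
            {
                "carcass_id": ["C2"],
                "species": ["crow"],
                "behavior": ["EATING"],
                "start_utc": pd.to_datetime(["2014-06-01 10:00"], utc=True),
                "end_utc": pd.to_datetime(["2014-06-01 10:01"], utc=True),
                "duration_min": [1.0],
            }
        )
        with pytest.raises(KeyError):
            first_arrival_latency(dep, obs)
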