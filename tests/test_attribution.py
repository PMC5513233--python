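"""Biomass attribution: hand-checked arithmetic, conservation, recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from carcassfate import (
    AttributionConfig,
    adjust_loss,
    allocate_carcass,
    attribute_study,
    calibrate_kappa,
    extract_observations,
    nonvertebrate_loss_fraction,
)
from carcassfate.attribution import CalibrationError, InsufficientDataError

from conftest import small_config
from carcassfate.simulate import simulate_study


def dep_row(initial=280.0, final=100.0, removed=0, **kw):
    row = {
        "carcass_id": kw.get("carcass_id", "C1"),
        "initial_mass_g": initial,
        "final_mass_g": final,
        "removed": removed,
    }
    row.update(kw)
    return pd.Series(row)


def deps(rows):
    return pd.DataFrame(rows)


class TestNonvertebrateFraction:
    def test_zero_loss_controls(self):
        controls = deps(
            [dict(carcass_id=f"K{i}", initial_mass_g=260.0, final_mass_g=260.0, removed=0)
             for i in range(3)]
        )
        assert nonvertebrate_loss_fraction(controls, controls.iloc[:0]) == 0.0

    def test_pooled_hand_arithmetic(self):
        controls = deps([dict(carcass_id="K1", initial_mass_g=250.0, final_mass_g=240.0, removed=0)])
        unscav = deps([dict(carcass_id="C9", initial_mass_g=300.0, final_mass_g=280.0, removed=0)])
        # (10 + 20) / (250 + 300)
        assert nonvertebrate_loss_fraction(controls, unscav) == pytest.approx(30 / 550)

    def test_empty_input_rejected(self):
        empty = deps([]).reindex(columns=["carcass_id", "initial_mass_g", "final_mass_g", "removed"])
        with pytest.raises(InsufficientDataError):
            nonvertebrate_loss_fraction(empty, empty)

    def test_removed_carcass_rejected(self):
        bad = deps([dict(carcass_id="C1", initial_mass_g=250.0, final_mass_g=0.0, removed=1)])
        with pytest.raises(ValueError, match="removed"):
            nonvertebrate_loss_fraction(bad, bad.iloc[:0])


class TestAdjustLoss:
    def test_zero_fraction_returns_measured_loss(self):
        assert adjust_loss(dep_row(initial=280, final=100), 0.0) == pytest.approx(180.0)

    def test_clamped_at_zero_when_loss_equals_background(self):
        d = dep_row(initial=250, final=250 * (1 - 0.096))
        assert adjust_loss(d, 0.096) == 0.0

    def test_removed_carcass_counts_full_initial_mass(self):
        d = dep_row(initial=280, final=0, removed=1)
        assert adjust_loss(d, 0.096) == pytest.approx(253.12)


class TestKappa:
    def test_single_point_reduces_to_ratio(self):
        assert calibrate_kappa([(90.0, 11.4)]) == pytest.approx(90 / 11.4)

    def test_two_point_ols_through_origin(self):
        # kappa = (90*11.4 + 50*5) / (11.4^2 + 5^2)
        assert calibrate_kappa([(90.0, 11.4), (50.0, 5.0)]) == pytest.approx(1276 / 154.96)

    def test_zero_losses_give_zero_kappa(self):
        assert calibrate_kappa([(0.0, 3.0), (0.0, 7.0)]) == 0.0

    def test_no_usable_carcasses_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_kappa([(90.0, 0.0)])


BODY = {"crow": 570.0, "magpie": 230.0, "fox": 6500.0}


class TestAllocateCarcass:
    def test_single_eater_takes_all(self):
        d = dep_row(initial=280, final=180)
        alloc = allocate_carcass(d, {"crow": 12.0}, None, BODY, 0.0)
        assert alloc == {"crow": pytest.approx(100.0)}

    def test_mass_times_time_weighting(self):
        d = dep_row(initial=300, final=200)
        alloc = allocate_carcass(d, {"crow": 30.0, "magpie": 30.0}, None, BODY, 0.0)
        assert alloc["crow"] == pytest.approx(71.25)
        assert alloc["magpie"] == pytest.approx(28.75)

    def test_no_eating_time_leaves_loss_unattributed(self):
        d = dep_row(initial=280, final=200)
        assert allocate_carcass(d, {}, None, BODY, 0.0) == {}

    def test_remover_with_no_prior_eating_gets_full_adjusted_loss(self):
        d = dep_row(initial=280, final=0, removed=1)
        alloc = allocate_carcass(d, {}, "fox", BODY, 0.096, kappa=8.0)
        assert alloc == {"fox": pytest.approx(253.12)}

    def test_kappa_split_between_eater_and_remover(self):
        d = dep_row(initial=280, final=0, removed=1)
        alloc = allocate_carcass(d, {"crow": 10.0}, "fox", BODY, 0.096, kappa=8.0)
        crow = 8.0 * 0.570 * 10.0
        assert alloc["crow"] == pytest.approx(crow)
        assert alloc["fox"] == pytest.approx(253.12 - crow)

    def test_insitu_credit_rescaled_when_exceeding_adjusted_loss(self):
        d = dep_row(initial=280, final=0, removed=1)
        alloc = allocate_carcass(d, {"crow": 1000.0}, "fox", BODY, 0.096, kappa=8.0)
        assert sum(alloc.values()) == pytest.approx(253.12)
        assert alloc["fox"] == pytest.approx(0.0, abs=1e-9)

    def test_proportional_rule_makes_remover_sole_consumer(self):
        d = dep_row(initial=280, final=0, removed=1)
        alloc = allocate_carcass(
            d, {"crow": 10.0}, "fox", BODY, 0.096, removal_rule="proportional"
        )
        assert alloc == {"fox": pytest.approx(253.12)}

    def test_remover_requires_removed_carcass(self):
        with pytest.raises(ValueError):
            allocate_carcass(dep_row(), {"crow": 5.0}, "fox", BODY, 0.0, kappa=1.0)

    def test_unknown_species_rejected(self):
        d = dep_row(initial=280, final=0, removed=1)
        with pytest.raises(KeyError, match="badger"):
            allocate_carcass(d, {"badger": 5.0}, None, BODY, 0.0)

    def test_scale_equivariance_of_body_masses(self):
        d = dep_row(initial=300, final=120)
        times = {"crow": 17.0, "magpie": 41.0, "fox": 3.0}
        a = allocate_carcass(d, times, None, BODY, 0.05)
        scaled = {k: 1000.0 * v for k, v in BODY.items()}
        b = allocate_carcass(d, times, None, scaled, 0.05)
        for sp in a:
            assert a[sp] == pytest.approx(b[sp], abs=1e-9)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=0.1, max_value=500.0),
        st.floats(min_value=0.1, max_value=500.0),
        st.floats(min_value=0.1, max_value=500.0),
    )
    def test_increasing_eating_time_never_reduces_share(self, t_crow, t_magpie, bump):
        d = dep_row(initial=300, final=100)
        a = allocate_carcass(d, {"crow": t_crow, "magpie": t_magpie}, None, BODY, 0.0)
        b = allocate_carcass(d, {"crow": t_crow + bump, "magpie": t_magpie}, None, BODY, 0.0)
        assert b["crow"] >= a["crow"] - 1e-9

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=300.0), min_size=1, max_size=3),
        st.floats(min_value=0.0, max_value=0.3),
    )
    def test_allocation_bounded_by_adjusted_loss(self, times, fraction):
        d = dep_row(initial=300, final=90)
        sp = ["crow", "magpie", "fox"][: len(times)]
        alloc = allocate_carcass(d, dict(zip(sp, times)), None, BODY, fraction)
        assert sum(alloc.values()) <= adjust_loss(d, fraction) + 1e-9


class TestAttributeStudy:
    def test_unscavenged_study_allocates_nothing(self):
        cfg = small_config(seed=31)
        for p in cfg.species_profiles:
            p.eat_prob_per_visit = 0.0
            p.removal_prob_per_visit = 0.0
        dep, frames, _ = simulate_study(cfg)
        obs = extract_observations(frames)
        res = attribute_study(dep, obs)
        assert len(res.allocations) == 0 or res.allocations["grams"].sum() == 0
        assert "SCAVENGED_ONLY" not in set(res.study_totals["scope"])

    def test_per_carcass_conservation_to_1e9(self, paperlike_study, paperlike_observations):
        _, dep, _, _ = paperlike_study
        res = attribute_study(dep, paperlike_observations)
        pc = res.per_carcass
        err = (pc["allocated_g"] + pc["unattributed_g"] - pc["adjusted_loss_g"]).abs()
        assert err.max() < 1e-9
        # measured loss decomposes into species + unattributed + non-vertebrate
        err2 = (
            pc["allocated_g"] + pc["unattributed_g"] + pc["nonvertebrate_g"]
            - pc["measured_loss_g"]
        ).abs()
        assert err2.max() < 1e-9

    def test_study_pools_sum_to_deployed_biomass(self, paperlike_study, paperlike_observations):
        _, dep, _, _ = paperlike_study
        res = attribute_study(dep, paperlike_observations)
        pc = res.per_carcass
        exp = dep[dep["is_control"] == 0]
        lhs = (
            pc["allocated_g"].sum()
            + pc["unattributed_g"].sum()
            + pc["nonvertebrate_g"].sum()
            + (exp["final_mass_g"]).sum()
        )
        assert lhs == pytest.approx(exp["initial_mass_g"].sum(), abs=1e-6)

    def test_fox_gets_removal_credit_without_eating(self, paperlike_study, paperlike_observations):
        _, dep, _, truth = paperlike_study
        res = attribute_study(dep, paperlike_observations)
        fox = res.allocations[res.allocations["species"] == "fox"]
        assert fox["grams"].sum() > 0
        eating = paperlike_observations[
            (paperlike_observations["species"] == "fox")
            & (paperlike_observations["behavior"] == "EATING")
        ]
        assert len(eating) == 0

    def test_recovers_truth_ledger_species_totals(self):
        cfg = small_config(seed=41, n_carcasses=200, n_controls=10)
        dep, frames, truth = simulate_study(cfg)
        obs = extract_observations(frames)
        res = attribute_study(dep, obs)
        est = res.allocations.groupby("species")["grams"].sum()
        true = truth.species_totals()["total_g"]
        for sp in true.index:
            rel = abs(est.get(sp, 0.0) - true[sp]) / true[sp]
            assert rel < 0.10, (sp, est.get(sp, 0.0), true[sp])

    def test_proportional_config_shifts_credit_to_remover(
        self, paperlike_study, paperlike_observations
    ):
        _, dep, _, _ = paperlike_study
        kappa_res = attribute_study(dep, paperlike_observations)
        prop_res = attribute_study(
            dep, paperlike_observations, config=AttributionConfig(removal_rule="proportional")
        )
        fox_k = kappa_res.allocations.query("species == 'fox'")["grams"].sum()
        fox_p = prop_res.allocations.query("species == 'fox'")["grams"].sum()
        assert fox_p >= fox_k
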