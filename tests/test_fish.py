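import numpy as np
import pytest

from hexstream.core_math import default_reach_params
from hexstream.fish import (FEED, HIDE, Fish, StepResources, apply_growth,
                            apply_survival_and_outmigration, biggest_length,
                            candidate_cells, cmax, condition, detect_distance,
                            food_intake, healthy_weight, max_move_distance,
                            max_swim_speed, new_year_update, respiration_rate,
                            select_habitat, staying_probability,
                            survival_probabilities)
from hexstream.habitat import Cell, Reach

from conftest import make_pair_reach


def make_fish(length=5.0, sp=None, species="trout", adult=False, nrep=1,
              weight=None, sex="F", age=None, fid=0):
    w = weight if weight is not None else float(healthy_weight(length, sp))
    return Fish(id=fid, species=species, sex=sex,
                age=age if age is not None else (4 if adult else 0),
                fishLength=length, fishWeight=w, nRep=nrep,
                isSalmonSpawner=adult,
                rng=np.random.default_rng([0, fid]))


class TestAllometry:
    def test_healthy_weight_values(self, trout, salmon):
        assert healthy_weight(8.0, salmon) == pytest.approx(5.44, abs=0.02)
        assert healthy_weight(10.0, trout) == pytest.approx(10.05, abs=0.03)

    def test_condition_is_one_at_healthy_weight(self, trout):
        f = make_fish(10.0, trout)
        assert condition(f, trout) == pytest.approx(1.0)

    def test_move_distance(self, trout):
        assert max_move_distance(2.0, trout) == pytest.approx(52.78, abs=0.05)
        assert max_move_distance(20.0, trout) == pytest.approx(13256.0, rel=1e-3)

    def test_candidate_set_includes_adjacency(self, small_reach, trout):
        f = make_fish(2.0, trout)
        f.cell = int(len(small_reach) // 2)
        cands = candidate_cells(f, small_reach, trout)
        assert f.cell in cands
        assert set(small_reach.neighbors_idx[f.cell]) <= set(cands)

    def test_single_cell_reach_degenerates(self, trout):
        cell = Cell(cellID=0, centroid=(0, 0), corners=[(0, 0)] * 6,
                    area=2.598, lookup_flows=np.array([1.0]),
                    lookup_depth=np.array([30.0]),
                    lookup_velocity=np.array([20.0]))
        reach = Reach([cell])
        f = make_fish(5.0, trout)
        assert list(candidate_cells(f, reach, trout)) == [0]


class TestFeeding:
    def test_detect_distance_day_night(self, trout):
        assert detect_distance(5.0, trout, is_night=False) == 14.0
        assert detect_distance(5.0, trout, is_night=True) == 7.0

    def test_adults_take_no_food(self, small_reach, trout):
        f = make_fish(77.0, trout, adult=True)
        intake = food_intake(
            f, small_reach, trout, depths=small_reach.depths_at(3.0),
            velocities=small_reach.velocities_at(3.0), temperature=10.0,
            is_night=False, activity=FEED, step_hours=12.0)
        assert np.all(intake == 0.0)

    def test_hiding_fish_take_no_food(self, small_reach, trout):
        f = make_fish(5.0, trout)
        intake = food_intake(
            f, small_reach, trout, depths=small_reach.depths_at(3.0),
            velocities=small_reach.velocities_at(3.0), temperature=10.0,
            is_night=False, activity=HIDE, step_hours=12.0)
        assert np.all(intake == 0.0)

    def test_capture_success_anchor(self, trout):
        from hexstream.fish import _curves
        assert _curves(trout)["capture"](0.5) == pytest.approx(0.9, abs=1e-9)
        assert _curves(trout)["capture"](1.6) == pytest.approx(0.1, abs=1e-9)

    def test_cmax_examples(self, trout):
        assert cmax(10.0, 10.0, 24.0, trout) == pytest.approx(1.574, abs=2e-3)
        assert cmax(10.0, 25.0, 24.0, trout) == 0.0
        assert cmax(10.0, 10.0, 12.0, trout) == pytest.approx(
            cmax(10.0, 10.0, 24.0, trout) / 2)

    def test_respiration_standard(self, trout):
        assert float(respiration_rate(trout, 10.0, 10.0, 0.0)) == pytest.approx(
            364.8, rel=2e-3)

    def test_weight_dynamics(self, trout):
        f = make_fish(10.0, trout)
        w0 = f.fishWeight
        f.growth_rate = -0.01
        apply_growth(f, trout, 24.0)
        assert f.fishWeight < w0
        assert f.fishLength == 10.0  # length never falls
        f.growth_rate = 0.0
        w1 = f.fishWeight
        apply_growth(f, trout, 24.0)
        assert f.fishWeight == w1

    def test_length_growth_restores_condition(self, trout):
        f = make_fish(10.0, trout)
        f.growth_rate = 0.05
        apply_growth(f, trout, 48.0)
        assert f.fishLength > 10.0
        assert condition(f, trout) == pytest.approx(1.0, abs=1e-9)


class TestSurvival:
    def test_max_swim_speed_example(self, trout):
        assert float(max_swim_speed(10.0, 10.0, trout)) == pytest.approx(
            45.08, abs=0.01)

    def test_survival_increase_orientations(self, small_reach, trout):
        rp = default_reach_params()
        f = make_fish(20.0, trout)
        s = survival_probabilities(f, small_reach, trout, temperature=10.0,
                                   depth=50.0, velocity=10.0, is_night=False)
        # aquatic length increase is 0.9 at 20 cm
        assert s["aquaticPredation"] >= rp.habMortFishAqPredDayMin + \
            (1 - rp.habMortFishAqPredDayMin) * 0.9 - 1e-9
        # terrestrial depth increase is 0.9 at 200 cm
        deep = survival_probabilities(f, small_reach, trout, temperature=10.0,
                                      depth=200.0, velocity=10.0,
                                      is_night=False)
        p = trout.mortFishTerrPredDayMin
        assert deep["terrestrialPredation"] >= p + (1 - p) * 0.9 - 1e-9
        assert all(0.0 <= v <= 1.0 for v in s.values())

    def test_stranding_risk_grows_in_shallow_water(self, small_reach, trout):
        f = make_fish(10.0, trout)
        shallow = survival_probabilities(f, small_reach, trout,
                                         temperature=10.0, depth=0.5,
                                         velocity=5.0, is_night=False)
        deep = survival_probabilities(f, small_reach, trout, temperature=10.0,
                                      depth=50.0, velocity=5.0, is_night=False)
        assert shallow["stranding"] < deep["stranding"]

    def test_step_draws_reproduce_daily_probability(self, trout):
        # two 12-h steps with one risky source: expected daily mortality 0.1
        n, deaths = 20000, 0
        surv = {s: 1.0 for s in
                ("highTemperature", "highVelocity", "stranding",
                 "aquaticPredation", "terrestrialPredation", "poorCondition")}
        surv["terrestrialPredation"] = 0.9
        for i in range(n):
            f = make_fish(5.0, trout, fid=i)
            for _ in range(2):
                out, _d = apply_survival_and_outmigration(f, surv, 12.0)
                if out == "death":
                    deaths += 1
                    break
        p_hat = deaths / n
        sigma = np.sqrt(0.1 * 0.9 / n)
        assert abs(p_hat - 0.1) < 3 * sigma

    def test_staying_logistic_orientation(self, salmon):
        assert staying_probability(23.375, salmon) == pytest.approx(0.5,
                                                                    abs=1e-9)
        assert staying_probability(28.08, salmon) == pytest.approx(0.1,
                                                                   abs=1e-9)
        lengths = np.linspace(2, 35, 50)
        probs = [staying_probability(x, salmon) for x in lengths]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_tiny_safe_fish_stays_alive(self, salmon):
        surv = {s: 1.0 for s in
                ("highTemperature", "highVelocity", "stranding",
                 "aquaticPredation", "terrestrialPredation", "poorCondition")}
        f = make_fish(0.5, salmon, species="salmon")
        for _ in range(50):
            out, _ = apply_survival_and_outmigration(
                f, surv, 24.0, staying=staying_probability(0.5, salmon))
            assert out == "alive"

    def test_adults_never_outmigrate(self, salmon):
        surv = {s: 1.0 for s in
                ("highTemperature", "highVelocity", "stranding",
                 "aquaticPredation", "terrestrialPredation", "poorCondition")}
        f = make_fish(77.0, salmon, species="salmon", adult=True)
        for _ in range(200):
            out, _ = apply_survival_and_outmigration(f, surv, 24.0,
                                                     staying=1e-6)
            assert out == "alive"


class TestHabitatSelection:
    def test_biggest_length_floor(self, species):
        assert biggest_length([], species) == 37.5
        big = make_fish(50.0, species["trout"])
        assert biggest_length([big], species) == 50.0

    def test_shelter_cell_preferred_by_feeding_fish(self, species):
        reach = make_pair_reach(shelter=(0.0, 0.5), velocity=40.0)
        f = make_fish(6.0, species["trout"])
        f.cell = 0
        depths = reach.depths_at(1.0)
        vels = reach.velocities_at(1.0)
        res = StepResources.for_step(reach, depths, vels)
        select_habitat([f], reach, species, temperature=10.0, depths=depths,
                       velocities=vels, is_night=False, resources=res)
        assert f.activity == FEED
        assert f.cell == 1  # the sheltered cell: lower swim cost, same food

    def test_dominance_order_preempts_shelter(self, species):
        reach = make_pair_reach(shelter=(0.0, 0.002), velocity=40.0)
        big = make_fish(7.0, species["trout"], fid=1)
        small = make_fish(5.0, species["trout"], fid=2)
        big.cell = small.cell = 0
        depths, vels = reach.depths_at(1.0), reach.velocities_at(1.0)
        res = StepResources.for_step(reach, depths, vels)
        select_habitat([small, big], reach, species, temperature=10.0,
                       depths=depths, velocities=vels, is_night=False,
                       resources=res)
        # only ~52 cm^2 of shelter exists; the big fish claims it first
        assert big.cell == 1
        assert res.shelter_area[1] < small.fishLength ** 2

    def test_adult_choice_trades_risk_only(self, species):
        reach = make_pair_reach(shelter=(0.0, 0.0), velocity=40.0)
        adult = make_fish(77.0, species["trout"], adult=True)
        adult.cell = 0
        depths, vels = reach.depths_at(1.0), reach.velocities_at(1.0)
        res = StepResources.for_step(reach, depths, vels)
        select_habitat([adult], reach, species, temperature=10.0,
                       depths=depths, velocities=vels, is_night=False,
                       resources=res)
        assert adult.intake_rate == 0.0
        assert adult.growth_rate < 0.0  # respiration only


class TestNewYear:
    def test_superindividual_split_conserves_count(self, species):
        fish = make_fish(3.0, species["trout"], nrep=10)
        pop, next_id = new_year_update([fish], next_id=1)
        assert len(pop) == 10
        assert all(f.nRep == 1 for f in pop)
        assert all(f.age == 1 for f in pop)
        assert all(f.fishLength == fish.fishLength for f in pop)

    def test_regular_individual_unchanged(self, species):
        fish = make_fish(10.0, species["trout"], age=1)
        pop, next_id = new_year_update([fish], next_id=1)
        assert len(pop) == 1 and pop[0] is fish and fish.age == 2

    def test_total_represented_count_invariant(self, species):
        pop = [make_fish(3.0, species["trout"], nrep=10, fid=i)
               for i in range(3)]
        before = sum(f.nRep for f in pop)
        after_pop, _ = new_year_update(pop, next_id=3)
        assert sum(f.nRep for f in after_pop) == before == 30
        assert len(after_pop) == 30
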