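"""Fish state, bioenergetics, survival submodels and habitat selection.

Individuals (or superindividuals representing ``nRep`` identical young of
the year) feed by drift interception or active search, grow by an energy
budget (intake energy minus respiration, converted at the fish energy
density), and face daily survival probabilities from high temperature,
high velocity, stranding, aquatic predation, terrestrial predation and
poor condition.  Juveniles additionally out-migrate stochastically, with a
daily *staying* probability that decreases with length; out-migrants are
removed from the simulation but never counted as deaths.

Habitat and activity selection maximises expected maturity over a fitness
horizon ``H`` (default 90 days):

    expectedMaturity = S_risks**H * S_starvation(H) * ln(1 + EL / BL)

where ``S_risks`` is the product of the (non-starvation) daily survival
probabilities in the candidate cell, ``S_starvation`` the poor-condition
survival at the condition factor projected to the end of the horizon,
``EL`` the projected length and ``BL`` the length of the biggest living
fish (floored at 1.5x the minimum spawning length).  Fish choose in
descending length order (a single cross-species dominance hierarchy) and
debit cell resources -- drift and search food, velocity shelter area,
hiding cover area -- as they choose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .core_math import AnchoredLogistic, ParameterError, ReachParams, SpeciesParams
from .habitat import Reach

__all__ = [
    "Fish",
    "StepResources",
    "healthy_weight",
    "condition",
    "length_from_weight",
    "max_move_distance",
    "candidate_cells",
    "detect_distance",
    "max_swim_speed",
    "cmax",
    "food_intake",
    "respiration_rate",
    "apply_growth",
    "survival_probabilities",
    "SURVIVAL_SOURCES",
    "apply_survival_and_outmigration",
    "select_habitat",
    "new_year_update",
    "biggest_length",
]

SURVIVAL_SOURCES = ("highTemperature", "highVelocity", "stranding",
                    "aquaticPredation", "terrestrialPredation", "poorCondition")

FEED, HIDE = "feed", "hide"


_CURVE_CACHE: dict = {}


def _curves(sp: SpeciesParams):
    """Per-species cache of the anchored logistics and suitability curves.

    Keyed by object identity (parameter sets are immutable and long-lived);
    hashing the full registry on every lookup would dominate the run time.
    """
    cached = _CURVE_CACHE.get(id(sp))
    if cached is not None and cached[0] is sp:
        return cached[1]
    curves = _build_curves(sp)
    _CURVE_CACHE[id(sp)] = (sp, curves)
    return curves


def _build_curves(sp: SpeciesParams):
    return {
        "hiT": AnchoredLogistic(sp.mortFishHiTT1, sp.mortFishHiTT9),
        "vel": AnchoredLogistic(sp.mortFishVelocityV1, sp.mortFishVelocityV9),
        "strand": AnchoredLogistic(sp.mortFishStrandD1, sp.mortFishStrandD9),
        "aqD": AnchoredLogistic(sp.mortFishAqPredD1, sp.mortFishAqPredD9),
        "aqL": AnchoredLogistic(sp.mortFishAqPredL1, sp.mortFishAqPredL9),
        "aqT": AnchoredLogistic(sp.mortFishAqPredT1, sp.mortFishAqPredT9),
        "terrD": AnchoredLogistic(sp.mortFishTerrPredD1, sp.mortFishTerrPredD9),
        "terrV": AnchoredLogistic(sp.mortFishTerrPredV1, sp.mortFishTerrPredV9),
        "terrL": AnchoredLogistic(sp.mortFishTerrPredL1, sp.mortFishTerrPredL9),
        "terrH": AnchoredLogistic(sp.mortFishTerrPredH1, sp.mortFishTerrPredH9),
        "cond": AnchoredLogistic(sp.mortFishConditionK1, sp.mortFishConditionK9),
        "capture": AnchoredLogistic(sp.fishCaptureParam1, sp.fishCaptureParam9),
        "stay": sp.staying_logistic(),
        "cmaxT": sp.cmax_temperature_curve(),
    }


def staying_probability(length: float, sp: SpeciesParams) -> float:
    """Daily probability that a juvenile stays (does not out-migrate)."""
    return float(_curves(sp)["stay"](length))


@dataclass
class Fish:
    """One simulated fish (or superindividual when ``nRep > 1``)."""

    id: int
    species: str
    sex: str                      # 'F' or 'M'
    age: int                      # years
    fishLength: float             # cm
    fishWeight: float             # g
    nRep: int = 1
    isSalmonSpawner: bool = False  # adult (arriving spawner) flag, both species
    hasSpawned: bool = False
    cell: int = 0                 # index into reach arrays
    activity: str = HIDE
    alive: bool = True
    rng: np.random.Generator = None  # per-fish stream, seeded by the engine

    # per-step feeding state, set by habitat selection
    intake_rate: float = 0.0      # g/h
    growth_rate: float = 0.0      # g/h (can be negative)

    def __post_init__(self):
        if self.fishLength <= 0 or self.fishWeight <= 0:
            raise ParameterError("fish length and weight must be positive")
        if self.nRep < 1:
            raise ParameterError("nRep must be >= 1")


@dataclass
class StepResources:
    """Per-cell depletable resources for one model time step (rates in g/h)."""

    drift_rate: np.ndarray     # drift food transport rate through each cell
    search_rate: np.ndarray    # benthic/surface production rate in each cell
    shelter_area: np.ndarray   # cm^2 of velocity shelter remaining
    hide_area: np.ndarray      # cm^2 of hiding cover remaining

    @classmethod
    def for_step(cls, reach: Reach, depths: np.ndarray, velocities: np.ndarray
                 ) -> "StepResources":
        rp = reach.params
        side_cm = np.sqrt(reach.area_cm2 / (1.5 * math.sqrt(3.0)))
        width_cm = reach.area_cm2 / (math.sqrt(3.0) * side_cm)
        drift = rp.habDriftConc * velocities * depths * width_cm * 3600.0
        search = rp.habSearchProd * reach.area_cm2
        return cls(
            drift_rate=np.maximum(drift, 0.0),
            search_rate=np.full(len(reach), search, dtype=float),
            shelter_area=reach.frac_shelter * reach.area_cm2,
            hide_area=reach.frac_hide * reach.area_cm2,
        )


# ---------------------------------------------------------------------------
# allometry and bioenergetics
# ---------------------------------------------------------------------------

def healthy_weight(length, sp: SpeciesParams):
    """Weight (g) of a fish in perfect condition at the given length (cm)."""
    if isinstance(length, (int, float)):
        if length <= 0:
            raise ParameterError("length must be positive")
        return sp.fishWeightParamA * length ** sp.fishWeightParamB
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ParameterError("length must be positive")
    return sp.fishWeightParamA * length ** sp.fishWeightParamB


def condition(fish: Fish, sp: SpeciesParams) -> float:
    """Condition factor K = observed weight / healthy weight."""
    return fish.fishWeight / float(healthy_weight(fish.fishLength, sp))


def length_from_weight(weight, sp: SpeciesParams):
    """Length (cm) at which the given weight corresponds to K = 1."""
    return (np.asarray(weight, dtype=float) / sp.fishWeightParamA) \
        ** (1.0 / sp.fishWeightParamB)


def max_move_distance(length: float, sp: SpeciesParams) -> float:
    """Maximum habitat-selection radius (cm)."""
    if length <= 0:
        raise ParameterError("length must be positive")
    return sp.fishMoveDistParamA * length ** sp.fishMoveDistParamB


def candidate_cells(fish: Fish, reach: Reach, sp: SpeciesParams) -> np.ndarray:
    """Candidate destination cells: within radius, plus adjacency, plus home."""
    radius_m = max_move_distance(fish.fishLength, sp) / 100.0
    within = reach.cells_within(tuple(reach.centroids[fish.cell]), radius_m)
    parts = [within, reach.neighbors_idx[fish.cell], np.asarray([fish.cell])]
    return np.unique(np.concatenate(parts))


def detect_distance(length: float, sp: SpeciesParams, is_night: bool) -> float:
    """Prey detection distance (cm) for drift feeding."""
    dd = sp.fishDetectDistanceParamA + sp.fishDetectDistanceParamB * length
    return dd * (sp.fishReactDistNightFactor if is_night else 1.0)


def max_swim_speed(length, temperature, sp: SpeciesParams):
    """Maximum sustainable swim speed (cm/s) at a length and temperature."""
    length = np.asarray(length, dtype=float)
    t = float(temperature)
    return (sp.fishMaxSwimParamA * length + sp.fishMaxSwimParamB) * (
        sp.fishMaxSwimParamC * t * t + sp.fishMaxSwimParamD * t
        + sp.fishMaxSwimParamE)


def cmax(weight: float, temperature: float, step_hours: float,
         sp: SpeciesParams) -> float:
    """Maximum consumption (g) over a time step."""
    if weight <= 0:
        raise ParameterError("weight must be positive")
    f_t = float(_curves(sp)["cmaxT"](temperature))
    daily = sp.fishCmaxParamA * weight ** (1.0 + sp.fishCmaxParamB) * f_t
    return daily * step_hours / 24.0


def _drift_rate(sp: SpeciesParams, rp: ReachParams, length: float,
                depths: np.ndarray, velocities: np.ndarray,
                temperature: float, is_night: bool) -> np.ndarray:
    """Drift-interception intake rate (g/h) per candidate cell."""
    dd = detect_distance(length, sp, is_night)
    capture_area = 2.0 * dd * np.minimum(dd, depths)       # cm^2
    vmax = float(max_swim_speed(length, temperature, sp))
    if vmax <= 0:
        return np.zeros_like(depths)
    ratio = velocities / vmax
    success = _curves(sp)["capture"](ratio)
    return rp.habDriftConc * velocities * capture_area * success * 3600.0


def _search_rate(sp: SpeciesParams, rp: ReachParams, is_night: bool) -> float:
    """Active-search intake rate (g/h), identical in every cell."""
    factor = sp.fishSearchNightFactor if is_night else 1.0
    return rp.habSearchProd * sp.fishSearchArea * factor


def food_intake(fish: Fish, reach: Reach, sp: SpeciesParams, *,
                depths: np.ndarray, velocities: np.ndarray,
                temperature: float, is_night: bool, activity: str,
                step_hours: float, cells: np.ndarray | None = None,
                resources: StepResources | None = None) -> np.ndarray:
    """Realised food intake (g) per candidate cell over a step.

    Adults and hiding fish take zero food everywhere.  Feeding juveniles
    use the better of drift interception and active search, capped by the
    remaining maximum consumption and by the remaining cell food supply.
    """
    if cells is None:
        cells = np.arange(len(reach))
    if fish.isSalmonSpawner or activity == HIDE:
        return np.zeros(len(cells))
    drift = _drift_rate(sp, reach.params, fish.fishLength,
                        depths[cells], velocities[cells], temperature, is_night)
    search = np.full(len(cells), _search_rate(sp, reach.params, is_night))
    if resources is not None:
        drift = np.minimum(drift, resources.drift_rate[cells] / fish.nRep)
        search = np.minimum(search, resources.search_rate[cells] / fish.nRep)
    cmax_rate = cmax(fish.fishWeight, temperature, 1.0, sp)
    rate = np.minimum(np.maximum(drift, search), cmax_rate)
    return rate * step_hours


def respiration_rate(sp: SpeciesParams, weight, temperature, swim_speed):
    """Respiration cost (J/d) at a weight, temperature and swim speed (cm/s)."""
    weight = np.asarray(weight, dtype=float)
    return sp.fishRespParamA * weight ** sp.fishRespParamB \
        * np.exp(sp.fishRespParamC * float(temperature)) \
        * np.exp(sp.fishRespParamD * np.asarray(swim_speed, dtype=float))


def apply_growth(fish: Fish, sp: SpeciesParams, step_hours: float) -> None:
    """Apply the stored growth rate over an elapsed step.

    Weight may fall; length only increases, and only when condition would
    exceed 1 (length is set so that K returns to 1).
    """
    fish.fishWeight = max(fish.fishWeight + fish.growth_rate * step_hours, 1e-6)
    wh = float(healthy_weight(fish.fishLength, sp))
    if fish.fishWeight > wh:
        fish.fishLength = float(length_from_weight(fish.fishWeight, sp))


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _survival_arrays(sp: SpeciesParams, rp: ReachParams, *, length: float,
                     k: float, temperature: float, depths, velocities,
                     dist_to_hide, activity: str, velocity_shelter,
                     cover_available, is_night: bool) -> Dict[str, np.ndarray]:
    """Daily survival per source, vectorised over cells.

    ``velocity_shelter`` and ``cover_available`` are booleans (scalar or
    per-cell): whether the fish benefits from a velocity shelter and, when
    hiding, whether it secured hiding cover.
    """
    depths = np.asarray(depths, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    ones = np.ones_like(depths)

    c = _curves(sp)
    s_hit = float(c["hiT"](temperature))

    vmax = float(max_swim_speed(length, temperature, sp))
    ratio = velocities / vmax if vmax > 0 else np.full_like(velocities, np.inf)
    s_vel = c["vel"](ratio)
    s_vel = np.where(velocity_shelter,
                     s_vel + (1.0 - s_vel) * sp.mortFishVelocityCoverFactor,
                     s_vel)

    s_strand = c["strand"](depths / length)

    hiding = activity == HIDE
    p_min_aq = rp.habMortFishAqPredNightMin if is_night \
        else rp.habMortFishAqPredDayMin
    f_depth = c["aqD"](depths)
    f_len = float(c["aqL"](length))
    f_temp = float(c["aqT"](temperature))
    f_cover = np.where(np.logical_and(hiding, cover_available),
                       sp.mortFishAqPredCoverFactor, 0.0)
    f_aq = np.maximum.reduce([f_depth, f_len * ones, f_temp * ones, f_cover * ones])
    s_aq = p_min_aq + (1.0 - p_min_aq) * f_aq

    p_min_terr = sp.mortFishTerrPredNightMin if is_night \
        else sp.mortFishTerrPredDayMin
    t_depth = c["terrD"](depths)
    t_vel = c["terrV"](velocities)
    t_len = float(c["terrL"](length))
    t_hide = c["terrH"](np.asarray(dist_to_hide, dtype=float))
    t_cover = np.where(np.logical_and(hiding, cover_available),
                       sp.mortFishTerrPredCoverFactor, 0.0)
    f_terr = np.maximum.reduce([t_depth, t_vel, t_len * ones,
                                t_hide * ones, t_cover * ones])
    s_terr = p_min_terr + (1.0 - p_min_terr) * f_terr

    s_cond = float(c["cond"](k))

    return {
        "highTemperature": s_hit * ones,
        "highVelocity": s_vel,
        "stranding": s_strand,
        "aquaticPredation": s_aq,
        "terrestrialPredation": s_terr,
        "poorCondition": s_cond * ones,
    }


def survival_probabilities(fish: Fish, reach: Reach, sp: SpeciesParams, *,
                           temperature: float, depth: float, velocity: float,
                           is_night: bool, velocity_shelter: bool = False,
                           cover_available: bool = False) -> Dict[str, float]:
    """Daily survival by source for a fish in its current cell and activity."""
    c = _curves(sp)
    rp = reach.params
    length = fish.fishLength
    hiding = fish.activity == HIDE

    s_vel_raw = 1.0
    vmax = float(max_swim_speed(length, temperature, sp))
    s_vel_raw = c["vel"](velocity / vmax) if vmax > 0 else 0.0
    if velocity_shelter:
        s_vel_raw += (1.0 - s_vel_raw) * sp.mortFishVelocityCoverFactor

    p_min_aq = rp.habMortFishAqPredNightMin if is_night \
        else rp.habMortFishAqPredDayMin
    f_aq = max(c["aqD"](depth), c["aqL"](length), c["aqT"](temperature),
               sp.mortFishAqPredCoverFactor if (hiding and cover_available)
               else 0.0)

    p_min_terr = sp.mortFishTerrPredNightMin if is_night \
        else sp.mortFishTerrPredDayMin
    f_terr = max(c["terrD"](depth), c["terrV"](velocity), c["terrL"](length),
                 c["terrH"](float(reach.dist_to_hide[fish.cell])),
                 sp.mortFishTerrPredCoverFactor if (hiding and cover_available)
                 else 0.0)

    return {
        "highTemperature": c["hiT"](temperature),
        "highVelocity": s_vel_raw,
        "stranding": c["strand"](depth / length),
        "aquaticPredation": p_min_aq + (1.0 - p_min_aq) * f_aq,
        "terrestrialPredation": p_min_terr + (1.0 - p_min_terr) * f_terr,
        "poorCondition": c["cond"](condition(fish, sp)),
    }


def apply_survival_and_outmigration(fish: Fish, survivals: Dict[str, float],
                                    step_hours: float,
                                    staying: float | None = None,
                                    rng: np.random.Generator | None = None):
    """Draw survival per source, then (for juveniles) the outmigration event.

    ``staying`` is the juvenile's daily probability of remaining in the
    reach (the decreasing length logistic); pass ``None`` for adults.
    Returns ``("alive", None)``, ``("death", source)`` or
    ``("outmigrated", length)``.  Sources are drawn independently against
    their step-scaled survivals; an out-migrant must first have survived
    the step.  Adults never out-migrate.
    """
    rng = rng if rng is not None else fish.rng
    exponent = step_hours / 24.0
    draws = rng.random(len(SURVIVAL_SOURCES) + 1)
    for i, src in enumerate(SURVIVAL_SOURCES):
        if draws[i] > survivals[src] ** exponent:
            fish.alive = False
            return ("death", src)
    if staying is not None and not fish.isSalmonSpawner:
        if draws[-1] > staying ** exponent:
            fish.alive = False
            return ("outmigrated", fish.fishLength)
    return ("alive", None)


# ---------------------------------------------------------------------------
# habitat selection
# ---------------------------------------------------------------------------

def biggest_length(population: Iterable[Fish], sp_by_species: Dict[str, SpeciesParams]
                   ) -> float:
    """Largest living fish length, floored at 1.5x minimum spawning length."""
    floor = max(1.5 * sp.fishSpawnMinLength for sp in sp_by_species.values())
    lengths = [f.fishLength for f in population if f.alive]
    return max([floor] + lengths)


def select_habitat(population: Sequence[Fish], reach: Reach,
                   sp_by_species: Dict[str, SpeciesParams], *,
                   temperature: float, depths: np.ndarray,
                   velocities: np.ndarray, is_night: bool,
                   resources: StepResources,
                   biggest: float | None = None) -> None:
    """Assign every fish a (cell, activity) maximising expected maturity.

    Processes fish in descending length order and debits step resources as
    each fish commits, so dominant fish pre-empt food, shelter and cover.
    Sets each fish's ``cell``, ``activity``, ``intake_rate`` and
    ``growth_rate`` (g/h) for the coming step.
    """
    alive = [f for f in population if f.alive]
    if biggest is None:
        biggest = biggest_length(alive, sp_by_species)
    order = sorted(alive, key=lambda f: -f.fishLength)

    for fish in order:
        sp = sp_by_species[fish.species]
        rp = reach.params
        cells = candidate_cells(fish, reach, sp)
        d = depths[cells]
        v = velocities[cells]
        dist_hide = reach.dist_to_hide[cells]
        need = fish.fishLength ** 2 * fish.nRep  # cm^2 of shelter/cover

        # feeding: shelter cuts swim speed where enough shelter area remains
        sheltered = resources.shelter_area[cells] >= need
        cover_ok = resources.hide_area[cells] >= need
        v_swim_feed = np.where(sheltered, v * rp.habShelterSpeedFrac, v)

        if fish.isSalmonSpawner:
            drift = search = np.zeros(len(cells))
        else:
            drift = np.minimum(
                _drift_rate(sp, rp, fish.fishLength, d, v, temperature, is_night),
                resources.drift_rate[cells] / fish.nRep)
            search = np.minimum(
                np.full(len(cells), _search_rate(sp, rp, is_night)),
                resources.search_rate[cells] / fish.nRep)
        cmax_rate = cmax(fish.fishWeight, temperature, 1.0, sp)
        use_drift = drift >= search
        intake_feed = np.minimum(np.where(use_drift, drift, search), cmax_rate)

        resp_feed = respiration_rate(sp, fish.fishWeight, temperature, v_swim_feed)
        resp_hide = float(respiration_rate(sp, fish.fishWeight, temperature, 0.0))

        k_now = condition(fish, sp)
        em = np.empty((2, len(cells)))
        growth = np.empty((2, len(cells)))
        for ai, (act, intake_rate, resp) in enumerate((
                (FEED, intake_feed, resp_feed),
                (HIDE, np.zeros(len(cells)), resp_hide))):
            net_j_day = intake_rate * 24.0 * rp.habPreyEnergyDensity - resp
            dw_day = net_j_day / sp.fishEnergyDensity
            growth[ai] = dw_day / 24.0
            surv = _survival_arrays(
                sp, rp, length=fish.fishLength, k=k_now,
                temperature=temperature, depths=d, velocities=v,
                dist_to_hide=dist_hide, activity=act,
                velocity_shelter=(sheltered if act == FEED
                                  else reach.frac_shelter[cells] > 0),
                cover_available=cover_ok, is_night=is_night)
            s_risks = (surv["highTemperature"] * surv["highVelocity"]
                       * surv["stranding"] * surv["aquaticPredation"]
                       * surv["terrestrialPredation"])
            h = sp.fishFitnessHorizon
            w_h = np.maximum(fish.fishWeight + h * dw_day, 1e-3)
            wh_now = float(healthy_weight(fish.fishLength, sp))
            exp_len = np.maximum(fish.fishLength,
                                 length_from_weight(w_h, sp))
            k_h = np.minimum(w_h / wh_now, 1.0)
            s_starv = _curves(sp)["cond"](k_h) ** h
            em[ai] = s_risks ** h * s_starv * np.log1p(exp_len / biggest)

        ai, ci = np.unravel_index(np.argmax(em), em.shape)
        fish.cell = int(cells[ci])
        fish.activity = FEED if ai == 0 else HIDE
        fish.intake_rate = float(intake_feed[ci]) if ai == 0 else 0.0
        fish.growth_rate = float(growth[ai, ci])

        # debit resources at the chosen cell
        if fish.activity == FEED:
            if fish.intake_rate > 0:
                pool = "drift_rate" if use_drift[ci] else "search_rate"
                arr = getattr(resources, pool)
                arr[fish.cell] = max(
                    arr[fish.cell] - fish.intake_rate * fish.nRep, 0.0)
            if sheltered[ci]:
                resources.shelter_area[fish.cell] = max(
                    resources.shelter_area[fish.cell] - need, 0.0)
        else:
            if cover_ok[ci]:
                resources.hide_area[fish.cell] = max(
                    resources.hide_area[fish.cell] - need, 0.0)


def new_year_update(population: List[Fish], next_id: int,
                    make_rng=None) -> tuple[List[Fish], int]:
    """January 1 update: increment ages and split superindividuals.

    Every fish with ``nRep = r > 1`` becomes ``r`` identical individuals
    with ``nRep = 1``; the represented-fish count is conserved exactly.
    Returns the new population list and the next unused fish id.
    """
    out: List[Fish] = []
    for f in population:
        f.age += 1
        if f.alive and f.nRep > 1:
            r = f.nRep
            f.nRep = 1
            out.append(f)
            for _ in range(r - 1):
                clone = Fish(
                    id=next_id, species=f.species, sex=f.sex, age=f.age,
                    fishLength=f.fishLength, fishWeight=f.fishWeight,
                    nRep=1, isSalmonSpawner=f.isSalmonSpawner,
                    hasSpawned=f.hasSpawned, cell=f.cell,
                    activity=f.activity, alive=True,
                    rng=make_rng(next_id) if make_rng else f.rng)
                next_id += 1
                out.append(clone)
        else:
            out.append(f)
    return out, next_id
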