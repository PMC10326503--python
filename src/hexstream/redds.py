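"""Adult arrival, spawning, and redd incubation dynamics.

Adult spawners (age 4, lengths from the arrival schedule's normal
distribution) enter at the downstream end of the reach in autumn.  A
female spawns on a day when the calendar window, the first-daylight-hour
temperature window, flow conditions and her own state (age, length,
condition, not yet spawned) allow it and a Bernoulli draw with
``fishSpawnProb`` succeeds.  She then picks the reachable cell maximising

    spawnQuality = depthSuit * velocitySuit * gravelArea * U,

with ``U = 1 + Rand(0,1) * fishSpawnCellUncert`` redrawn per cell, digs a
redd holding ``round(viability * fecundity(L))`` eggs, and loses
``fishSpawnWtLossFraction`` of her weight (spent spawners then starve:
adults never feed).

Redds lose eggs daily to dewatering, scour (critical Shields stress
exceedance at the daily peak flow), low and high temperature (anchored
logistics of the daily mean), and to superimposition when a later redd is
dug in the same cell.  Development accumulates daily as a quadratic
function of temperature; once complete, fry emerge over up to ten days
(10% of remaining eggs on day one, 20% on day two, ...) as
superindividuals of ``juveSuperindividualRatio`` eggs each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core_math import AnchoredLogistic, ParameterError, ReachParams, SpeciesParams
from .fish import FEED, HIDE, Fish, candidate_cells, healthy_weight
from .habitat import Reach

__all__ = [
    "ArrivalEvent",
    "Redd",
    "CRITICAL_SHIELDS",
    "stochastic_round",
    "instantiate_arrivals",
    "default_arrival_schedule",
    "ready_to_spawn",
    "spawn_quality",
    "select_spawning_cell",
    "create_redd",
    "superimpose_existing",
    "redd_daily_survival",
    "develop",
    "emerge",
]

#: critical dimensionless (Shields) shear stress for redd scour
CRITICAL_SHIELDS = 0.045

REDD_LOSS_SOURCES = ("dewatering", "scour", "lowTemperature",
                     "highTemperature", "superimposition")


@dataclass
class ArrivalEvent:
    """One day's scheduled arrival of adult spawners."""

    date: pd.Timestamp
    species: str
    count: int
    meanLength: float      # cm
    sdLength: float        # cm
    age: int = 4

    def __post_init__(self):
        if self.count < 0:
            raise ParameterError("arrival count must be non-negative")
        self.date = pd.Timestamp(self.date).normalize()


@dataclass
class Redd:
    """An egg cohort buried in one cell."""

    id: int
    species: str
    cell: int
    viableEggs: int
    createdOn: pd.Timestamp
    fracDeveloped: float = 0.0
    emergenceDay: int = 0            # 0 before emergence starts, then 1..10
    eggs_initial: int = 0
    eggs_emerged: int = 0
    eggs_lost: Dict[str, int] = field(default_factory=lambda: {
        src: 0 for src in REDD_LOSS_SOURCES})

    def __post_init__(self):
        if self.eggs_initial == 0:
            self.eggs_initial = self.viableEggs

    @property
    def empty(self) -> bool:
        return self.viableEggs <= 0

    def _lose(self, n: int, source: str) -> None:
        n = min(n, self.viableEggs)
        self.viableEggs -= n
        self.eggs_lost[source] += n


def stochastic_round(x: float, rng: np.random.Generator) -> int:
    """Unbiased integer rounding: floor plus a Bernoulli on the remainder."""
    lo = math.floor(x)
    return lo + (rng.random() < (x - lo))


# ---------------------------------------------------------------------------
# arrivals
# ---------------------------------------------------------------------------

def instantiate_arrivals(event: ArrivalEvent, reach: Reach, sp: SpeciesParams,
                         rng: np.random.Generator, id_start: int,
                         make_rng=None) -> List[Fish]:
    """Create the adults for one arrival event, placed in downstream cells."""
    d_cells = np.flatnonzero(reach.reach_end == "D")
    if d_cells.size == 0:
        d_cells = np.arange(len(reach))
    out: List[Fish] = []
    for k in range(event.count):
        length = -1.0
        while length <= 0:
            length = float(rng.normal(event.meanLength, event.sdLength)) \
                if event.sdLength > 0 else event.meanLength
        fid = id_start + k
        out.append(Fish(
            id=fid, species=event.species,
            sex="F" if rng.random() < 0.5 else "M",
            age=event.age, fishLength=length,
            fishWeight=float(healthy_weight(length, sp)),
            nRep=1, isSalmonSpawner=True,
            cell=int(rng.choice(d_cells)), activity=HIDE,
            rng=make_rng(fid) if make_rng else None))
    return out


def default_arrival_schedule(sp_by_species: Dict[str, SpeciesParams],
                             years: Sequence[int], per_year: int = 20
                             ) -> List[ArrivalEvent]:
    """Null-scenario schedule: one adult per day for 20 days per species,
    centred on the spawning start date (ten days before through ten after).
    """
    events: List[ArrivalEvent] = []
    lengths = {"trout": (77.38, 3.60), "salmon": (76.79, 5.90)}
    for year in years:
        for species, sp in sp_by_species.items():
            month, day = sp.fishSpawnStartDate
            start = pd.Timestamp(year=year, month=month, day=day) \
                - pd.Timedelta(days=10)
            mean_l, sd_l = lengths.get(species, (77.0, 4.0))
            base, extra = divmod(per_year, 20)
            for d in range(20):
                count = base + (1 if d < extra else 0)
                if count:
                    events.append(ArrivalEvent(
                        date=start + pd.Timedelta(days=d), species=species,
                        count=count, meanLength=mean_l, sdLength=sd_l))
    return sorted(events, key=lambda e: e.date)


# ---------------------------------------------------------------------------
# spawning
# ---------------------------------------------------------------------------

def _in_window(date: pd.Timestamp, start: tuple, end: tuple) -> bool:
    md = (date.month, date.day)
    if start <= end:
        return start <= md <= end
    return md >= start or md <= end  # window wrapping the new year


def ready_to_spawn(fish: Fish, sp: SpeciesParams, *, date: pd.Timestamp,
                   temp_first_daylight: float, flow_today: float,
                   flow_yesterday: float, max_spawn_flow: float,
                   rng: np.random.Generator | None = None) -> bool:
    """All spawning criteria for one female on one day.

    Temperature is the hourly temperature at the first hour of daylight;
    the flow-change criterion compares today's and yesterday's flows.
    """
    if fish.sex != "F" or not fish.isSalmonSpawner or fish.hasSpawned:
        return False
    if fish.age < sp.fishSpawnMinAge or fish.fishLength < sp.fishSpawnMinLength:
        return False
    if fish.fishWeight / float(healthy_weight(fish.fishLength, sp)) \
            < sp.fishSpawnMinCond:
        return False
    if not _in_window(date, sp.fishSpawnStartDate, sp.fishSpawnEndDate):
        return False
    if not sp.fishSpawnMinTemp <= temp_first_daylight <= sp.fishSpawnMaxTemp:
        return False
    if flow_today > max_spawn_flow:
        return False
    if flow_yesterday > 0 and \
            abs(flow_today - flow_yesterday) / flow_yesterday \
            > sp.fishSpawnMaxFlowChange:
        return False
    rng = rng if rng is not None else fish.rng
    return rng.random() < sp.fishSpawnProb


def spawn_quality(depth: float, velocity: float, frac_spawn: float,
                  area_cm2: float, sp: SpeciesParams, u: float = 1.0) -> float:
    """Quality of one candidate spawning cell (cm^2-weighted suitability)."""
    dsuit = float(sp.spawn_depth_suitability()(depth))
    vsuit = float(sp.spawn_velocity_suitability()(velocity))
    return dsuit * vsuit * frac_spawn * area_cm2 * u


def select_spawning_cell(female: Fish, reach: Reach, sp: SpeciesParams, *,
                         depths: np.ndarray, velocities: np.ndarray,
                         rng: np.random.Generator | None = None
                         ) -> Optional[int]:
    """Pick the reachable cell with the highest spawn quality, or None.

    Quality is the product of depth and velocity suitability, gravel area
    and the per-cell uncertainty factor ``U``; a female finding no cell of
    positive quality does not spawn.
    """
    rng = rng if rng is not None else female.rng
    cells = candidate_cells(female, reach, sp)
    dsuit = sp.spawn_depth_suitability()(depths[cells])
    vsuit = sp.spawn_velocity_suitability()(velocities[cells])
    gravel = reach.frac_spawn[cells] * reach.area_cm2[cells]
    u = 1.0 + rng.random(len(cells)) * sp.fishSpawnCellUncert
    quality = dsuit * vsuit * gravel * u
    best = int(np.argmax(quality))
    if quality[best] <= 0.0:
        return None
    return int(cells[best])


def create_redd(female: Fish, cell: int, sp: SpeciesParams, redd_id: int,
                date: pd.Timestamp) -> Redd:
    """Create the redd, apply the female's spawning weight loss."""
    eggs = int(round(sp.fishSpawnEggViability * sp.fishFecundParamA
                     * female.fishLength ** sp.fishFecundParamB))
    female.fishWeight *= (1.0 - sp.fishSpawnWtLossFraction)
    female.hasSpawned = True
    female.cell = cell
    return Redd(id=redd_id, species=female.species, cell=cell,
                viableEggs=eggs, createdOn=date)


def superimpose_existing(new_redd: Redd, existing: Sequence[Redd],
                         reach: Reach, sp: SpeciesParams,
                         rng: np.random.Generator) -> None:
    """A newly dug redd damages older redds in the same cell.

    Each existing redd is hit with probability
    ``min(1, reddSize / gravel area of the cell)`` and loses a
    Uniform(0, 1) fraction of its eggs (stochastically rounded).
    """
    gravel_cm2 = reach.frac_spawn[new_redd.cell] * reach.area_cm2[new_redd.cell]
    if gravel_cm2 <= 0:
        return
    p_hit = min(1.0, sp.reddSize / gravel_cm2)
    for redd in existing:
        if redd.cell != new_redd.cell or redd.id == new_redd.id or redd.empty:
            continue
        if rng.random() < p_hit:
            lost = stochastic_round(redd.viableEggs * rng.random(), rng)
            redd._lose(lost, "superimposition")


# ---------------------------------------------------------------------------
# daily redd survival, development and emergence
# ---------------------------------------------------------------------------

def redd_daily_survival(redd: Redd, sp: SpeciesParams, rp: ReachParams, *,
                        depth: float, daily_mean_temp: float,
                        daily_peak_flow: float,
                        rng: np.random.Generator) -> None:
    """One day's egg losses: dewatering, scour, low then high temperature.

    Scour destroys the whole redd when the dimensionless shear stress
    ``habShearParamA * Qpeak**habShearParamB`` exceeds the critical Shields
    value; with the default shear parameters this cannot happen below
    30 m^3/s.  Temperature losses scale the egg count by the anchored
    logistic daily survivals, with stochastic rounding.
    """
    if redd.empty:
        return
    if depth <= 0.0:
        survivors = stochastic_round(
            redd.viableEggs * sp.mortReddDewaterSurv, rng)
        redd._lose(redd.viableEggs - survivors, "dewatering")
        if redd.empty:
            return
    shear = rp.habShearParamA * daily_peak_flow ** rp.habShearParamB
    if shear > CRITICAL_SHIELDS:
        redd._lose(redd.viableEggs, "scour")
        return
    s_low = float(AnchoredLogistic(sp.mortReddLoTT1, sp.mortReddLoTT9)(
        daily_mean_temp))
    survivors = stochastic_round(redd.viableEggs * s_low, rng)
    redd._lose(redd.viableEggs - survivors, "lowTemperature")
    if redd.empty:
        return
    s_high = float(AnchoredLogistic(sp.mortReddHiTT1, sp.mortReddHiTT9)(
        daily_mean_temp))
    survivors = stochastic_round(redd.viableEggs * s_high, rng)
    redd._lose(redd.viableEggs - survivors, "highTemperature")


def develop(redd: Redd, sp: SpeciesParams, daily_mean_temp: float) -> None:
    """Advance the redd's development fraction by one day."""
    t = daily_mean_temp
    redd.fracDeveloped += (sp.reddDevelParamA + sp.reddDevelParamB * t
                           + sp.reddDevelParamC * t * t)


def emerge(redd: Redd, sp: SpeciesParams, rng: np.random.Generator,
           id_start: int, date: pd.Timestamp, make_rng=None) -> List[Fish]:
    """Convert ready eggs to superindividual fry on emergence days 1-10.

    On emergence day ``k`` a fraction ``k/10`` of the remaining eggs
    emerges (day 10 empties the redd).  Emerging eggs become
    ``ceil(eggs / juveSuperindividualRatio)`` fish with ``nRep`` equal to
    the ratio, lengths drawn from the emergence length distribution.
    """
    if redd.fracDeveloped < 1.0 or redd.empty:
        return []
    redd.emergenceDay = min(redd.emergenceDay + 1, 10)
    frac = redd.emergenceDay / 10.0
    eggs = redd.viableEggs if redd.emergenceDay >= 10 \
        else stochastic_round(redd.viableEggs * frac, rng)
    if eggs <= 0:
        return []
    redd.viableEggs -= eggs
    redd.eggs_emerged += eggs

    ratio = sp.juveSuperindividualRatio
    n_fish = math.ceil(eggs / ratio)
    out: List[Fish] = []
    for k in range(n_fish):
        length = -1.0
        while length <= 0:
            length = float(rng.normal(sp.reddNewLengthMean,
                                      sp.reddNewLengthStdDev))
        fid = id_start + k
        out.append(Fish(
            id=fid, species=redd.species,
            sex="F" if rng.random() < 0.5 else "M",
            age=0, fishLength=length,
            fishWeight=float(healthy_weight(length, sp)),
            nRep=ratio, cell=redd.cell, activity=FEED,
            rng=make_rng(fid) if make_rng else None))
    return out
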