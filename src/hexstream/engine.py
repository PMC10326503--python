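"""Event scheduler, run orchestration and output summaries.

A simulation advances hour by hour through the environment series and
executes, in order within each hour:

1.  clock and day/night phase update;
2.  flow and temperature input;
3.  on 1 January at 00 h: age increment and superindividual splitting;
4.  at 00 h: update of the biggest-fish length and daily reporting;
5.  at 10 h on arrival days: adult spawners enter downstream;
6.  at the first daylight hour: spawning;
7.  at the first daylight hour: redd survival, development, emergence;
8.  a *model time step* closes whenever the day/night phase flips, the
    flow changes by more than a relative tolerance, or the temperature
    changes by more than an absolute tolerance since the step began;
9.  fish survival draws and growth over the elapsed step;
10. per-step reporting (out-migrants, mortalities);
11. habitat and activity selection for the next step.

Fish survival, feeding and behaviour use the conditions prevailing when
the step began (conditions are constant within a step by construction).
All randomness comes from streams derived from the run seed: one
population-level stream plus one stream per fish keyed by fish id, so
runs are reproducible and robust to processing order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core_math import (ParameterError, ReachParams, SpeciesParams,
                        salmon_params, trout_params)
from .environment import EnvironmentSeries
from .fish import (FEED, HIDE, Fish, StepResources, apply_growth,
                   apply_survival_and_outmigration, biggest_length,
                   healthy_weight, new_year_update, select_habitat,
                   survival_probabilities, staying_probability)
from .habitat import Reach
from .redds import (ArrivalEvent, Redd, create_redd, develop, emerge,
                    instantiate_arrivals, ready_to_spawn, redd_daily_survival,
                    select_spawning_cell, superimpose_existing)

__all__ = [
    "RunConfig",
    "RunResult",
    "run_simulation",
    "trigger_steps",
    "summarize_large_outmigrants",
    "load_initial_population",
    "initial_population_table",
    "hydrological_year",
]

LARGE_OUTMIGRANT_CM = 12.0


def default_species() -> Dict[str, SpeciesParams]:
    return {"trout": trout_params(), "salmon": salmon_params()}


@dataclass
class RunConfig:
    """Everything needed for one reproducible simulation run."""

    reach: Reach
    environment: EnvironmentSeries
    arrivals: Sequence[ArrivalEvent] = ()
    initial_population: Optional[pd.DataFrame] = None
    species: Dict[str, SpeciesParams] = field(default_factory=default_species)
    start: Optional[pd.Timestamp] = None
    end: Optional[pd.Timestamp] = None
    seed: int = 0
    flow_step_tol: float = 0.05     # relative flow change starting a new step
    temp_step_tol: float = 0.5      # degC change starting a new step
    snapshot_daily: bool = False

    def __post_init__(self):
        idx = self.environment.index
        self.start = pd.Timestamp(self.start) if self.start is not None else idx[0]
        self.end = pd.Timestamp(self.end) if self.end is not None else \
            idx[-1] + pd.Timedelta(hours=1)
        if self.end <= self.start:
            raise ParameterError("end must be after start")
        if self.start < idx[0] or self.end > idx[-1] + pd.Timedelta(hours=1):
            raise ParameterError("run window not covered by environment series")


@dataclass
class RunResult:
    """Logs and conservation counters from one run."""

    mortality: pd.DataFrame
    outmigrants: pd.DataFrame
    redds: pd.DataFrame
    spawns: pd.DataFrame
    daily_age0: pd.DataFrame
    snapshots: pd.DataFrame
    event_log: List[tuple]
    population: List[Fish]
    initial_n: int
    arrivals_n: int
    emerged_n: int
    deaths_n: int
    outmigrants_n: int

    @property
    def final_live_n(self) -> int:
        return sum(f.nRep for f in self.population if f.alive)

    def conservation_residual(self) -> int:
        """initial + arrivals + emerged - deaths - outmigrants - live (exact 0)."""
        return (self.initial_n + self.arrivals_n + self.emerged_n
                - self.deaths_n - self.outmigrants_n - self.final_live_n)

    def write(self, outdir) -> None:
        import os
        os.makedirs(outdir, exist_ok=True)
        self.mortality.to_csv(f"{outdir}/mortality.csv", index=False)
        self.outmigrants.to_csv(f"{outdir}/outmigrants.csv", index=False)
        self.redds.to_csv(f"{outdir}/redds.csv", index=False)
        self.spawns.to_csv(f"{outdir}/spawns.csv", index=False)
        self.daily_age0.to_csv(f"{outdir}/daily_age0.csv", index=False)
        if len(self.snapshots):
            self.snapshots.to_csv(f"{outdir}/live_population.csv", index=False)


def hydrological_year(ts: pd.Timestamp) -> int:
    """Label of the hydrological year (20 September--19 September) of ``ts``.

    The label is the calendar year in which the hydrological year begins.
    """
    ts = pd.Timestamp(ts)
    return ts.year if (ts.month, ts.day) >= (9, 20) else ts.year - 1


def trigger_steps(env: EnvironmentSeries, *, start: pd.Timestamp | None = None,
                  end: pd.Timestamp | None = None, flow_tol: float = 0.05,
                  temp_tol: float = 0.5) -> List[tuple]:
    """Model time steps as ``(start_timestamp, length_hours)`` tuples.

    A new step begins at any hour where the day/night phase flips, the
    relative flow change since the step started exceeds ``flow_tol``, or
    the temperature change exceeds ``temp_tol``.
    """
    idx = env.index
    i0 = int(idx.searchsorted(start)) if start is not None else 0
    i1 = int(idx.searchsorted(end)) if end is not None else len(idx)
    bounds = [i0]
    q0, t0, p0 = env.flow[i0], env.temperature[i0], env.phase_day[i0]
    for i in range(i0 + 1, i1):
        q, t, p = env.flow[i], env.temperature[i], env.phase_day[i]
        flow_changed = abs(q - q0) > flow_tol * max(q0, 1e-9)
        if p != p0 or flow_changed or abs(t - t0) > temp_tol:
            bounds.append(i)
            q0, t0, p0 = q, t, p
    bounds.append(i1)
    return [(idx[a], (b - a) * 1.0) for a, b in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------------
# initial population
# ---------------------------------------------------------------------------

def initial_population_table() -> pd.DataFrame:
    """Default initial population: the 2008 electrofishing age structure."""
    rows = [
        {"species": "trout", "age": 0, "number": 29,
         "mean_length_cm": 10.4, "sd_length_cm": 1.6},
        {"species": "trout", "age": 1, "number": 3,
         "mean_length_cm": 15.0, "sd_length_cm": 0.9},
        {"species": "salmon", "age": 0, "number": 74,
         "mean_length_cm": 7.9, "sd_length_cm": 1.0},
        {"species": "salmon", "age": 1, "number": 0,
         "mean_length_cm": 12.0, "sd_length_cm": 1.0},
    ]
    return pd.DataFrame(rows)


def load_initial_population(table: pd.DataFrame, reach: Reach,
                            species: Dict[str, SpeciesParams],
                            rng: np.random.Generator, id_start: int = 0,
                            make_rng=None) -> List[Fish]:
    """Instantiate the initial population (all ``nRep = 1``).

    Lengths are drawn per row from a truncated-positive normal; weights
    are the healthy weight at the drawn length; cells are drawn uniformly.
    """
    out: List[Fish] = []
    next_id = id_start
    for row in table.itertuples(index=False):
        if row.number < 0:
            raise ParameterError(f"negative count in initial population: {row}")
        sp = species[row.species]
        for _ in range(int(row.number)):
            length = -1.0
            while length <= 0:
                length = float(rng.normal(row.mean_length_cm, row.sd_length_cm)) \
                    if row.sd_length_cm > 0 else float(row.mean_length_cm)
            out.append(Fish(
                id=next_id, species=row.species,
                sex="F" if rng.random() < 0.5 else "M",
                age=int(row.age), fishLength=length,
                fishWeight=float(healthy_weight(length, sp)),
                nRep=1, cell=int(rng.integers(len(reach))), activity=FEED,
                rng=make_rng(next_id) if make_rng else None))
            next_id += 1
    return out


# ---------------------------------------------------------------------------
# the run loop
# ---------------------------------------------------------------------------

def run_simulation(config: RunConfig) -> RunResult:
    """Execute the schedule over the configured window; fully seeded."""
    env = config.environment
    reach = config.reach
    species = config.species
    idx = env.index
    i0 = int(idx.searchsorted(config.start))
    i1 = int(idx.searchsorted(config.end))

    master = np.random.default_rng([config.seed, 0])

    def make_rng(fish_id: int) -> np.random.Generator:
        return np.random.default_rng([config.seed, 1, fish_id])

    next_fish_id = 0
    population: List[Fish] = []
    pending: List[Fish] = []
    if config.initial_population is not None:
        population = load_initial_population(
            config.initial_population, reach, species, master,
            id_start=0, make_rng=make_rng)
        next_fish_id = len(population)
    initial_n = sum(f.nRep for f in population)

    arrivals_by_day: Dict[pd.Timestamp, List[ArrivalEvent]] = {}
    for ev in config.arrivals:
        arrivals_by_day.setdefault(ev.date, []).append(ev)

    active_redds: List[Redd] = []
    all_redds: List[Redd] = []
    next_redd_id = 0

    mortality_rows, outmig_rows, spawn_rows, age0_rows, snap_rows = \
        [], [], [], [], []
    event_log: List[tuple] = []
    counters = {"arrivals": 0, "emerged": 0, "deaths": 0, "outmigrants": 0}

    daily_mean_temp = env.daily_mean_temp
    daily_max_flow = env.daily_max_flow
    daily_mean_flow = pd.Series(env.flow, index=idx).groupby(
        idx.normalize()).mean()

    hydro_cache: Dict[float, tuple] = {}

    def hydraulics(flow: float):
        key = round(flow, 9)
        if key not in hydro_cache:
            if len(hydro_cache) > 512:
                hydro_cache.clear()
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                hydro_cache[key] = (reach.depths_at(flow),
                                    reach.velocities_at(flow))
        return hydro_cache[key]

    # step state
    step_start_i = i0
    step_flow = env.flow[i0]
    step_temp = env.temperature[i0]
    step_phase = env.phase_day[i0]
    step_depths, step_vels = hydraulics(step_flow)
    biggest = biggest_length(population, species)

    def spawn_window_last_day(ts: pd.Timestamp, sp: SpeciesParams) -> bool:
        return (ts.month, ts.day) == sp.fishSpawnEndDate

    def close_step(i: int) -> None:
        """Steps 9-10: survive and grow over [step_start_i, i), then report."""
        nonlocal population
        hours = float(i - step_start_i)
        if hours <= 0:
            return
        ts_start = idx[step_start_i]
        ts_end = idx[i - 1] + pd.Timedelta(hours=1)
        is_night = not step_phase
        outmig_by_species: Dict[str, List] = {}

        for f in population:
            if not f.alive:
                continue
            sp = species[f.species]
            # unspawned adults starve out on the window's last day
            if f.isSalmonSpawner and not f.hasSpawned and \
                    spawn_window_last_day(ts_start, sp):
                f.fishWeight *= (1.0 - sp.fishSpawnWtLossFraction)
            depth = float(step_depths[f.cell])
            vel = float(step_vels[f.cell])
            survivals = survival_probabilities(
                f, reach, sp, temperature=step_temp, depth=depth,
                velocity=vel, is_night=is_night,
                velocity_shelter=reach.frac_shelter[f.cell] > 0,
                cover_available=reach.frac_hide[f.cell] > 0)
            stay = None if f.isSalmonSpawner else \
                staying_probability(f.fishLength, sp)
            outcome, detail = apply_survival_and_outmigration(
                f, survivals, hours, staying=stay)
            if outcome == "death":
                counters["deaths"] += f.nRep
                mortality_rows.append({
                    "timestamp": ts_end, "source": detail,
                    "species": f.species, "age": f.age,
                    "length_cm": f.fishLength, "nRep": f.nRep})
            elif outcome == "outmigrated":
                counters["outmigrants"] += f.nRep
                outmig_by_species.setdefault(f.species, []).append(
                    (f.nRep, f.fishLength))
            else:
                apply_growth(f, sp, hours)
                if not math.isfinite(f.fishWeight) or \
                        not math.isfinite(f.fishLength):
                    raise RuntimeError(
                        f"non-finite fish state at {ts_end} (fish {f.id})")
        population = [f for f in population if f.alive]
        for spc, items in outmig_by_species.items():
            n = sum(r for r, _ in items)
            mean_l = sum(r * l for r, l in items) / n
            outmig_rows.append({"timestamp": ts_end, "species": spc,
                                "n": n, "mean_length_cm": mean_l})
        event_log.append((ts_end, "survive"))
        event_log.append((ts_end, "report"))

    for i in range(i0, i1):
        ts = idx[i]
        day = ts.normalize()
        hour = ts.hour
        flow = env.flow[i]
        temp = env.temperature[i]
        phase = env.phase_day[i]

        # 3) 1 January 00 h: age and superindividual splitting
        if hour == 0 and ts.month == 1 and ts.day == 1:
            population, next_fish_id = new_year_update(
                population, next_fish_id, make_rng=make_rng)

        # 4) 00 h: biggest length and daily reporting
        if hour == 0:
            biggest = biggest_length(population, species)
            for spc in species:
                fishes = [f for f in population
                          if f.alive and f.species == spc and f.age == 0]
                n = sum(f.nRep for f in fishes)
                mean_l = (sum(f.nRep * f.fishLength for f in fishes) / n
                          if n else np.nan)
                age0_rows.append({"date": day, "species": spc, "n": n,
                                  "mean_length_cm": mean_l})
            if config.snapshot_daily:
                for f in population:
                    if f.alive:
                        snap_rows.append({
                            "date": day, "id": f.id, "species": f.species,
                            "age": f.age, "length_cm": f.fishLength,
                            "weight_g": f.fishWeight, "nRep": f.nRep,
                            "cellID": int(reach.ids[f.cell]),
                            "activity": f.activity})

        # 5) 10 h: arrivals
        if hour == 10 and day in arrivals_by_day:
            for ev in arrivals_by_day[day]:
                sp = species[ev.species]
                new = instantiate_arrivals(ev, reach, sp, master,
                                           next_fish_id, make_rng=make_rng)
                next_fish_id += len(new)
                counters["arrivals"] += sum(f.nRep for f in new)
                pending.extend(new)
                event_log.append((ts, "arrival"))

        # 6-7) first daylight hour: spawning, then redd dynamics
        if env.first_daylight[i]:
            depths_now, vels_now = hydraulics(flow)
            q_today = float(daily_mean_flow.loc[day])
            yesterday = day - pd.Timedelta(days=1)
            q_yesterday = float(daily_mean_flow.get(yesterday, q_today))
            for f in population:
                if not (f.alive and f.sex == "F" and f.isSalmonSpawner
                        and not f.hasSpawned):
                    continue
                sp = species[f.species]
                if not ready_to_spawn(
                        f, sp, date=ts, temp_first_daylight=temp,
                        flow_today=q_today, flow_yesterday=q_yesterday,
                        max_spawn_flow=reach.params.habMaxSpawnFlow,
                        rng=f.rng):
                    continue
                cell = select_spawning_cell(
                    f, reach, sp, depths=depths_now, velocities=vels_now,
                    rng=f.rng)
                if cell is None:
                    continue
                redd = create_redd(f, cell, sp, next_redd_id, day)
                next_redd_id += 1
                superimpose_existing(redd, active_redds, reach, sp, master)
                active_redds.append(redd)
                all_redds.append(redd)
                spawn_rows.append({"date": day, "species": f.species,
                                   "fish_id": f.id,
                                   "cellID": int(reach.ids[cell]),
                                   "eggs": redd.viableEggs})
                event_log.append((ts, "spawn"))

            t_day = float(daily_mean_temp.loc[day])
            q_peak = float(daily_max_flow.loc[day])
            still_active: List[Redd] = []
            for redd in active_redds:
                sp = species[redd.species]
                redd_daily_survival(
                    redd, sp, reach.params,
                    depth=float(depths_now[redd.cell]),
                    daily_mean_temp=t_day, daily_peak_flow=q_peak,
                    rng=master)
                develop(redd, sp, t_day)
                fry = emerge(redd, sp, master, next_fish_id, day,
                             make_rng=make_rng)
                if fry:
                    next_fish_id += len(fry)
                    counters["emerged"] += sum(f.nRep for f in fry)
                    pending.extend(fry)
                if not redd.empty:
                    still_active.append(redd)
            active_redds = still_active
            if all_redds:
                event_log.append((ts, "redd"))

        # 8-11) step trigger, survive/grow, report, select
        flow_changed = abs(flow - step_flow) > \
            config.flow_step_tol * max(step_flow, 1e-9)
        if i == i0 or phase != step_phase or flow_changed or \
                abs(temp - step_temp) > config.temp_step_tol:
            close_step(i)
            if pending:
                population.extend(pending)
                pending = []
            step_start_i = i
            step_flow, step_temp, step_phase = flow, temp, phase
            step_depths, step_vels = hydraulics(step_flow)
            resources = StepResources.for_step(reach, step_depths, step_vels)
            select_habitat(
                population, reach, species, temperature=step_temp,
                depths=step_depths, velocities=step_vels,
                is_night=not step_phase, resources=resources,
                biggest=biggest)
            event_log.append((ts, "select"))

    close_step(i1)
    if pending:
        population.extend(pending)

    def frame(rows, cols):
        return pd.DataFrame(rows, columns=cols) if rows else \
            pd.DataFrame(columns=cols)

    redd_rows = [{
        "reddID": r.id, "species": r.species,
        "cellID": int(reach.ids[r.cell]), "created": r.createdOn,
        "eggs_initial": r.eggs_initial, "eggs_emerged": r.eggs_emerged,
        **{f"lost_{src}": n for src, n in r.eggs_lost.items()},
        "eggs_remaining": r.viableEggs,
    } for r in all_redds]

    return RunResult(
        mortality=frame(mortality_rows, ["timestamp", "source", "species",
                                         "age", "length_cm", "nRep"]),
        outmigrants=frame(outmig_rows, ["timestamp", "species", "n",
                                        "mean_length_cm"]),
        redds=pd.DataFrame(redd_rows) if redd_rows else pd.DataFrame(
            columns=["reddID", "species", "cellID", "created", "eggs_initial",
                     "eggs_emerged", "eggs_remaining"]),
        spawns=frame(spawn_rows, ["date", "species", "fish_id", "cellID",
                                  "eggs"]),
        daily_age0=frame(age0_rows, ["date", "species", "n", "mean_length_cm"]),
        snapshots=frame(snap_rows, ["date", "id", "species", "age",
                                    "length_cm", "weight_g", "nRep", "cellID",
                                    "activity"]),
        event_log=event_log,
        population=[f for f in population if f.alive],
        initial_n=initial_n,
        arrivals_n=counters["arrivals"],
        emerged_n=counters["emerged"],
        deaths_n=counters["deaths"],
        outmigrants_n=counters["outmigrants"],
    )


def summarize_large_outmigrants(outmigrants: pd.DataFrame,
                                threshold_cm: float = LARGE_OUTMIGRANT_CM
                                ) -> pd.Series:
    """Annual count of out-migrants whose per-step mean length met the bar.

    Years are hydrological years (20 September through 19 September),
    labelled by the calendar year in which they begin.
    """
    if outmigrants.empty:
        return pd.Series(dtype=int, name="large_outmigrants")
    df = outmigrants.copy()
    df["hydro_year"] = [hydrological_year(t) for t in df["timestamp"]]
    big = df[df["mean_length_cm"] >= threshold_cm]
    out = big.groupby("hydro_year")["n"].sum()
    all_years = sorted(df["hydro_year"].unique())
    return out.reindex(all_years, fill_value=0).rename("large_outmigrants")
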