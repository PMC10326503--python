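"""Shared mathematical primitives and parameter registries.

The survival and behaviour submodels of the simulator are almost all built
from two small function families:

* :class:`AnchoredLogistic` -- a logistic curve specified by the two input
  values at which it evaluates to 0.1 and 0.9 (the ``X1``/``X9`` convention
  used throughout stream-salmonid IBMs).  Increasing when ``x9 > x1``,
  decreasing otherwise.
* :class:`SuitabilityCurve` -- a piecewise-linear curve through explicit
  breakpoints, clamped outside its range, used for spawning habitat
  suitability and the temperature dependence of maximum consumption.

The module also houses the immutable parameter registries
(:class:`SpeciesParams`, :class:`ReachParams`) whose field names follow the
conventional camel-case parameter vocabulary of this model family, plus flat
``key = value`` parameter-file I/O.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "ParameterError",
    "AnchoredLogistic",
    "make_anchored_logistic",
    "SuitabilityCurve",
    "evaluate_suitability",
    "step_survival",
    "SpeciesParams",
    "ReachParams",
    "trout_params",
    "salmon_params",
    "default_reach_params",
    "load_species_params",
    "load_reach_params",
    "write_params",
]

_LOGIT_09 = math.log(9.0)  # logit(0.9) = -logit(0.1)


class ParameterError(ValueError):
    """Invalid parameter value or unknown parameter name."""


class AnchoredLogistic:
    """Logistic function through (x1, 0.1) and (x9, 0.9).

    Evaluates ``f(x) = 1 / (1 + exp(-(a + b*x)))`` with
    ``b = 2*ln(9) / (x9 - x1)`` and ``a`` chosen so that ``f(x1) = 0.1``.

    Parameters
    ----------
    x1, x9 : float
        Input values (native units) at which the function equals 0.1 and
        0.9 respectively.  Must differ.
    """

    __slots__ = ("x1", "x9", "a", "b")

    def __init__(self, x1: float, x9: float):
        if not np.isfinite(x1) or not np.isfinite(x9):
            raise ParameterError("logistic anchors must be finite")
        if x1 == x9:
            raise ParameterError("logistic anchors x1 and x9 must differ")
        self.x1 = float(x1)
        self.x9 = float(x9)
        self.b = 2.0 * _LOGIT_09 / (self.x9 - self.x1)
        self.a = _LOGIT_09 - self.b * self.x9  # f(x9) = 0.9

    def __call__(self, x):
        if isinstance(x, (int, float)):
            z = self.a + self.b * x
            z = -700.0 if z < -700.0 else (700.0 if z > 700.0 else z)
            return 1.0 / (1.0 + math.exp(-z))
        z = self.a + self.b * np.asarray(x, dtype=float)
        # guard exp overflow far outside the anchor range
        z = np.minimum(np.maximum(z, -700.0), 700.0)
        return 1.0 / (1.0 + np.exp(-z))

    def __repr__(self) -> str:  # pragma: no cover
        return f"AnchoredLogistic(x1={self.x1!r}, x9={self.x9!r})"


def make_anchored_logistic(x1: float, x9: float) -> AnchoredLogistic:
    """Build the two-anchor logistic evaluator (see :class:`AnchoredLogistic`)."""
    return AnchoredLogistic(x1, x9)


class SuitabilityCurve:
    """Piecewise-linear suitability curve clamped outside its breakpoints."""

    __slots__ = ("x", "y")

    def __init__(self, breakpoints: Sequence[Tuple[float, float]]):
        if len(breakpoints) == 0:
            raise ParameterError("suitability curve needs at least one breakpoint")
        x = np.asarray([p[0] for p in breakpoints], dtype=float)
        y = np.asarray([p[1] for p in breakpoints], dtype=float)
        if np.any(np.diff(x) <= 0):
            raise ParameterError("suitability inputs must be strictly increasing")
        if np.any((y < 0) | (y > 1)):
            raise ParameterError("suitability values must lie in [0, 1]")
        self.x = x
        self.y = y

    def __call__(self, x):
        return np.interp(np.asarray(x, dtype=float), self.x, self.y)


def evaluate_suitability(curve: SuitabilityCurve, x) -> float:
    """Evaluate a suitability curve (linear interpolation, clamped ends)."""
    return curve(x)


def step_survival(daily_s: float, step_hours: float):
    """Scale a daily survival probability to a time step of ``step_hours``.

    ``step_survival(s, h) = s ** (h / 24)`` so that survivals over steps
    partitioning a day multiply back to the daily value.
    """
    daily_s = np.asarray(daily_s, dtype=float)
    if np.any(daily_s < 0) or np.any(daily_s > 1):
        raise ParameterError("daily survival must lie in [0, 1]")
    if step_hours <= 0:
        raise ParameterError("step length must be positive hours")
    return daily_s ** (step_hours / 24.0)


# ---------------------------------------------------------------------------
# Parameter registries
# ---------------------------------------------------------------------------

MonthDay = Tuple[int, int]


@dataclass(frozen=True)
class SpeciesParams:
    """All fish- and redd-level parameters for one species.

    Field names use the conventional parameter vocabulary of the model
    family.  Units: lengths/depths/distances cm, weights g, temperatures
    degC, energies J, times days unless noted.
    """

    species: str

    # spawning criteria
    fishSpawnMinAge: float = 4.0            # years
    fishSpawnMinLength: float = 25.0        # cm
    fishSpawnMinCond: float = 0.5
    fishSpawnStartDate: MonthDay = (10, 5)
    fishSpawnEndDate: MonthDay = (11, 10)
    fishSpawnMinTemp: float = 5.0
    fishSpawnMaxTemp: float = 10.0
    fishSpawnMaxFlowChange: float = 1.0     # fractional day-to-day change
    fishSpawnProb: float = 0.5
    fishSpawnCellUncert: float = 0.15

    # spawning depth suitability breakpoints (cm -> index)
    fishSpawnDSuitD1: float = 0.0
    fishSpawnDSuitD2: float = 15.0
    fishSpawnDSuitD3: float = 40.0
    fishSpawnDSuitD4: float = 50.0
    fishSpawnDSuitD5: float = 120.0
    fishSpawnDSuitS1: float = 0.0
    fishSpawnDSuitS2: float = 0.01
    fishSpawnDSuitS3: float = 1.0
    fishSpawnDSuitS4: float = 1.0
    fishSpawnDSuitS5: float = 0.0

    # spawning velocity suitability breakpoints (cm/s -> index)
    fishSpawnVSuitV1: float = 0.0
    fishSpawnVSuitV2: float = 43.0
    fishSpawnVSuitV3: float = 60.0
    fishSpawnVSuitV4: float = 95.0
    fishSpawnVSuitV5: float = 125.0
    fishSpawnVSuitV6: float = 200.0
    fishSpawnVSuitS1: float = 0.0
    fishSpawnVSuitS2: float = 1.0
    fishSpawnVSuitS3: float = 1.0
    fishSpawnVSuitS4: float = 0.6
    fishSpawnVSuitS5: float = 0.1
    fishSpawnVSuitS6: float = 0.1

    # redd creation
    fishFecundParamA: float = 2.2675
    fishFecundParamB: float = 1.746
    fishSpawnEggViability: float = 0.9
    fishSpawnWtLossFraction: float = 0.4

    # movement and fitness horizon
    fishMoveDistParamA: float = 10.0
    fishMoveDistParamB: float = 2.4
    fishFitnessHorizon: float = 90.0        # days

    # length-weight
    fishWeightParamA: float = 0.008476
    fishWeightParamB: float = 3.073956

    # drift foraging
    fishDetectDistanceParamA: float = 4.0   # cm
    fishDetectDistanceParamB: float = 2.0
    fishReactDistNightFactor: float = 0.5
    fishCaptureParam1: float = 1.6          # velocity / max swim speed ratio anchors
    fishCaptureParam9: float = 0.5

    # search foraging
    fishSearchArea: float = 20000.0         # cm^2
    fishSearchNightFactor: float = 0.5

    # maximum consumption
    fishCmaxParamA: float = 0.628
    fishCmaxParamB: float = -0.3
    fishCmaxTempT1: float = 0.0
    fishCmaxTempT2: float = 2.0
    fishCmaxTempT3: float = 10.0
    fishCmaxTempT4: float = 22.0
    fishCmaxTempT5: float = 23.0
    fishCmaxTempT6: float = 25.0
    fishCmaxTempT7: float = 100.0
    fishCmaxTempF1: float = 0.05
    fishCmaxTempF2: float = 0.05
    fishCmaxTempF3: float = 0.5
    fishCmaxTempF4: float = 1.0
    fishCmaxTempF5: float = 0.8
    fishCmaxTempF6: float = 0.0
    fishCmaxTempF7: float = 0.0

    # respiration and energetics
    fishRespParamA: float = 30.0
    fishRespParamB: float = 0.784
    fishRespParamC: float = 0.0693          # 1/degC
    fishRespParamD: float = 0.03            # s/cm
    fishEnergyDensity: float = 5900.0       # J/g

    # maximum sustainable swim speed
    fishMaxSwimParamA: float = 2.8          # 1/s
    fishMaxSwimParamB: float = 21.0         # cm/s
    fishMaxSwimParamC: float = -0.0029      # 1/degC^2
    fishMaxSwimParamD: float = 0.084        # 1/degC
    fishMaxSwimParamE: float = 0.37

    fishPiscivoryLength: float = 100.0      # cm; unreachable, keeps piscivory inert

    # fish survival
    mortFishHiTT1: float = 30.0
    mortFishHiTT9: float = 25.8
    mortFishVelocityV1: float = 1.8
    mortFishVelocityV9: float = 1.4
    mortFishVelocityCoverFactor: float = 0.75
    mortFishStrandD1: float = -0.3
    mortFishStrandD9: float = 0.3
    mortFishAqPredD1: float = 27.0
    mortFishAqPredD9: float = 10.0
    mortFishAqPredL1: float = 12.0
    mortFishAqPredL9: float = 20.0
    mortFishAqPredT1: float = 8.0
    mortFishAqPredT9: float = 2.0
    mortFishAqPredCoverFactor: float = 0.95
    mortFishTerrPredNightMin: float = 0.99
    mortFishTerrPredDayMin: float = 0.9775
    mortFishTerrPredD1: float = 50.0
    mortFishTerrPredD9: float = 200.0
    mortFishTerrPredV1: float = 50.0
    mortFishTerrPredV9: float = 150.0
    mortFishTerrPredL1: float = 30.0
    mortFishTerrPredL9: float = 50.0
    mortFishTerrPredH1: float = 500.0
    mortFishTerrPredH9: float = -100.0
    mortFishTerrPredCoverFactor: float = 0.95
    mortFishConditionK1: float = 0.3
    mortFishConditionK9: float = 0.6
    mortFishOutmigrationL1: float = 32.55
    mortFishOutmigrationL9: float = 21.09

    # redd survival and development
    mortReddDewaterSurv: float = 0.9
    mortReddScourDepth: float = 20.0        # cm
    mortReddLoTT1: float = -0.8
    mortReddLoTT9: float = 0.0
    mortReddHiTT1: float = 19.0
    mortReddHiTT9: float = 15.0
    reddSize: float = 20790.0               # cm^2
    reddDevelParamA: float = 0.001492714
    reddDevelParamB: float = 0.000813082
    reddDevelParamC: float = 0.000036268
    reddNewLengthMean: float = 2.0          # cm
    reddNewLengthStdDev: float = 0.2        # cm
    juveSuperindividualRatio: int = 10

    def __post_init__(self):
        probs = (
            "fishSpawnProb", "fishSpawnEggViability", "fishSpawnWtLossFraction",
            "fishReactDistNightFactor", "fishSearchNightFactor",
            "mortFishVelocityCoverFactor", "mortFishAqPredCoverFactor",
            "mortFishTerrPredNightMin", "mortFishTerrPredDayMin",
            "mortFishTerrPredCoverFactor", "mortReddDewaterSurv",
        )
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        r = self.juveSuperindividualRatio
        if int(r) != r or r < 1:
            raise ParameterError("juveSuperindividualRatio must be an integer >= 1")
        object.__setattr__(self, "juveSuperindividualRatio", int(r))
        if self.reddSize <= 0:
            raise ParameterError("reddSize must be positive")

    # convenience curve builders -------------------------------------------
    def spawn_depth_suitability(self) -> SuitabilityCurve:
        d = [getattr(self, f"fishSpawnDSuitD{i}") for i in range(1, 6)]
        s = [getattr(self, f"fishSpawnDSuitS{i}") for i in range(1, 6)]
        return SuitabilityCurve(list(zip(d, s)))

    def spawn_velocity_suitability(self) -> SuitabilityCurve:
        v = [getattr(self, f"fishSpawnVSuitV{i}") for i in range(1, 7)]
        s = [getattr(self, f"fishSpawnVSuitS{i}") for i in range(1, 7)]
        return SuitabilityCurve(list(zip(v, s)))

    def cmax_temperature_curve(self) -> SuitabilityCurve:
        t = [getattr(self, f"fishCmaxTempT{i}") for i in range(1, 8)]
        f = [getattr(self, f"fishCmaxTempF{i}") for i in range(1, 8)]
        return SuitabilityCurve(list(zip(t, f)))

    def staying_logistic(self) -> AnchoredLogistic:
        """Daily probability of *staying* (not out-migrating) vs length.

        Decreasing in length: staying is 0.1 at ``mortFishOutmigrationL1``
        and 0.9 at ``mortFishOutmigrationL9``.
        """
        return AnchoredLogistic(self.mortFishOutmigrationL1,
                                self.mortFishOutmigrationL9)


@dataclass(frozen=True)
class ReachParams:
    """Reach-level habitat parameters (one reach per simulation)."""

    habMortFishAqPredNightMin: float = 0.99
    habMortFishAqPredDayMin: float = 0.98
    habPreyEnergyDensity: float = 4000.0    # J/g
    habDriftRegenDist: float = 1000.0       # cm
    habShearParamA: float = 0.001           # s/m^3
    habShearParamB: float = 0.9
    habSearchProd: float = 1.75e-6          # g / (h cm^2); calibrated value
    habTwilightLength: float = 0.5          # h
    habShelterSpeedFrac: float = 0.5
    habMaxSpawnFlow: float = 30.0           # m^3/s
    habDriftConc: float = 1.1e-9            # g/cm^3; calibrated value

    def __post_init__(self):
        for f_ in fields(self):
            if getattr(self, f_.name) <= 0 and f_.name != "habShearParamB":
                raise ParameterError(f"{f_.name} must be positive")
        if self.habShearParamB <= 0:
            raise ParameterError("habShearParamB must be positive")


def trout_params(**overrides) -> SpeciesParams:
    """Default brown trout parameter set."""
    return replace(SpeciesParams(species="trout"), **overrides) if overrides \
        else SpeciesParams(species="trout")


def salmon_params(**overrides) -> SpeciesParams:
    """Default Atlantic salmon parameter set.

    Differs from trout in spawning window, fecundity (best fit was a
    constant number of eggs), length-weight, redd development rate and
    outmigration anchors.
    """
    base = SpeciesParams(
        species="salmon",
        fishSpawnStartDate=(11, 1),
        fishSpawnEndDate=(12, 5),
        fishFecundParamA=210.0,
        fishFecundParamB=0.0,
        fishWeightParamA=0.012784,
        fishWeightParamB=2.911403,
        reddDevelParamA=0.002239196,
        reddDevelParamB=0.00046686,
        reddDevelParamC=0.00005409,
        mortFishOutmigrationL1=28.08,
        mortFishOutmigrationL9=18.67,
    )
    return replace(base, **overrides) if overrides else base


def default_reach_params(**overrides) -> ReachParams:
    return replace(ReachParams(), **overrides) if overrides else ReachParams()


# ---------------------------------------------------------------------------
# flat key = value parameter files
# ---------------------------------------------------------------------------

def _parse_month_day(text: str) -> MonthDay:
    try:
        month, day = text.strip().split("/")
        md = (int(month), int(day))
    except Exception as exc:
        raise ParameterError(f"cannot parse date {text!r}; expected MM/DD") from exc
    if not (1 <= md[0] <= 12 and 1 <= md[1] <= 31):
        raise ParameterError(f"date {text!r} out of range")
    return md


def _parse_kv_lines(path) -> dict:
    out = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"{path}:{lineno}: expected 'name = value'")
            name, value = (part.strip() for part in line.split("=", 1))
            out[name] = value
    return out


def _coerce(fld: dataclasses.Field, value: str):
    if fld.name in ("fishSpawnStartDate", "fishSpawnEndDate"):
        return _parse_month_day(value)
    if fld.name == "species":
        return value
    if fld.name == "juveSuperindividualRatio":
        return int(float(value))
    return float(value)


def _load_dataclass(path, base):
    known = {f_.name: f_ for f_ in fields(base)}
    updates = {}
    for name, value in _parse_kv_lines(path).items():
        if name not in known:
            raise ParameterError(f"unknown parameter name {name!r} in {path}")
        updates[name] = _coerce(known[name], value)
    return replace(base, **updates)


def load_species_params(path, base: SpeciesParams | None = None) -> SpeciesParams:
    """Load species parameters from a flat ``name = value`` file.

    Values not present in the file keep their defaults from ``base``
    (trout defaults if no base is given, or salmon defaults if the file
    sets ``species = salmon``).  Unknown parameter names are a hard error.
    """
    if base is None:
        kv = _parse_kv_lines(path)
        base = salmon_params() if kv.get("species") == "salmon" else trout_params()
    return _load_dataclass(path, base)


def load_reach_params(path, base: ReachParams | None = None) -> ReachParams:
    return _load_dataclass(path, base or ReachParams())


def write_params(params, path) -> None:
    """Write a parameter registry as a flat ``name = value`` file."""
    with open(path, "w") as fh:
        for f_ in fields(params):
            v = getattr(params, f_.name)
            if isinstance(v, tuple):
                v = f"{v[0]:02d}/{v[1]:02d}"
            fh.write(f"{f_.name} = {v}\n")
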