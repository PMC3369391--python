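"""Flow-limited PBPK model of lithium disposition in pregnancy.

An eight-compartment physiologically based pharmacokinetic (PBPK) model of
lithium in a pregnant woman and her first-trimester fetus.  Each organ is a
well-mixed, constant-volume compartment perfused by plasma; blood leaving
compartment *i* is in diffusion equilibrium with the tissue, exiting at
concentration ``C_i / R_i`` where ``R_i`` is the tissue:plasma equilibrium
distribution ratio (flow-limited / perfusion-limited kinetics).  Lithium is
delivered orally as controlled-release lithium carbonate, absorbed through
the GI tract at a constant (zero-order) rate over each dose's release
window, and eliminated exclusively by renal clearance from the kidney
compartment.  The fetus exchanges lithium with the maternal circulation only
through the uterus, and has no clearance of its own — which is what makes
fetal accumulation the quantity of interest.

The module is organised in the order the method runs:

1.  physiology     — compartment parameterization, defaults, validation,
                     config file I/O
2.  dosing         — dosage regimens and the piecewise-constant
                     absorption input G(t)
3.  model core     — assembly of the coupled linear ODE right-hand side
4.  simulation     — numerical integration, terminal (periodic steady
                     state) cycle detection, summary metrics, half-life
5.  screening      — pathological reference levels and regimen
                     classification

Internal unit system: mEq, mL, min (consistent with the physiological
parameter table).  All *reported* concentrations are converted to mEq/L
(×1000) — see :data:`MEQ_PER_ML_TO_MEQ_PER_L` and docs/methods.md for why.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

logger = logging.getLogger("lipbpk")

# --------------------------------------------------------------------------
# Configuration constants (defaults for the whole pipeline)
# --------------------------------------------------------------------------

#: Reporting conversion: internal concentrations are mEq/mL; reports use mEq/L.
MEQ_PER_ML_TO_MEQ_PER_L = 1000.0

#: Default zero-order absorption window, min.  Controlled-release lithium
#: carbonate reaches peak serum levels 4-12 h after dosing; the 4-h lower end
#: is the worst case for peak tissue concentration and is the default.
DEFAULT_ABSORPTION_MIN = 240.0

#: Default dosing cycle, min (one day).
DEFAULT_CYCLE_MIN = 1440.0

#: Lithium content of lithium carbonate drug mass: a 300 mg tablet carries
#: 8 mEq of lithium (1 mEq = 1 mmol for the monovalent ion).
DEFAULT_LI_MEQ_PER_MG = 8.0 / 300.0

#: ODE solver defaults.  The system is mildly stiff: the kidney and thyroid
#: exchange on sub-minute time scales (V_i R_i / Q_i ≈ 0.2-0.3 min) while
#: elimination takes ~18 h, so an explicit method is stability-limited to
#: ~1.4-min steps and accumulates start-up error near its stability
#: boundary.  An implicit Runge-Kutta method (Radau IIA) with the exact —
#: constant — Jacobian integrates it to ~1e-9 relative accuracy cheaply.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12
DEFAULT_GRID_DT = 1.0  # min; output grid spacing

#: Terminal-cycle convergence defaults.
DEFAULT_PSS_TOL = 1e-6
DEFAULT_MAX_CYCLES = 60

#: State ordering used everywhere a state vector appears.
PLASMA = "plasma"
PERIPHERAL_COMPARTMENTS: Tuple[str, ...] = (
    "brain",
    "thyroid",
    "bone",
    "gi_tract",
    "kidney",
    "uterus",
    "fetus",
)
STATE_ORDER: Tuple[str, ...] = (PLASMA,) + PERIPHERAL_COMPARTMENTS
STATE_INDEX: Dict[str, int] = {name: i for i, name in enumerate(STATE_ORDER)}

#: Compartments that return blood directly to the plasma pool.  The fetus is
#: excluded: its perfusion is a sub-loop of the uterine circulation, so fetal
#: venous return enters the uterus, not the plasma compartment.
_PLASMA_EXCHANGING = ("brain", "thyroid", "bone", "gi_tract", "kidney", "uterus")


class PBPKError(Exception):
    """Base class for errors raised by this package."""


class SolverError(PBPKError):
    """ODE integration failed; the message names the failing time interval."""


class ConvergenceError(PBPKError):
    """A periodic steady state was required but not reached."""


class HorizonError(PBPKError):
    """The simulated horizon was too short for the requested measurement."""


# ==========================================================================
# 1. PHYSIOLOGY — compartment parameterization and validation
# ==========================================================================


@dataclass(frozen=True)
class CompartmentSpec:
    """One organ/tissue compartment.

    Parameters
    ----------
    name : str
        Compartment identifier (one of :data:`PERIPHERAL_COMPARTMENTS`).
    volume : float
        Tissue volume ``V_i``, mL.
    flow : float
        Plasma flow to the compartment ``Q_i``, mL/min.
    partition : float
        Tissue-to-plasma equilibrium distribution ratio ``R_i``
        (dimensionless).  Blood exits the compartment at ``C_i / R_i``.
    """

    name: str
    volume: float
    flow: float
    partition: float


@dataclass(frozen=True)
class PhysiologyParams:
    """Full physiological parameter set.

    ``compartments`` must hold exactly the seven named non-plasma
    compartments (brain, thyroid, bone, gi_tract, kidney, uterus, fetus).
    Construction is permissive; use :func:`validate` for invariant checks —
    it reports findings rather than raising so callers (and the CLI) can
    surface every problem at once.
    """

    compartments: Mapping[str, CompartmentSpec]
    plasma_volume: float  # V_P, mL
    renal_clearance: float  # kk, mL/min
    li_per_mg: float = DEFAULT_LI_MEQ_PER_MG  # mEq lithium per mg drug

    def volume(self, name: str) -> float:
        return self.plasma_volume if name == PLASMA else self.compartments[name].volume

    def flow(self, name: str) -> float:
        return self.compartments[name].flow

    def partition(self, name: str) -> float:
        """R_i; the plasma pool has no partition ratio (identically 1)."""
        return 1.0 if name == PLASMA else self.compartments[name].partition

    def with_compartment(self, name: str, **changes: float) -> "PhysiologyParams":
        """Return a copy with one compartment's fields replaced."""
        comps = dict(self.compartments)
        comps[name] = dataclasses.replace(comps[name], **changes)
        return dataclasses.replace(self, compartments=comps)

    def with_renal_clearance(self, kk: float) -> "PhysiologyParams":
        return dataclasses.replace(self, renal_clearance=kk)


# StateVector: a length-8 numpy array of concentrations (mEq/mL) ordered as
# STATE_ORDER.  Kept as a plain ndarray for solver interoperability.
StateVector = np.ndarray


def bone_volume(mass_kg: float, density_g_per_ml: float) -> float:
    """Bone compartment volume (mL) from bone mass (kg) and density (g/mL).

    Rounded to the nearest mL, matching the tabulated value
    ``bone_volume(8, 1.1) == 7273``.
    """
    if mass_kg <= 0 or density_g_per_ml <= 0:
        raise ValueError("bone mass and density must be positive")
    return float(round(1000.0 * mass_kg / density_g_per_ml))


def default_params() -> PhysiologyParams:
    """Baseline parameter set for a first-trimester pregnancy.

    Loaded from the packaged config file ``data/default_physiology.yaml``
    (volumes mL, flows mL/min, partition ratios; renal clearance 20 mL/min,
    the low end of the accepted 20-40 mL/min range; 8/300 mEq Li per mg of
    lithium carbonate).  The bone volume of 7273 mL is
    :func:`bone_volume` (8 kg, 1.1 g/mL); the fetal partition ratio defaults
    to 0.8 and is an ordinary overridable parameter — fetal concentrations
    scale linearly with it, so any choice leads to the same regimen
    classifications.
    """
    ref = resources.files("lipbpk").joinpath("data/default_physiology.yaml")
    with ref.open("r") as fh:
        return load_physiology(fh)


@dataclass
class ValidationReport:
    """Structured invariant-check findings; empty means valid."""

    findings: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __bool__(self) -> bool:  # truthy when valid
        return self.ok


def validate(params: PhysiologyParams) -> ValidationReport:
    """Check a parameter set against the model's structural invariants.

    Returns a report rather than raising: every violated invariant produces
    one finding, and the default parameter set yields none.
    """
    findings: List[str] = []
    expected = set(PERIPHERAL_COMPARTMENTS)
    present = set(params.compartments)
    for missing in sorted(expected - present):
        if missing == "uterus":
            findings.append(
                "uterus compartment missing: the fetus exchanges blood only "
                "through the uterus, so the model connectivity is broken"
            )
        else:
            findings.append(f"missing compartment '{missing}'")
    for extra in sorted(present - expected):
        findings.append(f"unknown compartment '{extra}'")
    for name in sorted(expected & present):
        spec = params.compartments[name]
        if not spec.volume > 0:
            findings.append(f"{name}: volume must be > 0 (got {spec.volume!r})")
        if not spec.flow > 0:
            findings.append(f"{name}: flow must be > 0 (got {spec.flow!r})")
        if not spec.partition > 0:
            findings.append(f"{name}: partition must be > 0 (got {spec.partition!r})")
    if not params.plasma_volume > 0:
        findings.append(f"plasma_volume must be > 0 (got {params.plasma_volume!r})")
    if params.renal_clearance < 0:
        findings.append(
            f"renal_clearance must be >= 0 (got {params.renal_clearance!r})"
        )
    if not params.li_per_mg > 0:
        findings.append(f"li_per_mg must be > 0 (got {params.li_per_mg!r})")
    return ValidationReport(findings)


def load_physiology(source) -> PhysiologyParams:
    """Read a :class:`PhysiologyParams` from a YAML path or open stream."""
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source, "r") as fh:
            raw = yaml.safe_load(fh)
    comps = {
        name: CompartmentSpec(
            name=name,
            volume=float(entry["volume_ml"]),
            flow=float(entry["flow_ml_min"]),
            partition=float(entry["partition"]),
        )
        for name, entry in raw["compartments"].items()
    }
    return PhysiologyParams(
        compartments=comps,
        plasma_volume=float(raw["plasma_volume_ml"]),
        renal_clearance=float(raw["renal_clearance_ml_min"]),
        li_per_mg=float(raw.get("li_meq_per_mg", DEFAULT_LI_MEQ_PER_MG)),
    )


def dump_physiology(params: PhysiologyParams, target) -> None:
    """Write a parameter set as YAML (round-trips bit-exactly)."""
    doc = {
        "plasma_volume_ml": float(params.plasma_volume),
        "renal_clearance_ml_min": float(params.renal_clearance),
        "li_meq_per_mg": float(params.li_per_mg),
        "compartments": {
            name: {
                "volume_ml": float(c.volume),
                "flow_ml_min": float(c.flow),
                "partition": float(c.partition),
            }
            for name, c in params.compartments.items()
        },
    }
    if hasattr(target, "write"):
        yaml.safe_dump(doc, target, sort_keys=False)
    else:
        with open(target, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ==========================================================================
# 2. DOSING — regimens and the zero-order absorption input G(t)
# ==========================================================================


@dataclass(frozen=True)
class DoseEvent:
    """One administered dose: ``mass`` mg of drug released at a constant
    rate over ``duration`` minutes starting at ``start_time`` (min since
    simulation start)."""

    start_time: float
    mass: float
    duration: float = DEFAULT_ABSORPTION_MIN

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"dose mass must be >= 0 mg (got {self.mass})")
        if self.duration <= 0:
            raise ValueError(
                f"absorption duration must be > 0 min (got {self.duration})"
            )

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class Regimen:
    """A daily (or other fixed-cycle) dosing schedule.

    ``doses`` is a sequence of ``(offset_min, mass_mg)`` pairs with offsets
    inside ``[0, cycle_length)``.  The conventional shorthand "450/900"
    means 450 mg at t=0 and 900 mg 12 h later, repeating daily.
    """

    doses: Tuple[Tuple[float, float], ...]
    cycle_length: float = DEFAULT_CYCLE_MIN
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple((float(o), float(m)) for o, m in self.doses))
        if not self.doses:
            raise ValueError("a regimen must contain at least one dose")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be > 0")
        for offset, mass in self.doses:
            if not (0 <= offset < self.cycle_length):
                raise ValueError(
                    f"dose offset {offset} min outside [0, {self.cycle_length})"
                )
            if mass < 0:
                raise ValueError(f"dose mass must be >= 0 mg (got {mass})")
        if not self.label:
            object.__setattr__(
                self, "label", "/".join(f"{m:g}" for _, m in self.doses)
            )

    @property
    def cycle_mass_mg(self) -> float:
        return sum(m for _, m in self.doses)

    def scaled(self, factor: float) -> "Regimen":
        """Same schedule with every dose mass multiplied by ``factor``."""
        return Regimen(
            tuple((o, m * factor) for o, m in self.doses),
            self.cycle_length,
            f"{self.label} x{factor:g}",
        )


def evenly_spaced(masses: Sequence[float], cycle_length: float = DEFAULT_CYCLE_MIN,
                  label: str = "") -> Regimen:
    """Build a regimen with ``len(masses)`` doses evenly spaced over the
    cycle: 12 h apart for 2 doses, 8 h for 3, 6 h for 4."""
    n = len(masses)
    if n == 0:
        raise ValueError("at least one dose mass required")
    step = cycle_length / n
    return Regimen(tuple((i * step, m) for i, m in enumerate(masses)),
                   cycle_length, label)


#: Named presets for every regimen discussed in the screening analysis.
#: Unequal-mass two-dose regimens keep their documented 12-h spacing; the
#: n-dose presets are evenly spaced.  "single-900" is a one-administration
#: schedule used for single-dose profile and half-life runs (n_cycles=1).
PRESETS: Dict[str, Regimen] = {
    "450/900": Regimen(((0.0, 450.0), (720.0, 900.0)), label="450/900"),
    "900/900": evenly_spaced([900.0, 900.0], label="900/900"),
    "700/700": evenly_spaced([700.0, 700.0], label="700/700"),
    "1000/300": Regimen(((0.0, 1000.0), (720.0, 300.0)), label="1000/300"),
    "300/300": evenly_spaced([300.0, 300.0], label="300/300"),
    "600/600": evenly_spaced([600.0, 600.0], label="600/600"),
    "300/300/500": Regimen(
        ((0.0, 300.0), (480.0, 300.0), (960.0, 500.0)), label="300/300/500"
    ),
    "400/400/400": evenly_spaced([400.0] * 3, label="400/400/400"),
    "300/300/300/300": evenly_spaced([300.0] * 4, label="300/300/300/300"),
    "single-900": Regimen(((0.0, 900.0),), label="single-900"),
}

#: The documented pathological regimen: 450 mg in the morning followed by
#: 900 mg in the evening, known to have caused birth defects.
PATHOLOGICAL_REGIMEN = PRESETS["450/900"]


def get_preset(name: str) -> Regimen:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown regimen preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def expand_regimen(
    regimen: Regimen,
    n_cycles: int,
    duration: float = DEFAULT_ABSORPTION_MIN,
) -> List[DoseEvent]:
    """Unroll a cyclic regimen into absolute-time dose events.

    One :class:`DoseEvent` per dose per cycle, at
    ``start_time = cycle_index * cycle_length + offset``, all with the given
    absorption window ``duration`` (min).
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1 (got {n_cycles})")
    events = [
        DoseEvent(k * regimen.cycle_length + offset, mass, duration)
        for k in range(n_cycles)
        for offset, mass in regimen.doses
    ]
    logger.debug(
        "expanded regimen %s: %d cycle(s) -> %d dose events",
        regimen.label, n_cycles, len(events),
    )
    return events


class AbsorptionProfile:
    """Piecewise-constant GI absorption input ``G(t)`` in mEq/min.

    Each dose event contributes ``mass * li_per_mg / duration`` while its
    release window ``[start, start + duration)`` is active; overlapping
    windows sum; the profile is zero outside all windows.
    """

    def __init__(self, events: Iterable[DoseEvent], li_per_mg: float):
        if li_per_mg <= 0:
            raise ValueError("li_per_mg must be > 0")
        self.events: Tuple[DoseEvent, ...] = tuple(events)
        self.li_per_mg = float(li_per_mg)

    def __call__(self, t):
        """Absorption rate at time ``t`` (scalar or array), mEq/min."""
        t = np.asarray(t, dtype=float)
        rate = np.zeros_like(t)
        for ev in self.events:
            active = (t >= ev.start_time) & (t < ev.end_time)
            rate = rate + active * (ev.mass * self.li_per_mg / ev.duration)
        return float(rate) if rate.ndim == 0 else rate

    def breakpoints(self) -> List[float]:
        """Sorted unique window boundaries (integration restart points)."""
        pts = {ev.start_time for ev in self.events} | {
            ev.end_time for ev in self.events
        }
        return sorted(pts)

    def integral(self, t0: float, t1: float) -> float:
        """Exact ``∫ G dt`` over ``[t0, t1]``, mEq (piecewise-constant)."""
        total = 0.0
        for ev in self.events:
            overlap = min(t1, ev.end_time) - max(t0, ev.start_time)
            if overlap > 0:
                total += overlap * ev.mass * self.li_per_mg / ev.duration
        return total


def make_absorption_profile(
    events: Iterable[DoseEvent], li_per_mg: float = DEFAULT_LI_MEQ_PER_MG
) -> AbsorptionProfile:
    """Build ``G(t)`` from dose events (see :class:`AbsorptionProfile`)."""
    return AbsorptionProfile(events, li_per_mg)


def cycle_dose_mEq(regimen: Regimen, li_per_mg: float = DEFAULT_LI_MEQ_PER_MG) -> float:
    """Total lithium delivered per cycle, mEq (Σ mass × li_per_mg)."""
    return regimen.cycle_mass_mg * li_per_mg


# ==========================================================================
# 3. MODEL CORE — the coupled ODE right-hand side
# ==========================================================================
#
# With concentrations as state (constant compartment volumes), the system is
# linear time-varying only through the absorption input:
#
#   dC/dt = A C + G(t)/V_G * e_GI
#
# where A encodes, per peripheral compartment i,
#   dC_i/dt = Q_i (C_P - C_i/R_i) / V_i
# with three structural exceptions:
#   * uterus: a second exchange term with the fetal sub-loop,
#       dC_U/dt = [Q_U (C_P - C_U/R_U) + Q_F (C_F/R_F - C_U/R_U)] / V_U
#   * fetus: exchanges only with the uterus (no direct plasma contact, no
#       clearance): dC_F/dt = Q_F (C_U/R_U - C_F/R_F) / V_F
#   * kidney: an extra elimination term -kk C_K/R_K / V_K
# and the plasma pool collects every direct venous return:
#   dC_P/dt = [Σ_i Q_i C_i/R_i - (Σ_i Q_i) C_P] / V_P  over the six
# plasma-exchanging compartments (the fetal flow routes through the uterus).


#: RateFunction: (t, StateVector) -> dState/dt, mEq/mL/min.  Linear in the
#: state for fixed t; the only affine offset is G(t)/V_G in the GI entry.
RateFunction = Callable[[float, StateVector], StateVector]


def _system_matrix(params: PhysiologyParams) -> np.ndarray:
    """Assemble the homogeneous part A of dC/dt = A C + input."""
    report = validate(params)
    if not report.ok:
        raise ValueError(
            "invalid physiology parameters:\n  " + "\n  ".join(report.findings)
        )
    A = np.zeros((len(STATE_ORDER), len(STATE_ORDER)))
    iP = STATE_INDEX[PLASMA]
    for name in ("brain", "thyroid", "bone", "gi_tract", "kidney"):
        c = params.compartments[name]
        i = STATE_INDEX[name]
        A[i, iP] += c.flow / c.volume
        A[i, i] -= c.flow / (c.partition * c.volume)
    # kidney elimination: -kk C_K / R_K / V_K
    k = params.compartments["kidney"]
    iK = STATE_INDEX["kidney"]
    A[iK, iK] -= params.renal_clearance / (k.partition * k.volume)
    # uterus <-> fetus sub-loop
    u = params.compartments["uterus"]
    f = params.compartments["fetus"]
    iU, iF = STATE_INDEX["uterus"], STATE_INDEX["fetus"]
    A[iU, iP] += u.flow / u.volume
    A[iU, iU] -= (u.flow + f.flow) / (u.partition * u.volume)
    A[iU, iF] += f.flow / (f.partition * u.volume)
    A[iF, iU] += f.flow / (u.partition * f.volume)
    A[iF, iF] -= f.flow / (f.partition * f.volume)
    # plasma: venous return from the six directly connected compartments
    total_flow = 0.0
    for name in _PLASMA_EXCHANGING:
        c = params.compartments[name]
        A[iP, STATE_INDEX[name]] += c.flow / (c.partition * params.plasma_volume)
        total_flow += c.flow
    A[iP, iP] -= total_flow / params.plasma_volume
    return A


def build_rhs(params: PhysiologyParams, absorption: AbsorptionProfile) -> RateFunction:
    """Build the ODE right-hand side for a physiology and absorption input.

    Raises ``ValueError`` at build time if the parameter set fails
    :func:`validate` (unknown or missing compartments, non-positive values).
    """
    A = _system_matrix(params)
    v_gi = params.compartments["gi_tract"].volume
    i_gi = STATE_INDEX["gi_tract"]

    def rhs(t: float, state: StateVector) -> StateVector:
        dstate = A @ state
        g = absorption(t)
        if g:
            dstate = dstate.copy()
            dstate[i_gi] += g / v_gi
        return dstate

    return rhs


def total_body_amount(state: StateVector, params: PhysiologyParams) -> float:
    """Total lithium in the body, mEq: Σ V_i C_i over all compartments
    including plasma (state in internal mEq/mL units)."""
    return float(
        sum(params.volume(name) * state[STATE_INDEX[name]] for name in STATE_ORDER)
    )


def effective_clearance(params: PhysiologyParams) -> float:
    """Whole-body plasma clearance implied by the kidney compartment, mL/min.

    At steady state the kidney flow balance gives
    ``C_K/R_K = Q_K/(Q_K + kk) * C_P``, so the elimination rate
    ``kk * C_K/R_K`` equals ``CL * C_P`` with ``CL = kk Q_K / (Q_K + kk)``.
    Limits: 0 when kk=0; → Q_K as kk → ∞ (perfusion-limited elimination).
    """
    kk = params.renal_clearance
    q_k = params.compartments["kidney"].flow
    return kk * q_k / (q_k + kk)


# ==========================================================================
# 4. SIMULATION — integration, terminal cycle, summary metrics
# ==========================================================================


@dataclass
class Trajectory:
    """Concentration-time courses on a dense grid.

    ``times`` are minutes since simulation start; ``concentrations`` maps
    compartment name → series in **mEq/L** (reporting units).
    """

    times: np.ndarray
    concentrations: Dict[str, np.ndarray]
    regimen_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_min": self.times})
        for name in STATE_ORDER:
            df[name] = self.concentrations[name]
        return df

    def to_csv(self, target) -> None:
        """CSV with a leading units comment row."""
        df = self.to_frame()
        if hasattr(target, "write"):
            target.write("# concentrations in mEq/L\n")
            df.to_csv(target, index=False)
        else:
            with open(target, "w") as fh:
                self.to_csv(fh)


@dataclass(frozen=True)
class CompartmentStats:
    """Terminal-cycle metrics for one compartment, mEq/L."""

    peak: float
    peak_time_min: float  # within the cycle
    average: float


@dataclass
class CycleSummary:
    """Per-compartment peak/average over one terminal cycle plus
    convergence metadata."""

    compartments: Dict[str, CompartmentStats]
    converged: bool
    n_cycles_run: int
    tolerance: float
    cycle_length: float
    regimen_label: str = ""

    def to_dict(self) -> dict:
        return {
            "regimen": self.regimen_label,
            "units": "mEq/L",
            "converged": self.converged,
            "n_cycles_run": self.n_cycles_run,
            "tolerance": self.tolerance,
            "cycle_length_min": self.cycle_length,
            "compartments": {
                name: {
                    "peak": s.peak,
                    "peak_time_min": s.peak_time_min,
                    "average": s.average,
                }
                for name, s in self.compartments.items()
            },
        }

    def to_json(self, target) -> None:
        if hasattr(target, "write"):
            json.dump(self.to_dict(), target, indent=2)
        else:
            with open(target, "w") as fh:
                json.dump(self.to_dict(), fh, indent=2)


def _segment_grid(a: float, b: float, dt: float) -> np.ndarray:
    """Grid over [a, b] with spacing <= dt, endpoints included."""
    n = max(1, int(math.ceil((b - a) / dt)))
    return np.linspace(a, b, n + 1)


def _integrate(
    params: PhysiologyParams,
    profile: AbsorptionProfile,
    t0: float,
    t1: float,
    y0: StateVector,
    grid_dt: float = DEFAULT_GRID_DT,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate the model over [t0, t1], restarting at every absorption
    window boundary so the discontinuous G(t) is never smoothed over.

    Returns ``(times, states)`` with states in internal mEq/mL units,
    shape (n_times, 8).
    """
    A = _system_matrix(params)
    v_gi = params.compartments["gi_tract"].volume
    i_gi = STATE_INDEX["gi_tract"]
    cuts = [t for t in profile.breakpoints() if t0 < t < t1]
    edges = [t0, *cuts, t1]
    times: List[np.ndarray] = []
    states: List[np.ndarray] = []
    y = np.asarray(y0, dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        g = profile(0.5 * (a + b))  # constant within the segment
        forcing = np.zeros(len(STATE_ORDER))
        forcing[i_gi] = g / v_gi

        def rhs(t, yy, _A=A, _f=forcing):
            return _A @ yy + _f

        t_eval = _segment_grid(a, b, grid_dt)
        sol = solve_ivp(
            rhs, (a, b), y, method="Radau", rtol=rtol, atol=atol,
            t_eval=t_eval, jac=A,
        )
        if not sol.success:
            raise SolverError(
                f"integration failed on interval [{a:.6g}, {b:.6g}] min: "
                f"{sol.message}"
            )
        y = sol.y[:, -1]
        skip = 1 if times else 0  # drop the duplicated segment start
        times.append(sol.t[skip:])
        states.append(sol.y[:, skip:].T)
    return np.concatenate(times), np.vstack(states)


def _refine_peak(t: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Grid maximum refined by a local quadratic through its neighbours."""
    i = int(np.argmax(y))
    if 0 < i < len(y) - 1:
        t0, t1, t2 = t[i - 1], t[i], t[i + 1]
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
        if denom != 0:
            a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
            b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
            if a < 0:  # genuine local maximum
                tv = -b / (2 * a)
                if t0 <= tv <= t2:
                    yv = a * tv**2 + b * tv + (y1 - a * t1**2 - b * t1)
                    return float(tv), float(max(yv, y1))
    return float(t[i]), float(y[i])


def simulate_events(
    params: PhysiologyParams,
    events: Sequence[DoseEvent],
    horizon_min: float,
    y0: Optional[StateVector] = None,
    grid_dt: float = DEFAULT_GRID_DT,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    label: str = "",
) -> Trajectory:
    """Integrate an explicit dose-event schedule from (by default) an
    all-zero initial state; returns a :class:`Trajectory` in mEq/L."""
    profile = make_absorption_profile(events, params.li_per_mg)
    if y0 is None:
        y0 = np.zeros(len(STATE_ORDER))
    t, y = _integrate(params, profile, 0.0, horizon_min, y0, grid_dt, rtol, atol)
    conc = {
        name: y[:, STATE_INDEX[name]] * MEQ_PER_ML_TO_MEQ_PER_L
        for name in STATE_ORDER
    }
    return Trajectory(times=t, concentrations=conc, regimen_label=label)


def simulate(
    params: PhysiologyParams,
    regimen: Regimen,
    n_cycles: int = 1,
    duration: float = DEFAULT_ABSORPTION_MIN,
    grid_dt: float = DEFAULT_GRID_DT,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Simulate ``n_cycles`` repeats of a regimen from an all-zero state.

    The output grid has spacing ≤ ``grid_dt`` (default 1 min) and contains
    every absorption-window boundary.
    """
    events = expand_regimen(regimen, n_cycles, duration)
    horizon = n_cycles * regimen.cycle_length
    return simulate_events(
        params, events, horizon, grid_dt=grid_dt, rtol=rtol, atol=atol,
        label=regimen.label,
    )


def _cycle_stats(
    t: np.ndarray, states: np.ndarray, t_start: float, cycle_length: float
) -> Dict[str, CompartmentStats]:
    stats = {}
    for name in STATE_ORDER:
        y = states[:, STATE_INDEX[name]] * MEQ_PER_ML_TO_MEQ_PER_L
        pk_t, pk = _refine_peak(t, y)
        avg = float(np.trapezoid(y, t) / cycle_length)
        stats[name] = CompartmentStats(
            peak=pk, peak_time_min=pk_t - t_start, average=avg
        )
    return stats


def find_terminal_cycle(
    params: PhysiologyParams,
    regimen: Regimen,
    duration: float = DEFAULT_ABSORPTION_MIN,
    tolerance: float = DEFAULT_PSS_TOL,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    grid_dt: float = DEFAULT_GRID_DT,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> CycleSummary:
    """Run cycle after cycle until the terminal (periodic steady-state)
    profile is reached, then summarize the last cycle.

    Convergence requires, for *every* compartment, the relative change of
    both the cycle peak and the cycle average between consecutive cycles to
    fall below ``tolerance``.  With a ~12 h plasma half-life the cycle map
    contracts by ~4x per day, so the default tolerance of 1e-6 is reached in
    roughly a dozen cycles.  Non-convergence within ``max_cycles`` is
    reported via ``converged=False``, not an exception.
    """
    # Integrate each cycle over the window [L, 2L] of a 2-cycle event
    # expansion: absorption windows that spill across a cycle boundary are
    # then represented exactly, and the window is identical every cycle.
    L = regimen.cycle_length
    events = expand_regimen(regimen, 2, duration)
    profile = make_absorption_profile(events, params.li_per_mg)
    y = np.zeros(len(STATE_ORDER))
    prev: Optional[Dict[str, CompartmentStats]] = None
    stats: Dict[str, CompartmentStats] = {}
    n_run = 0
    converged = False
    for k in range(max_cycles):
        t, states = _integrate(params, profile, L, 2 * L, y, grid_dt, rtol, atol)
        y = states[-1]
        stats = _cycle_stats(t, states, L, L)
        n_run = k + 1
        if prev is not None:
            drift = max(
                max(
                    abs(stats[n].peak - prev[n].peak) / max(abs(prev[n].peak), 1e-300),
                    abs(stats[n].average - prev[n].average)
                    / max(abs(prev[n].average), 1e-300),
                )
                if prev[n].peak or prev[n].average
                else abs(stats[n].peak) + abs(stats[n].average)
                for n in STATE_ORDER
            )
            if drift < tolerance:
                converged = True
                break
        prev = stats
    logger.info(
        "terminal cycle for %s: %d cycle(s), converged=%s (tol %.1e)",
        regimen.label, n_run, converged, tolerance,
    )
    return CycleSummary(
        compartments=stats,
        converged=converged,
        n_cycles_run=n_run,
        tolerance=tolerance,
        cycle_length=L,
        regimen_label=regimen.label,
    )


def analytic_steady_state_average(
    params: PhysiologyParams, regimen: Regimen
) -> Dict[str, float]:
    """Closed-form cycle-averaged concentrations at periodic steady state,
    mEq/L — the flow-balance oracle for the simulated terminal cycle.

    Averaging the linear system over one terminal cycle kills every d/dt
    term, leaving algebraic flow balances:

    * dosing rate = elimination rate  →
      ``avg C_P = (cycle dose / cycle length) / CL_eff``
    * every passive exchange balances →
      ``avg C_i / R_i = avg C_P`` (brain, thyroid, bone, uterus) and
      ``avg C_F / R_F = avg C_U / R_U`` (so fetal ≡ R_F × plasma average)
    * GI tract carries the absorption inflow:
      ``avg C_G / R_G = avg C_P + (dosing rate)/Q_G``
    * kidney: ``avg C_K / R_K = Q_K/(Q_K+kk) · avg C_P``

    Raises ``ValueError`` when clearance is zero (no steady state exists).
    """
    cl = effective_clearance(params)
    if cl <= 0:
        raise ValueError("no periodic steady state without renal clearance")
    dose_rate = cycle_dose_mEq(regimen, params.li_per_mg) / regimen.cycle_length
    avg_cp = dose_rate / cl
    kk = params.renal_clearance
    q_k = params.compartments["kidney"].flow
    out = {PLASMA: avg_cp}
    for name in PERIPHERAL_COMPARTMENTS:
        c = params.compartments[name]
        if name == "kidney":
            out[name] = c.partition * avg_cp * q_k / (q_k + kk)
        elif name == "gi_tract":
            out[name] = c.partition * (avg_cp + dose_rate / c.flow)
        else:
            out[name] = c.partition * avg_cp
    return {k: v * MEQ_PER_ML_TO_MEQ_PER_L for k, v in out.items()}


def estimate_half_life(
    params: PhysiologyParams,
    regimen: Regimen = PRESETS["single-900"],
    duration: float = DEFAULT_ABSORPTION_MIN,
    horizon_min: float = 2880.0,
    grid_dt: float = DEFAULT_GRID_DT,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float:
    """Plasma half-life (hours) after a single dose.

    Simulates the one-dose schedule well past absorption, locates the plasma
    maximum and returns the elapsed time until the plasma concentration
    first falls to half that maximum (linear interpolation on the dense
    grid).  Raises :class:`HorizonError` if the trajectory never reaches
    half-maximum within ``horizon_min``.
    """
    if len(regimen.doses) != 1:
        raise ValueError("half-life estimation requires a single-dose schedule")
    offset, mass = regimen.doses[0]
    events = [DoseEvent(offset, mass, duration)]
    profile = make_absorption_profile(events, params.li_per_mg)
    y0 = np.zeros(len(STATE_ORDER))
    t, states = _integrate(params, profile, 0.0, horizon_min, y0, grid_dt, rtol, atol)
    plasma = states[:, STATE_INDEX[PLASMA]]
    pk_t, pk = _refine_peak(t, plasma)
    half = pk / 2.0
    after = t >= pk_t
    t_a, y_a = t[after], plasma[after]
    below = np.nonzero(y_a <= half)[0]
    if len(below) == 0:
        raise HorizonError(
            f"plasma concentration did not fall to half-maximum within "
            f"{horizon_min:g} min; extend the simulation horizon"
        )
    j = below[0]
    if j == 0:
        t_half = t_a[0]
    else:
        # linear interpolation across the crossing
        t0, t1 = t_a[j - 1], t_a[j]
        y0_, y1_ = y_a[j - 1], y_a[j]
        t_half = t0 + (half - y0_) * (t1 - t0) / (y1_ - y0_)
    return (t_half - pk_t) / 60.0


# ==========================================================================
# 5. SCREENING — pathological reference levels and classification
# ==========================================================================

#: Relative band within which a fetal metric is treated as tied with the
#: reference.  Ties are conservatively NOT acceptable ("at_reference").
REFERENCE_TIE_RTOL = 1e-9

ACCEPTABLE = "acceptable"
AT_REFERENCE = "at_reference"
ELIMINATED_PEAK = "eliminated_peak"
ELIMINATED_AVERAGE = "eliminated_average"
ELIMINATED_BOTH = "eliminated_both"

#: Published terminal-cycle fetal levels (average, peak) in mEq/L for the
#: documented screening table, used only by the `table2` CLI report to show
#: per-cell deviations.  Never used as reference levels — those are always
#: re-simulated (see :func:`derive_reference`).
PUBLISHED_FETAL_LEVELS: Dict[str, Tuple[float, float]] = {
    "450/900": (0.965, 1.434),
    "300/300/500": (0.796, 1.021),
    "300/300": (0.419, 0.570),
    "300/300/300/300": (0.867, 0.960),
    "400/400/400": (0.860, 1.019),
    "600/600": (0.886, 1.141),
}

#: Regimen order of the published screening table.
TABLE_REGIMENS: Tuple[str, ...] = (
    "450/900",
    "300/300/500",
    "300/300",
    "300/300/300/300",
    "400/400/400",
    "600/600",
)


@dataclass(frozen=True)
class ReferenceLevels:
    """Not-to-exceed fetal levels derived from a pathological regimen.

    Always obtained by simulation under the *same* physiology as the
    candidate regimens (so overrides such as the fetal partition ratio
    propagate consistently), never hard-coded.
    """

    max_fetal_peak: float  # mEq/L
    max_fetal_average: float  # mEq/L
    provenance: str  # label of the regimen that produced them


@dataclass(frozen=True)
class ScreeningResult:
    regimen_label: str
    fetal_peak: float  # mEq/L
    fetal_average: float  # mEq/L
    classification: str
    peak_margin: float  # reference - value (positive = below reference)
    average_margin: float
    brain_average: float  # informational (maternal exposure), mEq/L
    converged: bool


def derive_reference(
    params: PhysiologyParams,
    regimen: Regimen = PATHOLOGICAL_REGIMEN,
    **solver_options,
) -> ReferenceLevels:
    """Terminal-cycle fetal peak and average of the pathological regimen.

    Raises :class:`ConvergenceError` if the terminal cycle is not reached.
    """
    summary = find_terminal_cycle(params, regimen, **solver_options)
    if not summary.converged:
        raise ConvergenceError(
            f"reference regimen {regimen.label} did not reach a terminal "
            f"cycle in {summary.n_cycles_run} cycles"
        )
    fetal = summary.compartments["fetus"]
    return ReferenceLevels(
        max_fetal_peak=fetal.peak,
        max_fetal_average=fetal.average,
        provenance=regimen.label,
    )


def _classify(
    peak: float, average: float, reference: ReferenceLevels
) -> str:
    tie = REFERENCE_TIE_RTOL
    peak_at = abs(peak - reference.max_fetal_peak) <= tie * reference.max_fetal_peak
    avg_at = (
        abs(average - reference.max_fetal_average)
        <= tie * reference.max_fetal_average
    )
    peak_over = not peak_at and peak > reference.max_fetal_peak
    avg_over = not avg_at and average > reference.max_fetal_average
    if peak_over and avg_over:
        return ELIMINATED_BOTH
    if peak_over:
        return ELIMINATED_PEAK
    if avg_over:
        return ELIMINATED_AVERAGE
    if peak_at or avg_at:
        return AT_REFERENCE
    return ACCEPTABLE


def screen_regimen(
    params: PhysiologyParams,
    regimen: Regimen,
    reference: ReferenceLevels,
    **solver_options,
) -> ScreeningResult:
    """Classify one candidate regimen against the reference levels.

    A regimen is eliminated if its terminal-cycle fetal peak or average
    strictly exceeds the corresponding reference level; values tied with the
    reference (within :data:`REFERENCE_TIE_RTOL` relative) are labelled
    ``at_reference`` and are not acceptable.
    """
    summary = find_terminal_cycle(params, regimen, **solver_options)
    if not summary.converged:
        raise ConvergenceError(
            f"regimen {regimen.label} did not reach a terminal cycle in "
            f"{summary.n_cycles_run} cycles"
        )
    fetal = summary.compartments["fetus"]
    return ScreeningResult(
        regimen_label=regimen.label,
        fetal_peak=fetal.peak,
        fetal_average=fetal.average,
        classification=_classify(fetal.peak, fetal.average, reference),
        peak_margin=reference.max_fetal_peak - fetal.peak,
        average_margin=reference.max_fetal_average - fetal.average,
        brain_average=summary.compartments["brain"].average,
        converged=summary.converged,
    )


def compare_regimens(
    params: PhysiologyParams,
    regimens: Sequence[Regimen],
    reference: Optional[ReferenceLevels] = None,
    **solver_options,
) -> List[ScreeningResult]:
    """Screen several regimens and rank them: acceptable first, then by
    fetal average descending (the search is for the *maximum* acceptable
    regimen).  The reference is derived from the pathological regimen under
    the same physiology unless supplied."""
    if not regimens:
        raise ValueError("at least one regimen is required")
    if reference is None:
        reference = derive_reference(params, **solver_options)
    results = [
        screen_regimen(params, r, reference, **solver_options) for r in regimens
    ]
    results.sort(
        key=lambda r: (0 if r.classification == ACCEPTABLE else 1, -r.fetal_average)
    )
    return results


def screening_frame(results: Sequence[ScreeningResult]) -> pd.DataFrame:
    """Tabular report of screening results (concentrations in mEq/L)."""
    return pd.DataFrame(
        [
            {
                "regimen": r.regimen_label,
                "fetal_average_mEq_L": r.fetal_average,
                "fetal_peak_mEq_L": r.fetal_peak,
                "classification": r.classification,
                "average_margin_mEq_L": r.average_margin,
                "peak_margin_mEq_L": r.peak_margin,
                "brain_average_mEq_L": r.brain_average,
            }
            for r in results
        ]
    )


def screening_results_to_json(results: Sequence[ScreeningResult], target) -> None:
    doc = screening_frame(results).to_dict(orient="records")
    if hasattr(target, "write"):
        json.dump(doc, target, indent=2)
    else:
        with open(target, "w") as fh:
            json.dump(doc, fh, indent=2)
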