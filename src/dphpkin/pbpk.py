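"""The DPHP/MPHP PBPK ODE system and its numerical simulation.

Model structure
---------------
Oral DPHP splits at ingestion into a stomach-lumen depot (fraction
``FracDOSEHep``), a lymphatic depot (``FracDoseLymph``) and faeces (the
remainder).  Stomach DPHP is taken up directly into venous blood
(``BELLYPERM``) or empties into the first gut section; gut-section DPHP is
absorbed into the portal circulation (``GIPERM1``/``GIPERM2``), metabolised
to MPHP in section 1, and transits to section 2 after a delay ``Gutlag``.
The lymph depot releases into venous blood after ``Lymphlag``, bypassing the
liver.  Liver DPHP undergoes clearance-based metabolism to MPHP and
first-order biliary excretion back to gut section 2 (enterohepatic
recirculation) with a transit delay.  Distribution to adipose, kidney and
rapidly/slowly perfused tissue is flow-limited and driven by the unbound
arterial concentration.

MPHP formed in the gut is absorbed with a fraction ``Escape_gu`` binding in
blood and bypassing the liver; of MPHP formed in the liver a fraction
``Escape_Li`` escapes immediate metabolism into venous blood.  Hepatic MPHP
metabolism feeds the OH-MPHP and cx-MPHP pools (fractions ``FracMetab_MOH``,
``FracMetab_cx``; the remainder is an unmodelled-metabolite sink), which are
cleared into urine by first-order rates, as is kidney MPHP.

All amounts are in mg; the mass-balance audit works in moles via the
molecular masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel as K
from .config import load_defaults
from .errors import InvalidInputError, NumericalFailureError
from .physiology import (
    AnatomySpec,
    BindingSpec,
    MetabolismSpec,
    PartitionTable,
    clearance_from_halflife,
    derive_flows,
    derive_volumes,
    gut_metabolism_rate,
)

__all__ = [
    "ParameterSet",
    "DoseEvent",
    "TimeCourse",
    "initialize_state",
    "derivatives",
    "simulate",
    "mass_balance_error",
    "STATE_NAMES",
    "OBSERVABLE_NAMES",
]

STATE_NAMES = K.STATE_NAMES
OBSERVABLE_NAMES = ("CBlood_DPHP", "CBlood_MPHP", "RUrine_MPHP", "RUrine_OH", "RUrine_cx")


@dataclass
class DoseEvent:
    """A single oral dose: time (h) and amount (mg)."""

    time: float = 0.0
    dose: float = 0.0
    route: str = "oral"

    def validate(self) -> "DoseEvent":
        if self.dose < 0:
            raise InvalidInputError(f"dose must be non-negative, got {self.dose}")
        if self.time < 0:
            raise InvalidInputError(f"dose time must be non-negative, got {self.time}")
        if self.route != "oral":
            raise InvalidInputError(f"only the oral route is modelled, got {self.route!r}")
        return self


@dataclass
class ParameterSet:
    """Full model parameterisation: physiology plus transport/elimination.

    Embeds the physiological sub-records and carries the uptake, routing and
    elimination constants.  ``pack()`` assembles the flat vector the compiled
    kernel consumes (deriving volumes, flows and clearances on the way).
    """

    anatomy: AnatomySpec = field(default_factory=AnatomySpec)
    partitions: PartitionTable = field(default_factory=PartitionTable)
    binding: BindingSpec = field(default_factory=BindingSpec)
    metabolism: MetabolismSpec = field(default_factory=MetabolismSpec)
    # uptake / transport
    FracDOSEHep: float = 0.202
    FracDoseLymph: float = 0.075
    BELLYPERM: float = 3.72
    GIPERM1: float = 4.98
    GIPERM2: float = 15.17
    Gutlag: float = 2.51
    k_transit: float = 1.0
    k_st_gut: float = 2.0
    Lymphlag: float = 3.50
    K1_Lymph: float = 1.53
    K1_DPHP_Liver: float = 10.0
    bile_delay: float = 1.0
    k_abs_MPHP_gut: float = 2.0
    # escape / metabolite routing
    Escape_gu: float = 0.5
    Escape_Li: float = 0.5
    FracMetab_MOH: float = 0.35
    FracMetab_cx: float = 0.03
    # elimination
    K1_MPHP: float = 2.52
    K1_MOH: float = 2.52
    K1_cx: float = 2.52
    # molecular masses (g/mol)
    MW_DPHP: float = 446.67
    MW_MPHP: float = 306.40
    MW_OH_MPHP: float = 322.40
    MW_cx_MPHP: float = 336.38
    # numerics
    hs_width: float = 0.01

    _FRACTION_FIELDS = (
        "FracDOSEHep", "FracDoseLymph", "Escape_gu", "Escape_Li",
        "FracMetab_MOH", "FracMetab_cx",
    )
    _RATE_FIELDS = (
        "BELLYPERM", "GIPERM1", "GIPERM2", "Gutlag", "k_transit", "k_st_gut",
        "Lymphlag", "K1_Lymph", "K1_DPHP_Liver", "bile_delay",
        "k_abs_MPHP_gut", "K1_MPHP", "K1_MOH", "K1_cx",
    )

    def validate(self, strict: bool = True) -> "ParameterSet":
        self.anatomy.validate(strict=strict)
        self.partitions.validate()
        self.binding.validate()
        self.metabolism.validate()
        for f in self._FRACTION_FIELDS:
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{f} must lie in [0, 1], got {v}")
        if self.FracDOSEHep + self.FracDoseLymph > 1.0 + 1e-12:
            raise InvalidInputError(
                "FracDOSEHep + FracDoseLymph exceeds 1: "
                f"{self.FracDOSEHep} + {self.FracDoseLymph}"
            )
        if self.FracMetab_MOH + self.FracMetab_cx > 1.0 + 1e-12:
            raise InvalidInputError("FracMetab_MOH + FracMetab_cx exceeds 1")
        for f in self._RATE_FIELDS:
            if getattr(self, f) < 0:
                raise InvalidInputError(f"{f} must be non-negative")
        if self.bile_delay <= 0:
            raise InvalidInputError("bile_delay must be positive")
        return self

    # -- construction -------------------------------------------------------
    @classmethod
    def from_config(cls, cfg: dict | None = None, strict: bool = True) -> "ParameterSet":
        """Build from a flat configuration mapping (bundled defaults if None)."""
        if cfg is None:
            cfg = load_defaults()
        ps = cls(
            anatomy=AnatomySpec.from_config(cfg, strict=strict),
            partitions=PartitionTable.from_config(cfg),
            binding=BindingSpec.from_config(cfg),
            metabolism=MetabolismSpec.from_config(cfg),
        )
        for f in (
            *cls._FRACTION_FIELDS, *cls._RATE_FIELDS,
            "MW_DPHP", "MW_MPHP", "MW_OH_MPHP", "MW_cx_MPHP", "hs_width",
        ):
            if f in cfg:
                setattr(ps, f, float(cfg[f]))
        return ps.validate(strict=strict)

    def with_overrides(self, overrides: dict, strict: bool = False) -> "ParameterSet":
        """Copy with named parameters replaced.

        Names follow the calibration symbol set: fields of this class, of the
        physiological sub-records, and the aliases ``DPHP_half_life`` /
        ``DPHP_GUT_half_life`` (for the in-vitro / gut half-lives) and ``BW``.
        """
        ps = replace(
            self,
            anatomy=replace(self.anatomy),
            partitions=replace(self.partitions),
            binding=replace(self.binding),
            metabolism=replace(self.metabolism),
        )
        alias = {"DPHP_half_life": "T_half_DPHP", "DPHP_GUT_half_life": "T_half_DPHP_gut",
                 "T_half_MPHP": "T_half_MPHP"}
        for name, value in overrides.items():
            name = alias.get(name, name)
            placed = False
            for obj in (ps, ps.anatomy, ps.partitions, ps.binding, ps.metabolism):
                if hasattr(obj, name):
                    setattr(obj, name, float(value))
                    placed = True
                    break
            if not placed:
                raise InvalidInputError(f"unknown parameter name {name!r}")
        return ps.validate(strict=strict)

    # -- kernel interface ----------------------------------------------------
    def pack(self) -> np.ndarray:
        """Assemble the flat parameter vector for the compiled kernel."""
        vols = derive_volumes(self.anatomy)
        flows = derive_flows(self.anatomy, check_sum=False)
        liver_g = vols["liver"] * 1000.0  # 1 kg/L tissue density
        met = self.metabolism
        cl_d = clearance_from_halflife(
            met.T_half_DPHP, met.MPY, liver_g, met.incubation_protein_conc
        )
        cl_m = clearance_from_halflife(
            met.T_half_MPHP, met.MPY, liver_g, met.incubation_protein_conc
        )
        k_gut = gut_metabolism_rate(met.T_half_DPHP_gut, met.MPYgu, met.MPYgu_default)
        pt = self.partitions
        p = np.empty(K.NP)
        p[K.P_V_LI] = vols["liver"]
        p[K.P_V_FA] = vols["adipose"]
        p[K.P_V_KI] = vols["kidney"]
        p[K.P_V_RPD] = vols["rapidly_perfused"]
        p[K.P_V_SPD] = vols["slowly_perfused"]
        p[K.P_V_BLD] = vols["blood"]
        p[K.P_Q_HEPART] = flows["hepatic_artery"]
        p[K.P_Q_KI] = flows["kidney"]
        p[K.P_Q_FA] = flows["adipose"]
        p[K.P_Q_GU] = flows["gut"]
        p[K.P_Q_ST] = flows["stomach"]
        p[K.P_Q_SPD] = flows["slowly_perfused"]
        p[K.P_Q_RPD] = flows["rapidly_perfused"]
        p[K.P_FU_D] = self.binding.fu_DPHP
        p[K.P_FU_M] = self.binding.fu_MPHP
        p[K.P_PFA_D] = pt.Pfab
        p[K.P_PKI_D] = pt.Pkib
        p[K.P_PLI_D] = pt.Plib
        p[K.P_PRPD_D] = pt.Prpdb
        p[K.P_PSPD_D] = pt.Pspdb
        p[K.P_PFA_M] = pt.PfaM
        p[K.P_PKI_M] = pt.PkiM
        p[K.P_PLI_M] = pt.PliM
        p[K.P_PRPD_M] = pt.PrpdM
        p[K.P_PSPD_M] = pt.PspdM
        p[K.P_CL_D] = cl_d
        p[K.P_CL_M] = cl_m
        p[K.P_K_GUT] = k_gut
        p[K.P_BELLYPERM] = self.BELLYPERM
        p[K.P_K_ST_GUT] = self.k_st_gut
        p[K.P_GIPERM1] = self.GIPERM1
        p[K.P_GIPERM2] = self.GIPERM2
        p[K.P_K_TRANSIT] = self.k_transit
        p[K.P_GUTLAG] = self.Gutlag
        p[K.P_K1_LYMPH] = self.K1_Lymph
        p[K.P_LYMPHLAG] = self.Lymphlag
        p[K.P_K1_DPHP_LIVER] = self.K1_DPHP_Liver
        p[K.P_K_BILE] = 1.0 / self.bile_delay
        p[K.P_K_ABS_MPHP] = self.k_abs_MPHP_gut
        p[K.P_ESCAPE_GU] = self.Escape_gu
        p[K.P_ESCAPE_LI] = self.Escape_Li
        p[K.P_FRAC_MOH] = self.FracMetab_MOH
        p[K.P_FRAC_CX] = self.FracMetab_cx
        p[K.P_K1_MPHP] = self.K1_MPHP
        p[K.P_K1_MOH] = self.K1_MOH
        p[K.P_K1_CX] = self.K1_cx
        p[K.P_R_MD] = self.MW_MPHP / self.MW_DPHP
        p[K.P_R_OM] = self.MW_OH_MPHP / self.MW_MPHP
        p[K.P_R_CM] = self.MW_cx_MPHP / self.MW_MPHP
        p[K.P_HS_WIDTH] = self.hs_width
        return p


@dataclass
class TimeCourse:
    """Solver output: states and derived observables on a time grid.

    ``states`` has one row per time, columns :data:`STATE_NAMES` (mg);
    ``observables`` columns :data:`OBSERVABLE_NAMES` (blood concentrations in
    mg/L, urinary deposition rates in mg/h).
    """

    t: np.ndarray
    states: np.ndarray
    observables: np.ndarray

    def obs(self, name: str) -> np.ndarray:
        return self.observables[:, OBSERVABLE_NAMES.index(name)]

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def at(self, name: str, time: float) -> float:
        """Linear interpolation of an observable at an arbitrary time."""
        return float(np.interp(time, self.t, self.obs(name)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        for i, name in enumerate(OBSERVABLE_NAMES):
            df[name] = self.observables[:, i]
        df.insert(0, "time_h", self.t)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeCourse":
        df = pd.read_csv(path)
        t = df["time_h"].to_numpy(float)
        states = df[list(STATE_NAMES)].to_numpy(float)
        observables = df[list(OBSERVABLE_NAMES)].to_numpy(float)
        return cls(t=t, states=states, observables=observables)


def initialize_state(dose: DoseEvent, params: ParameterSet) -> np.ndarray:
    """Initial state: dose split between stomach, lymph depot and faeces."""
    dose.validate()
    fh, fl = params.FracDOSEHep, params.FracDoseLymph
    if fh + fl > 1.0 + 1e-12:
        raise InvalidInputError("FracDOSEHep + FracDoseLymph exceeds 1")
    y0 = np.zeros(K.NSTATE)
    y0[K.S_ST] = fh * dose.dose
    y0[K.S_LYMPH] = fl * dose.dose
    y0[K.S_FAECES] = (1.0 - fh - fl) * dose.dose
    return y0


def derivatives(t: float, state: np.ndarray, params: ParameterSet) -> np.ndarray:
    """State rate-of-change (mg/h) at time ``t``; thin wrapper on the kernel."""
    if t < 0:
        raise InvalidInputError(f"time must be non-negative, got {t}")
    y = np.asarray(state, dtype=float)
    if y.shape != (K.NSTATE,):
        raise InvalidInputError(f"state must have {K.NSTATE} components")
    dy = np.zeros(K.NSTATE)
    K.rhs(float(t), y, params.pack(), dy)
    return dy


def _observables_from_states(states: np.ndarray, p: np.ndarray) -> np.ndarray:
    obs = np.empty((states.shape[0], 5))
    obs[:, 0] = states[:, K.S_BLD] / p[K.P_V_BLD]
    obs[:, 1] = states[:, K.S_BLDM] / p[K.P_V_BLD]
    obs[:, 2] = p[K.P_K1_MPHP] * states[:, K.S_KIM]
    obs[:, 3] = p[K.P_K1_MOH] * states[:, K.S_OH]
    obs[:, 4] = p[K.P_K1_CX] * states[:, K.S_CX]
    return obs


def simulate(
    params: ParameterSet,
    dose: DoseEvent,
    t_grid: np.ndarray,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-9,
) -> TimeCourse:
    """Integrate the model from the dose event over ``t_grid``.

    ``t_grid`` must be strictly increasing and start at or after the dose
    time.  Deterministic for fixed inputs and tolerances.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise InvalidInputError("t_grid must be a 1-D array with at least two times")
    if np.any(np.diff(t_grid) <= 0):
        raise InvalidInputError("t_grid must be strictly increasing")
    if t_grid[0] < dose.time:
        raise InvalidInputError(
            f"t_grid starts at {t_grid[0]} before the dose time {dose.time}"
        )
    if rel_tol <= 0 or abs_tol <= 0:
        raise InvalidInputError("tolerances must be positive")
    y0 = initialize_state(dose, params)
    p = params.pack()
    states, status, t_fail = K.integrate(p, y0, t_grid, rel_tol, abs_tol)
    if status != 0:
        reason = "step-size collapse" if status == 1 else "non-finite state"
        raise NumericalFailureError(
            f"ODE integration failed ({reason}) at t = {t_fail:.4f} h"
        )
    return TimeCourse(t=t_grid, states=states, observables=_observables_from_states(states, p))


def mass_balance_error(tc: TimeCourse, params: ParameterSet, dose: DoseEvent) -> float:
    """Maximum relative molar-mass-balance error over the time course.

    Sums all compartments plus the cumulative urine, faeces and
    other-metabolite pools in moles and compares with the dose in moles.
    Defined as 0 for a zero dose.
    """
    if dose.dose == 0:
        return 0.0
    s = tc.states
    mw_d, mw_m = params.MW_DPHP, params.MW_MPHP
    mw_oh, mw_cx = params.MW_OH_MPHP, params.MW_cx_MPHP
    moles = (
        s[:, [K.S_ST, K.S_GUT1, K.S_GUT2, K.S_LYMPH, K.S_BILE, K.S_LI, K.S_FA,
              K.S_KI, K.S_RPD, K.S_SPD, K.S_BLD, K.S_FAECES]].sum(axis=1) / mw_d
        + s[:, [K.S_GUTM, K.S_LIM, K.S_FAM, K.S_KIM, K.S_RPDM, K.S_SPDM,
                K.S_BLDM, K.S_URINEM, K.S_OTHER]].sum(axis=1) / mw_m
        + s[:, [K.S_OH, K.S_URINEOH]].sum(axis=1) / mw_oh
        + s[:, [K.S_CX, K.S_URINECX]].sum(axis=1) / mw_cx
    )
    return float(np.max(np.abs(moles / (dose.dose / mw_d) - 1.0)))
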