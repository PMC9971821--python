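"""Physiological parameterisation of the DPHP/MPHP PBPK model.

Turns body weight, tissue volume fractions, cardiac-output flow fractions,
tissue:blood partition coefficients, blood protein binding and in-vitro
metabolic half-lives into the volumes (L), blood flows (L/h) and intrinsic
clearances (L/h) that the ODE system consumes.

Conventions
-----------
* Tissue density is taken as 1 kg/L, so a volume fraction of body weight maps
  directly to litres.
* Cardiac output scales allometrically, ``QC = QCC * BW**0.75`` with the
  exponent exposed in configuration; linear scaling of the coefficient would
  give an implausible ~1000 L/h for a 72 kg adult.
* In-vitro substrate-depletion half-lives are scaled to whole-organ intrinsic
  clearance with the standard microsomal scale-up:
  ``CLint = (ln2 / T_half) / C_protein * MPY * organ_mass``
  converted from µL/min to L/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "AnatomySpec",
    "PartitionTable",
    "BindingSpec",
    "MetabolismSpec",
    "derive_volumes",
    "derive_flows",
    "clearance_from_halflife",
    "gut_metabolism_rate",
]

_VOLUME_KEYS = ("VLiC", "VKiC", "VFaC", "VGuC", "VStC", "VSpdC", "VRpdC", "VBldC")
_FLOW_KEYS = ("QHepartC", "QKiC", "QFaC", "QGuC", "QStC", "QSpdC", "QRpdC")

#: organ name used in the returned mappings, per fraction key
_ORGAN_OF_VOLUME = {
    "VLiC": "liver", "VKiC": "kidney", "VFaC": "adipose", "VGuC": "gut",
    "VStC": "stomach", "VSpdC": "slowly_perfused", "VRpdC": "rapidly_perfused",
    "VBldC": "blood",
}
_ORGAN_OF_FLOW = {
    "QHepartC": "hepatic_artery", "QKiC": "kidney", "QFaC": "adipose",
    "QGuC": "gut", "QStC": "stomach", "QSpdC": "slowly_perfused",
    "QRpdC": "rapidly_perfused",
}


@dataclass
class AnatomySpec:
    """Body weight plus volume- and flow-fraction allocation.

    Volume fractions are fractions of body weight; flow fractions are
    fractions of cardiac output.  ``validate(strict=True)`` additionally
    enforces the bookkeeping invariants (volume sum within the vascularised
    total, flow sum within [0.95, 1.05]); prior-sampled specs are checked
    non-strictly because independent marginal priors do not honour the sum
    constraints draw by draw.
    """

    BW: float = 72.3
    VLiC: float = 0.0309
    VKiC: float = 0.0058
    VFaC: float = 0.195
    VGuC: float = 0.015
    VStC: float = 0.0022
    VSpdC: float = 0.607
    VRpdC: float = 0.0371
    VBldC: float = 0.05
    VT: float = 0.95
    QCC: float = 14.0
    QHepartC: float = 0.069
    QKiC: float = 0.20
    QFaC: float = 0.05
    QGuC: float = 0.149
    QStC: float = 0.011
    QSpdC: float = 0.287
    QRpdC: float = 0.23
    allometric_exponent: float = 0.75

    def validate(self, strict: bool = True) -> "AnatomySpec":
        if not self.BW > 0:
            raise InvalidInputError(f"body weight must be positive, got {self.BW}")
        for key in _VOLUME_KEYS + _FLOW_KEYS:
            v = getattr(self, key)
            if not 0.0 < v < 1.0:
                raise InvalidInputError(f"{key} must lie in (0, 1), got {v}")
        if strict:
            vsum = sum(getattr(self, k) for k in _VOLUME_KEYS)
            if vsum > self.VT + 1e-12:
                raise ConfigurationError(
                    f"volume fractions sum to {vsum:.4f} > vascularised total VT={self.VT}"
                )
            qsum = sum(getattr(self, k) for k in _FLOW_KEYS)
            if not 0.95 <= qsum <= 1.05:
                raise ConfigurationError(
                    f"flow fractions sum to {qsum:.4f}, outside [0.95, 1.05]"
                )
        return self

    @classmethod
    def from_config(cls, cfg: dict, strict: bool = True) -> "AnatomySpec":
        kwargs = {f: cfg[f] for f in (
            "BW", "VT", "QCC", *_VOLUME_KEYS, *_FLOW_KEYS) if f in cfg}
        if "allometric_exponent" in cfg:
            kwargs["allometric_exponent"] = cfg["allometric_exponent"]
        return cls(**kwargs).validate(strict=strict)


@dataclass
class PartitionTable:
    """Tissue:blood partition coefficients for DPHP and MPHP.

    Stomach, rapidly and slowly perfused entries are surrogates for gut,
    spleen and muscle respectively when built from defaults.  The plasma and
    gut coefficients are carried because they are named calibration symbols,
    but they do not enter the lumped-blood / lumen-only gut dynamics.
    """

    # DPHP ("b" suffix in the calibration symbol set)
    Pbab: float = 15.5
    Pfab: float = 63.4
    Plib: float = 5.89
    Pkib: float = 5.89
    Pmub: float = 3.29
    Prbb: float = 3.01
    Pgub: float = 7.4
    Pspb: float = 3.7
    Pstb: float = 7.4
    Prpdb: float = 3.7
    Pspdb: float = 3.29
    # MPHP
    PbaM: float = 25.23
    PfaM: float = 29.10
    PliM: float = 54.8
    PkiM: float = 15.5
    PmuM: float = 7.51
    PrbM: float = 6.67
    PguM: float = 25.2
    PspM: float = 12.20
    PstM: float = 25.2
    PrpdM: float = 12.20
    PspdM: float = 7.51
    LogPow_DPHP: float = 10.83
    LogPow_MPHP: float = 5.3

    def validate(self) -> "PartitionTable":
        for f in self.__dataclass_fields__:
            if f.startswith("P") and getattr(self, f) <= 0:
                raise InvalidInputError(f"partition coefficient {f} must be > 0")
        return self

    @classmethod
    def from_config(cls, cfg: dict) -> "PartitionTable":
        kwargs = {f: cfg[f] for f in cls.__dataclass_fields__ if f in cfg}
        return cls(**kwargs).validate()


@dataclass
class BindingSpec:
    """Bound fractions of DPHP and MPHP in arterial blood.

    Only the unbound fraction ``fu = 1 - FB`` is available for distribution
    to tissues and for metabolism.
    """

    FB_DPHP: float = 0.9975
    FB_MPHP: float = 0.9854

    def validate(self) -> "BindingSpec":
        for f in ("FB_DPHP", "FB_MPHP"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{f} must lie in [0, 1], got {v}")
        return self

    @property
    def fu_DPHP(self) -> float:
        return 1.0 - self.FB_DPHP

    @property
    def fu_MPHP(self) -> float:
        return 1.0 - self.FB_MPHP

    @classmethod
    def from_config(cls, cfg: dict) -> "BindingSpec":
        return cls(FB_DPHP=cfg["FB_DPHP"], FB_MPHP=cfg["FB_MPHP"]).validate()


@dataclass
class MetabolismSpec:
    """In-vitro half-lives and microsomal protein yields.

    ``T_half_DPHP`` / ``T_half_MPHP`` are in-vitro hepatic substrate-depletion
    half-lives (min); ``T_half_DPHP_gut`` is the in-vivo gut half-life (min).
    ``MPY`` / ``MPYgu`` are microsomal protein yields (mg per g of organ).
    """

    T_half_DPHP: float = 3.0
    T_half_MPHP: float = 8.05
    T_half_DPHP_gut: float = 60.0
    MPY: float = 34.0
    MPYgu: float = 3.9
    MPYgu_default: float = 3.9
    incubation_protein_conc: float = 1.0

    def validate(self) -> "MetabolismSpec":
        for f in self.__dataclass_fields__:
            if getattr(self, f) <= 0:
                raise InvalidInputError(f"{f} must be strictly positive")
        return self

    @classmethod
    def from_config(cls, cfg: dict) -> "MetabolismSpec":
        return cls(
            T_half_DPHP=cfg["T_half_DPHP"],
            T_half_MPHP=cfg["T_half_MPHP"],
            T_half_DPHP_gut=cfg["T_half_DPHP_gut"],
            MPY=cfg["MPY"],
            MPYgu=cfg["MPYgu"],
            MPYgu_default=cfg.get("MPYgu_default", cfg["MPYgu"]),
            incubation_protein_conc=cfg["incubation_protein_conc"],
        ).validate()


def derive_volumes(anatomy: AnatomySpec) -> dict[str, float]:
    """Compartment volumes (L) from body weight and volume fractions.

    Tissue density is taken as 1 kg/L, so ``V_organ = fraction * BW``.
    """
    if not anatomy.BW > 0:
        raise InvalidInputError(f"body weight must be positive, got {anatomy.BW}")
    return {
        _ORGAN_OF_VOLUME[k]: getattr(anatomy, k) * anatomy.BW for k in _VOLUME_KEYS
    }


def derive_flows(anatomy: AnatomySpec, check_sum: bool = True) -> dict[str, float]:
    """Organ blood flows (L/h) plus cardiac output and derived aggregates.

    ``QC = QCC * BW**exponent`` (allometric, exponent 0.75 by default).
    Portal flow is the gut+stomach flow; total liver outflow is hepatic
    artery + portal.  With ``check_sum`` the flow fractions must sum within
    [0.95, 1.05]; prior-sampled specs pass ``check_sum=False`` because the
    venous return is computed as the sum of tissue outflows, which keeps any
    allocation internally mass-consistent.
    """
    if not anatomy.BW > 0:
        raise InvalidInputError(f"body weight must be positive, got {anatomy.BW}")
    if check_sum:
        qsum = sum(getattr(anatomy, k) for k in _FLOW_KEYS)
        if not 0.95 <= qsum <= 1.05:
            raise ConfigurationError(
                f"flow fractions sum to {qsum:.4f}, outside [0.95, 1.05]"
            )
    qc = anatomy.QCC * anatomy.BW ** anatomy.allometric_exponent
    flows = {_ORGAN_OF_FLOW[k]: getattr(anatomy, k) * qc for k in _FLOW_KEYS}
    flows["cardiac_output"] = qc
    flows["portal"] = flows["gut"] + flows["stomach"]
    flows["liver_total"] = flows["hepatic_artery"] + flows["portal"]
    return flows


def clearance_from_halflife(
    T_half: float,
    MPY: float,
    organ_mass: float,
    incubation_protein_conc: float = 1.0,
) -> float:
    """Whole-organ intrinsic clearance (L/h) from an in-vitro half-life.

    Standard substrate-depletion scale-up:
    per-mg clearance ``(ln2 / T_half) * 1000 / C_protein`` (µL min^-1 mg^-1)
    multiplied by microsomal protein yield (mg/g) and organ mass (g), then
    converted µL/min -> L/h.

    Parameters
    ----------
    T_half:
        In-vitro substrate-depletion half-life, minutes.
    MPY:
        Microsomal protein yield, mg per g organ.
    organ_mass:
        Organ mass in grams.
    incubation_protein_conc:
        Protein concentration of the in-vitro incubation, mg/mL.
    """
    if T_half <= 0:
        raise InvalidInputError(f"half-life must be positive, got {T_half}")
    if MPY <= 0 or organ_mass <= 0 or incubation_protein_conc <= 0:
        raise InvalidInputError("MPY, organ mass and protein concentration must be positive")
    clint_per_mg = (math.log(2.0) / T_half) * 1000.0 / incubation_protein_conc
    return clint_per_mg * MPY * organ_mass * 60.0 * 1e-6


def gut_metabolism_rate(
    T_half_DPHP_gut: float, MPYgu: float, MPYgu_default: float
) -> float:
    """First-order DPHP -> MPHP rate in gut section 1 (h^-1).

    ``k = (ln2 / T_half_gut) * 60 * (MPYgu / MPYgu_default)`` — the in-vivo
    gut half-life sets the baseline rate and the gut microsomal protein yield
    scales it multiplicatively around its default.  ``MPYgu = 0`` is allowed
    and switches gut metabolism off.
    """
    if T_half_DPHP_gut <= 0:
        raise InvalidInputError(f"gut half-life must be positive, got {T_half_DPHP_gut}")
    if MPYgu_default <= 0:
        raise ConfigurationError("default gut microsomal protein yield must be positive")
    if MPYgu < 0:
        raise InvalidInputError(f"MPYgu must be non-negative, got {MPYgu}")
    return (math.log(2.0) / T_half_DPHP_gut) * 60.0 * (MPYgu / MPYgu_default)
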