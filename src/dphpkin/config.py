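"""Baseline configuration: bundled defaults and study-design constants.

The bundled ``data/defaults.yaml`` reproduces the model's published default
parameterisation (partition coefficients, physiological fractions, binding,
metabolic half-lives) with percent entries stored as printed; :func:`load_defaults`
converts them to the fractions the model consumes.  ``data/volunteers.csv``
carries the six-volunteer study table (body weights, doses, urinary recovery
fractions).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError

# Keys stored as percentages in the flat configuration file.
_PERCENT_KEYS = frozenset(
    {
        "VLiC", "VKiC", "VFaC", "VGuC", "VStC", "VSpdC", "VRpdC", "VBldC",
        "QHepartC", "QKiC", "QFaC", "QGuC", "QStC", "QSpdC", "QRpdC",
        "FB_DPHP", "FB_MPHP",
    }
)

#: Blood-sampling schedule of the volunteer study (hours after ingestion).
BLOOD_SCHEDULE = (0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 10.0, 24.0)

#: Urine-void schedule of the volunteer study (hours after ingestion).
URINE_SCHEDULE = (
    1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 14.0,
    18.0, 22.0, 26.0, 30.0, 34.0, 38.0, 42.0, 46.0,
)

#: Mean study dose (mg per kg body weight), used where no volunteer is singled out.
MEAN_STUDY_DOSE = 0.738

#: Calibrated global-parameter central estimates (posterior medians).  Used as
#: the default "truth" for synthetic-study generation and as chain start points.
GLOBAL_POSTERIOR_MEDIANS = {
    "FB_DPHP": 0.987,
    "FB_MPHP": 0.945,
    "DPHP_GUT_half_life": 42.72,
    "DPHP_half_life": 7.73,
    "Pbab": 18.17,
    "Pgub": 31.99,
    "Plib": 2.03,
    "PbaM": 36.86,
    "PliM": 6.28,
    "PguM": 16.89,
    "PkiM": 4.08,
    "K1_MPHP": 0.72,
    "K1_MOH": 2.69,
    "K1_cx": 1.64,
    "FracMetab_MOH": 0.221,
    "FracMetab_cx": 0.010,
    "Escape_gu": 0.59,
    "Escape_Li": 0.59,
}

#: Calibrated residual-error standard deviations (posterior medians), on the
#: observation scales (mg/L for blood, mg/h for urinary deposition rates).
#: These are the study-condition noise levels of the synthetic generator.
ERROR_SD_POSTERIOR_MEDIANS = {
    "sigma_DPHP_B": 0.0048,
    "sigma_MPHP_B": 0.017,
    "sigma_MPHP_U": 0.0017,
    "sigma_OH_U": 0.0085,
    "sigma_cx_U": 0.00042,
}

#: Calibrated volunteer-specific (local) central estimates, per retained
#: volunteer.  VGuC for volunteer A is printed as 0.17 in the source table,
#: inconsistent with its prior support (0.010, 0.020); read as 0.017.
LOCAL_POSTERIOR_MEDIANS = {
    "A": {
        "K1_DPHP_Liver": 0.703, "FracDOSEHep": 0.221, "BELLYPERM": 0.329,
        "GIPERM1": 1.79, "GIPERM2": 0.75, "Gutlag": 2.99,
        "FracDoseLymph": 0.021, "Lymphlag": 6.47, "K1_Lymph": 2.58,
        "MPY": 30.97, "MPYgu": 0.525, "VBldC": 0.04, "VLiC": 0.018,
        "VGuC": 0.017, "VKiC": 0.0059, "QGuC": 0.19,
    },
    "B": {
        "K1_DPHP_Liver": 5.99, "FracDOSEHep": 0.054, "BELLYPERM": 0.67,
        "GIPERM1": 3.77, "GIPERM2": 14.64, "Gutlag": 1.81,
        "FracDoseLymph": 0.002, "Lymphlag": 3.88, "K1_Lymph": 1.01,
        "MPY": 36.79, "MPYgu": 1.73, "VBldC": 0.05, "VLiC": 0.032,
        "VGuC": 0.015, "VKiC": 0.006, "QGuC": 0.16,
    },
    "D": {
        "K1_DPHP_Liver": 3.37, "FracDOSEHep": 0.036, "BELLYPERM": 0.57,
        "GIPERM1": 2.54, "GIPERM2": 17.13, "Gutlag": 2.57,
        "FracDoseLymph": 0.009, "Lymphlag": 3.60, "K1_Lymph": 0.46,
        "MPY": 39.05, "MPYgu": 2.49, "VBldC": 0.054, "VLiC": 0.033,
        "VGuC": 0.013, "VKiC": 0.0047, "QGuC": 0.17,
    },
    "F": {
        "K1_DPHP_Liver": 5.18, "FracDOSEHep": 0.103, "BELLYPERM": 2.75,
        "GIPERM1": 7.54, "GIPERM2": 19.50, "Gutlag": 2.16,
        "FracDoseLymph": 0.010, "Lymphlag": 2.99, "K1_Lymph": 0.69,
        "MPY": 39.17, "MPYgu": 4.66, "VBldC": 0.048, "VLiC": 0.033,
        "VGuC": 0.011, "VKiC": 0.006, "QGuC": 0.22,
    },
}

#: Volunteers retained for calibration after the consistency screen.
RETAINED_VOLUNTEERS = ("A", "B", "D", "F")


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("dphpkin") / "data" / name))


def load_defaults(path: str | Path | None = None) -> dict:
    """Load the flat key/value defaults file and normalise units.

    Percent entries (volume/flow fractions, protein binding) are divided by
    100 so every downstream consumer sees fractions.

    Parameters
    ----------
    path:
        Optional alternative configuration file; defaults to the bundled one.
    """
    p = Path(path) if path is not None else _data_path("defaults.yaml")
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"configuration file {p} did not parse to a mapping")
    out = {}
    for key, value in raw.items():
        if not isinstance(value, (int, float)):
            raise ConfigurationError(f"configuration key {key!r} is not numeric: {value!r}")
        out[key] = value / 100.0 if key in _PERCENT_KEYS else float(value)
    return out


def volunteer_table(path: str | Path | None = None) -> pd.DataFrame:
    """The six-volunteer study table (id, body weight, dose, recovery fractions)."""
    p = Path(path) if path is not None else _data_path("volunteers.csv")
    df = pd.read_csv(p, dtype={"id": str})
    df = df.set_index("id", drop=False)
    return df
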