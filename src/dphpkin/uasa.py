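"""Uncertainty analysis and Morris sensitivity screening.

Implements the model-testing stage: a maximin Latin hypercube design over
the model's prior distributions, a plausibility (rejection) filter on the
simulated blood MPHP profile — peak within [0.025, 0.3] mg/L and the 48-h
concentration at most 0.025 mg/L — and Morris elementary-effects screening
of blood MPHP concentration and urinary MPHP deposition rate at 0.5 h and
3 h after ingestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .config import MEAN_STUDY_DOSE
from .errors import InvalidInputError
from .pbpk import DoseEvent, ParameterSet, TimeCourse, simulate
from .priors import PriorSpec, fit_prior_from_summary, sample_prior  # noqa: F401  (re-export)

__all__ = [
    "DesignMatrix",
    "lhs_maximin",
    "rejection_filter",
    "morris_screen",
    "MorrisResult",
    "build_ua_priors",
    "simulate_design",
    "run_uncertainty_analysis",
    "PEAK_BAND",
    "END_CEILING",
]

#: plausibility band for peak blood MPHP (mg/L)
PEAK_BAND = (0.025, 0.3)
#: ceiling for blood MPHP at 48 h (mg/L)
END_CEILING = 0.025


@dataclass
class DesignMatrix:
    """n x d design in natural units plus its unit-cube (rank-space) sample."""

    df: pd.DataFrame
    provenance: str
    seed: int
    unit: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.df)

    def row_overrides(self, i: int) -> dict:
        return {k: float(v) for k, v in self.df.iloc[i].items()}


def _lhs_unit(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """One Latin hypercube sample in [0,1]^d: a jittered permutation per column."""
    u = np.empty((n, d))
    for j in range(d):
        u[:, j] = (rng.permutation(n) + rng.uniform(size=n)) / n
    return u


def lhs_maximin(
    priors: list[PriorSpec],
    n: int,
    seed: int,
    n_candidates: int = 100,
) -> DesignMatrix:
    """Maximin Latin hypercube design over the priors.

    Among ``n_candidates`` random Latin hypercubes the one maximising the
    minimum pairwise Euclidean distance in the unit cube is kept; marginals
    are then transformed through each prior's (truncated) quantile function.
    """
    if n < 2:
        raise InvalidInputError("a Latin hypercube design needs n >= 2")
    if n_candidates < 1:
        raise InvalidInputError("need at least one candidate design")
    rng = np.random.default_rng(seed)
    d = len(priors)
    best, best_crit = None, -np.inf
    for _ in range(n_candidates):
        u = _lhs_unit(n, d, rng)
        crit = pdist(u).min()
        if crit > best_crit:
            best, best_crit = u, crit
    cols = {spec.name: spec.ppf(best[:, j]) for j, spec in enumerate(priors)}
    return DesignMatrix(df=pd.DataFrame(cols), provenance="LHS", seed=seed, unit=best)


def rejection_filter(
    design: DesignMatrix | None,
    simulations: list[TimeCourse],
    peak_band: tuple[float, float] = PEAK_BAND,
    end_time: float = 48.0,
    end_ceiling: float = END_CEILING,
) -> np.ndarray:
    """Indices of simulations passing the blood-MPHP plausibility screen.

    Retained iff the peak blood MPHP concentration lies within ``peak_band``
    and the concentration at ``end_time`` does not exceed ``end_ceiling``.
    """
    if design is not None and len(simulations) != design.n:
        raise InvalidInputError("one simulation per design row is required")
    retained = []
    for i, tc in enumerate(simulations):
        if tc.t[-1] < end_time:
            raise InvalidInputError(
                f"simulation {i} ends at {tc.t[-1]} h, before the {end_time}-h check"
            )
        c = tc.obs("CBlood_MPHP")
        peak = float(c.max())
        c_end = tc.at("CBlood_MPHP", end_time)
        if peak_band[0] <= peak <= peak_band[1] and c_end <= end_ceiling:
            retained.append(i)
    return np.asarray(retained, dtype=int)


# --- Morris elementary-effects screening -------------------------------------

@dataclass
class MorrisResult:
    """Per-output tables of mu* (mean |elementary effect|) and sigma."""

    tables: dict[str, pd.DataFrame]
    n_runs: int
    n_excluded: int

    def ranking(self, output: str) -> list[str]:
        return list(self.tables[output].sort_values("mu_star", ascending=False).index)


def morris_screen(
    priors: list[PriorSpec],
    model,
    r: int,
    seed: int,
    levels: int = 4,
    q_clip: float = 0.0,
) -> MorrisResult:
    """Morris one-at-a-time screening with ``r`` trajectories.

    Each trajectory evaluates the model at ``k + 1`` points differing in one
    coordinate by the standard jump ``delta = levels / (2 (levels - 1))`` on a
    ``levels``-level grid in the unit cube (coordinates mapped to natural
    units through the priors' quantile functions).  ``model`` maps a
    parameter-name dict to a dict of scalar outputs.  Runs with non-finite
    outputs are excluded with a warning.  ``q_clip > 0`` truncates each
    prior to its (q_clip, 1 - q_clip) quantile range so grid endpoints stay
    inside open supports (a half-normal's 0th percentile is 0, which a
    positive-rate parameter cannot take).
    """
    if r < 2:
        raise InvalidInputError("Morris screening needs r >= 2 trajectories")
    rng = np.random.default_rng(seed)
    k = len(priors)
    delta = levels / (2.0 * (levels - 1))
    grid = np.arange(levels) / (levels - 1)
    base_grid = grid[grid <= 1.0 - delta + 1e-12]

    effects: dict[str, dict[str, list[float]]] = {}
    n_runs = 0
    n_excluded = 0

    def _eval(u_point):
        nonlocal n_runs
        n_runs += 1
        uq = q_clip + (1.0 - 2.0 * q_clip) * u_point
        values = {spec.name: float(spec.ppf(uq[j])) for j, spec in enumerate(priors)}
        return model(values)

    for _ in range(r):
        lo = rng.choice(base_grid, size=k)
        start_high = rng.integers(0, 2, size=k).astype(bool)
        order = rng.permutation(k)
        u = np.where(start_high, lo + delta, lo)
        f_prev = _eval(u)
        for dim in order:
            sign = -1.0 if start_high[dim] else 1.0
            u = u.copy()
            u[dim] += sign * delta
            f_new = _eval(u)
            for out_name, v_new in f_new.items():
                v_prev = f_prev[out_name]
                ee = (v_new - v_prev) / (sign * delta)
                if np.isfinite(ee):
                    effects.setdefault(out_name, {}).setdefault(
                        priors[dim].name, []
                    ).append(ee)
                else:
                    n_excluded += 1
                    warnings.warn(
                        f"non-finite elementary effect for {priors[dim].name} "
                        f"on {out_name}; run excluded"
                    )
            f_prev = f_new

    tables = {}
    names = [s.name for s in priors]
    for out_name, per_param in effects.items():
        mu_star = [np.mean(np.abs(per_param.get(nm, [np.nan]))) for nm in names]
        sigma = [
            np.std(per_param.get(nm, [np.nan]), ddof=1)
            if len(per_param.get(nm, [])) > 1
            else np.nan
            for nm in names
        ]
        tables[out_name] = pd.DataFrame(
            {"mu_star": mu_star, "sigma": sigma}, index=pd.Index(names, name="parameter")
        )
    return MorrisResult(tables=tables, n_runs=n_runs, n_excluded=n_excluded)


# --- assembled prior set and end-to-end uncertainty analysis -----------------

# Physiological priors (normal/lognormal truncated at the 5th/95th percentiles
# per the population-generator convention).  Volume/flow entries are fractions.
_PHYSIOLOGY_PRIORS = [
    ("BW", "normal", (72.3, 9.05)),
    ("VLiC", "normal", (0.0309, 0.008)),
    ("VKiC", "normal", (0.0058, 0.0015)),
    ("VFaC", "lognormal", (3.42 - np.log(100.0), 0.43)),
    ("VGuC", "normal", (0.015, 0.002)),
    ("VStC", "normal", (0.0022, 0.0007)),
    ("VSpdC", "normal", (0.607, 0.094)),
    ("VRpdC", "normal", (0.037, 0.0026)),
    ("VBldC", "normal", (0.05, 0.01)),
    ("QCC", "normal", (13.8, 2.5)),
    ("QHepartC", "normal", (0.069, 0.005)),
    ("QKiC", "normal", (0.20, 0.03)),
    ("QFaC", "normal", (0.053, 0.003)),
    ("QGuC", "normal", (0.149, 0.03)),
    ("QStC", "normal", (0.011, 0.001)),
    ("QSpdC", "normal", (0.287, 0.019)),
    ("QRpdC", "normal", (0.23, 0.028)),
]

# Metabolic / binding / biliary priors (not percentile-truncated; normals on
# positive quantities are truncated at zero).
_KINETIC_PRIORS = [
    ("DPHP_half_life", "halfnormal", (10.0,), None),
    ("T_half_MPHP", "normal", (8.05, 4.0), 0.0),
    ("DPHP_GUT_half_life", "normal", (30.0, 10.0), 0.0),
    ("FB_DPHP", "uniform", (0.95, 1.00), None),
    ("FB_MPHP", "uniform", (0.90, 1.00), None),
    ("K1_DPHP_Liver", "halfnormal", (10.0,), None),
    ("MPY", "normal", (34.0, 10.0), 0.0),
    ("MPYgu", "normal", (3.9, 2.0), 0.0),
]

# Priors published only as median (95% interval) summaries: back-fitted.
_SUMMARY_PRIORS = [
    ("Pbab", "uniform", 15.5, 1.785, 29.27),
    ("Pgub", "uniform", 25.23, 2.12, 48.70),
    ("Plib", "uniform", 25.23, 2.12, 48.70),
    ("PbaM", "uniform", 25.23, 2.12, 48.70),
    ("PliM", "uniform", 15.5, 1.785, 29.27),
    ("PguM", "uniform", 15.5, 1.785, 29.27),
    ("PkiM", "uniform", 15.5, 1.785, 29.27),
    ("K1_MPHP", "uniform", 2.52, 0.15, 4.87),
    ("K1_MOH", "uniform", 2.52, 0.15, 4.87),
    ("K1_cx", "uniform", 2.52, 0.15, 4.87),
    ("FracMetab_MOH", "normal", 0.35, 0.21, 0.49),
    ("FracMetab_cx", "normal", 0.03, 0.011, 0.049),
    ("Escape_gu", "uniform", 0.50, 0.028, 0.977),
    ("Escape_Li", "uniform", 0.50, 0.028, 0.977),
    ("FracDOSEHep", "uniform", 0.202, 0.011, 0.39),
    ("BELLYPERM", "uniform", 3.72, 0.24, 7.30),
    ("GIPERM1", "uniform", 4.98, 0.28, 9.74),
    ("GIPERM2", "uniform", 15.17, 0.72, 29.20),
    ("Gutlag", "uniform", 2.51, 0.13, 4.87),
    ("FracDoseLymph", "uniform", 0.075, 0.005, 0.146),
    ("Lymphlag", "uniform", 3.50, 0.18, 6.81),
    ("K1_Lymph", "uniform", 1.53, 0.13, 2.92),
]

# Remaining tissue partition coefficients, varied with the same
# uniform-around-default pattern (0.05x .. 1.95x) that the back-fitted
# partition priors above follow.
_EXTRA_PARTITION_PRIORS = [
    ("Pfab", 63.4), ("Pkib", 5.89), ("Prpdb", 3.7), ("Pspdb", 3.29),
    ("PfaM", 29.10), ("PrpdM", 12.20), ("PspdM", 7.51),
]

_FRACTION_PARAMS = frozenset(
    {"Escape_gu", "Escape_Li", "FracMetab_MOH", "FracMetab_cx",
     "FracDOSEHep", "FracDoseLymph", "FB_DPHP", "FB_MPHP"}
)


def _clip_fraction(spec: PriorSpec) -> PriorSpec:
    if spec.name not in _FRACTION_PARAMS:
        return spec
    if spec.family == "uniform":
        a, b = spec.params
        return PriorSpec(spec.name, "uniform", (max(a, 0.0), min(b, 1.0)))
    lo = 0.0 if spec.lower is None else max(spec.lower, 0.0)
    hi = 1.0 if spec.upper is None else min(spec.upper, 1.0)
    return PriorSpec(spec.name, spec.family, spec.params, lower=lo, upper=hi)


def build_ua_priors() -> list[PriorSpec]:
    """The full varied-parameter prior list for uncertainty/sensitivity work.

    Combines the tabulated physiological priors (5th–95th percentile
    truncated), the metabolic/binding priors, and the back-fitted priors for
    the uptake, partition, routing and elimination parameters published only
    as summaries.  Fraction-valued parameters are clipped to [0, 1].
    """
    priors = [
        PriorSpec(name, fam, p).truncated_at_quantiles(0.05, 0.95)
        for name, fam, p in _PHYSIOLOGY_PRIORS
    ]
    for name, fam, p, lower in _KINETIC_PRIORS:
        priors.append(_clip_fraction(PriorSpec(name, fam, p, lower=lower)))
    for name, fam, med, lo, hi in _SUMMARY_PRIORS:
        priors.append(_clip_fraction(fit_prior_from_summary(med, lo, hi, fam, name=name)))
    for name, v in _EXTRA_PARTITION_PRIORS:
        priors.append(PriorSpec(name, "uniform", (0.05 * v, 1.95 * v)))
    return priors


def simulate_design(
    design: DesignMatrix,
    dose_mg_per_kg: float = MEAN_STUDY_DOSE,
    horizon: float = 48.0,
    grid_step: float = 0.05,
    base: ParameterSet | None = None,
) -> list[TimeCourse]:
    """Run the PBPK model for every design row at a fixed per-kg dose."""
    base = base if base is not None else ParameterSet.from_config()
    grid = np.arange(0.0, horizon + grid_step / 2, grid_step)
    sims = []
    for i in range(design.n):
        params = base.with_overrides(design.row_overrides(i), strict=False)
        dose = DoseEvent(0.0, dose_mg_per_kg * params.anatomy.BW)
        sims.append(simulate(params, dose, grid))
    return sims


def run_uncertainty_analysis(
    n: int = 500,
    seed: int = 0,
    dose_mg_per_kg: float = MEAN_STUDY_DOSE,
    n_candidates: int = 100,
    priors: list[PriorSpec] | None = None,
) -> dict:
    """Maximin-LHS uncertainty analysis with the plausibility filter.

    Returns the design, simulations, retained indices and the per-run peak
    and 48-h blood MPHP concentrations.
    """
    priors = priors if priors is not None else build_ua_priors()
    design = lhs_maximin(priors, n=n, seed=seed, n_candidates=n_candidates)
    sims = simulate_design(design, dose_mg_per_kg=dose_mg_per_kg)
    retained = rejection_filter(design, sims)
    peaks = np.array([tc.obs("CBlood_MPHP").max() for tc in sims])
    c48 = np.array([tc.at("CBlood_MPHP", 48.0) for tc in sims])
    return {
        "design": design,
        "simulations": sims,
        "retained": retained,
        "peak_CBlood_MPHP": peaks,
        "CBlood_MPHP_48h": c48,
    }


def pbpk_morris_model(
    base: ParameterSet | None = None,
    dose_mg_per_kg: float = MEAN_STUDY_DOSE,
    times: tuple[float, ...] = (0.5, 3.0),
):
    """Model wrapper for Morris: blood MPHP and urinary MPHP deposition rate.

    Outputs ``CBlood_MPHP@{t}h`` and ``RUrine_MPHP@{t}h`` for each requested
    time (pre-peak 0.5 h and post-peak 3 h by default).
    """
    base = base if base is not None else ParameterSet.from_config()
    grid = np.unique(np.concatenate([[0.0], np.asarray(times, dtype=float)]))

    names = [f"{obs}@{t}h" for t in times for obs in ("CBlood_MPHP", "RUrine_MPHP")]

    def model(values: dict) -> dict:
        try:
            params = base.with_overrides(values, strict=False)
            dose = DoseEvent(0.0, dose_mg_per_kg * params.anatomy.BW)
            tc = simulate(params, dose, grid)
        except Exception as exc:  # failed run -> NaN outputs
            warnings.warn(f"Morris run failed: {exc}")
            return {name: np.nan for name in names}
        out = {}
        for t in times:
            out[f"CBlood_MPHP@{t}h"] = tc.at("CBlood_MPHP", t)
            out[f"RUrine_MPHP@{t}h"] = tc.at("RUrine_MPHP", t)
        return out

    return model
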