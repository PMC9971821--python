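"""Prior-distribution specification, sampling and summary back-fitting.

A :class:`PriorSpec` names one parameter and its marginal distribution
(normal, lognormal, half-normal or uniform) with optional truncation bounds.
Anatomical/physiological priors are conventionally truncated at their 5th and
95th percentiles; several calibration priors are published only as a median
and 95% interval, and :func:`fit_prior_from_summary` reconstructs the family
parameters from those summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, FitFailureError, InvalidInputError

__all__ = ["PriorSpec", "sample_prior", "fit_prior_from_summary"]

_FAMILIES = ("normal", "lognormal", "halfnormal", "uniform")


@dataclass
class PriorSpec:
    """One parameter's prior: family, family parameters, truncation bounds.

    Family parameters: normal ``(mean, sd)``; lognormal ``(mu_log, sd_log)``
    (so the median is ``exp(mu_log)``); halfnormal ``(scale,)``; uniform
    ``(a, b)``.
    """

    name: str
    family: str
    params: tuple
    lower: float | None = None
    upper: float | None = None

    # Instances are treated as immutable after construction: the frozen scipy
    # distribution and truncation probabilities are cached (construction of a
    # frozen distribution is expensive and logpdf sits in the MCMC hot loop).

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown prior family {self.family!r}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if self.family == "normal":
            if len(p) != 2 or p[1] <= 0:
                raise ConfigurationError(f"normal prior needs (mean, sd > 0), got {p}")
        elif self.family == "lognormal":
            if len(p) != 2 or p[1] <= 0:
                raise ConfigurationError(f"lognormal prior needs (mu_log, sd_log > 0), got {p}")
        elif self.family == "halfnormal":
            if len(p) != 1 or p[0] <= 0:
                raise ConfigurationError(f"halfnormal prior needs (scale > 0,), got {p}")
        elif self.family == "uniform":
            if len(p) != 2 or p[1] <= p[0]:
                raise ConfigurationError(f"uniform prior needs a < b, got {p}")
        if self.lower is not None and self.upper is not None and self.lower >= self.upper:
            raise ConfigurationError(
                f"{self.name}: truncation bounds ({self.lower}, {self.upper}) are empty"
            )
        lo, hi = self._trunc_probs()
        if hi - lo <= 0:
            raise ConfigurationError(f"{self.name}: truncation interval has zero prior mass")

    # -- scipy plumbing ------------------------------------------------------
    def dist(self):
        """The untruncated frozen scipy distribution (cached)."""
        cached = self.__dict__.get("_dist")
        if cached is not None:
            return cached
        p = self.params
        if self.family == "normal":
            d = stats.norm(loc=p[0], scale=p[1])
        elif self.family == "lognormal":
            d = stats.lognorm(s=p[1], scale=np.exp(p[0]))
        elif self.family == "halfnormal":
            d = stats.halfnorm(scale=p[0])
        else:
            d = stats.uniform(loc=p[0], scale=p[1] - p[0])
        self.__dict__["_dist"] = d
        return d

    def _trunc_probs(self) -> tuple[float, float]:
        cached = self.__dict__.get("_tp")
        if cached is not None:
            return cached
        d = self.dist()
        lo = float(d.cdf(self.lower)) if self.lower is not None else 0.0
        hi = float(d.cdf(self.upper)) if self.upper is not None else 1.0
        self.__dict__["_tp"] = (lo, hi)
        return lo, hi

    # -- quantities ----------------------------------------------------------
    def ppf(self, q):
        """Quantile function of the (truncated) prior."""
        lo, hi = self._trunc_probs()
        return self.dist().ppf(lo + np.asarray(q, dtype=float) * (hi - lo))

    def median(self) -> float:
        return float(self.ppf(0.5))

    def interval95(self) -> tuple[float, float]:
        return float(self.ppf(0.025)), float(self.ppf(0.975))

    def support(self) -> tuple[float, float]:
        cached = self.__dict__.get("_support")
        if cached is not None:
            return cached
        lo, hi = self.dist().support()
        if self.lower is not None:
            lo = max(lo, self.lower)
        if self.upper is not None:
            hi = min(hi, self.upper)
        self.__dict__["_support"] = (float(lo), float(hi))
        return float(lo), float(hi)

    def logpdf(self, x):
        """Log density of the truncated, renormalised prior; -inf outside."""
        x = np.asarray(x, dtype=float)
        lo, hi = self._trunc_probs()
        out = self.dist().logpdf(x) - np.log(hi - lo)
        slo, shi = self.support()
        return np.where((x < slo) | (x > shi), -np.inf, out)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """i.i.d. draws honouring truncation (inverse-CDF on uniforms)."""
        if n < 1:
            raise InvalidInputError("n must be >= 1")
        return self.ppf(rng.uniform(size=n))

    def truncated_at_quantiles(self, q_lo: float = 0.05, q_hi: float = 0.95) -> "PriorSpec":
        """Copy truncated at the given quantiles of the untruncated family."""
        d = self.dist()
        return replace(self, lower=float(d.ppf(q_lo)), upper=float(d.ppf(q_hi)))


def sample_prior(spec: PriorSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Reproducible i.i.d. draws from one prior."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return spec.sample(n, rng)


def _quantiles(spec: PriorSpec) -> np.ndarray:
    return np.array([spec.ppf(0.5), spec.ppf(0.025), spec.ppf(0.975)])


def fit_prior_from_summary(
    median: float,
    lo: float,
    hi: float,
    family: str,
    name: str = "",
    tol: float = 0.02,
) -> PriorSpec:
    """Reconstruct a prior from its printed median and 95% interval.

    Inverts the family's quantile function; a normal family that cannot match
    an asymmetric summary falls back to a zero-truncated normal fitted by
    least squares.  Residuals are measured relative to the interval width
    ``hi - lo``; a fit whose worst residual exceeds ``tol`` raises
    :class:`FitFailureError` carrying the residuals.
    """
    if not (lo < median < hi):
        raise FitFailureError(
            f"{name or family}: need lo < median < hi, got ({median}, {lo}, {hi})",
            residuals=None,
        )
    width = hi - lo
    target = np.array([median, lo, hi])

    def _check(spec: PriorSpec) -> PriorSpec:
        res = (_quantiles(spec) - target) / width
        if np.max(np.abs(res)) > tol:
            raise FitFailureError(
                f"{name or family}: back-fit residuals {res.round(4).tolist()} exceed {tol}",
                residuals=res,
            )
        return spec

    if family == "uniform":
        w = width / 0.95
        a = lo - 0.025 * w
        b = a + w
        # nonnegative quantities often print a 2.5th percentile whose exact
        # inversion lands a hair below zero; clip and let the residual check rule
        if -0.05 * w < a < 0.0:
            a = 0.0
        return _check(PriorSpec(name=name, family="uniform", params=(a, b)))

    if family == "normal":
        spec = PriorSpec(name=name, family="normal", params=(median, width / 3.92))
        try:
            return _check(spec)
        except FitFailureError:
            pass
        # zero-truncated normal: asymmetry from a lower bound at 0

        def resid(x):
            s = PriorSpec(name=name, family="normal", params=(x[0], abs(x[1]) + 1e-12), lower=0.0)
            return _quantiles(s) - target

        sol = optimize.least_squares(resid, x0=[median, width / 3.92], xtol=1e-12)
        spec = PriorSpec(
            name=name, family="normal", params=(sol.x[0], abs(sol.x[1])), lower=0.0
        )
        return _check(spec)

    if family == "lognormal":
        if lo <= 0:
            raise FitFailureError(f"{name}: lognormal summaries must be positive")
        spec = PriorSpec(
            name=name,
            family="lognormal",
            params=(np.log(median), (np.log(hi) - np.log(lo)) / 3.92),
        )
        return _check(spec)

    if family == "halfnormal":
        scale = median / stats.halfnorm.ppf(0.5)
        return _check(PriorSpec(name=name, family="halfnormal", params=(scale,)))

    raise ConfigurationError(f"unknown prior family {family!r}")
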