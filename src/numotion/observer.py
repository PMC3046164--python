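"""Simulated numerosity estimation with scalar variability.

The observer follows Stevens' power law, psi = c * phi**n, with
multiplicative lognormal noise of constant coefficient of variation (CV) —
the minimal generative model producing scalar variability, the signature of
estimating (as opposed to counting).  Estimates are produced per subject,
condition (first- vs second-order motion) and repetition, with a
per-condition multiplicative gain and the mean bar height of each trial's
layout carried along as a covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stimulus import BAR_HEIGHTS_DEG

CONDITIONS: tuple[str, str] = ("first_order", "second_order")

#: CSV column order of an estimate table.
TABLE_COLUMNS = ["subject", "condition", "numerosity", "bar_height",
                 "estimate", "trial"]


@dataclass(frozen=True)
class PowerLawParams:
    """psi = c * phi**n with c > 0; log psi = n log phi + log c."""

    c: float = 20.0 ** 0.15  # anchors psi(20) = 20 with the default exponent
    n: float = 0.85

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("power-law constant c must be positive")


def power_law(phi, params: PowerLawParams):
    """Mean estimated numerosity for physical numerosity ``phi``."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("physical numerosity must be positive")
    out = params.c * phi ** params.n
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of the simulated observer.

    cv
        Coefficient of variation of the multiplicative noise (SD/mean of
        repeated estimates at fixed numerosity); 0.33 is the human level.
    condition_gain
        Per-condition multiplicative factor on the mean; first-order
        estimates run higher than second-order ones.
    condition_exponent_offset
        Optional per-condition additive offset on the exponent n, off by
        default; a positive first-order offset reproduces an
        order-by-numerosity interaction.
    subject_sd_log_c, subject_sd_n
        SDs of per-subject jitter on log c and on n (0 disables).
    round_responses
        Round to the nearest integer >= 1, mirroring typed responses.
    """

    power: PowerLawParams = field(default_factory=PowerLawParams)
    cv: float = 0.33
    condition_gain: dict = field(
        default_factory=lambda: {"first_order": 1.1, "second_order": 1.0})
    condition_exponent_offset: dict = field(
        default_factory=lambda: {"first_order": 0.0, "second_order": 0.0})
    subject_sd_log_c: float = 0.0
    subject_sd_n: float = 0.0
    round_responses: bool = True

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if any(g <= 0 for g in self.condition_gain.values()):
            raise ValueError("condition gains must be positive")

    @property
    def log_noise_sd(self) -> float:
        """sigma of the zero-mean Gaussian log-noise giving the target CV
        (lognormal identity cv = sqrt(exp(sigma^2) - 1))."""
        return math.sqrt(math.log(1.0 + self.cv ** 2))


def _round_response(psi: np.ndarray) -> np.ndarray:
    return np.maximum(np.rint(psi), 1.0)


def sample_mean_bar_height(n: int, rng: np.random.Generator) -> float:
    """Mean height of ``n`` bars whose heights are i.i.d. uniform over the
    two height classes."""
    short, tall = BAR_HEIGHTS_DEG
    n_tall = int(rng.binomial(n, 0.5))
    return (short * (n - n_tall) + tall * n_tall) / n


def simulate_estimates(numerosities, subjects: int, reps: int,
                       params: ObserverParams | None = None,
                       seed: int | np.random.Generator = 0,
                       conditions: tuple[str, ...] = CONDITIONS) -> pd.DataFrame:
    """Simulate an estimate table for a within-subjects design.

    Every subject sees every (condition, numerosity) cell ``reps`` times.
    psi = gain_cond * c_s * phi**(n_s + off_cond) * exp(eps), with eps
    zero-mean Gaussian scaled to the configured CV, then rounded to an
    integer >= 1.  Returns a tidy DataFrame with columns
    subject, condition, numerosity, bar_height, estimate, trial.
    """
    params = params or ObserverParams()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    numerosities = [int(v) for v in numerosities]
    sigma = params.log_noise_sd
    rows = []
    for s in range(1, subjects + 1):
        log_c = math.log(params.power.c)
        n_exp = params.power.n
        if params.subject_sd_log_c > 0:
            log_c += rng.normal(0.0, params.subject_sd_log_c)
        if params.subject_sd_n > 0:
            n_exp += rng.normal(0.0, params.subject_sd_n)
        for cond in conditions:
            gain = params.condition_gain[cond]
            n_c = n_exp + params.condition_exponent_offset.get(cond, 0.0)
            trial = 0
            for phi in numerosities:
                for _ in range(reps):
                    trial += 1
                    height = sample_mean_bar_height(phi, rng)
                    eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                    psi = gain * math.exp(log_c) * phi ** n_c * math.exp(eps)
                    if params.round_responses:
                        psi = float(_round_response(np.asarray(psi)))
                    rows.append((s, cond, phi, height, psi, trial))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log psi on log phi."""

    c: float
    n: float
    se_c: float
    se_n: float
    r_squared: float
    nobs: int

    @property
    def params(self) -> PowerLawParams:
        return PowerLawParams(c=self.c, n=self.n)


def fit_power_law(table: pd.DataFrame, estimate_col: str = "estimate",
                  numerosity_col: str = "numerosity") -> PowerLawFit:
    """Fit psi = c * phi**n by ordinary least squares in log-log space.

    Requires at least two distinct numerosities; the intercept exp() gives
    c with a delta-method standard error.
    """
    import statsmodels.api as sm

    phi = np.asarray(table[numerosity_col], dtype=float)
    psi = np.asarray(table[estimate_col], dtype=float)
    if np.unique(phi).size < 2:
        raise ValueError("need >= 2 distinct numerosities to fit a power law")
    if np.any(phi <= 0) or np.any(psi <= 0):
        raise ValueError("numerosities and estimates must be positive")
    X = sm.add_constant(np.log(phi))
    res = sm.OLS(np.log(psi), X).fit()
    intercept, slope = res.params
    se_int, se_slope = res.bse
    c = math.exp(intercept)
    return PowerLawFit(c=c, n=float(slope), se_c=c * float(se_int),
                       se_n=float(se_slope), r_squared=float(res.rsquared),
                       nobs=int(res.nobs))


def perturb_for_subject(params: ObserverParams,
                        rng: np.random.Generator) -> ObserverParams:
    """One subject's parameters with the configured jitter applied."""
    if params.subject_sd_log_c == 0 and params.subject_sd_n == 0:
        return params
    power = PowerLawParams(
        c=params.power.c * math.exp(rng.normal(0, params.subject_sd_log_c))
        if params.subject_sd_log_c > 0 else params.power.c,
        n=params.power.n + (rng.normal(0, params.subject_sd_n)
                            if params.subject_sd_n > 0 else 0.0),
    )
    return replace(params, power=power)


def draw_estimate(phi: int, condition: str,
                  params: ObserverParams, rng: np.random.Generator) -> float:
    """A single simulated response (used by the session runner)."""
    sigma = params.log_noise_sd
    gain = params.condition_gain[condition]
    n_c = params.power.n + params.condition_exponent_offset.get(condition, 0.0)
    eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
    psi = gain * params.power.c * phi ** n_c * math.exp(eps)
    if params.round_responses:
        psi = float(_round_response(np.asarray(psi)))
    return psi
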