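"""Synthetic qPCR data generation and Monte-Carlo power / size estimation.

Two generators:

* :func:`gen_two_group` — the two-group design used for power analysis:
  target Ct normal per group, normalizer Ct normal (independent by
  default, optional correlation), raw values left intact so the cutoff
  censoring is applied downstream exactly as on real data.  Population
  parameters play the role of the sample estimates they stand in for.
* :func:`gen_ph_regression` — a generator in which the proportional
  CTOT-rate assumption holds exactly: cycle-to-threshold times are
  Weibull with the covariate scaling the rate by ``exp(beta_true * x)``,
  so the regression module's estimand is the generator's ``beta_true``.

:func:`estimate_power` runs the CTOT test and the comparator methods on
the *same* generated frame within each replicate (paired comparison, one
master seed with per-replicate substreams) and reports per-method
rejection proportions with Monte-Carlo standard errors.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from .comparators import co_method, mc_method
from .dataio import AnalysisFrame
from .errors import AnalysisNotPossible, CTOTError
from .regression import fit_ctot_regression
from .twogroup import ctot_two_group_test

__all__ = [
    "SimulationSpec",
    "PHRegressionSpec",
    "PowerEstimate",
    "RecoveryEstimate",
    "gen_two_group",
    "gen_ph_regression",
    "estimate_power",
    "regression_recovery",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Two-group power/size simulation design.

    Target and normalizer Ct values are normal; means and standard
    deviations are in cycles.  ``correlation`` couples a sample's target
    and normalizer draws (default 0, independent).
    """

    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    norm_mean: float = 20.0
    norm_sd: float = 0.5
    cutoff: float = 40.0
    alpha: float = 0.05
    n_reps: int = 1000
    seed: int = 1
    correlation: float = 0.0
    methods: tuple = ("ctot", "mc", "co")
    rho: float = 0.0
    gamma: float = 0.0
    null: str = "auto"
    B: int = 2000
    mc_variant: str = "welch"

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise CTOTError("n1 and n2 must be at least 2")
        if self.sd1 <= 0 or self.sd2 <= 0 or self.norm_sd <= 0:
            raise CTOTError("standard deviations must be positive")
        if not 0 < self.alpha < 1:
            raise CTOTError("alpha must be in (0, 1)")
        if self.n_reps < 1:
            raise CTOTError("n_reps must be at least 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d


@dataclass(frozen=True)
class PHRegressionSpec:
    """Proportional CTOT-rate generator for parameter-recovery studies.

    ``T_i = (-ln U_i / (lam * exp(beta_true * x_i)))**(1/shape)`` with
    ``U_i`` uniform — Weibull(shape, lam) baseline on the cycle axis —
    recorded as the Ct value; censoring happens downstream at ``cutoff``.
    The covariate defaults match a hemolysis-absorbance-like reading
    (mean 0.51, sd 0.41).  Baseline shape 2 and rate 4.6e-4 put typical
    crossing times near cycle 30, so a cutoff of 40 censors roughly a
    quarter to a third of the samples.
    """

    n: int = 200
    beta_true: float = 1.0
    cov_mean: float = 0.51
    cov_sd: float = 0.41
    shape: float = 2.0
    rate: float = 4.6e-4
    cutoff: float = 40.0
    n_reps: int = 500
    seed: int = 1
    ci_level: float = 0.95

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise CTOTError("Weibull shape and rate must be positive")


@dataclass(frozen=True)
class PowerEstimate:
    """Per-method rejection proportions with Monte-Carlo uncertainty."""

    power: dict                # method -> rejection proportion
    mc_se: dict                # method -> sqrt(p(1-p)/n_reps)
    n_not_analyzable: dict     # method -> CNA-style failures (counted as non-rejections)
    n_reps: int
    alpha: float
    spec: dict

    def to_dict(self) -> dict:
        return {
            "power": self.power,
            "mc_se": self.mc_se,
            "n_not_analyzable": self.n_not_analyzable,
            "n_reps": self.n_reps,
            "alpha": self.alpha,
            "spec": self.spec,
        }


@dataclass(frozen=True)
class RecoveryEstimate:
    mean_beta: float
    sd_beta: float
    ci_coverage: float
    n_converged: int
    n_reps: int
    beta_true: float


def _rep_rng(seed: int, rep_index: int, stream: int = 0) -> np.random.Generator:
    # independent substream per (seed, replicate): methods inside one
    # replicate see identical data (paired comparison)
    return np.random.default_rng([int(seed), int(rep_index), int(stream)])


def gen_two_group(spec: SimulationSpec, rep_index: int) -> AnalysisFrame:
    """Draw one two-group replicate; deterministic given (seed, rep_index)."""
    rng = _rep_rng(spec.seed, rep_index)
    n = spec.n1 + spec.n2
    z_t = rng.standard_normal(n)
    z_n = rng.standard_normal(n)
    r = spec.correlation
    z_n = r * z_t + np.sqrt(1.0 - r**2) * z_n
    means = np.concatenate([np.full(spec.n1, spec.mean1), np.full(spec.n2, spec.mean2)])
    sds = np.concatenate([np.full(spec.n1, spec.sd1), np.full(spec.n2, spec.sd2)])
    ct = means + sds * z_t
    norm = spec.norm_mean + spec.norm_sd * z_n
    group = np.concatenate([np.zeros(spec.n1, dtype=int), np.ones(spec.n2, dtype=int)])
    return AnalysisFrame(
        ct=ct,
        normalizer_ct=norm,
        cutoff=spec.cutoff,
        group=group,
        group_levels=("group1", "group2"),
    )


def gen_ph_regression(spec: PHRegressionSpec, rep_index: int) -> AnalysisFrame:
    """Draw one proportional-rate replicate (normalizer held at 0)."""
    rng = _rep_rng(spec.seed, rep_index)
    x = spec.cov_mean + spec.cov_sd * rng.standard_normal(spec.n)
    u = rng.random(spec.n)
    t = (-np.log(u) / (spec.rate * np.exp(spec.beta_true * x))) ** (1.0 / spec.shape)
    return AnalysisFrame(
        ct=t,
        normalizer_ct=np.zeros(spec.n),
        cutoff=spec.cutoff,
        covariate=x,
    )


def estimate_power(spec: SimulationSpec, methods: Optional[Sequence[str]] = None) -> PowerEstimate:
    """Monte-Carlo rejection rates for the requested methods.

    Each replicate generates one frame and runs every method on it,
    recording rejection at ``spec.alpha`` (two-sided tests throughout).
    A replicate a method cannot analyze — e.g. complete observations
    with an emptied group — counts as a non-rejection and is tallied
    separately.
    """
    methods = tuple(methods if methods is not None else spec.methods)
    unknown = set(methods) - {"ctot", "mc", "co"}
    if unknown:
        raise CTOTError(f"unknown methods: {sorted(unknown)}")
    rejections = {m: 0 for m in methods}
    failures = {m: 0 for m in methods}
    for rep in range(spec.n_reps):
        frame = gen_two_group(spec, rep)
        for m in methods:
            try:
                if m == "ctot":
                    perm_seed = int(_rep_rng(spec.seed, rep, stream=7).integers(2**31))
                    res = ctot_two_group_test(
                        frame, rho=spec.rho, gamma=spec.gamma,
                        null=spec.null, B=spec.B, seed=perm_seed,
                        normalizer_policy="drop",
                    )
                    p = res.p_value
                elif m == "mc":
                    p = mc_method(frame, variant=spec.mc_variant).p_value
                else:
                    p = co_method(frame, variant=spec.mc_variant).p_value
            except (AnalysisNotPossible, CTOTError):
                failures[m] += 1
                continue
            if p <= spec.alpha:
                rejections[m] += 1
    power = {m: rejections[m] / spec.n_reps for m in methods}
    mc_se = {
        m: float(np.sqrt(power[m] * (1.0 - power[m]) / spec.n_reps)) for m in methods
    }
    return PowerEstimate(
        power=power,
        mc_se=mc_se,
        n_not_analyzable=failures,
        n_reps=spec.n_reps,
        alpha=spec.alpha,
        spec=spec.to_dict(),
    )


def regression_recovery(spec: PHRegressionSpec, ties: str = "efron") -> RecoveryEstimate:
    """Repeatedly fit the CTOT regression on proportional-rate data and
    summarize estimator bias and Wald-CI coverage of ``beta_true``."""
    betas, covered = [], 0
    for rep in range(spec.n_reps):
        frame = gen_ph_regression(spec, rep)
        try:
            res = fit_ctot_regression(frame, ties=ties, ci_level=spec.ci_level)
        except CTOTError:
            continue
        betas.append(res.beta)
        lo, hi = np.log(res.ci_low), np.log(res.ci_high)
        if lo <= spec.beta_true <= hi:
            covered += 1
    if not betas:
        raise CTOTError("no replicate produced a converged fit")
    betas = np.asarray(betas)
    return RecoveryEstimate(
        mean_beta=float(betas.mean()),
        sd_beta=float(betas.std(ddof=1)) if len(betas) > 1 else 0.0,
        ci_coverage=covered / len(betas),
        n_converged=len(betas),
        n_reps=spec.n_reps,
        beta_true=spec.beta_true,
    )
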