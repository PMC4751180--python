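"""Heritability-based parameterization of mixture-cure simulation designs.

A simulation cell is described on the heritability scale (fraction of
linear-scale variance explained by the SNP or by the polygenic background)
and translated into linear-scale coefficients: a log odds ratio for the
logistic (lifetime risk) component and a log hazard ratio for the survival
(age of onset) component.  The survival effect lives on the standardized
``shape * log(time)`` scale of a Weibull accelerated failure time model,
where the error is standard minimum extreme-value with variance pi^2/6, so
the solved coefficient is directly a log hazard ratio; the logistic error
is standard logistic with variance pi^2/3.

Fixing the genotype variance (``2 p (1-p)`` = 0.375 at allele frequency
0.25), the background variance (37,500, the normal limit of 100,000
background SNPs) and the error variances gives a one-to-one map between
heritability and odds/hazard ratio.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "VAR_EPS_LOGISTIC",
    "VAR_EPS_SURVIVAL",
    "ParameterError",
    "DegenerateDesignError",
    "SimDesign",
    "EffectSet",
    "beta_from_bg_h2",
    "beta_from_snp_h2",
    "loghr_to_aft",
    "solve_cure_intercept",
    "resolve_effects",
    "build_grid",
    "grid_table",
]

#: Variance of the standard logistic distribution (error of a logistic model
#: on the log-odds scale).
VAR_EPS_LOGISTIC = math.pi**2 / 3.0

#: Variance of the standard minimum extreme-value (Gumbel) distribution, the
#: error of a Weibull model on the shape*log(time) scale.
VAR_EPS_SURVIVAL = math.pi**2 / 6.0


class ParameterError(ValueError):
    """An input parameter is outside its valid domain."""


class DegenerateDesignError(ParameterError):
    """The design admits no meaningful model (e.g. cure fraction 1)."""


@dataclass(frozen=True)
class SimDesign:
    """One simulation cell.

    Parameters
    ----------
    cure_fraction
        Marginal probability of never developing the disease, in ``[0, 1)``.
        0 means everyone is at risk (a plain survival model).
    h2_snp_logistic, h2_snp_survival
        SNP heritability of the lifetime-risk and age-of-onset effects.
    h2_bg_logistic, h2_bg_survival
        Background (polygenic) heritability of the two effects.
    allele_freq
        Risk allele frequency of the analyzed SNP.
    n_bg_snps
        Number of background SNPs the normal background score stands in for.
    weibull_shape, weibull_scale
        Baseline age-of-onset distribution for subjects at risk, in years.
    censor_low, censor_high
        Bounds of the uniform right-censoring ages, in years.
    n_subjects
        Cohort size.
    """

    cure_fraction: float
    h2_snp_logistic: float = 0.0
    h2_snp_survival: float = 0.0
    h2_bg_logistic: float = 0.0
    h2_bg_survival: float = 0.0
    allele_freq: float = 0.25
    n_bg_snps: int = 100_000
    weibull_shape: float = 20.0
    weibull_scale: float = 20.0
    censor_low: float = 15.0
    censor_high: float = 25.0
    n_subjects: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.cure_fraction < 1.0:
            raise ParameterError(
                f"cure_fraction must be in [0, 1), got {self.cure_fraction}"
            )
        for name in (
            "h2_snp_logistic",
            "h2_snp_survival",
            "h2_bg_logistic",
            "h2_bg_survival",
        ):
            value = getattr(self, name)
            if not 0.0 <= value < 1.0:
                raise ParameterError(f"{name} must be in [0, 1), got {value}")
        if not 0.0 < self.allele_freq < 1.0:
            raise ParameterError("allele_freq must be in (0, 1)")
        if self.n_bg_snps < 1:
            raise ParameterError("n_bg_snps must be positive")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ParameterError("Weibull shape and scale must be positive")
        if not self.censor_low < self.censor_high:
            raise ParameterError("censor_low must be below censor_high")
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be at least 2")

    @property
    def var_snp(self) -> float:
        """Variance of the allele count, ``2 p (1 - p)``."""
        return 2.0 * self.allele_freq * (1.0 - self.allele_freq)

    @property
    def var_bg(self) -> float:
        """Variance of the background score, ``n_bg_snps * var_snp``."""
        return self.n_bg_snps * self.var_snp

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimDesign":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown design fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimDesign":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError("design config must be a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class EffectSet:
    """Linear-scale coefficients resolved from a :class:`SimDesign`.

    ``beta_*_aft * weibull_shape == -beta_*_loghr`` exactly: a risk allele
    with a positive log hazard ratio accelerates onset, i.e. shrinks the
    Weibull time scale.
    """

    intercept_logistic: float
    beta_snp_logistic: float
    beta_bg_logistic: float
    beta_snp_loghr: float
    beta_bg_loghr: float
    beta_snp_aft: float
    beta_bg_aft: float
    var_eps_logistic: float = VAR_EPS_LOGISTIC
    var_eps_survival: float = VAR_EPS_SURVIVAL

    def to_dict(self) -> dict:
        return asdict(self)


def beta_from_bg_h2(h2_bg: float, var_bg: float, var_eps: float) -> float:
    """Background coefficient giving heritability ``h2_bg``.

    Inverts ``h2 = b^2 V / (b^2 V + var_eps)`` for the (non-negative) b.
    """
    if not 0.0 <= h2_bg < 1.0:
        raise ParameterError(f"h2_bg must be in [0, 1), got {h2_bg}")
    if var_bg <= 0 or var_eps <= 0:
        raise ParameterError("variances must be positive")
    return math.sqrt(h2_bg * var_eps / ((1.0 - h2_bg) * var_bg))


def beta_from_snp_h2(
    h2_snp: float,
    var_snp: float,
    bg_variance_component: float,
    var_eps: float,
) -> float:
    """SNP coefficient giving heritability ``h2_snp``.

    The denominator of the SNP heritability includes the variance already
    explained by the background, ``bg_variance_component = b_bg^2 * var_bg``,
    so a larger background inflates the coefficient needed for the same h2.
    """
    if not 0.0 <= h2_snp < 1.0:
        raise ParameterError(f"h2_snp must be in [0, 1), got {h2_snp}")
    if var_snp <= 0 or var_eps <= 0 or bg_variance_component < 0:
        raise ParameterError("invalid variance arguments")
    return math.sqrt(
        h2_snp * (bg_variance_component + var_eps) / ((1.0 - h2_snp) * var_snp)
    )


def loghr_to_aft(log_hr: float, shape: float) -> float:
    """Convert a log hazard ratio to a Weibull log acceleration factor.

    Under a Weibull with the given shape k, multiplying times by
    ``exp(-log_hr / k)`` multiplies the hazard by ``exp(log_hr)``.
    """
    if shape <= 0:
        raise ParameterError("Weibull shape must be positive")
    return -log_hr / shape


# Gauss-Hermite rule reused across intercept solves (physicists' convention).
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)


def solve_cure_intercept(
    design: SimDesign, beta_snp_logistic: float, beta_bg_logistic: float
) -> float:
    """Logistic intercept c with E[1 - expit(c + b_s X + b_b B)] = cure_fraction.

    The expectation is exact over the three genotypes (binomial(2, p)) and
    uses 80-node Gauss-Hermite quadrature over the normal background score.
    """
    cure = design.cure_fraction
    if cure <= 0.0 or cure >= 1.0:
        raise DegenerateDesignError(
            "cure fraction 0 has no logistic component; cure fraction 1 is degenerate"
        )
    if beta_snp_logistic == 0.0 and beta_bg_logistic == 0.0:
        return float(logit(1.0 - cure))

    p = design.allele_freq
    geno = np.array([0.0, 1.0, 2.0])
    geno_probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    sigma_bg = math.sqrt(design.var_bg)
    bg_nodes = math.sqrt(2.0) * sigma_bg * _GH_NODES
    bg_weights = _GH_WEIGHTS / math.sqrt(math.pi)

    lin = beta_snp_logistic * geno[:, None] + beta_bg_logistic * bg_nodes[None, :]

    def at_risk_prob(c: float) -> float:
        probs = expit(c + lin)
        return float(geno_probs @ probs @ bg_weights)

    target = 1.0 - cure
    lo, hi = -60.0, 60.0
    return float(brentq(lambda c: at_risk_prob(c) - target, lo, hi, xtol=1e-12))


def resolve_effects(design: SimDesign) -> EffectSet:
    """Translate a design's heritabilities into simulation coefficients.

    The logistic chain uses the standard-logistic error variance, the
    survival chain the standard minimum extreme-value error variance; the
    survival coefficient is solved on the log-HR scale and mirrored to the
    AFT scale.  At cure fraction 0 every subject is at risk and the logistic
    intercept is +inf by convention.
    """
    b_bg_log = beta_from_bg_h2(design.h2_bg_logistic, design.var_bg, VAR_EPS_LOGISTIC)
    b_snp_log = beta_from_snp_h2(
        design.h2_snp_logistic,
        design.var_snp,
        b_bg_log**2 * design.var_bg,
        VAR_EPS_LOGISTIC,
    )
    b_bg_hr = beta_from_bg_h2(design.h2_bg_survival, design.var_bg, VAR_EPS_SURVIVAL)
    b_snp_hr = beta_from_snp_h2(
        design.h2_snp_survival,
        design.var_snp,
        b_bg_hr**2 * design.var_bg,
        VAR_EPS_SURVIVAL,
    )
    if design.cure_fraction == 0.0:
        intercept = math.inf
    else:
        intercept = solve_cure_intercept(design, b_snp_log, b_bg_log)
    return EffectSet(
        intercept_logistic=intercept,
        beta_snp_logistic=b_snp_log,
        beta_bg_logistic=b_bg_log,
        beta_snp_loghr=b_snp_hr,
        beta_bg_loghr=b_bg_hr,
        beta_snp_aft=loghr_to_aft(b_snp_hr, design.weibull_shape),
        beta_bg_aft=loghr_to_aft(b_bg_hr, design.weibull_shape),
    )


def _cure_fractions_traditional() -> list[float]:
    return [round(0.05 * i, 2) for i in range(19)]  # 0, 0.05, ..., 0.90


def build_grid(which: str) -> list[SimDesign]:
    """Enumerate the experiment grids.

    ``traditional``: cure fraction 0-0.90 in steps of 0.05, each SNP
    heritability 0 or 1% independently, background heritability 0 or 50%
    for both effects jointly — 152 cells.

    ``cure``: both SNP heritabilities jointly 0 or 1%, background 0 or 50%,
    cure fraction {0.1, 0.3, 0.5, 0.7, 0.9} — 20 cells.
    """
    designs: list[SimDesign] = []
    if which == "traditional":
        for cure in _cure_fractions_traditional():
            for h2_log in (0.0, 0.01):
                for h2_surv in (0.0, 0.01):
                    for h2_bg in (0.0, 0.5):
                        designs.append(
                            SimDesign(
                                cure_fraction=cure,
                                h2_snp_logistic=h2_log,
                                h2_snp_survival=h2_surv,
                                h2_bg_logistic=h2_bg,
                                h2_bg_survival=h2_bg,
                            )
                        )
    elif which == "cure":
        for h2_snp in (0.0, 0.01):
            for h2_bg in (0.0, 0.5):
                for cure in (0.1, 0.3, 0.5, 0.7, 0.9):
                    designs.append(
                        SimDesign(
                            cure_fraction=cure,
                            h2_snp_logistic=h2_snp,
                            h2_snp_survival=h2_snp,
                            h2_bg_logistic=h2_bg,
                            h2_bg_survival=h2_bg,
                        )
                    )
    else:
        raise ParameterError(f"unknown grid {which!r}; expected 'traditional' or 'cure'")
    return designs


def grid_table(designs: list[SimDesign]) -> pd.DataFrame:
    """One row per cell: every design field plus the resolved coefficients."""
    rows = []
    for design in designs:
        row = design.to_dict()
        row.update(resolve_effects(design).to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
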