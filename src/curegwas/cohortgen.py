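"""Synthetic cohort generation under the mixture-cure model, plus cohort I/O.

Each subject carries a biallelic genotype dosage, a normal polygenic
background score, a latent at-risk indicator drawn from the logistic
component, a Weibull age of onset (at-risk subjects only) accelerated or
decelerated by the SNP and background effects, and an independent uniform
right-censoring age.  The observed data are ``obs_time`` (onset if the event
happened before censoring, otherwise the censoring age) and the ``event``
indicator; truth columns (``at_risk``, ``onset_time``) are carried along for
validation but never read by the estimators.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DegenerateDesignError, EffectSet, SimDesign

__all__ = [
    "COHORT_COLUMNS",
    "CohortFormatError",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "validate_cohort",
]

#: Column order of the cohort table; the first six are the observed data,
#: ``at_risk`` and ``onset_time`` are simulation truth.
COHORT_COLUMNS = [
    "id",
    "genotype",
    "bg_score",
    "censor_time",
    "obs_time",
    "event",
    "at_risk",
    "onset_time",
]

_OBSERVED_COLUMNS = ["id", "genotype", "bg_score", "censor_time", "obs_time", "event"]


class CohortFormatError(ValueError):
    """A cohort file does not conform to the documented layout."""


def simulate_cohort(design: SimDesign, effects: EffectSet, seed: int) -> pd.DataFrame:
    """Draw one cohort; identical inputs produce a bit-identical table.

    Draw order is fixed: genotypes, background scores, at-risk indicators,
    standard Weibull onset variates, censoring ages.  At cure fraction 0 the
    latent indicator is deterministically true but the uniform draw is still
    consumed so cohorts at different cure fractions stay comparable.
    Onset times exceeding the censoring age are simply censored; there is no
    truncation.
    """
    if design.n_subjects < 2:
        raise DegenerateDesignError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    n = design.n_subjects

    genotype = rng.binomial(2, design.allele_freq, size=n)
    bg_score = rng.normal(0.0, math.sqrt(design.var_bg), size=n)

    risk_uniform = rng.uniform(size=n)
    if design.cure_fraction == 0.0:
        at_risk = np.ones(n, dtype=bool)
    else:
        lin = (
            effects.intercept_logistic
            + effects.beta_snp_logistic * genotype
            + effects.beta_bg_logistic * bg_score
        )
        at_risk = risk_uniform < expit(lin)

    # standard Weibull(shape) variate, time-scaled per subject on the AFT scale
    v = rng.weibull(design.weibull_shape, size=n)
    accel = np.exp(
        effects.beta_snp_aft * genotype + effects.beta_bg_aft * bg_score
    )
    onset = design.weibull_scale * accel * v
    onset = np.where(at_risk, onset, np.nan)

    censor = rng.uniform(design.censor_low, design.censor_high, size=n)
    event = at_risk & (onset <= censor)
    obs_time = np.where(event, onset, censor)

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "genotype": genotype,
            "bg_score": bg_score,
            "censor_time": censor,
            "obs_time": obs_time,
            "event": event,
            "at_risk": at_risk,
            "onset_time": onset,
        }
    )


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the cohort invariants; raise :class:`CohortFormatError` if violated."""
    if len(cohort) == 0:
        raise CohortFormatError("cohort is empty")
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortFormatError(f"cohort is missing columns: {missing}")
    event = cohort["event"].to_numpy(dtype=bool)
    at_risk = cohort["at_risk"].to_numpy(dtype=bool)
    obs = cohort["obs_time"].to_numpy(dtype=float)
    censor = cohort["censor_time"].to_numpy(dtype=float)
    onset = cohort["onset_time"].to_numpy(dtype=float)
    if np.any(event & ~at_risk):
        raise CohortFormatError("event recorded for a subject not at risk")
    if np.any(event & ~(onset <= censor)):
        raise CohortFormatError("event recorded after the censoring age")
    if not np.allclose(obs[event], onset[event], equal_nan=False):
        raise CohortFormatError("obs_time of events must equal onset_time")
    if not np.allclose(obs[~event], censor[~event]):
        raise CohortFormatError("obs_time of non-events must equal censor_time")


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort as a tab-separated table (missing onset written as NA)."""
    validate_cohort(cohort)
    out = cohort[COHORT_COLUMNS].copy()
    out["event"] = out["event"].astype(int)
    out["at_risk"] = out["at_risk"].astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort` (lossless round trip)."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", na_values=["NA"])
    except pd.errors.EmptyDataError as exc:
        raise CohortFormatError(f"{path}: file is empty") from exc
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing columns {missing} in header")
    if len(table) == 0:
        raise CohortFormatError(f"{path}: no subjects in file")
    for column in ("genotype", "bg_score", "censor_time", "obs_time"):
        if table[column].isna().any():
            line = int(table[column].isna().idxmax()) + 2  # 1-based, after header
            raise CohortFormatError(f"{path}: missing {column} value at line {line}")
    table["event"] = table["event"].astype(bool)
    table["at_risk"] = table["at_risk"].astype(bool)
    table["genotype"] = table["genotype"].astype(np.int64)
    table["id"] = table["id"].astype(np.int64)
    validate_cohort(table)
    return table[COHORT_COLUMNS]
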