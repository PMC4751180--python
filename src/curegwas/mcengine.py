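"""Monte Carlo driver: rejection rates (type-1 error / power) and median bias.

One *cell* is a simulation design; each replicate simulates a fresh cohort
and fits the requested analyses.  The cure model contributes two tests
(``cure_or`` and ``cure_hr``) from a single EM fit.  Per-replicate seeds are
derived from the cell seed with :class:`numpy.random.SeedSequence`, so a
grid run is reproducible and identical regardless of worker count.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cohortgen import simulate_cohort
from .design import ParameterError, SimDesign, build_grid, resolve_effects
from .estimators import IdentifiabilityError, fit_cox, fit_cure_cox, fit_logistic

__all__ = ["run_cell", "run_grid", "summarize_curves"]

#: Test names produced by each requested analysis.
_ANALYSIS_TESTS = {
    "logistic": ("logistic",),
    "cox": ("cox",),
    "cure": ("cure_or", "cure_hr"),
}


def _derived_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def run_cell(
    design: SimDesign,
    analyses: Sequence[str] = ("logistic", "cox"),
    n_reps: int = 1000,
    alpha: float = 0.1,
    seed: int = 0,
    bootstrap_reps: int = 100,
    em_max_iter: int = 500,
    em_tol: float = 1e-6,
) -> dict:
    """Simulate and analyze one cell; return a flat summary row.

    Rejection rates (fraction of two-sided Wald p-values below ``alpha``)
    and median exponentiated estimates are computed over converged fits
    only, with convergence counts reported alongside.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be at least 1")
    if not 0.0 < alpha <= 1.0:
        raise ParameterError("alpha must be in (0, 1]")
    for name in analyses:
        if name not in _ANALYSIS_TESTS:
            raise ParameterError(f"unknown analysis {name!r}")

    effects = resolve_effects(design)
    tests = [t for a in analyses for t in _ANALYSIS_TESTS[a]]
    estimates: dict[str, list[float]] = {t: [] for t in tests}
    pvalues: dict[str, list[float]] = {t: [] for t in tests}

    for rep in range(n_reps):
        seq = np.random.SeedSequence([seed, rep])
        cohort_seed = _derived_seed(seq)
        cohort = simulate_cohort(design, effects, cohort_seed)
        if "logistic" in analyses:
            _collect("logistic", fit_logistic(cohort), estimates, pvalues)
        if "cox" in analyses:
            _collect("cox", fit_cox(cohort), estimates, pvalues)
        if "cure" in analyses:
            boot_seed = _derived_seed(np.random.SeedSequence([seed, rep, 1]))
            try:
                cure = fit_cure_cox(
                    cohort,
                    max_iter=em_max_iter,
                    tol=em_tol,
                    bootstrap_reps=bootstrap_reps,
                    seed=boot_seed,
                )
            except IdentifiabilityError:
                pass
            else:
                _collect("cure_or", cure.logistic_part, estimates, pvalues)
                _collect("cure_hr", cure.survival_part, estimates, pvalues)

    row: dict = dict(design.to_dict())
    row.update(
        n_reps=n_reps,
        alpha=alpha,
        seed=seed,
        true_or=float(np.exp(effects.beta_snp_logistic)),
        true_hr=float(np.exp(effects.beta_snp_loghr)),
    )
    for t in tests:
        est = np.asarray(estimates[t])
        pv = np.asarray(pvalues[t])
        row[f"{t}_rejection"] = float(np.mean(pv < alpha)) if pv.size else float("nan")
        row[f"{t}_median"] = float(np.median(np.exp(est))) if est.size else float("nan")
        row[f"{t}_n_converged"] = int(est.size)
        row[f"{t}_n_tested"] = int(pv.size)
    return row


def _collect(test, fit, estimates, pvalues) -> None:
    """Converged estimates feed the medians; finite p-values feed rejection."""
    if fit.converged and np.isfinite(fit.estimate):
        estimates[test].append(fit.estimate)
        if np.isfinite(fit.p_value):
            pvalues[test].append(fit.p_value)


def _cell_safe(index: int, design: SimDesign, **kwargs) -> dict:
    try:
        row = run_cell(design, **kwargs)
    except Exception as exc:  # keep the grid running; surface the failure
        row = dict(design.to_dict())
        row["error"] = f"{type(exc).__name__}: {exc}"
    row["cell"] = index
    return row


def run_grid(
    which: str,
    n_reps: int = 1000,
    alpha: float = 0.1,
    seed: int = 0,
    parallel_workers: int = 1,
    bootstrap_reps: int = 100,
    n_subjects: int | None = None,
) -> pd.DataFrame:
    """Run every cell of a grid; one summary row per cell.

    The ``traditional`` grid (152 cells) runs logistic + Cox; the ``cure``
    grid (20 cells) additionally runs the mixture-cure model.  ``n_subjects``
    overrides the per-cohort sample size for scaled-down runs.  Results are
    identical for any worker count because each cell gets its own seed.
    """
    designs = build_grid(which)
    if n_subjects is not None:
        designs = [
            SimDesign(**{**d.to_dict(), "n_subjects": n_subjects}) for d in designs
        ]
    analyses = ("logistic", "cox") if which == "traditional" else ("logistic", "cox", "cure")
    cell_seeds = [_derived_seed(np.random.SeedSequence([seed, i])) for i in range(len(designs))]
    rows = Parallel(n_jobs=parallel_workers)(
        delayed(_cell_safe)(
            i,
            design,
            analyses=analyses,
            n_reps=n_reps,
            alpha=alpha,
            seed=cell_seeds[i],
            bootstrap_reps=bootstrap_reps,
        )
        for i, design in enumerate(designs)
    )
    table = pd.DataFrame(rows).set_index("cell", drop=False)
    return table.sort_index()


_QUANTITY_TESTS = {
    "rejection": ("logistic", "cox", "cure_or", "cure_hr"),
    "median_or": ("logistic", "cure_or"),
    "median_hr": ("cox", "cure_hr"),
}


def summarize_curves(cell_table: pd.DataFrame, quantity: str) -> pd.DataFrame:
    """Melt a grid table into long-format curves over the cure fraction.

    One row per (analysis test, cell), keyed by the SNP heritabilities and
    background level, with the simulated true OR/HR carried along as the
    reference line for bias plots.
    """
    if quantity not in _QUANTITY_TESTS:
        raise ParameterError(
            f"unknown quantity {quantity!r}; expected one of {sorted(_QUANTITY_TESTS)}"
        )
    suffix = "_rejection" if quantity == "rejection" else "_median"
    ref_col = {"rejection": None, "median_or": "true_or", "median_hr": "true_hr"}[quantity]
    rows = []
    if len(cell_table) == 0:
        return pd.DataFrame(
            columns=[
                "analysis",
                "cure_fraction",
                "h2_snp_logistic",
                "h2_snp_survival",
                "h2_background",
                "value",
                "reference",
            ]
        )
    for _, cell in cell_table.iterrows():
        for test in _QUANTITY_TESTS[quantity]:
            col = f"{test}{suffix}"
            if col not in cell_table.columns or pd.isna(cell.get(col)):
                continue
            rows.append(
                {
                    "analysis": test,
                    "cure_fraction": cell["cure_fraction"],
                    "h2_snp_logistic": cell["h2_snp_logistic"],
                    "h2_snp_survival": cell["h2_snp_survival"],
                    "h2_background": cell["h2_bg_logistic"],
                    "value": cell[col],
                    "reference": cell[ref_col] if ref_col else float("nan"),
                }
            )
    return pd.DataFrame(rows)
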