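"""Differential cell-type abundance with the local true sign rate (LTSR).

Per cell type, the per-sample nucleus count is modelled with a Poisson
log-linear GLM with an offset for the per-sample total,

    count_s ~ Poisson(exp(alpha + beta * HP_s + log(total_s))),

so ``beta`` is the natural-log fold-change of the type's *relative* abundance
between conditions (reported on the log2 scale). The Wald standard error is
inflated by a quasi-Poisson dispersion factor ``max(1, Pearson chi2 / df)``
whenever residual degrees of freedom exist, guarding against between-sample
overdispersion at low replication.

The LTSR — the probability that the estimated direction of the fold-change
is correct given its mean and variance — is computed under a normal
approximation of the estimator as ``Phi(|log2FC| / SE)``. Types with
``LTSR > 0.9`` (strictly) are called as significantly shifted.

Types with zero counts in one condition receive a Haldane-style +0.5
continuity addition to every cell of their type × sample subtable so that
rare types remain reportable; these fits are flagged in the output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .datatypes import ConfigError

__all__ = [
    "CompositionCounts",
    "tabulate_composition",
    "fit_abundance_model",
    "ltsr",
    "call_shifts",
    "abundance_analysis",
]

LN2 = math.log(2.0)
#: Largest reportable LTSR; keeps finite estimates inside [0.5, 1).
_LTSR_MAX = float(np.nextafter(1.0, 0.0))


@dataclass
class CompositionCounts:
    """Nucleus counts per (cell type, sample) with sample condition labels."""

    counts: pd.DataFrame  # index: cell type, columns: sample ids
    sample_condition: pd.Series  # index: sample ids, values: condition labels

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.sample_condition.index):
            raise ConfigError("counts columns must match sample_condition index")
        if (self.counts.to_numpy() < 0).any():
            raise ConfigError("composition counts must be non-negative")

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def tabulate_composition(table: pd.DataFrame) -> CompositionCounts:
    """Contingency table of nuclei by (cell type, sample); zeros explicit."""
    if len(table) == 0:
        return CompositionCounts(pd.DataFrame(), pd.Series(dtype=object))
    cond_per_sample = table.groupby("sample_id")["condition"].nunique()
    if (cond_per_sample > 1).any():
        bad = list(cond_per_sample[cond_per_sample > 1].index)
        raise ConfigError(f"samples mapped to more than one condition: {bad}")
    counts = pd.crosstab(table["cell_type"], table["sample_id"])
    counts = counts.sort_index(axis=0).sort_index(axis=1)
    sample_condition = (
        table.drop_duplicates("sample_id").set_index("sample_id")["condition"].loc[counts.columns]
    )
    return CompositionCounts(counts, sample_condition)


def fit_abundance_model(
    counts: CompositionCounts, baseline: str = "LP", treatment: str = "HP"
) -> pd.DataFrame:
    """Per-type log2 fold-change of relative abundance (treatment vs baseline).

    Returns a DataFrame indexed by cell type with columns
    ``log2fc, se, n_baseline, n_treatment, continuity_corrected``.
    """
    if counts.counts.empty:
        raise ConfigError("empty composition table")
    cond = counts.sample_condition
    for label in (baseline, treatment):
        if label not in set(cond):
            raise ConfigError(f"condition {label!r} absent from the table")
    totals = counts.sample_totals.to_numpy(dtype=float)
    if np.any(totals[np.isin(cond.to_numpy(), [baseline, treatment])] == 0):
        raise ConfigError("a sample has zero total nuclei")
    is_trt = (cond == treatment).to_numpy(dtype=float)
    use = np.isin(cond.to_numpy(), [baseline, treatment])
    X = sm.add_constant(is_trt[use])
    offset = np.log(totals[use])

    rows = []
    for cell_type, row in counts.counts.iterrows():
        y = row.to_numpy(dtype=float)[use]
        zero_cond = (y[is_trt[use] == 1].sum() == 0) or (y[is_trt[use] == 0].sum() == 0)
        if zero_cond:
            y = y + 0.5
        with warnings.catch_warnings():
            # saturated two-sample fits have zero residual df; the Wald SE
            # comes from the information matrix, not the residual scale
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        beta, se = fit.params[1], fit.bse[1]
        df = len(y) - 2
        if df > 0:
            mu = fit.mu
            pearson = float(((y - mu) ** 2 / mu).sum())
            se *= math.sqrt(max(1.0, pearson / df))
        rows.append(
            {
                "cell_type": cell_type,
                "log2fc": beta / LN2,
                "se": se / LN2,
                "n_baseline": float(row[cond == baseline].sum()),
                "n_treatment": float(row[cond == treatment].sum()),
                "continuity_corrected": bool(zero_cond),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


def ltsr(estimate, se):
    """Local true sign rate of an estimate under a normal approximation.

    ``Phi(|estimate| / se)``: 0.5 for a zero estimate, approaching 1 as the
    estimate grows relative to its uncertainty. Accepts scalars or arrays;
    requires ``se > 0`` elementwise.
    """
    estimate = np.asarray(estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ConfigError("standard errors must be > 0")
    out = np.minimum(norm.cdf(np.abs(estimate) / se), _LTSR_MAX)
    return float(out) if out.ndim == 0 else out


def call_shifts(results: pd.DataFrame, threshold: float = 0.9) -> list:
    """Cell types with LTSR strictly above ``threshold``, best first."""
    called = results[results["ltsr"] > threshold]
    return list(called.sort_values("ltsr", ascending=False).index)


def abundance_analysis(
    table: pd.DataFrame, threshold: float = 0.9, baseline: str = "LP", treatment: str = "HP"
) -> pd.DataFrame:
    """Tabulate, fit, and score in one step.

    Returns a per-type DataFrame with ``log2fc, se, ltsr, direction, called``
    plus the per-condition nucleus counts.
    """
    counts = tabulate_composition(table)
    fits = fit_abundance_model(counts, baseline=baseline, treatment=treatment)
    fits["ltsr"] = ltsr(fits["log2fc"].to_numpy(), fits["se"].to_numpy())
    fits["direction"] = np.sign(fits["log2fc"]).astype(int)
    fits["called"] = fits["ltsr"] > threshold
    return fits
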