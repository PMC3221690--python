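"""Per-gene F-like statistics for the probe-by-group interaction.

All statistics share the interaction mean square MSI_i as numerator and
differ only in the error variance estimate in the denominator:

=========  =====================================================
F1         gene-specific MSE_i (the classical split-plot F)
F2         0.5·MSE_i + 0.5·σ̂²_pool (Wu et al.)
F3         σ̂²_pool, the mean of all gene-specific MSEs
FCui       σ̃²_Cui,i — gene-level shrinkage toward the common mean
FGen       mean_k σ̃²_Gen,i,k — gene-by-group additive target
FGenGene   mean_k σ̃²_Gen-gene,i,k — gene-mean target
FGenGrp    mean_k σ̃²_Gen-grp,i,k — group-mean target
FGenCe     mean_k σ̃²_Gen-ce,i,k — grand-mean (common error) target
=========  =====================================================

Null distributions of the shrinkage statistics are not named
distributions; they are obtained by permutation (see
:mod:`shrinkf.permutation`).  Only F1 also admits tabled p-values from the
central F distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .anova import AnovaSummaries
from .shrinkage import (
    LogChiSquareMoments,
    ShrunkenVarianceTable,
    _shrink_cui_values,
    _shrink_values,
    log_chisq_moments,
)

__all__ = ["StatisticMatrix", "STATISTIC_IDS", "compute_statistic", "tabled_pvalue_f1"]

STATISTIC_IDS = ("F1", "F2", "F3", "FCui", "FGen", "FGenGene", "FGenGrp", "FGenCe")

#: statistic id -> shrinkage target behind it (None for moment-free ones)
_SHRINK_TARGET = {
    "FGen": "gen",
    "FGenGene": "gene",
    "FGenGrp": "group",
    "FGenCe": "common",
}


@dataclass(frozen=True)
class StatisticMatrix:
    """Values of one statistic across genes, plus the denominators used."""

    statistic_id: str
    values: np.ndarray
    denominators: np.ndarray


def _ratio(msi: np.ndarray, den: np.ndarray, warn: bool = False) -> np.ndarray:
    """MSI / denominator with zero denominators mapped to +inf.

    Infinite values rank above every finite value in permutation
    comparisons, which makes the resulting p-values conservative.
    """
    den = np.asarray(den, dtype=float)
    if warn and np.any(den == 0):
        warnings.warn("zero denominator: statistic set to +inf", RuntimeWarning, stacklevel=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, msi / np.where(den > 0, den, 1.0), np.inf)
    return out


def _statistic_arrays(statistic_id: str, msi: np.ndarray, mse: np.ndarray,
                      group_var: np.ndarray, nu: int, K: int) -> np.ndarray:
    """Batched statistic values; gene axis last, arbitrary leading axes.

    Shapes: ``msi``/``mse`` are ``(..., I)``, ``group_var`` is
    ``(..., I, K)``.  The pooled variance and every shrinkage table are
    recomputed within each leading slice — shrinkage borrows strength
    across genes, so a permutation replicate must re-shrink globally.
    """
    if statistic_id == "F1":
        den = mse
    elif statistic_id == "F2":
        den = 0.5 * mse + 0.5 * mse.mean(axis=-1, keepdims=True)
    elif statistic_id == "F3":
        den = np.broadcast_to(mse.mean(axis=-1, keepdims=True), mse.shape)
    elif statistic_id == "FCui":
        values, _ = _shrink_cui_values(mse, log_chisq_moments(K * nu))
        den = values
    elif statistic_id in _SHRINK_TARGET:
        values, _ = _shrink_values(_SHRINK_TARGET[statistic_id], group_var, log_chisq_moments(nu))
        den = values.mean(axis=-1)
    else:
        raise ValueError(f"unknown statistic {statistic_id!r}")
    return _ratio(msi, den)


def compute_statistic(statistic_id: str, summaries: AnovaSummaries,
                      tables: Mapping[str, ShrunkenVarianceTable] | None = None,
                      ) -> StatisticMatrix:
    """Compute one F-like statistic for every gene.

    ``tables`` may supply precomputed shrinkage tables keyed by target
    ({'gen', 'gene', 'group', 'common', 'cui'}); missing tables are
    computed on the fly from the summaries.
    """
    if statistic_id not in STATISTIC_IDS:
        raise ValueError(f"unknown statistic {statistic_id!r}; choose from {STATISTIC_IDS}")
    tables = dict(tables or {})
    msi, mse = summaries.msi, summaries.mse
    K, nu = summaries.design.n_groups, summaries.group_df

    if statistic_id == "F1":
        den = mse.copy()
    elif statistic_id == "F2":
        den = 0.5 * mse + 0.5 * summaries.pooled_var
    elif statistic_id == "F3":
        den = np.full_like(mse, summaries.pooled_var)
    elif statistic_id == "FCui":
        if "cui" not in tables:
            values, _ = _shrink_cui_values(mse, log_chisq_moments(K * nu))
            den = values
        else:
            den = np.asarray(tables["cui"].values, dtype=float)
    else:
        target = _SHRINK_TARGET[statistic_id]
        if target not in tables:
            values, _ = _shrink_values(target, summaries.group_var, log_chisq_moments(nu))
        else:
            values = np.asarray(tables[target].values, dtype=float)
        den = values.mean(axis=-1)
    return StatisticMatrix(statistic_id=statistic_id,
                           values=_ratio(msi, den, warn=True),
                           denominators=np.asarray(den, dtype=float))


def tabled_pvalue_f1(statistic: StatisticMatrix, msi_df: int, mse_df: int) -> np.ndarray:
    """Upper-tail p-values of F1 from the central F(msi_df, mse_df) table.

    Only F1 has a known null distribution under iid normal errors; the
    shrinkage statistics require permutation p-values.
    """
    if statistic.statistic_id != "F1":
        raise ValueError("tabled p-values are defined for F1 only")
    vals = np.asarray(statistic.values, dtype=float)
    p = np.where(np.isinf(vals), 0.0, sps.f.sf(np.where(np.isinf(vals), 0.0, vals), msi_df, mse_df))
    return p
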