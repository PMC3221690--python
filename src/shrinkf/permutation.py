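"""Permutation null distributions for the interaction statistics.

There is no exact permutation test for an interaction term, so approximate
procedures are used.  Four are implemented, the cross of

* **mode** — permute *residuals* of the reduced additive model with fixed
  effects for probe and group only, or permute the *raw* observations;
* **restriction** — *unrestricted* (any observation slot may move anywhere)
  or *restricted* (observations are exchanged only within their own group
  level, preserving group-specific variance structure when within-gene
  heteroscedasticity is present).

By default one shared column bijection is applied to every gene's row:
the shrinkage denominators couple genes, and a shared permutation keeps
that cross-gene structure intact.  A per-gene-independent variant is
available for sensitivity analysis.

Permuted matrices are re-analyzed with the *full* cross-gene pipeline
(ANOVA, shrinkage, statistic) — shrinkage borrows information across
genes, so recomputation is global per replicate, never per gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .anova import DesignError, ExperimentDesign, _anova_arrays
from .statistics import STATISTIC_IDS, _statistic_arrays

__all__ = ["PermutationPlan", "EmpiricalNull", "reduced_model_residuals",
           "permute_once", "build_null"]


@dataclass(frozen=True)
class PermutationPlan:
    """How to build the empirical null.

    ``restricted`` permutations never move an observation across group
    (line) levels — the factor whose levels carry within-gene
    heteroscedasticity.
    """

    mode: str = "residual"          # "residual" or "raw"
    restricted: bool = False
    n_perm: int = 1000
    seed: int = 0
    share_indices_across_genes: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("residual", "raw"):
            raise ValueError(f"mode must be 'residual' or 'raw', got {self.mode!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def describe(self) -> str:
        r = "restricted" if self.restricted else "unrestricted"
        return f"{r}-{self.mode}"


@dataclass(frozen=True)
class EmpiricalNull:
    """Gene-specific empirical null of one statistic.

    ``p_values[i] = (1 + #{b : null[i, b] >= observed[i]}) / (B + 1)`` —
    the add-one form never returns an exact zero, and ties count against
    the null (conservative).
    """

    statistic_id: str
    null_values: np.ndarray   # (I, B)
    observed: np.ndarray      # (I,)
    p_values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        B = self.null_values.shape[1]
        count = np.sum(self.null_values >= self.observed[:, None], axis=1)
        object.__setattr__(self, "p_values", (1.0 + count) / (B + 1.0))


def reduced_model_residuals(Y: np.ndarray, design: ExperimentDesign) -> np.ndarray:
    """Residuals of the additive probe + group fixed-effects fit, per gene.

    ``r = y − ȳ_probe − ȳ_group + ȳ``; replicate and interaction structure
    is deliberately left in the residuals — it is what the permutation
    redistributes.  Residuals sum to zero within every probe level and
    every group level.
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[None, :]
    if Y.shape[-1] != design.n_obs:
        raise DesignError(f"expected {design.n_obs} observation columns, got {Y.shape[-1]}")
    P, K, R = design.n_probes, design.n_groups, design.n_reps
    Yr = Y[..., design.canonical_order].reshape(Y.shape[:-1] + (P, K, R))
    m_p = Yr.mean(axis=(-2, -1), keepdims=True)
    m_k = Yr.mean(axis=(-3, -1), keepdims=True)
    grand = Yr.mean(axis=(-3, -2, -1), keepdims=True)
    res_canon = (Yr - m_p - m_k + grand).reshape(Y.shape)
    out = np.empty_like(res_canon)
    out[..., design.canonical_order] = res_canon
    return out[0] if squeeze else out


def _permutation_indices(design: ExperimentDesign, plan: PermutationPlan,
                         rng: np.random.Generator, n_rows: int = 1) -> np.ndarray:
    """Draw ``plan.n_perm`` column bijections, shape (B, n) or (B, I, n).

    Restricted permutations act on the (probe, replicate) subplot slot
    labels: one random bijection of the P·R slots is drawn per replicate
    and applied inside every group block, so observations never cross
    group levels and all groups are relabeled coherently.
    """
    n = design.n_obs
    B = plan.n_perm
    shape = (B, n) if plan.share_indices_across_genes else (B, n_rows, n)
    idx = np.broadcast_to(np.arange(n), shape).copy()
    if plan.restricted:
        # columns of each group, ordered by (probe, replicate) slot
        slot_order = np.lexsort((design.rep_idx, design.probe_idx))
        group_cols = []
        for k in range(design.n_groups):
            cols = slot_order[design.group_idx[slot_order] == k]
            if cols.size < 2:
                raise ValueError("restricted permutation needs >= 2 observations per group")
            group_cols.append(cols)
        n_slots = group_cols[0].size
        perm = rng.permuted(
            np.broadcast_to(np.arange(n_slots), shape[:-1] + (n_slots,)).copy(), axis=-1)
        for cols in group_cols:
            idx[..., cols] = cols[perm]
    else:
        idx = rng.permuted(idx, axis=-1)
    return idx


def permute_once(data: np.ndarray, plan: PermutationPlan,
                 rng: np.random.Generator, design: ExperimentDesign) -> np.ndarray:
    """Apply one random column bijection (shared across genes by default)."""
    data = np.asarray(data, dtype=float)
    one = PermutationPlan(mode=plan.mode, restricted=plan.restricted, n_perm=1,
                          seed=plan.seed,
                          share_indices_across_genes=plan.share_indices_across_genes)
    idx = _permutation_indices(design, one, rng, n_rows=data.shape[0])
    if plan.share_indices_across_genes:
        return data[:, idx[0]]
    return np.take_along_axis(data, idx[0], axis=-1)


def build_null(Y: np.ndarray, design: ExperimentDesign, statistic_ids,
               plan: PermutationPlan) -> dict[str, EmpiricalNull]:
    """Empirical nulls for one or more statistics under one permutation plan.

    Every permutation replicate re-runs the entire pipeline on the permuted
    matrix; all requested statistics share the per-replicate ANOVA pass.
    """
    if isinstance(statistic_ids, str):
        statistic_ids = (statistic_ids,)
    statistic_ids = tuple(statistic_ids)
    for sid in statistic_ids:
        if sid not in STATISTIC_IDS:
            raise ValueError(f"unknown statistic {sid!r}")
    Y = np.asarray(Y, dtype=float)
    I = Y.shape[0]
    K, nu = design.n_groups, design.group_df

    min_p = 1.0 / (plan.n_perm + 1)
    if min_p > 0.05:
        warnings.warn(
            f"B={plan.n_perm} permutations cannot reach p <= 0.05 "
            f"(minimum attainable p is {min_p:.3f})", UserWarning, stacklevel=2)

    data = reduced_model_residuals(Y, design) if plan.mode == "residual" else Y
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
    idx = _permutation_indices(design, plan, rng, n_rows=I)
    if plan.share_indices_across_genes:
        perm = data[:, idx].transpose(1, 0, 2)          # (B, I, n)
    else:
        perm = np.take_along_axis(data[None, :, :], idx, axis=-1)

    msi_o, mse_o, gv_o = _anova_arrays(Y, design)
    msi_b, mse_b, gv_b = _anova_arrays(perm, design)

    out: dict[str, EmpiricalNull] = {}
    for sid in statistic_ids:
        obs = _statistic_arrays(sid, msi_o, mse_o, gv_o, nu, K)
        null = _statistic_arrays(sid, msi_b, mse_b, gv_b, nu, K)   # (B, I)
        out[sid] = EmpiricalNull(statistic_id=sid, null_values=null.T, observed=obs)
    return out
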