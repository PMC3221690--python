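"""Balanced split-plot ANOVA decomposition per gene.

Each gene is measured on ``n = P * K * R`` observations laid out as a
balanced crossed design: ``P`` probe levels, ``K`` group levels ("lines"),
and ``R`` replicates nested within each group.  The probe-by-group
interaction mean square (MSI) is tested against the subplot residual mean
square (MSE); for a balanced design both are available in closed form, so
no mixed-model solver is needed even though replicate-within-group is a
random (whole-plot) effect.

The group-specific residual variance of gene *i* in group *k* is the
residual mean square of the additive probe + replicate two-way fit inside
that group; summed over groups it reproduces the full-model residual SS,
which gives the balanced-design identity ``MSE = mean_k(group_var[k])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExperimentDesign",
    "GeneAnovaSummary",
    "AnovaSummaries",
    "decompose_gene",
    "decompose_all",
]


class DesignError(ValueError):
    """Raised for unbalanced or otherwise unusable designs."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Factor structure of one gene's observations, shared across genes.

    Parameters
    ----------
    observation_ids
        Labels for the ``n`` observation columns.
    probe_level, group_level, replicate_level
        Per-observation categorical labels.  Replicates are nested within
        groups: replicate "1" of group 1 and of group 2 are distinct units.
    """

    observation_ids: tuple[str, ...]
    probe_level: tuple[str, ...]
    group_level: tuple[str, ...]
    replicate_level: tuple[str, ...]

    # derived index arrays, filled in __post_init__
    probe_idx: np.ndarray = field(init=False, repr=False, compare=False)
    group_idx: np.ndarray = field(init=False, repr=False, compare=False)
    rep_idx: np.ndarray = field(init=False, repr=False, compare=False)
    canonical_order: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.observation_ids)
        if not (len(self.probe_level) == len(self.group_level) == len(self.replicate_level) == n):
            raise DesignError("design columns have unequal lengths")
        if len(set(self.observation_ids)) != n:
            raise DesignError("duplicate observation ids")

        probes = sorted(set(self.probe_level))
        groups = sorted(set(self.group_level))
        p_idx = np.array([probes.index(p) for p in self.probe_level])
        k_idx = np.array([groups.index(g) for g in self.group_level])
        # replicate labels are nested in group: index them within each group
        rep_labels: dict[str, list[str]] = {g: sorted({r for r, gg in zip(self.replicate_level, self.group_level) if gg == g}) for g in groups}
        reps_per_group = {g: len(v) for g, v in rep_labels.items()}
        if len(set(reps_per_group.values())) != 1:
            raise DesignError(f"unequal replicate counts per group: {reps_per_group}")
        r_idx = np.array([rep_labels[g].index(r) for r, g in zip(self.replicate_level, self.group_level)])

        P, K, R = len(probes), len(groups), next(iter(reps_per_group.values()))
        if P < 2 or K < 2 or R < 2:
            raise DesignError(f"need P>=2, K>=2, R>=2; got P={P}, K={K}, R={R}")
        counts = np.zeros((P, K, R), dtype=int)
        np.add.at(counts, (p_idx, k_idx, r_idx), 1)
        if not np.all(counts == 1):
            bad = np.argwhere(counts != 1)[0]
            raise DesignError(
                f"design is not balanced: cell (probe={probes[bad[0]]}, "
                f"group={groups[bad[1]]}, replicate index {bad[2]}) occurs "
                f"{counts[tuple(bad)]} times, expected exactly 1"
            )

        object.__setattr__(self, "probe_idx", p_idx)
        object.__setattr__(self, "group_idx", k_idx)
        object.__setattr__(self, "rep_idx", r_idx)
        # column order that reshapes a row into a (P, K, R) array
        order = np.lexsort((r_idx, k_idx, p_idx))
        object.__setattr__(self, "canonical_order", order)

    # dimensions -----------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return len(set(self.probe_level))

    @property
    def n_groups(self) -> int:
        return len(set(self.group_level))

    @property
    def n_reps(self) -> int:
        return len(self.observation_ids) // (self.n_probes * self.n_groups)

    @property
    def n_obs(self) -> int:
        return len(self.observation_ids)

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.group_level))

    # degrees of freedom ---------------------------------------------------
    @property
    def msi_df(self) -> int:
        return (self.n_probes - 1) * (self.n_groups - 1)

    @property
    def group_df(self) -> int:
        """Residual df of the probe+replicate fit within one group, ν."""
        return (self.n_probes - 1) * (self.n_reps - 1)

    @property
    def mse_df(self) -> int:
        return self.n_groups * self.group_df

    @classmethod
    def balanced(cls, n_probes: int = 2, n_groups: int = 2, n_reps: int = 3) -> "ExperimentDesign":
        """Construct a fully crossed balanced design with synthetic labels."""
        ids, pl, gl, rl = [], [], [], []
        for k in range(n_groups):
            for r in range(n_reps):
                for p in range(n_probes):
                    ids.append(f"line{k + 1}_rep{r + 1}_probe{p + 1}")
                    pl.append(f"probe{p + 1}")
                    gl.append(f"line{k + 1}")
                    rl.append(f"rep{r + 1}")
        return cls(tuple(ids), tuple(pl), tuple(gl), tuple(rl))


@dataclass(frozen=True)
class GeneAnovaSummary:
    """Per-gene mean squares and group-specific residual variances."""

    msi: float
    msi_df: int
    mse: float
    mse_df: int
    group_var: np.ndarray  # length K
    group_df: int


@dataclass(frozen=True)
class AnovaSummaries:
    """Vectorized ANOVA summaries for ``I`` genes under one design."""

    msi: np.ndarray        # (I,)
    mse: np.ndarray        # (I,)
    group_var: np.ndarray  # (I, K)
    msi_df: int
    mse_df: int
    group_df: int
    design: ExperimentDesign

    def __len__(self) -> int:
        return len(self.msi)

    def __getitem__(self, i: int) -> GeneAnovaSummary:
        return GeneAnovaSummary(
            msi=float(self.msi[i]), msi_df=self.msi_df,
            mse=float(self.mse[i]), mse_df=self.mse_df,
            group_var=self.group_var[i].copy(), group_df=self.group_df,
        )

    @property
    def pooled_var(self) -> float:
        """σ̂²_pool: the mean over genes of the per-gene MSE."""
        return float(np.mean(self.mse))


def _anova_arrays(Y: np.ndarray, design: ExperimentDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form mean squares; ``Y`` may carry arbitrary leading axes.

    Returns ``(msi, mse, group_var)`` with shapes ``Y.shape[:-1]`` and
    ``Y.shape[:-1] + (K,)``.  Broadcasting over leading axes is what makes
    whole permutation nulls computable in a single pass.
    """
    P, K, R = design.n_probes, design.n_groups, design.n_reps
    if Y.shape[-1] != design.n_obs:
        raise DesignError(f"expected {design.n_obs} observations, got {Y.shape[-1]}")
    Yr = np.asarray(Y, dtype=float)[..., design.canonical_order].reshape(Y.shape[:-1] + (P, K, R))

    cell = Yr.mean(axis=-1)                                  # ȳ_pk·
    m_p = cell.mean(axis=-1, keepdims=True)                  # ȳ_p·
    m_k = cell.mean(axis=-2, keepdims=True)                  # ȳ_·k
    grand = cell.mean(axis=(-2, -1), keepdims=True)
    inter = cell - m_p - m_k + grand
    msi = R * np.sum(inter**2, axis=(-2, -1)) / ((P - 1) * (K - 1))

    # within each group: residuals of the additive probe + replicate fit
    m_pk = Yr.mean(axis=-1, keepdims=True)                   # ȳ_pk·
    m_kr = Yr.mean(axis=-3, keepdims=True)                   # ȳ_·kr
    m_g = Yr.mean(axis=(-3, -1), keepdims=True)              # ȳ_··k
    resid = Yr - m_pk - m_kr + m_g
    group_var = np.sum(resid**2, axis=(-3, -1)) / ((P - 1) * (R - 1))  # (..., K)
    mse = group_var.mean(axis=-1)
    return msi, mse, group_var


def decompose_gene(y: Sequence[float] | np.ndarray, design: ExperimentDesign) -> GeneAnovaSummary:
    """Split-plot decomposition of one gene's expression vector.

    Returns the interaction mean square, the subplot residual mean square,
    and the per-group residual variances σ̂²_{i,k} with their degrees of
    freedom.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.shape[0] != design.n_obs:
        raise DesignError(f"expected a length-{design.n_obs} vector, got shape {y.shape}")
    if np.any(~np.isfinite(y)):
        raise ValueError("non-finite expression values")
    msi, mse, gv = _anova_arrays(y, design)
    return GeneAnovaSummary(
        msi=float(msi), msi_df=design.msi_df,
        mse=float(mse), mse_df=design.mse_df,
        group_var=gv, group_df=design.group_df,
    )


def decompose_all(Y: np.ndarray, design: ExperimentDesign) -> AnovaSummaries:
    """Decompose every row of a gene × observation matrix."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] == 0:
        raise ValueError("Y must be a non-empty 2-D gene x observation matrix")
    if Y.shape[1] != design.n_obs:
        raise DesignError(f"expected {design.n_obs} observation columns, got {Y.shape[1]}")
    if np.any(~np.isfinite(Y)):
        raise ValueError("non-finite expression values in matrix")
    msi, mse, gv = _anova_arrays(Y, design)
    return AnovaSummaries(
        msi=msi, mse=mse, group_var=gv,
        msi_df=design.msi_df, mse_df=design.mse_df, group_df=design.group_df,
        design=design,
    )
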