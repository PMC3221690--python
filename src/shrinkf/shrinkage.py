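"""Empirical-Bayes shrinkage of log error variances.

The residual variance estimates ``σ̂²_{i,k}`` (gene *i*, group *k*) satisfy
``ν σ̂²_{i,k} / σ²_{i,k} ~ χ²_ν``, so on the log scale

    X_{i,k} = log σ̂²_{i,k} − m,    m = E[log(χ²_ν / ν)],

is approximately normal around ``log σ²_{i,k}`` with known variance
``s² = Var[log(χ²_ν / ν)]``.  A two-way normal hierarchy on the latent log
variances,

    X_{i,k} | θ_{i,k} ~ N(θ_{i,k}, s²),   θ_{i,k} ~ N(μ + α_i + β_k, τ²),

yields positive-part James–Stein estimators that pull each ``X_{i,k}``
toward one of four fitted targets: the gene-by-group additive fit
(``gen``), the gene mean (``gene``), the group mean (``group``), or the
grand mean (``common``).  The classical gene-level estimator of Cui et al.
shrinks the per-gene MSE (with ``K·ν`` df) toward its mean (``cui``).

All shrunken variances have the form ``exp(m + fitted + f·residual)`` with
a single positive-part factor ``f = max(0, 1 − c·s²/S)`` where ``S`` is the
residual sum of squares and ``c`` the James–Stein constant of the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import polygamma, psi

__all__ = [
    "LogChiSquareMoments",
    "AdditiveLogVarianceFit",
    "ShrunkenVarianceTable",
    "log_chisq_moments",
    "center_log_variances",
    "additive_fit",
    "shrink",
    "shrink_cui",
    "TARGETS",
]

#: floor applied to variance estimates before taking logs (degenerate
#: zero-residual genes); the continuous limit sends f -> 0 (full shrinkage)
VAR_FLOOR = 1e-300

TARGETS = ("gen", "gene", "group", "common")


@dataclass(frozen=True)
class LogChiSquareMoments:
    """Mean ``m`` and variance ``s2`` of ``log(χ²_df / df)``."""

    df: float
    m: float
    s2: float


@dataclass(frozen=True)
class AdditiveLogVarianceFit:
    """Least-squares additive fit to the centered log variances."""

    X: np.ndarray           # (I, K)
    mu_hat: float
    alpha_hat: np.ndarray   # (I,), sums to zero
    beta_hat: np.ndarray    # (K,), sums to zero
    residual_ss: float
    tau2_hat: float


@dataclass(frozen=True)
class ShrunkenVarianceTable:
    """Shrinkage variance estimates for one target.

    ``values`` is (I, K) for the four generalized targets and (I,) for the
    Cui estimator (one value per gene, no group index).
    """

    target: str
    values: np.ndarray
    shrinkage_factor: float


def log_chisq_moments(df: float) -> LogChiSquareMoments:
    """Exact moments of ``log(χ²_df / df)`` via digamma / trigamma.

    ``m = ψ(df/2) + log(2/df)`` and ``s2 = ψ'(df/2)``; for example at
    df = 2, ``m`` is minus the Euler–Mascheroni constant and ``s2 = π²/6``.
    """
    if df <= 0:
        raise ValueError(f"df must be positive, got {df}")
    m = float(psi(df / 2.0) + math.log(2.0 / df))
    s2 = float(polygamma(1, df / 2.0))
    return LogChiSquareMoments(df=float(df), m=m, s2=s2)


def center_log_variances(group_var: np.ndarray, moments: LogChiSquareMoments) -> np.ndarray:
    """``X_{i,k} = log σ̂²_{i,k} − m`` (unbiased for log σ² on the log scale)."""
    gv = np.asarray(group_var, dtype=float)
    if np.any(gv < 0):
        raise ValueError("negative variance estimates")
    return np.log(np.maximum(gv, VAR_FLOOR)) - moments.m


def additive_fit(X: np.ndarray, moments: LogChiSquareMoments | None = None) -> AdditiveLogVarianceFit:
    """Fit ``μ + α_i + β_k`` to the centered log variances by least squares.

    When ``moments`` is given, ``tau2_hat`` is the positive part of the
    method-of-moments estimate ``S / (IK − (I+K−1) − 2) − s²``; it is
    diagnostic only — the shrinkage factor absorbs it.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("X must be I x K with I >= 2 and K >= 2")
    I, K = X.shape
    mu = float(X.mean())
    alpha = X.mean(axis=1) - mu
    beta = X.mean(axis=0) - mu
    resid = X - mu - alpha[:, None] - beta[None, :]
    ss = float(np.sum(resid**2))
    c = I * K - (I + K - 1) - 2
    if c <= 0:
        tau2 = math.nan
    elif moments is None:
        tau2 = math.nan
    else:
        tau2 = max(0.0, ss / c - moments.s2)
    return AdditiveLogVarianceFit(X=X, mu_hat=mu, alpha_hat=alpha, beta_hat=beta,
                                  residual_ss=ss, tau2_hat=tau2)


def _shrink_values(target: str, group_var: np.ndarray, moments: LogChiSquareMoments
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Batched core of :func:`shrink`.

    ``group_var`` has shape ``(..., I, K)``; returns ``(values, factor)``
    with shapes ``(..., I, K)`` and ``(...,)``.
    """
    gv = np.asarray(group_var, dtype=float)
    I, K = gv.shape[-2:]
    X = np.log(np.maximum(gv, VAR_FLOOR)) - moments.m
    mu = X.mean(axis=(-2, -1), keepdims=True)
    if target == "gen":
        alpha = X.mean(axis=-1, keepdims=True) - mu
        beta = X.mean(axis=-2, keepdims=True) - mu
        fitted = mu + alpha + beta
        c = I * K - (I + K - 1) - 2
    elif target == "gene":
        fitted = X.mean(axis=-1, keepdims=True)          # μ̂ + α̂_i
        c = I * K - (I - 1) - 2
    elif target == "group":
        fitted = X.mean(axis=-2, keepdims=True)          # μ̂ + β̂_k
        c = I * K - (K - 1) - 2
    elif target == "common":
        fitted = mu
        c = I * K - 3
    else:
        raise ValueError(f"unknown shrinkage target {target!r}")
    if c <= 0:
        raise ValueError(f"too few genes/groups for target {target!r} (constant {c} <= 0)")
    resid = X - fitted
    S = np.sum(resid**2, axis=(-2, -1), keepdims=True)
    with np.errstate(divide="ignore"):
        f = np.maximum(0.0, 1.0 - c * moments.s2 / np.where(S > 0, S, np.inf))
    values = np.exp(moments.m + fitted + f * resid)
    return values, f[..., 0, 0]


def shrink(target: str, group_var: np.ndarray, moments: LogChiSquareMoments) -> ShrunkenVarianceTable:
    """Positive-part shrinkage of the I×K variance table toward ``target``.

    ``moments`` must be the log-chi-square moments for the per-cell df ν.
    """
    gv = np.asarray(group_var, dtype=float)
    if gv.ndim != 2:
        raise ValueError("group_var must be an I x K matrix")
    if np.any(gv < 0):
        raise ValueError("negative variance estimates")
    values, f = _shrink_values(target, gv, moments)
    return ShrunkenVarianceTable(target=target, values=values, shrinkage_factor=float(f))


def _shrink_cui_values(mse: np.ndarray, moments: LogChiSquareMoments
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Batched core of :func:`shrink_cui`; ``mse`` has shape ``(..., I)``."""
    mse = np.asarray(mse, dtype=float)
    I = mse.shape[-1]
    if I <= 3:
        raise ValueError(f"Cui estimator needs I >= 4 genes, got {I}")
    X = np.log(np.maximum(mse, VAR_FLOOR)) - moments.m
    Xbar = X.mean(axis=-1, keepdims=True)
    resid = X - Xbar
    S = np.sum(resid**2, axis=-1, keepdims=True)
    with np.errstate(divide="ignore"):
        f = np.maximum(0.0, 1.0 - (I - 3) * moments.s2 / np.where(S > 0, S, np.inf))
    values = np.exp(moments.m + Xbar + f * resid)
    return values, f[..., 0]


def shrink_cui(mse: np.ndarray, moments: LogChiSquareMoments) -> ShrunkenVarianceTable:
    """Gene-level shrinkage of the per-gene MSE toward its common mean.

    ``moments`` must be computed at ``K·ν`` degrees of freedom (the df of
    the pooled per-gene residual mean square).
    """
    mse = np.asarray(mse, dtype=float)
    if mse.ndim != 1:
        raise ValueError("mse must be a length-I vector")
    if np.any(mse < 0):
        raise ValueError("negative variance estimates")
    values, f = _shrink_cui_values(mse, moments)
    return ShrunkenVarianceTable(target="cui", values=values, shrinkage_factor=float(f))
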