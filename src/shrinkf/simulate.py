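"""Synthetic split-plot expression data with controlled heteroscedasticity.

Data are generated gene by gene from the split-plot model

    y_pkr = P_p + L_k + RL_kr + PL_pk + ε_pkr

with probe p, group (line) k, replicate r nested in line.  Main effects
are generated as zero: every implemented statistic is invariant to
additive probe and line effects, so nonzero values would only clutter the
truth records.  The whole-plot random effect RL defaults to zero variance
as well and can be switched on for robustness studies.

Four null variance structures are available, plus variants with a
quantitative probe-by-line interaction of magnitude δ:

==========  ===========================================================
null-ce     all observations iid standard normal (common error)
null-gh     gene-specific variances ~ lognormal(meanlog 0, sdlog 2),
            identical across lines (between-gene heteroscedasticity)
null-wgh    every gene has line-1 variance = 100 x line-2 variance
            (within-gene heteroscedasticity; line-2 variance is 1)
null-bgh    null-gh with line-1 variance additionally x 100 (both)
ce/gh/...   same structures plus the ±δ/2 interaction pattern
==========  ===========================================================

The interaction is the canonical 2x2 opposite-direction contrast:
+δ/2 on the (probe1, line1) and (probe2, line2) cells, −δ/2 on the other
two (placed on the first 2x2 subtable when P or K exceeds 2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .anova import ExperimentDesign

__all__ = ["ScenarioConfig", "SCENARIOS", "generate", "delta_for_power"]

SCENARIOS = ("null-ce", "null-gh", "null-wgh", "null-bgh", "ce", "gh", "wgh", "bgh")


@dataclass(frozen=True)
class ScenarioConfig:
    """One named simulation scenario with all distributional parameters."""

    name: str = "null-ce"
    n_genes: int = 100
    n_probes: int = 2
    n_groups: int = 2
    n_reps: int = 3
    lognormal_sdlog: float = 2.0    # sdlog of gene-specific error variances (gh/bgh)
    wgh_ratio: float = 100.0        # line-1 variance multiplier (wgh/bgh)
    interaction_delta: float = 0.0  # δ, magnitude of the probe x line interaction
    whole_plot_sd: float = 0.0      # SD of the RL random effect
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIOS}")
        if self.name.startswith("null-") and self.interaction_delta != 0:
            raise ValueError("null-* scenarios require interaction_delta = 0")
        if self.wgh_ratio <= 0 or self.lognormal_sdlog < 0 or self.interaction_delta < 0:
            raise ValueError("invalid scenario parameters")

    @property
    def base(self) -> str:
        """Variance structure without the null- prefix: ce/gh/wgh/bgh."""
        return self.name.removeprefix("null-")


@dataclass(frozen=True)
class TruthRecord:
    """Generative ground truth: per-gene true group variances and δ."""

    group_variances: np.ndarray   # (I, K)
    interaction_delta: float
    scenario: str


def _group_variances(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    I, K = config.n_genes, config.n_groups
    base = config.base
    if base == "ce":
        var = np.ones((I, K))
    elif base == "gh":
        var = np.repeat(rng.lognormal(0.0, config.lognormal_sdlog, size=I)[:, None], K, axis=1)
    elif base == "wgh":
        var = np.ones((I, K))
        var[:, 0] = config.wgh_ratio
    else:  # bgh
        var = np.repeat(rng.lognormal(0.0, config.lognormal_sdlog, size=I)[:, None], K, axis=1)
        var[:, 0] *= config.wgh_ratio
    return var


def _interaction_pattern(design: ExperimentDesign, delta: float) -> np.ndarray:
    """±δ/2 cell offsets as a length-n vector in observation order."""
    pl = np.zeros(design.n_obs)
    if delta == 0:
        return pl
    on_diag = (design.probe_idx == design.group_idx)
    in_block = (design.probe_idx < 2) & (design.group_idx < 2)
    pl[in_block] = np.where(on_diag[in_block], delta / 2.0, -delta / 2.0)
    return pl


def generate(config: ScenarioConfig) -> tuple[np.ndarray, ExperimentDesign, TruthRecord]:
    """Generate one gene x observation matrix plus its design and truth.

    Deterministic: identical config (including seed) gives a bitwise
    identical dataset.
    """
    design = ExperimentDesign.balanced(config.n_probes, config.n_groups, config.n_reps)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    var = _group_variances(config, rng)                       # (I, K)
    sd_per_obs = np.sqrt(var)[:, design.group_idx]            # (I, n)
    Y = rng.standard_normal((config.n_genes, design.n_obs)) * sd_per_obs
    if config.whole_plot_sd > 0:
        rl = rng.normal(0.0, config.whole_plot_sd,
                        size=(config.n_genes, config.n_groups, config.n_reps))
        Y += rl[:, design.group_idx, design.rep_idx]
    Y += _interaction_pattern(design, config.interaction_delta)[None, :]
    truth = TruthRecord(group_variances=var, interaction_delta=config.interaction_delta,
                        scenario=config.name)
    return Y, design, truth


def expected_error_variance(config: ScenarioConfig) -> float:
    """Mean error variance entering MSE, averaged over groups and genes."""
    base = config.base
    gh_mean = float(np.exp(config.lognormal_sdlog**2 / 2.0))
    per_group_one = {"ce": 1.0, "gh": gh_mean, "wgh": 1.0, "bgh": gh_mean}[base]
    group_mult = np.ones(config.n_groups)
    if base in ("wgh", "bgh"):
        group_mult[0] = config.wgh_ratio
    return per_group_one * float(group_mult.mean())


def delta_for_power(target_power: float, scenario: ScenarioConfig | str,
                    alpha: float = 0.05, msi_df: int | None = None,
                    mse_df: int | None = None) -> float:
    """Interaction magnitude δ giving the tabled-p F1 test a target power.

    Uses the noncentral-F relationship for the 2x2 interaction contrast:
    with R replicates per (probe, line) cell the noncentrality is
    ``λ = R δ² / σ²_eff`` where σ²_eff is the average error variance
    entering MSE.  Monotone in δ, solved by bracketing root-finding.
    """
    if not (0 < target_power < 1):
        raise ValueError("target power must be in (0, 1)")
    cfg = ScenarioConfig(name=scenario) if isinstance(scenario, str) else scenario
    d1 = msi_df if msi_df is not None else (cfg.n_probes - 1) * (cfg.n_groups - 1)
    d2 = mse_df if mse_df is not None else cfg.n_groups * (cfg.n_probes - 1) * (cfg.n_reps - 1)
    sigma2 = expected_error_variance(cfg)
    crit = sps.f.ppf(1.0 - alpha, d1, d2)

    def power(delta: float) -> float:
        lam = cfg.n_reps * delta**2 / sigma2
        return float(sps.ncf.sf(crit, d1, d2, lam))

    if target_power <= alpha + 1e-12:
        if abs(target_power - alpha) < 1e-12:
            return 0.0
        raise ValueError(f"target power {target_power} below the level {alpha} is unattainable")
    hi = 1.0
    while power(hi) < target_power:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("target power unattainable")
    return float(optimize.brentq(lambda d: power(d) - target_power, 0.0, hi, xtol=1e-10))


def with_interaction(config: ScenarioConfig, delta: float) -> ScenarioConfig:
    """Effect-scenario twin of a null config with interaction magnitude δ."""
    return replace(config, name=config.base, interaction_delta=delta)
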