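# Methods

## Model and decomposition

Each gene is observed on a balanced split-plot design: `P ≥ 2` probes
(subplot factor) crossed with `K ≥ 2` groups ("lines"), with `R ≥ 2`
replicates nested within each group. The generative model per gene is

    y_pkr = P_p + L_k + RL_kr + PL_pk + ε_pkr ,

where `RL` is the whole-plot (replicate-within-line) random effect and
`PL` the probe-by-line interaction under test. For a balanced design the
interaction mean square (MSI, df `(P−1)(K−1)`) is tested against the
subplot residual mean square (MSE, df `K(P−1)(R−1)`), and both are
closed-form sums of squares; no REML or mixed-model iteration is used.
This is exact for balanced data and orders of magnitude faster inside
permutation loops, which is why unbalanced designs are rejected outright
rather than approximated.

The group-specific residual variance `σ̂²_{ik}` is the residual mean
square of the additive probe + replicate two-way fit inside group *k*
(df `ν = (P−1)(R−1)`). Summed over groups this reproduces the full-model
residual SS, giving the identity `MSE = mean_k σ̂²_{ik}` that the tests
enforce.

## Shrinkage estimators

On the log scale, `X_{ik} = log σ̂²_{ik} − m` is an unbiased estimate of
`log σ²_{ik}`, with `m = ψ(ν/2) + log(2/ν)` and known variance
`s² = ψ′(ν/2)`. The moments are computed analytically from
digamma/trigamma rather than from simulation tables: exact, reproducible,
and any residual difference from tabulated approximations only rescales
the estimators by a constant, which cancels in permutation p-values (a
property the suite tests end-to-end).

Each estimator shrinks `X` toward a least-squares fitted subspace with a
single positive-part factor `f = (1 − c·s²/S)₊`, where `S` is the
residual sum of squares around the target fit:

| target | fitted value | constant `c` |
|---|---|---|
| gene × group additive (`gen`) | `μ̂ + α̂_i + β̂_k` | `IK − (I+K−1) − 2` |
| gene (`gene`) | `μ̂ + α̂_i` | `IK − (I−1) − 2` |
| group (`group`) | `μ̂ + β̂_k` | `IK − (K−1) − 2` |
| common (`common`) | `μ̂` | `IK − 3` |
| Cui (per-gene MSE, `Kν` df) | mean of `X_i` | `I − 3` |

All five return `exp(m + fitted + f·residual)`. The constants are used
exactly as printed in the originating formulas even though the gene- and
group-target ones are one larger than the canonical James–Stein `n−d−2`
for their subspace dimensions; with `I = 100` genes the difference is
far below Monte-Carlo resolution. The published displays are inconsistent
about whether the gene-by-group estimator carries the `+m` term; the
family is implemented uniformly with `+m`, and the end-to-end scale
invariance above makes the choice inferentially immaterial. The
method-of-moments `τ̂²` is exposed for diagnostics only — the
positive-part factor absorbs it.

Zero variance estimates (possible for degenerate genes) are floored at
1e−300 before the log; if the residual SS around the target is zero the
factor is set to 0 (full shrinkage), the continuous limit of the
formulas. Zero statistic denominators map to `+inf`, which ranks above
every finite null value, making the resulting p-values conservative.

## Permutation procedures

Interaction terms admit no exact permutation test, so approximate nulls
are built from B column bijections of either the raw matrix or the
residuals of the reduced fixed model with probe and group effects only
(`r = y − ȳ_p − ȳ_k + ȳ`). Permuted residuals are analyzed directly as
data, without re-adding the reduced-model fits: additive probe/group
structure is annihilated by every statistic, an identity the suite
verifies numerically.

Two design choices deserve note because the originating description
leaves them open:

* **Shared column bijections.** One bijection per permutation replicate is
  applied to every gene's row (default). The shrinkage denominators couple
  genes, and a shared permutation preserves that cross-gene structure.
  The alternative — independent bijections per gene — is available via
  `share_indices_across_genes=False` for sensitivity analysis, but it
  decouples the pooled denominators from the permuted numerators and
  drives statistics with strongly pooled denominators (`F3`, `FGenGrp`)
  to severely conservative error rates under restricted permutation, a
  behavior incompatible with the reference simulation tables.
* **Synchronized restriction.** Restricted permutations never move an
  observation across group levels. They are implemented by drawing one
  random bijection of the `P·R` (probe, replicate) subplot slot labels
  and applying it inside *every* group block, so all groups are relabeled
  coherently. Independent within-group bijections are the other natural
  reading; both preserve the within-group value multisets, but only the
  synchronized form reproduces the characteristic conservative behavior
  of restricted residual permutation in the reference tables (e.g. F1
  near 4.6% rather than 5.9% under a common-error null), so it is the
  implemented behavior.

p-values use the add-one estimator `(1 + #{null ≥ observed})/(B + 1)`
with ties counted against the null. Defaults are B = 1000 and α = 0.05.
A single integer seed determines the whole permutation stream through
`numpy` `SeedSequence` spawning, so results are reproducible and cells
can be recomputed independently.

## Simulation scenarios

The generator emulates a small oligonucleotide study: 100 genes, 2 probes,
2 lines, 3 replicates per line. Error structures:

* `null-ce` — all observations iid standard normal;
* `null-gh` — gene variances lognormal (meanlog 0, sdlog 2), equal across
  lines;
* `null-wgh` — line-1 variance 100 × line-2 (variance scale), identical
  across genes;
* `null-bgh` — `null-gh` with line-1 variance additionally × 100.

`ce/gh/wgh/bgh` add a quantitative interaction: ±δ/2 offsets of opposite
sign on the first 2×2 probe-by-line subtable. Main effects are generated
as zero because every statistic is provably invariant to them, and the
whole-plot standard deviation defaults to zero (the common-error
description implies no separate whole-plot variance in generation) but is
configurable. `delta_for_power` calibrates δ against the tabled-p F1 test
through the noncentral-F relationship `λ = R δ²/σ²_eff`, with `σ²_eff`
the expected error variance entering MSE for the scenario.

What the generator does **not** emulate: correlation between genes,
non-normal errors, probe-sequence effects, and unbalanced designs.
Calibration results under these scenarios therefore demonstrate
correctness of the procedures under the stated model, not robustness to
real-data pathologies beyond the two heteroscedasticity types.

## Error-rate estimation

A CWER/power cell averages per-gene rejection indicators over genes and
simulation runs; the reported standard error is the SD of the pooled
indicators divided by `sqrt(total gene-tests)` (the pooled-indicator
convention, which matches the magnitude of the reference tables'
standard errors). The acceptance script runs 900 simulation runs of 100
genes with B = 1000 permutations per cell — the same scale as the
reference study; the test suite uses 40–150 runs and B = 200–400 for the
qualitative pattern checks to keep it fast.

## Known limitations

* Balanced designs only; covariates and more than two crossed fixed
  factors are out of scope.
* The Cui-type estimator requires `I ≥ 4` genes; the generalized targets
  need `IK` large enough that their James–Stein constants are positive.
* Restricted permutation requires at least two observations per group.
* Under within-gene heteroscedasticity the raw-data unrestricted
  procedure and the `F1`/`FCui` statistics are included for comparison
  but are not valid tests; the CLI warns on these pairings.
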