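# Methods

This document describes the models, estimators and numerical choices behind
`demoscope`. The package addresses a classic confounding problem in
demographic inference: a genome-wide coalescence-rate trajectory (what PSMC
estimates) produced by a *structured* population with changing connectivity
is indistinguishable, curve-for-curve, from that of a *panmictic* population
with changing size. The package provides both readings of the data and the
machinery to compare them.

## 1. The IICR under the n-island model

For a sample of two gene copies with coalescence time `T2`, the inverse
instantaneous coalescent rate is

```
IICR(t) = P(T2 > t) / f_T2(t)
```

Under panmixia this equals the (relative) population-size trajectory
`lambda(t)`; under structure it does not, which is the crux of the
confounding.

We model a symmetric n-island metapopulation with piecewise-constant
parameters. For two lineages the state space collapses to three states:
`same` (both lineages in one deme), `diff` (different demes), and
`coalesced`. Within an epoch with scaled migration rate `M` and relative
deme size `lambda` the generator is

```
           same                diff             coalesced
same    -(1/lambda + M)         M                1/lambda
diff      M/(n-1)           -M/(n-1)                0
```

(rows sum to zero; `coalesced` is absorbing). Time is measured in units of
`N` (haploid deme size) generations.

* **Exact IICR** (`iicr_exact`): propagate the state distribution through
  the epochs with matrix exponentials; `IICR(t) = lambda(t) * (p_same +
  p_diff) / p_same` where `p_*` are the non-absorbed state probabilities.
* **Closed-form checks**: `E[T2 | same] = n * lambda` independent of `M`,
  and `E[T2 | diff] = n * lambda + (n-1)/M` for constant parameters; the
  large-`t` IICR plateau follows from the dominant eigenvector.
* **Simulation** (`simulate_t2`): exact Gillespie jumps of the same chain,
  with epoch boundaries clamping waiting times (valid by memorylessness).

### The windowed empirical IICR and its discretization bias

The empirical estimator on a window `[a, b)` is
`(1 - F(a)) * (b - a) / (F(b) - F(a))` with `F` the empirical CDF of the
draws. Its estimand is not the pointwise IICR but the *windowed functional*
`S(a) * (b - a) / (S(a) - S(b))`, which under a constant-rate truth equals
`dt / (1 - exp(-dt))` with `dt = b - a` — an upward bias that grows with
window width (79% for a window of width 1.4 in coalescent units). No
consistent estimator of this form can be uniformly within a few percent of
the pointwise IICR on wide log-spaced windows. Tests therefore compare the
estimator against the exact windowed functional (`exact_windowed_iicr`),
restricted to well-populated windows (>= 20,000 events out of 10^6 draws),
where the Monte-Carlo sup-deviation across ~20-40 windows stays below 2%.

## 2. PSMC parsing and scaling

`parse_psmc` reads the standard PSMC text output, keeps the final (converged)
`TR`/`RS` block, and scales with

```
N0 = theta / (4 * mu * s),    t_years = 2 * N0 * t_k * g,    N_k = lambda_k * N0
```

with per-site mutation rate `mu`, bin size `s` bp and generation time `g`.
The study constants are `mu = 1.2e-8` (pedigree-based mouse-lemur estimate),
`s = 100`, and `g` in {1.0, 2.5, 4.5} with 2.5 primary. The unbounded last
interval is closed geometrically (`t_end = t_last^2 / t_prev`).

## 3. Fitting connectivity histories to an IICR curve

`fit_connectivity` minimizes the RMS of `log10` differences between the
target curve and a candidate IICR on a log-spaced grid — scale-free in both
axes. Two candidate families compete directly: n-island models with `c`
connectivity changes (sizes fixed), and panmictic models with `c` size
changes.

Key choices:

* **Identical rendering pipeline.** When the target is a step curve (the
  shape PSMC emits and `make_target_curve` produces), candidates are
  sampled on the same log grid, log-log interpolated and trapezoid-averaged
  over the target's own intervals — the same arithmetic used to generate
  synthetic targets. A target discretized from a candidate model therefore
  scores *exactly* zero, making noise-free recovery exact rather than
  approximate.
* **Search.** Per (family, island count, change count): deterministic
  coordinate descent over default grids (change times at 16 points per
  decade on [0.01, 10]; migration on {0} plus 25 log-spaced points over
  [0.01, 100], the study's stated ranges), followed by a joint bounded
  L-BFGS-B polish of the log-coordinates started both from the grid optimum
  and from a change-point-style init at the target's largest level jumps.
  The polish is what resolves the narrow, correlated valley around the true
  (times, rates) vector; grid-only search plateaus at a distance floor set
  by grid resolution.
* **Parsimony.** Ties (distances equal after rounding to 12 decimals) are
  broken by fewer changes, then fewer islands, then smaller total migration.

The reference recovery experiment generates the noise-free 64-interval
discretization of the best structured model — 29 islands with connectivity
changes at 1.5, 12.5, 40 and 65 kyr (coalescent times scaled by one unit =
2 * 5000 * 2.5 years) and per-epoch `M` levels on the default grid — and
searches islands 20-40 with four changes. The search recovers the island
count and all four change times to within ~1e-5 relative error.

## 4. SFS composite likelihood and model selection

The folded SFS (1d or joint 2d) is indexed by minor-allele counts; cell
`(i, j)` and its complement are merged onto a canonical cell and monomorphic
corners are masked. Expected spectra come from Monte-Carlo genealogies: a
Gillespie simulator over event-based multi-deme demographies (deme sizes,
`2NM0` migration, resize / merge / set-migration events) accumulates the
branch length subtending each sample-configuration class; normalized branch
lengths are the SNP class probabilities under infinite sites. The simulator
is validated against closed forms (e.g. the folded constant-size `n = 4`
law `(8/11, 3/11)`), against the two-lineage chain of Section 1 (an island
scenario with haploid deme size `N` and migration `G = 2NM0` matches the
chain with `M = 2G` and time unit `N` generations), and against msprime.

The composite log-likelihood treats SNPs as independent draws:
`lnCL = sum_e m_e ln p_e` over canonical cells, with expected probabilities
floored at `eps = 1e-10` and renormalized. Model selection uses
`AIC = 2k - 2 lnCL` and reports delta-AIC. Fitting is multi-start
Nelder-Mead in log-transformed coordinates with common random numbers
across evaluations; 1-D profile estimation scans a log grid and refines by
golden-section search with the same variance-reduction trick.

The scenario registry M1-M13 mirrors the study's candidate set, with M7
(three demes — north, south, ghost — with migration `2NM0`, a stepwise size
change at `T1` and panmictic ancestry of size `NANC` beyond `T2`) as the
best-supported model, parameterized by the Table-1 ML values.

### Identifiability of T1

The generating M7 parameter set moves the deme size by only ~3% at `T1`
(14,329 -> 13,937 haploid). At `S = 50,000` SNPs the composite-likelihood
signal over the whole admissible `T1` range is below ~0.2 lnCL units —
smaller than the Monte-Carlo evaluation noise — so the profile estimate of
`T1` is essentially unconstrained by construction. The corresponding
acceptance check is expected to fail, and the failure is informative: it
reproduces, on synthetic data, how weakly this parameter is determined.

## 5. Bootstrap confidence intervals

`block_bootstrap` resamples SNP blocks (the linkage units; 50 SNPs per
block by default, standing in for RAD loci) with replacement, rebuilds the
observed SFS and re-estimates parameters per replicate; percentile CIs are
reported. A pluggable `fit_fn` lets replicates use a cheap 1-D profile
instead of a full refit. Coverage is checked on a controlled one-parameter
family (two demes, free `2NM0`, joint 6+6 SFS) where the truth is known:
nominal 95% intervals must cover in a single `B = 100` run and must achieve
>= 13/15 coverage over independent datasets (two binomial standard errors
below nominal). The percentile CI of a composite likelihood need not
contain the ML point — the study's own ancestral-size estimate falls
outside its CI, which the data structures deliberately permit.

## 6. Synthetic data realism

* SNP data: multinomial draws from the expected folded SFS in consecutive
  blocks (i.i.d. mode), or one genealogy per block with that block's SNPs
  drawn from its own branch-length spectrum (linked mode, inducing the
  within-block correlation the block bootstrap exists to absorb).
* IICR targets: exact model IICR discretized to 64 log-spaced intervals
  (PSMC-like), optionally with per-interval multiplicative lognormal noise
  mimicking the scale-proportional scatter of PSMC bootstrap replicates.
* All generators are seed-deterministic; fixtures round-trip losslessly
  through TSV/JSON with a manifest recording types and seeds.

## 7. Limitations

* The genealogy simulator is Monte-Carlo; expected-SFS noise at feasible
  replicate counts (1e4-1e6) sets the floor on profile precision. Common
  random numbers mitigate but do not remove this.
* The composite likelihood ignores linkage; its CIs are percentile
  bootstrap, not likelihood-ratio intervals.
* `fit_connectivity` fixes deme sizes within the island family (sizes and
  connectivity are not jointly free), matching the study's design.
* PSMC itself is consumed via its output files; no HMM inference is
  reimplemented.
* Windowed empirical IICR values in sparsely populated windows (tails) are
  noise-dominated and are merged/excluded rather than corrected.
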