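"""Composite-likelihood fitting of demographic scenarios to folded spectra,
AIC model ranking, 1-D profile estimation and block-bootstrap CIs.

The composite log-likelihood treats SNPs as independent draws from the
expected folded spectrum: ``lnCL = sum_e m_e ln p_e`` over unmasked
polymorphic cells, with expected probabilities floored at ``eps`` and
renormalized so cells observed but unattainable under a candidate model
penalize rather than annihilate it.  AIC = 2k - 2 lnCL (natural log
throughout; ranking is invariant to the base as long as it is consistent).
Fitting is derivative-free multi-start Nelder-Mead in log-transformed
coordinates with common random numbers across evaluations, mirroring a
"keep the run with the highest composite likelihood" strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .genealogy import expected_sfs
from .scenarios import ScenarioTemplate
from .sfs import BlockedSNPs, FoldedSFS

__all__ = [
    "FitOptions",
    "ModelFit",
    "ModelRanking",
    "BootstrapCI",
    "composite_loglik",
    "fit_scenario",
    "profile_parameter",
    "rank_models",
    "block_bootstrap",
]


@dataclass(frozen=True)
class FitOptions:
    """Knobs of a composite-likelihood fit.

    R: replicate genealogies per likelihood evaluation (>= 100).
    eps: zero-probability floor (0 < eps <= 1e-6).
    n_starts: multi-start count; budget: function evaluations per start.
    common_random_numbers: reuse one simulation seed across evaluations so
    differences between parameter vectors are not drowned in Monte-Carlo
    noise.
    """

    R: int = 10_000
    eps: float = 1e-10
    n_starts: int = 20
    budget: int = 200
    seed: int = 0
    common_random_numbers: bool = True

    def __post_init__(self) -> None:
        if self.R < 100:
            raise ValueError("R must be >= 100")
        if not (0 < self.eps <= 1e-6):
            raise ValueError("eps must be in (0, 1e-6]")
        if self.n_starts < 1:
            raise ValueError("need at least one start")
        if self.budget < self.n_starts:
            raise ValueError("budget must cover at least one evaluation per start")


@dataclass(frozen=True)
class ModelFit:
    template_id: str
    params: dict
    lnCL: float
    k: int
    n_evaluations: int = 0

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.lnCL


@dataclass(frozen=True)
class ModelRanking:
    fits: tuple[ModelFit, ...]
    delta_aic: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(self.delta_aic[0]) > 1e-9 or any(
            d2 < d1 for d1, d2 in zip(self.delta_aic, self.delta_aic[1:])
        ):
            raise ValueError("delta AIC must start at 0 and be non-decreasing")

    @property
    def best(self) -> ModelFit:
        return self.fits[0]


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap bounds per parameter.  The ML estimate is not
    required to fall inside (composite-likelihood CIs can exclude it, as the
    ancestral-size estimate of the study itself illustrates)."""

    lower: dict
    upper: dict
    B: int
    level: float = 0.95
    estimates: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in self.lower:
            if self.lower[name] > self.upper[name]:
                raise ValueError(f"lower > upper for {name}")


def composite_loglik(obs: FoldedSFS, expected: FoldedSFS, eps: float = 1e-10) -> float:
    """Multinomial composite log-likelihood of observed counts under expected
    cell probabilities (floored at eps, then renormalized)."""
    if obs.sample_sizes != expected.sample_sizes:
        raise ValueError("observed and expected SFS shapes do not match")
    m = obs.flat()
    if m.sum() < 1:
        raise ValueError("observed SFS holds no SNPs")
    p = np.maximum(expected.flat(), eps)
    p = p / p.sum()
    return float(m @ np.log(p))


def _eval_seed(options: FitOptions, counter: int) -> int:
    if options.common_random_numbers:
        return options.seed % (2**31 - 1)
    return (options.seed * 1_000_003 + counter) % (2**31 - 1)


def _objective_factory(obs: FoldedSFS, template: ScenarioTemplate, options: FitOptions):
    nsam = obs.sample_sizes
    state = {"count": 0}

    def neg_lnCL(x: np.ndarray) -> float:
        params = template.from_vector(x)
        scenario = template.build(params)
        seed = _eval_seed(options, state["count"])
        state["count"] += 1
        try:
            exp = expected_sfs(scenario, nsam, R=options.R, seed=seed)
        except (ValueError, RuntimeError):
            return 1e12
        return -composite_loglik(obs, exp, options.eps)

    return neg_lnCL, state


def fit_scenario(
    obs: FoldedSFS, template: ScenarioTemplate, options: FitOptions
) -> ModelFit:
    """Multi-start bounded Nelder-Mead maximization of the composite
    likelihood over the template's parameter box (log scale where flagged)."""
    neg_lnCL, state = _objective_factory(obs, template, options)
    rng = np.random.default_rng(options.seed)
    lo = np.array([np.log(b[0]) if b[2] else b[0] for b in template.bounds.values()])
    hi = np.array([np.log(b[1]) if b[2] else b[1] for b in template.bounds.values()])
    bounds = optimize.Bounds(lo, hi)
    best_x, best_f = None, np.inf
    starts = [lo + (hi - lo) * rng.random(len(lo)) for _ in range(options.n_starts)]
    if template.defaults:
        starts[0] = template.to_vector(template.defaults)
    for x0 in starts:
        res = optimize.minimize(
            neg_lnCL,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxfev": options.budget, "xatol": 1e-3, "fatol": 1e-3},
        )
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    params = template.from_vector(best_x)
    return ModelFit(
        template.template_id,
        params,
        lnCL=-best_f,
        k=template.k,
        n_evaluations=state["count"],
    )


def profile_parameter(
    obs: FoldedSFS,
    template: ScenarioTemplate,
    name: str,
    fixed: dict,
    options: FitOptions,
    bounds: tuple[float, float] | None = None,
    n_grid: int = 15,
    refine_iters: int = 12,
) -> tuple[float, np.ndarray, np.ndarray]:
    """1-D profile composite likelihood: scan ``name`` on a (log) grid with
    every other parameter fixed, then refine around the best grid point by
    deterministic golden-section search.

    Returns (estimate, grid, lnCL values on the grid).
    """
    lo_b, hi_b, log = template.bounds[name]
    if bounds is not None:
        lo_b, hi_b = bounds
    grid = np.geomspace(lo_b, hi_b, n_grid) if log else np.linspace(lo_b, hi_b, n_grid)
    state = {"count": 0}

    def lnCL_at(value: float) -> float:
        params = dict(fixed)
        params[name] = float(value)
        scenario = template.build(params)
        seed = _eval_seed(options, state["count"])
        state["count"] += 1
        exp = expected_sfs(scenario, obs.sample_sizes, R=options.R, seed=seed)
        return composite_loglik(obs, exp, options.eps)

    values = np.array([lnCL_at(g) for g in grid])
    i = int(np.argmax(values))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    if log:
        a, b = np.log(a), np.log(b)

    # golden-section maximization on [a, b]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc = lnCL_at(np.exp(c) if log else c)
    fd = lnCL_at(np.exp(d) if log else d)
    for _ in range(refine_iters):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = lnCL_at(np.exp(c) if log else c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = lnCL_at(np.exp(d) if log else d)
    x = 0.5 * (a + b)
    est = float(np.exp(x)) if log else float(x)
    # keep the grid point if refinement did not beat it
    best_ref = max(fc, fd)
    if values[i] > best_ref:
        est = float(grid[i])
    return est, grid, values


def rank_models(fits: list[ModelFit]) -> ModelRanking:
    if not fits:
        raise ValueError("need at least one fit to rank")
    ordered = tuple(sorted(fits, key=lambda f: f.aic))
    best = ordered[0].aic
    return ModelRanking(ordered, tuple(f.aic - best for f in ordered))


def block_bootstrap(
    blocks: BlockedSNPs,
    template: ScenarioTemplate,
    B: int,
    options: FitOptions,
    fit_fn=None,
    level: float = 0.95,
) -> BootstrapCI:
    """Percentile CIs from B block-bootstrap replicates.

    Blocks are resampled with replacement to the original block count, the
    observed SFS rebuilt and the template refit.  ``fit_fn(obs, seed) ->
    dict`` may replace the default full refit (e.g. a 1-D profile) to keep
    replicate cost down.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(options.seed)
    n_blocks = len(blocks.blocks)
    estimates: list[dict] = []
    for b in range(B):
        ids = rng.integers(0, n_blocks, size=n_blocks)
        obs_b = blocks.to_sfs(ids)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if fit_fn is not None:
            estimates.append(fit_fn(obs_b, rep_seed))
        else:
            fit = fit_scenario(obs_b, template, replace(options, seed=rep_seed))
            estimates.append(fit.params)
    names = list(estimates[0])
    alpha = (1.0 - level) / 2.0
    lower, upper = {}, {}
    for name in names:
        vals = np.array([e[name] for e in estimates])
        lower[name] = float(np.quantile(vals, alpha))
        upper[name] = float(np.quantile(vals, 1.0 - alpha))
    return BootstrapCI(lower, upper, B=B, level=level, estimates=tuple(estimates))
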