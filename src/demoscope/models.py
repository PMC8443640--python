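"""Two-lineage structured coalescent under piecewise-constant n-island demographies.

Time is measured in coalescent units of ``2 * N_ref`` generations.  A pair of
lineages in the same deme coalesces at rate ``1 / lambda`` (``lambda`` is the
deme size relative to ``N_ref``); each lineage migrates at rate ``M / 2``, so
the pair moves same -> different demes at rate ``M`` and back at rate
``M / (n - 1)``.  With these conventions the classical identities
``E[T2 | same] = n * lambda`` and ``E[T2 | diff] = n * lambda + (n - 1) / M``
hold for a single epoch and serve as free analytic checks.

The inverse instantaneous coalescent rate (IICR) of a sample of two is
``P(T2 > t) / f(t)``; under panmixia it equals the size trajectory
``lambda(t)``, while under structure it mixes size and connectivity -- which is
exactly why a PSMC curve cannot by itself distinguish the two.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .curves import IICRCurve

__all__ = [
    "EpochSchedule",
    "IslandModel",
    "PanmicticModel",
    "T2Sample",
    "CoalescenceUnreachableError",
    "DivergentExpectationError",
    "island_generator",
    "iicr_exact",
    "simulate_t2",
    "empirical_iicr",
    "mean_t2",
    "default_grid",
    "model_to_dict",
    "model_from_dict",
]

SAME, DIFF, COAL = 0, 1, 2


class CoalescenceUnreachableError(ValueError):
    """Raised when the sampled configuration can never coalesce (M = 0 everywhere)."""


class DivergentExpectationError(ValueError):
    """Raised when E[T2] is infinite (absorbing state unreachable in the last epoch)."""


@dataclass(frozen=True)
class EpochSchedule:
    """Piecewise-constant (migration, size) schedule.

    ``breakpoints[k]`` is the start of epoch ``k`` in coalescent units; the
    first breakpoint must be exactly 0 and the last epoch is unbounded.
    """

    breakpoints: tuple[float, ...]
    M: tuple[float, ...]
    lam: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = tuple(float(t) for t in self.breakpoints)
        M = tuple(float(m) for m in self.M)
        lam = tuple(float(x) for x in self.lam)
        if len(bp) == 0 or bp[0] != 0.0:
            raise ValueError("first breakpoint must be exactly 0")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if not (len(bp) == len(M) == len(lam)):
            raise ValueError("breakpoints, M and lam must have equal length")
        if any(m < 0 for m in M):
            raise ValueError("migration rates must be >= 0")
        if any(x <= 0 for x in lam):
            raise ValueError("size scales must be > 0")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "lam", lam)

    @property
    def n_epochs(self) -> int:
        return len(self.breakpoints)

    def epoch_index(self, t: np.ndarray) -> np.ndarray:
        return np.clip(
            np.searchsorted(self.breakpoints, t, side="right") - 1, 0, self.n_epochs - 1
        )

    def lam_at(self, t: np.ndarray) -> np.ndarray:
        return np.asarray(self.lam)[self.epoch_index(np.asarray(t, dtype=float))]

    @classmethod
    def constant(cls, M: float = 0.0, lam: float = 1.0) -> "EpochSchedule":
        return cls((0.0,), (float(M),), (float(lam),))


@dataclass(frozen=True)
class IslandModel:
    """Symmetric n-island model: ``n`` demes of relative size ``lam`` exchanging
    migrants at scaled rate ``M`` per epoch."""

    n: int
    schedule: EpochSchedule
    sampling: str = "same_deme"

    def __post_init__(self) -> None:
        if int(self.n) < 2:
            raise ValueError("island count must be >= 2")
        if self.sampling not in ("same_deme", "different_demes"):
            raise ValueError("sampling must be 'same_deme' or 'different_demes'")
        object.__setattr__(self, "n", int(self.n))


@dataclass(frozen=True)
class PanmicticModel:
    """Single panmictic population whose size follows ``schedule.lam``;
    migration entries of the schedule are ignored."""

    schedule: EpochSchedule


Model = IslandModel | PanmicticModel


@dataclass(frozen=True)
class T2Sample:
    """Seeded sample of pairwise coalescence times (coalescent units)."""

    draws: np.ndarray
    seed: int
    model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=float)
        if draws.size < 1:
            raise ValueError("T2Sample requires at least one draw")
        if np.any(draws <= 0):
            raise ValueError("all coalescence times must be > 0")
        object.__setattr__(self, "draws", draws)


def island_generator(n: int, M: float, lam: float) -> np.ndarray:
    """3x3 rate matrix over the 2-lineage states (same, diff, coalesced)."""
    if n < 2:
        raise ValueError("island count must be >= 2")
    if M < 0:
        raise ValueError("migration rate must be >= 0")
    if lam <= 0:
        raise ValueError("size scale must be > 0")
    c = 1.0 / lam
    back = M / (n - 1)
    return np.array(
        [
            [-(c + M), M, c],
            [back, -back, 0.0],
            [0.0, 0.0, 0.0],
        ]
    )


def _sub_generator(n: int, M: float, lam: float) -> np.ndarray:
    """2x2 generator restricted to the transient states (same, diff)."""
    return island_generator(n, M, lam)[:2, :2]


def _expm_action(A: np.ndarray, p0: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """Rows ``p0 @ expm(A * dt)`` for each dt, via the 2x2 spectral formula.

    The discriminant ``(a - d)^2 + 4 b c`` is non-negative for these matrices
    (b, c >= 0) so both eigenvalues are real.
    """
    tr = A[0, 0] + A[1, 1]
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    disc = max(tr * tr - 4.0 * det, 0.0)
    s = math.sqrt(disc)
    l1, l2 = 0.5 * (tr + s), 0.5 * (tr - s)
    dts = np.asarray(dts, dtype=float)
    scale = max(abs(l1), abs(l2), 1.0)
    if s <= 1e-12 * scale:
        # near-degenerate: expm(A t) = e^{l t} (I + (A - l I) t)
        l = 0.5 * tr
        N = A - l * np.eye(2)
        base = p0[None, :] + dts[:, None] * (p0 @ N)[None, :]
        return np.exp(l * dts)[:, None] * base
    P1 = (A - l2 * np.eye(2)) / (l1 - l2)
    P2 = (A - l1 * np.eye(2)) / (l2 - l1)
    a1 = p0 @ P1
    a2 = p0 @ P2
    return np.exp(l1 * dts)[:, None] * a1[None, :] + np.exp(l2 * dts)[:, None] * a2[None, :]


def _initial_state(model: Model) -> np.ndarray:
    if isinstance(model, PanmicticModel):
        return np.array([1.0, 0.0])
    if model.sampling == "same_deme":
        return np.array([1.0, 0.0])
    return np.array([0.0, 1.0])


def _propagate(model: IslandModel, times: np.ndarray) -> np.ndarray:
    """State distribution (p_same, p_diff) at each (sorted, positive) time."""
    sched = model.schedule
    out = np.empty((len(times), 2))
    p = _initial_state(model)
    bps = list(sched.breakpoints) + [np.inf]
    for k in range(sched.n_epochs):
        A = _sub_generator(model.n, sched.M[k], sched.lam[k])
        lo, hi = bps[k], bps[k + 1]
        mask = (times > lo) & (times <= hi) if np.isfinite(hi) else (times > lo)
        if np.any(mask):
            out[mask] = _expm_action(A, p, times[mask] - lo)
        if np.isfinite(hi):
            p = _expm_action(A, p, np.array([hi - lo]))[0]
    return out


def default_grid(t_min: float = 1e-3, t_max: float = 1e2, n: int = 200) -> np.ndarray:
    """Default evaluation grid: log-spaced coalescent times."""
    return np.geomspace(t_min, t_max, n)


def iicr_exact(model: Model, grid: np.ndarray | None = None) -> IICRCurve:
    """Exact IICR curve ``lambda(t) (p_s + p_d) / p_s`` on the given time grid.

    For a panmictic model this is exactly the size function.  If ``p_same``
    underflows, the curve is truncated at the last representable time.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or np.any(grid <= 0):
        raise ValueError("grid must be strictly increasing and positive")
    sched = model.schedule
    lam_t = sched.lam_at(grid)
    prov = {"model": model_to_dict(model)}
    if isinstance(model, PanmicticModel):
        return IICRCurve(grid, lam_t, kind="sampled", provenance=prov)
    ps_pd = _propagate(model, grid)
    p_s, p_d = ps_pd[:, 0], ps_pd[:, 1]
    ok = p_s > 1e-300
    if not np.all(ok):
        last = np.nonzero(ok)[0]
        if last.size == 0:
            raise ValueError("state distribution underflowed on the whole grid")
        grid, p_s, p_d, lam_t = (a[ok] for a in (grid, p_s, p_d, lam_t))
        prov["truncated"] = True
    values = lam_t * (p_s + p_d) / p_s
    return IICRCurve(grid, values, kind="sampled", provenance=prov)


def _as_rate_model(model: Model) -> tuple[int, EpochSchedule, int]:
    """(n, schedule, initial state) with panmixia mapped onto M = 0, same deme."""
    if isinstance(model, PanmicticModel):
        sched = EpochSchedule(
            model.schedule.breakpoints,
            (0.0,) * model.schedule.n_epochs,
            model.schedule.lam,
        )
        return 2, sched, SAME
    state = SAME if model.sampling == "same_deme" else DIFF
    return model.n, model.schedule, state


def simulate_t2(model: Model, n_draws: int, seed: int) -> T2Sample:
    """Draw pairwise coalescence times by exact time-inhomogeneous Gillespie.

    Waiting times are redrawn at every epoch boundary (exact by memorylessness
    of the exponential).  Vectorized over draws.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    n, sched, init = _as_rate_model(model)
    if init == DIFF and all(m == 0 for m in sched.M):
        raise CoalescenceUnreachableError(
            "coalescence unreachable: different-deme sampling with M = 0 in every epoch"
        )
    rng = np.random.default_rng(seed)
    bps = np.asarray(sched.breakpoints + (np.inf,))
    Ms = np.asarray(sched.M)
    lams = np.asarray(sched.lam)

    t = np.zeros(n_draws)
    state = np.full(n_draws, init, dtype=np.int8)
    result = np.empty(n_draws)
    active = np.ones(n_draws, dtype=bool)
    # Each pass handles one (event or boundary-crossing) step for every active draw.
    for _ in range(100_000):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        ts = t[idx]
        ks = np.clip(np.searchsorted(sched.breakpoints, ts, side="right") - 1, 0, len(Ms) - 1)
        same = state[idx] == SAME
        coal_rate = np.where(same, 1.0 / lams[ks], 0.0)
        mig_rate = np.where(same, Ms[ks], Ms[ks] / (n - 1))
        total = coal_rate + mig_rate
        epoch_end = bps[ks + 1]
        # zero total rate: sit until the epoch boundary
        stuck = total == 0
        tau = np.full(idx.size, np.inf)
        tau[~stuck] = rng.exponential(1.0 / total[~stuck])
        t_event = ts + tau
        crosses = t_event > epoch_end
        # boundary crossing: clamp and redraw next pass
        cross_idx = idx[crosses]
        t[cross_idx] = epoch_end[crosses]
        # event within epoch
        ev = ~crosses
        ev_idx = idx[ev]
        if ev_idx.size:
            u = rng.random(ev_idx.size)
            is_coal = u * total[ev] < coal_rate[ev]
            t[ev_idx] = t_event[ev]
            coal_ids = ev_idx[is_coal]
            result[coal_ids] = t[coal_ids]
            active[coal_ids] = False
            flip = ev_idx[~is_coal]
            state[flip] = np.where(state[flip] == SAME, DIFF, SAME)
    else:  # pragma: no cover - defensive
        raise RuntimeError("Gillespie failed to absorb within the iteration cap")
    return T2Sample(result, seed=seed, model=model_to_dict(model))


def empirical_iicr(sample: T2Sample, grid: np.ndarray) -> IICRCurve:
    """Discretized IICR estimator from T2 draws.

    On each window ``[a, b)`` the estimate is
    ``(1 - F(a)) * (b - a) / (F(b) - F(a))`` with ``F`` the empirical CDF.
    Windows holding no coalescence are merged rightward; windows past the
    largest draw are dropped.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    draws = np.sort(sample.draws)
    ntot = draws.size
    if draws[-1] < grid[0]:
        raise ValueError("all draws fall below the start of the grid: empty curve")
    cdf_at = np.searchsorted(draws, grid, side="right") / ntot
    edges: list[float] = [grid[0]]
    values: list[float] = []
    i = 0
    while i < len(grid) - 1:
        j = i + 1
        while j < len(grid) and cdf_at[j] == cdf_at[i]:
            j += 1  # merge empty windows rightward
        if j >= len(grid):
            break
        a, b = grid[i], grid[j]
        dF = cdf_at[j] - cdf_at[i]
        values.append((1.0 - cdf_at[i]) * (b - a) / dF)
        edges.append(b)
        i = j
    if not values:
        raise ValueError("no window holds a coalescence event: empty curve")
    return IICRCurve(
        np.asarray(edges),
        np.asarray(values),
        kind="step",
        provenance={"estimator": "empirical_iicr", "n_draws": int(ntot), "seed": sample.seed},
    )


def exact_windowed_iicr(model: Model, edges: np.ndarray) -> np.ndarray:
    """Exact value of the windowed IICR functional
    ``S(a) (b - a) / (S(a) - S(b))`` on each ``[a, b)`` window, with ``S`` the
    exact survival function of T2.  This is what :func:`empirical_iicr`
    estimates, so Monte-Carlo output converges to it window by window."""
    edges = np.asarray(edges, dtype=float)
    if isinstance(model, PanmicticModel):
        sched = model.schedule
        # survival from the piecewise-linear cumulative hazard
        bps = np.asarray(sched.breakpoints)
        lam = np.asarray(sched.lam)
        cumH = np.concatenate(([0.0], np.cumsum(np.diff(bps) / lam[:-1])))

        def S(t: np.ndarray) -> np.ndarray:
            k = sched.epoch_index(t)
            return np.exp(-(cumH[k] + (t - bps[k]) / lam[k]))

        Sv = S(edges)
    else:
        Sv = _propagate(model, edges).sum(axis=1)
    return Sv[:-1] * np.diff(edges) / (Sv[:-1] - Sv[1:])


def _epoch_survival_integrals(model: IslandModel) -> float:
    """Integral of P(T2 > t) over [0, inf) by per-epoch spectral integration."""
    sched = model.schedule
    p = _initial_state(model)
    total = 0.0
    ones = np.ones(2)
    bps = list(sched.breakpoints) + [np.inf]
    for k in range(sched.n_epochs):
        A = _sub_generator(model.n, sched.M[k], sched.lam[k])
        dt = bps[k + 1] - bps[k]
        tr = A[0, 0] + A[1, 1]
        det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
        s = math.sqrt(max(tr * tr - 4.0 * det, 0.0))
        l1, l2 = 0.5 * (tr + s), 0.5 * (tr - s)
        last = not np.isfinite(dt)

        def integ(lam_eig: float) -> float:
            if last:
                if lam_eig >= 0:
                    return np.inf
                return -1.0 / lam_eig
            if abs(lam_eig) < 1e-14:
                return dt
            return (math.exp(lam_eig * dt) - 1.0) / lam_eig

        if s <= 1e-12 * max(abs(l1), abs(l2), 1.0):
            # degenerate pair: integrate e^{l t}(p + t p N) termwise
            l = 0.5 * tr
            N = A - l * np.eye(2)
            if last:
                if l >= 0:
                    return np.inf
                total += float((p @ ones) * (-1.0 / l) + (p @ N @ ones) * (1.0 / l**2))
            else:
                i0 = integ(l)
                i1 = (dt * math.exp(l * dt) - i0) / l if abs(l) > 1e-14 else dt * dt / 2
                total += float((p @ ones) * i0 + (p @ N @ ones) * i1)
        else:
            P1 = (A - l2 * np.eye(2)) / (l1 - l2)
            P2 = (A - l1 * np.eye(2)) / (l2 - l1)
            c1, c2 = float(p @ P1 @ ones), float(p @ P2 @ ones)
            i1, i2 = integ(l1), integ(l2)
            if (np.isinf(i1) and abs(c1) > 1e-300) or (np.isinf(i2) and abs(c2) > 1e-300):
                return np.inf
            total += c1 * (0.0 if np.isinf(i1) else i1) + c2 * (0.0 if np.isinf(i2) else i2)
        if not last:
            p = _expm_action(A, p, np.array([dt]))[0]
    return total


def mean_t2(model: Model) -> float:
    """E[T2] in coalescent units; closed form for single-epoch models."""
    if isinstance(model, PanmicticModel):
        sched = model.schedule
        total, p = 0.0, 1.0
        bps = list(sched.breakpoints) + [np.inf]
        for k in range(sched.n_epochs):
            lam = sched.lam[k]
            dt = bps[k + 1] - bps[k]
            if np.isfinite(dt):
                total += p * lam * (1.0 - math.exp(-dt / lam))
                p *= math.exp(-dt / lam)
            else:
                total += p * lam
        return total
    sched = model.schedule
    if sched.n_epochs == 1:
        n, M, lam = model.n, sched.M[0], sched.lam[0]
        if model.sampling == "same_deme":
            return n * lam
        if M == 0:
            raise DivergentExpectationError("E[T2] diverges: isolated demes, no migration")
        return n * lam + (n - 1) / M
    if model.sampling == "different_demes" and all(m == 0 for m in sched.M):
        raise DivergentExpectationError("E[T2] diverges: isolated demes in every epoch")
    value = _epoch_survival_integrals(model)
    if not np.isfinite(value):
        raise DivergentExpectationError("E[T2] diverges under this schedule")
    return value


def model_to_dict(model: Model) -> dict:
    """JSON/YAML-ready descriptor: {type, n, epochs: [{start, M, lambda}], sampling}."""
    sched = model.schedule
    epochs = [
        {"start": sched.breakpoints[k], "M": sched.M[k], "lambda": sched.lam[k]}
        for k in range(sched.n_epochs)
    ]
    if isinstance(model, PanmicticModel):
        return {"type": "panmictic", "epochs": epochs}
    return {"type": "island", "n": model.n, "epochs": epochs, "sampling": model.sampling}


def model_from_dict(d: dict) -> Model:
    epochs = d["epochs"]
    sched = EpochSchedule(
        tuple(e["start"] for e in epochs),
        tuple(e.get("M", 0.0) for e in epochs),
        tuple(e["lambda"] for e in epochs),
    )
    if d["type"] == "panmictic":
        return PanmicticModel(sched)
    if d["type"] == "island":
        return IslandModel(int(d["n"]), sched, d.get("sampling", "same_deme"))
    raise ValueError(f"unknown model type {d['type']!r}")


def iicr_plateau(model: IslandModel) -> float:
    """Long-time IICR limit of a constant island model from the dominant
    eigenvector of the (same, diff) sub-generator."""
    sched = model.schedule
    A = _sub_generator(model.n, sched.M[-1], sched.lam[-1])
    w, V = np.linalg.eig(A.T)
    v = np.real(V[:, np.argmax(np.real(w))])
    v = v / v.sum()
    return float(sched.lam[-1] * (v[0] + v[1]) / v[0])
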