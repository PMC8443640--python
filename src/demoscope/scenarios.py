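"""Event-based multi-deme demographies and the M1-M13 scenario registry.

A :class:`Scenario` holds per-deme haploid sizes, a symmetric migration
parameter ``2NM0`` (the average number of haploid immigrants entering each
deme per generation), timed events in generations before present (stepwise
size changes, migration-rate changes, backward-time deme merges = forward-time
splits), and the deme assignment of the sampled populations.

The registry covers the thirteen candidate demographies compared for the
mouse-lemur data: panmictic size-change models (M1-M3), anciently and recently
structured models with a ghost deme (M4, M6-M9), and connectivity-change
models (M5, M10-M13).  M7 -- the best-supported model -- is specified exactly:
an ancestral panmictic population of size NANC splits at T2 into north, south
and ghost demes of size N1POP exchanging 2NM0 haploid immigrants per deme per
generation, followed by a second stepwise decline to N0POP at T1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "Event",
    "Scenario",
    "CompiledTimeline",
    "ScenarioTemplate",
    "compile_timeline",
    "scale_scenario_times",
    "m7_scenario",
    "TABLE1_M7",
    "TABLE1_M7_CI",
    "REGISTRY",
    "get_template",
]


@dataclass(frozen=True)
class Event:
    """Demographic event at ``time`` generations before present.

    kinds: ``resize`` (deme, size), ``resize_all`` (size), ``set_migration``
    (2NM0 value), ``merge`` (src deme's lineages move into dst; src retires).
    """

    time: float
    kind: str
    deme: int | None = None
    dest: int | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event times must be >= 0")
        if self.kind not in ("resize", "resize_all", "set_migration", "merge"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class Scenario:
    """Piecewise-constant multi-deme demography.

    ``deme_sizes``: present-day haploid sizes.  ``migration``: present-day
    2NM0.  ``samples``: deme index housing each observed population's sample.
    Backward in time the active deme count must be non-increasing down to a
    single ancestral deme (or migration must remain positive so that the
    sample can find a common ancestor).
    """

    deme_sizes: tuple[float, ...]
    migration: float = 0.0
    events: tuple[Event, ...] = ()
    samples: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.deme_sizes)
        if any(s <= 0 for s in sizes):
            raise ValueError("deme sizes must be > 0")
        if self.migration < 0:
            raise ValueError("migration must be >= 0")
        events = tuple(sorted(self.events, key=lambda e: e.time))
        if any(d < 0 or d >= len(sizes) for d in self.samples):
            raise ValueError("sample deme index out of range")
        object.__setattr__(self, "deme_sizes", sizes)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "samples", tuple(int(d) for d in self.samples))

    @property
    def n_demes(self) -> int:
        return len(self.deme_sizes)


@dataclass(frozen=True)
class CompiledTimeline:
    """Segment-wise arrays consumed by the genealogy simulator.

    For segment ``s`` (``boundaries[s-1] <= t < boundaries[s]``):
    ``sizes[s, d]`` haploid size, ``mig_rate[s, d]`` per-lineage backward
    migration rate (``2NM0 / size`` toward a uniform other active deme),
    ``active[s, d]`` whether deme ``d`` can hold lineages.  ``remap[b, d]``
    moves lineages across boundary ``b``.
    """

    boundaries: np.ndarray
    sizes: np.ndarray
    mig_rate: np.ndarray
    active: np.ndarray
    remap: np.ndarray

    @property
    def coalescence_reachable(self) -> bool:
        last = -1
        n_active = int(self.active[last].sum())
        return n_active == 1 or self.mig_rate[last][self.active[last]].max() > 0


def compile_timeline(scenario: Scenario) -> CompiledTimeline:
    D = scenario.n_demes
    times = sorted({e.time for e in scenario.events if e.time > 0})
    boundaries = np.asarray(times, dtype=float)
    S = len(boundaries) + 1
    sizes = np.zeros((S, D))
    mig = np.zeros(S)
    active = np.ones((S, D), dtype=np.bool_)
    remap = np.tile(np.arange(D), (len(boundaries), 1)).astype(np.int64)

    cur_sizes = np.asarray(scenario.deme_sizes, dtype=float)
    cur_mig = float(scenario.migration)
    cur_active = np.ones(D, dtype=bool)
    seg_start_events: dict[float, list[Event]] = {}
    for e in scenario.events:
        seg_start_events.setdefault(e.time, []).append(e)

    def apply(events: list[Event], b_idx: int | None) -> None:
        nonlocal cur_mig
        for e in events:
            if e.kind == "resize":
                cur_sizes[e.deme] = e.value
            elif e.kind == "resize_all":
                cur_sizes[cur_active] = e.value
            elif e.kind == "set_migration":
                cur_mig = float(e.value)
            elif e.kind == "merge":
                if not cur_active[e.dest]:
                    raise ValueError("merge destination deme is not active")
                cur_active[e.deme] = False
                if b_idx is not None:
                    src = remap[b_idx] == e.deme
                    remap[b_idx, src] = e.dest
                if e.value is not None:
                    cur_sizes[e.dest] = e.value

    apply(seg_start_events.get(0.0, []), None)
    sizes[0], mig[0], active[0] = cur_sizes.copy(), cur_mig, cur_active.copy()
    for b, tb in enumerate(boundaries):
        apply(seg_start_events.get(tb, []), b)
        sizes[b + 1] = cur_sizes
        mig[b + 1] = cur_mig
        active[b + 1] = cur_active
    if active[-1].sum() < 1:
        raise ValueError("no active deme in the final segment")
    mig_rate = np.zeros((S, D))
    for s in range(S):
        n_act = active[s].sum()
        if n_act > 1 and mig[s] > 0:
            mig_rate[s, active[s]] = mig[s] / sizes[s, active[s]]
    tl = CompiledTimeline(boundaries, sizes, mig_rate, active, remap)
    return tl


def scale_scenario_times(params: dict, g: float, to_years: bool = True) -> dict:
    """Multiply (or divide) the time-valued entries of a parameter dict by the
    generation time ``g``; keys starting with 'T' are treated as times."""
    if g <= 0:
        raise ValueError("generation time must be > 0")
    f = g if to_years else 1.0 / g
    return {k: (v * f if k.upper().startswith("T") else v) for k, v in params.items()}


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioTemplate:
    """Named demography family: free parameters with bounds (log- or linear-
    scale) and a total builder mapping any in-bounds vector to a Scenario."""

    template_id: str
    description: str
    bounds: dict  # name -> (lo, hi, log_scale)
    builder: Callable[[dict], Scenario]
    defaults: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.bounds)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bounds)

    def build(self, params: dict) -> Scenario:
        for name, (lo, hi, log) in self.bounds.items():
            v = params[name]
            if not (lo <= v <= hi):
                raise ValueError(f"{self.template_id}: {name}={v} outside [{lo}, {hi}]")
            if log and lo <= 0:
                raise ValueError(f"{self.template_id}: log-scaled bound must be positive")
        return self.builder(params)

    def to_vector(self, params: dict) -> np.ndarray:
        out = []
        for name, (_, _, log) in self.bounds.items():
            v = params[name]
            out.append(np.log(v) if log else v)
        return np.asarray(out)

    def from_vector(self, x: np.ndarray) -> dict:
        params = {}
        for val, (name, (lo, hi, log)) in zip(x, self.bounds.items()):
            v = float(np.exp(val)) if log else float(val)
            params[name] = min(max(v, lo), hi)
        return params


# Table 1 maximum-likelihood estimates for model M7 (GT = 2.5 yr; sizes in
# haploid copies, times in years) and their block-bootstrap 95% CIs.
TABLE1_M7 = {
    "N0POP": 13937.0,
    "N1POP": 14329.0,
    "NANC": 151573.0,
    "T1": 1073.0,
    "T2": 4893.0,
    "2NM0": 7.23,
}
TABLE1_M7_CI = {
    "N0POP": (11796.0, 14133.0),
    "N1POP": (13161.0, 17773.0),
    "NANC": (109463.0, 147754.0),  # ML estimate falls outside; treated with caution
    "T1": (910.0, 2025.0),
    "T2": (4018.0, 5430.0),
    "2NM0": (6.73, 9.34),
}

_SIZE = (1e2, 1e7, True)
_TIME = (1.0, 1e5, True)
_MIG = (1e-3, 1e3, True)


def _ordered_times(p: dict, first: str, second: str) -> tuple[float, float]:
    """Totality guard: return (recent, older) even if the vector is inverted."""
    t1, t2 = p[first], p[second]
    if t2 <= t1:
        t1, t2 = min(t1, t2), max(t1, t2) + 1.0
    return t1, t2


def m7_scenario(params: dict | None = None, g_scale: float = 1.0) -> Scenario:
    """Best-supported model M7 at the given parameters (times in generations).

    ``params`` defaults to the Table 1 ML values (years, GT = 2.5) converted
    to generations.
    """
    if params is None:
        params = scale_scenario_times(TABLE1_M7, 2.5, to_years=False)
    t1, t2 = _ordered_times(params, "T1", "T2")
    n0, n1, nanc, mig = params["N0POP"], params["N1POP"], params["NANC"], params["2NM0"]
    return Scenario(
        deme_sizes=(n0, n0, n0),
        migration=mig,
        events=(
            Event(t1, "resize_all", value=n1),
            Event(t2, "merge", deme=1, dest=0),
            Event(t2, "merge", deme=2, dest=0),
            Event(t2, "resize", deme=0, value=nanc),
            Event(t2, "set_migration", value=0.0),
        ),
        samples=(0, 1),
    )


def _m1(p: dict) -> Scenario:
    return Scenario(deme_sizes=(p["NANC"],), samples=(0, 0))


def _single_change(p: dict) -> Scenario:
    return Scenario(
        deme_sizes=(p["N0POP"],),
        events=(Event(max(p["T1"], 1.0), "resize", deme=0, value=p["NANC"]),),
        samples=(0, 0),
    )


def _m4(p: dict) -> Scenario:
    tanc = max(p["TANC"], 1.0)
    return Scenario(
        deme_sizes=(p["N0POP"],) * 3,
        migration=p["2NM0"],
        events=(
            Event(tanc, "merge", deme=1, dest=0),
            Event(tanc, "merge", deme=2, dest=0),
            Event(tanc, "resize", deme=0, value=p["NANC"]),
            Event(tanc, "set_migration", value=0.0),
        ),
        samples=(0, 1),
    )


def _m5(p: dict) -> Scenario:
    tc = max(p["TC"], 1.0)
    return Scenario(
        deme_sizes=(p["N0POP"],) * 3,
        migration=p["2NM0"],
        events=(Event(tc, "set_migration", value=p["2NM1"]),),
        samples=(0, 1),
    )


def _m6(p: dict) -> Scenario:
    t2 = max(p["T2"], 1.0)
    return Scenario(
        deme_sizes=(p["N0POP"],) * 3,
        migration=p["2NM0"],
        events=(
            Event(t2, "merge", deme=1, dest=0),
            Event(t2, "merge", deme=2, dest=0),
            Event(t2, "resize", deme=0, value=p["NANC"]),
            Event(t2, "set_migration", value=0.0),
        ),
        samples=(0, 1),
    )


def _m8(p: dict) -> Scenario:
    base = _m6(p)
    t2 = max(p["T2"], 1.0)
    texp = max(p["TEXP"], t2 + 1.0)
    return replace(
        base, events=base.events + (Event(texp, "resize", deme=0, value=p["NANC2"]),)
    )


def _m9(p: dict) -> Scenario:
    base = m7_scenario(p)
    _, t2 = _ordered_times(p, "T1", "T2")
    texp = max(p["TEXP"], t2 + 1.0)
    return replace(
        base, events=base.events + (Event(texp, "resize", deme=0, value=p["NANC2"]),)
    )


def _m10(p: dict) -> Scenario:
    t2 = max(p["T2"], 1.0)
    tc = min(max(p["TC"], 1.0), t2 - 0.5)
    return Scenario(
        deme_sizes=(p["N0POP"],) * 3,
        migration=p["2NM0"],
        events=(
            Event(tc, "set_migration", value=p["2NM1"]),
            Event(t2, "merge", deme=1, dest=0),
            Event(t2, "merge", deme=2, dest=0),
            Event(t2, "resize", deme=0, value=p["NANC"]),
            Event(t2, "set_migration", value=0.0),
        ),
        samples=(0, 1),
    )


def _m11(p: dict) -> Scenario:
    base = _m10(p)
    t2 = max(p["T2"], 1.0)
    tc = min(max(p["TC"], 1.0), t2 - 0.5)
    extra = (Event(tc, "resize_all", value=p["N1POP"]),)
    return replace(base, events=base.events + extra)


def _m12(p: dict) -> Scenario:
    # migration change coincident with the structuring event: a single
    # structured phase whose migration differs from the present one
    t2 = max(p["T2"], 1.0)
    return Scenario(
        deme_sizes=(p["N0POP"],) * 3,
        migration=p["2NM0"],
        events=(
            Event(t2 / 2.0, "set_migration", value=p["2NM1"]),
            Event(t2, "merge", deme=1, dest=0),
            Event(t2, "merge", deme=2, dest=0),
            Event(t2, "resize", deme=0, value=p["NANC"]),
            Event(t2, "set_migration", value=0.0),
        ),
        samples=(0, 1),
    )


def _m13(p: dict) -> Scenario:
    base = _m10(p)
    t2 = max(p["T2"], 1.0)
    tc = min(max(p["TC"], 1.0), t2 - 0.5)
    t1 = min(max(p["T1"], 0.5), tc - 0.25)
    extra = (Event(t1, "resize_all", value=p["N1POP"]),)
    return replace(base, events=base.events + extra)


REGISTRY: dict[str, ScenarioTemplate] = {
    "M1": ScenarioTemplate(
        "M1", "constant panmictic size", {"NANC": _SIZE}, _m1
    ),
    "M2": ScenarioTemplate(
        "M2",
        "panmictic expansion (forward growth from NANC to N0POP)",
        {"N0POP": _SIZE, "NANC": _SIZE, "T1": _TIME},
        _single_change,
    ),
    "M3": ScenarioTemplate(
        "M3",
        "panmictic bottleneck (forward decline from NANC to N0POP)",
        {"N0POP": _SIZE, "NANC": _SIZE, "T1": _TIME},
        _single_change,
    ),
    "M4": ScenarioTemplate(
        "M4",
        "ancient structure: north/south/ghost demes since TANC",
        {"N0POP": _SIZE, "NANC": _SIZE, "TANC": _TIME, "2NM0": _MIG},
        _m4,
    ),
    "M5": ScenarioTemplate(
        "M5",
        "connectivity change at TC under constant structure",
        {"N0POP": _SIZE, "2NM0": _MIG, "2NM1": _MIG, "TC": _TIME},
        _m5,
    ),
    "M6": ScenarioTemplate(
        "M6",
        "recent structuring with one size change at the split",
        {"N0POP": _SIZE, "NANC": _SIZE, "T2": _TIME, "2NM0": _MIG},
        _m6,
    ),
    "M7": ScenarioTemplate(
        "M7",
        "recent structuring with two stepwise declines (best-supported model)",
        {
            "N0POP": _SIZE,
            "N1POP": _SIZE,
            "NANC": _SIZE,
            "T1": _TIME,
            "T2": _TIME,
            "2NM0": _MIG,
        },
        m7_scenario,
        defaults=scale_scenario_times(TABLE1_M7, 2.5, to_years=False),
    ),
    "M8": ScenarioTemplate(
        "M8",
        "recent structuring preceded by an ancient expansion",
        {"N0POP": _SIZE, "NANC": _SIZE, "NANC2": _SIZE, "T2": _TIME, "TEXP": _TIME,
         "2NM0": _MIG},
        _m8,
    ),
    "M9": ScenarioTemplate(
        "M9",
        "M7 with an additional ancient expansion",
        {"N0POP": _SIZE, "N1POP": _SIZE, "NANC": _SIZE, "NANC2": _SIZE, "T1": _TIME,
         "T2": _TIME, "TEXP": _TIME, "2NM0": _MIG},
        _m9,
    ),
    "M10": ScenarioTemplate(
        "M10",
        "recent structuring with a later connectivity change, no size change",
        {"N0POP": _SIZE, "NANC": _SIZE, "T2": _TIME, "TC": _TIME, "2NM0": _MIG,
         "2NM1": _MIG},
        _m10,
    ),
    "M11": ScenarioTemplate(
        "M11",
        "recent structuring with connectivity change and one size change",
        {"N0POP": _SIZE, "N1POP": _SIZE, "NANC": _SIZE, "T2": _TIME, "TC": _TIME,
         "2NM0": _MIG, "2NM1": _MIG},
        _m11,
    ),
    "M12": ScenarioTemplate(
        "M12",
        "connectivity change parallel to the structuring event",
        {"N0POP": _SIZE, "NANC": _SIZE, "T2": _TIME, "2NM0": _MIG, "2NM1": _MIG},
        _m12,
    ),
    "M13": ScenarioTemplate(
        "M13",
        "connectivity change plus two stepwise size changes",
        {"N0POP": _SIZE, "N1POP": _SIZE, "NANC": _SIZE, "T1": _TIME, "T2": _TIME,
         "TC": _TIME, "2NM0": _MIG, "2NM1": _MIG},
        _m13,
    ),
}


def scenario_to_dict(s: Scenario) -> dict:
    return {
        "deme_sizes": list(s.deme_sizes),
        "migration": s.migration,
        "events": [
            {k: v for k, v in vars(e).items() if v is not None} for e in s.events
        ],
        "samples": list(s.samples),
    }


def scenario_from_dict(d: dict) -> Scenario:
    return Scenario(
        deme_sizes=tuple(d["deme_sizes"]),
        migration=d.get("migration", 0.0),
        events=tuple(Event(**e) for e in d.get("events", [])),
        samples=tuple(d.get("samples", (0,))),
    )


def get_template(template_id: str) -> ScenarioTemplate:
    try:
        return REGISTRY[template_id]
    except KeyError:
        raise KeyError(
            f"unknown template {template_id!r}; available: {sorted(REGISTRY)}"
        ) from None
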