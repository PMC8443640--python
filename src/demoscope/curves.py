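"""IICR curve container, unit conversions, distance metric and PSMC-style
discretization.

A curve is either ``sampled`` (pointwise values on a time grid, interpolated
log-linearly) or ``step`` (``len(times) == len(values) + 1`` interval edges,
piecewise constant -- the shape PSMC emits).  The time axis carries a unit tag
(coalescent units of 2*N_ref generations, generations, or years) and values
are either dimensionless inverse coalescence rates (``relative``) or scaled to
effective sizes (``effective``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "IICRCurve",
    "ScalingConstants",
    "rescale_curve",
    "curve_distance",
    "discretize_like_psmc",
    "write_curve_tsv",
    "read_curve_tsv",
]

TIME_UNITS = ("coalescent", "generations", "years")
SIZE_UNITS = ("relative", "effective")


@dataclass(frozen=True)
class ScalingConstants:
    """PSMC scaling constants: per-generation per-site mutation rate ``mu``,
    generation time ``g`` in years, and PSMC bin size ``s`` in bp."""

    mu: float = 1.2e-8
    g: float = 2.5
    s: int = 100

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.g <= 0 or int(self.s) <= 0:
            raise ValueError("mu, g and s must all be positive")
        object.__setattr__(self, "s", int(self.s))


@dataclass(frozen=True)
class IICRCurve:
    times: np.ndarray
    values: np.ndarray
    time_units: str = "coalescent"
    size_units: str = "relative"
    kind: str = "sampled"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if self.kind not in ("sampled", "step"):
            raise ValueError("kind must be 'sampled' or 'step'")
        expected = len(values) if self.kind == "sampled" else len(values) + 1
        if len(times) != expected:
            raise ValueError(
                f"{self.kind} curve needs {expected} times for {len(values)} values"
            )
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(values <= 0) or not np.all(np.isfinite(values)):
            raise ValueError("IICR values must be positive and finite")
        if self.time_units not in TIME_UNITS:
            raise ValueError(f"unknown time units {self.time_units!r}")
        if self.size_units not in SIZE_UNITS:
            raise ValueError(f"unknown size units {self.size_units!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    # -- evaluation ---------------------------------------------------------

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def _positive_start(self) -> float:
        if self.times[0] > 0:
            return float(self.times[0])
        # step curve starting at 0: use a small fraction of the first interior edge
        return float(self.times[1]) * 1e-3

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the curve; constant extrapolation outside the span."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.kind == "step":
            idx = np.clip(
                np.searchsorted(self.times, t, side="right") - 1, 0, len(self.values) - 1
            )
            return self.values[idx]
        lo = self._positive_start()
        logt = np.log(np.clip(t, lo, None))
        return np.exp(
            np.interp(logt, np.log(np.clip(self.times, lo, None)), np.log(self.values))
        )

    def mean_over(self, edges: np.ndarray, n_sub: int = 8) -> np.ndarray:
        """Time-averaged value over each ``[edges[i], edges[i+1])`` interval
        (trapezoid on ``n_sub`` log-spaced sub-points)."""
        edges = np.asarray(edges, dtype=float)
        lo = np.maximum(edges[:-1], self._positive_start() * 1e-6)
        out = np.empty(len(edges) - 1)
        for i in range(len(out)):
            a, b = lo[i], edges[i + 1]
            sub = np.geomspace(max(a, b * 1e-12), b, n_sub) if a > 0 else np.linspace(a, b, n_sub)
            v = self(sub)
            out[i] = np.trapezoid(v, sub) / (sub[-1] - sub[0])
        return out


def rescale_curve(
    curve: IICRCurve,
    scaling: ScalingConstants,
    N_ref: float | None = None,
    time_units: str = "coalescent",
    size_units: str | None = None,
) -> IICRCurve:
    """Convert a curve between coalescent / generation / year time axes and
    relative / effective-size value scalings.

    Coalescent -> generations multiplies times by ``2 * N_ref``; generations ->
    years multiplies by ``g``.  Relative -> effective multiplies values by
    ``N_ref``.  Round trips are exact to floating point.
    """
    size_units = curve.size_units if size_units is None else size_units
    needs_nref = (
        ("coalescent" in (curve.time_units, time_units) and curve.time_units != time_units)
        or curve.size_units != size_units
    )
    if needs_nref and N_ref is None:
        raise ValueError("N_ref is required for this unit conversion")

    def to_gen(t: np.ndarray) -> np.ndarray:
        if curve.time_units == "coalescent":
            return t * (2.0 * N_ref)
        if curve.time_units == "years":
            return t / scaling.g
        return t

    t_gen = to_gen(curve.times)
    if time_units == "generations":
        times = t_gen
    elif time_units == "years":
        times = t_gen * scaling.g
    elif time_units == "coalescent":
        times = t_gen / (2.0 * N_ref)
    else:
        raise ValueError(f"unknown time units {time_units!r}")

    values = curve.values
    if curve.size_units != size_units:
        values = values * N_ref if size_units == "effective" else values / N_ref
    return replace(
        curve, times=times, values=values, time_units=time_units, size_units=size_units
    )


def _overlap_grid(a: IICRCurve, b: IICRCurve, n_points: int) -> np.ndarray:
    lo = max(a._positive_start(), b._positive_start())
    hi = min(a.span[1], b.span[1])
    if hi <= lo:
        raise ValueError("curves have disjoint time supports")
    return np.geomspace(lo, hi, n_points)


def curve_distance(a: IICRCurve, b: IICRCurve, n_points: int = 64) -> float:
    """RMS of ``log10(a) - log10(b)`` on a log-spaced grid over the overlap.

    Symmetric, non-negative, zero iff the curves agree on the grid;
    scale-free in both axes' absolute normalization provided units match.
    """
    if a.time_units != b.time_units or a.size_units != b.size_units:
        raise ValueError("curves must share time and size units")
    grid = _overlap_grid(a, b, n_points)
    d = np.log10(a(grid)) - np.log10(b(grid))
    return float(np.sqrt(np.mean(d * d)))


def discretize_like_psmc(curve: IICRCurve, n_intervals: int) -> IICRCurve:
    """Piecewise-constant rendering on log-spaced intervals; each level is the
    time-average of the input over its interval (mimics PSMC step output)."""
    if n_intervals < 2:
        raise ValueError("need at least 2 intervals")
    lo = curve._positive_start()
    hi = curve.span[1]
    edges = np.geomspace(lo, hi, n_intervals + 1)
    levels = curve.mean_over(edges)
    prov = dict(curve.provenance)
    prov["discretized"] = {"n_intervals": int(n_intervals)}
    return IICRCurve(
        edges,
        levels,
        time_units=curve.time_units,
        size_units=curve.size_units,
        kind="step",
        provenance=prov,
    )


def write_curve_tsv(curve: IICRCurve, path: str) -> None:
    """TSV with columns time, iicr, units; provenance JSON in the header line."""
    header = {
        "kind": curve.kind,
        "size_units": curve.size_units,
        "provenance": curve.provenance,
    }
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(header)}\n")
        fh.write("time\tiicr\tunits\n")
        if curve.kind == "step":
            for t, v in zip(curve.times[:-1], curve.values):
                fh.write(f"{float(t)!r}\t{float(v)!r}\t{curve.time_units}\n")
            fh.write(f"{float(curve.times[-1])!r}\tNA\t{curve.time_units}\n")
        else:
            for t, v in zip(curve.times, curve.values):
                fh.write(f"{float(t)!r}\t{float(v)!r}\t{curve.time_units}\n")


def read_curve_tsv(path: str) -> IICRCurve:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing provenance header line")
        meta = json.loads(first[1:].strip())
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["time", "iicr"]:
            raise ValueError(f"{path}: unexpected column header {header}")
        times, values, units = [], [], None
        for line in fh:
            if not line.strip():
                continue
            t, v, u = line.rstrip("\n").split("\t")
            times.append(float(t))
            if v != "NA":
                values.append(float(v))
            units = u
    return IICRCurve(
        np.asarray(times),
        np.asarray(values),
        time_units=units,
        size_units=meta.get("size_units", "relative"),
        kind=meta.get("kind", "sampled"),
        provenance=meta.get("provenance", {}),
    )
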