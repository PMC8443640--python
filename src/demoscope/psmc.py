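"""Reader/writer for PSMC text output and its scaling conventions.

PSMC emits one block per EM iteration, delimited by ``//``.  Each block holds a
``TR <theta> <rho>`` line and ``RS <k> <t_k> <lambda_k> ...`` lines giving the
left edge ``t_k`` of interval ``k`` in units of ``2 * N0`` generations and the
relative size ``lambda_k``.  Only the final block (the converged iterate) is
used.  With per-site theta over bins of ``s`` bp,

    N0 = theta / (4 * mu * s),
    time_k [years] = 2 * N0 * t_k * g,
    value_k [haploid-pair effective size] = lambda_k * N0.
"""

from __future__ import annotations

import numpy as np

from .curves import IICRCurve, ScalingConstants

__all__ = ["PSMCParseError", "parse_psmc", "parse_psmc_file", "write_psmc"]

# PSMC's -t option caps the TMRCA (default 15, the study used -t5); used only to
# close the unbounded last interval of a single-interval curve.
_DEFAULT_TMAX = 5.0


class PSMCParseError(ValueError):
    pass


def _parse_blocks(text: str) -> list[dict]:
    blocks: list[dict] = []
    cur: dict = {"theta": None, "t": [], "lam": [], "round": None}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tag, _, rest = line.partition("\t")
        if tag == "//":
            if cur["t"] or cur["theta"] is not None:
                blocks.append(cur)
            cur = {"theta": None, "t": [], "lam": [], "round": None}
            continue
        if tag == "RD":
            try:
                cur["round"] = int(rest.split()[0])
            except (ValueError, IndexError):
                raise PSMCParseError(f"line {lineno}: malformed RD line: {raw!r}")
        elif tag == "TR":
            try:
                cur["theta"] = float(rest.split()[0])
            except (ValueError, IndexError):
                raise PSMCParseError(f"line {lineno}: malformed TR line: {raw!r}")
        elif tag == "RS":
            fields = rest.split()
            try:
                cur["t"].append(float(fields[1]))
                cur["lam"].append(float(fields[2]))
            except (ValueError, IndexError):
                raise PSMCParseError(f"line {lineno}: malformed RS line: {raw!r}")
    if cur["t"] or cur["theta"] is not None:
        blocks.append(cur)
    return blocks


def parse_psmc(text: str, scaling: ScalingConstants = ScalingConstants()) -> IICRCurve:
    """Parse PSMC output text into a year-scaled effective-size step curve."""
    blocks = [b for b in _parse_blocks(text) if b["t"] and b["theta"] is not None]
    if not blocks:
        raise PSMCParseError("no complete result block (TR + RS lines) found")
    block = blocks[-1]
    t = np.asarray(block["t"], dtype=float)
    lam = np.asarray(block["lam"], dtype=float)
    if t[0] != 0.0 or np.any(np.diff(t) < 0):
        raise PSMCParseError("RS times must be non-decreasing and start at 0")
    # collapse duplicated time points (PSMC may repeat edges)
    keep = np.concatenate(([True], np.diff(t) > 0))
    t, lam = t[keep], lam[keep]
    theta = float(block["theta"])
    if theta <= 0:
        raise PSMCParseError("theta must be positive")
    N0 = theta / (4.0 * scaling.mu * scaling.s)
    # close the unbounded last interval geometrically
    if len(t) >= 3 and t[-2] > 0:
        t_edge = t[-1] ** 2 / t[-2]
    elif len(t) >= 2:
        t_edge = 2.0 * t[-1]
    else:
        t_edge = _DEFAULT_TMAX
    edges_years = 2.0 * N0 * np.concatenate((t, [t_edge])) * scaling.g
    values = lam * N0
    if edges_years[0] == 0.0 and len(edges_years) > 2:
        pass  # step curves may start at 0; evaluation clips below the first edge
    return IICRCurve(
        edges_years,
        values,
        time_units="years",
        size_units="effective",
        kind="step",
        provenance={
            "source": "psmc",
            "theta": theta,
            "N0": N0,
            "round": block["round"],
            "t_k": t.tolist(),
            "lambda_k": lam.tolist(),
            "scaling": {"mu": scaling.mu, "g": scaling.g, "s": scaling.s},
        },
    )


def parse_psmc_file(path: str, scaling: ScalingConstants = ScalingConstants()) -> IICRCurve:
    with open(path) as fh:
        return parse_psmc(fh.read(), scaling)


def write_psmc(
    theta: float,
    t: np.ndarray,
    lam: np.ndarray,
    rho: float | None = None,
    n_iterations: int = 1,
) -> str:
    """Emit a minimal PSMC-format text (``n_iterations`` identical blocks) for
    the given interval left-edges ``t`` (2*N0-generation units) and sizes."""
    t = np.asarray(t, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if len(t) != len(lam):
        raise ValueError("t and lam must have equal length")
    rho = theta / 5.0 if rho is None else rho
    lines = []
    for it in range(n_iterations):
        lines.append(f"RD\t{it}")
        lines.append(f"TR\t{theta:.6f}\t{rho:.6f}")
        for k, (tk, lk) in enumerate(zip(t, lam)):
            lines.append(f"RS\t{k}\t{tk:.6f}\t{lk:.6f}\t0.0000\t0.0000")
        lines.append("//")
    return "\n".join(lines) + "\n"
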