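"""Synthetic inputs for the whole pipeline: blocked SNP datasets drawn from
expected folded spectra, and PSMC-like step IICR target curves.

The default dataset mirrors the study's reduced sampling design: 10 + 10
chromosomes across the two sampled populations, 50,000 SNPs in blocks of 50
(a stand-in for RAD loci as linkage units).  Curve noise is multiplicative
lognormal per interval, matching the roughly scale-proportional scatter of
PSMC bootstrap replicates.  All randomness flows from the explicit seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .curves import IICRCurve, discretize_like_psmc, read_curve_tsv, write_curve_tsv
from .genealogy import branch_length_spectrum, expected_sfs
from .models import Model, iicr_exact, model_from_dict, model_to_dict
from .scenarios import Scenario, scenario_from_dict, scenario_to_dict
from .sfs import (
    BlockedSNPs,
    FoldedSFS,
    canonical_mask,
    fold_array,
    read_blocks_tsv,
    read_sfs_tsv,
    write_blocks_tsv,
    write_sfs_tsv,
)

__all__ = [
    "SyntheticDatasetSpec",
    "draw_observed_sfs",
    "make_target_curve",
    "write_fixtures",
    "read_fixtures",
]


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """What to generate: a scenario (for SNP data) and/or an IICR model (for
    target curves), with sizes, block structure and noise level."""

    scenario: Scenario | None = None
    model: Model | None = None
    S: int = 50_000
    block_size: int = 50
    nsam: tuple[int, ...] = (10, 10)
    R: int = 100_000
    n_intervals: int = 64
    sigma: float = 0.0
    seed: int = 0
    linked: bool = False
    grid: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.sigma < 0:
            raise ValueError("noise level sigma must be >= 0")
        if self.block_size < 1:
            raise ValueError("block size must be >= 1")


def _split_blocks(cell_ids: np.ndarray, block_size: int) -> tuple[np.ndarray, ...]:
    return tuple(
        cell_ids[i : i + block_size] for i in range(0, len(cell_ids), block_size)
    )


def draw_observed_sfs(spec: SyntheticDatasetSpec) -> tuple[FoldedSFS, BlockedSNPs]:
    """Draw S SNPs from the generating scenario's expected folded SFS.

    Default (i.i.d.) mode draws SNP cells multinomially and groups them into
    consecutive blocks; linked mode simulates one genealogy per block and
    draws that block's SNPs from its own branch-length spectrum, inducing
    within-block correlation.
    """
    if spec.scenario is None:
        raise ValueError("spec.scenario is required to draw SNP data")
    rng = np.random.default_rng(spec.seed)
    sizes = tuple(int(n) for n in spec.nsam if n > 0)
    mask = canonical_mask(sizes)
    n_cells = int(mask.sum())
    if spec.linked:
        n_blocks = int(np.ceil(spec.S / spec.block_size))
        blocks = []
        remaining = spec.S
        for b in range(n_blocks):
            bs = min(spec.block_size, remaining)
            remaining -= bs
            L = branch_length_spectrum(
                spec.scenario, spec.nsam, R=1, seed=int(rng.integers(2**31 - 1))
            )
            if len(sizes) == 1:
                L = L.sum(axis=1)
            p = fold_array(L, sizes)[mask]
            if p.sum() <= 0:
                raise ValueError("degenerate expected SFS: all mass masked")
            blocks.append(rng.choice(n_cells, size=bs, p=p / p.sum()))
        blocked = BlockedSNPs(sizes, tuple(blocks))
    else:
        exp = expected_sfs(
            spec.scenario, spec.nsam, R=spec.R, seed=int(rng.integers(2**31 - 1))
        )
        p = exp.flat()
        if p.sum() <= 0:
            raise ValueError("degenerate expected SFS: all mass masked")
        cell_ids = rng.choice(n_cells, size=spec.S, p=p / p.sum())
        blocked = BlockedSNPs(sizes, _split_blocks(cell_ids, spec.block_size))
    obs = blocked.to_sfs()
    obs = FoldedSFS(
        obs.sample_sizes,
        obs.data,
        is_counts=True,
        provenance={"seed": spec.seed, "S": spec.S, "linked": spec.linked},
    )
    return obs, blocked


def make_target_curve(spec: SyntheticDatasetSpec) -> IICRCurve:
    """PSMC-like step target: exact IICR, discretized to log-spaced intervals,
    each level multiplied by lognormal(0, sigma) noise (sigma = 0 returns the
    noise-free discretization)."""
    if spec.model is None:
        raise ValueError("spec.model is required to make a target curve")
    curve = iicr_exact(spec.model, spec.grid)
    step = discretize_like_psmc(curve, spec.n_intervals)
    if spec.sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = step.values * rng.lognormal(0.0, spec.sigma, size=len(step.values))
        step = IICRCurve(
            step.times,
            noisy,
            time_units=step.time_units,
            size_units=step.size_units,
            kind="step",
            provenance={**step.provenance, "sigma": spec.sigma, "seed": spec.seed},
        )
    return step


# ---------------------------------------------------------------------------
# fixture round trips
# ---------------------------------------------------------------------------

_WRITERS = {
    "IICRCurve": (write_curve_tsv, read_curve_tsv, ".tsv"),
    "FoldedSFS": (write_sfs_tsv, read_sfs_tsv, ".sfs.tsv"),
    "BlockedSNPs": (write_blocks_tsv, read_blocks_tsv, ".blocks.tsv"),
}


def write_fixtures(path: str, objects: dict, seeds: dict | None = None) -> None:
    """Write a directory of fixtures with a manifest recording types and the
    seeds used to generate them; every object round-trips losslessly."""
    os.makedirs(path, exist_ok=True)
    manifest = {"seeds": seeds or {}, "objects": {}}
    for name, obj in objects.items():
        tname = type(obj).__name__
        if tname in _WRITERS:
            writer, _, ext = _WRITERS[tname]
            fname = name + ext
            writer(obj, os.path.join(path, fname))
        elif tname == "Scenario":
            fname = name + ".scenario.json"
            with open(os.path.join(path, fname), "w") as fh:
                json.dump(scenario_to_dict(obj), fh, indent=1)
        elif hasattr(obj, "schedule"):  # IICR demography model
            tname = "Model"
            fname = name + ".model.json"
            with open(os.path.join(path, fname), "w") as fh:
                json.dump(model_to_dict(obj), fh, indent=1)
        else:
            raise TypeError(f"no fixture writer for {tname}")
        manifest["objects"][name] = {"type": tname, "file": fname}
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_fixtures(path: str) -> dict:
    mpath = os.path.join(path, "manifest.json")
    try:
        with open(mpath) as fh:
            manifest = json.load(fh)
    except FileNotFoundError:
        raise FileNotFoundError(f"{mpath}: fixture manifest missing")
    except json.JSONDecodeError as e:
        raise ValueError(f"{mpath}: corrupted manifest ({e})") from e
    out = {}
    for name, entry in manifest["objects"].items():
        fpath = os.path.join(path, entry["file"])
        tname = entry["type"]
        try:
            if tname in _WRITERS:
                _, reader, _ = _WRITERS[tname]
                out[name] = reader(fpath)
            elif tname == "Scenario":
                with open(fpath) as fh:
                    out[name] = scenario_from_dict(json.load(fh))
            elif tname == "Model":
                with open(fpath) as fh:
                    out[name] = model_from_dict(json.load(fh))
            else:
                raise TypeError(f"unknown fixture type {tname}")
        except (ValueError, KeyError, json.JSONDecodeError) as e:
            raise ValueError(f"{fpath}: failed to read field of {name} ({e})") from e
    out["_manifest"] = manifest
    return out
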