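"""Backward-time Gillespie simulation of genealogies under event-based
multi-deme demographies, and Monte-Carlo expected folded SFS.

Within deme ``d`` every lineage pair coalesces at rate ``1 / N_d`` per
generation (haploid size ``N_d``); every lineage emigrates at rate
``2NM0 / N_d`` toward a uniformly chosen other active deme, so the expected
number of haploid immigrants entering each deme per generation equals the
``2NM0`` parameter of the scenario.  Event boundaries clamp the waiting time
(exact by memorylessness); deme merges relabel lineages deterministically.

The expected SFS accumulates, over replicate genealogies, the branch length
subtending each (pop0, pop1) sample-configuration class; with a unit mutation
rate the normalized branch lengths are the probabilities that a random SNP
falls in each class (infinite-sites).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .scenarios import CompiledTimeline, Scenario, compile_timeline
from .sfs import FoldedSFS, canonical_mask, fold_array

__all__ = ["simulate_pairwise_tmrca", "branch_length_spectrum", "expected_sfs"]


@njit(cache=True)
def _sim_kernel(
    R: int,
    deme0: np.ndarray,
    lab0: np.ndarray,
    lab1: np.ndarray,
    n0: int,
    n1: int,
    boundaries: np.ndarray,
    sizes: np.ndarray,
    mig_rate: np.ndarray,
    active: np.ndarray,
    remap: np.ndarray,
    seed: int,
    collect_tmrca: int,
):
    """Simulate R genealogies; return (branch-length matrix, TMRCA draws).

    ``lab0/lab1``: per starting lineage, subtended sample counts in the two
    observed populations.  Branch lengths accumulate into L[i, j].
    """
    np.random.seed(seed)
    nsam = deme0.shape[0]
    D = sizes.shape[1]
    B = boundaries.shape[0]
    L = np.zeros((n0 + 1, n1 + 1))
    tmrcas = np.zeros(R if collect_tmrca == 1 else 0)

    deme = np.empty(nsam, dtype=np.int64)
    li = np.empty(nsam, dtype=np.int64)
    lj = np.empty(nsam, dtype=np.int64)
    cnt = np.empty(D, dtype=np.int64)

    for rep in range(R):
        for a in range(nsam):
            deme[a] = deme0[a]
            li[a] = lab0[a]
            lj[a] = lab1[a]
        k = nsam
        t = 0.0
        seg = 0
        while k > 1:
            for d in range(D):
                cnt[d] = 0
            for a in range(k):
                cnt[deme[a]] += 1
            tot = 0.0
            for d in range(D):
                if cnt[d] > 0:
                    tot += 0.5 * cnt[d] * (cnt[d] - 1) / sizes[seg, d]
                    tot += cnt[d] * mig_rate[seg, d]
            tb = boundaries[seg] if seg < B else np.inf
            if tot <= 0.0:
                if seg >= B:
                    raise RuntimeError("non-coalescing configuration: no events possible")
                dt = tb - t
                for a in range(k):
                    L[li[a], lj[a]] += dt
                t = tb
                for a in range(k):
                    deme[a] = remap[seg, deme[a]]
                seg += 1
                continue
            tau = np.random.exponential(1.0 / tot)
            if seg < B and t + tau >= tb:
                dt = tb - t
                for a in range(k):
                    L[li[a], lj[a]] += dt
                t = tb
                for a in range(k):
                    deme[a] = remap[seg, deme[a]]
                seg += 1
                continue
            for a in range(k):
                L[li[a], lj[a]] += tau
            t += tau
            # choose the event
            r = np.random.random() * tot
            acc = 0.0
            done = False
            for d in range(D):
                if cnt[d] == 0:
                    continue
                c_rate = 0.5 * cnt[d] * (cnt[d] - 1) / sizes[seg, d]
                if r < acc + c_rate:
                    # coalescence in deme d: pick an unordered pair uniformly
                    u = int(np.random.random() * cnt[d])
                    v = int(np.random.random() * (cnt[d] - 1))
                    if v >= u:
                        v += 1
                    a1 = -1
                    a2 = -1
                    seen = 0
                    for a in range(k):
                        if deme[a] == d:
                            if seen == u:
                                a1 = a
                            if seen == v:
                                a2 = a
                            seen += 1
                    li[a1] += li[a2]
                    lj[a1] += lj[a2]
                    deme[a2] = deme[k - 1]
                    li[a2] = li[k - 1]
                    lj[a2] = lj[k - 1]
                    k -= 1
                    done = True
                    break
                acc += c_rate
                m_rate = cnt[d] * mig_rate[seg, d]
                if r < acc + m_rate:
                    # migration out of deme d
                    u = int(np.random.random() * cnt[d])
                    a1 = -1
                    seen = 0
                    for a in range(k):
                        if deme[a] == d:
                            if seen == u:
                                a1 = a
                                break
                            seen += 1
                    n_act = 0
                    for dd in range(D):
                        if active[seg, dd] and dd != d:
                            n_act += 1
                    pick = int(np.random.random() * n_act)
                    seen = 0
                    for dd in range(D):
                        if active[seg, dd] and dd != d:
                            if seen == pick:
                                deme[a1] = dd
                                break
                            seen += 1
                    done = True
                    break
                acc += m_rate
            if not done:
                # numerical edge: attribute to the last positive-rate deme
                for d in range(D - 1, -1, -1):
                    if cnt[d] > 1:
                        a1 = -1
                        a2 = -1
                        seen = 0
                        for a in range(k):
                            if deme[a] == d:
                                if a1 < 0:
                                    a1 = a
                                elif a2 < 0:
                                    a2 = a
                                    break
                        li[a1] += li[a2]
                        lj[a1] += lj[a2]
                        deme[a2] = deme[k - 1]
                        li[a2] = li[k - 1]
                        lj[a2] = lj[k - 1]
                        k -= 1
                        break
        if collect_tmrca == 1:
            tmrcas[rep] = t
    return L, tmrcas


def _starting_lineages(
    scenario: Scenario, nsam: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    if len(nsam) != len(scenario.samples):
        raise ValueError(
            f"scenario defines {len(scenario.samples)} sampled populations, "
            f"got sample sizes for {len(nsam)}"
        )
    deme0, lab0, lab1 = [], [], []
    for pop, (deme, n) in enumerate(zip(scenario.samples, nsam)):
        for _ in range(int(n)):
            deme0.append(deme)
            lab0.append(1 if pop == 0 else 0)
            lab1.append(1 if pop == 1 else 0)
    n0 = int(nsam[0])
    n1 = int(nsam[1]) if len(nsam) > 1 else 0
    return (
        np.asarray(deme0, dtype=np.int64),
        np.asarray(lab0, dtype=np.int64),
        np.asarray(lab1, dtype=np.int64),
        n0,
        n1,
    )


def _run(
    scenario: Scenario,
    nsam: tuple[int, ...],
    R: int,
    seed: int,
    collect_tmrca: bool,
) -> tuple[np.ndarray, np.ndarray]:
    if sum(nsam) < 2:
        raise ValueError("need at least 2 sampled chromosomes")
    tl: CompiledTimeline = compile_timeline(scenario)
    if not tl.coalescence_reachable:
        raise ValueError(
            "non-coalescing configuration: isolated demes with zero migration "
            "and no merge into a common ancestral deme"
        )
    deme0, lab0, lab1, n0, n1 = _starting_lineages(scenario, nsam)
    return _sim_kernel(
        int(R),
        deme0,
        lab0,
        lab1,
        n0,
        n1,
        tl.boundaries,
        tl.sizes,
        tl.mig_rate,
        tl.active,
        tl.remap,
        int(seed) % (2**31 - 1),
        1 if collect_tmrca else 0,
    )


def simulate_pairwise_tmrca(
    scenario: Scenario, nsam: tuple[int, ...], R: int, seed: int
) -> np.ndarray:
    """TMRCA draws (generations) for the full sample over R replicates."""
    _, tm = _run(scenario, nsam, R, seed, collect_tmrca=True)
    return tm


def branch_length_spectrum(
    scenario: Scenario, nsam: tuple[int, ...], R: int, seed: int
) -> np.ndarray:
    """Summed branch length per (pop0, pop1) subtended-sample class over R
    genealogies (unfolded; generations)."""
    L, _ = _run(scenario, nsam, R, seed, collect_tmrca=False)
    return L


def expected_sfs(
    scenario: Scenario,
    nsam: tuple[int, ...],
    R: int = 10_000,
    seed: int = 0,
) -> FoldedSFS:
    """Monte-Carlo expected folded SFS under the scenario.

    Unsampled (ghost) demes shape the genealogy but contribute no observed
    class.  ``R >= 100`` replicate genealogies are averaged.
    """
    if R < 100:
        raise ValueError("R must be >= 100 for a usable expected SFS")
    L = branch_length_spectrum(scenario, nsam, R, seed)
    sizes = tuple(int(n) for n in nsam if n > 0)
    if len(sizes) == 1:
        L = L.sum(axis=1) if nsam[0] > 0 else L.sum(axis=0)
    folded = fold_array(L, sizes)
    mask = canonical_mask(sizes)
    tot = folded[mask].sum()
    if tot <= 0:
        raise ValueError("degenerate expected SFS: no polymorphic branch length")
    folded[mask] /= tot
    return FoldedSFS(
        sizes,
        folded,
        is_counts=False,
        provenance={"R": int(R), "seed": int(seed), "nsam": list(nsam)},
    )
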