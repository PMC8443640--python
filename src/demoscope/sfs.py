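"""Folded site-frequency spectra (1d and joint 2d) and block-structured SNPs.

The folded SFS is indexed by minor-allele count; for a joint spectrum over two
sampled populations a cell ``(i, j)`` and its complement ``(n1-i, n2-j)``
describe the same unpolarized site and are merged onto a canonical cell.
Monomorphic corners are masked.  Readers/writers cover the fastsimcoal2
``.obs`` dialect ("1 observations" header, ``d0_``/``d1_`` labels) and plain
TSV; SNP blocks (the linkage units resampled by the block bootstrap) round-trip
through TSV.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FoldedSFS",
    "BlockedSNPs",
    "canonical_mask",
    "fold_array",
    "write_obs",
    "read_obs",
    "write_sfs_tsv",
    "read_sfs_tsv",
    "write_blocks_tsv",
    "read_blocks_tsv",
]


def _complement(cell: tuple[int, ...], sizes: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(n - c for c, n in zip(cell, sizes))


def canonical_mask(sample_sizes: tuple[int, ...]) -> np.ndarray:
    """Boolean array marking canonical polymorphic cells of the folded SFS."""
    shape = tuple(n + 1 for n in sample_sizes)
    total = sum(sample_sizes)
    mask = np.zeros(shape, dtype=bool)
    for cell in itertools.product(*(range(s) for s in shape)):
        m = sum(cell)
        if m == 0 or m == total:
            continue  # monomorphic
        comp = _complement(cell, sample_sizes)
        if 2 * m < total or (2 * m == total and cell <= comp):
            mask[cell] = True
    return mask


def fold_array(arr: np.ndarray, sample_sizes: tuple[int, ...]) -> np.ndarray:
    """Fold an unfolded spectrum onto canonical minor-allele cells."""
    out = np.zeros_like(arr, dtype=float)
    mask = canonical_mask(sample_sizes)
    for cell in np.argwhere(mask):
        cell = tuple(int(c) for c in cell)
        comp = _complement(cell, sample_sizes)
        out[cell] = arr[cell] + (arr[comp] if comp != cell else 0.0)
    return out


@dataclass(frozen=True)
class FoldedSFS:
    """Folded spectrum: ``data`` is the full (n1+1[, n2+1]) array with all mass
    on canonical cells; ``is_counts`` distinguishes observed counts from
    expected probabilities (which must sum to 1 over unmasked cells)."""

    sample_sizes: tuple[int, ...]
    data: np.ndarray
    is_counts: bool = True
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = tuple(int(n) for n in self.sample_sizes)
        data = np.asarray(self.data, dtype=float)
        if data.shape != tuple(n + 1 for n in sizes):
            raise ValueError(f"data shape {data.shape} does not match samples {sizes}")
        if np.any(data < 0):
            raise ValueError("SFS entries must be non-negative")
        mask = canonical_mask(sizes)
        if np.any(data[~mask] != 0):
            raise ValueError("mass found on masked (non-canonical or monomorphic) cells")
        if not self.is_counts:
            s = data[mask].sum()
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"expected SFS must sum to 1 over unmasked cells (got {s})")
        object.__setattr__(self, "sample_sizes", sizes)
        object.__setattr__(self, "data", data)

    @property
    def dim(self) -> int:
        return len(self.sample_sizes)

    @property
    def mask(self) -> np.ndarray:
        return canonical_mask(self.sample_sizes)

    @property
    def cells(self) -> np.ndarray:
        """Canonical cell coordinates, row-major, shape (n_cells, dim)."""
        return np.argwhere(self.mask)

    def flat(self) -> np.ndarray:
        """Values on canonical cells in the same order as :attr:`cells`."""
        return self.data[self.mask]

    def total(self) -> float:
        return float(self.flat().sum())

    def probabilities(self) -> "FoldedSFS":
        data = np.zeros_like(self.data)
        m = self.mask
        data[m] = self.data[m] / self.data[m].sum()
        return FoldedSFS(self.sample_sizes, data, is_counts=False, provenance=self.provenance)

    @classmethod
    def from_flat(
        cls,
        sample_sizes: tuple[int, ...],
        values: np.ndarray,
        is_counts: bool = True,
        provenance: dict | None = None,
    ) -> "FoldedSFS":
        mask = canonical_mask(tuple(sample_sizes))
        data = np.zeros(mask.shape)
        data[mask] = values
        return cls(tuple(sample_sizes), data, is_counts=is_counts, provenance=provenance or {})


@dataclass(frozen=True)
class BlockedSNPs:
    """Block-structured SNPs: each block is an array of indices into the
    canonical-cell list of a folded SFS with the given sample sizes."""

    sample_sizes: tuple[int, ...]
    blocks: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(n) for n in self.sample_sizes)
        n_cells = int(canonical_mask(sizes).sum())
        blocks = tuple(np.asarray(b, dtype=np.int64) for b in self.blocks)
        if len(blocks) == 0:
            raise ValueError("need at least one block")
        for b in blocks:
            if b.size < 1:
                raise ValueError("block sizes must be >= 1")
            if np.any(b < 0) or np.any(b >= n_cells):
                raise ValueError("SNP cell index outside the unmasked SFS")
        object.__setattr__(self, "sample_sizes", sizes)
        object.__setattr__(self, "blocks", blocks)

    @property
    def n_snps(self) -> int:
        return int(sum(b.size for b in self.blocks))

    def to_sfs(self, block_ids: np.ndarray | None = None) -> FoldedSFS:
        """Observed folded SFS from all blocks, or from a resampled multiset of
        block ids (bootstrap replicate)."""
        n_cells = int(canonical_mask(self.sample_sizes).sum())
        counts = np.zeros(n_cells)
        ids = range(len(self.blocks)) if block_ids is None else block_ids
        for b in ids:
            np.add.at(counts, self.blocks[int(b)], 1.0)
        return FoldedSFS.from_flat(self.sample_sizes, counts, is_counts=True)


# ---------------------------------------------------------------------------
# fastsimcoal2 .obs dialect
# ---------------------------------------------------------------------------


def write_obs(sfs: FoldedSFS, path: str) -> None:
    """Write in the fastsimcoal2 observed-SFS dialect (folded / MAF)."""
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        if sfs.dim == 1:
            n = sfs.sample_sizes[0]
            fh.write("\t".join(f"d0_{i}" for i in range(n + 1)) + "\n")
            fh.write("\t".join(repr(float(v)) for v in sfs.data) + "\n")
        else:
            n1, n2 = sfs.sample_sizes
            fh.write("\t" + "\t".join(f"d0_{j}" for j in range(n1 + 1)) + "\n")
            for i in range(n2 + 1):
                row = "\t".join(repr(float(sfs.data[j, i])) for j in range(n1 + 1))
                fh.write(f"d1_{i}\t{row}\n")


def read_obs(path: str, is_counts: bool = True) -> FoldedSFS:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or "observations" not in lines[0]:
        raise ValueError(f"{path}: missing '<k> observations' header")
    header = lines[1].split("\t")
    if header and header[0] == "":
        # 2d layout: rows d1_i, columns d0_j
        n1 = len(header) - 2
        rows = lines[2:]
        n2 = len(rows) - 1
        data = np.zeros((n1 + 1, n2 + 1))
        for i, row in enumerate(rows):
            fields = row.split("\t")
            if not fields[0].startswith("d1_"):
                raise ValueError(f"{path}: expected d1_ row label, got {fields[0]!r}")
            data[:, i] = [float(x) for x in fields[1:]]
        return FoldedSFS((n1, n2), data, is_counts=is_counts)
    n = len(header) - 1
    data = np.asarray([float(x) for x in lines[2].split("\t")])
    return FoldedSFS((n,), data, is_counts=is_counts)


def write_sfs_tsv(sfs: FoldedSFS, path: str) -> None:
    """Plain TSV: one canonical cell per row."""
    cols = [f"cell_{k}" for k in range(sfs.dim)]
    with open(path, "w") as fh:
        fh.write("\t".join(cols + ["value"]) + "\n")
        fh.write(f"# sample_sizes={','.join(map(str, sfs.sample_sizes))}"
                 f" is_counts={int(sfs.is_counts)}\n")
        for cell, v in zip(sfs.cells, sfs.flat()):
            fh.write("\t".join(map(str, cell)) + f"\t{float(v)!r}\n")


def read_sfs_tsv(path: str) -> FoldedSFS:
    with open(path) as fh:
        fh.readline()
        meta = fh.readline().strip()
        if not meta.startswith("#"):
            raise ValueError(f"{path}: missing metadata line")
        kv = dict(item.split("=") for item in meta[1:].split())
        sizes = tuple(int(x) for x in kv["sample_sizes"].split(","))
        is_counts = bool(int(kv["is_counts"]))
        values = [float(line.rstrip("\n").split("\t")[-1]) for line in fh if line.strip()]
    return FoldedSFS.from_flat(sizes, np.asarray(values), is_counts=is_counts)


def write_blocks_tsv(blocks: BlockedSNPs, path: str) -> None:
    """TSV: block_id, cell coordinates, count (SNPs in that block and cell)."""
    cells = np.argwhere(canonical_mask(blocks.sample_sizes))
    dim = cells.shape[1]
    with open(path, "w") as fh:
        fh.write(f"# sample_sizes={','.join(map(str, blocks.sample_sizes))}\n")
        fh.write("\t".join(["block_id"] + [f"cell_{k}" for k in range(dim)] + ["count"]) + "\n")
        for bid, b in enumerate(blocks.blocks):
            ids, counts = np.unique(b, return_counts=True)
            for cid, cnt in zip(ids, counts):
                coords = "\t".join(map(str, cells[cid]))
                fh.write(f"{bid}\t{coords}\t{cnt}\n")


def read_blocks_tsv(path: str) -> BlockedSNPs:
    with open(path) as fh:
        meta = fh.readline().strip()
        if not meta.startswith("#"):
            raise ValueError(f"{path}: missing sample_sizes metadata line")
        sizes = tuple(int(x) for x in meta[1:].split("=")[1].split(","))
        fh.readline()
        mask = canonical_mask(sizes)
        cells = np.argwhere(mask)
        index = {tuple(c): k for k, c in enumerate(cells)}
        per_block: dict[int, list[int]] = {}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            bid = int(fields[0])
            cell = tuple(int(x) for x in fields[1:-1])
            cnt = int(fields[-1])
            if cell not in index:
                raise ValueError(f"{path}: cell {cell} is not an unmasked SFS cell")
            per_block.setdefault(bid, []).extend([index[cell]] * cnt)
    blocks = tuple(np.asarray(per_block[b]) for b in sorted(per_block))
    return BlockedSNPs(sizes, blocks)
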