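"""Folded SFS containers: canonical-cell folding, validation, block structure
and file round trips (fastsimcoal2 .obs dialect and TSV)."""

import numpy as np
import pytest

from demoscope import (
    BlockedSNPs,
    FoldedSFS,
    canonical_mask,
    fold_array,
    read_blocks_tsv,
    read_obs,
    read_sfs_tsv,
    write_blocks_tsv,
    write_obs,
    write_sfs_tsv,
)


class TestCanonicalMask:
    def test_1d_small(self):
        # nsam=4: minor counts 1 and 2 are canonical; 0, 3, 4 are not
        mask = canonical_mask((4,))
        assert mask.tolist() == [False, True, True, False, False]

    def test_2d_cell_count(self):
        # (10,10): 121 cells, 2 monomorphic, 119 polymorphic folding in
        # complementary pairs with one self-complementary cell (5,5)
        mask = canonical_mask((10, 10))
        assert mask.sum() == 60
        assert mask[5, 5]
        assert not mask[0, 0] and not mask[10, 10]

    def test_complement_cells_excluded(self):
        mask = canonical_mask((3, 3))
        for cell in np.argwhere(mask):
            comp = tuple(3 - c for c in cell)
            if comp != tuple(cell):
                assert not mask[comp]


class TestFoldArray:
    def test_mass_conserved(self):
        rng = np.random.default_rng(0)
        arr = rng.random((5, 5))
        arr[0, 0] = arr[4, 4] = 0.0
        folded = fold_array(arr, (4, 4))
        assert folded.sum() == pytest.approx(arr.sum())

    def test_pairs_summed_self_cell_not_doubled(self):
        arr = np.zeros((5, 5))
        arr[1, 0] = 2.0
        arr[3, 4] = 3.0  # complement of (1, 0)
        arr[2, 2] = 7.0  # self-complementary
        folded = fold_array(arr, (4, 4))
        assert folded[1, 0] == 5.0
        assert folded[2, 2] == 7.0


class TestFoldedSFS:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            FoldedSFS((4,), np.zeros(4))

    def test_negative_entries(self):
        data = np.zeros(5)
        data[1] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            FoldedSFS((4,), data)

    def test_mass_on_masked_cell(self):
        data = np.zeros(5)
        data[3] = 1.0  # complement of 1, not canonical
        with pytest.raises(ValueError, match="masked"):
            FoldedSFS((4,), data)

    def test_probabilities_must_sum_to_one(self):
        data = np.zeros(5)
        data[1], data[2] = 0.5, 0.4
        with pytest.raises(ValueError, match="sum to 1"):
            FoldedSFS((4,), data, is_counts=False)

    def test_probabilities_normalization(self):
        data = np.zeros(5)
        data[1], data[2] = 30.0, 10.0
        p = FoldedSFS((4,), data).probabilities()
        assert not p.is_counts
        assert np.allclose(p.flat(), [0.75, 0.25])

    def test_flat_from_flat_round_trip(self):
        values = np.arange(1.0, 61.0)
        sfs = FoldedSFS.from_flat((10, 10), values)
        assert np.array_equal(sfs.flat(), values)
        assert sfs.total() == pytest.approx(values.sum())

    def test_cells_align_with_flat(self):
        sfs = FoldedSFS.from_flat((4,), np.array([2.0, 5.0]))
        cells = sfs.cells
        assert cells.tolist() == [[1], [2]]
        assert sfs.data[1] == 2.0 and sfs.data[2] == 5.0


class TestBlockedSNPs:
    def make(self):
        return BlockedSNPs((4,), (np.array([0, 0, 1]), np.array([1]), np.array([0, 1])))

    def test_n_snps(self):
        assert self.make().n_snps == 6

    def test_to_sfs_all_blocks(self):
        sfs = self.make().to_sfs()
        assert sfs.flat().tolist() == [3.0, 3.0]

    def test_resampled_multiset(self):
        blocks = self.make()
        sfs = blocks.to_sfs(np.array([0, 0, 2]))
        # block 0 twice plus block 2: cell0 -> 2*2+1, cell1 -> 2*1+1
        assert sfs.flat().tolist() == [5.0, 3.0]

    def test_validation(self):
        with pytest.raises(ValueError, match="at least one block"):
            BlockedSNPs((4,), ())
        with pytest.raises(ValueError, match=">= 1"):
            BlockedSNPs((4,), (np.array([], dtype=int),))
        with pytest.raises(ValueError, match="outside"):
            BlockedSNPs((4,), (np.array([2]),))  # only 2 canonical cells: 0, 1


class TestObsDialect:
    def test_1d_round_trip(self, tmp_path):
        sfs = FoldedSFS.from_flat((6,), np.array([10.0, 4.0, 1.5]))
        path = tmp_path / "sfs_MAFpop0.obs"
        write_obs(sfs, str(path))
        back = read_obs(str(path))
        assert back.sample_sizes == (6,)
        assert np.array_equal(back.data, sfs.data)
        assert "observations" in path.read_text().splitlines()[0]

    def test_2d_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        mask = canonical_mask((10, 10))
        sfs = FoldedSFS.from_flat((10, 10), rng.integers(0, 50, mask.sum()).astype(float))
        path = tmp_path / "sfs_jointMAFpop1_0.obs"
        write_obs(sfs, str(path))
        back = read_obs(str(path))
        assert back.sample_sizes == (10, 10)
        assert np.array_equal(back.data, sfs.data)

    def test_2d_labels(self, tmp_path):
        sfs = FoldedSFS.from_flat((2, 2), np.array([1.0, 2.0, 3.0, 4.0]))
        path = tmp_path / "joint.obs"
        write_obs(sfs, str(path))
        lines = path.read_text().splitlines()
        assert lines[1].split("\t")[1] == "d0_0"
        assert lines[2].startswith("d1_0")

    def test_missing_header(self, tmp_path):
        path = tmp_path / "bad.obs"
        path.write_text("d0_0\td0_1\n0\t1\n")
        with pytest.raises(ValueError, match="header"):
            read_obs(str(path))


class TestTSV:
    def test_sfs_round_trip(self, tmp_path):
        sfs = FoldedSFS.from_flat((4,), np.array([0.75, 0.25]), is_counts=False)
        path = tmp_path / "sfs.tsv"
        write_sfs_tsv(sfs, str(path))
        back = read_sfs_tsv(str(path))
        assert not back.is_counts
        assert np.array_equal(back.data, sfs.data)

    def test_blocks_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        n_cells = int(canonical_mask((10, 10)).sum())
        blocks = BlockedSNPs(
            (10, 10), tuple(rng.integers(0, n_cells, size=50) for _ in range(7))
        )
        path = tmp_path / "blocks.tsv"
        write_blocks_tsv(blocks, str(path))
        back = read_blocks_tsv(str(path))
        assert back.sample_sizes == (10, 10)
        assert len(back.blocks) == 7
        # order within a block is not meaningful; compare as multisets
        for a, b in zip(back.blocks, blocks.blocks):
            assert np.array_equal(np.sort(a), np.sort(b))

    def test_blocks_bad_metadata(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("block_id\tcell_0\tcount\n0\t1\t3\n")
        with pytest.raises(ValueError, match="metadata"):
            read_blocks_tsv(str(path))

    def test_blocks_bad_cell(self, tmp_path):
        path = tmp_path / "bad2.tsv"
        path.write_text("# sample_sizes=4\nblock_id\tcell_0\tcount\n0\t3\t2\n")
        with pytest.raises(ValueError, match="unmasked"):
            read_blocks_tsv(str(path))
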