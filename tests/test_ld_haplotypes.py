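from fractions import Fraction

import numpy as np
import pytest

from haplofoot.errors import LDUndefinedError, SentinelNotFoundError
from haplofoot.ld_haplotypes import (
    HaplotypeBlock,
    PhasedPanel,
    blocks_to_intervals,
    compute_r2,
    expand_blocks,
    expand_haplotype,
    r2_one_vs_many,
    read_panel,
    write_panel,
)


def r2_by_counts(a, b):
    """Independent oracle: exact rational evaluation of the 2x2-table formula."""
    a, b = np.asarray(a), np.asarray(b)
    n, ca, cb, cab = len(a), int(a.sum()), int(b.sum()), int((a & b).sum())
    num = Fraction(n * cab - ca * cb) ** 2
    den = Fraction(ca * (n - ca)) * Fraction(cb * (n - cb))
    return float(num / den)


class TestComputeR2:
    def test_identical_columns(self):
        assert compute_r2([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_independent_columns(self):
        assert compute_r2([1, 1, 0, 0], [1, 0, 1, 0]) == 0.0

    def test_printed_formula_example(self):
        # 2x2 haplotype table: n=8, pA=3/8, pB=2/8, pAB=2/8 -> r2 = 5/9
        a = [1, 1, 1, 0, 0, 0, 0, 0]
        b = [1, 1, 0, 0, 0, 0, 0, 0]
        assert compute_r2(a, b) == pytest.approx(5 / 9, abs=1e-12)
        assert r2_by_counts(a, b) == pytest.approx(5 / 9, abs=1e-15)

    def test_monomorphic_raises(self):
        with pytest.raises(LDUndefinedError):
            compute_r2([0, 0, 0, 0], [1, 0, 1, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_label_swap_and_pearson(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        a = (rng.random(n) < 0.4).astype(int)
        b = np.where(rng.random(n) < 0.2, 1 - a, a)
        if a.sum() in (0, n) or b.sum() in (0, n):
            pytest.skip("monomorphic draw")
        r = compute_r2(a, b)
        assert r == pytest.approx(compute_r2(b, a), abs=1e-15)
        assert r == pytest.approx(compute_r2(1 - a, b), abs=1e-12)
        assert r == pytest.approx(np.corrcoef(a, b)[0, 1] ** 2, abs=1e-12)
        assert r == pytest.approx(r2_by_counts(a, b), abs=1e-12)


def make_panel(matrix, positions, chrom="chr1"):
    matrix = np.asarray(matrix, dtype=np.uint8)
    n = matrix.shape[1]
    return PhasedPanel(
        ids=np.asarray([f"v{i}" for i in range(n)]),
        chrom=np.asarray([chrom] * n),
        pos=np.asarray(positions),
        ref=np.asarray(["A"] * n),
        alt=np.asarray(["G"] * n),
        matrix=matrix,
    )


class TestExpandHaplotype:
    def test_no_linked_variant_gives_singleton(self):
        rng = np.random.default_rng(0)
        m = (rng.random((40, 5)) < 0.5).astype(np.uint8)
        panel = make_panel(m, [100, 200, 300, 400, 500])
        block = expand_haplotype(panel, "v0", min_r2=0.999)
        assert block.member_ids() == ["v0"]

    def test_perfect_ld_block(self):
        col = np.array([1, 0, 1, 1, 0, 0], dtype=np.uint8)
        m = np.tile(col[:, None], (1, 5))
        panel = make_panel(m, [10, 20, 30, 40, 50])
        block = expand_haplotype(panel, "v2", min_r2=0.8)
        assert sorted(block.member_ids()) == [f"v{i}" for i in range(5)]
        assert all(r == pytest.approx(1.0) for _, r in block.members)

    def test_window_excludes_distant_variants(self):
        col = np.array([1, 0, 1, 1, 0, 0], dtype=np.uint8)
        m = np.tile(col[:, None], (1, 3))
        panel = make_panel(m, [100, 200, 5000])
        block = expand_haplotype(panel, "v0", min_r2=0.5, window_bp=1000)
        assert sorted(block.member_ids()) == ["v0", "v1"]

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(7)
        n_var, n_hap = 50, 80
        anc = (rng.random(n_hap) < 0.5).astype(np.uint8)
        m = np.empty((n_hap, n_var), dtype=np.uint8)
        for j in range(n_var):
            flip = (rng.random(n_hap) < 0.15).astype(np.uint8)
            m[:, j] = anc ^ flip
        panel = make_panel(m, np.arange(1, n_var + 1) * 100)
        block = expand_haplotype(panel, "v25", min_r2=0.5)
        expected = {"v25"}
        for j in range(n_var):
            if j == 25:
                continue
            try:
                if compute_r2(m[:, 25], m[:, j]) >= 0.5:
                    expected.add(f"v{j}")
            except LDUndefinedError:
                pass
        assert set(block.member_ids()) == expected

    def test_threshold_nesting(self):
        rng = np.random.default_rng(8)
        anc = (rng.random(100) < 0.5).astype(np.uint8)
        m = np.stack(
            [anc ^ (rng.random(100) < f).astype(np.uint8) for f in
             (0.0, 0.02, 0.05, 0.1, 0.2, 0.4)], axis=1,
        )
        panel = make_panel(m, np.arange(1, 7) * 50)
        loose = set(expand_haplotype(panel, "v0", 0.5).member_ids())
        tight = set(expand_haplotype(panel, "v0", 0.8).member_ids())
        assert tight <= loose

    def test_missing_sentinel_lists_near_ids(self):
        panel = make_panel(np.eye(4, dtype=np.uint8), [1, 2, 3, 4])
        with pytest.raises(SentinelNotFoundError, match="v1"):
            expand_haplotype(panel, "v11")

    def test_expand_blocks_keeps_duplicates(self):
        col = np.array([1, 0, 1, 0], dtype=np.uint8)
        panel = make_panel(col[:, None], [10])
        blocks = expand_blocks(panel, ["v0", "v0"])
        assert len(blocks) == 2


class TestBlocksToIntervals:
    def test_coordinate_conversion(self):
        panel = make_panel(np.array([[1], [0], [1], [0]], dtype=np.uint8), [100])
        block = HaplotypeBlock("v0", [("v0", 1.0)], 0.5, 10**7)
        ivs = blocks_to_intervals(block, panel)
        assert (ivs[0].start, ivs[0].end) == (99, 100)
        assert ivs[0].tags["sentinel"] == "v0"

    def test_one_interval_per_member_and_round_trip(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(10_000, 20, replace=False)) + 1
        m = (rng.random((30, 20)) < 0.5).astype(np.uint8)
        panel = make_panel(m, pos)
        block = HaplotypeBlock(
            "v0", [(f"v{i}", 1.0) for i in range(20)], 0.5, 10**7
        )
        ivs = blocks_to_intervals(block, panel)
        assert len(ivs) == 20
        back = [iv.start + 1 for iv in ivs]
        assert back == pos.tolist()


class TestPanelIO:
    def test_round_trip(self, tmp_path, small_dataset):
        panel = small_dataset.panel
        p = tmp_path / "panel.tsv"
        write_panel(panel, p)
        back = read_panel(p)
        assert np.array_equal(back.matrix, panel.matrix)
        assert np.array_equal(back.pos, panel.pos)
        assert back.ids.tolist() == panel.ids.tolist()
        assert back.ref.tolist() == panel.ref.tolist()

    def test_vectorised_r2_matches_scalar(self, small_dataset):
        m = small_dataset.panel.matrix
        idx = np.arange(1, 40)
        vec = r2_one_vs_many(m, 0, idx)
        for k, j in enumerate(idx):
            try:
                assert vec[k] == pytest.approx(
                    compute_r2(m[:, 0], m[:, j]), abs=1e-12
                )
            except LDUndefinedError:
                assert np.isnan(vec[k])
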