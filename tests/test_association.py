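import numpy as np
import pytest
import scipy.stats

from chromasym.association import (
    ReplicationTiming,
    chromatin_bound_fraction,
    chromatin_bound_fraction_stack,
    nuclear_size_single_slice,
    nuclear_size_volume,
    replication_ratio,
    select_chromatin_slice,
    spearman_coloc,
    timing_curve,
)
from chromasym.errors import ContractError, DegenerateStatisticError, UndefinedRatioError
from chromasym.imgio import ImageStack, RegionOfInterest
from chromasym.quant3d import TotalSignal
from chromasym.synthetic import AssociationSpec, generate_association_cell
from conftest import spearman_formula


def _ts(fs, label="r"):
    return TotalSignal(label, "c", [0], [fs], [0])


class TestChromatinBoundFraction:
    def _worked_example(self):
        # chromatin 10 px at mean 5, cell 40 px at mean 2
        img = np.zeros((10, 10))
        chrom = np.zeros((10, 10), bool)
        cell = np.zeros((10, 10), bool)
        cell[:5, :8] = True  # 40 px
        chrom[:2, :5] = True  # 10 px
        img[chrom] = 5.0
        img[cell & ~chrom] = 1.0  # 30 counts over 30 px -> cell mean 2
        return img, chrom, cell

    def test_worked_example(self):
        img, chrom, cell = self._worked_example()
        assoc = chromatin_bound_fraction(img, chrom, cell)
        assert assoc.amount_bound == 50.0
        assert assoc.amount_excluded == 30.0
        assert assoc.bound_ratio == pytest.approx(5 / 3)

    def test_uniform_ratio_is_area_ratio(self):
        img = np.full((10, 10), 3.0)
        chrom = np.zeros((10, 10), bool)
        cell = np.zeros((10, 10), bool)
        cell[:5, :8] = True
        chrom[:2, :5] = True
        assert chromatin_bound_fraction(img, chrom, cell).bound_ratio == pytest.approx(
            10 / 30
        )

    def test_gain_invariance(self):
        img, chrom, cell = self._worked_example()
        base = chromatin_bound_fraction(img, chrom, cell).bound_ratio
        scaled = chromatin_bound_fraction(img * 11.0, chrom, cell).bound_ratio
        assert scaled == pytest.approx(base)

    def test_all_signal_on_chromatin_flagged(self):
        img, chrom, cell = self._worked_example()
        img[cell & ~chrom] = 0.0
        with pytest.raises(UndefinedRatioError):
            _ = chromatin_bound_fraction(img, chrom, cell).bound_ratio

    def test_chromatin_outside_cell_rejected(self):
        img, chrom, cell = self._worked_example()
        chrom[9, 9] = True
        with pytest.raises(ContractError, match="inside"):
            chromatin_bound_fraction(img, chrom, cell)

    def test_noisy_recovery_50_cells(self):
        spec = AssociationSpec(bound_fraction=0.75, intensity_scale=0.05, poisson=True)
        values = []
        for seed in range(50):
            img, chrom, cell, _ = generate_association_cell(spec, seed)
            values.append(chromatin_bound_fraction(img, chrom, cell).bound_ratio)
        se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(np.mean(values) - 3.0) < 3 * se


class TestSliceSelection:
    def test_largest_slice_lowest_z_on_tie(self):
        masks = np.zeros((4, 6, 6), bool)
        masks[1, :2, :2] = True  # area 4
        masks[2, :3, :3] = True  # area 9
        masks[3, 3:, 3:] = True  # area 9, tie -> z=2 wins
        assert select_chromatin_slice(masks) == 2

    def test_stack_wrapper(self):
        arr = np.zeros((3, 8, 8), dtype=np.uint16)
        arr[1] = 4
        stack = ImageStack({"Cdc6": arr})
        chrom = np.zeros((3, 8, 8), bool)
        cell = np.zeros((3, 8, 8), bool)
        chrom[1, :2, :2] = True
        cell[1, :4, :6] = True
        arr[1, :2, :2] = 12
        assoc, z = chromatin_bound_fraction_stack(stack, "Cdc6", chrom, cell)
        assert z == 1
        assert assoc.chromatin_area == 4


class TestSpearman:
    def test_perfect_and_anti(self, rng):
        a = rng.integers(0, 1000, size=(12, 12))
        mask = np.ones((12, 12), bool)
        assert spearman_coloc(a, a, mask).rho == pytest.approx(1.0)
        assert spearman_coloc(a, 1000 - a, mask).rho == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        a = np.array([[1, 2, 3, 4]])
        b = np.array([[1, 3, 2, 4]])
        mask = np.ones((1, 4), bool)
        assert spearman_coloc(a, b, mask).rho == pytest.approx(0.8)

    def test_independent_noise_near_zero(self, rng):
        a = rng.random((100, 100))
        b = rng.random((100, 100))
        assert abs(spearman_coloc(a, b, np.ones((100, 100), bool)).rho) < 0.05

    def test_constant_channel_flagged(self):
        with pytest.raises(DegenerateStatisticError):
            spearman_coloc(np.ones((3, 3)), np.arange(9.0).reshape(3, 3),
                           np.ones((3, 3), bool))

    def test_monotone_transform_invariance(self, rng):
        a = rng.random((20, 20))
        b = rng.random((20, 20))
        mask = np.ones((20, 20), bool)
        base = spearman_coloc(a, b, mask).rho
        assert spearman_coloc(np.exp(3 * a), b**3 + 5, mask).rho == pytest.approx(base)

    def test_matches_formula_oracle(self, rng):
        a = rng.permutation(100).reshape(10, 10)
        b = rng.permutation(100).reshape(10, 10)
        mask = np.ones((10, 10), bool)
        assert spearman_coloc(a, b, mask).rho == pytest.approx(
            spearman_formula(a.ravel(), b.ravel())
        )


class TestNuclearSize:
    def test_max_of_slices(self):
        rois = [
            RegionOfInterest("n", "circle", center=(16.5, 16.5), radius=r, slices=[z])
            for z, r in enumerate([4.0, 5.0, 4.5])
        ]
        best = nuclear_size_single_slice((32, 32), rois)
        areas = [nuclear_size_single_slice((32, 32), [r]) for r in rois]
        assert best == max(areas)

    def test_volume_sum_times_step(self):
        rois = [
            RegionOfInterest("n", "circle", center=(16.5, 16.5), radius=4.0, slices=[z])
            for z in range(3)
        ]
        area = nuclear_size_single_slice((32, 32), [rois[0]])
        assert nuclear_size_volume((32, 32), rois, z_step_um=0.5) == pytest.approx(
            3 * area * 0.5
        )

    def test_ellipsoid_geometry(self):
        # per-slice circles of an ellipsoid nucleus (a=b=10 px, c=8 um half-depth)
        b_px, c_um, dz = 10.0, 8.0, 0.25
        zs = np.arange(-c_um + dz / 2, c_um, dz)
        rois = [
            RegionOfInterest("n", "circle", center=(24.5, 24.5),
                             radius=b_px * np.sqrt(1 - (z / c_um) ** 2), slices=[i])
            for i, z in enumerate(zs)
            if b_px * np.sqrt(1 - (z / c_um) ** 2) >= 0.8
        ]
        eq_area = nuclear_size_single_slice((49, 49), rois)
        assert eq_area == pytest.approx(np.pi * b_px**2, rel=0.05)
        vol = nuclear_size_volume((49, 49), rois, z_step_um=dz)
        assert vol == pytest.approx(4 / 3 * np.pi * b_px**2 * c_um, rel=0.10)

    def test_no_rois(self):
        with pytest.raises(ContractError):
            nuclear_size_single_slice((10, 10), [])


class TestReplicationRatio:
    def test_gb_double_is_minus_one(self):
        assert replication_ratio(_ts(50, "GSC"), _ts(100, "GB")) == pytest.approx(-1.0)

    def test_equal_zero(self):
        assert replication_ratio(_ts(80), _ts(80)) == 0.0

    def test_gb_brighter_negative(self):
        assert replication_ratio(_ts(90, "GSC"), _ts(95, "GB")) < 0

    def test_antisymmetry(self):
        fwd = replication_ratio(_ts(70), _ts(120))
        rev = replication_ratio(_ts(120), _ts(70))
        assert fwd == pytest.approx(-rev)

    def test_nonpositive_flagged(self):
        with pytest.raises(UndefinedRatioError):
            replication_ratio(_ts(0), _ts(10))


class TestTimingCurve:
    def _entry(self, pid, size, ratio):
        return ReplicationTiming(pid, size, "slice", "PCNA", ratio)

    def test_sorted_stable(self):
        entries = [self._entry("a", 30, 0.1), self._entry("b", 10, -0.5),
                   self._entry("c", 30, 0.2), self._entry("d", 20, -0.1)]
        df = timing_curve(entries)
        assert list(df["pair_id"]) == ["b", "d", "a", "c"]

    def test_single_entry(self):
        assert len(timing_curve([self._entry("a", 5, 0.0)])) == 1

    def test_early_pairs_negative_at_small_sizes(self, rng):
        # construction: early (small) pairs get negative log2 ratios
        entries = [self._entry(f"e{i}", rng.uniform(5, 10), rng.uniform(-1.5, -0.5))
                   for i in range(10)]
        entries += [self._entry(f"l{i}", rng.uniform(20, 30), rng.uniform(-0.1, 0.1))
                    for i in range(10)]
        rng.shuffle(entries)
        df = timing_curve(entries)
        assert (df["log2_ratio"].iloc[:10] < -0.4).all()

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            timing_curve([])
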