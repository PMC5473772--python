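"""Area binning, control subtraction, regression, fold-change estimation."""

import numpy as np
import pytest

from bifcros.population import (
    bin_by_area,
    estimate_fold_change,
    regress_signal_vs_background,
    subtract_control,
)
from bifcros.quantify import CellQuant


def quant(area=100, mean=500.0, signal=None, background=None, cell_id=0):
    signal = mean * 2 if signal is None else signal
    background = mean / 2 if background is None else background
    return CellQuant(
        cell_id=cell_id, area=area, mean_intensity=mean, signal=signal,
        background=background, ratio=signal / background if background else 1.0,
        max_pixel=signal,
    )


class TestBinByArea:
    def test_window_below_min_cells_excluded(self):
        quants = [quant(area=105, cell_id=i) for i in range(9)]
        assert bin_by_area(quants, window=10, min_cells=10) == []

    def test_identical_cells_one_bin(self):
        quants = [quant(area=105, mean=321.0, cell_id=i) for i in range(25)]
        bins = bin_by_area(quants, window=10, min_cells=10)
        assert len(bins) == 1
        assert bins[0].mean_intensity == pytest.approx(321.0)
        assert bins[0].n_cells == 25
        assert bins[0].bin_lower == 100.0 and bins[0].bin_upper == 110.0

    def test_disjoint_bins_match_brute_force_grouping(self, rng):
        quants = [
            quant(area=int(a), mean=float(m), cell_id=i)
            for i, (a, m) in enumerate(
                zip(rng.integers(80, 400, 500), rng.uniform(50, 5000, 500))
            )
        ]
        bins = bin_by_area(quants, window=10, min_cells=10)
        # brute-force independent grouping
        groups = {}
        for q in quants:
            groups.setdefault(q.area // 10, []).append(q.mean_intensity)
        expected = {
            k: (len(v), float(np.mean(v))) for k, v in groups.items() if len(v) >= 10
        }
        assert len(bins) == len(expected)
        for b in bins:
            n, m = expected[int(b.bin_lower // 10)]
            assert b.n_cells == n
            assert b.mean_intensity == pytest.approx(m)

    def test_sliding_mode_windows_overlap(self):
        quants = [quant(area=a, cell_id=i) for i, a in enumerate([100] * 12 + [105] * 12)]
        sliding = bin_by_area(quants, window=10, min_cells=10, mode="sliding")
        assert len(sliding) > len(bin_by_area(quants, window=10, min_cells=10))

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            bin_by_area([], mode="hexagonal")


class TestSubtractControl:
    def test_grand_mean_subtracted(self):
        control = [quant(mean=100.0, cell_id=i) for i in range(5)]
        (adj,) = subtract_control([quant(mean=350.0)], control)
        assert adj.mean_intensity == pytest.approx(250.0)
        assert not adj.clamped

    def test_constant_population_self_subtraction_is_zero(self):
        pop = [quant(mean=77.0, cell_id=i) for i in range(8)]
        adjusted = subtract_control(pop, pop)
        assert all(a.mean_intensity == 0.0 for a in adjusted)

    def test_clamped_count_matches_cells_below_control_mean(self, rng):
        pop = [quant(mean=float(m), cell_id=i) for i, m in enumerate(rng.uniform(0, 200, 300))]
        control = [quant(mean=100.0, cell_id=i) for i in range(10)]
        adjusted = subtract_control(pop, control)
        n_clamped = sum(a.clamped for a in adjusted)
        assert n_clamped == sum(q.mean_intensity < 100.0 for q in pop)
        assert all(a.mean_intensity >= 0.0 for a in adjusted)

    def test_inputs_not_mutated(self):
        pop = [quant(mean=350.0)]
        subtract_control(pop, [quant(mean=100.0)])
        assert pop[0].mean_intensity == 350.0

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            subtract_control([quant()], [])


class TestRegression:
    def test_exact_line_recovered(self):
        quants = [
            quant(signal=float(x), background=0.2 * x + 50.0, cell_id=i)
            for i, x in enumerate(range(100, 1100, 100))
        ]
        fit = regress_signal_vs_background(quants)
        assert fit.slope == pytest.approx(0.2)
        assert fit.intercept == pytest.approx(50.0)
        assert fit.n_points == 10

    def test_axis_caps_exclude_points(self):
        quants = [quant(signal=70000.0, background=100.0, cell_id=i) for i in range(5)]
        with pytest.raises(ValueError, match="axis caps"):
            regress_signal_vs_background(quants)

    def test_matches_covariance_formula(self, rng):
        xs = rng.uniform(100, 60000, 20)
        ys = rng.uniform(10, 14000, 20)
        quants = [
            quant(signal=float(x), background=float(y), cell_id=i)
            for i, (x, y) in enumerate(zip(xs, ys))
        ]
        fit = regress_signal_vs_background(quants)
        slope = np.cov(xs, ys, ddof=1)[0, 1] / np.var(xs, ddof=1)
        intercept = ys.mean() - slope * xs.mean()
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)


class TestFoldChange:
    def test_identical_populations_give_unity(self):
        pop = [quant(mean=500.0, cell_id=i) for i in range(20)]
        assert estimate_fold_change(pop, pop).fold == pytest.approx(1.0)

    def test_doubled_intensities_give_two(self, rng):
        a = [quant(mean=float(m), cell_id=i) for i, m in enumerate(rng.uniform(100, 900, 50))]
        b = [quant(mean=2 * q.mean_intensity, cell_id=q.cell_id) for q in a]
        assert estimate_fold_change(a, b).fold == pytest.approx(2.0)

    def test_brightest_half_subset(self):
        a = [quant(mean=m, cell_id=i) for i, m in enumerate([10.0] * 10 + [100.0] * 10)]
        fc = estimate_fold_change(a, a, subset_fraction=0.5)
        assert fc.denominator_mean == pytest.approx(100.0)
        assert fc.n_denominator == 10

    def test_zero_mean_control_leaves_fold_unchanged(self, rng):
        a = [quant(mean=float(m), cell_id=i) for i, m in enumerate(rng.uniform(100, 900, 30))]
        b = [quant(mean=3 * q.mean_intensity, cell_id=q.cell_id) for q in a]
        control = [quant(mean=0.0, cell_id=i) for i in range(10)]
        assert estimate_fold_change(a, b, control=control).fold == pytest.approx(
            estimate_fold_change(a, b).fold
        )

    def test_control_subtraction_order_subset_then_subtract(self):
        # brightest-half selection happens before control subtraction
        a = [quant(mean=m, cell_id=i) for i, m in enumerate([10.0] * 10 + [100.0] * 10)]
        control = [quant(mean=50.0, cell_id=i) for i in range(5)]
        fc = estimate_fold_change(a, a, subset_fraction=0.5, control=control)
        assert fc.denominator_mean == pytest.approx(50.0)  # 100 - 50

    def test_empty_strain_rejected(self):
        with pytest.raises(ValueError):
            estimate_fold_change([], [quant()])

    def test_zero_denominator_rejected(self):
        a = [quant(mean=10.0, cell_id=i) for i in range(5)]
        control = [quant(mean=50.0, cell_id=i) for i in range(5)]
        with pytest.raises(ValueError, match="zero"):
            estimate_fold_change(a, a, control=control)
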