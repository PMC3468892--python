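"""Variability metrics: ranges, significance proportions, peaks, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fmriverse import metrics as mx
from fmriverse.multiverse import FactorGrid, PipelineSpec, enumerate_pipelines


def _stack_from_values(values, shape=(2, 2, 2)):
    """One constant map per value, to make hand calculations transparent."""
    return np.stack([np.full(shape, v, float) for v in values])


MASK = np.ones((2, 2, 2), dtype=bool)


class TestAnalyticRange:
    def test_identical_maps_give_zero_range(self):
        r = mx.analytic_range(_stack_from_values([1.5, 1.5, 1.5]), MASK)
        assert np.all(r.analytic_range == 0)

    def test_hand_example_one_two_four(self):
        r = mx.analytic_range(_stack_from_values([1, 2, 4]), MASK)
        assert np.allclose(r.analytic_range, 3.0)
        assert np.allclose(r.mean_activation, 7.0 / 3.0)

    def test_duplicate_map_leaves_range_unchanged(self):
        a = mx.analytic_range(_stack_from_values([1, 2, 4]), MASK)
        b = mx.analytic_range(_stack_from_values([1, 2, 4, 4]), MASK)
        assert np.allclose(a.analytic_range, b.analytic_range, equal_nan=True)

    def test_single_map_rejected(self):
        with pytest.raises(ValueError):
            mx.analytic_range(_stack_from_values([1.0]), MASK)


class TestStepRange:
    def test_three_option_hand_example(self):
        """mean(|1-2|, |1-4|, |2-4|) = 2 for a single other-factor setting."""
        grid = FactorGrid((("smoothing", ("4", "8", "12")),))
        pipes = enumerate_pipelines(grid)
        stack = _stack_from_values([1, 2, 4])
        out = mx.step_range(stack, grid, pipes, "smoothing")
        assert np.allclose(out, 2.0)

    def test_identical_maps_give_zero(self):
        grid = FactorGrid((("a", ("x", "y")), ("b", ("p", "q"))))
        pipes = enumerate_pipelines(grid)
        stack = _stack_from_values([3, 3, 3, 3])
        assert np.allclose(mx.step_range(stack, grid, pipes, "a"), 0.0)

    def test_two_option_factor_is_mean_absolute_difference(self):
        grid = FactorGrid((("a", ("x", "y")), ("b", ("p", "q"))))
        pipes = enumerate_pipelines(grid)
        # order: (x,p), (x,q), (y,p), (y,q)
        stack = _stack_from_values([1.0, 5.0, 2.0, 3.0])
        out = mx.step_range(stack, grid, pipes, "a")
        # settings of b: p -> |1-2| = 1; q -> |5-3| = 2; mean = 1.5
        assert np.allclose(out, 1.5)

    def test_incomplete_stack_reports_gaps(self):
        grid = FactorGrid((("a", ("x", "y")),))
        pipes = enumerate_pipelines(grid)[:1]
        with pytest.raises(ValueError, match="incomplete"):
            mx.step_range(_stack_from_values([1.0]), grid, pipes, "a")

    def test_step_range_bounded_by_analytic_range(self, rng):
        grid = FactorGrid((("a", ("x", "y")), ("b", ("p", "q", "r"))))
        pipes = enumerate_pipelines(grid)
        stack = rng.standard_normal((6, 2, 2, 2))
        ar = mx.analytic_range(stack, MASK).analytic_range
        for fac in ("a", "b"):
            sr = mx.step_range(stack, grid, pipes, fac)
            assert np.all(sr <= ar + 1e-12)


class TestSignificance:
    def test_proportion_extremes_and_counts(self):
        stack = np.stack([np.ones((2, 2, 2), bool)] * 3 + [np.zeros((2, 2, 2), bool)] * 2)
        prop = mx.significance_proportion(stack, MASK)
        assert np.allclose(prop, 3 / 5)
        assert np.allclose(
            mx.significance_proportion(stack[:3], MASK), 1.0
        )
        assert np.allclose(
            mx.significance_proportion(stack[3:], MASK), 0.0
        )

    def test_discordance_paper_boundary_values(self):
        assert mx.discordance(np.array([0.5]))[0] == 0.5
        assert mx.discordance(np.array([0.0]))[0] == 0.0
        assert mx.discordance(np.array([1.0]))[0] == 0.0
        assert mx.discordance(np.array([0.3]))[0] == pytest.approx(0.3)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(0, 1))
    def test_discordance_symmetric_and_bounded(self, p):
        d1 = mx.discordance(np.array([p]))[0]
        d2 = mx.discordance(np.array([1 - p]))[0]
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0.0 <= d1 <= 0.5

    def test_out_of_range_proportion_rejected(self):
        with pytest.raises(ValueError):
            mx.discordance(np.array([1.2]))


def _pipes(n):
    return [PipelineSpec((("p", str(i)),)) for i in range(n)]


class TestPeakTable:
    affine = np.array([
        [2.0, 0, 0, -10.0], [0, 2.0, 0, -10.0], [0, 0, 2.0, -10.0], [0, 0, 0, 1.0],
    ])

    def test_identical_maps_one_unique_location(self, rng):
        vol = rng.standard_normal((8, 8, 8))
        stack = np.stack([vol] * 4)
        scope = np.ones((8, 8, 8), bool)
        table, summary = mx.peak_table(stack, _pipes(4), {"all": scope}, self.affine)
        assert summary["all"]["n_unique_locations"] == 1
        assert all(v == 0.0 for v in summary["all"]["sd_mm"].values())

    def test_two_point_dispersion_hand_computed(self):
        stack = np.zeros((2, 8, 8, 8))
        stack[0, 0, 4, 4] = 5.0  # world x = -10
        stack[1, 4, 4, 4] = 5.0  # world x = -2
        scope = np.ones((8, 8, 8), bool)
        table, summary = mx.peak_table(stack, _pipes(2), {"all": scope}, self.affine)
        assert summary["all"]["n_unique_locations"] == 2
        # SD of {-10, -2} with ddof=1 is 8/sqrt(2)
        assert summary["all"]["sd_mm"]["x"] == pytest.approx(8 / np.sqrt(2))
        assert summary["all"]["sd_mm"]["y"] == 0.0
        assert summary["all"]["sd_mm"]["z"] == 0.0

    def test_tie_breaks_to_lowest_linear_index(self):
        vol = np.zeros((4, 4, 4))
        vol[1, 1, 1] = 7.0
        vol[3, 3, 3] = 7.0
        scope = np.ones((4, 4, 4), bool)
        table, _ = mx.peak_table(vol[None], _pipes(1), {"all": scope}, self.affine)
        row = table.iloc[0]
        assert (row["x"], row["y"], row["z"]) == (-8.0, -8.0, -8.0)

    def test_peaks_lie_inside_scope(self, rng):
        stack = rng.standard_normal((3, 8, 8, 8))
        scope = np.zeros((8, 8, 8), bool)
        scope[5:, :, :] = True
        table, _ = mx.peak_table(stack, _pipes(3), {"right": scope}, self.affine)
        assert (table["x"] >= self.affine[0, 0] * 5 + self.affine[0, 3]).all()

    def test_all_nan_scope_flagged_absent(self):
        stack = np.full((1, 4, 4, 4), np.nan)
        scope = np.ones((4, 4, 4), bool)
        table, summary = mx.peak_table(stack, _pipes(1), {"all": scope}, self.affine)
        assert table["absent"].all()
        assert summary["all"]["n_unique_locations"] == 0


class TestMapCorrelations:
    mask = np.ones(5, dtype=bool).reshape(5)

    def test_self_correlation_one(self, rng):
        m = np.ones((5,), bool)
        a = rng.standard_normal(5)
        assert mx.map_correlations(a, a, m) == pytest.approx(1.0)
        assert mx.map_correlations(a, -a, m) == pytest.approx(-1.0)

    def test_fixed_vectors_match_manual_pearson(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        m = np.ones(5, bool)
        am, bm = a - a.mean(), b - b.mean()
        manual = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
        assert mx.map_correlations(a, b, m) == pytest.approx(manual)

    def test_step_pairwise_summary(self, rng):
        m = np.ones((10,), bool)
        maps = {k: rng.standard_normal(10) for k in "abc"}
        out = mx.step_pairwise_correlation(maps, m)
        assert out["n_pairs"] == 3
        assert 0 <= out["mean_abs_r"] <= 1
        assert out["mean_r2"] <= out["mean_abs_r"] + 1e-12


class TestExtentSummary:
    def test_counts_against_sorting_oracle(self, tiny_cohort):
        from fmriverse import multiverse as mv
        from conftest import BASE_OPTIONS

        res = mv.run_multiverse(
            tiny_cohort,
            constraints={**BASE_OPTIONS, "smoothing_fwhm": ["4", "8"]},
            methods=[s for s in __import__("fmriverse").default_threshold_specs()
                     if s.method in ("fdr", "rft")],
            seed=4,
        )
        out = mx.extent_summary(res)
        n_mask = res.mask.sum()
        pooled = []
        for j in range(len(res.methods)):
            for i in range(res.n_pipelines):
                pooled.append(res.thresholded[i, j].sum() / n_mask)
        assert out["overall"]["median"] == pytest.approx(np.median(sorted(pooled)))
        assert out["overall"]["n_maps"] == len(pooled)

    def test_single_map_fraction(self):
        from fmriverse.multiverse import MultiverseResult, FactorGrid
        from fmriverse.thresholding import ThresholdSpec

        mask = np.ones((5, 5, 4), bool)  # 100 voxels
        sig = np.zeros((1, 1, 5, 5, 4), bool)
        sig[0, 0, :2, :5, 0] = True  # 10 voxels
        res = MultiverseResult(
            grid=FactorGrid((("a", ("x",)),)),
            pipelines=_pipes(1),
            methods=[ThresholdSpec("fdr", corrected_p=0.05)],
            zmaps=np.zeros((1, 5, 5, 4)),
            thresholded=sig,
            mask=mask,
            affine=np.eye(4),
            smoothness=np.full((1, 3), 3.0),
            threshold_details=[[ThresholdSpec("fdr", corrected_p=0.05)]],
        )
        out = mx.extent_summary(res)
        assert out["per_method"]["fdr"]["median"] == pytest.approx(0.10)
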