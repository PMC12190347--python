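"""Preprocessing: imputation, negative correction, log transform, fold
changes and differential-expression selection."""

import numpy as np
import pytest

from hepatwin.grid import TimeGrid
from hepatwin.preprocess import (
    correct_negatives,
    impute_missing,
    log_transform,
    preprocess_pipeline,
    select_degs,
    to_log2fc,
)
from hepatwin.synth import DEG_TOY_GRID, SynthConfig, gen_cohort, gen_deg_toy


def _single_gene_tensor(make, row, mask_row=None):
    """One gene, several patients, one time point per column of ``row``."""
    values = np.asarray(row, dtype=float)[None, :, None]
    mask = None
    if mask_row is not None:
        mask = np.asarray(mask_row, dtype=bool)[None, :, None]
    return make(values, mask=mask)


class TestImputeMissing:
    def test_mean_of_other_patients(self, tensor_factory):
        t = _single_gene_tensor(tensor_factory, [0.0, 2.0, 4.0], [False, True, True])
        res = impute_missing(t)
        assert res.tensor.values[0, 0, 0] == pytest.approx(3.0)
        assert res.tensor.mask[0, 0, 0]
        assert res.imputed[0, 0, 0]

    def test_single_other_patient(self, tensor_factory):
        t = _single_gene_tensor(tensor_factory, [0.0, 5.0], [False, True])
        assert impute_missing(t).tensor.values[0, 0, 0] == pytest.approx(5.0)

    def test_cell_with_no_observations_reported(self, tensor_factory):
        t = _single_gene_tensor(tensor_factory, [0.0, 0.0], [False, False])
        with pytest.warns(UserWarning, match="no patient"):
            res = impute_missing(t)
        assert not res.tensor.mask[0, 0, 0]
        assert res.unfilled == [(0, 0)]

    def test_idempotent(self, tensor_factory):
        rng = np.random.default_rng(0)
        values = rng.gamma(2.0, 2.0, size=(4, 5, 3))
        mask = rng.random(values.shape) > 0.3
        t = tensor_factory(values, mask=mask)
        once = impute_missing(t).tensor
        twice = impute_missing(once).tensor
        np.testing.assert_array_equal(once.values, twice.values)
        np.testing.assert_array_equal(once.mask, twice.mask)

    def test_rejects_log_scale(self, tensor_factory):
        t = tensor_factory(np.ones((1, 2, 1)), scale="log1p")
        with pytest.raises(ValueError, match="raw"):
            impute_missing(t)


class TestCorrectNegatives:
    def test_mean_of_nonnegative_others(self, tensor_factory):
        t = _single_gene_tensor(tensor_factory, [-0.5, 2.0, 4.0])
        res = correct_negatives(t)
        assert res.tensor.values[0, 0, 0] == pytest.approx(3.0)
        assert res.replaced[0, 0, 0]

    def test_zero_is_not_negative(self, tensor_factory):
        t = _single_gene_tensor(tensor_factory, [0.0, 2.0])
        res = correct_negatives(t)
        assert res.tensor.values[0, 0, 0] == 0.0
        assert not res.replaced.any()

    def test_all_others_unusable_falls_back_to_zero(self, tensor_factory):
        t = _single_gene_tensor(tensor_factory, [-1.0, -2.0], [True, False])
        with pytest.warns(UserWarning, match="no non-negative"):
            res = correct_negatives(t)
        assert res.tensor.values[0, 0, 0] == 0.0
        assert res.zero_filled == [(0, 0, 0)]

    def test_idempotent(self, tensor_factory):
        rng = np.random.default_rng(1)
        t = tensor_factory(rng.normal(1.0, 1.5, size=(5, 4, 3)))
        once = correct_negatives(t).tensor
        twice = correct_negatives(once).tensor
        np.testing.assert_array_equal(once.values, twice.values)


class TestLogTransform:
    @pytest.mark.parametrize("x, expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
    def test_log2_of_one_plus_x(self, tensor_factory, x, expected):
        t = tensor_factory(np.full((1, 1, 1), x))
        assert log_transform(t).values[0, 0, 0] == pytest.approx(expected)

    def test_negative_input_rejected(self, tensor_factory):
        t = tensor_factory(np.full((1, 1, 1), -1.0))
        with pytest.raises(ValueError, match="correct_negatives"):
            log_transform(t)

    def test_idempotent(self, tensor_factory):
        t = tensor_factory(np.arange(6, dtype=float).reshape(1, 2, 3))
        once = log_transform(t)
        twice = log_transform(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert twice.scale == "log1p"


class TestToLog2fc:
    def test_subtracts_baseline(self, tensor_factory, small_grid):
        values = np.array([[[2.0, 3.0, 2.0, 2.5, 2.0]]])
        t = tensor_factory(values, scale="log1p")
        res = to_log2fc(t, small_grid)
        np.testing.assert_allclose(
            res.tensor.values[0, 0], [0.0, 1.0, 0.0, 0.5, 0.0]
        )
        assert res.tensor.scale == "log2fc"

    def test_missing_baseline_masks_pair(self, tensor_factory, small_grid):
        values = np.ones((1, 2, 5))
        mask = np.ones_like(values, dtype=bool)
        mask[0, 1, 0] = False
        t = tensor_factory(values, scale="log1p", mask=mask)
        with pytest.warns(UserWarning, match="baseline"):
            res = to_log2fc(t, small_grid)
        assert not res.tensor.mask[0, 1].any()
        assert res.missing_baseline == [(0, 1)]

    def test_scale_order_enforced(self, tensor_factory, small_grid):
        t = tensor_factory(np.ones((1, 1, 5)), scale="raw")
        with pytest.raises(ValueError, match="log1p"):
            to_log2fc(t, small_grid)


class TestSelectDegs:
    def test_toy_enumeration(self):
        """Hand-enumerated 5-gene toy: 3 pass two-fold, 1 excluded, 2 fail."""
        tensor, toy_grid, expected = gen_deg_toy(0)
        report = select_degs(tensor, toy_grid)
        assert report.n_input == expected.n_input
        assert report.n_twofold == expected.n_twofold
        assert report.n_presurgical_excluded == expected.n_presurgical_excluded
        assert report.n_selected == expected.n_selected
        assert report.selected == expected.selected
        np.testing.assert_array_equal(report.twofold_flags, expected.twofold_flags)

    def test_single_spike_not_selected(self, tensor_factory, small_grid):
        values = np.zeros((1, 1, 5))
        values[0, 0, 2] = 3.0
        report = select_degs(tensor_factory(values, scale="log2fc"), small_grid)
        assert report.n_selected == 0

    def test_pre_resection_exclusion(self):
        tensor, toy_grid, _ = gen_deg_toy(0)
        report = select_degs(tensor, toy_grid)
        assert "PRE_CONFOUNDED" not in report.selected
        assert report.presurgical_flags[2]

    def test_monotone_in_threshold(self):
        tensor, toy_grid, _ = gen_deg_toy(0)
        sizes = [
            select_degs(tensor, toy_grid, twofold_log2=thr).n_selected
            for thr in (0.5, 1.0, 1.5, 2.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_too_few_postop_points_rejected(self, tensor_factory):
        grid = TimeGrid(
            labels=("Before Surgery", "Post Incision", "1 d"),
            hours=(0.0, 0.1, 24.0),
            pre_resection=(True, True, False),
        )
        t = tensor_factory(np.zeros((1, 1, 3)), scale="log2fc")
        with pytest.raises(ValueError, match="post-operative"):
            select_degs(t, grid)

    def test_noise_free_recovery(self, grid):
        """With no noise, selection recovers exactly the genes built to
        exceed both thresholds."""
        cfg = SynthConfig(n_patients=4, K=4, genes_per_cluster=10,
                          noise_sd=0.0, gene_scale_sd=0.0, seed=7,
                          missing_late=(0, 0, 0, 0))
        lfc, _, truth = gen_cohort(cfg)
        report = select_degs(lfc, grid)
        # expected: clusters whose truth trajectory sustains |lfc| >= 1 over
        # two consecutive post-op points for any patient-average profile
        mean_truth = np.mean(
            [truth.cluster_truth[p] for p in lfc.patient_ids], axis=0
        )
        post = grid.postop_indices
        expect = set()
        for k in range(cfg.K):
            prof = np.abs(mean_truth[k][post])
            if np.any((prof[:-1] >= 1.0) & (prof[1:] >= 1.0)):
                expect.update(
                    g for g, lab in zip(lfc.gene_ids, truth.labels) if lab == k + 1
                )
        assert set(report.selected) == expect


def test_pipeline_round_trips_synthetic_raw(grid):
    """The raw-scale synthetic tensor round-trips to the log2fc truth."""
    cfg = SynthConfig(n_patients=6, K=5, genes_per_cluster=8, seed=3)
    lfc, raw, _ = gen_cohort(cfg)
    processed, _ = preprocess_pipeline(raw, grid)
    obs = processed.mask & lfc.mask
    assert obs.any()
    np.testing.assert_allclose(processed.values[obs], lfc.values[obs], atol=1e-9)
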