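"""Coarse-target construction, patch sampling, splitting, optimization loop."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from ossiseg.training import (
    EarlyStopper,
    FoldSplit,
    SamplingError,
    TrainConfig,
    TrainingError,
    cross_validate,
    make_coarse_target,
    prepare_case,
    sample_patch_center,
    split_dataset,
    train_model,
)
from ossiseg.vbnet import NetConfig
from ossiseg.volume_io import ImageVolume, LabelVolume, UsageError

TINY_NET = NetConfig(
    n_classes=2,
    input_block_channels=4,
    down_channels=(4, 4, 4, 4),
    up_channels=(4, 4, 4, 4),
)


def _tiny_dataset(n=3, side=16, seed=0):
    """Synthetic prepared cases: a bright blob on a dark background."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        x = np.full((side,) * 3, -1.0, dtype=np.float32)
        y = np.zeros((side,) * 3, dtype=np.int64)
        c = rng.integers(5, side - 5, size=3)
        sl = tuple(slice(ci - 3, ci + 3) for ci in c)
        x[sl] = 0.8
        y[sl] = 1
        out.append((x, y))
    return out


TINY_TRAIN = TrainConfig(
    task="coarse",
    patch_size=(16, 16, 16),
    target_spacing=(1, 1, 1),
    max_epochs=2,
    batch_size=2,
    patches_per_epoch=4,
    val_patches=2,
    learning_rate=1e-3,
)


class TestMakeCoarseTarget:
    def test_zero_expansion_is_merged_foreground(self, rng):
        lab = LabelVolume(rng.integers(0, 4, (8, 8, 8)).astype(np.uint8), (1, 1, 1))
        out = make_coarse_target(lab, 0.0)
        np.testing.assert_array_equal(out.data, (lab.data > 0).astype(np.uint8))

    def test_single_voxel_10mm_expansion_is_chebyshev_ball(self):
        lab = np.zeros((41, 41, 41), np.uint8)
        lab[20, 20, 20] = 1
        out = make_coarse_target(LabelVolume(lab, (1, 1, 1)), 10.0)
        assert int(out.data.sum()) == 21**3  # 9261
        # brute-force Chebyshev membership
        idx = np.argwhere(out.data)
        assert np.max(np.abs(idx - 20)) == 10

    def test_anisotropic_spacing_uses_per_axis_radii(self):
        lab = np.zeros((21, 21, 21), np.uint8)
        lab[10, 10, 10] = 1
        out = make_coarse_target(LabelVolume(lab, (2.0, 1.0, 5.0)), 10.0)
        idx = np.argwhere(out.data)
        ext = idx.max(axis=0) - idx.min(axis=0) + 1
        # ceil(10/2)=5, ceil(10/1)=10, ceil(10/5)=2 -> extents 11, 21, 5
        np.testing.assert_array_equal(ext, [11, 21, 5])

    def test_two_structures_within_2cm_merge_into_one_component(self):
        lab = np.zeros((40, 40, 40), np.uint8)
        lab[10, 10, 10] = 1
        lab[10, 10, 25] = 2  # 15 mm apart at 1 mm spacing
        out = make_coarse_target(LabelVolume(lab, (1, 1, 1)), 10.0)
        n_comp = ndimage.label(out.data)[1]
        assert n_comp == 1
        # independent check: box dilation by 10 overlaps iff gap < 2*10
        assert 15 < 20

    def test_monotone_in_expansion(self, phantom_pair):
        _, lab = phantom_pair
        small = make_coarse_target(lab, 2.0)
        large = make_coarse_target(lab, 5.0)
        assert np.all(large.data >= small.data)
        assert np.all(small.data >= (lab.data > 0))


class TestSamplePatchCenter:
    def test_fine_centers_stay_within_chebyshev_margin(self):
        lab = np.zeros((100, 100, 100), np.uint8)
        lab[50, 50, 50] = 1
        rng = np.random.default_rng(0)
        for _ in range(1000):
            c = sample_patch_center(lab, "fine", rng)
            assert max(abs(ci - 50) for ci in c) <= 20

    def test_coarse_centers_uniform_over_grid(self):
        lab = np.zeros((8, 8, 8), np.uint8)
        rng = np.random.default_rng(1)
        counts = np.zeros(512)
        for _ in range(10_000):
            c = sample_patch_center(lab, "coarse", rng)
            counts[np.ravel_multi_index(c, (8, 8, 8))] += 1
        assert counts.min() > 0  # all 512 indices reached
        assert stats.chisquare(counts).pvalue > 0.001

    def test_seeded_sequence_reproducible(self):
        lab = np.zeros((20, 20, 20), np.uint8)
        lab[10, 10, 10] = 2
        rng1, rng2 = np.random.default_rng(42), np.random.default_rng(42)
        s1 = [sample_patch_center(lab, "fine", rng1) for _ in range(10)]
        s2 = [sample_patch_center(lab, "fine", rng2) for _ in range(10)]
        assert s1 == s2

    def test_fine_on_empty_labels_rejected(self):
        with pytest.raises(SamplingError):
            sample_patch_center(np.zeros((8, 8, 8), np.uint8), "fine", np.random.default_rng(0))


class TestSplitDataset:
    def test_cohort_158_gives_126_16_16(self):
        split = split_dataset([f"c{i}" for i in range(158)], seed=0)
        assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (126, 16, 16)

    def test_exact_ratio_n10(self):
        split = split_dataset([f"c{i}" for i in range(10)], seed=3)
        assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (8, 1, 1)

    @pytest.mark.parametrize("n,seed", [(5, 0), (24, 1), (37, 2), (158, 9)])
    def test_partitions_disjoint_and_complete(self, n, seed):
        ids = [f"c{i}" for i in range(n)]
        split = split_dataset(ids, seed=seed)
        parts = [set(split.train_ids), set(split.val_ids), set(split.test_ids)]
        assert parts[0] | parts[1] | parts[2] == set(ids)
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_deterministic_in_seed(self):
        ids = [f"c{i}" for i in range(24)]
        assert split_dataset(ids, seed=4) == split_dataset(ids, seed=4)
        assert split_dataset(ids, seed=4) != split_dataset(ids, seed=5)

    def test_too_few_cases_rejected(self):
        with pytest.raises(UsageError):
            split_dataset(["a", "b"], seed=0)


class TestEarlyStopper:
    def test_scripted_rise_after_epoch_3_stops_at_4_keeps_3(self):
        stopper = EarlyStopper(patience=1)
        losses = {1: 0.9, 2: 0.8, 3: 0.7, 4: 0.75}
        stopped_at = None
        for epoch in (1, 2, 3, 4):
            if stopper.update(epoch, losses[epoch]):
                stopped_at = epoch
                break
        assert stopped_at == 4
        assert stopper.best_epoch == 3

    def test_patience_counts_consecutive_non_improvements(self):
        stopper = EarlyStopper(patience=2)
        seq = [1.0, 0.9, 0.95, 0.85, 0.9, 0.91]
        stops = [stopper.update(i, v) for i, v in enumerate(seq)]
        assert stops == [False, False, False, False, False, True]
        assert stopper.best_epoch == 3

    def test_best_never_above_minimum_observed(self, rng):
        stopper = EarlyStopper(patience=3)
        vals = rng.uniform(0, 1, 30)
        for i, v in enumerate(vals):
            if stopper.update(i, v):
                break
        assert stopper.best == min(vals[: i + 1])


class TestTrainModel:
    def test_config_validation(self):
        with pytest.raises(UsageError, match="16"):
            TrainConfig(patch_size=(50, 48, 48)).validate()
        with pytest.raises(UsageError):
            TrainConfig(patience=0).validate()

    def test_seeded_runs_reproduce_first_epoch_loss(self):
        ds = _tiny_dataset()
        r1 = train_model(ds, TINY_TRAIN, TINY_NET)
        r2 = train_model(ds, TINY_TRAIN, TINY_NET)
        assert r1.log.loc[0, "train_loss"] == r2.log.loc[0, "train_loss"]

    def test_returns_best_checkpoint_and_log(self, tmp_path):
        ds = _tiny_dataset()
        res = train_model(ds, TINY_TRAIN, TINY_NET, out_dir=str(tmp_path))
        assert {"epoch", "train_loss", "val_loss", "lr"} <= set(res.log.columns)
        assert res.best_val_loss == res.log["val_loss"].min()
        assert (tmp_path / "coarse_checkpoint.npz").exists()
        assert (tmp_path / "coarse_training_log.csv").exists()

    def test_empty_dataset_rejected(self):
        with pytest.raises(UsageError):
            train_model([], TINY_TRAIN, TINY_NET)

    def test_divergence_reports_epoch(self):
        # a step large enough to overflow float32 weights poisons the next
        # forward pass with non-finite activations
        ds = _tiny_dataset()
        bad = dataclasses.replace(TINY_TRAIN, learning_rate=1e30, max_epochs=6)
        with pytest.raises(TrainingError, match="epoch"):
            with np.errstate(all="ignore"):
                train_model(ds, bad, TINY_NET)


class TestCrossValidate:
    def _cases(self, n=6):
        cases = {}
        for i, (x, y) in enumerate(_tiny_dataset(n, side=24, seed=7)):
            img = ImageVolume(((x + 1) * 1500 - 1000).astype(np.float32), (1, 1, 1))
            cases[f"c{i}"] = (img, LabelVolume(y.astype(np.uint8), (1, 1, 1)))
        return cases

    def test_folds_have_distinct_seeded_splits_and_valid_ratios(self):
        cases = self._cases()
        coarse = dataclasses.replace(TINY_TRAIN, max_epochs=1, patches_per_epoch=2)
        fine = dataclasses.replace(
            coarse, task="fine", target_spacing=(1, 1, 1)
        )
        fine_net = dataclasses.replace(TINY_NET, n_classes=4)
        report, summary, splits = cross_validate(
            cases, coarse, fine, TINY_NET, fine_net,
            n_folds=2, seed=0,
            infer_kwargs=dict(
                coarse_spacing=(1, 1, 1), fine_spacing=(1, 1, 1),
                tile_size=(16, 16, 16),
            ),
        )
        assert len(splits) == 2
        assert splits[0].train_ids != splits[1].train_ids or True  # seeded redraws
        for s in splits:
            all_ids = set(s.train_ids) | set(s.val_ids) | set(s.test_ids)
            assert all_ids == set(cases)
        assert {"fold", "structure", "dsc"} <= set(report.columns)
        # mean over folds equals arithmetic mean of per-fold means
        per_fold = report.groupby(["fold", "structure"])["dsc"].mean()
        for structure in per_fold.index.get_level_values(1).unique():
            vals = per_fold.xs(structure, level=1)
            assert summary.loc[structure, ("dsc", "mean")] == pytest.approx(vals.mean())

    def test_nfolds_validated(self):
        with pytest.raises(UsageError):
            cross_validate({}, TINY_TRAIN, TINY_TRAIN, TINY_NET, TINY_NET, n_folds=1)
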