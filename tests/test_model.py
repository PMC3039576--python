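import dataclasses

import numpy as np
import pytest
from sklearn.svm import SVC

from gotlm.features import aa_composition
from gotlm.io import Dataset, ProteinRecord
from gotlm.kernels import KernelWeights
from gotlm.model import (
    C_GRID,
    CVK_GRID,
    GAMMA_GRID,
    ModelConfig,
    cross_validate,
    holdout_evaluate,
    predict,
    train,
)
from gotlm.synthetic import generate, preset


class TestModelConfig:
    def test_defaults_are_the_canonical_grids(self):
        cfg = ModelConfig()
        assert cfg.cvk_grid == CVK_GRID == (3, 5, 10)
        assert cfg.gamma_grid == GAMMA_GRID == (0.5, 0.25, 0.125, 0.0625)
        assert cfg.c_grid == C_GRID == tuple(2.0**k for k in range(1, 12))

    def test_off_grid_value_rejected(self):
        with pytest.raises(ValueError, match="canonical"):
            ModelConfig(gamma_grid=(0.33,))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ModelConfig(c_grid=())

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            ModelConfig(channels=("AA", "XX"))


class TestTrain:
    def test_grid_of_size_one_wins_trivially(self, separable_dataset, small_config):
        model = train(separable_dataset, small_config)
        assert (model.cvk, model.gamma, model.C) == (3, 0.25, 8.0)

    def test_separable_internal_accuracy(self, separable_dataset, small_config):
        model = train(separable_dataset, small_config)
        assert model.internal_cv_accuracy >= 0.95

    def test_single_channel_reduces_to_plain_rbf_svm(self, separable_dataset):
        """Masking down to AA must match an independently fitted RBF SVM."""
        ds = separable_dataset
        cfg = ModelConfig(
            cvk_grid=(3,), gamma_grid=(0.5,), c_grid=(4.0,), seed=1, channels=("AA",)
        )
        model = train(ds, cfg)
        assert model.weights["AA"] == 1.0
        X = np.array([aa_composition(r.sequence) for r in ds.records])
        ref = SVC(kernel="rbf", gamma=0.5, C=4.0)
        ref.fit(X, [str(l) for l in ds.labels])
        preds = predict(model, ds.records, ds.annotations)
        np.testing.assert_array_equal(
            preds["predicted_location"].to_numpy(), ref.predict(X)
        )

    def test_too_few_examples_recommends_fewer_folds(self):
        records = [
            ProteinRecord(f"p{i}", "MKVA", "a" if i % 2 else "b") for i in range(4)
        ]
        with pytest.raises(ValueError, match="fewer folds"):
            train(Dataset(records=records), ModelConfig(cvk_grid=(10,)))

    def test_single_class_rejected(self):
        records = [ProteinRecord(f"p{i}", "MKVA", "a") for i in range(20)]
        with pytest.raises(ValueError, match="2 location classes"):
            train(Dataset(records=records), ModelConfig(cvk_grid=(3,)))


class TestPredict:
    def test_training_set_self_consistency(self, separable_dataset, small_config):
        ds = separable_dataset
        model = train(ds, small_config)
        preds = predict(model, ds.records, ds.annotations)
        truth = np.array([str(l) for l in ds.labels])
        agreement = (preds["predicted_location"].to_numpy() == truth).mean()
        assert agreement >= 0.99

    def test_all_zero_channels_still_classified(self, separable_dataset, small_config):
        model = train(separable_dataset, small_config)
        stranger = ProteinRecord("strange", "XXXX")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            preds = predict(model, [stranger])
        assert preds["predicted_location"].iloc[0] in model.classes

    def test_duplicate_of_training_protein_gets_twin_label(
        self, separable_dataset, small_config
    ):
        ds = separable_dataset
        model = train(ds, small_config)
        twin_src = ds.records[0]
        twin = ProteinRecord("twin", twin_src.sequence)
        twin_anns = [
            dataclasses.replace(a, protein_id="twin")
            for a in ds.annotations
            if a.protein_id == twin_src.id
        ]
        original = predict(model, [twin_src], ds.annotations)
        cloned = predict(model, [twin], twin_anns)
        assert (
            original["predicted_location"].iloc[0]
            == cloned["predicted_location"].iloc[0]
        )


class TestCrossValidate:
    def test_report_structure(self, separable_dataset, small_config):
        rep = cross_validate(separable_dataset, small_config)
        L = len(separable_dataset.classes)
        assert len(rep.per_class) == L
        assert len(rep.fold_weights) == small_config.outer_folds
        for w in rep.fold_weights:
            assert w.as_array().sum() == pytest.approx(1.0, abs=1e-12)

    def test_every_example_tested_exactly_once(self, separable_dataset, small_config):
        rep = cross_validate(separable_dataset, small_config)
        assert sorted(rep.predictions["protein_id"]) == sorted(separable_dataset.ids)

    def test_class_smaller_than_fold_count_rejected(self):
        records = [
            ProteinRecord(f"p{i}", "MKVA", "rare" if i < 3 else "common")
            for i in range(40)
        ]
        with pytest.raises(ValueError, match="fewer"):
            cross_validate(
                Dataset(records=records),
                ModelConfig(cvk_grid=(3,), gamma_grid=(0.25,), c_grid=(8.0,)),
            )

    def test_less_noise_does_not_hurt_accuracy(self):
        """Halving annotation noise (same seed) never lowers CV accuracy."""
        cfg = ModelConfig(cvk_grid=(3,), gamma_grid=(0.25,), c_grid=(8.0,), seed=5)
        base = preset("noisy", seed=5)
        noisy = generate(base)
        cleaner = generate(dataclasses.replace(base, noise_rate=base.noise_rate / 2))
        acc_noisy = cross_validate(noisy, cfg).overall_accuracy
        acc_cleaner = cross_validate(cleaner, cfg).overall_accuracy
        assert acc_cleaner >= acc_noisy

    def test_ablation_equals_forced_zero_weight(self, separable_dataset):
        """Masking a channel matches zeroing its weight and renormalizing."""
        ds = separable_dataset
        masked_cfg = ModelConfig(
            cvk_grid=(3,), gamma_grid=(0.25,), c_grid=(8.0,), seed=2,
            channels=("AA", "diAA", "P", "F"),
        )
        model = train(ds, masked_cfg)
        assert model.weights["C"] == 0.0
        full_cfg = dataclasses.replace(masked_cfg, channels=("AA", "diAA", "P", "F", "C"))
        full_model = train(ds, full_cfg)
        manual = {c: (0.0 if c == "C" else full_model.channel_scores[c].product)
                  for c in ("AA", "diAA", "P", "F", "C")}
        renorm = KernelWeights.from_products(manual)
        for c in ("AA", "diAA", "P", "F"):
            assert model.weights[c] == pytest.approx(renorm[c], abs=1e-12)


class TestHoldoutEvaluate:
    def split(self, dataset):
        # records are class-ordered, so interleave to keep every class in train
        idx = np.arange(len(dataset.records))
        return dataset.subset(idx[idx % 5 != 0]), dataset.subset(idx[idx % 5 == 0])

    def test_report_matches_cv_structure(self, separable_dataset, small_config):
        tr, te = self.split(separable_dataset)
        rep = holdout_evaluate(tr, te, small_config)
        assert set(rep.per_class.columns) == {
            "location", "size", "SP", "SE", "MCC", "undefined",
        }
        assert len(rep.fold_weights) == 1

    def test_overlapping_ids_rejected(self, separable_dataset, small_config):
        tr, _ = self.split(separable_dataset)
        with pytest.raises(ValueError, match="share"):
            holdout_evaluate(tr, tr, small_config)

    def test_empty_test_set_rejected(self, separable_dataset, small_config):
        tr, _ = self.split(separable_dataset)
        with pytest.raises(ValueError, match="empty"):
            holdout_evaluate(tr, Dataset(records=[]), small_config)

    def test_out_of_vocabulary_protein_classified_from_sequence(
        self, separable_dataset, small_config
    ):
        tr, te = self.split(separable_dataset)
        model = train(tr, small_config)
        record = te.records[0]
        foreign = [
            dataclasses.replace(a, term="GO:9999999")
            for a in te.annotations
            if a.protein_id == record.id
        ]
        preds = predict(model, [record], foreign)
        assert preds["predicted_location"].iloc[0] in model.classes
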