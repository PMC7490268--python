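"""Pixel classifiers: the rule-based reference, the learned MLP, and the
shared prediction contract."""

import numpy as np
import pytest

from sporefit.repaint import (
    CLASS_BACKGROUND,
    ContractViolationError,
    RuleBasedClassifier,
    TrainingConfig,
    segment,
    train_classifier,
    well_disk_mask,
)

from conftest import annotated_crops


class BadClassifier:
    def predict_proba(self, pixels):
        return np.full(pixels.shape[:2] + (3,), 0.5)  # sums to 1.5


class ConstantClassifier:
    def __init__(self, cls):
        self.cls = cls

    def predict_proba(self, pixels):
        probs = np.zeros(pixels.shape[:2] + (3,))
        probs[..., self.cls] = 1.0
        return probs


class TestSegmentContract:
    def test_non_normalized_probabilities_raise_contract_error(self, default_plate):
        _, _, image, _ = default_plate
        crop = image[:256, :256]
        with pytest.raises(ContractViolationError, match="sum to 1"):
            segment(crop, BadClassifier())

    def test_all_one_class_probabilities_give_single_class_mask(self, default_plate):
        _, _, image, _ = default_plate
        crop = image[:256, :256]
        for cls in range(3):
            mask = segment(crop, ConstantClassifier(cls))
            assert (mask.labels == cls).all()

    def test_segmentation_is_deterministic(self, default_plate):
        crops, _ = annotated_crops(seed=55, n=2)
        rule = RuleBasedClassifier()
        a = segment(crops[0], rule)
        b = segment(crops[0], rule)
        assert (a.labels == b.labels).all()


class TestRuleBasedClassifier:
    def test_empty_medium_well_is_nearly_all_background(self):
        from sporefit.repaint import crop_and_normalize, detect_wells
        from sporefit.synth import PlateSpec, generate_plate_image

        image, _ = generate_plate_image(PlateSpec(seed=60))  # empty plate
        region = detect_wells(image)[0]
        mask = segment(crop_and_normalize(image, region), RuleBasedClassifier())
        disk = well_disk_mask()
        assert (mask.labels[disk] == CLASS_BACKGROUND).mean() >= 0.99

    def test_high_pixel_accuracy_against_generator_truth(self):
        crops, masks = annotated_crops(seed=61, n=6)
        rule = RuleBasedClassifier()
        accs = [
            (segment(c, rule).labels == m.labels).mean() for c, m in zip(crops, masks)
        ]
        assert np.mean(accs) >= 0.97


@pytest.fixture(scope="module")
def trained():
    crops, masks = annotated_crops(seed=62, n=10)
    return train_classifier(crops, masks, TrainingConfig(seed=0)), crops


class TestTrainedClassifier:
    def test_training_requires_at_least_two_crops(self):
        crops, masks = annotated_crops(seed=63, n=2)
        with pytest.raises(ValueError, match="at least 2"):
            train_classifier(crops[:1], masks[:1])

    def test_single_class_training_set_rejected(self):
        crops, _ = annotated_crops(seed=64, n=2)
        flat = [np.zeros((256, 256), dtype=np.uint8)] * 2
        with pytest.raises(ValueError, match="one class"):
            train_classifier(crops, flat)

    def test_loss_decreases_while_memorizing_one_example(self):
        crops, masks = annotated_crops(seed=65, n=1)
        clf = train_classifier(
            [crops[0], crops[0]], [masks[0], masks[0]],
            TrainingConfig(seed=1, max_iter=6),
        )
        losses = clf.loss_curve[:5]
        assert all(b <= a for a, b in zip(losses, losses[1:]))

    def test_same_seed_trains_identical_predictors(self):
        crops, masks = annotated_crops(seed=66, n=4)
        probe = crops[0]
        a = train_classifier(crops, masks, TrainingConfig(seed=3, max_iter=15))
        b = train_classifier(crops, masks, TrainingConfig(seed=3, max_iter=15))
        assert (segment(probe, a).labels == segment(probe, b).labels).all()

    def test_held_out_pixel_accuracy_clears_95_percent(self, trained):
        clf, _ = trained
        test_crops, test_masks = annotated_crops(seed=67, n=6)
        accs = [
            (segment(c, clf).labels == m.labels).mean()
            for c, m in zip(test_crops, test_masks)
        ]
        assert np.mean(accs) >= 0.95

    def test_rule_and_learned_classifiers_agree_on_low_noise_images(self, trained):
        clf, _ = trained
        crops, _ = annotated_crops(seed=68, n=4, noise_sd=0.002, color_jitter_sd=0.005)
        rule = RuleBasedClassifier()
        agree = [
            (segment(c, clf).labels == segment(c, rule).labels).mean() for c in crops
        ]
        assert np.mean(agree) >= 0.9

    def test_jitter_augmented_training_matches_rule_under_doubled_jitter(self):
        crops_a, masks_a = annotated_crops(seed=69, n=6)
        crops_b, masks_b = annotated_crops(seed=70, n=6, color_jitter_sd=0.04)
        clf = train_classifier(
            crops_a + crops_b, masks_a + masks_b, TrainingConfig(seed=2)
        )
        rule = RuleBasedClassifier()
        test_crops, test_masks = annotated_crops(seed=71, n=6, color_jitter_sd=0.04)
        acc_learned = np.mean(
            [(segment(c, clf).labels == m.labels).mean()
             for c, m in zip(test_crops, test_masks)]
        )
        acc_rule = np.mean(
            [(segment(c, rule).labels == m.labels).mean()
             for c, m in zip(test_crops, test_masks)]
        )
        assert acc_learned >= acc_rule - 0.005

    def test_metadata_reports_kind_and_config_digest(self, trained):
        clf, _ = trained
        assert clf.metadata["kind"] == "learned"
        assert len(clf.metadata["config_digest"]) == 12
        assert RuleBasedClassifier().metadata["kind"] == "rule_based"
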