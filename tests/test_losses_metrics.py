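"""Hybrid BCE+Dice objective and the Dice/IoU/PR/SE evaluation metrics."""

import numpy as np
import pytest

from wranet.autograd import Tensor
from wranet.losses import LossConfig, bce_loss, dice_loss, hybrid_loss
from wranet.metrics import MetricsReport, segmentation_metrics


# -- binary cross-entropy ----------------------------------------------------

def test_bce_is_near_zero_for_perfect_prediction():
    y = np.array([1.0, 0.0, 1.0, 1.0])
    assert bce_loss(y, y) <= -np.log(1 - 1e-7) + 1e-12


def test_bce_at_half_is_log_two():
    y = (np.random.default_rng(0).random((4, 8)) > 0.5).astype(float)
    assert bce_loss(np.full((4, 8), 0.5), y) == pytest.approx(np.log(2.0), abs=1e-12)


def test_bce_two_pixel_hand_computation():
    value = bce_loss(np.array([0.9, 0.2]), np.array([1.0, 0.0]))
    assert value == pytest.approx(-(np.log(0.9) + np.log(0.8)) / 2, abs=1e-12)
    assert value == pytest.approx(0.164252, abs=1e-6)


def test_bce_rejects_soft_targets_and_shape_mismatch():
    with pytest.raises(ValueError, match="binary"):
        bce_loss(np.array([0.5]), np.array([0.3]))
    with pytest.raises(ValueError, match="shape"):
        bce_loss(np.zeros(3), np.zeros(4))


# -- soft Dice ---------------------------------------------------------------

def test_dice_loss_perfect_full_mask():
    ones = np.ones(100)
    assert dice_loss(ones, ones, lambda_smooth=1.0) == pytest.approx(1 - 200 / 201,
                                                                     abs=1e-12)


def test_dice_loss_no_overlap_is_one():
    assert dice_loss(np.zeros(64), np.ones(64)) == pytest.approx(1.0, abs=1e-12)


def test_dice_loss_empty_mask_degeneracy():
    """A perfectly predicted empty mask still scores loss 1 (documented)."""
    zeros = np.zeros(32)
    assert dice_loss(zeros, zeros, lambda_smooth=1.0) == pytest.approx(1.0)


def test_dice_loss_on_hard_masks_complements_dice_metric(rng):
    pred = (rng.random((1, 16, 16)) > 0.5).astype(float)
    gt = (rng.random((1, 16, 16)) > 0.5).astype(float)
    lam = 1e-9
    soft = dice_loss(pred, gt, lambda_smooth=lam)
    hard = segmentation_metrics(pred, gt).dice
    assert soft == pytest.approx(1.0 - hard, abs=1e-6)


# -- hybrid objective --------------------------------------------------------

def test_hybrid_combination_of_stated_components():
    value = 0.4 * np.log(2.0) + 0.6 * 1.0
    assert value == pytest.approx(0.877259, abs=1e-6)
    y = np.ones(50)
    p = np.full(50, 0.5)
    # p = 0.5 everywhere against all-ones: BCE = ln2, Dice term = 1 - 50/101
    expected = 0.4 * np.log(2.0) + 0.6 * (1 - 2 * 25 / (75 + 1))
    assert hybrid_loss(p, y) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("alpha,beta,ref", [(1.0, 0.0, "bce"), (0.0, 1.0, "dice")])
def test_hybrid_degenerates_to_its_components(rng, alpha, beta, ref):
    p = rng.random(64)
    y = (rng.random(64) > 0.6).astype(float)
    cfg = LossConfig(alpha_weight=alpha, beta_weight=beta)
    expected = bce_loss(p, y) if ref == "bce" else dice_loss(p, y)
    assert hybrid_loss(p, y, cfg) == pytest.approx(expected, abs=1e-12)


def test_hybrid_decreases_as_prediction_approaches_target(rng):
    y = (rng.random((8, 8)) > 0.7).astype(float)
    losses = []
    for t in np.linspace(0.0, 0.95, 12):
        p = 0.5 + t * (y - 0.5)   # elementwise move toward y
        losses.append(hybrid_loss(p, y))
    assert all(a > b for a, b in zip(losses, losses[1:]))
    assert min(losses) >= 0.0


def test_losses_differentiate_through_the_graph(rng):
    p = Tensor(rng.uniform(0.1, 0.9, (4, 4)), requires_grad=True)
    y = (rng.random((4, 4)) > 0.5).astype(float)
    hybrid_loss(p, y).backward()
    assert p.grad is not None and np.all(np.isfinite(p.grad))


def test_loss_config_validation():
    with pytest.raises(ValueError, match="weights"):
        LossConfig(alpha_weight=1.5)
    with pytest.raises(ValueError, match="lambda"):
        LossConfig(lambda_smooth=0.0)


# -- evaluation metrics ------------------------------------------------------

def test_identical_nonempty_masks_score_one(rng):
    m = (rng.random((2, 8, 8)) > 0.5).astype(float)
    r = segmentation_metrics(m, m)
    assert (r.dice, r.iou, r.precision, r.sensitivity) == (1.0, 1.0, 1.0, 1.0)
    assert r.fp == r.fn == 0


def test_disjoint_nonempty_masks_score_zero():
    pred = np.zeros((1, 4, 4))
    pred[0, :2] = 1
    gt = np.zeros((1, 4, 4))
    gt[0, 2:] = 1
    r = segmentation_metrics(pred, gt)
    assert (r.dice, r.iou, r.precision, r.sensitivity) == (0.0, 0.0, 0.0, 0.0)


def test_counts_toy_case():
    """|gt|=4, |pred|=6, overlap 3 -> Dice .6, IoU 3/7, PR .5, SE .75."""
    gt = np.zeros((1, 4, 4))
    gt[0, 0, :4] = 1
    pred = np.zeros((1, 4, 4))
    pred[0, 0, 1:4] = 1       # overlap 3
    pred[0, 1, :3] = 1        # 3 false positives
    r = segmentation_metrics(pred, gt)
    assert r.tp == 3 and r.fp == 3 and r.fn == 1
    assert r.dice == pytest.approx(0.6)
    assert r.iou == pytest.approx(3 / 7)
    assert r.precision == pytest.approx(0.5)
    assert r.sensitivity == pytest.approx(0.75)


def test_empty_mask_conventions():
    empty = np.zeros((1, 4, 4))
    full = np.ones((1, 4, 4))
    both = segmentation_metrics(empty, empty)
    assert (both.dice, both.iou, both.precision, both.sensitivity) == (1, 1, 1, 1)
    one = segmentation_metrics(empty, full)
    assert (one.dice, one.iou, one.precision, one.sensitivity) == (0, 0, 0, 0)


def test_iou_equals_dice_over_two_minus_dice(rng):
    """Algebraic identity checked on 100 random mask pairs."""
    for _ in range(100):
        pred = (rng.random((6, 6)) > rng.random()).astype(float)
        gt = (rng.random((6, 6)) > rng.random()).astype(float)
        r = segmentation_metrics(pred, gt)
        assert r.iou == pytest.approx(r.dice / (2.0 - r.dice), abs=1e-12)


def test_metrics_invariant_under_joint_permutation(rng):
    pred = rng.random((1, 8, 8))
    gt = (rng.random((1, 8, 8)) > 0.6).astype(float)
    perm = rng.permutation(64)
    p2 = pred.reshape(1, -1)[:, perm].reshape(1, 8, 8)
    g2 = gt.reshape(1, -1)[:, perm].reshape(1, 8, 8)
    assert segmentation_metrics(pred, gt) == segmentation_metrics(p2, g2)


def test_macro_vs_micro_averaging():
    pred = np.zeros((2, 2, 2))
    gt = np.zeros((2, 2, 2))
    pred[0], gt[0] = 1, 1                     # image 1 perfect (4 px)
    gt[1, 0, 0] = 1                           # image 2: all-background pred, 1 fg px
    macro = segmentation_metrics(pred, gt, average="macro")
    micro = segmentation_metrics(pred, gt, average="micro")
    assert macro.dice == pytest.approx(0.5)
    assert micro.dice == pytest.approx(2 * 4 / (2 * 4 + 0 + 1))


def test_report_serializes_to_json_fractions(rng):
    m = (rng.random((1, 4, 4)) > 0.5).astype(float)
    r = segmentation_metrics(m, m)
    restored = MetricsReport.from_json(r.to_json())
    assert restored == r
    assert 0.0 <= restored.dice <= 1.0
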