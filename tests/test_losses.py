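"""Loss functions against independent brute-force oracles and closed forms."""

import math

import numpy as np
import pytest

from vesselkd.losses import (
    LossWeights,
    ce_loss,
    channel_softmax,
    combined_loss,
    combined_loss_grad,
    dice_loss,
    kd_loss,
)

# ---------------------------------------------------------------------------
# brute-force double-loop oracles, kept deliberately naive and separate from
# the vectorised implementations they check
# ---------------------------------------------------------------------------


def oracle_channel_softmax(logits, tau):
    h, w, c = logits.shape
    out = np.zeros_like(logits, dtype=float)
    for ch in range(c):
        denom = 0.0
        for i in range(h):
            for j in range(w):
                denom += math.exp(logits[i, j, ch] / tau)
        for i in range(h):
            for j in range(w):
                out[i, j, ch] = math.exp(logits[i, j, ch] / tau) / denom
    return out


def oracle_kd(teacher, student, tau):
    h, w, c = teacher.shape
    pt = oracle_channel_softmax(teacher, tau)
    ps = oracle_channel_softmax(student, tau)
    total = 0.0
    for ch in range(c):
        for i in range(h):
            for j in range(w):
                total += pt[i, j, ch] * math.log(pt[i, j, ch] / ps[i, j, ch])
    return tau**2 / c * total


def oracle_ce(gt, logits):
    h, w, c = logits.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            denom = sum(math.exp(logits[i, j, k]) for k in range(c))
            total -= math.log(math.exp(logits[i, j, gt[i, j]]) / denom)
    return total / (h * w)


def oracle_dice(gt, logits, eps=1e-6):
    h, w, c = logits.shape
    acc = 0.0
    for ch in range(c):
        inter = psum = gsum = 0.0
        for i in range(h):
            for j in range(w):
                denom = sum(math.exp(logits[i, j, k]) for k in range(c))
                p = math.exp(logits[i, j, ch]) / denom
                g = 1.0 if gt[i, j] == ch else 0.0
                inter += p * g
                psum += p
                gsum += g
        acc += (2 * inter + eps) / (psum + gsum + eps)
    return 1.0 - acc / c


def _random_case(rng, max_c=4, max_hw=8):
    h = int(rng.integers(1, max_hw + 1))
    w = int(rng.integers(1, max_hw + 1))
    c = int(rng.integers(2, max_c + 1))
    logits = rng.normal(scale=2.0, size=(h, w, c))
    gt = rng.integers(0, c, size=(h, w))
    return gt, logits


# ---------------------------------------------------------------------------
# worked examples (hand-derived values)
# ---------------------------------------------------------------------------


def test_channel_softmax_constant_logits_uniform():
    logits = np.full((4, 8, 3), 2.5)
    p = channel_softmax(logits, tau=3.0)
    assert np.allclose(p, 1.0 / 32)


def test_channel_softmax_two_pixel_example():
    logits = np.zeros((1, 2, 2))
    logits[0, 1, :] = math.log(3.0)
    p = channel_softmax(logits, tau=1.0)
    assert np.allclose(p[0, :, 0], [0.25, 0.75])
    assert np.allclose(p[0, :, 1], [0.25, 0.75])


def test_channel_softmax_high_temperature_limit():
    rng = np.random.default_rng(0)
    logits = rng.normal(size=(4, 4, 2))
    p = channel_softmax(logits, tau=1e6)
    assert np.allclose(p, 1.0 / 16, atol=1e-6)


def test_channel_softmax_shift_invariance(rng):
    logits = rng.normal(size=(5, 5, 3))
    shifted = logits + np.array([3.0, -1.0, 10.0])  # per-channel constants
    assert np.allclose(channel_softmax(logits, 2.0), channel_softmax(shifted, 2.0))


def test_kd_identical_logits_zero(rng):
    logits = rng.normal(size=(6, 6, 4))
    for tau in (0.5, 1.0, 4.0):
        assert kd_loss(logits, logits.copy(), tau) == pytest.approx(0.0, abs=1e-12)


def test_kd_two_pixel_worked_example():
    """KL([.25,.75] || [.5,.5]) = 0.25·ln(.5) + 0.75·ln(1.5) ≈ 0.13081."""
    teacher = np.zeros((1, 2, 2))
    teacher[0, 1, :] = math.log(3.0)
    student = np.zeros((1, 2, 2))
    expected = 0.25 * math.log(0.25 / 0.5) + 0.75 * math.log(0.75 / 0.5)
    # both channels carry the same distributions; τ²/C with τ=1, C=2 averages them
    assert kd_loss(teacher, student, tau=1.0) == pytest.approx(expected, abs=1e-9)


def test_ce_uniform_logits_log_c():
    gt = np.zeros((3, 3), dtype=int)
    assert ce_loss(gt, np.zeros((3, 3, 4))) == pytest.approx(math.log(4.0), abs=1e-12)


def test_ce_confident_correct_near_zero(rng):
    gt = rng.integers(0, 3, size=(5, 5))
    logits = np.full((5, 5, 3), -50.0)
    logits[np.arange(5)[:, None], np.arange(5)[None, :], gt] = 50.0
    assert ce_loss(gt, logits) < 1e-8
    assert dice_loss(gt, logits) < 1e-5


def test_dice_disjoint_prediction():
    """All-background prediction vs pure-foreground truth: foreground term → 1."""
    gt = np.ones((4, 4), dtype=int)
    logits = np.full((4, 4, 2), -30.0)
    logits[..., 0] = 30.0
    # class 0: p=1,g=0 → ~0; class 1: p=0,g=1 → ~0; loss = 1 - mean ≈ 1
    assert dice_loss(gt, logits) == pytest.approx(1.0, abs=1e-4)


# ---------------------------------------------------------------------------
# randomized oracle equivalence
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("case", range(40))
def test_losses_match_bruteforce_oracles(case):
    rng = np.random.default_rng(1000 + case)
    gt, logits = _random_case(rng)
    teacher = rng.normal(scale=2.0, size=logits.shape)
    tau = float(rng.uniform(0.5, 5.0))
    assert kd_loss(teacher, logits, tau) == pytest.approx(
        oracle_kd(teacher, logits, tau), abs=1e-10
    )
    assert ce_loss(gt, logits) == pytest.approx(oracle_ce(gt, logits), abs=1e-10)
    assert dice_loss(gt, logits) == pytest.approx(oracle_dice(gt, logits), abs=1e-10)


def test_kd_nonnegative_randomised():
    rng = np.random.default_rng(7)
    for _ in range(300):
        gt, student = _random_case(rng)
        teacher = rng.normal(scale=3.0, size=student.shape)
        assert kd_loss(teacher, student, float(rng.uniform(0.3, 6.0))) >= 0.0


def test_channel_softmax_normalisation_randomised():
    rng = np.random.default_rng(8)
    for _ in range(300):
        _, logits = _random_case(rng)
        p = channel_softmax(logits, float(rng.uniform(0.3, 6.0)))
        assert np.allclose(p.sum(axis=(0, 1)), 1.0, atol=1e-6)


def test_kd_support_masking(rng):
    """With a support mask, only supported pixels shape the distributions."""
    teacher = rng.normal(size=(4, 4, 3))
    student = rng.normal(size=(4, 4, 3))
    support = np.zeros((4, 4), dtype=np.uint8)
    support[:2] = 1
    v_masked = kd_loss(teacher, student, 2.0, support=support)
    v_sub = kd_loss(teacher[:2], student[:2], 2.0)
    assert v_masked == pytest.approx(v_sub, abs=1e-12)
    with pytest.raises(ValueError, match="empty"):
        kd_loss(teacher, student, 2.0, support=np.zeros((4, 4), dtype=np.uint8))


# ---------------------------------------------------------------------------
# combined objective
# ---------------------------------------------------------------------------


def test_combined_gamma_zero_ignores_teacher(rng):
    gt, logits = _random_case(rng)
    w = LossWeights(alpha=1.0, beta=1.0, gamma=0.0)
    bd = combined_loss(gt, logits, teacher_logits=None, weights=w)
    assert bd.total == pytest.approx(bd.ce + bd.dice, abs=1e-12)
    assert bd.kd == 0.0


def test_combined_requires_teacher_when_gamma_positive(rng):
    gt, logits = _random_case(rng)
    with pytest.raises(ValueError, match="teacher"):
        combined_loss(gt, logits, None, LossWeights(gamma=1.0, tau=2.0))


def test_combined_component_sum_and_linearity(rng):
    gt, student = _random_case(rng)
    teacher = rng.normal(size=student.shape)
    w = LossWeights(alpha=1.0, beta=1.0, gamma=3.0, tau=4.0)
    bd = combined_loss(gt, student, teacher, w)
    assert bd.total == pytest.approx(
        1.0 * oracle_ce(gt, student)
        + 1.0 * oracle_dice(gt, student)
        + 3.0 * oracle_kd(teacher, student, 4.0),
        abs=1e-10,
    )
    w2 = LossWeights(alpha=2.0, beta=0.5, gamma=6.0, tau=4.0)
    bd2 = combined_loss(gt, student, teacher, w2)
    assert bd2.total == pytest.approx(2 * bd.ce + 0.5 * bd.dice + 2 * (3.0 * bd.kd), abs=1e-10)


def test_combined_gradient_matches_central_differences(rng):
    gt = rng.integers(0, 3, size=(3, 4))
    student = rng.normal(size=(3, 4, 3))
    teacher = rng.normal(size=(3, 4, 3))
    support = np.ones((3, 4), dtype=np.uint8)
    support[0, 0] = 0
    w = LossWeights(alpha=1.0, beta=1.0, gamma=3.0, tau=4.0)
    _, grad = combined_loss_grad(gt, student, teacher, w, support)
    assert np.all(np.isfinite(grad))
    eps = 1e-6
    for pos in [(0, 0, 0), (1, 2, 1), (2, 3, 2), (0, 3, 1)]:
        plus, minus = student.copy(), student.copy()
        plus[pos] += eps
        minus[pos] -= eps
        num = (
            combined_loss(gt, plus, teacher, w, support).total
            - combined_loss(gt, minus, teacher, w, support).total
        ) / (2 * eps)
        assert grad[pos] == pytest.approx(num, abs=1e-7)


def test_nonfinite_logits_rejected():
    bad = np.zeros((2, 2, 2))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        channel_softmax(bad, 1.0)
    with pytest.raises(ValueError, match="non-finite"):
        ce_loss(np.zeros((2, 2), dtype=int), bad)


def test_invalid_weights_rejected():
    with pytest.raises(ValueError):
        LossWeights(tau=0.0)
    with pytest.raises(ValueError):
        LossWeights(alpha=-1.0)


def test_class_id_out_of_range_rejected(rng):
    logits = rng.normal(size=(2, 2, 3))
    gt = np.full((2, 2), 3)
    with pytest.raises(ValueError, match="classes"):
        ce_loss(gt, logits)
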