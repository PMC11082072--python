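"""Loss equations against hand-evaluated and brute-force loop oracles."""

import math

import numpy as np
import pytest

from pepclr import combined_loss, contrastive_loss, mixed_cross_entropy
from pepclr.losses import LossConfigError, LossWeights

RNG = np.random.default_rng(7)


def random_probs(n):
    p = RNG.uniform(0.05, 0.95, size=n)
    return np.column_stack([1 - p, p])


def unit_rows(n, d, rng):
    z = rng.normal(size=(n, d))
    return z / np.linalg.norm(z, axis=1, keepdims=True)


# -- cross-entropy ---------------------------------------------------------------

def naive_mixed_ce(labels, p1, p2, beta):
    total = 0.0
    for y, a, b in zip(labels, p1, p2):
        total += -(1 - beta) * math.log(a[y]) - beta * math.log(b[y])
    return total


def test_perfect_predictions_give_zero_loss():
    labels = np.array([1, 0, 1])
    perfect = np.array([[0, 1], [1, 0], [0, 1]], dtype=float)
    for beta in (0.0, 0.3, 1.0):
        assert mixed_cross_entropy(labels, perfect, perfect, beta).item() == \
            pytest.approx(0.0, abs=1e-10)


def test_beta_endpoints_select_single_head():
    labels = RNG.integers(0, 2, size=6)
    p1, p2 = random_probs(6), random_probs(6)
    head1_only = mixed_cross_entropy(labels, p1, p2, beta=0.0).item()
    head2_only = mixed_cross_entropy(labels, p1, p2, beta=1.0).item()
    assert head1_only == pytest.approx(naive_mixed_ce(labels, p1, p2, 0.0), abs=1e-9)
    assert head2_only == pytest.approx(naive_mixed_ce(labels, p1, p2, 1.0), abs=1e-9)
    # head-1 CE must not depend on head 2 at all
    assert mixed_cross_entropy(labels, p1, random_probs(6), 0.0).item() == \
        pytest.approx(head1_only, abs=1e-12)


def test_hand_evaluated_single_sample():
    # true class prob 0.5 in head 1, 0.25 in head 2, beta = 0.5
    labels = np.array([1])
    p1 = np.array([[0.5, 0.5]])
    p2 = np.array([[0.75, 0.25]])
    expected = 0.5 * (-math.log(0.5)) + 0.5 * (-math.log(0.25))
    assert mixed_cross_entropy(labels, p1, p2, 0.5).item() == \
        pytest.approx(expected, abs=1e-12)


def test_ce_is_affine_in_beta():
    labels = RNG.integers(0, 2, size=10)
    p1, p2 = random_probs(10), random_probs(10)
    at0 = mixed_cross_entropy(labels, p1, p2, 0.0).item()
    at1 = mixed_cross_entropy(labels, p1, p2, 1.0).item()
    for beta in (0.2, 0.5, 0.77):
        assert mixed_cross_entropy(labels, p1, p2, beta).item() == \
            pytest.approx((1 - beta) * at0 + beta * at1, abs=1e-9)


def test_ce_loop_oracle_agreement_and_mean_reduction():
    labels = RNG.integers(0, 2, size=8)
    p1, p2 = random_probs(8), random_probs(8)
    expected = naive_mixed_ce(labels, p1, p2, 0.4)
    assert mixed_cross_entropy(labels, p1, p2, 0.4).item() == \
        pytest.approx(expected, abs=1e-9)
    assert mixed_cross_entropy(labels, p1, p2, 0.4, reduction="mean").item() == \
        pytest.approx(expected / 8, abs=1e-9)


def test_ce_input_validation():
    with pytest.raises(ValueError, match="mismatch"):
        mixed_cross_entropy(np.array([1, 0]), random_probs(3), random_probs(2), 0.5)
    with pytest.raises(LossConfigError):
        mixed_cross_entropy(np.array([1]), random_probs(1), random_probs(1), 1.5)


# -- contrastive loss -------------------------------------------------------------

def naive_contrastive(z1, z2, tau, include_positive=False):
    n = z1.shape[0]
    total = 0.0
    for i in range(n):
        pos = math.exp(np.dot(z1[i], z2[i]) / tau)
        denom = 0.0
        for j in range(n):
            if j == i and not include_positive:
                continue
            denom += math.exp(np.dot(z1[i], z2[j]) / tau)
        total += -math.log(pos / denom)
    return total


def test_orthonormal_batch_of_two_hand_value():
    z = np.eye(2)
    # each term: -log(exp(1)/exp(0)) = -1
    assert contrastive_loss(z, z, tau=1.0).item() == pytest.approx(-2.0, abs=1e-9)


def test_loss_can_be_negative_unlike_infonce():
    z = np.eye(2)
    assert contrastive_loss(z, z, tau=1.0).item() < 0
    assert contrastive_loss(z, z, tau=1.0,
                            include_positive_in_denominator=True).item() > 0


@pytest.mark.parametrize("include_positive", [False, True])
@pytest.mark.parametrize("tau", [0.1, 0.5, 1.0])
def test_vectorized_matches_loop_oracle(tau, include_positive):
    rng = np.random.default_rng(13)
    z1, z2 = unit_rows(8, 16, rng), unit_rows(8, 16, rng)
    expected = naive_contrastive(z1, z2, tau, include_positive)
    got = contrastive_loss(z1, z2, tau,
                           include_positive_in_denominator=include_positive).item()
    assert got == pytest.approx(expected, abs=1e-6)


def test_symmetric_variant_averages_both_directions():
    rng = np.random.default_rng(14)
    z1, z2 = unit_rows(6, 8, rng), unit_rows(6, 8, rng)
    expected = 0.5 * (naive_contrastive(z1, z2, 0.2) + naive_contrastive(z2, z1, 0.2))
    assert contrastive_loss(z1, z2, 0.2, symmetric=True).item() == \
        pytest.approx(expected, abs=1e-6)


def test_permutation_invariance():
    rng = np.random.default_rng(15)
    z1, z2 = unit_rows(7, 8, rng), unit_rows(7, 8, rng)
    perm = rng.permutation(7)
    assert contrastive_loss(z1[perm], z2[perm], 0.3).item() == \
        pytest.approx(contrastive_loss(z1, z2, 0.3).item(), abs=1e-9)


def test_monotone_in_positive_similarity():
    """Raising z_{i,1}·z_{i,2} with all cross-pairs fixed lowers the loss.

    Construction: z_{i,1} = e_i and z_{i,2} = cosθ·e_i + sinθ·f_i with
    e_i ⊥ f_j for all i, j, so every cross similarity is exactly 0 while
    the positive similarity is cosθ.
    """
    n = 4
    d = 2 * n
    z1 = np.zeros((n, d))
    z1[np.arange(n), np.arange(n)] = 1.0
    losses = []
    for theta in (1.2, 0.8, 0.4, 0.0):  # cosθ increasing
        z2 = np.zeros((n, d))
        z2[np.arange(n), np.arange(n)] = math.cos(theta)
        z2[np.arange(n), n + np.arange(n)] = math.sin(theta)
        losses.append(contrastive_loss(z1, z2, 0.5).item())
    assert losses == sorted(losses, reverse=True)
    assert losses[0] > losses[-1]


def test_large_tau_limit():
    """As tau → ∞ every similarity flattens and the loss → Σ log(n-1)."""
    rng = np.random.default_rng(17)
    n = 9
    z1, z2 = unit_rows(n, 8, rng), unit_rows(n, 8, rng)
    value = contrastive_loss(z1, z2, tau=1e6).item()
    assert value == pytest.approx(n * math.log(n - 1), abs=1e-3)


def test_contrastive_input_validation():
    z = unit_rows(1, 4, np.random.default_rng(0))
    with pytest.raises(ValueError, match="batch"):
        contrastive_loss(z, z, 0.5)
    z = unit_rows(3, 4, np.random.default_rng(0))
    with pytest.raises(LossConfigError):
        contrastive_loss(z, z, tau=0.0)
    with pytest.raises(ValueError, match="shape"):
        contrastive_loss(z, z[:, :2], 0.5)


# -- combined loss ----------------------------------------------------------------

def test_combined_blend_and_endpoints():
    assert combined_loss(2.0, 4.0, 0.5).item() == pytest.approx(3.0)
    assert combined_loss(2.0, 4.0, 0.0).item() == 2.0
    assert combined_loss(2.0, 4.0, 1.0).item() == 4.0
    assert combined_loss(2.0, 4.0, 0.9).item() == \
        pytest.approx(0.1 * 2.0 + 0.9 * 4.0, abs=1e-15)
    with pytest.raises(LossConfigError):
        combined_loss(1.0, 1.0, 1.1)


def test_loss_weights_validation():
    LossWeights(alpha=0.0, beta=1.0, tau=0.05)
    with pytest.raises(LossConfigError):
        LossWeights(alpha=-0.1)
    with pytest.raises(LossConfigError):
        LossWeights(tau=0.0)
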