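"""Loss values against brute-force oracles, gradients against finite
differences, and the rank-consistency guarantees of the chained heads."""

import numpy as np
import pytest

from ordvert import losses as L
from ordvert.encodings import ordinal_target_profile, OrdinalLabel

from conftest import random_prob_vector
from oracles import oracle_cdw, oracle_ce, oracle_corn, oracle_ordl, oracle_orl


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------


def test_cross_entropy_examples():
    assert L.cross_entropy([0, 1, 0, 0], 1) == 0.0
    assert L.cross_entropy([0.2, 0.7, 0.1, 0.0], 1) == pytest.approx(
        -np.log(0.7), abs=1e-9
    )
    # clamped at the simplex corner: -log(eps)
    assert L.cross_entropy([1, 0, 0, 0], 3) == pytest.approx(-np.log(1e-12), rel=1e-9)


def test_ordinal_residual_loss_examples():
    # one-hot at the true class still pays for missing the decaying tail
    expected = -(np.log(1 / 3) + np.log(2 / 3))
    assert L.ordinal_residual_loss([1, 0, 0, 0], 0) == pytest.approx(expected, abs=1e-9)
    # uniform prediction, c=0: each term evaluated independently
    u = [0.25] * 4
    expected = -(
        np.log(0.25) + np.log(1 - 5 / 12) + np.log(1 - 1 / 12) + np.log(0.75)
    )
    assert L.ordinal_residual_loss(u, 0) == pytest.approx(expected, abs=1e-9)


def test_ordl_is_additive_and_reduces_to_ce():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(2, 9))
        p = random_prob_vector(rng, n)
        c = int(rng.integers(n))
        lam = float(rng.uniform(0, 3))
        combined = L.ordinal_residual_dual_loss(p, c, lam)
        assert combined == pytest.approx(
            L.cross_entropy(p, c) + lam * L.ordinal_residual_loss(p, c), abs=1e-12
        )
        # lam = 0 degenerates to plain CE, bit-identically
        assert L.ordinal_residual_dual_loss(p, c, 0.0) == L.cross_entropy(p, c)
    with pytest.raises(ValueError):
        L.ordinal_residual_dual_loss([0.5, 0.5], 0, -0.1)


def test_cdw_ce_examples():
    assert L.cdw_ce([0, 1, 0, 0], 1, 2.0) == 0.0
    p = [0.1, 0.6, 0.1, 0.2]
    assert L.cdw_ce(p, 1, 1.0) == pytest.approx(
        -(np.log(0.9) + np.log(0.9) + 2 * np.log(0.8)), abs=1e-9
    )
    a2 = L.cdw_ce(p, 1, 2.0)
    assert a2 == pytest.approx(-(np.log(0.9) + np.log(0.9) + 4 * np.log(0.8)), abs=1e-9)
    assert a2 > L.cdw_ce(p, 1, 1.0)  # stronger distance penalty


def test_signed_residual_variant_can_reward_underprediction():
    """The literal signed reading produces a negative contribution when a
    class is under-predicted; the default absolute form never does."""
    p = [1.0, 0.0, 0.0, 0.0]
    assert L.ordinal_residual_loss(p, 0, signed=True) < L.ordinal_residual_loss(p, 0)


# ---------------------------------------------------------------------------
# oracle equivalence en masse
# ---------------------------------------------------------------------------


def test_losses_match_bruteforce_oracles():
    rng = np.random.default_rng(42)
    for _ in range(400):
        n = int(rng.integers(2, 11))
        p = random_prob_vector(rng, n)
        c = int(rng.integers(n))
        lam = float(rng.uniform(0, 2))
        a = float(rng.uniform(0, 4))
        assert L.cross_entropy(p, c) == pytest.approx(oracle_ce(list(p), c), abs=1e-10)
        assert L.ordinal_residual_loss(p, c) == pytest.approx(
            oracle_orl(list(p), c), abs=1e-10
        )
        assert L.ordinal_residual_dual_loss(p, c, lam) == pytest.approx(
            oracle_ordl(list(p), c, lam), abs=1e-10
        )
        assert L.cdw_ce(p, c, a) == pytest.approx(oracle_cdw(list(p), c, a), abs=1e-10)


def test_corn_loss_matches_per_pair_enumeration():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(2, 8))
        b = int(rng.integers(1, 9))
        z = rng.normal(scale=2.0, size=(b, n - 1))
        labs = rng.integers(0, n, size=b)
        got = L.corn_loss(z, labs)
        assert got == pytest.approx(oracle_corn(z.tolist(), labs.tolist()), abs=1e-10)


def test_corn_subsets_and_degenerate_cases():
    sizes = [len(s) for s in L.corn_conditional_subsets([0, 1, 2, 3], 4)]
    assert sizes == [4, 3, 2]
    assert all(
        len(s) == 3 for s in L.corn_conditional_subsets([3, 3, 3], 4)
    )  # maximal labels: every subset full
    sizes = [len(s) for s in L.corn_conditional_subsets([0, 0, 0, 0, 0], 4)]
    assert sizes == [5, 0, 0]  # later tasks starve
    with pytest.raises(ValueError):
        L.corn_conditional_subsets([], 4)
    # single sample at the top rank, confident logits -> near-zero loss
    assert L.corn_loss(np.full((1, 3), 20.0), [3]) == pytest.approx(0.0, abs=1e-6)
    # c=0, N=4: only task 0 contributes
    z0 = 0.7
    expected = -np.log(1 - 1 / (1 + np.exp(-z0)))
    assert L.corn_loss(np.array([[z0, 5.0, -5.0]]), [0]) == pytest.approx(
        expected, abs=1e-10
    )


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("name", ["ce", "orl", "ordl", "cdw_ce"])
def test_softmax_loss_gradients_match_finite_differences(name):
    rng = np.random.default_rng(11)
    h = 1e-5
    for _ in range(25):
        n = int(rng.integers(2, 8))
        z = rng.normal(size=(2, n))
        labs = rng.integers(0, n, size=2)
        kw = dict(lam=float(rng.uniform(0.2, 2)), alpha=float(rng.uniform(0.5, 3)))
        _, grad = L.softmax_loss_and_grad(name, z, labs, **kw)
        for i in range(2):
            for j in range(n):
                zp, zm = z.copy(), z.copy()
                zp[i, j] += h
                zm[i, j] -= h
                num = (
                    L.softmax_loss_and_grad(name, zp, labs, **kw)[0]
                    - L.softmax_loss_and_grad(name, zm, labs, **kw)[0]
                ) / (2 * h)
                assert grad[i, j] == pytest.approx(num, rel=1e-4, abs=1e-7)


def test_corn_gradient_matches_finite_differences():
    rng = np.random.default_rng(12)
    h = 1e-5
    for _ in range(25):
        n = int(rng.integers(2, 7))
        z = rng.normal(scale=2, size=(3, n - 1))
        labs = rng.integers(0, n, size=3)
        _, grad = L.corn_loss_and_grad(z, labs)
        for i in range(3):
            for j in range(n - 1):
                zp, zm = z.copy(), z.copy()
                zp[i, j] += h
                zm[i, j] -= h
                num = (L.corn_loss(zp, labs) - L.corn_loss(zm, labs)) / (2 * h)
                assert grad[i, j] == pytest.approx(num, rel=1e-4, abs=1e-8)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------


def test_all_losses_non_negative():
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = int(rng.integers(2, 11))
        p = random_prob_vector(rng, n)
        c = int(rng.integers(n))
        assert L.cross_entropy(p, c) >= 0
        assert L.ordinal_residual_loss(p, c) >= 0
        assert L.ordinal_residual_dual_loss(p, c, rng.uniform(0, 2)) >= 0
        assert L.cdw_ce(p, c, rng.uniform(0, 4)) >= 0
        z = rng.normal(size=(3, n - 1))
        assert L.corn_loss(z, rng.integers(0, n, size=3)) >= 0


def test_orl_zero_exactly_at_matching_profile():
    # with N=2 the target profile is itself a distribution, so ORL can hit 0
    o = ordinal_target_profile(OrdinalLabel(1, 2))
    assert L.ordinal_residual_loss(o, 1) == 0.0


def test_cdw_monotone_in_negative_mass():
    """Moving probability mass from the true class to any negative class never
    decreases the distance-weighted loss."""
    rng = np.random.default_rng(6)
    for _ in range(50):
        n = int(rng.integers(3, 8))
        c = int(rng.integers(n))
        p = random_prob_vector(rng, n)
        p[c] += 1 - p.sum()  # exact renormalisation onto the true class
        if p[c] < 0.2:
            continue
        j = int(rng.choice([i for i in range(n) if i != c]))
        q = p.copy()
        q[j] += 0.1
        q[c] -= 0.1
        a = float(rng.uniform(0.5, 3))
        assert L.cdw_ce(q, c, a) >= L.cdw_ce(p, c, a) - 1e-12


def test_corn_chain_probs_consistency():
    rng = np.random.default_rng(7)
    np.testing.assert_allclose(L.corn_chain_probs([0.9, 0.8, 0.5]), [0.9, 0.72, 0.36])
    np.testing.assert_array_equal(L.corn_chain_probs([1.0, 1.0]), [1.0, 1.0])
    np.testing.assert_array_equal(L.corn_chain_probs([0.5, 0.0, 0.9])[1:], [0.0, 0.0])
    for _ in range(500):
        f = rng.uniform(size=int(rng.integers(1, 12)))
        q = L.corn_chain_probs(f)
        assert np.all(np.diff(q) <= 1e-15)


def test_coral_head_monotone_when_biases_sorted():
    np.testing.assert_allclose(
        L.coral_task_probs(0.0, [1.0, 0.0, -1.0]),
        [0.7310585786300049, 0.5, 0.2689414213699951],
        atol=1e-9,
    )
    np.testing.assert_array_equal(L.coral_task_probs(0.0, [0.0, 0.0, 0.0]), [0.5] * 3)
    rng = np.random.default_rng(8)
    for _ in range(100):
        b = -np.sort(rng.normal(size=int(rng.integers(2, 10))))  # descending
        g = float(rng.normal(scale=3))
        q = L.coral_task_probs(g, b)
        assert np.all(np.diff(q) <= 1e-15)


def test_softmax_stability_and_shift_invariance():
    np.testing.assert_allclose(L.probs_from_logits([0.0, 0, 0, 0]), [0.25] * 4)
    p = L.probs_from_logits([1000.0, 0.0, 0.0, 0.0])
    assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)
    z = np.array([0.3, -1.2, 2.0])
    np.testing.assert_allclose(
        L.probs_from_logits(z), L.probs_from_logits(z + 17.5), atol=1e-12
    )
    assert abs(L.probs_from_logits(z).sum() - 1) < 1e-9
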