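"""Entropy-threshold and time-based decision policies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rvt.decision import (
    DecisionPolicy,
    ReadoutSequence,
    cumulative_readout,
    decide,
    entropy,
    evaluate,
)

rng = np.random.default_rng(11)


def random_sequence(n_images=20, n_steps=5, n_classes=4, seed=0, sharpen=True):
    """Random readout sequences whose confidence tends to rise over time."""
    r = np.random.default_rng(seed)
    logits = r.normal(0, 1, (n_images, n_steps, n_classes))
    if sharpen:
        logits *= np.linspace(0.5, 3.0, n_steps)[None, :, None]
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return ReadoutSequence(probs=e / e.sum(axis=-1, keepdims=True))


# ------------------------------------------------------------ entropy

def test_entropy_reference_values():
    assert entropy(np.array([1.0, 0.0, 0.0])) == 0.0
    np.testing.assert_allclose(entropy(np.full(7, 1 / 7)), np.log(7), atol=1e-12)
    np.testing.assert_allclose(entropy(np.array([0.5, 0.5])), 0.6931, atol=1e-4)


def test_entropy_rejects_negative():
    with pytest.raises(ValueError, match="non-negative"):
        entropy(np.array([1.2, -0.2]))


# ------------------------------------------------- cumulative readout

def test_cumulative_readout_examples():
    d = np.array([0.7, 0.2, 0.1])
    seq = ReadoutSequence(probs=np.stack([d, d, d])[None])
    np.testing.assert_allclose(cumulative_readout(seq, 3)[0], d)
    seq2 = ReadoutSequence(probs=np.array([[[1.0, 0.0], [0.0, 1.0]]]))
    np.testing.assert_allclose(cumulative_readout(seq2, 2)[0], [0.5, 0.5])
    with pytest.raises(ValueError, match="t must be"):
        cumulative_readout(seq, 4)


def test_cumulative_equals_instantaneous_at_first_step():
    seq = random_sequence(seed=1)
    np.testing.assert_allclose(seq.cumulative()[:, 0], seq.probs[:, 0], atol=1e-12)
    np.testing.assert_allclose(seq.cumulative().sum(axis=-1), 1.0, atol=1e-12)


# -------------------------------------------------------------- decide

def test_threshold_at_max_entropy_stops_immediately():
    seq = random_sequence(seed=2)
    policy = DecisionPolicy(entropy_threshold=np.log(seq.n_classes))
    assert np.all(decide(seq, policy).reaction_time == 1)


def test_unreachable_threshold_falls_back_to_final_step():
    seq = ReadoutSequence(probs=np.full((3, 4, 5), 0.2))  # uniform forever
    dec = decide(seq, DecisionPolicy(entropy_threshold=1e-6))
    assert np.all(dec.reaction_time == seq.n_steps)


def _dist_with_entropy(h, tol=1e-12):
    lo, hi = 0.5, 1 - 1e-12
    for _ in range(200):
        mid = (lo + hi) / 2
        if -(mid * np.log(mid) + (1 - mid) * np.log(1 - mid)) > h:
            lo = mid
        else:
            hi = mid
    return [mid, 1 - mid]


def test_threshold_scan_oracle_three_step_binary():
    seq = ReadoutSequence(probs=np.array([[_dist_with_entropy(h) for h in (0.69, 0.5, 0.1)]]))
    policy = DecisionPolicy(readout_mode="instantaneous", entropy_threshold=0.45)
    dec = decide(seq, policy)
    # linear-scan oracle: first step with entropy <= 0.45 is step 3
    assert dec.reaction_time[0] == 3
    assert dec.entropy_at_decision[0] <= 0.45


def test_decide_is_pure():
    seq = random_sequence(seed=3)
    policy = DecisionPolicy(entropy_threshold=0.8)
    d1, d2 = decide(seq, policy), decide(seq, policy)
    np.testing.assert_array_equal(d1.reaction_time, d2.reaction_time)
    np.testing.assert_array_equal(d1.predicted_class, d2.predicted_class)


def test_policy_validation():
    with pytest.raises(ValueError):
        DecisionPolicy(mode="threshold_based")
    with pytest.raises(ValueError):
        DecisionPolicy(mode="time_based")
    with pytest.raises(ValueError):
        DecisionPolicy(mode="time_based", fixed_time=2, entropy_threshold=0.5)


# ------------------------------------------------------------ evaluate

def test_threshold_extremes_match_time_based_policies():
    seq = random_sequence(n_images=50, seed=4)
    labels = rng.integers(0, seq.n_classes, 50)
    top = evaluate(seq, labels, DecisionPolicy(entropy_threshold=np.log(seq.n_classes)))
    t1 = evaluate(seq, labels, DecisionPolicy(mode="time_based", fixed_time=1))
    assert top == t1
    bottom = evaluate(seq, labels, DecisionPolicy(entropy_threshold=0.0))
    tT = evaluate(seq, labels, DecisionPolicy(mode="time_based", fixed_time=seq.n_steps))
    assert bottom == tT


def test_oracle_constant_sequences_score_one():
    labels = np.arange(4)
    probs = np.zeros((4, 3, 4))
    probs[np.arange(4), :, labels] = 1.0
    seq = ReadoutSequence(probs=probs)
    for policy in (DecisionPolicy(entropy_threshold=0.5),
                   DecisionPolicy(mode="time_based", fixed_time=2),
                   DecisionPolicy(readout_mode="instantaneous", entropy_threshold=0.0)):
        assert evaluate(seq, labels, policy) == 1.0


def test_evaluate_length_mismatch():
    with pytest.raises(ValueError, match="lengths"):
        evaluate(random_sequence(), np.zeros(3), DecisionPolicy(entropy_threshold=1.0))


# ----------------------------------------------------------- properties

@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000),
       theta=st.floats(0.0, 1.5), delta=st.floats(0.0, 1.0))
def test_reaction_time_monotone_in_threshold(seed, theta, delta):
    """theta1 <= theta2 implies per-image RT(theta1) >= RT(theta2)."""
    seq = random_sequence(n_images=10, seed=seed)
    lo = decide(seq, DecisionPolicy(entropy_threshold=theta))
    hi = decide(seq, DecisionPolicy(entropy_threshold=theta + delta))
    assert np.all(lo.reaction_time >= hi.reaction_time)
    assert lo.cost_at_decision.mean() >= hi.cost_at_decision.mean()
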