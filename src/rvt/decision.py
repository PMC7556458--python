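"""Anytime decision policies over per-time-step readout distributions.

A recurrent classifier emits one probability distribution over classes per
time step.  A decision policy turns that sequence into a single prediction
and a reaction time: either at a fixed time step (time-based) or at the first
step where the readout's Shannon entropy falls to or below a confidence
threshold theta (threshold-based), reading either the instantaneous
distribution or the cumulative readout (the running mean of distributions,
which aggregates evidence across time).

Entropy is measured in nats throughout (divide by ln 2 for bits).  The
threshold comparison is inclusive, so theta = ln(n_classes) always stops at
the first step.  If the threshold is never reached the final step is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np


@dataclass
class ReadoutSequence:
    """Per-time-step class probabilities for a batch of images.

    ``probs`` has shape (n_images, n_steps, n_classes); every row is a
    probability distribution.  ``site_costs`` gives the cumulative
    floating-point operations spent up to each readout and must be strictly
    increasing.
    """

    probs: np.ndarray
    site_costs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim == 2:  # single image convenience
            self.probs = self.probs[None]
        if self.probs.ndim != 3:
            raise ValueError("probs must be (n_images, n_steps, n_classes)")
        sums = self.probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each readout row must sum to 1 within 1e-6")
        if self.site_costs is None:
            self.site_costs = np.arange(1, self.n_steps + 1, dtype=float)
        else:
            self.site_costs = np.asarray(self.site_costs, dtype=float)
            if self.site_costs.shape != (self.n_steps,):
                raise ValueError("site_costs must have one entry per step")
            if np.any(np.diff(self.site_costs) <= 0):
                raise ValueError("site_costs must be strictly increasing")

    @property
    def n_images(self) -> int:
        return self.probs.shape[0]

    @property
    def n_steps(self) -> int:
        return self.probs.shape[1]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[2]

    def cumulative(self) -> np.ndarray:
        """Cumulative readouts at every step, same shape as ``probs``."""
        return np.cumsum(self.probs, axis=1) / np.arange(
            1, self.n_steps + 1, dtype=float
        )[None, :, None]


@dataclass(frozen=True)
class DecisionPolicy:
    """How and when a prediction is triggered."""

    mode: Literal["time_based", "threshold_based"] = "threshold_based"
    readout_mode: Literal["instantaneous", "cumulative"] = "cumulative"
    entropy_threshold: float | None = None
    fixed_time: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "threshold_based":
            if self.entropy_threshold is None or self.entropy_threshold < 0:
                raise ValueError("threshold_based mode needs entropy_threshold >= 0")
            if self.fixed_time is not None:
                raise ValueError("fixed_time is not valid in threshold_based mode")
        elif self.mode == "time_based":
            if self.fixed_time is None or self.fixed_time < 1:
                raise ValueError("time_based mode needs fixed_time >= 1")
            if self.entropy_threshold is not None:
                raise ValueError("entropy_threshold is not valid in time_based mode")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Decisions:
    """Vector outcome of applying one policy to a batch of images."""

    predicted_class: np.ndarray
    reaction_time: np.ndarray  # 1-based step index
    entropy_at_decision: np.ndarray  # nats
    cost_at_decision: np.ndarray


def entropy(dist: np.ndarray) -> np.ndarray:
    """Shannon entropy in nats along the last axis; 0*log(0) := 0."""
    p = np.asarray(dist, dtype=float)
    if np.any(p < -1e-12):
        raise ValueError("probabilities must be non-negative")
    p = np.clip(p, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=-1)


def cumulative_readout(seq: ReadoutSequence, t: int) -> np.ndarray:
    """Arithmetic mean of the per-step distributions for steps 1..t."""
    if not 1 <= t <= seq.n_steps:
        raise ValueError(f"t must be in 1..{seq.n_steps}, got {t}")
    return seq.probs[:, :t].mean(axis=1)


def _policy_readouts(seq: ReadoutSequence, policy: DecisionPolicy) -> np.ndarray:
    if policy.readout_mode == "cumulative":
        return seq.cumulative()
    return seq.probs


def decide(seq: ReadoutSequence, policy: DecisionPolicy) -> Decisions:
    """Apply a decision policy to every image in the sequence.

    Threshold mode stops at the first step whose readout entropy is <= theta
    (the final step if the threshold is never reached); argmax ties break
    toward the lowest class index (numpy argmax convention).
    """
    readouts = _policy_readouts(seq, policy)
    ent = entropy(readouts)  # (n_images, n_steps)
    if policy.mode == "time_based":
        rt = np.full(seq.n_images, policy.fixed_time, dtype=int)
        if policy.fixed_time > seq.n_steps:
            raise ValueError("fixed_time exceeds the number of steps")
    else:
        reached = ent <= policy.entropy_threshold
        rt = np.where(reached.any(axis=1), reached.argmax(axis=1), seq.n_steps - 1) + 1
    sel = rt - 1
    rows = np.arange(seq.n_images)
    chosen = readouts[rows, sel]
    return Decisions(
        predicted_class=chosen.argmax(axis=1),
        reaction_time=rt,
        entropy_at_decision=ent[rows, sel],
        cost_at_decision=seq.site_costs[sel],
    )


def evaluate(seq: ReadoutSequence, labels: Sequence[int], policy: DecisionPolicy) -> float:
    """Top-1 proportion correct under the policy."""
    labels = np.asarray(labels)
    if labels.shape[0] != seq.n_images:
        raise ValueError("labels and sequences have different lengths")
    dec = decide(seq, policy)
    return float(np.mean(dec.predicted_class == labels))
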