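"""Warmup scheduling of data-augmentation probability.

Rather than warming up the learning rate, training warms up *augmentation*:
with ``N = current_epoch * 5 / total_epochs``, the warmup factor is
``P = min(N, 1)``. Every augmentation's base probability is multiplied by
``P``, so no augmentation fires in epoch 0, the full default pipeline is
active from one-fifth of training onwards, and early training sees the
unperturbed data distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ScheduleState:
    """Position within training; epochs are 0-based."""

    current_epoch: int
    total_epochs: int

    def __post_init__(self):
        if self.total_epochs <= 0:
            raise ValueError("total_epochs must be >= 1")
        if not 0 <= self.current_epoch <= self.total_epochs:
            raise ValueError(
                f"current_epoch {self.current_epoch} outside [0, {self.total_epochs}]")


@dataclass(frozen=True)
class AugmentationPlan:
    """Per-epoch effective augmentation probabilities."""

    warmup_factor: float
    base_probabilities: dict
    effective_probabilities: dict = field(default=None)

    def __post_init__(self):
        if not 0.0 <= self.warmup_factor <= 1.0:
            raise ValueError(f"warmup factor {self.warmup_factor} outside [0,1]")
        for name, p in self.base_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"base probability {name}={p} outside [0,1]")
        if self.effective_probabilities is None:
            object.__setattr__(self, "effective_probabilities", {
                k: self.warmup_factor * v
                for k, v in self.base_probabilities.items()})


def warmup_probability(state: ScheduleState) -> float:
    """Warmup factor P in [0,1]; reaches exactly 1 at one-fifth of training."""
    n = state.current_epoch * 5.0 / state.total_epochs
    return 1.0 if n >= 1.0 else n


def effective_plan(state: ScheduleState, base: dict) -> AugmentationPlan:
    """Scale every base probability by the epoch's warmup factor."""
    return AugmentationPlan(warmup_factor=warmup_probability(state),
                            base_probabilities=dict(base))
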