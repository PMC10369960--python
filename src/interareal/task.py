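"""Checkerboard decision task: conditions, epochs, and input/target time series.

A trial presents two colored targets (one left, one right; one red, one green,
assigned at random) followed by a red/green checkerboard whose dominant color
the agent must report by "reaching" to the matching target.  The color evidence
is summarized by the signed color coherence (R - G) / (R + G); the mapping from
color decision to direction decision is decoupled by the random target
configuration.

Trials unfold in four epochs on a discrete simulation grid (``dt`` ms):

1. Center Hold  — all inputs zero; duration ~ Normal(200, 50^2) ms, truncated.
2. Targets      — channels 1-2 carry the left/right target colors, noiseless;
                  duration ~ Uniform[600, 1000] ms.
3. Decision     — channels 3-4 additionally carry the signed red and green
                  coherences plus i.i.d. Gaussian noise (SD 0.1); 1500 ms.
4. Stimulus Off — all inputs return to zero.

The desired output is a pair of decision variables (left, right): zero outside
the Decision epoch, and a unit step on the correct side during it.  The loss
mask excludes the first 200 ms of the Decision epoch so a non-instantaneous
rise of the decision variable is not penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "TrialCondition",
    "TrialBatch",
    "signed_coherence",
    "default_coherence_levels",
    "sample_conditions",
    "sample_training_conditions",
    "generate_trial",
    "generate_batch",
    "save_batch",
    "load_batch",
]

# input channel layout
CH_LEFT_TARGET = 0   # -1 red, +1 green
CH_RIGHT_TARGET = 1  # -1 red, +1 green
CH_RED_COH = 2       # signed red coherence, (R-G)/(R+G)
CH_GREEN_COH = 3     # signed green coherence, (G-R)/(R+G)

# output channel layout
CH_LEFT_DV = 0
CH_RIGHT_DV = 1

TARGET_CONFIGS = ("left_red", "left_green")


def default_coherence_levels() -> tuple[float, ...]:
    """The 14 signed coherence levels, symmetric about zero."""
    mags = (0.05, 0.15, 0.30, 0.45, 0.60, 0.75, 0.90)
    return tuple(sorted([-m for m in mags] + list(mags)))


@dataclass(frozen=True)
class TaskConfig:
    """Task timing, coherence set, and noise parameters.

    Durations are in milliseconds and are rounded to the nearest whole number
    of ``dt`` steps when a trial is laid out.
    """

    dt: float = 10.0
    center_hold_mean: float = 200.0
    center_hold_sd: float = 50.0
    targets_min: float = 600.0
    targets_max: float = 1000.0
    decision_len: float = 1500.0
    stim_off_len: float = 300.0
    coherence_levels: tuple[float, ...] = field(default_factory=default_coherence_levels)
    input_noise_sd: float = 0.1
    catch_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        levels = tuple(self.coherence_levels)
        object.__setattr__(self, "coherence_levels", levels)
        if len(levels) != len(set(levels)):
            raise ValueError("coherence levels must be distinct")
        if any(v == 0 for v in levels):
            raise ValueError("coherence levels must be nonzero")
        if any(abs(v) >= 1 for v in levels):
            raise ValueError("coherence levels must lie in (-1, 1)")
        if set(levels) != {-v for v in levels}:
            raise ValueError("coherence levels must be symmetric about 0")
        for name in ("dt", "center_hold_mean", "targets_min",
                     "targets_max", "decision_len", "stim_off_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.center_hold_sd < 0:
            raise ValueError("center_hold_sd must be nonnegative")
        if self.targets_max < self.targets_min:
            raise ValueError("targets_max must be >= targets_min")
        if self.input_noise_sd < 0:
            raise ValueError("input_noise_sd must be nonnegative")
        if not 0 <= self.catch_fraction < 1:
            raise ValueError("catch_fraction must be in [0, 1)")

    @property
    def n_conditions(self) -> int:
        return len(self.coherence_levels) * len(TARGET_CONFIGS)

    def with_(self, **kwargs) -> "TaskConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrialCondition:
    """A single trial's condition labels.

    ``correct_color`` is red iff the signed coherence is positive;
    ``correct_direction`` is the side whose target matches the correct color.
    """

    signed_coherence: float
    target_config: Literal["left_red", "left_green"]
    is_catch: bool = False
    catch_kind: Literal["no_input", "targets_only", "none"] = "none"

    def __post_init__(self) -> None:
        if not -1 <= self.signed_coherence <= 1:
            raise ValueError("signed coherence must be in [-1, 1]")
        if self.target_config not in TARGET_CONFIGS:
            raise ValueError(f"unknown target config {self.target_config!r}")
        if self.is_catch != (self.catch_kind != "none"):
            raise ValueError("catch_kind must be set iff is_catch")
        if not self.is_catch and self.signed_coherence == 0:
            raise ValueError("non-catch trials require nonzero signed coherence")

    @property
    def correct_color(self) -> str:
        return "red" if self.signed_coherence > 0 else "green"

    @property
    def correct_direction(self) -> str:
        left_color = "red" if self.target_config == "left_red" else "green"
        return "left" if left_color == self.correct_color else "right"


@dataclass
class TrialBatch:
    """A batch of trials on a common (padded) time grid.

    Attributes
    ----------
    inputs : (trials, time, 4) float array
    z_des : (trials, time, 2) desired decision variables in {0, 1}
    loss_mask : (trials, time) bool — time points entering the output loss
    epoch_bounds : (trials, 5) int — start steps of the four epochs followed
        by the per-trial length; padding steps beyond the length carry zero
        inputs and a false loss mask
    conditions : per-trial condition labels
    dt : step in ms
    """

    inputs: np.ndarray
    z_des: np.ndarray
    loss_mask: np.ndarray
    epoch_bounds: np.ndarray
    conditions: list[TrialCondition]
    dt: float

    @property
    def n_trials(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_steps(self) -> int:
        return self.inputs.shape[1]

    @property
    def decision_onset(self) -> np.ndarray:
        """Checkerboard-onset step per trial."""
        return self.epoch_bounds[:, 2]

    @property
    def decision_end(self) -> np.ndarray:
        """Stimulus-Off onset step per trial (end of the Decision epoch)."""
        return self.epoch_bounds[:, 3]


def signed_coherence(n_red: int, n_green: int) -> float:
    """Signed color coherence (R - G) / (R + G) of a checkerboard."""
    total = n_red + n_green
    if total <= 0:
        raise ValueError("checkerboard must contain at least one square")
    return (n_red - n_green) / total


def sample_conditions(
    n_per_condition: int,
    config: TaskConfig,
    rng: np.random.Generator | None = None,
) -> list[TrialCondition]:
    """A balanced, catch-free condition set: every (coherence, configuration)
    cell appears exactly ``n_per_condition`` times (order shuffled if an rng
    is given).  This is the validation/test protocol; catch trials occur only
    in training streams."""
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    conds = [
        TrialCondition(signed_coherence=coh, target_config=cfg)
        for coh in config.coherence_levels
        for cfg in TARGET_CONFIGS
        for _ in range(n_per_condition)
    ]
    if rng is not None:
        order = rng.permutation(len(conds))
        conds = [conds[i] for i in order]
    return conds


def sample_training_conditions(
    n_trials: int,
    config: TaskConfig,
    rng: np.random.Generator,
) -> list[TrialCondition]:
    """A training stream: conditions drawn uniformly at random, with catch
    trials at rate ``catch_fraction`` split evenly between the no-input and
    targets-only kinds."""
    conds: list[TrialCondition] = []
    for _ in range(n_trials):
        coh = float(rng.choice(config.coherence_levels))
        cfg = TARGET_CONFIGS[int(rng.integers(2))]
        if rng.random() < config.catch_fraction:
            kind = "no_input" if rng.random() < 0.5 else "targets_only"
            conds.append(TrialCondition(coh, cfg, is_catch=True, catch_kind=kind))
        else:
            conds.append(TrialCondition(coh, cfg))
    return conds


def _epoch_steps(config: TaskConfig, rng: np.random.Generator) -> tuple[int, int, int, int]:
    dt = config.dt
    hold_ms = rng.normal(config.center_hold_mean, config.center_hold_sd)
    hold = max(1, int(round(hold_ms / dt)))
    targets = max(1, int(round(rng.uniform(config.targets_min, config.targets_max) / dt)))
    decision = max(1, int(round(config.decision_len / dt)))
    stim_off = max(1, int(round(config.stim_off_len / dt)))
    return hold, targets, decision, stim_off


def generate_trial(
    cond: TrialCondition,
    config: TaskConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Lay out one trial.

    Returns ``(inputs, z_des, loss_mask, bounds)`` where ``inputs`` is
    (T, 4), ``z_des`` is (T, 2), ``loss_mask`` is (T,) bool and ``bounds``
    holds the four epoch start steps plus the trial length.
    """
    hold, targets, decision, stim_off = _epoch_steps(config, rng)
    t_targets = hold
    t_decision = hold + targets
    t_off = hold + targets + decision
    T = t_off + stim_off

    u = np.zeros((T, 4))
    z_des = np.zeros((T, 2))
    mask = np.ones(T, dtype=bool)

    left_color = +1.0 if cond.target_config == "left_green" else -1.0

    if cond.catch_kind != "no_input":
        u[t_targets:t_off, CH_LEFT_TARGET] = left_color
        u[t_targets:t_off, CH_RIGHT_TARGET] = -left_color

    if not cond.is_catch:
        u[t_decision:t_off, CH_RED_COH] = cond.signed_coherence
        u[t_decision:t_off, CH_GREEN_COH] = -cond.signed_coherence
        if config.input_noise_sd > 0:
            noise = rng.normal(0.0, config.input_noise_sd,
                               size=(t_off - t_decision, 2))
            u[t_decision:t_off, CH_RED_COH:] += noise
        side = CH_LEFT_DV if cond.correct_direction == "left" else CH_RIGHT_DV
        z_des[t_decision:t_off, side] = 1.0
        # grace period: no penalty while the DV steps up
        grace = int(round(200.0 / config.dt))
        mask[t_decision:min(t_decision + grace, T)] = False

    bounds = np.array([0, t_targets, t_decision, t_off, T], dtype=np.int64)
    return u, z_des, mask, bounds


def generate_batch(
    conditions: Sequence[TrialCondition],
    config: TaskConfig,
    rng: np.random.Generator,
) -> TrialBatch:
    """Generate and zero-pad a batch of trials onto a common time grid."""
    trials = [generate_trial(c, config, rng) for c in conditions]
    T = max(u.shape[0] for u, *_ in trials)
    B = len(trials)
    inputs = np.zeros((B, T, 4))
    z_des = np.zeros((B, T, 2))
    mask = np.zeros((B, T), dtype=bool)
    bounds = np.zeros((B, 5), dtype=np.int64)
    for i, (u, z, m, b) in enumerate(trials):
        n = u.shape[0]
        inputs[i, :n] = u
        z_des[i, :n] = z
        mask[i, :n] = m
        bounds[i] = b
    return TrialBatch(inputs, z_des, mask, bounds, list(conditions), config.dt)


def save_batch(path, batch: TrialBatch, seed: int | None = None) -> None:
    """Persist a batch as an NPZ container with named datasets."""
    labels = np.array(
        [(c.signed_coherence, c.target_config, int(c.is_catch), c.catch_kind)
         for c in batch.conditions],
        dtype=[("signed_coherence", "f8"), ("target_config", "U10"),
               ("is_catch", "i4"), ("catch_kind", "U12")],
    )
    np.savez(
        path,
        inputs=batch.inputs,
        z_des=batch.z_des,
        mask=batch.loss_mask,
        epoch_bounds=batch.epoch_bounds,
        labels=labels,
        dt=np.array(batch.dt),
        seed=np.array(-1 if seed is None else seed),
    )


def load_batch(path) -> TrialBatch:
    with np.load(path, allow_pickle=False) as f:
        labels = f["labels"]
        conds = [
            TrialCondition(
                float(row["signed_coherence"]), str(row["target_config"]),
                bool(row["is_catch"]), str(row["catch_kind"]),
            )
            for row in labels
        ]
        return TrialBatch(
            f["inputs"], f["z_des"], f["mask"].astype(bool),
            f["epoch_bounds"], conds, float(f["dt"]),
        )
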