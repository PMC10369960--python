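"""Backpropagation-through-time training of the multi-area RNN.

The objective is a masked mean-squared error on the decision variables plus
Frobenius-norm penalties on the input, recurrent and output weights, an
optional rate penalty, and a vanishing-gradient regularizer that penalizes
shrinkage of the backpropagated error norm between consecutive time steps
(the norm-ratio penalty of Pascanu et al., differentiated under the standard
first-order approximation that treats the incoming backpropagated error as
constant).  Optimization is Adam with global-norm gradient clipping;
after every step the parameters are projected back onto the connectivity-mask
and Dale-sign constraint set.

Training stops when, on a balanced validation set evaluated 500 ms before
checkerboard offset, the correct decision variable both exceeds the other and
the 0.6 threshold on at least 65% of leftward AND 65% of rightward trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import ArchitectureConfig, NetworkParams, build_connectivity, simulate
from .task import (
    CH_LEFT_DV,
    CH_RIGHT_DV,
    TaskConfig,
    TrialBatch,
    generate_batch,
    sample_conditions,
    sample_training_conditions,
)

__all__ = [
    "LossConfig",
    "ValidationPolicy",
    "mse_loss",
    "full_loss",
    "forward_backward",
    "validate",
    "train",
    "TrainResult",
]


@dataclass(frozen=True)
class LossConfig:
    """Loss coefficients and optimizer settings."""

    lambda_in: float = 1.0
    lambda_rec: float = 1.0
    lambda_out: float = 1.0
    lambda_r: float = 0.0
    lambda_omega: float = 2.0
    grad_clip_norm: float = 1.0
    learning_rate: float = 5e-5

    def __post_init__(self) -> None:
        for name in ("lambda_in", "lambda_rec", "lambda_out", "lambda_r", "lambda_omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.grad_clip_norm <= 0 or self.learning_rate <= 0:
            raise ValueError("grad_clip_norm and learning_rate must be positive")

    def with_(self, **kwargs) -> "LossConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ValidationPolicy:
    """When and how training success is judged."""

    interval_epochs: int = 200
    n_val_trials: int = 2800
    dv_threshold: float = 0.6
    eval_before_end_ms: float = 500.0
    success_fraction: float = 0.65

    def __post_init__(self) -> None:
        if not 0.5 < self.success_fraction <= 1:
            raise ValueError("success_fraction must lie in (0.5, 1]")

    def with_(self, **kwargs) -> "ValidationPolicy":
        return replace(self, **kwargs)


def mse_loss(z: np.ndarray, z_des: np.ndarray, mask: np.ndarray) -> float:
    """Masked output loss: mean over masked (trial, time) points of the
    squared Euclidean error of the 2-vector output."""
    n = int(mask.sum())
    if n == 0:
        raise ValueError("loss mask selects no time points")
    err = ((z - z_des) ** 2).sum(axis=-1)
    return float((err * mask).sum() / n)


def _l2_terms(params: NetworkParams, cfg: LossConfig) -> float:
    N = params.arch.n_units
    n_in = params.W_in.shape[1]
    n_out = params.W_out.shape[0]
    return float(
        cfg.lambda_in * (params.W_in ** 2).sum() / (N * n_in)
        + cfg.lambda_rec * (params.W_rec ** 2).sum() / (N * N)
        + cfg.lambda_out * (params.W_out ** 2).sum() / (N * n_out)
    )


def full_loss(
    params: NetworkParams,
    rates: np.ndarray,
    z: np.ndarray,
    z_des: np.ndarray,
    mask: np.ndarray,
    cfg: LossConfig,
    omega: float = 0.0,
) -> float:
    """Composite training loss.

    ``omega`` is the value of the vanishing-gradient penalty, which is only
    available from a backward pass; it defaults to zero for forward-only
    evaluation.
    """
    loss = mse_loss(z, z_des, mask) + _l2_terms(params, cfg)
    if cfg.lambda_r > 0:
        B, T = rates.shape[:2]
        loss += cfg.lambda_r * (rates ** 2).sum() / (B * T)
    return loss + cfg.lambda_omega * omega


def forward_backward(
    params: NetworkParams,
    batch: TrialBatch,
    cfg: LossConfig,
    rng: np.random.Generator | None,
    rec_noise_sd: float | None = None,
    dtype=np.float32,
) -> tuple[dict, dict]:
    """One noisy forward pass and full BPTT backward pass on a batch.

    Returns ``(loss_terms, grads)`` where grads holds dW_in, dW_rec, dW_out,
    db_rec (already masked to the constraint pattern).
    """
    arch = params.arch
    alpha = arch.alpha
    sd = arch.rec_noise_sd if rec_noise_sd is None else rec_noise_sd
    if arch.noise_scaling == "sqrt2_alpha":
        step_sd = alpha * np.sqrt(2.0 / alpha) * sd
    else:
        step_sd = sd
    if step_sd > 0 and rng is None:
        raise ValueError("an rng is required when noise is enabled")

    B, T, _ = batch.inputs.shape
    N = arch.n_units
    W_rec = params.W_rec.astype(dtype)
    W_in = params.W_in.astype(dtype)
    W_out = params.W_out.astype(dtype)
    b = params.b_rec.astype(dtype)
    u = batch.inputs.astype(dtype)
    z_des = batch.z_des.astype(dtype)
    mask = batch.loss_mask

    # ---- forward, storing rates and the relu gate
    rs = np.empty((B, T, N), dtype=dtype)
    fps = np.empty((B, T, N), dtype=dtype)
    drive = u @ W_in.T + b
    if step_sd > 0:
        noise = rng.standard_normal((T, B, N)).astype(dtype) * dtype(step_sd)
    x = np.zeros((B, N), dtype=dtype)
    for t in range(T):
        np.maximum(x, 0.0, out=rs[:, t])
        fps[:, t] = x > 0
        r = rs[:, t]
        x = (1.0 - alpha) * x + alpha * (r @ W_rec.T + drive[:, t])
        if step_sd > 0:
            x += noise[t]
    z = rs.reshape(B * T, N) @ W_out.T
    z = z.reshape(B, T, 2)

    n_masked = int(mask.sum())
    err = (z - z_des) * mask[:, :, None]
    l_mse = float((err.astype(np.float64) ** 2).sum() / n_masked)
    dz = (2.0 / n_masked) * err  # (B, T, 2)

    rate_coeff = dtype(2.0 * cfg.lambda_r / (B * T)) if cfg.lambda_r > 0 else None
    l_rate = cfg.lambda_r * float((rs.astype(np.float64) ** 2).sum()) / (B * T)

    # ---- backward: per-step error recursion, then batched weight accumulation
    deltas = np.zeros((B, T, N), dtype=dtype)       # dL/dx_t
    omega_w = np.zeros((B, T, N), dtype=dtype)      # f'(x_t) * dOmega_t/dh_t
    direct = (dz.reshape(B * T, 2) @ W_out).reshape(B, T, N)
    if rate_coeff is not None:
        direct = direct + rate_coeff * rs
    omega_sum = 0.0
    use_omega = cfg.lambda_omega > 0
    eps = 1e-12
    delta_next = np.zeros((B, N), dtype=dtype)
    for t in range(T - 1, -1, -1):
        fp = fps[:, t]
        # error propagated through the transition x_{t+1}(x_t)
        h = (1.0 - alpha) * delta_next + alpha * fp * (delta_next @ W_rec)
        if use_omega and t < T - 1:
            gn = np.linalg.norm(delta_next, axis=1).astype(np.float64)
            hn = np.linalg.norm(h, axis=1).astype(np.float64)
            valid = gn > eps
            if valid.any():
                ratio = np.where(valid, hn / np.maximum(gn, eps), 1.0)
                omega_sum += float(((ratio - 1.0) ** 2 * valid).sum())
                coef = np.where(
                    valid,
                    2.0 * (ratio - 1.0) / (np.maximum(hn, eps) * np.maximum(gn, eps)),
                    0.0,
                ).astype(dtype)
                omega_w[:, t] = fp * (coef[:, None] * h)
        delta_next = fp * direct[:, t] + h
        deltas[:, t] = delta_next

    omega = omega_sum / (B * T)
    omega_coeff = cfg.lambda_omega / (B * T)

    # transition gradients pair delta_{t+1} with r_t / u_t
    d_next = deltas[:, 1:].reshape(B * (T - 1), N)
    r_prev = rs[:, :-1].reshape(B * (T - 1), N)
    dW_rec = alpha * (d_next.T @ r_prev).astype(np.float64)
    dW_rec += (omega_coeff * alpha) * (
        d_next.T @ omega_w[:, :-1].reshape(B * (T - 1), N)
    ).astype(np.float64)
    dW_in = alpha * (d_next.T @ u[:, :-1].reshape(B * (T - 1), 4)).astype(np.float64)
    db = alpha * d_next.sum(axis=0).astype(np.float64)
    dW_out = (
        dz.reshape(B * T, 2).T @ rs.reshape(B * T, N)
    ).astype(np.float64)

    dW_in += 2.0 * cfg.lambda_in / (N * 4) * params.W_in
    dW_rec += 2.0 * cfg.lambda_rec / (N * N) * params.W_rec
    dW_out += 2.0 * cfg.lambda_out / (N * 2) * params.W_out

    # project gradients onto the trainable pattern
    dW_rec *= params.connectivity_mask
    dW_in *= params.in_mask
    dW_out *= params.out_mask

    loss_terms = {
        "mse": l_mse,
        "l2": _l2_terms(params, cfg),
        "rate": l_rate,
        "omega": omega,
        "total": l_mse + _l2_terms(params, cfg) + l_rate + cfg.lambda_omega * omega,
    }
    grads = {"W_in": dW_in, "W_rec": dW_rec, "W_out": dW_out, "b_rec": db}
    return loss_terms, grads


def clip_gradients(grads: dict, max_norm: float) -> float:
    """Scale all gradients jointly so the global norm is at most ``max_norm``.
    Returns the pre-clip global norm."""
    total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total


class Adam:
    """Adam optimizer over the named parameter dict."""

    def __init__(self, shapes: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def validate(
    params: NetworkParams,
    batch: TrialBatch,
    policy: ValidationPolicy,
    rng: np.random.Generator,
    rec_noise_sd: float | None = None,
    chunk: int = 512,
) -> dict:
    """Evaluate the bilateral success criterion on a validation batch.

    A trial counts as correct when, at ``eval_before_end_ms`` before the end
    of the Decision epoch, the correct-side DV exceeds both the other DV and
    the threshold.
    """
    steps_before = int(round(policy.eval_before_end_ms / batch.dt))
    correct = np.zeros(batch.n_trials, dtype=bool)
    is_left = np.array([c.correct_direction == "left" for c in batch.conditions])
    for start in range(0, batch.n_trials, chunk):
        sl = slice(start, min(start + chunk, batch.n_trials))
        sub = TrialBatch(batch.inputs[sl], batch.z_des[sl], batch.loss_mask[sl],
                         batch.epoch_bounds[sl], batch.conditions[sl], batch.dt)
        res = simulate(params, sub, rng, rec_noise_sd, store="")
        for i in range(sub.n_trials):
            t_eval = int(sub.decision_end[i]) - steps_before
            zrow = res.z[i, t_eval]
            side = CH_LEFT_DV if sub.conditions[i].correct_direction == "left" else CH_RIGHT_DV
            other = CH_RIGHT_DV if side == CH_LEFT_DV else CH_LEFT_DV
            correct[start + i] = (zrow[side] > zrow[other]) and (zrow[side] > policy.dv_threshold)
    frac_left = float(correct[is_left].mean()) if is_left.any() else 0.0
    frac_right = float(correct[~is_left].mean()) if (~is_left).any() else 0.0
    return {
        "frac_left": frac_left,
        "frac_right": frac_right,
        "passed": frac_left >= policy.success_fraction and frac_right >= policy.success_fraction,
    }


@dataclass
class TrainResult:
    params: NetworkParams
    log: list
    converged: bool
    n_epochs: int


def train(
    arch: ArchitectureConfig,
    task_cfg: TaskConfig,
    loss_cfg: LossConfig,
    val_policy: ValidationPolicy,
    rng: np.random.Generator,
    max_epochs: int = 20000,
    batch_size: int = 64,
    params: NetworkParams | None = None,
    post_criterion_epochs: int = 0,
    verbose: bool = False,
) -> TrainResult:
    """Train a network to the bilateral validation criterion.

    One "epoch" is one minibatch update on freshly sampled trials (with catch
    trials at the configured rate).  Training stops once the criterion is
    met — or, with ``post_criterion_epochs``, continues for that many further
    updates past the first pass (the criterion is "at least 65%"; continued
    optimization sharpens behavior and lets the weight penalties compress
    task-irrelevant structure).  If the criterion is never met within
    ``max_epochs``, the best checkpoint by the smaller of the two directional
    fractions is returned with ``converged=False``.
    """
    if params is None:
        params = build_connectivity(arch, rng)
    pdict = {"W_in": params.W_in, "W_rec": params.W_rec,
             "W_out": params.W_out, "b_rec": params.b_rec}
    opt = Adam({k: v.shape for k, v in pdict.items()}, lr=loss_cfg.learning_rate)

    n_per_cond = max(1, val_policy.n_val_trials // task_cfg.n_conditions)
    val_batch = generate_batch(
        sample_conditions(n_per_cond, task_cfg, rng), task_cfg, rng)

    log: list[dict] = []
    best = params.copy()
    best_score = -1.0
    converged = False
    first_pass: int | None = None
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        conds = sample_training_conditions(batch_size, task_cfg, rng)
        batch = generate_batch(conds, task_cfg, rng)
        terms, grads = forward_backward(params, batch, loss_cfg, rng)
        pre_norm = clip_gradients(grads, loss_cfg.grad_clip_norm)
        opt.step(pdict, grads)
        params.project_constraints()

        if epoch % val_policy.interval_epochs == 0 or epoch == max_epochs:
            val = validate(params, val_batch, val_policy, rng)
            entry = {"epoch": epoch, **terms, "grad_norm": pre_norm, **val}
            log.append(entry)
            if verbose:
                print({k: (round(v, 4) if isinstance(v, float) else v)
                       for k, v in entry.items()})
            score = min(val["frac_left"], val["frac_right"])
            if score > best_score:
                best_score = score
                best = params.copy()
            if val["passed"] and first_pass is None:
                converged = True
                first_pass = epoch
            if first_pass is not None and epoch >= first_pass + post_criterion_epochs:
                best = params.copy()
                break
    if converged and epoch >= max_epochs and first_pass is not None:
        best = params.copy()
    return TrainResult(params=best, log=log, converged=converged, n_epochs=epoch)
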