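"""Continuous-time multi-area rate RNN with Dale's law and sparse inter-areal
connectivity.

The network state x obeys  tau * dx/dt = -x + W_rec r + W_in u + b_rec + eps,
with rates r = relu(x) and a linear readout z = W_out r.  It is simulated by
forward Euler with alpha = dt / tau.  Areas are blocks of units along the
diagonal of W_rec; only adjacent areas are connected, feedforward connections
originate from excitatory units of area k into area k+1 (E->E at one density,
optionally E->I at another) and feedback connections from excitatory units of
area k+1 into area k.  Task inputs drive only the first area; the readout
draws only on the last area's excitatory units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .task import CH_LEFT_DV, CH_RIGHT_DV, TaskConfig, TrialBatch, sample_conditions, generate_batch

__all__ = [
    "ArchitectureConfig",
    "NetworkParams",
    "SimResult",
    "build_connectivity",
    "simulate",
    "decide",
    "behavior_curves",
    "save_params",
    "load_params",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Network size, areal layout, connection densities and dynamics constants.

    ``ff_ee_density``/``fb_ee_density`` are Bernoulli inclusion probabilities
    for excitatory-to-excitatory connections between adjacent areas (forward /
    backward); ``ff_ei_density`` likewise for feedforward excitatory-to-
    inhibitory connections.  ``rec_noise_sd`` is the per-step SD of the
    recurrent state noise (``noise_scaling='sqrt2_alpha'`` instead injects
    alpha * sqrt(2/alpha) * sd * xi, the continuous-time convention).
    """

    n_units: int = 300
    n_areas: int = 3
    exc_fraction: float = 0.8
    ff_ee_density: float = 0.10
    fb_ee_density: float = 0.05
    ff_ei_density: float = 0.0
    dale: bool = True
    tau: float = 50.0
    dt: float = 10.0
    rec_noise_sd: float = 0.05
    spectral_radius: float = 1.5
    noise_scaling: str = "plain"
    readout_last_area_only: bool = True
    input_first_area_only: bool = True

    def __post_init__(self) -> None:
        if self.n_units % self.n_areas:
            raise ValueError("n_units must be divisible by n_areas")
        for name in ("ff_ee_density", "fb_ee_density", "ff_ei_density", "exc_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.noise_scaling not in ("plain", "sqrt2_alpha"):
            raise ValueError("noise_scaling must be 'plain' or 'sqrt2_alpha'")

    @property
    def units_per_area(self) -> int:
        return self.n_units // self.n_areas

    @property
    def alpha(self) -> float:
        return self.dt / self.tau

    def area_slice(self, k: int) -> slice:
        """Unit index range of area ``k`` (0-based)."""
        n = self.units_per_area
        return slice(k * n, (k + 1) * n)

    def exc_indices(self, k: int) -> np.ndarray:
        n = self.units_per_area
        n_exc = int(round(self.exc_fraction * n))
        return np.arange(k * n, k * n + n_exc)

    def inh_indices(self, k: int) -> np.ndarray:
        n = self.units_per_area
        n_exc = int(round(self.exc_fraction * n))
        return np.arange(k * n + n_exc, (k + 1) * n)

    def with_(self, **kwargs) -> "ArchitectureConfig":
        return replace(self, **kwargs)


@dataclass
class NetworkParams:
    """Trainable parameters plus the fixed connectivity mask and Dale signs."""

    W_in: np.ndarray       # (N, 4)
    W_rec: np.ndarray      # (N, N)
    W_out: np.ndarray      # (2, N)
    b_rec: np.ndarray      # (N,)
    sign_vector: np.ndarray        # (N,) +1 excitatory / -1 inhibitory
    connectivity_mask: np.ndarray  # (N, N) bool
    in_mask: np.ndarray            # (N, 4) bool
    out_mask: np.ndarray           # (2, N) bool
    arch: ArchitectureConfig

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.W_in.copy(), self.W_rec.copy(), self.W_out.copy(),
            self.b_rec.copy(), self.sign_vector.copy(),
            self.connectivity_mask.copy(), self.in_mask.copy(),
            self.out_mask.copy(), self.arch,
        )

    def project_constraints(self) -> None:
        """Project parameters onto the mask and Dale-sign constraint set.

        Applied after every optimizer step: masked-out entries are zeroed and,
        under Dale's law, wrong-signed entries of W_rec (per presynaptic
        column) and negative readout weights are clipped to zero.
        """
        self.W_rec *= self.connectivity_mask
        self.W_in *= self.in_mask
        self.W_out *= self.out_mask
        if self.arch.dale:
            s = self.sign_vector[None, :]
            np.multiply(self.W_rec, (self.W_rec * s > 0), out=self.W_rec)
            np.clip(self.W_out, 0.0, None, out=self.W_out)


def _interareal_block(rng, n_rows, n_cols, density) -> np.ndarray:
    return rng.random((n_rows, n_cols)) < density


def build_connectivity(arch: ArchitectureConfig, rng: np.random.Generator) -> NetworkParams:
    """Build masks, Dale signs, and initial weights for a multi-area network.

    Within-area connectivity is dense (no self-connections).  Initial
    recurrent magnitudes are folded Gaussian, sign-projected, then rescaled so
    the spectral radius of W_rec matches ``arch.spectral_radius``.
    """
    N, m = arch.n_units, arch.n_areas
    mask = np.zeros((N, N), dtype=bool)
    sign = np.ones(N)
    for k in range(m):
        sl = arch.area_slice(k)
        mask[sl, sl] = True
        sign[arch.inh_indices(k)] = -1.0
    np.fill_diagonal(mask, False)

    for k in range(m - 1):
        e_src = arch.exc_indices(k)
        e_dst = arch.exc_indices(k + 1)
        i_dst = arch.inh_indices(k + 1)
        e_back = arch.exc_indices(k + 1)
        # feedforward E->E and E->I (rows receive, columns send)
        mask[np.ix_(e_dst, e_src)] = _interareal_block(
            rng, e_dst.size, e_src.size, arch.ff_ee_density)
        if arch.ff_ei_density > 0:
            mask[np.ix_(i_dst, e_src)] = _interareal_block(
                rng, i_dst.size, e_src.size, arch.ff_ei_density)
        # feedback E->E
        mask[np.ix_(e_src, e_back)] = _interareal_block(
            rng, e_src.size, e_back.size, arch.fb_ee_density)

    W_rec = np.abs(rng.normal(0.0, 1.0 / np.sqrt(N), size=(N, N)))
    if arch.dale:
        # balance excitation and inhibition: scale inhibitory columns so
        # expected row sums vanish (4x for the 80/20 E/I split)
        n_exc = int(round(arch.exc_fraction * arch.units_per_area))
        n_inh = arch.units_per_area - n_exc
        if n_inh > 0:
            W_rec[:, sign < 0] *= n_exc / n_inh
        W_rec *= sign[None, :]
    else:
        W_rec *= rng.choice([-1.0, 1.0], size=(N, N))
    W_rec *= mask
    radius = np.max(np.abs(np.linalg.eigvals(W_rec)))
    if radius > 0:
        W_rec *= arch.spectral_radius / radius

    in_mask = np.zeros((N, 4), dtype=bool)
    if arch.input_first_area_only:
        in_mask[arch.area_slice(0), :] = True
    else:
        in_mask[:, :] = True
    W_in = rng.normal(0.0, 1.0 / np.sqrt(4), size=(N, 4)) * in_mask

    out_mask = np.zeros((2, N), dtype=bool)
    last = m - 1 if arch.readout_last_area_only else None
    if last is not None:
        cols = arch.exc_indices(last) if arch.dale else np.arange(*arch.area_slice(last).indices(N)[:2])
        out_mask[:, cols] = True
    else:
        out_mask[:, :] = True
    n_read = max(1, int(out_mask[0].sum()))
    if arch.dale:
        # all-positive readout weights sum coherently: scale by 1/n_read
        W_out = np.abs(rng.normal(0.0, 1.0 / n_read, size=(2, N))) * out_mask
    else:
        W_out = rng.normal(0.0, 1.0 / np.sqrt(n_read), size=(2, N)) * out_mask

    b_rec = np.zeros(N)
    params = NetworkParams(W_in, W_rec, W_out, b_rec, sign, mask, in_mask, out_mask, arch)
    params.project_constraints()
    return params


@dataclass
class SimResult:
    """Simulated trajectories and decisions for a batch of trials."""

    x: np.ndarray | None    # (trials, time, N) currents, optional
    r: np.ndarray | None    # (trials, time, N) rates
    z: np.ndarray           # (trials, time, 2) decision variables
    choice: np.ndarray | None = None       # 0 left / 1 right
    rt: np.ndarray | None = None           # ms from checkerboard onset, nan if none
    criterion: np.ndarray | None = None    # "threshold" / "endpoint"


def simulate(
    params: NetworkParams,
    batch: TrialBatch,
    rng: np.random.Generator | None = None,
    rec_noise_sd: float | None = None,
    store: str = "rz",
    dtype=np.float64,
    x0: np.ndarray | None = None,
) -> SimResult:
    """Forward-Euler simulation of a trial batch.

    ``store`` selects which trajectories are kept: any of "x", "r" in
    addition to the always-returned readout z.  Noise requires ``rng``.
    ``x0`` (broadcast to (trials, N)) defaults to zero.
    """
    arch = params.arch
    if abs(batch.dt - arch.dt) > 1e-9:
        raise ValueError("batch dt does not match architecture dt")
    sd = arch.rec_noise_sd if rec_noise_sd is None else rec_noise_sd
    alpha = arch.alpha
    B, T, _ = batch.inputs.shape
    N = arch.n_units

    W_rec_T = np.ascontiguousarray(params.W_rec.T, dtype=dtype)
    W_in_T = np.ascontiguousarray(params.W_in.T, dtype=dtype)
    W_out_T = np.ascontiguousarray(params.W_out.T, dtype=dtype)
    b = params.b_rec.astype(dtype)
    u = batch.inputs.astype(dtype)

    if sd > 0 and rng is None:
        raise ValueError("an rng is required when noise is enabled")
    if arch.noise_scaling == "sqrt2_alpha":
        step_sd = alpha * np.sqrt(2.0 / alpha) * sd
    else:
        step_sd = sd

    keep_x = "x" in store
    keep_r = "r" in store
    xs = np.zeros((B, T, N), dtype=dtype) if keep_x else None
    rs = np.zeros((B, T, N), dtype=dtype) if keep_r else None
    z = np.zeros((B, T, 2), dtype=dtype)

    x = np.zeros((B, N), dtype=dtype)
    if x0 is not None:
        x += np.asarray(x0, dtype=dtype)
    drive = u @ W_in_T + b  # (B, T, N) precomputed input drive
    for t in range(T):
        r = np.maximum(x, 0.0)
        if keep_x:
            xs[:, t] = x
        if keep_r:
            rs[:, t] = r
        z[:, t] = r @ W_out_T
        upd = r @ W_rec_T
        upd += drive[:, t]
        x = (1.0 - alpha) * x + alpha * upd
        if step_sd > 0:
            x += rng.normal(0.0, step_sd, size=(B, N))
    return SimResult(x=xs, r=rs, z=z)


def decide(
    z: np.ndarray,
    threshold: float,
    decision_onset: np.ndarray,
    decision_end: np.ndarray,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read out choices and reaction times from decision-variable traces.

    The decision is for whichever DV first crosses ``threshold`` after
    checkerboard onset (RT = crossing time - onset).  If neither crosses by
    the end of the Decision epoch, the decision falls to the larger DV at
    that time and no RT is defined.  If both DVs cross within the same step,
    the larger one wins (exact tie: left).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    B = z.shape[0]
    choice = np.zeros(B, dtype=np.int64)
    rt = np.full(B, np.nan)
    criterion = np.empty(B, dtype="U9")
    for i in range(B):
        t0, t1 = int(decision_onset[i]), int(decision_end[i])
        seg = z[i, t0:t1]
        above = seg >= threshold
        any_above = above.any(axis=1)
        if any_above.any():
            tc = int(np.argmax(any_above))
            row = seg[tc]
            if above[tc, CH_LEFT_DV] and above[tc, CH_RIGHT_DV]:
                c = CH_RIGHT_DV if row[CH_RIGHT_DV] > row[CH_LEFT_DV] else CH_LEFT_DV
            else:
                c = CH_RIGHT_DV if above[tc, CH_RIGHT_DV] else CH_LEFT_DV
            choice[i] = c
            rt[i] = tc * dt
            criterion[i] = "threshold"
        else:
            row = z[i, t1 - 1]
            choice[i] = CH_RIGHT_DV if row[CH_RIGHT_DV] > row[CH_LEFT_DV] else CH_LEFT_DV
            criterion[i] = "endpoint"
    return choice, rt, criterion


def simulate_decide(
    params: NetworkParams,
    batch: TrialBatch,
    rng: np.random.Generator | None,
    rec_noise_sd: float | None = None,
    threshold: float = 0.6,
    store: str = "",
) -> SimResult:
    """Simulate a batch and attach choices/RTs."""
    res = simulate(params, batch, rng, rec_noise_sd, store=store + "z" if "z" not in store else store)
    choice, rt, crit = decide(res.z, threshold, batch.decision_onset,
                              batch.decision_end, batch.dt)
    res.choice, res.rt, res.criterion = choice, rt, crit
    return res


def iter_chunks(n: int, chunk: int) -> Iterable[slice]:
    for start in range(0, n, chunk):
        yield slice(start, min(start + chunk, n))


def behavior_curves(
    params: NetworkParams,
    config: TaskConfig,
    n_per_condition: int,
    rng: np.random.Generator,
    rec_noise_sd: float | None = None,
    threshold: float = 0.6,
    chunk: int = 400,
):
    """Psychometric and chronometric tables from simulated behavior.

    For each signed coherence: the proportion of red decisions (the decision's
    color is that of the chosen target) and the mean RT over trials decided by
    threshold crossing; endpoint-criterion trials contribute to the
    psychometric but not to RT.  Returns a pandas DataFrame sorted by
    coherence, plus the overall endpoint fraction in ``df.attrs``.
    """
    import pandas as pd

    conds = sample_conditions(n_per_condition, config, rng)
    rows = []
    endpoint = 0
    for sl in iter_chunks(len(conds), chunk):
        sub = conds[sl.start:sl.stop]
        batch = generate_batch(sub, config, rng)
        res = simulate_decide(params, batch, rng, rec_noise_sd, threshold)
        for c, ch, rt_i, crit in zip(sub, res.choice, res.rt, res.criterion):
            chosen_side = "left" if ch == CH_LEFT_DV else "right"
            left_color = "red" if c.target_config == "left_red" else "green"
            chosen_color = left_color if chosen_side == "left" else (
                "green" if left_color == "red" else "red")
            rows.append((c.signed_coherence, chosen_color == "red", rt_i,
                         crit == "endpoint",
                         chosen_side == c.correct_direction))
            endpoint += crit == "endpoint"
    df = pd.DataFrame(rows, columns=["coherence", "chose_red", "rt", "endpoint", "correct"])
    out = (
        df.groupby("coherence")
        .agg(p_red=("chose_red", "mean"),
             mean_rt=("rt", lambda v: np.nanmean(v) if np.isfinite(v).any() else np.nan),
             p_correct=("correct", "mean"),
             n=("chose_red", "size"))
        .reset_index()
    )
    out.attrs["endpoint_fraction"] = endpoint / len(conds)
    return out


def save_params(path, params: NetworkParams, seed: int | None = None,
                extra: dict | None = None) -> None:
    """Persist parameters, masks, signs and architecture to an NPZ checkpoint."""
    import dataclasses
    arch_items = dataclasses.asdict(params.arch)
    np.savez(
        path,
        W_in=params.W_in, W_rec=params.W_rec, W_out=params.W_out,
        b_rec=params.b_rec, sign_vector=params.sign_vector,
        connectivity_mask=params.connectivity_mask,
        in_mask=params.in_mask, out_mask=params.out_mask,
        arch_keys=np.array(list(arch_items.keys())),
        arch_vals=np.array([repr(v) for v in arch_items.values()]),
        seed=np.array(-1 if seed is None else seed),
        **(extra or {}),
    )


def load_params(path) -> NetworkParams:
    import ast
    with np.load(path, allow_pickle=False) as f:
        arch_kwargs = {
            k: ast.literal_eval(v)
            for k, v in zip(f["arch_keys"], f["arch_vals"])
        }
        arch = ArchitectureConfig(**arch_kwargs)
        return NetworkParams(
            f["W_in"], f["W_rec"], f["W_out"], f["b_rec"], f["sign_vector"],
            f["connectivity_mask"].astype(bool), f["in_mask"].astype(bool),
            f["out_mask"].astype(bool), arch,
        )
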