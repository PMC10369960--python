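"""Exemplar-network analysis suite.

Bundles the full characterization applied to a trained multi-area network:

* psychometric / chronometric behavior,
* per-area demixed PCA (leading direction, color, target-configuration and
  condition-independent axes, captured variances, axis overlaps),
* per-area decoding and usable information from RT-aligned window averages,
* potent/null projection sweeps of task axes through recurrent blocks and
  the inter-areal feedforward E->E matrices,
* CCA similarity of each area against DLPFC-like and PMd-like synthetic
  reference populations.

Analysis trials use deterministic epoch durations (center hold at its mean,
targets interval at the midpoint of its range) so that trials share a time
base and condition averages are well defined without restretching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import population as pop
from .connectivity import projection_sweep
from .info import DecodeDataset, build_rnn_decode_dataset, decode_variable
from .network import NetworkParams, behavior_curves, iter_chunks, simulate
from .synth import generate_session, preset
from .task import TaskConfig, generate_batch, sample_conditions

__all__ = [
    "AnalysisSizes",
    "fixed_timing",
    "rnn_condition_tensor",
    "area_dpca_report",
    "area_info_report",
    "projection_report",
    "cca_report",
    "exemplar_report",
]

VARIABLES = ("direction", "color", "target_config")


@dataclass(frozen=True)
class AnalysisSizes:
    """Problem sizes for the analysis stages."""

    n_behavior_per_condition: int = 200
    n_tensor_per_condition: int = 25
    n_decode_train: int = 700
    n_decode_test: int = 2100
    decoder_epochs: int = 200
    decode_noise_sd: float = 0.1
    cca_window_ms: tuple = (-400.0, 400.0)


def fixed_timing(cfg: TaskConfig) -> TaskConfig:
    """Deterministic epoch timing: center hold at its mean, targets interval
    at the midpoint of its range."""
    mid = 0.5 * (cfg.targets_min + cfg.targets_max)
    return cfg.with_(center_hold_sd=0.0, targets_min=mid, targets_max=mid)


def rnn_condition_tensor(
    params: NetworkParams,
    task_cfg: TaskConfig,
    rng: np.random.Generator,
    n_per_condition: int = 25,
    rec_noise_sd: float | None = None,
    chunk: int = 400,
) -> tuple[np.ndarray, dict]:
    """Condition-averaged rate tensor X[unit, color, direction, time] over
    whole fixed-timing trials, plus timing metadata (checkerboard onset
    step, dt)."""
    cfg = fixed_timing(task_cfg)
    conds = sample_conditions(n_per_condition, cfg, rng)
    sums = None
    counts = np.zeros((2, 2))
    meta = {}
    for sl in iter_chunks(len(conds), chunk):
        sub = conds[sl.start:sl.stop]
        batch = generate_batch(sub, cfg, rng)
        res = simulate(params, batch, rng, rec_noise_sd, store="r", dtype=np.float32)
        if sums is None:
            T = batch.n_steps
            sums = np.zeros((params.arch.n_units, 2, 2, T))
            meta = {"cb_step": int(batch.decision_onset[0]), "dt": cfg.dt}
        for i, c in enumerate(sub):
            s = int(c.correct_color == "red")
            d = int(c.correct_direction == "right")
            sums[:, s, d, :] += res.r[i].T
            counts[s, d] += 1
    X = sums / counts[None, :, :, None]
    return X, meta


def area_dpca_report(
    params: NetworkParams,
    X: np.ndarray,
    k_per_marginal: int = 1,
    excitatory_only: bool = False,
) -> dict:
    """Per-area dPCA: axes, captured variances and pairwise axis overlaps.

    Returns {area_name: {"axes": MarginalAxes dict, "variance": {...},
    "overlap": {...}, "unit_index": indices}} with areas named "area1"... ;
    ``excitatory_only`` restricts each area to its excitatory units (the
    convention for inter-areal projection analyses).
    """
    arch = params.arch
    out = {}
    for k in range(arch.n_areas):
        idx = (arch.exc_indices(k) if excitatory_only
               else np.arange(*arch.area_slice(k).indices(arch.n_units)[:2]))
        axes = pop.dpca(X[idx], k_per_marginal=k_per_marginal)
        variance = {m: float(ax.variance_captured[0]) for m, ax in axes.items()}
        overlap = {}
        for i, a in enumerate(VARIABLES):
            for b in VARIABLES[i + 1:]:
                overlap[f"{a}__{b}"] = pop.axis_overlap(axes[a].axis, axes[b].axis)
        out[f"area{k + 1}"] = {
            "axes": axes, "variance": variance, "overlap": overlap,
            "unit_index": idx,
        }
    return out


def area_info_report(
    params: NetworkParams,
    ds: DecodeDataset,
    rng: np.random.Generator,
    epochs: int = 200,
) -> dict:
    """Decode accuracy and usable information per area and variable."""
    arch = params.arch
    out = {}
    for k in range(arch.n_areas):
        idx = np.arange(*arch.area_slice(k).indices(arch.n_units)[:2])
        reports = {}
        for v in VARIABLES:
            reports[v] = decode_variable(ds, v, rng, unit_index=idx, epochs=epochs)
        out[f"area{k + 1}"] = reports
    return out


def projection_report(
    params: NetworkParams,
    X: np.ndarray,
    rng: np.random.Generator,
    n_random: int = 100,
):
    """Potent/null projection sweep of dPCA task axes.

    Recurrent-block axes come from dPCA over all units of an area;
    inter-areal axes from dPCA over the source area's excitatory units (the
    feedforward blocks are E->E).  Returns the tidy profile DataFrame from
    :func:`interareal.connectivity.projection_sweep`.
    """
    all_units = area_dpca_report(params, X, excitatory_only=False)
    exc_only = area_dpca_report(params, X, excitatory_only=True)
    axes = {}
    for k in range(params.arch.n_areas):
        name = f"area{k + 1}"
        for v in ("direction", "color"):
            axes[f"{name}:{v}"] = all_units[name]["axes"][v].axis
            axes[f"{name}_exc:{v}"] = exc_only[name]["axes"][v].axis
    return projection_sweep(params, axes, rng, n_random=n_random)


def rnn_cca_matrix(
    params: NetworkParams,
    X: np.ndarray,
    meta: dict,
    window_ms: tuple = (-400.0, 400.0),
) -> np.ndarray:
    """Per-area (unit, condition x time) matrices around checkerboard onset
    with the condition-independent signal removed."""
    cb = meta["cb_step"]
    dt = meta["dt"]
    a = cb + int(round(window_ms[0] / dt))
    b = cb + int(round(window_ms[1] / dt)) + 1
    Xw = X[:, :, :, max(a, 0):b]
    resid, _, _ = pop.remove_condition_independent(Xw)
    return resid


def synthetic_reference_matrix(
    name: str,
    rng: np.random.Generator,
    n_trials: int = 400,
    window_ms: tuple = (-400.0, 400.0),
) -> np.ndarray:
    """Condition-averaged, checkerboard-aligned, CI-removed (unit, 2, 2, T)
    reference from a synthetic session preset."""
    sess, _ = generate_session(preset(name).with_(n_trials=n_trials), rng)
    dt = sess.dt
    lo = int(round(window_ms[0] / dt))
    hi = int(round(window_ms[1] / dt))
    T = sess.rates.shape[2]
    slices = []
    keep = []
    for i in range(sess.rates.shape[0]):
        c = int(round(sess.cb_time[i] / dt))
        if c + lo < 0 or c + hi + 1 > T:
            continue
        slices.append(sess.rates[i, :, c + lo:c + hi + 1])
        keep.append(i)
    trials = np.stack(slices)
    lab = sess.labels.iloc[keep]
    Xc = pop.condition_average(trials, lab["color"].to_numpy(),
                               lab["direction"].to_numpy())
    resid, _, _ = pop.remove_condition_independent(Xc)
    return resid


def cca_report(
    params: NetworkParams,
    X: np.ndarray,
    meta: dict,
    rng: np.random.Generator,
    window_ms: tuple = (-400.0, 400.0),
) -> dict:
    """Mean canonical correlation of every area against DLPFC-like and
    PMd-like synthetic reference populations (PCA depth 4 and 2)."""
    arch = params.arch
    resid = rnn_cca_matrix(params, X, meta, window_ms)
    refs = {
        "dlpfc_like": (synthetic_reference_matrix("dlpfc_like", rng,
                                                  window_ms=window_ms), 4),
        "pmd_like": (synthetic_reference_matrix("pmd_like", rng,
                                                window_ms=window_ms), 2),
    }
    # time axes may differ by a bin between RNN and reference grids
    out = {}
    for ref_name, (ref, n_pcs) in refs.items():
        T = min(resid.shape[-1], ref.shape[-1])
        ref_flat = ref[..., :T].reshape(ref.shape[0], -1)
        for k in range(arch.n_areas):
            idx = np.arange(*arch.area_slice(k).indices(arch.n_units)[:2])
            a_flat = resid[idx, :, :, :T].reshape(idx.size, -1)
            out[f"area{k + 1}__{ref_name}"] = pop.cca_similarity(
                a_flat, ref_flat, n_pcs_a=n_pcs, n_pcs_b=n_pcs)
    return out


def exemplar_report(
    params: NetworkParams,
    task_cfg: TaskConfig,
    rng: np.random.Generator,
    sizes: AnalysisSizes = AnalysisSizes(),
) -> dict:
    """Run the full analysis suite on a trained network.

    Returns a nested dict with keys behavior, dpca, info, projections, cca.
    """
    behavior = behavior_curves(params, task_cfg, sizes.n_behavior_per_condition, rng)
    X, meta = rnn_condition_tensor(params, task_cfg, rng,
                                   sizes.n_tensor_per_condition)
    dpca_rep = area_dpca_report(params, X)
    ds = build_rnn_decode_dataset(
        params, task_cfg, rng,
        n_train=sizes.n_decode_train, n_test=sizes.n_decode_test,
        rec_noise_sd=sizes.decode_noise_sd,
    )
    info_rep = area_info_report(params, ds, rng, epochs=sizes.decoder_epochs)
    proj = projection_report(params, X, rng)
    cca = cca_report(params, X, meta, rng, sizes.cca_window_ms)
    return {
        "behavior": behavior,
        "tensor_meta": meta,
        "dpca": dpca_rep,
        "info": info_rep,
        "projections": proj,
        "cca": cca,
    }
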