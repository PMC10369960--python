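"""Population-level dimensionality reduction for rate data.

Works on two array layouts:

* condition-averaged 4-D tensors ``X[unit, color, direction, time]`` — the
  2 x 2 color-by-direction grid is in one-to-one correspondence with
  (color, target configuration), so the configuration signal appears as the
  color x direction interaction marginal;
* single-trial stacks ``R[trial, unit, time]`` with per-trial labels.

Provided analyses: square-root 99th-percentile normalization, removal of the
condition-independent (time-only) signal, piecewise-linear time restretching
onto median event intervals, PCA, demixed PCA (per-marginal reduced-rank
regression with ridge shrinkage), axis overlaps, and CCA similarity between
two populations after PCA denoising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarginalAxes",
    "StretchPolicy",
    "normalize_units",
    "condition_average",
    "remove_condition_independent",
    "restretch",
    "pca",
    "PCAResult",
    "dpca",
    "dpca_marginalize",
    "axis_overlap",
    "cca_similarity",
    "MARGINALS",
]

MARGINALS = ("condition_independent", "color", "direction", "target_config")


def normalize_units(rates: np.ndarray, unit_axis: int = 0) -> np.ndarray:
    """Divide each unit by the square root of its 99th-percentile rate.

    Equalizes the PCA contribution of high- and low-rate units; all-zero
    units are left unchanged.
    """
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    moved = np.moveaxis(rates, unit_axis, 0)
    flat = moved.reshape(moved.shape[0], -1)
    q99 = np.percentile(flat, 99, axis=1)
    scale = np.where(q99 > 0, np.sqrt(np.maximum(q99, 1e-300)), 1.0)
    out = moved / scale[(slice(None),) + (None,) * (moved.ndim - 1)]
    return np.moveaxis(out, 0, unit_axis)


def condition_average(
    trials: np.ndarray,
    color_labels: np.ndarray,
    direction_labels: np.ndarray,
) -> np.ndarray:
    """Average single trials (trial, unit, time) into X[unit, color, direction, time].

    Labels are binary (0/1); empty condition cells raise.
    """
    X = np.zeros((trials.shape[1], 2, 2, trials.shape[2]))
    for s in (0, 1):
        for d in (0, 1):
            sel = (np.asarray(color_labels) == s) & (np.asarray(direction_labels) == d)
            if not sel.any():
                raise ValueError(f"empty condition cell color={s} direction={d}")
            X[:, s, d, :] = trials[sel].mean(axis=0)
    return X


def remove_condition_independent(
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Subtract the per-unit mean over conditions at each time bin.

    ``X`` is (unit, conditions..., time) with one or more condition axes.
    Returns ``(residual, ci, ci_fraction)`` where ``ci`` is (unit, time) and
    ``ci_fraction`` is the removed share of total variance (about each
    unit's grand mean, summed over units, conditions and time).
    """
    if X.ndim < 3:
        raise ValueError("expected (unit, conditions..., time)")
    cond_axes = tuple(range(1, X.ndim - 1))
    n_cond = int(np.prod([X.shape[a] for a in cond_axes]))
    if n_cond < 2:
        raise ValueError("need at least two conditions")
    ci = X.mean(axis=cond_axes)  # (unit, time)
    shape = (X.shape[0],) + (1,) * len(cond_axes) + (X.shape[-1],)
    residual = X - ci.reshape(shape)
    grand = X.mean(axis=cond_axes + (X.ndim - 1,))
    v_tot = float(((X - grand.reshape((-1,) + (1,) * (X.ndim - 1))) ** 2).sum())
    v_ci = float(n_cond * ((ci - grand[:, None]) ** 2).sum())
    frac = v_ci / v_tot if v_tot > 0 else 0.0
    return residual, ci, frac


@dataclass(frozen=True)
class StretchPolicy:
    """Alignment windows and median intervals for time restretching.

    The canonical (post-stretch) timeline puts target onset at 0 ms,
    checkerboard onset at ``median_tc`` and movement onset at
    ``median_tc + median_rt``.  ``segments`` lists (alignment, start, end)
    windows in ms, alignment "target" or "checkerboard", concatenated after
    stretching.
    """

    median_tc: float = 735.0
    median_rt: float = 527.0
    segments: tuple = (("target", -100.0, 1200.0),)

    @classmethod
    def dlpfc_style(cls) -> "StretchPolicy":
        """One target-aligned window [-100, 1200] ms."""
        return cls()

    @classmethod
    def pmd_style(cls) -> "StretchPolicy":
        """Target-aligned [-100, 367] ms concatenated with
        checkerboard-aligned [-368, 465] ms."""
        return cls(segments=(("target", -100.0, 367.0),
                             ("checkerboard", -368.0, 465.0)))

    def canonical_times(self, dt: float) -> np.ndarray:
        parts = []
        for align, lo, hi in self.segments:
            off = 0.0 if align == "target" else self.median_tc
            parts.append(np.arange(lo, hi + 0.5 * dt, dt) + off)
        return np.concatenate(parts)


def restretch(
    trials: np.ndarray,
    target_on: np.ndarray,
    checkerboard_on: np.ndarray,
    move_on: np.ndarray,
    dt: float,
    policy: StretchPolicy,
) -> tuple[np.ndarray, np.ndarray]:
    """Stretch each trial's TC interval and RT onto the policy's medians.

    ``trials`` is (trial, unit, time); event arguments give per-trial event
    times in ms on that axis (bin i at i * dt).  The time map is piecewise
    linear through (target, checkerboard, movement) knots with identity
    slope outside; rates are linearly interpolated onto the canonical grid.
    Trials whose required samples fall outside the recording are dropped.

    Returns ``(stretched, kept_index)``; stretched is
    (kept trials, unit, canonical bins).
    """
    B, n, T = trials.shape
    grid = policy.canonical_times(dt)
    canon_knots = np.array([0.0, policy.median_tc,
                            policy.median_tc + policy.median_rt])
    out, kept = [], []
    t_axis = np.arange(T) * dt
    for i in range(B):
        knots = np.array([target_on[i], checkerboard_on[i], move_on[i]], dtype=float)
        if not np.all(np.diff(knots) > 0):
            continue
        orig = np.interp(grid, canon_knots, knots)
        before = grid < canon_knots[0]
        after = grid > canon_knots[-1]
        orig[before] = knots[0] + (grid[before] - canon_knots[0])
        orig[after] = knots[-1] + (grid[after] - canon_knots[-1])
        if orig.min() < t_axis[0] - 0.5 * dt or orig.max() > t_axis[-1] + 0.5 * dt:
            continue
        stretched = np.empty((n, grid.size))
        for u_i in range(n):
            stretched[u_i] = np.interp(orig, t_axis, trials[i, u_i])
        out.append(stretched)
        kept.append(i)
    if not out:
        return np.zeros((0, n, grid.size)), np.array([], dtype=int)
    return np.stack(out), np.array(kept, dtype=int)


@dataclass
class PCAResult:
    axes: np.ndarray                 # (k, unit)
    projections: np.ndarray          # (k, samples)
    variance_fraction: np.ndarray    # (k,)


def pca(X: np.ndarray, n_components: int) -> PCAResult:
    """PCA of (unit, samples...) data; units are features, all remaining
    axes are flattened into samples.  Components are capped at the rank."""
    from sklearn.decomposition import PCA as SkPCA

    flat = X.reshape(X.shape[0], -1)
    k = min(n_components, *flat.shape)
    model = SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(flat.T)  # (samples, k)
    return PCAResult(
        axes=model.components_,
        projections=scores.T,
        variance_fraction=model.explained_variance_ratio_,
    )


def dpca_marginalize(X: np.ndarray) -> dict[str, np.ndarray]:
    """Split a centered X[unit, color, direction, time] into four
    marginalized tensors broadcast to the full shape: condition-independent
    (time only), color, direction, and the color x direction interaction,
    which carries the target-configuration signal.  They sum exactly to the
    centered tensor."""
    if X.ndim != 4:
        raise ValueError("expected X[unit, color, direction, time]")
    Xc = X - X.mean(axis=(1, 2, 3), keepdims=True)
    m_t = Xc.mean(axis=(1, 2), keepdims=True)
    m_color = Xc.mean(axis=2, keepdims=True) - m_t
    m_dir = Xc.mean(axis=1, keepdims=True) - m_t
    m_int = Xc - m_t - m_color - m_dir
    bc = np.broadcast_to
    return {
        "condition_independent": bc(m_t, Xc.shape).copy(),
        "color": bc(m_color, Xc.shape).copy(),
        "direction": bc(m_dir, Xc.shape).copy(),
        "target_config": bc(m_int, Xc.shape).copy(),
    }


@dataclass
class MarginalAxes:
    """Demixed axes for one marginal: orthonormal encoder columns,
    unconstrained decoder rows, and per-component captured variance as a
    fraction of total (centered) variance."""

    marginal: str
    encoder: np.ndarray            # (unit, k)
    decoder: np.ndarray            # (k, unit)
    variance_captured: np.ndarray  # (k,)

    @property
    def axis(self) -> np.ndarray:
        """The leading encoder axis as a unit vector over units."""
        v = self.encoder[:, 0]
        nrm = np.linalg.norm(v)
        return v if nrm == 0 else v / nrm


def dpca(
    X: np.ndarray,
    k_per_marginal: int = 1,
    regularization: float = 1e-6,
    marginals: tuple[str, ...] = MARGINALS,
) -> dict[str, MarginalAxes]:
    """Demixed PCA of X[unit, color, direction, time].

    Per marginal c the loss ||X_c - P_c D_c X||^2 is minimized by ridge
    reduced-rank regression: the rank-k truncation of the ridge prediction
    of the marginalized tensor from the full centered tensor gives the
    orthonormal encoder P_c and decoder D_c.  ``regularization`` scales the
    ridge relative to the mean per-unit signal power.  Marginals with no
    variance return zero-variance axes.
    """
    parts = dpca_marginalize(X)
    n = X.shape[0]
    Xf = (X - X.mean(axis=(1, 2, 3), keepdims=True)).reshape(n, -1)
    total_var = float((Xf ** 2).sum())
    lam = regularization * total_var / n
    G_inv = np.linalg.inv(Xf @ Xf.T + lam * np.eye(n)) if total_var > 0 else np.eye(n)
    out: dict[str, MarginalAxes] = {}
    for name in marginals:
        Xc = parts[name].reshape(n, -1)
        k = min(k_per_marginal, n)
        A = Xc @ Xf.T @ G_inv
        pred = A @ Xf
        if not np.any(pred):
            enc = np.eye(n)[:, :k]
            out[name] = MarginalAxes(name, enc, np.zeros((k, n)), np.zeros(k))
            continue
        U, _, _ = np.linalg.svd(pred, full_matrices=False)
        P = U[:, :k]
        D = P.T @ A
        comp = D @ Xf
        var = (comp ** 2).sum(axis=1) / total_var if total_var > 0 else np.zeros(k)
        out[name] = MarginalAxes(name, P, D, var)
    return out


def axis_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute dot product of two unit axes (axis sign is arbitrary)."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm axis")
    return float(abs(np.dot(a / na, b / nb)))


def cca_similarity(
    pop_a: np.ndarray,
    pop_b: np.ndarray,
    n_pcs_a: int = 4,
    n_pcs_b: int = 2,
    n_cca_dims: int = 2,
) -> float:
    """Mean canonical correlation between two populations observed over the
    same samples.

    Inputs are (unit, samples) matrices over matched condition-by-time
    samples (typically 10 ms bins in [-400, 400] ms around checkerboard
    onset, condition-independent signal removed).  Each population is
    PCA-reduced to denoise, then a CCA with ``n_cca_dims`` dimensions is
    fit and the canonical correlations averaged.
    """
    from sklearn.cross_decomposition import CCA

    a = pop_a.reshape(pop_a.shape[0], -1)
    b = pop_b.reshape(pop_b.shape[0], -1)
    if a.shape[1] != b.shape[1]:
        raise ValueError("populations must share the sample axis")
    ka = min(n_pcs_a, *a.shape)
    kb = min(n_pcs_b, *b.shape)
    if a.shape[1] <= max(ka, kb):
        raise ValueError("fewer samples than PCA dimensions")
    k = min(n_cca_dims, ka, kb)
    sa = pca(a, ka).projections.T  # (samples, ka)
    sb = pca(b, kb).projections.T
    model = CCA(n_components=k, max_iter=2000)
    ua, ub = model.fit_transform(sa, sb)
    corrs = [abs(np.corrcoef(ua[:, i], ub[:, i])[0, 1]) for i in range(k)]
    return float(np.mean(corrs))
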