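"""Synthetic DLPFC-like and PMd-like sessions with planted ground truth.

Each session emulates a small simultaneously recorded population (2-49
units) during the checkerboard task: a dominant condition-independent
temporal component (~80% of variance by default), low-variance coding axes
for direction, color and target configuration with configurable pairwise
alignment, trial-to-trial noise (Gaussian or Poisson), and task-like trial
timing (target onset, a variable target-to-checkerboard interval, and a
coherence-dependent lognormal reaction time).

Because amplitudes are calibrated against the empirically realized
component variances, the planted variance fractions hold exactly in the
generated session, and the Bayes-optimal decode accuracy of each variable
is known (closed form for orthogonal axes, likelihood-ratio evaluation
otherwise), giving every downstream analysis a quantitative oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .task import default_coherence_levels

__all__ = [
    "SyntheticSessionConfig",
    "SyntheticGroundTruth",
    "Session",
    "generate_session",
    "calibrate_axis_variance",
    "preset",
]

VARIABLES = ("direction", "color", "target_config")


@dataclass(frozen=True)
class SyntheticSessionConfig:
    """Parameters of one synthetic session.

    ``axis_variance`` maps each task variable to its share of total session
    variance; ``ci_variance_fraction`` is the condition-independent share;
    the remainder is trial-to-trial noise.  ``axis_alignment`` gives target
    pairwise cosines between coding axes.
    """

    n_units: int = 24
    n_trials: int = 400
    ci_variance_fraction: float = 0.80
    axis_variance: dict = field(default_factory=lambda: {
        "direction": 0.03, "color": 0.005, "target_config": 0.01})
    axis_alignment: dict = field(default_factory=lambda: {
        ("direction", "color"): 0.2,
        ("direction", "target_config"): 0.2,
        ("color", "target_config"): 0.5,
    })
    noise_model: str = "gaussian"
    noise_sd: float = 1.0              # per unit per bin, gaussian mode
    slow_noise_fraction: float = 0.5   # share of noise variance that is a
                                       # per-trial constant (does not average
                                       # out over the decode window)
    baseline_rate: float = 10.0        # Hz offset, poisson mode
    rt_median_ms: float = 450.0        # scaled up for low-coherence trials
    rt_sigma: float = 0.15             # lognormal shape
    rt_coh_slope: float = 0.35         # median multiplier 1 + slope*(1-|coh|)
    tc_bounds: tuple = (500.0, 1000.0)
    pre_target_ms: float = 100.0
    post_move_ms: float = 200.0
    dt: float = 10.0
    coherence_levels: tuple = field(default_factory=default_coherence_levels)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_units:
            raise ValueError("need at least 2 units")
        total = self.ci_variance_fraction + sum(self.axis_variance.values())
        if total >= 1.0:
            raise ValueError("variance fractions must sum to < 1 (noise needs a share)")
        for cos in self.axis_alignment.values():
            if not 0 <= cos <= 1:
                raise ValueError("alignment cosines must lie in [0, 1]")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be gaussian or poisson")

    def with_(self, **kwargs) -> "SyntheticSessionConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticGroundTruth:
    """What was planted: unit-norm axes, realized variance fractions, the
    Bayes decode accuracy per variable, and the calibrated amplitudes."""

    axes: dict
    variance_fractions: dict
    ci_fraction: float
    noise_fraction: float
    bayes_accuracy: dict
    channel_information: dict
    amplitudes: dict
    noise_sd: float


@dataclass
class Session:
    """One synthetic recording: rates (trial, unit, time) plus labels.

    ``labels`` is a pandas DataFrame with binary direction (1 = right),
    color (1 = red), target_config (1 = left_red), the signed coherence,
    and per-trial event times in ms (columns tc_ms, rt_ms).  ``move_time``
    is the movement-onset time on the session clock.
    """

    rates: np.ndarray
    dt: float
    labels: "object"
    target_time: float
    cb_time: np.ndarray
    move_time: np.ndarray

    @property
    def n_units(self) -> int:
        return self.rates.shape[1]

    def save(self, path) -> None:
        np.savez(
            path,
            rates=self.rates, dt=np.array(self.dt),
            target_time=np.array(self.target_time),
            cb_time=self.cb_time, move_time=self.move_time,
            label_cols=np.array(list(self.labels.columns)),
            label_vals=self.labels.to_numpy(dtype=float),
        )

    @classmethod
    def load(cls, path) -> "Session":
        import pandas as pd
        with np.load(path, allow_pickle=False) as f:
            labels = pd.DataFrame(f["label_vals"], columns=list(f["label_cols"]))
            for c in ("direction", "color", "target_config"):
                labels[c] = labels[c].astype(int)
            return cls(f["rates"], float(f["dt"]), labels,
                       float(f["target_time"]), f["cb_time"], f["move_time"])


def _axes_with_gram(n_units: int, cosines: dict, rng) -> dict:
    """Unit-norm axes with the requested pairwise |cosines| (Gram-factor
    construction on a random orthonormal frame)."""
    G = np.eye(3)
    for i, a in enumerate(VARIABLES):
        for j, b in enumerate(VARIABLES):
            if i < j:
                c = cosines.get((a, b), cosines.get((b, a), 0.0))
                G[i, j] = G[j, i] = c
    evals = np.linalg.eigvalsh(G)
    if evals.min() < -1e-10:
        raise ValueError("requested alignment cosines are not realizable (Gram not PSD)")
    L = np.linalg.cholesky(G + 1e-12 * np.eye(3))
    Q, _ = np.linalg.qr(rng.normal(size=(n_units, 3)))
    A = Q @ L.T  # columns have unit norm, Gram = G
    return {v: A[:, i] for i, v in enumerate(VARIABLES)}


def _bayes_accuracy(
    v: str, amps: dict, axes: dict, env_means: np.ndarray, sigma_feat: float,
    seed: int,
) -> float:
    """Bayes decode accuracy of variable ``v`` from window-averaged features.

    The generative label distribution is uniform over (color, config) with
    direction = color XOR config, so the three labels are pairwise
    independent but jointly deterministic — a variable can be decodable
    through the other two axes even with zero planted amplitude of its own.
    Feature means are mu = sum_w s_w a_w env axis_w over the four label
    combinations with isotropic Gaussian noise.  When each class maps to a
    single feature mean the accuracy is the closed form
    Phi(||mu1 - mu0|| / (2 sigma)); degenerate identical mixtures give 0.5;
    the general mixture case is evaluated by a Monte-Carlo likelihood-ratio
    test in the 3-dim axis subspace (deterministic seed).
    """
    env_means = np.atleast_1d(np.asarray(env_means, dtype=float))
    env_mean = float(env_means.mean())
    # enumerate the four (color, config) label combinations
    combos = []
    for color in (0, 1):
        for config in (0, 1):
            s = {"color": 2 * color - 1, "target_config": 2 * config - 1,
                 "direction": 2 * (color ^ config) - 1}
            mu = sum(s[w] * amps.get(w, 0.0) * env_mean * axes[w]
                     for w in VARIABLES)
            combos.append((s[v], mu))
    basis = np.linalg.qr(np.stack([axes[w] for w in VARIABLES], axis=1))[0][:, :3]
    class_means = {
        cls: [basis.T @ mu for s, mu in combos if s == cls] for cls in (+1, -1)
    }

    def same(a, b):
        return np.allclose(a, b, atol=1e-12)

    m_pos, m_neg = class_means[+1], class_means[-1]
    # identical mixtures -> variable is undecodable
    if (same(m_pos[0], m_neg[0]) and same(m_pos[1], m_neg[1])) or (
            same(m_pos[0], m_neg[1]) and same(m_pos[1], m_neg[0])):
        return 0.5
    if same(m_pos[0], m_pos[1]) and same(m_neg[0], m_neg[1]):
        # single Gaussian per class: average the closed form over the
        # per-trial envelope values (the effective separation scales with
        # each trial's window-averaged envelope)
        d = np.linalg.norm(m_pos[0] - m_neg[0])
        scaled = d * env_means / max(env_mean, 1e-300)
        return float(norm.cdf(scaled / (2 * sigma_feat)).mean())
    rng = np.random.default_rng(seed)
    n_mc = 200_000
    correct = 0
    mus = [np.array(m_pos), np.array(m_neg)]
    for cls, mu_rows in enumerate(mus):
        pick = rng.integers(len(mu_rows), size=n_mc // 2)
        x = mu_rows[pick] + rng.normal(0, sigma_feat, size=(n_mc // 2, 3))
        # each class log-likelihood is a log-sum-exp over its combos
        lls = []
        for rows in mus:
            d2 = ((x[:, None, :] - rows[None, :, :]) ** 2).sum(axis=2)
            lls.append(np.logaddexp.reduce(-d2 / (2 * sigma_feat ** 2), axis=1))
        correct += int((np.argmax(np.stack(lls), axis=0) == cls).sum())
    return correct / n_mc


def _channel_information(
    v: str, amps: dict, axes: dict, env_means: np.ndarray, sigma_feat: float,
) -> float | None:
    """Exact mutual information (bits) between variable ``v`` and the
    feature vector, for the case where each class maps to a single Gaussian
    (then the scalar projection onto the discriminant is sufficient and
    I(Y;X) = 1 - E_x[H_b(posterior)] by quadrature, averaged over the
    per-trial envelope).  Returns None in the general mixture case."""
    combos = []
    for color in (0, 1):
        for config in (0, 1):
            s = {"color": 2 * color - 1, "target_config": 2 * config - 1,
                 "direction": 2 * (color ^ config) - 1}
            mu = sum(s[w] * amps.get(w, 0.0) * axes[w] for w in VARIABLES)
            combos.append((s[v], mu))
    m_pos = [mu for s, mu in combos if s == +1]
    m_neg = [mu for s, mu in combos if s == -1]
    if not (np.allclose(m_pos[0], m_pos[1]) and np.allclose(m_neg[0], m_neg[1])):
        return None
    d_unit = np.linalg.norm(m_pos[0] - m_neg[0])
    if d_unit == 0:
        return 0.0
    xs = np.linspace(-10, 10, 2001)
    vals = []
    for e in np.atleast_1d(env_means):
        a = d_unit * e / 2.0 / sigma_feat
        p1 = norm.pdf(xs, a, 1.0)
        p0 = norm.pdf(xs, -a, 1.0)
        post = p1 / (p1 + p0)
        with np.errstate(divide="ignore", invalid="ignore"):
            hb = -(post * np.log2(post) + (1 - post) * np.log2(1 - post))
        hb = np.nan_to_num(hb)
        vals.append(1.0 - np.trapezoid(0.5 * (p1 + p0) * hb, xs))
    return float(np.mean(vals))


def generate_session(
    cfg: SyntheticSessionConfig,
    rng: np.random.Generator,
) -> tuple[Session, SyntheticGroundTruth]:
    """Generate one session and its ground truth.

    Rates are  ci(t) * w_ci  +  sum_v s_v a_v axis_v env(t)  +  noise, with
    a shared sigmoidal condition-independent time course, a post-checkerboard
    sigmoidal tuning envelope (choice information appears only after the
    stimulus), and amplitudes calibrated so each component's share of total
    variance equals its requested fraction exactly.
    """
    import pandas as pd

    n, B, dt = cfg.n_units, cfg.n_trials, cfg.dt

    # --- labels and timing
    coh = rng.choice(cfg.coherence_levels, size=B)
    config = rng.integers(2, size=B)          # 1 = left_red
    color = (coh > 0).astype(int)             # 1 = red
    direction = color ^ config                # 1 = right
    tc = rng.uniform(*cfg.tc_bounds, size=B)
    med = cfg.rt_median_ms * (1 + cfg.rt_coh_slope * (1 - np.abs(coh)))
    rt = np.exp(rng.normal(np.log(med), cfg.rt_sigma))
    t_target = cfg.pre_target_ms
    cb_time = t_target + tc
    move_time = cb_time + rt
    T = int(np.ceil((move_time.max() + cfg.post_move_ms) / dt))
    tgrid = np.arange(T) * dt

    # --- noise-free components at unit amplitude
    ci_t = norm.cdf((tgrid - (t_target + 400.0)) / 250.0)  # shared time course
    w_ci = np.abs(rng.normal(size=n))
    w_ci /= np.linalg.norm(w_ci)
    ci_comp = np.broadcast_to(ci_t[None, None, :] * w_ci[None, :, None], (B, n, T))

    axes = _axes_with_gram(n, cfg.axis_alignment, rng)
    env = 1.0 / (1.0 + np.exp(-(tgrid[None, :] - cb_time[:, None] - 150.0) / 80.0))
    signs = {"direction": 2 * direction - 1, "color": 2 * color - 1,
             "target_config": 2 * config - 1}
    comps = {
        v: signs[v][:, None, None] * axes[v][None, :, None] * env[:, None, :]
        for v in VARIABLES
    }

    def elem_var(c):
        grand = c.mean(axis=(0, 2), keepdims=True)  # per-unit grand mean
        return float(((c - grand) ** 2).mean())

    s_ci = elem_var(ci_comp)
    s_v = {v: elem_var(comps[v]) for v in VARIABLES}

    f_axis = {v: cfg.axis_variance.get(v, 0.0) for v in VARIABLES}
    f_noise = 1.0 - cfg.ci_variance_fraction - sum(f_axis.values())
    sigma = cfg.noise_sd
    amp_ci = np.sqrt(cfg.ci_variance_fraction * sigma ** 2 / (f_noise * s_ci))
    amps = {
        v: (np.sqrt(f_axis[v] * sigma ** 2 / (f_noise * s_v[v]))
            if f_axis[v] > 0 and s_v[v] > 0 else 0.0)
        for v in VARIABLES
    }

    signal = amp_ci * ci_comp + sum(amps[v] * comps[v] for v in VARIABLES)
    phi = cfg.slow_noise_fraction
    slow = rng.normal(0, np.sqrt(phi) * sigma, size=(B, n))[:, :, None]
    fast_sd = np.sqrt(1 - phi) * sigma
    if cfg.noise_model == "gaussian":
        rates = signal + slow + rng.normal(0, fast_sd, size=signal.shape)
    else:
        lam = np.maximum(signal + slow + cfg.baseline_rate, 0.0) * (dt / 1000.0)
        rates = rng.poisson(lam) / (dt / 1000.0)

    labels = pd.DataFrame({
        "direction": direction, "color": color, "target_config": config,
        "coherence": coh, "tc_ms": tc, "rt_ms": rt,
    })
    session = Session(rates, dt, labels, t_target, cb_time, move_time)

    # --- oracle quantities
    window = (-300.0, 100.0)
    n_bins = int(round((window[1] - window[0]) / dt))
    env_means = np.empty(B)
    for i in range(B):
        a = max(0, int(round((move_time[i] + window[0]) / dt)))
        b = min(T, int(round((move_time[i] + window[1]) / dt)) + 1)
        env_means[i] = env[i, a:b].mean()
    sigma_feat = sigma * np.sqrt(phi + (1 - phi) / n_bins)
    if cfg.noise_model == "poisson":
        # approximate: Poisson counting noise at the baseline working point
        # plus the slow component
        lam0 = cfg.baseline_rate * (dt / 1000.0)
        fast_var = lam0 / (dt / 1000.0) ** 2 / n_bins
        sigma_feat = np.sqrt(phi * sigma ** 2 + fast_var)
    bayes = {
        v: _bayes_accuracy(v, amps, axes, env_means, sigma_feat, cfg.seed + 17)
        for v in VARIABLES
    }
    chan = {
        v: _channel_information(v, amps, axes, env_means, sigma_feat)
        for v in VARIABLES
    }
    truth = SyntheticGroundTruth(
        axes=axes,
        variance_fractions=dict(f_axis),
        ci_fraction=cfg.ci_variance_fraction,
        noise_fraction=f_noise,
        bayes_accuracy=bayes,
        channel_information=chan,
        amplitudes=amps,
        noise_sd=sigma,
    )
    return session, truth


def calibrate_axis_variance(
    cfg: SyntheticSessionConfig,
    variable: str,
    target_accuracy: float,
    rng: np.random.Generator,
) -> SyntheticSessionConfig:
    """Rescale one variable's planted variance fraction so its Bayes decode
    accuracy lands near ``target_accuracy`` (amplitude scales with the square
    root of the fraction; one probe session measures the realized
    amplitude-to-accuracy map).  The exact accuracy of the resulting session
    is still reported in its ground truth."""
    if not 0.5 < target_accuracy < 1:
        raise ValueError("target accuracy must lie in (0.5, 1)")
    probe = cfg.axis_variance.get(variable, 0.0) or 1e-3
    cfg0 = cfg.with_(axis_variance={**cfg.axis_variance, variable: probe})
    _, truth = generate_session(cfg0, rng)
    acc0 = truth.bayes_accuracy[variable]
    z0 = norm.ppf(min(acc0, 1 - 1e-12))
    z1 = norm.ppf(target_accuracy)
    new = probe * (z1 / max(z0, 1e-9)) ** 2
    return cfg.with_(axis_variance={**cfg.axis_variance, variable: new})


def preset(name: str) -> SyntheticSessionConfig:
    """Named session configurations.

    ``dlpfc_like`` plants direction >> target_config >= color variance with
    an aligned config-color pair (cosine 0.5) and a more orthogonal
    direction axis (cosine 0.2); ``pmd_like`` plants direction only.  Both
    put ~80% of variance in the condition-independent component.
    """
    if name == "dlpfc_like":
        return SyntheticSessionConfig()
    if name == "pmd_like":
        return SyntheticSessionConfig(
            axis_variance={"direction": 0.06, "color": 0.0, "target_config": 0.0},
            axis_alignment={},
        )
    raise ValueError(f"unknown preset {name!r}")
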