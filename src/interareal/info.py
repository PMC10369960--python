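"""Decoding and usable information.

"Usable information" is a variational lower bound on the mutual information
between population activity and a binary task variable Y: a decoder trained
with cross-entropy gives held-out cross-entropy L_CE (in bits), and
I_usable = max(0, H(Y) - L_CE) with H(Y) = 1 bit for balanced labels.  The
bound tightens as the decoder family grows, and is clipped at zero since a
poor decoder can make H(Y) - L_CE negative.

Two decoder families are provided: a small multilayer perceptron (three
hidden layers of 64 rectified units with slope-0.2 leak and dropout 0.5; the
"linear" variant removes the nonlinearity and raises dropout to 0.8) used
for network activity, and a support-vector classifier used per recorded (or
synthetic) session, with trial-shuffle significance testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkParams, iter_chunks, simulate_decide
from .task import CH_LEFT_DV, TaskConfig, generate_batch, sample_conditions

__all__ = [
    "DecodeDataset",
    "InfoReport",
    "MLPDecoder",
    "build_rnn_decode_dataset",
    "train_mlp_decoder",
    "decode_variable",
    "usable_information",
    "binary_entropy",
    "svm_session_decode",
    "shuffle_significance",
]

VARIABLES = ("direction", "color", "target_config")


def usable_information(l_ce: float, h_y: float = 1.0) -> float:
    """Variational mutual-information lower bound max(0, H(Y) - L_CE), bits."""
    if l_ce < -1e-9:
        raise ValueError("cross-entropy cannot be negative")
    return max(0.0, h_y - max(0.0, l_ce))


def binary_entropy(p: float) -> float:
    """Entropy in bits of a Bernoulli(p) variable."""
    if p <= 0 or p >= 1:
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


@dataclass
class DecodeDataset:
    """Window-averaged trial features with binary labels and a fixed split."""

    features: np.ndarray          # (trials, units)
    labels: dict                  # variable -> (trials,) int array in {0, 1}
    train_idx: np.ndarray
    test_idx: np.ndarray
    window_ms: tuple = (-300.0, 100.0)
    n_dropped: int = 0            # trials excluded for lacking an RT

    def split(self, variable: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        y = self.labels[variable]
        return (self.features[self.train_idx], y[self.train_idx],
                self.features[self.test_idx], y[self.test_idx])


def build_rnn_decode_dataset(
    params: NetworkParams,
    task_cfg: TaskConfig,
    rng: np.random.Generator,
    n_train: int = 700,
    n_test: int = 2100,
    rec_noise_sd: float = 0.1,
    window_ms: tuple = (-300.0, 100.0),
    threshold: float = 0.6,
    chunk: int = 200,
) -> DecodeDataset:
    """Simulate decode trials and extract RT-aligned window-averaged rates.

    Trials are balanced over the 28 conditions and simulated with the
    recurrent noise SD raised to ``rec_noise_sd`` (which counteracts decoder
    overfitting); features are per-unit rates averaged over ``window_ms``
    around each trial's threshold-crossing reaction time.  Trials that never
    cross the threshold have no RT and are dropped (counted in
    ``n_dropped``).  Labels: direction = choice side, color = chosen
    target's color, target_config = trial configuration.
    """
    n_total = n_train + n_test
    n_per = int(np.ceil(n_total / task_cfg.n_conditions))
    conds = sample_conditions(n_per, task_cfg, rng)[:n_total]
    dt = task_cfg.dt
    lo = int(round(window_ms[0] / dt))
    hi = int(round(window_ms[1] / dt))

    feats, direction, color, config = [], [], [], []
    dropped = 0
    for sl in iter_chunks(len(conds), chunk):
        sub = conds[sl.start:sl.stop]
        batch = generate_batch(sub, task_cfg, rng)
        res = simulate_decide(params, batch, rng, rec_noise_sd, threshold, store="r")
        for i, c in enumerate(sub):
            if res.criterion[i] != "threshold":
                dropped += 1
                continue
            t_rt = int(batch.decision_onset[i]) + int(round(res.rt[i] / dt))
            a = max(0, t_rt + lo)
            b = min(int(batch.epoch_bounds[i, 4]), t_rt + hi)
            feats.append(res.r[i, a:b].mean(axis=0))
            right = int(res.choice[i]) != CH_LEFT_DV
            left_red = c.target_config == "left_red"
            chosen_red = left_red != right  # chose-left & left-red, or chose-right & right-red
            direction.append(int(right))
            color.append(int(chosen_red))
            config.append(int(left_red))
    X = np.asarray(feats)
    n_kept = X.shape[0]
    n_tr = min(n_train, n_kept)
    perm = rng.permutation(n_kept)
    return DecodeDataset(
        features=X,
        labels={"direction": np.asarray(direction), "color": np.asarray(color),
                "target_config": np.asarray(config)},
        train_idx=perm[:n_tr],
        test_idx=perm[n_tr:n_tr + n_test],
        window_ms=window_ms,
        n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# MLP decoder (numpy)

def _leaky(x, alpha):
    return np.where(x > 0, x, alpha * x)


def _leaky_grad(x, alpha):
    return np.where(x > 0, 1.0, alpha)


class MLPDecoder:
    """Small dropout-regularized MLP classifier trained with cross-entropy.

    Nonlinear variant: three hidden layers of 64 units, leaky-rectifier
    slope 0.2, dropout 0.5.  Linear variant: same shape without activation
    functions and dropout 0.8.  Adam on minibatches; the kept parameters are
    those of the epoch with the lowest validation cross-entropy.
    """

    def __init__(self, n_in: int, variant: str = "nonlinear",
                 hidden: int = 64, n_layers: int = 3, seed: int = 0):
        if variant not in ("nonlinear", "linear"):
            raise ValueError("variant must be 'nonlinear' or 'linear'")
        self.variant = variant
        self.alpha = 0.2
        self.dropout = 0.5 if variant == "nonlinear" else 0.8
        rng = np.random.default_rng(seed)
        dims = [n_in] + [hidden] * n_layers + [2]
        self.W = [rng.normal(0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
                  for d_in, d_out in zip(dims[:-1], dims[1:])]
        self.b = [np.zeros(d) for d in dims[1:]]
        self.mu = np.zeros(n_in)
        self.sd = np.ones(n_in)

    def _forward(self, X, rng=None):
        """Returns (logits, cache).  Dropout is active iff rng is given."""
        h = X
        cache = []
        L = len(self.W)
        for i in range(L):
            pre = h @ self.W[i] + self.b[i]
            if i < L - 1:
                act = _leaky(pre, self.alpha) if self.variant == "nonlinear" else pre
                if rng is not None and self.dropout > 0:
                    keep = (rng.random(act.shape) >= self.dropout)
                    act = act * keep / (1.0 - self.dropout)
                else:
                    keep = None
                cache.append((h, pre, keep))
                h = act
            else:
                cache.append((h, pre, None))
        return pre, cache

    @staticmethod
    def _softmax(logits):
        m = logits.max(axis=1, keepdims=True)
        e = np.exp(logits - m)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward((X - self.mu) / self.sd)
        return self._softmax(logits)

    def cross_entropy_bits(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(X)
        eps = 1e-12
        ce = float(-np.mean(np.log2(p[np.arange(len(y)), y] + eps)))
        return max(0.0, ce)  # guard the -log2(1 + eps) rounding artifact

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict_proba(X).argmax(axis=1) == y).mean())

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        rng: np.random.Generator,
        epochs: int = 200,
        batch_size: int = 64,
        lr: float = 1e-3,
        val_fraction: float = 0.15,
    ) -> "MLPDecoder":
        self.mu = X.mean(axis=0)
        self.sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = (X - self.mu) / self.sd
        n = len(y)
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        val, tr = perm[:n_val], perm[n_val:]
        Xtr, ytr, Xval, yval = Xs[tr], y[tr], Xs[val], y[val]

        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(bb) for bb in self.b]
        vb = [np.zeros_like(bb) for bb in self.b]
        t = 0
        best_ce = np.inf
        best = None
        b1, b2, eps = 0.9, 0.999, 1e-8
        for _ in range(epochs):
            order = rng.permutation(len(ytr))
            for start in range(0, len(ytr), batch_size):
                idx = order[start:start + batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                logits, cache = self._forward(xb, rng=rng)
                p = self._softmax(logits)
                g = p.copy()
                g[np.arange(len(yb)), yb] -= 1.0
                g /= len(yb)  # dCE(nats)/dlogits
                t += 1
                grad_next = g
                for i in range(len(self.W) - 1, -1, -1):
                    h_in, pre, keep = cache[i]
                    gW = h_in.T @ grad_next
                    gb = grad_next.sum(axis=0)
                    if i > 0:
                        gh = grad_next @ self.W[i].T
                        _, pre_prev, keep_prev = cache[i - 1]
                        if keep_prev is not None:
                            gh = gh * keep_prev / (1.0 - self.dropout)
                        if self.variant == "nonlinear":
                            gh = gh * _leaky_grad(pre_prev, self.alpha)
                        grad_next = gh
                    for store_m, store_v, grad, param in (
                        (mW, vW, gW, self.W), (mb, vb, gb, self.b),
                    ):
                        store_m[i] = b1 * store_m[i] + (1 - b1) * grad
                        store_v[i] = b2 * store_v[i] + (1 - b2) * grad * grad
                        mh = store_m[i] / (1 - b1 ** t)
                        vh = store_v[i] / (1 - b2 ** t)
                        param[i] -= lr * mh / (np.sqrt(vh) + eps)
            logits, _ = self._forward(Xval)
            pv = self._softmax(logits)
            ce = float(-np.mean(np.log2(pv[np.arange(len(yval)), yval] + 1e-12)))
            if ce < best_ce:
                best_ce = ce
                best = ([w.copy() for w in self.W], [bb.copy() for bb in self.b])
        if best is not None:
            self.W, self.b = best
        return self


@dataclass
class InfoReport:
    """Decode accuracy and usable information for one variable."""

    variable: str
    accuracy: float
    cross_entropy_bits: float
    usable_bits: float
    h_y: float = 1.0
    shuffle_p99: float | None = None
    significant: bool | None = None


def train_mlp_decoder(
    ds: DecodeDataset,
    variable: str,
    rng: np.random.Generator,
    variant: str = "nonlinear",
    epochs: int = 200,
    unit_index: np.ndarray | None = None,
) -> tuple[MLPDecoder, InfoReport]:
    """Fit the MLP decoder for one variable and report held-out accuracy,
    cross-entropy (bits) and usable information."""
    Xtr, ytr, Xte, yte = ds.split(variable)
    if unit_index is not None:
        Xtr, Xte = Xtr[:, unit_index], Xte[:, unit_index]
    classes = np.unique(ytr)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must be binary {0, 1} with both classes present")
    model = MLPDecoder(Xtr.shape[1], variant, seed=int(rng.integers(2 ** 31)))
    model.fit(Xtr, ytr, rng, epochs=epochs)
    ce = model.cross_entropy_bits(Xte, yte)
    acc = model.accuracy(Xte, yte)
    p1 = float(np.mean(np.concatenate([ytr, yte])))
    h_y = binary_entropy(p1)
    return model, InfoReport(variable, acc, ce, usable_information(ce, h_y), h_y)


def decode_variable(
    ds: DecodeDataset,
    variable: str,
    rng: np.random.Generator,
    unit_index: np.ndarray | None = None,
    **kwargs,
) -> InfoReport:
    """Convenience wrapper returning only the report."""
    _, report = train_mlp_decoder(ds, variable, rng, unit_index=unit_index, **kwargs)
    return report


# ---------------------------------------------------------------------------
# session-level SVM decoding with shuffle significance

def session_features(session, window_ms: tuple = (-300.0, 100.0)) -> np.ndarray:
    """Per-trial rates averaged in a movement-aligned window (trials, units)."""
    dt = session.dt
    B, n, T = session.rates.shape
    feats = np.empty((B, n))
    for i in range(B):
        m = session.move_time[i]
        a = max(0, int(round((m + window_ms[0]) / dt)))
        b = min(T, int(round((m + window_ms[1]) / dt)) + 1)
        feats[i] = session.rates[i, :, a:b].mean(axis=1)
    return feats


def svm_session_decode(
    session,
    variable: str,
    rng: np.random.Generator,
    kernel: str = "rbf",
    test_fraction: float = 0.2,
    labels: np.ndarray | None = None,
) -> float:
    """Support-vector decode accuracy for one session and variable.

    Features are movement-aligned 400 ms window averages; an 80/20
    train/test split is drawn with the supplied rng.
    """
    from sklearn.svm import SVC

    X = session_features(session)
    y = np.asarray(session.labels[variable]) if labels is None else np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("session has a single label class")
    n = len(y)
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test, train = perm[:n_test], perm[n_test:]
    clf = SVC(kernel=kernel)
    clf.fit(X[train], y[train])
    return float((clf.predict(X[test]) == y[test]).mean())


def shuffle_significance(
    session,
    variable: str,
    rng: np.random.Generator,
    n_shuffles: int = 100,
    percentile: float = 99.0,
    kernel: str = "rbf",
) -> dict:
    """Trial-shuffle significance of a session's decode accuracy.

    The labels are permuted across trials ``n_shuffles`` times; the true
    accuracy is deemed significant if it exceeds the given percentile of
    the null accuracies.
    """
    true_acc = svm_session_decode(session, variable, rng, kernel=kernel)
    y = np.asarray(session.labels[variable])
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        null[k] = svm_session_decode(session, variable, rng, kernel=kernel,
                                     labels=rng.permutation(y))
    thresh = float(np.percentile(null, percentile))
    return {
        "true_accuracy": true_acc,
        "null": null,
        "threshold": thresh,
        "significant": bool(true_acc > thresh),
    }
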