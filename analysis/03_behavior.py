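"""Psychometric and chronometric behavior of a trained exemplar.

Reads results/exemplar_seed<k>/checkpoint.npz, simulates 200 trials per
condition, and writes results/behavior_seed<k>.csv.

Finding: the proportion of red choices rises monotonically with signed
coherence, mean RT falls with |coherence|, and endpoint-criterion (never
crossing threshold) decisions are rare.
"""

import sys
from pathlib import Path

import numpy as np

from interareal.network import behavior_curves, load_params
from interareal.task import TaskConfig

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0, n_per_condition: int = 200) -> None:
    ckpt = OUT / f"exemplar_seed{seed}" / "checkpoint.npz"
    params = load_params(ckpt)
    rng = np.random.default_rng(seed + 10_000)
    df = behavior_curves(params, TaskConfig(), n_per_condition, rng)
    df.to_csv(OUT / f"behavior_seed{seed}.csv", index=False)
    ez = df.loc[df.coherence.abs() > 0.7, "mean_rt"].mean()
    hard = df.loc[df.coherence.abs() < 0.2, "mean_rt"].mean()
    print(f"endpoint fraction {df.attrs['endpoint_fraction']:.4f}; "
          f"mean RT easy {ez:.0f} ms vs hard {hard:.0f} ms; "
          f"p(red) at +/-0.9: {df.p_red.iloc[-1]:.2f} / {df.p_red.iloc[0]:.2f}")


if __name__ == "__main__":
    main(*(int(a) for a in sys.argv[1:3]))
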