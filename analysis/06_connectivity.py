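"""Potent/null alignment of task axes with recurrent and inter-areal
weights of a trained exemplar.

Writes results/projections_seed<k>.csv (potent squared projection vs.
subspace dimension m for the direction axis, color axis and a 100-vector
random baseline, for each area's recurrent block and each feedforward E->E
matrix).

Finding: the direction axis aligns with the top right singular vectors of
the first inter-areal matrix well above the m/d chance line while the color
axis tracks the random baseline — direction information is preferentially
propagated, color information is passed only at chance ("propagate", not
"attenuate").
"""

import sys
from pathlib import Path

import numpy as np

from interareal.analyses import projection_report, rnn_condition_tensor
from interareal.network import load_params
from interareal.task import TaskConfig

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0, n_per_condition: int = 25) -> None:
    params = load_params(OUT / f"exemplar_seed{seed}" / "checkpoint.npz")
    rng = np.random.default_rng(seed + 40_000)
    X, _ = rnn_condition_tensor(params, TaskConfig(), rng, n_per_condition)
    prof = projection_report(params, X, rng)
    prof.to_csv(OUT / f"projections_seed{seed}.csv", index=False)
    w21 = prof[prof.matrix == "W21"]
    d = w21.m.max()
    p1 = {ax: float(w21[(w21.axis == ax) & (w21.m == 1)].potent_sq_norm.iloc[0])
          for ax in ("direction", "color", "random")}
    print(f"W21 potent(1): direction {p1['direction']:.3f}, color "
          f"{p1['color']:.3f}, random baseline {p1['random']:.3f} (m/d = {1/d:.3f})")


if __name__ == "__main__":
    main(*(int(a) for a in sys.argv[1:3]))
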