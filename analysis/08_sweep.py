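"""Reduced architecture/hyperparameter sweep over the information
bottleneck.

Trains networks over a small grid (number of areas 1-4; feedforward E->I
density 0 vs 0.05; Dale on/off) at a reduced seed count and records the
final area's color/direction dPCA variance, decode accuracy and usable
information.  Writes results/sweep/sweep.csv.

Finding: with 3 or more areas and a feedforward connection bottleneck the
final area loses color information; single-area networks keep color well
above chance.

This is the heaviest driver (each cell trains a network); the default grid
and 2 seeds per cell take a few hours on one CPU.  Pass a JSON grid file to
customize.
"""

import json
import sys
from pathlib import Path

from interareal.pipeline import reduced_exemplar_manifest, run_sweep

OUT = Path(__file__).resolve().parents[1] / "results"

DEFAULT_GRID = [
    {"architecture.n_areas": 1},
    {"architecture.n_areas": 2},
    {"architecture.n_areas": 3},
    {"architecture.n_areas": 4, "architecture.n_units": 88},
    {"architecture.ff_ei_density": 0.05},
    {"architecture.dale": False},
]


def main(seed: int = 0, seeds_per_cell: int = 2, grid_path: str | None = None) -> None:
    grid = (json.loads(Path(grid_path).read_text()) if grid_path
            else DEFAULT_GRID)
    manifest = reduced_exemplar_manifest(seed=seed, n_units=90, max_epochs=8000)
    df = run_sweep(OUT / "sweep", grid, manifest,
                   seeds_per_cell=seeds_per_cell, verbose=True)
    print(df[["cell", "seed", "converged", "final_color_accuracy",
              "final_color_usable_bits"]].to_string(index=False))


if __name__ == "__main__":
    args = sys.argv[1:]
    main(int(args[0]) if args else 0,
         int(args[1]) if len(args) > 1 else 2,
         args[2] if len(args) > 2 else None)
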