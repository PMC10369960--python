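"""Run orchestration: manifests, the full train-and-analyze pipeline, and
the architecture/hyperparameter sweep driver.

A run directory contains ``manifest.json`` (all configurations, seeds and
artifact paths — sufficient to regenerate every number in the reports), an
NPZ checkpoint, and CSV reports for each analysis stage.  All stage seeds
are spawned deterministically from the manifest seed, so re-running an
identical manifest reproduces identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np

from .analyses import AnalysisSizes, exemplar_report
from .network import ArchitectureConfig, load_params, save_params
from .task import TaskConfig
from .training import LossConfig, ValidationPolicy, train

__all__ = ["make_manifest", "reduced_exemplar_manifest", "run_pipeline", "run_sweep"]

VARIABLES = ("direction", "color", "target_config")


def _cfg_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def make_manifest(
    seed: int,
    task: TaskConfig,
    arch: ArchitectureConfig,
    loss: LossConfig,
    val: ValidationPolicy,
    sizes: AnalysisSizes,
    max_epochs: int,
    batch_size: int,
    post_criterion_epochs: int = 0,
) -> dict:
    from . import __version__

    return {
        "run_id": f"run-seed{seed}",
        "seed": seed,
        "task": _cfg_dict(task),
        "architecture": _cfg_dict(arch),
        "loss": _cfg_dict(loss),
        "validation": _cfg_dict(val),
        "analysis_sizes": _cfg_dict(sizes),
        "max_epochs": max_epochs,
        "batch_size": batch_size,
        "post_criterion_epochs": post_criterion_epochs,
        "version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def reduced_exemplar_manifest(
    seed: int = 0,
    n_units: int = 90,
    max_epochs: int = 9000,
    post_criterion_epochs: int = 1600,
    n_val_trials: int = 560,
    learning_rate: float = 2e-4,
    sizes: AnalysisSizes | None = None,
) -> dict:
    """Desk-scale exemplar: the full task and training protocol with a
    smaller 3-area Dale network (default 30 units per area), a reduced
    validation set, a learning rate scaled up for the smaller problem, and
    continued optimization past the bilateral criterion (which is "at
    least 65%") — trainable on one CPU in minutes."""
    return make_manifest(
        seed=seed,
        task=TaskConfig(),
        arch=ArchitectureConfig(n_units=n_units, n_areas=3),
        loss=LossConfig(learning_rate=learning_rate),
        val=ValidationPolicy(interval_epochs=200, n_val_trials=n_val_trials),
        sizes=sizes or AnalysisSizes(),
        max_epochs=max_epochs,
        batch_size=64,
        post_criterion_epochs=post_criterion_epochs,
    )


def _rebuild(manifest: dict):
    def tup(d, keys):
        return {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}

    task = TaskConfig(**tup(manifest["task"], None))
    arch = ArchitectureConfig(**manifest["architecture"])
    loss = LossConfig(**manifest["loss"])
    val = ValidationPolicy(**manifest["validation"])
    sizes = AnalysisSizes(**tup(manifest["analysis_sizes"], None))
    return task, arch, loss, val, sizes


def run_pipeline(
    outdir,
    manifest: dict,
    analysis_only: bool = False,
    verbose: bool = False,
) -> dict:
    """Execute train -> behavior -> dPCA -> decode/info -> projections -> CCA.

    Writes all artifacts under ``outdir``; with ``analysis_only`` an
    existing checkpoint is reused (missing checkpoint raises).  Returns the
    in-memory report dict.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    task, arch, loss, val, sizes = _rebuild(manifest)
    seed = int(manifest["seed"])
    ss = np.random.SeedSequence(seed)
    train_rng, analysis_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    ckpt = outdir / "checkpoint.npz"
    manifest = dict(manifest)
    manifest["artifacts"] = {
        "checkpoint": ckpt.name,
        "training_log": "training_log.csv",
        "behavior": "behavior.csv",
        "dpca_variance": "dpca_variance.csv",
        "dpca_overlap": "dpca_overlap.csv",
        "info": "info.csv",
        "projections": "projections.csv",
        "cca": "cca.csv",
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if analysis_only:
        if not ckpt.exists():
            raise FileNotFoundError(f"analysis-only run requires {ckpt}")
        params = load_params(ckpt)
        converged = None
    else:
        result = train(arch, task, loss, val, train_rng,
                       max_epochs=int(manifest["max_epochs"]),
                       batch_size=int(manifest["batch_size"]),
                       post_criterion_epochs=int(manifest.get(
                           "post_criterion_epochs", 0)),
                       verbose=verbose)
        params = result.params
        converged = result.converged
        save_params(ckpt, params, seed=seed)
        pd.DataFrame(result.log).to_csv(outdir / "training_log.csv", index=False)

    report = exemplar_report(params, task, analysis_rng, sizes)
    report["converged"] = converged

    report["behavior"].to_csv(outdir / "behavior.csv", index=False)
    rows_v, rows_o = [], []
    for area, rep in report["dpca"].items():
        for marg, var in rep["variance"].items():
            rows_v.append({"area": area, "marginal": marg, "variance_captured": var})
        for pair, ov in rep["overlap"].items():
            rows_o.append({"area": area, "pair": pair, "overlap": ov})
    pd.DataFrame(rows_v).to_csv(outdir / "dpca_variance.csv", index=False)
    pd.DataFrame(rows_o).to_csv(outdir / "dpca_overlap.csv", index=False)
    rows = []
    for area, reps in report["info"].items():
        for v, r in reps.items():
            rows.append({"area": area, "variable": v, "accuracy": r.accuracy,
                         "cross_entropy_bits": r.cross_entropy_bits,
                         "usable_bits": r.usable_bits})
    pd.DataFrame(rows).to_csv(outdir / "info.csv", index=False)
    report["projections"].to_csv(outdir / "projections.csv", index=False)
    pd.DataFrame(
        [{"pair": k, "mean_cca": v} for k, v in report["cca"].items()]
    ).to_csv(outdir / "cca.csv", index=False)
    return report


def run_sweep(
    outdir,
    grid: list[dict],
    base_manifest: dict,
    seeds_per_cell: int = 3,
    verbose: bool = False,
):
    """Architecture/hyperparameter sweep over the information bottleneck.

    ``grid`` lists cells of overrides, e.g. ``{"architecture.n_areas": 1}``
    or ``{"loss.learning_rate": 1e-4}``.  Per cell and seed the network is
    trained and the final area's color/direction dPCA variance, decode
    accuracy and usable information are recorded.  Non-convergent cells are
    recorded, not fatal.  Returns (and writes) a tidy summary DataFrame.
    """
    import pandas as pd

    from .analyses import area_dpca_report, rnn_condition_tensor
    from .info import build_rnn_decode_dataset, decode_variable

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cell_id, overrides in enumerate(grid):
        manifest = json.loads(json.dumps(base_manifest))  # deep copy
        for key, value in overrides.items():
            section, name = key.split(".")
            manifest[section][name] = value
        for s in range(seeds_per_cell):
            cell_seed = int(manifest["seed"]) + 1000 * cell_id + s
            manifest["seed"] = cell_seed
            task, arch, loss, val, sizes = _rebuild(manifest)
            ss = np.random.SeedSequence(cell_seed)
            train_rng, analysis_rng = (np.random.default_rng(x) for x in ss.spawn(2))
            result = train(arch, task, loss, val, train_rng,
                           max_epochs=int(manifest["max_epochs"]),
                           batch_size=int(manifest["batch_size"]))
            row = {"cell": cell_id, **overrides, "seed": cell_seed,
                   "converged": result.converged, "epochs": result.n_epochs}
            X, _ = rnn_condition_tensor(result.params, task, analysis_rng,
                                        sizes.n_tensor_per_condition)
            dp = area_dpca_report(result.params, X)
            last = f"area{arch.n_areas}"
            row["final_color_variance"] = dp[last]["variance"]["color"]
            row["final_direction_variance"] = dp[last]["variance"]["direction"]
            ds = build_rnn_decode_dataset(
                result.params, task, analysis_rng,
                n_train=sizes.n_decode_train, n_test=sizes.n_decode_test,
                rec_noise_sd=sizes.decode_noise_sd)
            idx = np.arange(*arch.area_slice(arch.n_areas - 1).indices(arch.n_units)[:2])
            for v in ("color", "direction"):
                rep = decode_variable(ds, v, analysis_rng, unit_index=idx,
                                      epochs=sizes.decoder_epochs)
                row[f"final_{v}_accuracy"] = rep.accuracy
                row[f"final_{v}_usable_bits"] = rep.usable_bits
            rows.append(row)
            if verbose:
                print(row)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "sweep.csv", index=False)
    return df
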