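"""End-to-end workflow: generate/ingest data, train the surrogate, run a
design campaign, re-simulate the designs, retrain.

Every stage is a plain function over the library types so it can be driven
from Python, from the thin CLI, or from the active-learning loop.  Each
output directory receives a JSON manifest (config + seeds) sufficient to
reproduce it bit-exactly; no stage ever invokes an external simulation
binary — re-simulation goes through the synthetic world, and real
trajectory data enters only through files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    ALPHABET,
    CaTrace,
    build_features,
    distance_matrix,
    frenet_features,
    graph_laplacian,
    soft_adjacency,
)
from .optimizer import (
    DesignConfig,
    SurrogateObjective,
    batch_design,
    count_mutations,
    start_matrix,
)
from .surrogate import (
    LabeledExample,
    SurrogateModel,
    TrainConfig,
    init_model,
    predict_design_metrics,
    standardize_targets,
    train,
    validation_relative_error,
)
from .synthetic import SyntheticDataset, SyntheticWorld, make_dataset, simulate_trajectory
from .trajectory import summarize

log = logging.getLogger("pinndesign")


@dataclass
class RunConfig:
    """One reproducible run: world + training + design settings."""

    n_designs: int = 300
    n_residues: int = 25
    frames: int = 50
    target_kind: str = "random_smooth"
    kernel_scale: float = 8.0
    width: int = 64
    depth: int = 5
    train: TrainConfig = field(default_factory=TrainConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    n_starts: int = 50
    active_rounds: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        # JSON round-trip normalizes tuples to lists for YAML/JSON dumps
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("train"), dict):
            d["train"] = TrainConfig(**d["train"])
        if isinstance(d.get("design"), dict):
            d["design"] = DesignConfig(**d["design"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def target_operators(target: CaTrace, kernel_scale: float = 8.0):
    """Geometric rows and Laplacian of a target structure (fixed per design)."""
    geo = frenet_features(target)
    feats = build_features(target, geo)
    geo_rows = feats[len(ALPHABET):]
    lap = graph_laplacian(
        soft_adjacency(distance_matrix(target), kernel_scale), kernel_scale
    )
    return geo_rows, lap


def dataset_to_examples(dataset: SyntheticDataset, kernel_scale: float = 8.0) -> list:
    """Turn generated (trace, trajectory, summary) triples into training examples."""
    geo_rows, lap = target_operators(dataset.target, kernel_scale)
    examples = []
    for trace, _traj, summ in dataset.entries:
        feats = build_features(trace)
        examples.append(
            LabeledExample(
                features=feats, laplacian=lap, targets=summ.targets(), id=trace.id
            )
        )
    return examples


def _write_manifest(out_dir: Path, config: RunConfig, extra: dict) -> None:
    manifest = {"config": config.to_dict(), "config_hash": config.config_hash()}
    manifest.update(extra)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def run_train(
    config: RunConfig,
    out_dir=None,
    dataset: SyntheticDataset | None = None,
    world: SyntheticWorld | None = None,
):
    """Generate (or accept) a dataset and fit the surrogate.

    Returns ``(model, history, dataset, world)``; if ``out_dir`` is given,
    writes the checkpoint, the per-epoch loss curve (CSV) and a manifest.
    """
    t0 = time.time()
    if world is None:
        world = SyntheticWorld.from_seed(config.seed, kernel_scale=config.kernel_scale)
    if dataset is None:
        dataset = make_dataset(
            config.n_designs,
            config.n_residues,
            world,
            frames=config.frames,
            seed=config.seed,
            target_kind=config.target_kind,
        )
    examples = dataset_to_examples(dataset, config.kernel_scale)
    std_examples, stats = standardize_targets(examples)
    model = init_model(
        in_channels=examples[0].features.shape[0],
        width=config.width,
        depth=config.depth,
        seed=config.train.seed,
    )
    model.norm_stats = stats
    model, history = train(model, std_examples, config.train)
    rel = validation_relative_error(model, std_examples)
    log.info(
        "trained surrogate in %.1fs: final val loss %.3g, rel err (energy, rmsd) = (%.3g, %.3g)",
        time.time() - t0,
        history.val_loss[-1],
        rel[0],
        rel[1],
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        model.save(out_dir / "model.ckpt.npz")
        history.to_frame().to_csv(out_dir / "loss_curve.csv", index=False)
        dataset.save_manifest(out_dir / "dataset_manifest.json")
        _write_manifest(
            out_dir,
            config,
            {"stage": "train", "seed": config.train.seed, "final_val_loss": history.val_loss[-1]},
        )
    return model, history, dataset, world


def select_starts(
    model: SurrogateModel, dataset: SyntheticDataset, m: int, kernel_scale: float = 8.0
) -> list:
    """Pick the best ``m`` starting sequences by predicted total energy."""
    import warnings

    geo_rows, lap = target_operators(dataset.target, kernel_scale)
    scored = []
    for trace, _t, _s in dataset.entries:
        S = start_matrix(trace.sequence)
        e, _, _ = predict_design_metrics(model, S, geo_rows, lap)
        scored.append((e, trace.sequence))
    scored.sort(key=lambda p: p[0])
    if m > len(scored):
        warnings.warn(
            f"requested {m} starts but only {len(scored)} available", stacklevel=2
        )
        m = len(scored)
    return [seq for _, seq in scored[:m]]


def run_design(
    config: RunConfig,
    model: SurrogateModel,
    dataset: SyntheticDataset,
    out_dir=None,
):
    """Select the best starts and run the batch design campaign.

    Returns ``(results, start_sequences)``; optionally writes designed
    sequences (FASTA), per-design traces (CSV) and the run manifest with
    termination reasons and the campaign mutation total.
    """
    starts = select_starts(model, dataset, config.n_starts, config.kernel_scale)
    geo_rows, lap = target_operators(dataset.target, config.kernel_scale)
    objective = SurrogateObjective(model, geo_rows, lap, config.design)
    results = batch_design([start_matrix(s) for s in starts], objective, config.design)
    total = sum(r.mutations for r in results)
    log.info(
        "designed %d sequences: %d total mutations (mean %.2f)",
        len(results),
        total,
        total / len(results),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .io import write_fasta

        write_fasta(
            {f"design_{i}": r.sequence for i, r in enumerate(results)},
            out_dir / "designs.fasta",
        )
        import pandas as pd

        rows = []
        for i, r in enumerate(results):
            for it, (e, mu) in enumerate(zip(r.energy_trace, r.mutation_trace)):
                rows.append(
                    {
                        "design": i,
                        "iteration": it,
                        "objective": e,
                        "stability": r.stability_trace[it] if r.stability_trace else np.nan,
                        "mutations": mu,
                    }
                )
        pd.DataFrame(rows).to_csv(out_dir / "traces.csv", index=False)
        _write_manifest(
            out_dir,
            config,
            {
                "stage": "design",
                "seed": config.design.seed,
                "total_mutations": total,
                "terminations": [r.termination for r in results],
            },
        )
    return results, starts


def resimulate(
    sequences: list,
    dataset: SyntheticDataset,
    world: SyntheticWorld,
    seed: int,
):
    """Synthetic re-simulation of designed sequences against the same target."""
    rng = np.random.default_rng(seed)
    entries = []
    for i, seq in enumerate(sequences):
        sim_seed = int(rng.integers(0, 2**31 - 1))
        traj = simulate_trajectory(
            seq, dataset.target, world, frames=dataset.frames, seed=sim_seed
        )
        summ = summarize(traj, dataset.target)
        trace = CaTrace(sequence=seq, coords=dataset.target.coords, id=f"resim-{i}")
        entries.append((trace, traj, summ))
    return entries


def run_active_loop(config: RunConfig, rounds: int | None = None, out_dir=None):
    """Alternate design, synthetic re-simulation, and cumulative retraining.

    Each round appends the re-simulated designs to the training corpus and
    retrains from the same initialization seed; ``rounds=0`` reduces to a
    single :func:`run_train`.  Returns ``(model, dataset, per_round_log)``.
    """
    rounds = config.active_rounds if rounds is None else rounds
    model, history, dataset, world = run_train(config, out_dir=out_dir)
    round_log = [{"round": 0, "n_examples": len(dataset), "val_loss": history.val_loss[-1]}]
    for rnd in range(1, rounds + 1):
        try:
            results, _ = run_design(config, model, dataset)
            new_entries = resimulate(
                [r.sequence for r in results], dataset, world, seed=config.seed + rnd
            )
            dataset = SyntheticDataset(
                entries=dataset.entries + new_entries,
                target=dataset.target,
                world=world,
                seed=config.seed,
                frames=dataset.frames,
            )
            model, history, _, _ = run_train(config, dataset=dataset, world=world)
        except Exception:
            log.exception("active-learning round %d aborted; keeping prior model", rnd)
            break
        round_log.append(
            {"round": rnd, "n_examples": len(dataset), "val_loss": history.val_loss[-1]}
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "active_loop.json", "w") as fh:
            json.dump(round_log, fh, indent=1)
    return model, dataset, round_log
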