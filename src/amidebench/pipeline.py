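"""End-to-end orchestration: generate -> augment -> featurize -> benchmark ->
stack -> cliff audit, with a manifest that makes every artifact re-derivable.

The configuration is one document (YAML or JSON) with per-stage sections;
its SHA-256 over the canonical JSON serialization is recorded in the
manifest together with package and library versions, so a run directory can
be reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benchmark import (
    ModelSpec,
    SplitPlan,
    StackSpec,
    evaluate,
    make_splits,
    run_benchmark,
    stack_fit_predict,
)
from .cliffs import find_cliffs, find_uncertain, remove_and_reevaluate
from .core import ReactionDataset, write_reaction_table
from .features import ReactionFeaturizer
from .mechanism import annotate_reaction_centers, make_o_acylisourea
from .synthetic import GeneratorConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "augment_dataset", "config_hash"]

STAGES = ("generate", "augment", "featurize", "benchmark", "stack", "cliffs")


class ConfigError(ValueError):
    """Raised before any compute when the configuration is invalid."""


@dataclass
class PipelineConfig:
    """Single source of truth for one pipeline run."""

    seed: int = 0
    generator: dict = field(default_factory=dict)
    blocks: list[str] = field(
        default_factory=lambda: ["fingerprint", "battery2d", "aev", "qm"]
    )
    models: list[str] = field(default_factory=lambda: ["mean_baseline", "ridge"])
    n_splits: int = 5
    train_fraction: float = 0.9
    include_context: bool = False
    variance_threshold: float = 0.0
    sim_threshold: float = 0.9
    yield_gap: float = 30.0
    uncertain_tolerance: float = 0.0
    with_intermediates: bool = False

    _KNOWN = {
        "seed", "generator", "blocks", "models", "n_splits", "train_fraction",
        "include_context", "variance_threshold", "sim_threshold", "yield_gap",
        "uncertain_tolerance", "with_intermediates",
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - cls._KNOWN
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**data)
            # fail fast on bad generator keys too
            GeneratorConfig(**{**cfg.generator, "seed": cfg.seed})
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def augment_dataset(dataset: ReactionDataset) -> pd.DataFrame:
    """Mechanism augmentation table: intermediate SMILES + center indices.

    Center atom indices refer to canonical atom order and are ';'-joined.
    """
    rows = []
    for rec in dataset.records:
        inter = make_o_acylisourea(rec.acid, rec.coupling_agent)
        centers = annotate_reaction_centers(rec.acid, rec.amine, rec.product)
        rows.append(
            {
                "reaction_id": rec.reaction_id,
                "intermediate_smiles": inter.smiles,
                "acid_centers": ";".join(map(str, sorted(centers.acid_atoms))),
                "amine_centers": ";".join(map(str, sorted(centers.amine_atoms))),
                "product_centers": ";".join(map(str, sorted(centers.product_atoms))),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir: "str | Path") -> Path:
    """Execute all stages, writing artifacts and a manifest to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "version": __version__,
        "stages": [],
    }

    def record_stage(name: str, t0: float, **info) -> None:
        manifest["stages"].append(
            {"stage": name, "seconds": round(time.time() - t0, 2), **info}
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    # generate -------------------------------------------------------------
    t0 = time.time()
    gen_cfg = GeneratorConfig(**{**config.generator, "seed": config.seed})
    dataset, truth = generate_dataset(gen_cfg)
    write_reaction_table(dataset, out / "reactions.csv")
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "cliff_pairs": truth.cliff_pairs,
                "uncertain_groups": truth.uncertain_groups,
                "latent_yield": truth.latent_yield,
                "latent_variance": truth.latent_variance,
            },
            indent=2,
        )
    )
    record_stage("generate", t0, n_reactions=len(dataset))

    # augment ---------------------------------------------------------------
    t0 = time.time()
    if config.with_intermediates:
        augment_dataset(dataset).to_csv(out / "augmented.csv", index=False)
    record_stage("augment", t0, enabled=config.with_intermediates)

    # featurize -------------------------------------------------------------
    t0 = time.time()
    featurizer = ReactionFeaturizer(dataset, qm_provider=truth.qm_provider())
    shapes = {}
    for name in config.blocks:
        block = featurizer.raw_block(name)
        shapes[name] = list(block.matrix.shape)
    record_stage("featurize", t0, shapes=shapes)

    # benchmark -------------------------------------------------------------
    t0 = time.time()
    plan = SplitPlan(
        n_splits=config.n_splits,
        train_fraction=config.train_fraction,
        base_seed=config.seed,
    )
    specs = [ModelSpec(m) for m in config.models]
    result = run_benchmark(
        dataset, featurizer, config.blocks, specs, plan,
        include_context=config.include_context,
        variance_threshold=config.variance_threshold,
    )
    result.to_frame().to_csv(out / "benchmark.csv", index=False)
    record_stage("benchmark", t0, cells=len(result.cells))

    # stack -----------------------------------------------------------------
    t0 = time.time()
    stack_spec = StackSpec()
    y = np.asarray(dataset.yields())
    r2s, maes = [], []
    for si, (tr, te) in enumerate(make_splits(len(dataset), plan)):
        train_blocks, test_blocks = {}, {}
        for b in stack_spec.blocks:
            blk = featurizer.split_block(b, tr)
            train_blocks[b], test_blocks[b] = blk.matrix[tr], blk.matrix[te]
        stacked, _ = stack_fit_predict(
            stack_spec, train_blocks, y[tr], test_blocks, seed=plan.seeds[si]
        )
        r2, mae = evaluate(y[te], stacked)
        r2s.append(r2)
        maes.append(mae)
    stack_summary = {
        "r2_mean": float(np.mean(r2s)),
        "r2_std": float(np.std(r2s)),
        "mae_mean": float(np.mean(maes)),
        "mae_std": float(np.std(maes)),
    }
    (out / "stack.json").write_text(json.dumps(stack_summary, indent=2))
    record_stage("stack", t0, **stack_summary)

    # cliffs ----------------------------------------------------------------
    t0 = time.time()
    pairs = find_cliffs(
        dataset, sim_threshold=config.sim_threshold, yield_gap=config.yield_gap
    )
    groups = find_uncertain(dataset, tolerance=config.uncertain_tolerance)

    def bench(d: ReactionDataset):
        fz = (
            featurizer
            if d is dataset
            else ReactionFeaturizer(d, qm_provider=truth.qm_provider())
        )
        return run_benchmark(
            d, fz, [config.blocks[0]], [ModelSpec(config.models[-1])], plan,
            include_context=config.include_context,
            variance_threshold=config.variance_threshold,
        )

    report = remove_and_reevaluate(dataset, pairs, groups, bench)
    pd.DataFrame(
        [
            {"id_a": p.id_a, "id_b": p.id_b, "similarity": p.similarity,
             "yield_gap": p.yield_gap}
            for p in pairs
        ]
    ).to_csv(out / "cliff_pairs.csv", index=False)
    pd.DataFrame(
        [
            {"reaction_ids": ";".join(g.reaction_ids),
             "yields": ";".join(map(str, g.yields)), "spread": g.spread}
            for g in groups
        ]
    ).to_csv(out / "uncertain_groups.csv", index=False)
    before = report.before.to_frame().assign(phase="before")
    after = report.after.to_frame().assign(phase="after")
    pd.concat([before, after]).to_csv(out / "cliff_reevaluation.csv", index=False)
    record_stage(
        "cliffs", t0, n_pairs=len(pairs), n_groups=len(groups),
        n_removed=report.n_removed,
    )
    return out
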