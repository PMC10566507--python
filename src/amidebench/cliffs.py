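"""Reactivity-cliff and uncertain-record detection, and removal re-evaluation.

A *reactivity cliff* is a pair of reactions with highly similar reactants
and context (cosine similarity of the concatenated acid+amine fingerprints
plus the context multi-hot above a threshold, default 0.9) whose yields
differ by at least a gap (default 30 percentage points).  An *uncertain*
record group is the same reaction — identical reactants, product, coupling
agent and context — reported with two or more different yields.  Both
inflate the apparent noise floor of yield models; this module finds them
exactly (equivalent to the full O(n^2) scan) and quantifies the benchmark
effect of removing them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .benchmark import BenchmarkResult
from .core import ReactionDataset, ReactionRecord
from .featurize2d import FeatureBlock, morgan_fingerprint, encode_context

__all__ = [
    "ReactionSignature",
    "CliffPair",
    "UncertainGroup",
    "CliffReport",
    "reaction_signature",
    "find_uncertain",
    "pairwise_similarity",
    "cliff_feature_block",
    "find_cliffs",
    "remove_and_reevaluate",
]


@dataclass(frozen=True)
class ReactionSignature:
    """Identity of a reaction for the 'same reaction, multiple records' sense."""

    acid: str
    amine: str
    product: str
    coupling_agent: str
    reagents: tuple[str, ...]
    solvents: tuple[str, ...]
    conditions: tuple[str, ...]
    temperature_c: float | None
    time_h: float | None


def reaction_signature(record: ReactionRecord) -> ReactionSignature:
    """Canonical, context-order-insensitive signature of a record."""
    ctx = record.context
    return ReactionSignature(
        acid=record.acid.smiles,
        amine=record.amine.smiles,
        product=record.product.smiles,
        coupling_agent=record.coupling_agent,
        reagents=tuple(sorted(ctx.reagents)),
        solvents=tuple(sorted(ctx.solvents)),
        conditions=tuple(sorted(ctx.conditions)),
        temperature_c=ctx.temperature_c,
        time_h=ctx.time_h,
    )


@dataclass(frozen=True)
class UncertainGroup:
    signature: ReactionSignature
    reaction_ids: tuple[str, ...]
    yields: tuple[float, ...]

    @property
    def spread(self) -> float:
        return max(self.yields) - min(self.yields)


def find_uncertain(
    dataset: ReactionDataset, tolerance: float = 0.0
) -> list[UncertainGroup]:
    """Groups of signature-identical records whose yields differ by more
    than *tolerance* (default 0: any difference counts)."""
    groups: dict[ReactionSignature, list[ReactionRecord]] = {}
    for rec in dataset.records:
        groups.setdefault(reaction_signature(rec), []).append(rec)
    out = []
    for sig, members in groups.items():
        if len(members) < 2:
            continue
        ys = [m.yield_percent for m in members]
        if max(ys) - min(ys) > tolerance:
            out.append(
                UncertainGroup(
                    sig,
                    tuple(m.reaction_id for m in members),
                    tuple(ys),
                )
            )
    out.sort(key=lambda g: g.reaction_ids)
    return out


@dataclass(frozen=True)
class CliffPair:
    id_a: str
    id_b: str
    similarity: float
    yield_gap: float


def pairwise_similarity(features: FeatureBlock, i: int, j: int) -> float:
    """Cosine similarity between rows i and j of a feature block."""
    a, b = features.matrix[i], features.matrix[j]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def cliff_feature_block(
    dataset: ReactionDataset, radius: int = 2, n_bits: int = 2048
) -> FeatureBlock:
    """The similarity space used for cliff detection: concatenated acid and
    amine Morgan fingerprints plus the context multi-hot slice."""
    vocab = dataset.context_vocab
    rows = [
        np.concatenate(
            [
                morgan_fingerprint(r.acid, radius, n_bits),
                morgan_fingerprint(r.amine, radius, n_bits),
                encode_context(r.context, vocab),
            ]
        )
        for r in dataset.records
    ]
    names = (
        [f"fingerprint|acid|bit{i:04d}" for i in range(n_bits)]
        + [f"fingerprint|amine|bit{i:04d}" for i in range(n_bits)]
        + [f"context|{f}={l}" for f, l in vocab.labels]
    )
    return FeatureBlock("cliff-space", np.vstack(rows), names)


def find_cliffs(
    dataset: ReactionDataset,
    features: FeatureBlock | None = None,
    sim_threshold: float = 0.9,
    yield_gap: float = 30.0,
    block_size: int = 512,
) -> list[CliffPair]:
    """All unordered pairs with cosine > *sim_threshold* and yield difference
    >= *yield_gap* whose signatures differ (signature-identical duplicates
    belong to :func:`find_uncertain`, not here).

    Exact: a blocked matrix scan equivalent to the full O(n^2) loop.
    """
    if features is None:
        features = cliff_feature_block(dataset)
    if features.matrix.shape[0] != len(dataset):
        raise ValueError("feature block is not row-aligned with the dataset")
    X = features.matrix
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = int(np.where(norms == 0)[0][0])
        raise ValueError(f"zero feature vector at row {bad}")
    Xn = X / norms[:, None]
    y = np.asarray(dataset.yields(), dtype=float)
    sigs = [reaction_signature(r) for r in dataset.records]
    ids = [r.reaction_id for r in dataset.records]
    n = len(dataset)
    pairs: list[CliffPair] = []
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        sims = Xn[start:stop] @ Xn.T  # (block, n)
        gaps = np.abs(y[start:stop, None] - y[None, :])
        hit = (sims > sim_threshold) & (gaps >= yield_gap)
        for bi, j in zip(*np.nonzero(hit)):
            i = start + bi
            if j <= i or sigs[i] == sigs[j]:
                continue
            pairs.append(CliffPair(ids[i], ids[j], float(sims[bi, j]), float(gaps[bi, j])))
    pairs.sort(key=lambda p: (p.id_a, p.id_b))
    return pairs


@dataclass
class CliffReport:
    """Detection output plus before/after benchmark bookkeeping."""

    cliff_pairs: list[CliffPair]
    uncertain_groups: list[UncertainGroup]
    removed_ids: set[str]
    before: BenchmarkResult | None = None
    after: BenchmarkResult | None = None

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)


def remove_and_reevaluate(
    dataset: ReactionDataset,
    cliff_pairs: list[CliffPair],
    uncertain_groups: list[UncertainGroup],
    benchmark_fn: Callable[[ReactionDataset], BenchmarkResult],
    min_rows: int = 20,
) -> CliffReport:
    """Drop every record in any cliff pair or uncertain group and re-run the
    identical benchmark on the reduced dataset.

    *benchmark_fn* encapsulates the benchmark configuration (blocks, models,
    split plan, seeds) so before and after are directly comparable.
    """
    removed: set[str] = set()
    for p in cliff_pairs:
        removed.update((p.id_a, p.id_b))
    for g in uncertain_groups:
        removed.update(g.reaction_ids)
    keep = [i for i, r in enumerate(dataset.records) if r.reaction_id not in removed]
    if len(keep) < min_rows:
        raise ValueError(
            f"removal leaves only {len(keep)} records (< {min_rows})"
        )
    before = benchmark_fn(dataset)
    after = benchmark_fn(dataset.subset(keep))
    return CliffReport(
        cliff_pairs=list(cliff_pairs),
        uncertain_groups=list(uncertain_groups),
        removed_ids=removed,
        before=before,
        after=after,
    )
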