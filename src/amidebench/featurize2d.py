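"""Connectivity-derived reaction descriptors.

Four things live here: Morgan circular fingerprints, a broad 2D
physicochemical/topological descriptor battery, multi-hot context encoding,
and the assembly/selection machinery that turns per-molecule descriptors
into reaction-level feature matrices (one row per reaction, concatenated
over molecule roles, optionally with the context slice appended).

All descriptor functions are pure and cached per canonical SMILES, so
repeated molecules across reactions are computed once.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit import RDLogger
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFE

from .core import Context, ContextVocabulary, ReactionDataset, mol_from_smiles

RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "FeatureBlock",
    "SelectionPlan",
    "VarianceFilter",
    "morgan_fingerprint",
    "battery_2d",
    "battery_2d_names",
    "encode_context",
    "assemble_reaction_features",
    "variance_filter",
    "rfe_select",
]

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048
DEFAULT_ROLES = ("acid", "amine", "product")


@dataclass
class FeatureBlock:
    """A named reactions x features numeric matrix for one descriptor family."""

    name: str
    matrix: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.matrix.shape[1]} columns vs {len(self.feature_names)} names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def hstack(self, other: "FeatureBlock", name: str | None = None) -> "FeatureBlock":
        return FeatureBlock(
            name or f"{self.name}+{other.name}",
            np.hstack([self.matrix, other.matrix]),
            self.feature_names + other.feature_names,
        )


@functools.lru_cache(maxsize=200_000)
def _fingerprint_cached(smiles: str, radius: int, n_bits: int) -> np.ndarray:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.float64)
    fp = gen.GetFingerprint(mol_from_smiles(smiles))
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    arr.setflags(write=False)
    return arr


def morgan_fingerprint(
    mol_or_smiles, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> np.ndarray:
    """Binary Morgan fingerprint (counts folded to 0/1), deterministic."""
    if n_bits <= 0:
        raise ValueError("n_bits must be positive")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    smiles = getattr(mol_or_smiles, "smiles", None)
    if smiles is None:
        smiles = Chem.MolToSmiles(mol_or_smiles) if isinstance(
            mol_or_smiles, Chem.Mol
        ) else str(mol_or_smiles)
    return _fingerprint_cached(smiles, radius, n_bits)


_DESC_LIST = [(name, fn) for name, fn in Descriptors.descList]


def battery_2d_names() -> list[str]:
    """Names of the 2D descriptor battery, in column order."""
    return [name for name, _ in _DESC_LIST]


@functools.lru_cache(maxsize=100_000)
def _battery_cached(smiles: str) -> np.ndarray:
    mol = mol_from_smiles(smiles)
    values = np.empty(len(_DESC_LIST), dtype=np.float64)
    for i, (_name, fn) in enumerate(_DESC_LIST):
        try:
            v = fn(mol)
        except Exception:
            v = np.nan
        values[i] = v if (v is not None and np.isfinite(v)) else np.nan
    values.setflags(write=False)
    return values


def battery_2d(mol_or_smiles) -> np.ndarray:
    """Fixed-length vector of 2D physicochemical/topological descriptors.

    Entries that cannot be computed are NaN; downstream variance filtering
    removes such columns rather than imputing them.
    """
    smiles = getattr(mol_or_smiles, "smiles", None)
    if smiles is None:
        smiles = Chem.MolToSmiles(mol_or_smiles) if isinstance(
            mol_or_smiles, Chem.Mol
        ) else str(mol_or_smiles)
    return _battery_cached(smiles)


def encode_context(ctx: Context, vocab: ContextVocabulary) -> np.ndarray:
    """Multi-hot encoding of the categorical context over *vocab*.

    Unknown labels (absent from the training-built vocabulary) contribute
    nothing — no leakage from test-time contexts.
    """
    vec = np.zeros(vocab.dimension, dtype=np.float64)
    for fname, label in ctx.labels():
        idx = vocab.index(fname, label)
        if idx is not None:
            vec[idx] = 1.0
    return vec


_MOLECULE_BLOCKS = {"fingerprint": None, "battery2d": None}


def assemble_reaction_features(
    dataset: ReactionDataset,
    blocks: "str | list[str]" = "fingerprint",
    roles: tuple[str, ...] = DEFAULT_ROLES,
    include_context: bool = False,
    vocab: ContextVocabulary | None = None,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> FeatureBlock:
    """Concatenate per-molecule descriptors over *roles* into a reaction matrix.

    Column provenance is recorded in ``feature_names`` as
    ``"<block>|<role>|<feature>"``.  When *include_context* is true the
    context multi-hot slice (using *vocab*, default the dataset's own
    vocabulary) is appended.
    """
    block_list = [blocks] if isinstance(blocks, str) else list(blocks)
    if not block_list:
        raise ValueError("at least one block required")
    if not roles:
        raise ValueError("at least one molecule role required")
    for b in block_list:
        if b not in _MOLECULE_BLOCKS:
            raise ValueError(f"unknown 2D block {b!r}; known: {sorted(_MOLECULE_BLOCKS)}")

    columns: list[np.ndarray] = []
    names: list[str] = []
    for block in block_list:
        for role in roles:
            rows = []
            for rec in dataset.records:
                mol = getattr(rec, role, None)
                if mol is None:
                    raise ValueError(
                        f"reaction {rec.reaction_id!r} has no molecule in role {role!r}"
                    )
                if block == "fingerprint":
                    rows.append(_fingerprint_cached(mol.smiles, radius, n_bits))
                else:
                    rows.append(_battery_cached(mol.smiles))
            mat = np.vstack(rows)
            columns.append(mat)
            if block == "fingerprint":
                names += [f"fingerprint|{role}|bit{i:04d}" for i in range(n_bits)]
            else:
                names += [f"battery2d|{role}|{n}" for n in battery_2d_names()]
    if include_context:
        vocab = vocab or dataset.context_vocab
        ctx = np.vstack([encode_context(r.context, vocab) for r in dataset.records])
        columns.append(ctx)
        names += [f"context|{f}={l}" for f, l in vocab.labels]
    return FeatureBlock("+".join(block_list), np.hstack(columns), names)


class VarianceFilter:
    """Drop columns with variance below a threshold or containing NaNs.

    Fit on training rows only, then applied unchanged to test rows, so a
    column that is constant in training is removed everywhere (no leakage).
    """

    def __init__(self, threshold: float = 0.0):
        if threshold < 0:
            raise ValueError("variance threshold must be >= 0")
        self.threshold = threshold
        self.keep_: np.ndarray | None = None

    def fit(self, matrix: np.ndarray) -> "VarianceFilter":
        matrix = np.asarray(matrix, dtype=np.float64)
        finite = np.isfinite(matrix).all(axis=0)
        var = np.zeros(matrix.shape[1])
        var[finite] = matrix[:, finite].var(axis=0)
        if self.threshold > 0:
            keep = finite & (var >= self.threshold)
        else:
            keep = finite
        self.keep_ = keep
        return self

    def transform(self, block: FeatureBlock) -> FeatureBlock:
        if self.keep_ is None:
            raise RuntimeError("filter not fitted")
        keep = self.keep_
        return FeatureBlock(
            block.name,
            block.matrix[:, keep],
            [n for n, k in zip(block.feature_names, keep) if k],
        )


def variance_filter(block: FeatureBlock, threshold: float = 0.0) -> FeatureBlock:
    """Fit-and-transform convenience wrapper (see :class:`VarianceFilter`)."""
    out = VarianceFilter(threshold).fit(block.matrix).transform(block)
    if out.n_features == 0:
        raise ValueError("variance filter removed every column")
    return out


@dataclass
class SelectionPlan:
    """Recursive-feature-elimination plan: per-block target widths.

    ``step`` is the fraction of remaining features dropped per elimination
    round; the ranking model is a seeded random forest refit each round.
    """

    targets: dict[str, int]
    step: float = 0.1
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name, t in self.targets.items():
            if t < 1:
                raise ValueError(f"target for block {name!r} must be >= 1")
        if not (0 < self.step < 1):
            raise ValueError("step must be in (0, 1)")


def rfe_select(
    blocks: list[FeatureBlock], y: np.ndarray, plan: SelectionPlan
) -> FeatureBlock:
    """Per-block recursive feature elimination, then column-wise merge.

    Each block is reduced independently to its target width by iteratively
    refitting the ranking forest and dropping the lowest-importance features;
    the surviving columns of all blocks are concatenated in block order.
    Seeded and reproducible.
    """
    y = np.asarray(y, dtype=np.float64)
    selected: list[FeatureBlock] = []
    for block in blocks:
        target = plan.targets.get(block.name)
        if target is None:
            raise ValueError(f"no target width for block {block.name!r}")
        if target > block.n_features:
            raise ValueError(
                f"target {target} exceeds block width {block.n_features} "
                f"for {block.name!r}"
            )
        if target == block.n_features:
            selected.append(block)
            continue
        ranker = RandomForestRegressor(
            n_estimators=plan.n_trees,
            max_features="sqrt",
            random_state=plan.seed,
            n_jobs=1,
        )
        rfe = RFE(ranker, n_features_to_select=target, step=plan.step)
        rfe.fit(block.matrix, y)
        keep = rfe.support_
        selected.append(
            FeatureBlock(
                block.name,
                block.matrix[:, keep],
                [n for n, k in zip(block.feature_names, keep) if k],
            )
        )
    merged = selected[0]
    for extra in selected[1:]:
        merged = merged.hstack(extra)
    merged.name = "merged"
    return merged
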