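"""Reaction-level feature factory shared by the benchmark and cliff modules.

Builds the per-descriptor-family matrices (fingerprint, battery2d, aev, qm,
steric, context) for a dataset, with per-molecule caching, and provides the
leakage-safe per-split assembly: the context vocabulary and the variance
filter are fitted on training rows only and then applied unchanged to the
full matrix.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .core import ContextVocabulary, ReactionDataset
from .featurize2d import (
    FeatureBlock,
    VarianceFilter,
    battery_2d,
    battery_2d_names,
    encode_context,
    morgan_fingerprint,
)
from .featurize3d import (
    AEVParams,
    QMProvider,
    REACTION_QM_NAMES,
    StericParams,
    aev_for_molecule,
    buried_volume,
    derive_reaction_qm,
    embed_conformer,
)
from .mechanism import annotate_reaction_centers

__all__ = ["ReactionFeaturizer", "BLOCK_NAMES"]

BLOCK_NAMES = ("fingerprint", "battery2d", "aev", "qm", "steric", "context")


@functools.lru_cache(maxsize=200_000)
def _centers_cached(acid: str, amine: str, product: str):
    return annotate_reaction_centers(acid, amine, product)


@dataclass
class ReactionFeaturizer:
    """Computes row-aligned descriptor matrices for one dataset.

    Molecule-level descriptors are cached by canonical SMILES, so replicate
    datasets drawn from the same fragment library share all the heavy
    computation.  ``qm_provider`` must be set to build the ``qm`` block
    (the synthetic oracle in tests; any provider honouring the contract).
    """

    dataset: ReactionDataset
    qm_provider: QMProvider | None = None
    fingerprint_roles: tuple[str, ...] = ("acid", "amine")
    battery_roles: tuple[str, ...] = ("acid", "amine")
    aev_roles: tuple[str, ...] = ("acid", "amine")
    radius: int = 2
    n_bits: int = 2048
    aev_params: AEVParams = field(default_factory=AEVParams)
    steric_params: StericParams = field(default_factory=StericParams)
    conformer_seed: int = 0

    def __post_init__(self) -> None:
        self._raw: dict[str, FeatureBlock] = {}

    # ------------------------------------------------------------------
    def raw_block(self, name: str) -> FeatureBlock:
        """Unfitted reactions x features matrix for one descriptor family."""
        if name not in self._raw:
            builder = getattr(self, f"_build_{name}", None)
            if builder is None:
                raise ValueError(f"unknown feature block {name!r}")
            self._raw[name] = builder()
        return self._raw[name]

    def _per_role(self, roles, fn, names, prefix) -> FeatureBlock:
        cols, out_names = [], []
        for role in roles:
            rows = [fn(getattr(rec, role)) for rec in self.dataset.records]
            cols.append(np.vstack(rows))
            out_names += [f"{prefix}|{role}|{n}" for n in names]
        return FeatureBlock(prefix, np.hstack(cols), out_names)

    def _build_fingerprint(self) -> FeatureBlock:
        names = [f"bit{i:04d}" for i in range(self.n_bits)]
        return self._per_role(
            self.fingerprint_roles,
            lambda m: morgan_fingerprint(m, self.radius, self.n_bits),
            names,
            "fingerprint",
        )

    def _build_battery2d(self) -> FeatureBlock:
        return self._per_role(
            self.battery_roles, battery_2d, battery_2d_names(), "battery2d"
        )

    def _build_aev(self) -> FeatureBlock:
        names = [f"g{i:04d}" for i in range(self.aev_params.length)]
        return self._per_role(
            self.aev_roles,
            lambda m: aev_for_molecule(m, self.aev_params, self.conformer_seed),
            names,
            "aev",
        )

    def _build_qm(self) -> FeatureBlock:
        if self.qm_provider is None:
            raise ValueError("qm block requires a QM provider")
        e_water = self.qm_provider.compute("O").energy
        qm_cache: dict[str, object] = {}

        def qm_of(smiles: str):
            if smiles not in qm_cache:
                qm_cache[smiles] = self.qm_provider.compute(smiles)
            return qm_cache[smiles]

        rows = []
        for rec in self.dataset.records:
            centers = _centers_cached(
                rec.acid.smiles, rec.amine.smiles, rec.product.smiles
            )
            rows.append(
                derive_reaction_qm(
                    qm_of(rec.acid.smiles),
                    qm_of(rec.amine.smiles),
                    qm_of(rec.product.smiles),
                    centers,
                    e_water,
                )
            )
        return FeatureBlock(
            "qm", np.vstack(rows), [f"qm|{n}" for n in REACTION_QM_NAMES]
        )

    def _build_steric(self) -> FeatureBlock:
        bv_cache: dict[tuple[str, int], float] = {}

        def bv(smiles: str, center: int) -> float:
            key = (smiles, center)
            if key not in bv_cache:
                conf = embed_conformer(smiles, self.conformer_seed)
                bv_cache[key] = buried_volume(conf, center, self.steric_params)
            return bv_cache[key]

        rows = []
        for rec in self.dataset.records:
            centers = _centers_cached(
                rec.acid.smiles, rec.amine.smiles, rec.product.smiles
            )
            rows.append(
                [
                    bv(rec.acid.smiles, centers.acid_carbon),
                    bv(rec.amine.smiles, centers.amine_nitrogen),
                ]
            )
        return FeatureBlock(
            "steric",
            np.asarray(rows, dtype=np.float64),
            ["steric|acid_c_vbur", "steric|amine_n_vbur"],
        )

    def _build_context(self) -> FeatureBlock:
        vocab = self.dataset.context_vocab
        mat = np.vstack(
            [encode_context(r.context, vocab) for r in self.dataset.records]
        )
        return FeatureBlock(
            "context", mat, [f"context|{f}={l}" for f, l in vocab.labels]
        )

    # ------------------------------------------------------------------
    def split_block(
        self,
        name: str,
        train_idx: np.ndarray,
        include_context: bool = False,
        variance_threshold: float = 0.0,
    ) -> FeatureBlock:
        """Leakage-safe per-split matrix for one block.

        The context vocabulary (when appended) is built from the training
        rows only; test-time labels outside it encode to zero.  The variance
        filter is fitted on the training rows and applied to all rows, so
        any column constant in training is dropped everywhere.
        """
        if name == "context":
            vocab = ContextVocabulary.from_contexts(
                self.dataset.records[i].context for i in train_idx
            )
            mat = np.vstack(
                [encode_context(r.context, vocab) for r in self.dataset.records]
            )
            block = FeatureBlock(
                "context", mat, [f"context|{f}={l}" for f, l in vocab.labels]
            )
        else:
            block = self.raw_block(name)
        if include_context and name != "context":
            vocab = ContextVocabulary.from_contexts(
                self.dataset.records[i].context for i in train_idx
            )
            ctx = np.vstack(
                [encode_context(r.context, vocab) for r in self.dataset.records]
            )
            block = block.hstack(
                FeatureBlock(
                    "context", ctx, [f"context|{f}={l}" for f, l in vocab.labels]
                ),
                name=block.name,
            )
        vf = VarianceFilter(variance_threshold).fit(block.matrix[train_idx])
        return vf.transform(block)
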