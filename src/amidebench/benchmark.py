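"""Model-evaluation harness: fixed splits, model registry, stacking, subsets.

Evaluation follows the convention of reporting the coefficient of
determination R^2 (about the test-fold mean) and the mean absolute error in
yield percentage points, each computed per split and aggregated as
mean +/- standard deviation over the split set (default: five seeded 90/10
train/test splits).  The stacking meta-predictor is the arithmetic mean of
four per-descriptor base models — exactly, with no learned meta-weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .core import Molecule, ReactionDataset, ReactionRecord
from .features import ReactionFeaturizer
from .mechanism import AmineClass, MechanismError, classify_amine, condense_product

__all__ = [
    "SplitPlan",
    "ModelSpec",
    "StackSpec",
    "BenchmarkResult",
    "MODEL_FAMILIES",
    "make_splits",
    "evaluate",
    "fit_predict",
    "run_benchmark",
    "stack_fit_predict",
    "augment_negatives",
    "subset_by_amine_class",
]

MODEL_FAMILIES = (
    "mean_baseline",
    "ridge",
    "lasso",
    "svm",
    "random_forest",
    "gradient_boosting",
    "mlp",
)


@dataclass(frozen=True)
class SplitPlan:
    """Seeded train/test split schedule (default five 90/10 splits)."""

    n_splits: int = 5
    train_fraction: float = 0.9
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("need at least one split")

    @property
    def seeds(self) -> tuple[int, ...]:
        return tuple(self.base_seed + i for i in range(self.n_splits))


def make_splits(
    n_rows: int, plan: SplitPlan
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Realized (train, test) index pairs: disjoint, exhaustive, seeded."""
    if n_rows <= 10:
        raise ValueError("need more than 10 rows to split")
    n_train = int(np.floor(plan.train_fraction * n_rows))
    out = []
    for seed in plan.seeds:
        perm = np.random.default_rng(seed).permutation(n_rows)
        out.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return out


def evaluate(y_true, y_pred) -> tuple[float, float]:
    """(R^2, MAE) of predictions; R^2 is about the test-set mean."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    if np.var(y_true) == 0:
        raise ValueError("R^2 undefined: zero variance in y_true")
    return float(r2_score(y_true, y_pred)), float(mean_absolute_error(y_true, y_pred))


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus hyperparameter overrides and a seed."""

    family: str
    params: tuple[tuple[str, object], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; known: {MODEL_FAMILIES}"
            )

    def with_seed(self, seed: int) -> "ModelSpec":
        return ModelSpec(self.family, self.params, seed)

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


def _build_estimator(spec: ModelSpec):
    p = spec.param_dict
    if spec.family == "mean_baseline":
        return DummyRegressor(strategy="mean")
    if spec.family == "ridge":
        return make_pipeline(StandardScaler(), Ridge(alpha=p.get("alpha", 1.0)))
    if spec.family == "lasso":
        return make_pipeline(
            StandardScaler(), Lasso(alpha=p.get("alpha", 0.01), max_iter=5000)
        )
    if spec.family == "svm":
        return make_pipeline(
            StandardScaler(),
            SVR(C=p.get("C", 10.0), gamma=p.get("gamma", "scale")),
        )
    if spec.family == "random_forest":
        return RandomForestRegressor(
            n_estimators=p.get("n_estimators", 500),
            max_features=p.get("max_features", "sqrt"),
            min_samples_leaf=p.get("min_samples_leaf", 1),
            random_state=spec.seed,
            n_jobs=p.get("n_jobs", 1),
        )
    if spec.family == "gradient_boosting":
        return HistGradientBoostingRegressor(
            max_iter=p.get("n_estimators", 500),
            max_depth=p.get("max_depth", 3),
            learning_rate=p.get("learning_rate", 0.05),
            random_state=spec.seed,
        )
    if spec.family == "mlp":
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=p.get("hidden_layer_sizes", (256, 64)),
                early_stopping=True,
                validation_fraction=0.1,
                max_iter=p.get("max_iter", 300),
                random_state=spec.seed,
            ),
        )
    raise ValueError(spec.family)  # pragma: no cover


def fit_predict(
    spec: ModelSpec, X_train, y_train, X_test
) -> np.ndarray:
    """Fit the specified model and predict the test rows, clipped to [0, 100]."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if not (np.isfinite(X_train).all() and np.isfinite(X_test).all()):
        raise ValueError("feature matrices must be finite (filter first)")
    est = _build_estimator(spec)
    est.fit(X_train, np.asarray(y_train, dtype=float))
    return np.clip(est.predict(X_test), 0.0, 100.0)


@dataclass
class BenchmarkResult:
    """Per (model family, feature block) aggregated metrics over splits."""

    cells: dict[tuple[str, str], dict] = field(default_factory=dict)

    def add(self, model: str, block: str, r2s: list[float], maes: list[float]) -> None:
        r2s, maes = list(map(float, r2s)), list(map(float, maes))
        self.cells[(model, block)] = {
            "r2_mean": float(np.mean(r2s)),
            "r2_std": float(np.std(r2s)),
            "mae_mean": float(np.mean(maes)),
            "mae_std": float(np.std(maes)),
            "r2_values": r2s,
            "mae_values": maes,
        }

    def cell(self, model: str, block: str) -> dict:
        return self.cells[(model, block)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model": m, "features": b, **{k: v for k, v in c.items() if not k.endswith("_values")}}
            for (m, b), c in self.cells.items()
        ]
        return pd.DataFrame(rows)


def run_benchmark(
    dataset: ReactionDataset,
    featurizer: ReactionFeaturizer,
    block_names: list[str],
    model_specs: list[ModelSpec],
    plan: SplitPlan | None = None,
    include_context: bool = False,
    variance_threshold: float = 0.0,
) -> BenchmarkResult:
    """Full model x feature-block grid, aggregated over the split plan.

    All supervised or vocabulary state (context encoding, variance filter)
    is fitted per split on the training fold only.
    """
    plan = plan or SplitPlan()
    if featurizer.dataset is not dataset:
        raise ValueError("featurizer is not aligned with this dataset")
    y = np.asarray(dataset.yields(), dtype=float)
    splits = make_splits(len(dataset), plan)
    result = BenchmarkResult()
    for block_name in block_names:
        per_split = {}
        for si, (tr, te) in enumerate(splits):
            block = featurizer.split_block(
                block_name, tr, include_context=include_context,
                variance_threshold=variance_threshold,
            )
            per_split[si] = (block.matrix[tr], block.matrix[te])
        for spec in model_specs:
            r2s, maes = [], []
            for si, (tr, te) in enumerate(splits):
                X_tr, X_te = per_split[si]
                pred = fit_predict(spec.with_seed(plan.seeds[si]), X_tr, y[tr], X_te)
                r2, mae = evaluate(y[te], pred)
                r2s.append(r2)
                maes.append(mae)
            label = block_name + ("+context" if include_context else "")
            result.add(spec.family, label, r2s, maes)
    return result


@dataclass(frozen=True)
class StackSpec:
    """Four per-descriptor base models; the meta-rule is the arithmetic mean."""

    base: tuple[tuple[str, ModelSpec], ...] = (
        ("fingerprint", ModelSpec("ridge", params=(("alpha", 10.0),))),
        ("battery2d", ModelSpec("ridge", params=(("alpha", 10.0),))),
        ("aev", ModelSpec("ridge", params=(("alpha", 10.0),))),
        ("qm", ModelSpec("ridge", params=(("alpha", 10.0),))),
    )

    def __post_init__(self) -> None:
        blocks = [b for b, _ in self.base]
        if len(set(blocks)) != len(blocks):
            raise ValueError("exactly one base model per descriptor block")

    @property
    def blocks(self) -> tuple[str, ...]:
        return tuple(b for b, _ in self.base)


def stack_fit_predict(
    spec: StackSpec,
    train_blocks: dict[str, np.ndarray],
    y_train,
    test_blocks: dict[str, np.ndarray],
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Stacked prediction: the exact arithmetic mean of the base predictions.

    Returns (stacked predictions, per-block base predictions).
    """
    missing = [b for b in spec.blocks if b not in train_blocks or b not in test_blocks]
    if missing:
        raise ValueError(f"missing feature blocks for stacking: {missing}")
    base_preds: dict[str, np.ndarray] = {}
    for block_name, model in spec.base:
        base_preds[block_name] = fit_predict(
            model.with_seed(seed),
            train_blocks[block_name],
            y_train,
            test_blocks[block_name],
        )
    stacked = np.mean(np.vstack(list(base_preds.values())), axis=0)
    return stacked, base_preds


def augment_negatives(
    dataset: ReactionDataset, fraction: float, seed: int = 0
) -> ReactionDataset:
    """Append synthetic zero-yield reactions from unobserved acid-amine pairs.

    Mimics injecting artificial negative reactions into a training set to
    counter the high-yield reporting bias of literature data.  Contexts are
    sampled from the existing records; products come from the condensation
    so every appended record still passes validation.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    n_new = int(np.floor(fraction * len(dataset)))
    if n_new == 0:
        return dataset
    rng = np.random.default_rng(seed)
    acids = sorted({r.acid.smiles for r in dataset.records})
    amines = sorted({r.amine.smiles for r in dataset.records})
    existing = {(r.acid.smiles, r.amine.smiles) for r in dataset.records}
    candidates = [
        (a, m) for a in acids for m in amines if (a, m) not in existing
    ]
    if len(candidates) < n_new:
        raise ValueError(
            f"fragment pool exhausted: only {len(candidates)} unused pairs "
            f"for {n_new} negatives"
        )
    chosen = [candidates[i] for i in rng.choice(len(candidates), n_new, replace=False)]
    records = list(dataset.records)
    agents = ("EDC", "DCC", "DIC")
    for i, (acid, amine) in enumerate(chosen):
        donor = dataset.records[int(rng.integers(len(dataset)))]
        records.append(
            ReactionRecord(
                reaction_id=f"synthneg-{i:05d}",
                acid=Molecule(acid, "acid"),
                amine=Molecule(amine, "amine"),
                product=condense_product(acid, amine),
                coupling_agent=agents[int(rng.integers(3))],
                yield_percent=0.0,
                context=donor.context,
                synthetic_negative=True,
            )
        )
    return ReactionDataset(records)


def subset_by_amine_class(
    dataset: ReactionDataset,
) -> dict[AmineClass, ReactionDataset]:
    """Partition the dataset by amine nucleophile class (disjoint, exhaustive)."""
    buckets: dict[AmineClass, list[int]] = {cls: [] for cls in AmineClass}
    for i, rec in enumerate(dataset.records):
        try:
            cls = classify_amine(rec.amine)
        except MechanismError as exc:
            raise MechanismError(
                f"reaction {rec.reaction_id}: {exc}"
            ) from exc
        buckets[cls].append(i)
    return {cls: dataset.subset(idx) for cls, idx in buckets.items()}
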