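"""Literature-like synthetic amide-coupling datasets with known ground truth.

Real literature reaction corpora are license-encumbered, so every stage of
the pipeline is exercised on generated data that emulates their statistical
fingerprints: a high-yield-skewed distribution (configurable mean, default
64.1%), three amine classes, a categorical context vocabulary with mild
yield effects, planted reactivity cliffs (near-identical reactant pairs with
large forced yield gaps), planted uncertain records (the same reaction
reported with several different yields), and latent per-molecule electronic
energies giving a weak negative yield-vs-reaction-energy correlation.

The noiseless latent yield is a deterministic function of interpretable
structure terms — amine class, steric crowding around the amine nitrogen,
electron-withdrawing substitution and size/aromaticity of the acid — plus
seeded categorical context effects.  Observed yields add clipped Gaussian
noise.  All ground truth (latent yields, planted pair/group ids, molecular
energies, oracle QM records) is returned alongside the dataset so detectors
and models can be scored against it.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .core import (
    Context,
    Molecule,
    ReactionDataset,
    ReactionRecord,
    molecular_formula,
)
from .featurize2d import morgan_fingerprint
from .featurize3d import SUPPORTED_ELEMENTS, CoverageError, QMRecord
from .mechanism import (
    AmineClass,
    MechanismError,
    classify_amine,
    condense_product,
    find_carboxyl,
    find_reactive_amine,
    make_o_acylisourea,
)

__all__ = [
    "GeneratorConfig",
    "LatentCoefficients",
    "GroundTruth",
    "OracleQMProvider",
    "GenerationError",
    "build_fragment_library",
    "structure_terms",
    "latent_yield",
    "generate_dataset",
    "WATER_ENERGY",
]

WATER_ENERGY = -76.4


class GenerationError(RuntimeError):
    """Raised when planting constraints cannot be satisfied."""


@functools.lru_cache(maxsize=200_000)
def product_of(acid: str, amine: str) -> str:
    """Canonical amide SMILES for one acid/amine pair (globally cached)."""
    return condense_product(acid, amine).smiles


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatentCoefficients:
    """Coefficients of the latent structure-yield function (yield points).

    Signs follow textbook intuition: steric crowding around the nucleophilic
    nitrogen and weakly nucleophilic aryl amines depress yields; mild
    electron-withdrawing substitution on the acid activates it.
    """

    intercept: float = 64.1
    ewg: float = 3.0
    aromatic_acid: float = -5.0
    acid_size: float = -0.4
    steric: float = -2.8
    class_offsets: tuple[tuple[str, float], ...] = (
        ("primary_aliphatic", 5.0),
        ("primary_aromatic", -7.0),
        ("secondary", -2.0),
    )

    def class_offset(self, cls: AmineClass) -> float:
        return dict(self.class_offsets)[cls.value]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_reactions: int = 5000
    n_acids: int = 60
    n_amines_per_class: int = 20
    target_mean_yield: float = 64.1
    yield_noise_sd: float = 8.0
    n_solvents: int = 10
    n_reagents: int = 8
    n_conditions: int = 5
    n_planted_cliffs: int = 150
    cliff_yield_gap: float = 45.0
    cliff_sim_threshold: float = 0.9
    n_planted_uncertain: int = 25
    uncertain_group_size: int = 3
    uncertain_span: tuple[float, float] = (30.0, 90.0)
    target_energy_corr: float = -0.12
    coefficients: LatentCoefficients = field(default_factory=LatentCoefficients)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cliff_yield_gap <= 100):
            raise ValueError("cliff yield gap must be in (0, 100]")
        if not (-1 < self.target_energy_corr < 1):
            raise ValueError("target correlation must be in (-1, 1)")
        if self.uncertain_group_size < 2:
            raise ValueError("uncertain groups need >= 2 members")
        overhead = (
            2 * self.n_planted_cliffs
            + self.n_planted_uncertain * self.uncertain_group_size
        )
        if overhead > self.n_reactions:
            raise ValueError(
                f"planted records ({overhead}) exceed n_reactions ({self.n_reactions})"
            )


# ---------------------------------------------------------------------------
# Fragment library
# ---------------------------------------------------------------------------

_PARA_SUBS = ["C", "CC", "CO", "F", "Cl", "FC(F)(F)", "N#C", "CS"]

# Two-ring, drug-like members: typical of literature amide couplings, and
# large enough that a remote methyl/methoxy edit keeps fingerprint cosine
# similarity above 0.9 (the cliff-planting regime).
_BIG_ACIDS = [
    "OC(=O)c1ccc(-c2ccccc2)cc1",
    "OC(=O)c1ccc(OCc2ccccc2)cc1",
    "OC(=O)c1ccc(COc2ccccc2)cc1",
    "OC(=O)Cc1ccc(OCc2ccccc2)cc1",
    "OC(=O)c1ccc(CSc2ccccc2)cc1",
    "OC(=O)c1ccc(OCCOc2ccccc2)cc1",
    "OC(=O)c1ccc(Oc2ccccc2)cc1",
    "OC(=O)c1ccc(CCc2ccccc2)cc1",
    "OC(=O)c1ccc(OCc2ccc(F)cc2)cc1",
    "OC(=O)c1ccc(OCc2ccc(C)cc2)cc1",
    "OC(=O)c1cccc(OCc2ccccc2)c1",
    "OC(=O)Cc1ccc(Oc2ccccc2)cc1",
    "OC(=O)c1ccc(Cc2ccccc2)cc1",
    "OC(=O)c1ccc(OCc2cccs2)cc1",
    "OC(=O)c1ccc(OCc2ccco2)cc1",
    "OC(=O)CCc1ccc(Oc2ccccc2)cc1",
]

_ACID_POOL = (
    _BIG_ACIDS
    + ["OC(=O)c1ccccc1"]
    + [s + "c1ccc(C(=O)O)cc1" for s in _PARA_SUBS]
    + [s + "c1cccc(C(=O)O)c1" for s in _PARA_SUBS]
    + ["OC(=O)Cc1ccccc1"]
    + [s + "c1ccc(CC(=O)O)cc1" for s in _PARA_SUBS]
    + [
        "CC(=O)O", "CCC(=O)O", "CCCC(=O)O", "CCCCC(=O)O", "CCCCCC(=O)O",
        "CCCCCCC(=O)O", "CC(C)C(=O)O", "CC(C)CC(=O)O", "CC(C)(C)C(=O)O",
        "CCC(C)C(=O)O", "OC(=O)C1CC1", "OC(=O)C1CCC1", "OC(=O)C1CCCC1",
        "OC(=O)C1CCCCC1", "OC(=O)CC1CCCCC1", "OC(=O)CCc1ccccc1",
        "COCC(=O)O", "CCOCC(=O)O", "CSCC(=O)O", "ClCC(=O)O", "FCC(=O)O",
        "OC(=O)C(F)(F)F", "CC(Cl)C(=O)O", "COCCC(=O)O", "CCCCCCCC(=O)O",
        "OC(=O)CCC1CCCCC1", "OC(=O)CCc1ccc(C)cc1", "OC(=O)CCc1ccc(OC)cc1",
        "CC(F)C(=O)O", "OC(=O)C1CCCC1C",
    ]
    + [
        "OC(=O)c1ccco1", "OC(=O)c1cccs1", "OC(=O)c1ccncc1", "OC(=O)c1cccnc1",
        "OC(=O)Cc1cccs1", "OC(=O)Cc1ccco1",
    ]
)

_PRIMARY_ALIPHATIC_POOL = [
    "NCc1ccc(OCc2ccccc2)cc1", "NCc1ccc(-c2ccccc2)cc1",
    "NCCc1ccc(Oc2ccccc2)cc1", "NCc1ccc(Oc2ccccc2)cc1",
    "NCCc1ccc(OCc2ccccc2)cc1", "NCc1cccc(OCc2ccccc2)c1",
    "CN", "CCN", "CCCN", "CCCCN", "CCCCCN", "CC(C)N", "CC(C)CN", "CC(C)(C)N",
    "CCC(C)N", "NC1CC1", "NC1CCC1", "NC1CCCC1", "NC1CCCCC1", "NCC1CCCCC1",
    "NCc1ccccc1", "NCCc1ccccc1", "NCc1ccc(C)cc1", "NCc1ccc(CO)cc1",
    "NCc1ccc(F)cc1", "NCc1ccc(Cl)cc1", "NCCCOC", "NCCOC", "CC(N)Cc1ccccc1",
]

_PRIMARY_AROMATIC_POOL = (
    [
        "Nc1ccc(OCc2ccccc2)cc1", "Nc1ccc(-c2ccccc2)cc1",
        "Nc1ccc(Oc2ccccc2)cc1", "Nc1ccc(Cc2ccccc2)cc1",
        "Nc1cccc(OCc2ccccc2)c1", "Nc1ccc(CCc2ccccc2)cc1",
    ]
    + ["Nc1ccccc1", "Nc1ccc2ccccc2c1"]
    + [s + "c1ccc(N)cc1" for s in _PARA_SUBS]
    + [s + "c1cccc(N)c1" for s in _PARA_SUBS]
    + ["Cc1ccc(N)c(C)c1", "COc1ccc(N)c(OC)c1", "Fc1ccc(N)c(F)c1"]
)

_SECONDARY_POOL = [
    "CNCc1ccc(OCc2ccccc2)cc1", "CNCc1ccc(-c2ccccc2)cc1",
    "CNCc1ccc(Oc2ccccc2)cc1", "CNCCc1ccc(Oc2ccccc2)cc1",
    "C1CCNCC1Cc1ccccc1", "C1CCNCC1COc1ccccc1",
    "CNC", "CCNC", "CNCC", "CCNCC", "CCCNC", "CNCCC", "CC(C)NC", "CC(C)NCC",
    "CNCC(C)C", "CNC1CCCC1", "CNC1CCCCC1", "CNCc1ccccc1", "CCNCc1ccccc1",
    "CNCCc1ccccc1", "CNCCOC", "C1CCNC1", "C1CCNCC1", "C1CCCNCC1", "C1COCCN1",
    "CNc1ccccc1", "CCNc1ccccc1", "CNCc1ccc(C)cc1",
]


def _usable_acid(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    if {a.GetSymbol() for a in mol.GetAtoms()} - SUPPORTED_ELEMENTS:
        return False
    try:
        find_carboxyl(mol)
    except MechanismError:
        return False
    try:
        find_reactive_amine(mol)
    except MechanismError:
        return True  # acids must NOT contain a reactive amine
    return False


def _usable_amine(smiles: str, wanted: AmineClass) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    if {a.GetSymbol() for a in mol.GetAtoms()} - SUPPORTED_ELEMENTS:
        return False
    try:
        return classify_amine(smiles) is wanted
    except MechanismError:
        return False


def build_fragment_library(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[list[str], dict[AmineClass, list[str]]]:
    """Curated mono-acid and amine SMILES pools, canonicalized.

    The pools are fixed enumerations filtered through the mechanistic
    preconditions (exactly one COOH, exactly one reactive amine of the
    intended class, supported elements only), truncated to the configured
    sizes.  Identical for every seed, so per-molecule descriptor caches are
    shared across replicate datasets.
    """
    acids = [Molecule(s, "acid").smiles for s in _ACID_POOL if _usable_acid(s)]
    if len(acids) < config.n_acids:
        raise GenerationError(
            f"acid pool exhausted: {len(acids)} < {config.n_acids}"
        )
    amines: dict[AmineClass, list[str]] = {}
    pools = {
        AmineClass.PRIMARY_ALIPHATIC: _PRIMARY_ALIPHATIC_POOL,
        AmineClass.PRIMARY_AROMATIC: _PRIMARY_AROMATIC_POOL,
        AmineClass.SECONDARY: _SECONDARY_POOL,
    }
    for cls, pool in pools.items():
        good = [Molecule(s, "amine").smiles for s in pool if _usable_amine(s, cls)]
        if len(good) < config.n_amines_per_class:
            raise GenerationError(
                f"{cls.value} pool exhausted: {len(good)} < {config.n_amines_per_class}"
            )
        amines[cls] = good[: config.n_amines_per_class]
    return acids[: config.n_acids], amines


# ---------------------------------------------------------------------------
# Latent structure-yield function
# ---------------------------------------------------------------------------


def structure_terms(acid_smiles: str, amine_smiles: str) -> dict[str, float]:
    """Interpretable structure terms feeding the latent yield.

    ``ewg``: count of electron-withdrawing atoms (F, Cl, nitrile N) on the
    acid; ``aromatic_acid``: carboxyl carbon attached to an aromatic ring;
    ``acid_size``: heavy-atom count of the acid; ``steric``: heavy atoms
    within three bonds of the amine nitrogen; ``amine_class``: nucleophile
    class.
    """
    return dict(_structure_terms_cached(acid_smiles, amine_smiles))


@functools.lru_cache(maxsize=200_000)
def _structure_terms_cached(acid_smiles: str, amine_smiles: str):
    acid = Chem.MolFromSmiles(acid_smiles)
    amine = Chem.MolFromSmiles(amine_smiles)
    c_idx, _o1, _o2 = find_carboxyl(acid)
    ewg = 0.0
    for atom in acid.GetAtoms():
        sym = atom.GetSymbol()
        if sym in ("F", "Cl"):
            ewg += 1
        elif sym == "N" and any(
            b.GetBondType() == Chem.BondType.TRIPLE for b in atom.GetBonds()
        ):
            ewg += 1
    aromatic = float(
        any(nb.GetIsAromatic() for nb in acid.GetAtomWithIdx(c_idx).GetNeighbors())
    )
    n_idx = find_reactive_amine(amine)
    dmat = Chem.GetDistanceMatrix(amine)
    steric = float(((dmat[n_idx] >= 1) & (dmat[n_idx] <= 3)).sum())
    return (
        ("ewg", ewg),
        ("aromatic_acid", aromatic),
        ("acid_size", float(acid.GetNumAtoms())),
        ("steric", steric),
        ("amine_class", classify_amine(amine_smiles).value),
    )


def _structural_part(terms: dict[str, float], coeff: LatentCoefficients) -> float:
    return (
        coeff.ewg * terms["ewg"]
        + coeff.aromatic_acid * terms["aromatic_acid"]
        + coeff.acid_size * terms["acid_size"]
        + coeff.steric * terms["steric"]
        + dict(coeff.class_offsets)[terms["amine_class"]]
    )


def _context_part(ctx: Context, table: dict[tuple[str, str], float]) -> float:
    eff = sum(table.get(pair, 0.0) for pair in ctx.labels())
    if ctx.temperature_c is not None:
        eff += 0.02 * (ctx.temperature_c - 25.0)
    if ctx.time_h is not None:
        eff += 0.05 * min(ctx.time_h, 24.0)
    return eff


def latent_yield(
    acid_smiles: str,
    amine_smiles: str,
    context: Context,
    coefficients: LatentCoefficients,
    context_table: dict[tuple[str, str], float] | None = None,
) -> float:
    """Noiseless yield in [0, 100] for one (acid, amine, context) triple.

    Purely deterministic: substituents that enter no term (e.g. a remote
    methyl with zero coefficient weight beyond the size term) leave the
    value unchanged.
    """
    terms = structure_terms(acid_smiles, amine_smiles)
    raw = (
        coefficients.intercept
        + _structural_part(terms, coefficients)
        + _context_part(context, context_table or {})
    )
    return float(min(100.0, max(0.0, raw)))


# ---------------------------------------------------------------------------
# Ground truth container and oracle QM provider
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything the generator knows that the models must rediscover."""

    cliff_pairs: list[tuple[str, str]]
    uncertain_groups: list[list[str]]
    latent_yield: dict[str, float]
    molecule_energy: dict[str, float]
    qm_records: dict[str, QMRecord]
    water_energy: float = WATER_ENERGY
    coefficients: LatentCoefficients = field(default_factory=LatentCoefficients)
    context_table: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def latent_variance(self) -> float:
        vals = np.fromiter(self.latent_yield.values(), dtype=float)
        return float(vals.var())

    def qm_provider(self) -> "OracleQMProvider":
        return OracleQMProvider(self)


class OracleQMProvider:
    """QM provider returning the generator's latent values exactly."""

    name = "synthetic-oracle"

    def __init__(self, truth: GroundTruth):
        self._truth = truth

    def compute(self, smiles: str) -> QMRecord:
        rec = self._truth.qm_records.get(smiles)
        if rec is None:
            raise CoverageError(f"no oracle QM record for {smiles}")
        return rec


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

_SOLVENT_NAMES = [
    "dmf", "dcm", "thf", "acetonitrile", "dmso", "dioxane", "toluene",
    "ethyl acetate", "chloroform", "nmp", "methanol", "pyridine",
]
_REAGENT_NAMES = [
    "dmap", "hobt", "hoat", "triethylamine", "diisopropylethylamine",
    "n-methylmorpholine", "sodium bicarbonate", "oxyma", "collidine", "imidazole",
]
_CONDITION_NAMES = [
    "rt", "reflux", "inert atmosphere", "dark", "microwave", "sonication", "0 c",
]


@dataclass
class _Proto:
    acid: str
    amine: str
    product: str
    agent: str
    context: Context
    latent: float
    observed: float
    synthetic: str = ""  # "", "cliff-hi", "cliff-lo", "uncertain"


def _sample_context(rng: np.random.Generator, vocab: dict[str, list[str]]) -> Context:
    reagents = list(
        rng.choice(vocab["reagent"], size=rng.integers(1, 3), replace=False)
    )
    solvents = [str(rng.choice(vocab["solvent"]))]
    conditions = (
        [str(rng.choice(vocab["condition"]))] if rng.random() < 0.6 else []
    )
    temperature = float(np.round(rng.normal(25, 15), 1)) if rng.random() < 0.8 else None
    time_h = float(np.round(rng.lognormal(1.5, 0.8), 1)) if rng.random() < 0.7 else None
    return Context(
        reagents=[str(r) for r in reagents],
        solvents=solvents,
        conditions=conditions,
        temperature_c=temperature,
        time_h=time_h,
    )


def _remote_decorations(acid_smiles: str) -> list[str]:
    """Acid variants with a methyl or methoxy added to an aromatic CH at
    least four bonds from the carboxyl carbon (far from the reaction center)."""
    mol = Chem.MolFromSmiles(acid_smiles)
    c_idx, _o1, _o2 = find_carboxyl(mol)
    dmat = Chem.GetDistanceMatrix(mol)
    out = []
    for atom in mol.GetAtoms():
        if not (atom.GetIsAromatic() and atom.GetSymbol() == "C"):
            continue
        if atom.GetTotalNumHs() < 1 or dmat[c_idx][atom.GetIdx()] < 4:
            continue
        for group in ("methyl", "methoxy"):
            rw = Chem.RWMol(mol)
            if group == "methyl":
                new_c = rw.AddAtom(Chem.Atom(6))
                rw.AddBond(atom.GetIdx(), new_c, Chem.BondType.SINGLE)
            else:
                new_o = rw.AddAtom(Chem.Atom(8))
                new_c = rw.AddAtom(Chem.Atom(6))
                rw.AddBond(atom.GetIdx(), new_o, Chem.BondType.SINGLE)
                rw.AddBond(new_o, new_c, Chem.BondType.SINGLE)
            try:
                edited = rw.GetMol()
                Chem.SanitizeMol(edited)
                smiles = Chem.MolToSmiles(edited)
            except Exception:
                continue
            if _usable_acid(smiles) and smiles != acid_smiles:
                out.append(smiles)
    return out


def _cliff_feature(proto: _Proto, vocab_pairs, n_bits: int = 2048) -> np.ndarray:
    fp = np.concatenate(
        [morgan_fingerprint(proto.acid, 2, n_bits), morgan_fingerprint(proto.amine, 2, n_bits)]
    )
    ctx = np.zeros(len(vocab_pairs))
    index = {p: i for i, p in enumerate(vocab_pairs)}
    for pair in proto.context.labels():
        if pair in index:
            ctx[index[pair]] = 1.0
    return np.concatenate([fp, ctx])


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    return float(a @ b / (na * nb))


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[ReactionDataset, GroundTruth]:
    """Emit a synthetic reaction dataset plus its ground truth.

    Deterministic under ``config.seed``: the same configuration reproduces
    the emitted CSV byte-for-byte.  Every record passes ``validate_record``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    acids, amines_by_class = build_fragment_library(config)
    amines = [s for cls in AmineClass for s in amines_by_class[cls]]

    vocab = {
        "solvent": _SOLVENT_NAMES[: config.n_solvents],
        "reagent": _REAGENT_NAMES[: config.n_reagents],
        "condition": _CONDITION_NAMES[: config.n_conditions],
    }
    vocab_pairs = [
        (f, l) for f in ("reagent", "solvent", "condition") for l in vocab[f]
    ]
    context_table = {
        pair: float(rng.normal(0, sd))
        for pair, sd in zip(
            vocab_pairs,
            itertools.chain(
                itertools.repeat(1.0, len(vocab["reagent"])),
                itertools.repeat(1.5, len(vocab["solvent"])),
                itertools.repeat(1.0, len(vocab["condition"])),
            ),
        )
    }

    # calibrate the intercept so the sampled latent mean hits the target
    struct_cache: dict[tuple[str, str], float] = {}

    def struct(acid: str, amine: str) -> float:
        key = (acid, amine)
        if key not in struct_cache:
            struct_cache[key] = _structural_part(
                structure_terms(acid, amine), config.coefficients
            )
        return struct_cache[key]

    n_uncertain_extra = config.n_planted_uncertain * (config.uncertain_group_size - 1)
    n_base = config.n_reactions - config.n_planted_cliffs - n_uncertain_extra
    if n_base < config.n_planted_cliffs + config.n_planted_uncertain:
        raise GenerationError("too few base reactions to host the planted structure")

    base_pairs = [
        (acids[rng.integers(len(acids))], amines[rng.integers(len(amines))])
        for _ in range(n_base)
    ]
    contexts = [_sample_context(rng, vocab) for _ in range(n_base)]
    agents = [("EDC", "DCC", "DIC")[rng.integers(3)] for _ in range(n_base)]

    mean_struct = float(np.mean([struct(a, m) for a, m in base_pairs]))
    mean_ctx = float(np.mean([_context_part(c, context_table) for c in contexts]))
    coeff = LatentCoefficients(
        intercept=config.target_mean_yield - mean_struct - mean_ctx,
        ewg=config.coefficients.ewg,
        aromatic_acid=config.coefficients.aromatic_acid,
        acid_size=config.coefficients.acid_size,
        steric=config.coefficients.steric,
        class_offsets=config.coefficients.class_offsets,
    )


    protos: list[_Proto] = []
    for (acid, amine), ctx, agent in zip(base_pairs, contexts, agents):
        lat = latent_yield(acid, amine, ctx, coeff, context_table)
        obs = float(min(100.0, max(0.0, lat + rng.normal(0, config.yield_noise_sd))))
        protos.append(_Proto(acid, amine, product_of(acid, amine), agent, ctx, lat, obs))

    # ---- plant reactivity cliffs ------------------------------------------
    cliff_pairs_proto: list[tuple[_Proto, _Proto]] = []
    candidates = rng.permutation(n_base)
    used: set[int] = set()
    ci = 0
    for idx in candidates:
        if len(cliff_pairs_proto) == config.n_planted_cliffs:
            break
        if idx in used:
            continue
        base = protos[idx]
        variants = _remote_decorations(base.acid)
        if not variants:
            continue
        partner = None
        for var in variants:
            cand = _Proto(
                var, base.amine, product_of(var, base.amine), base.agent,
                base.context,
                latent_yield(var, base.amine, base.context, coeff, context_table),
                0.0,
            )
            sim = _cosine(
                _cliff_feature(base, vocab_pairs), _cliff_feature(cand, vocab_pairs)
            )
            if sim >= config.cliff_sim_threshold:
                partner = cand
                break
        if partner is None:
            continue
        y_hi = float(rng.uniform(max(72.0, config.cliff_yield_gap + 2.0), 95.0))
        y_lo = float(
            max(0.5, y_hi - (config.cliff_yield_gap + rng.uniform(0.0, 10.0)))
        )
        if y_hi - y_lo < config.cliff_yield_gap:
            y_lo = y_hi - config.cliff_yield_gap
        if rng.random() < 0.5:
            base.observed, partner.observed = y_hi, y_lo
            base.synthetic, partner.synthetic = "cliff-hi", "cliff-lo"
        else:
            base.observed, partner.observed = y_lo, y_hi
            base.synthetic, partner.synthetic = "cliff-lo", "cliff-hi"
        used.add(idx)
        cliff_pairs_proto.append((base, partner))
        ci += 1
    if len(cliff_pairs_proto) < config.n_planted_cliffs:
        raise GenerationError(
            f"could only plant {len(cliff_pairs_proto)} of "
            f"{config.n_planted_cliffs} cliffs at similarity >= "
            f"{config.cliff_sim_threshold}"
        )

    # ---- plant uncertain groups -------------------------------------------
    uncertain_groups_proto: list[list[_Proto]] = []
    lo, hi = config.uncertain_span
    for idx in candidates[::-1]:
        if len(uncertain_groups_proto) == config.n_planted_uncertain:
            break
        if idx in used:
            continue
        base = protos[idx]
        yields = rng.uniform(lo, hi, size=config.uncertain_group_size)
        while len(set(np.round(yields, 1))) < 2:  # need >= 2 distinct yields
            yields = rng.uniform(lo, hi, size=config.uncertain_group_size)
        group = [base]
        base.observed = float(round(yields[0], 1))
        base.synthetic = "uncertain"
        for y in yields[1:]:
            dup = _Proto(
                base.acid, base.amine, base.product, base.agent, base.context,
                base.latent, float(round(y, 1)), "uncertain",
            )
            group.append(dup)
        used.add(idx)
        uncertain_groups_proto.append(group)
    if len(uncertain_groups_proto) < config.n_planted_uncertain:
        raise GenerationError("could not plant the requested uncertain groups")

    all_protos = protos + [p for _, p in cliff_pairs_proto]
    for g in uncertain_groups_proto:
        all_protos.extend(g[1:])
    order = rng.permutation(len(all_protos))
    shuffled = [all_protos[i] for i in order]

    ids = {id(p): f"rxn-{i:06d}" for i, p in enumerate(shuffled)}
    records = [
        ReactionRecord(
            reaction_id=ids[id(p)],
            acid=Molecule(p.acid, "acid"),
            amine=Molecule(p.amine, "amine"),
            product=Molecule(p.product, "product"),
            coupling_agent=p.agent,
            yield_percent=round(p.observed, 1),
            context=p.context,
        )
        for p in shuffled
    ]
    dataset = ReactionDataset(records)

    # ---- latent molecular energies and oracle QM records ------------------
    truth = _build_ground_truth(
        config, rng, shuffled, ids, coeff, context_table, struct
    )
    truth.cliff_pairs = [
        (ids[id(a)], ids[id(b)]) for a, b in cliff_pairs_proto
    ]
    truth.uncertain_groups = [
        [ids[id(p)] for p in group] for group in uncertain_groups_proto
    ]
    return dataset, truth


def _build_ground_truth(
    config: GeneratorConfig,
    rng: np.random.Generator,
    protos: list[_Proto],
    ids: dict[int, str],
    coeff: LatentCoefficients,
    context_table: dict[tuple[str, str], float],
    struct,
) -> GroundTruth:
    latent = {ids[id(p)]: p.latent for p in protos}

    # per-fragment energies; product energy carries the reaction-energy signal
    frag_energy: dict[str, float] = {}
    for p in protos:
        for s in (p.acid, p.amine):
            if s not in frag_energy:
                n_heavy = Chem.MolFromSmiles(s).GetNumAtoms()
                frag_energy[s] = float(-38.0 * n_heavy + rng.normal(0, 3.0))

    pair_struct: dict[tuple[str, str], float] = {}
    pair_product: dict[tuple[str, str], str] = {}
    for p in protos:
        key = (p.acid, p.amine)
        pair_struct.setdefault(key, struct(p.acid, p.amine))
        pair_product.setdefault(key, p.product)

    obs = np.array([p.observed for p in protos])
    s_per_record = np.array([struct(p.acid, p.amine) for p in protos])
    var_s = float(s_per_record.var())
    sd_y = float(obs.std())
    rho = config.target_energy_corr
    sigma_r = 10.0
    a = rho * sd_y * sigma_r / var_s if var_s > 0 else 0.0
    resid_var = sigma_r**2 - a**2 * var_s
    if resid_var <= 0:
        raise GenerationError(
            "target energy correlation is too strong for the latent variance"
        )
    # constant shift keeps the condensation exothermic on average without
    # touching the correlation structure
    keys = sorted(pair_struct)
    r_pair = {
        k: float(
            -15.0
            + a * (pair_struct[k] - s_per_record.mean())
            + rng.normal(0, math.sqrt(resid_var))
        )
        for k in keys
    }

    molecule_energy = dict(frag_energy)
    molecule_energy["O"] = WATER_ENERGY
    for (acid, amine), r in r_pair.items():
        prod = pair_product[(acid, amine)]
        molecule_energy[prod] = (
            frag_energy[acid] + frag_energy[amine] - WATER_ENERGY + r
        )

    qm_records = _oracle_qm_records(
        rng, protos, molecule_energy, coeff, struct
    )
    return GroundTruth(
        cliff_pairs=[],
        uncertain_groups=[],
        latent_yield=latent,
        molecule_energy=molecule_energy,
        qm_records=qm_records,
        coefficients=coeff,
        context_table=context_table,
    )


def _oracle_qm_records(
    rng: np.random.Generator,
    protos: list[_Proto],
    molecule_energy: dict[str, float],
    coeff: LatentCoefficients,
    struct,
) -> dict[str, QMRecord]:
    """Latent QM records whose reactivity quantities encode the structure
    terms (with small jitter), the way real electronic descriptors track
    nucleophilicity and electrophilicity."""
    acid_term: dict[str, float] = {}
    amine_term: dict[str, float] = {}
    for p in protos:
        if p.acid not in acid_term:
            t = structure_terms(p.acid, "CN")
            acid_term[p.acid] = (
                coeff.ewg * t["ewg"]
                + coeff.aromatic_acid * t["aromatic_acid"]
                + coeff.acid_size * t["acid_size"]
            )
        if p.amine not in amine_term:
            t = structure_terms("CC(=O)O", p.amine)
            amine_term[p.amine] = coeff.steric * t["steric"] + dict(
                coeff.class_offsets
            )[t["amine_class"]]

    records: dict[str, QMRecord] = {}

    def base_record(smiles: str, energy: float) -> QMRecord:
        n = Chem.MolFromSmiles(smiles).GetNumAtoms()
        return QMRecord(
            energy=energy,
            charges=rng.normal(0, 0.05, n),
            fukui_plus=np.abs(rng.normal(0.05, 0.02, n)),
            fukui_minus=np.abs(rng.normal(0.05, 0.02, n)),
            ionization_potential=float(rng.normal(9.0, 0.1)),
            electron_affinity=float(rng.normal(1.0, 0.1)),
        )

    for smiles in sorted(acid_term):
        rec = base_record(smiles, molecule_energy[smiles])
        mol = Chem.MolFromSmiles(smiles)
        c_idx, _o1, _o2 = find_carboxyl(mol)
        t = acid_term[smiles]
        rec.charges[c_idx] = 0.35 + 0.01 * t + rng.normal(0, 0.005)
        rec.fukui_plus[c_idx] = 0.15 + 0.012 * t + rng.normal(0, 0.003)
        rec.ionization_potential = 9.5 - 0.05 * t + float(rng.normal(0, 0.02))
        rec.electron_affinity = 1.2 + 0.04 * t + float(rng.normal(0, 0.02))
        records[smiles] = rec
    for smiles in sorted(amine_term):
        rec = base_record(smiles, molecule_energy[smiles])
        n_idx = find_reactive_amine(Chem.MolFromSmiles(smiles))
        t = amine_term[smiles]
        rec.charges[n_idx] = -0.65 + 0.008 * t + rng.normal(0, 0.004)
        rec.fukui_minus[n_idx] = 0.25 + 0.01 * t + rng.normal(0, 0.003)
        rec.ionization_potential = 8.8 - 0.05 * t + float(rng.normal(0, 0.02))
        rec.electron_affinity = 0.6 + 0.03 * t + float(rng.normal(0, 0.02))
        records[smiles] = rec
    for p in protos:
        if p.product not in records:
            records[p.product] = base_record(p.product, molecule_energy[p.product])
    records["O"] = QMRecord(
        energy=WATER_ENERGY,
        charges=np.array([-0.8]),
        fukui_plus=np.array([0.1]),
        fukui_minus=np.array([0.4]),
        ionization_potential=12.6,
        electron_affinity=-0.5,
    )
    return records
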