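"""Domain types, canonicalization, validation and file I/O for reaction tables.

A literature amide-coupling dataset couples a carboxylic acid with an amine
under a carbodiimide coupling agent (EDC, DCC or DIC) to give an amide plus
water.  Every record carries the reactant/product structures, the reported
yield, and the reaction context (reagents, solvents, temperature, time,
free-form condition labels).  These types are the in-memory currency of the
whole pipeline; everything downstream (mechanism augmentation, featurization,
benchmarking, cliff auditing) consumes :class:`ReactionDataset`.
"""

from __future__ import annotations

import functools
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem


__all__ = [
    "Molecule",
    "Conformer3D",
    "Context",
    "ReactionRecord",
    "ReactionDataset",
    "ContextVocabulary",
    "COUPLING_AGENTS",
    "CARBODIIMIDE_SMILES",
    "SmilesParseError",
    "SchemaError",
    "FormatError",
    "canonicalize",
    "mol_from_smiles",
    "molecular_formula",
    "validate_record",
    "read_reaction_table",
    "write_reaction_table",
    "read_conformer",
    "write_xyz",
]

#: Carbodiimide coupling agents handled by the pipeline (structures are fixed
#: constants; the catalyst set is closed).
CARBODIIMIDE_SMILES: dict[str, str] = {
    "EDC": "CCN=C=NCCCN(C)C",
    "DCC": "C1CCCCC1N=C=NC1CCCCC1",
    "DIC": "CC(C)N=C=NC(C)C",
}
COUPLING_AGENTS = tuple(CARBODIIMIDE_SMILES)

WATER_FORMULA = Counter({"H": 2, "O": 1})


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class SchemaError(ValueError):
    """Raised when an input table does not match the expected schema."""


class FormatError(ValueError):
    """Raised when a structure file is malformed."""


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES for *smiles*.

    Canonicalization is idempotent: ``canonicalize(canonicalize(s)) ==
    canonicalize(s)``.  Unparseable input raises :class:`SmilesParseError`
    naming the offending string.
    """
    return _canonicalize_cached(smiles)


@functools.lru_cache(maxsize=500_000)
def _canonicalize_cached(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse *smiles* into an RDKit molecule, raising on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    return mol


def molecular_formula(mol_or_smiles: "Chem.Mol | str") -> Counter:
    """Element -> count map including hydrogens."""
    mol = (
        mol_from_smiles(mol_or_smiles)
        if isinstance(mol_or_smiles, str)
        else mol_or_smiles
    )
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
    counts += Counter()  # drop zero entries
    return counts


@dataclass
class Conformer3D:
    """A single low-energy 3D conformer.

    Coordinates are in Angstrom.  ``energy`` is the surrogate electronic
    energy in whatever units the producing provider uses; ``None`` marks a
    missing value (e.g. an XYZ file without an energy comment).
    """

    species: list[str]
    coords: "list[tuple[float, float, float]]"
    energy: float | None = None
    net_charge: int = 0

    def __post_init__(self) -> None:
        if len(self.species) != len(self.coords):
            raise ValueError(
                f"species/coords length mismatch: {len(self.species)} vs {len(self.coords)}"
            )
        for row in self.coords:
            if len(row) != 3 or not all(math.isfinite(x) for x in row):
                raise ValueError(f"non-finite or malformed coordinate row: {row!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.species)


@dataclass
class Molecule:
    """A molecule in a fixed reaction role, stored as canonical SMILES."""

    smiles: str
    role: str = "reactant"
    conformer: Conformer3D | None = None

    ROLES = ("acid", "amine", "product", "intermediate", "carbodiimide", "reactant")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ValueError(f"unknown molecule role: {self.role!r}")
        self.smiles = canonicalize(self.smiles)

    def to_rdkit(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)

    @property
    def formula(self) -> Counter:
        return molecular_formula(self.smiles)


def _norm_label(label: str) -> str:
    return " ".join(label.strip().lower().split())


@dataclass
class Context:
    """Reaction context: categorical labels plus optional numeric conditions.

    Labels are normalized (lowercased, whitespace-collapsed) on construction
    so that vocabulary building is deterministic.  Missing temperature/time
    stay ``None`` — never silently defaulted; encoders decide what to do.
    """

    reagents: list[str] = field(default_factory=list)
    solvents: list[str] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)
    temperature_c: float | None = None
    time_h: float | None = None

    def __post_init__(self) -> None:
        for fname in ("reagents", "solvents", "conditions"):
            labels = getattr(self, fname)
            cleaned = [_norm_label(l) for l in labels]
            if any(not l for l in cleaned):
                raise ValueError(f"empty label in context field {fname!r}")
            setattr(self, fname, cleaned)

    def labels(self) -> list[tuple[str, str]]:
        """All (field, label) pairs, field in {reagent, solvent, condition}."""
        out = [("reagent", l) for l in self.reagents]
        out += [("solvent", l) for l in self.solvents]
        out += [("condition", l) for l in self.conditions]
        return out


@dataclass
class ContextVocabulary:
    """Ordered unique list of (field, label) pairs defining the context encoding."""

    labels: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("context vocabulary labels must be unique")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def dimension(self) -> int:
        return len(self.labels)

    def index(self, field_name: str, label: str) -> int | None:
        return self._index.get((field_name, label))

    @classmethod
    def from_contexts(cls, contexts: Iterable[Context]) -> "ContextVocabulary":
        seen: dict[tuple[str, str], None] = {}
        for ctx in contexts:
            for pair in ctx.labels():
                seen.setdefault(pair)
        return cls(sorted(seen))


@dataclass
class ReactionRecord:
    """One amide coupling: acid + amine -> product + H2O, under a carbodiimide."""

    reaction_id: str
    acid: Molecule
    amine: Molecule
    product: Molecule
    coupling_agent: str
    yield_percent: float
    context: Context = field(default_factory=Context)
    intermediate: Molecule | None = None
    synthetic_negative: bool = False

    def __post_init__(self) -> None:
        if not self.reaction_id:
            raise ValueError("reaction_id must be non-empty")


def validate_record(record: ReactionRecord) -> list[str]:
    """Check a record against the A + B = C + H2O contract.

    Returns a list of violation messages; an empty list means the record is
    valid.  Violations are returned, never raised.
    """
    violations: list[str] = []
    if record.coupling_agent not in COUPLING_AGENTS:
        violations.append(
            f"unknown coupling agent {record.coupling_agent!r}; expected one of {COUPLING_AGENTS}"
        )
    if not (0.0 <= record.yield_percent <= 100.0):
        violations.append(f"yield out of range: {record.yield_percent}")
    try:
        lhs = record.acid.formula + record.amine.formula
        rhs = record.product.formula + WATER_FORMULA
        if lhs != rhs:
            violations.append(
                "formula mismatch: acid+amine != product+H2O "
                f"({dict(lhs)} vs {dict(rhs)})"
            )
    except SmilesParseError as exc:  # pragma: no cover - molecules pre-parsed
        violations.append(str(exc))
    if record.intermediate is not None and record.coupling_agent in COUPLING_AGENTS:
        agent = molecular_formula(CARBODIIMIDE_SMILES[record.coupling_agent])
        if record.intermediate.formula != record.acid.formula + agent:
            violations.append("intermediate formula mismatch: acid+carbodiimide")
    return violations


@dataclass
class ReactionDataset:
    """Ordered collection of reaction records plus the context vocabulary."""

    records: list[ReactionRecord]
    context_vocab: ContextVocabulary | None = None

    def __post_init__(self) -> None:
        ids = [r.reaction_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate reaction_id values: {dupes[:5]}")
        if self.context_vocab is None:
            self.context_vocab = ContextVocabulary.from_contexts(
                r.context for r in self.records
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def yields(self) -> "list[float]":
        return [r.yield_percent for r in self.records]

    def subset(self, indices: Sequence[int]) -> "ReactionDataset":
        """Row subset preserving order; vocabulary is rebuilt from the subset."""
        return ReactionDataset([self.records[i] for i in indices])


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "reaction_id",
    "acid_smiles",
    "amine_smiles",
    "product_smiles",
    "intermediate_smiles",
    "coupling_agent",
    "yield",
    "reagents",
    "solvents",
    "temperature_c",
    "time_h",
    "conditions",
]

_LIST_SEP = ";"


def _join(labels: list[str]) -> str:
    return _LIST_SEP.join(labels)


def _split(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return []
    return [part for part in str(cell).split(_LIST_SEP) if part.strip()]


def _opt_float(cell) -> float | None:
    if cell is None or cell == "":
        return None
    if isinstance(cell, float) and math.isnan(cell):
        return None
    return float(cell)


def read_reaction_table(
    path: "str | Path", schema: dict[str, str] | None = None
) -> ReactionDataset:
    """Read a reaction CSV into a :class:`ReactionDataset`.

    *schema* optionally maps the expected column names (:data:`CSV_COLUMNS`)
    to the names actually present in the file.  Row order is preserved; the
    context vocabulary is built from the observed labels.  Rows with invalid
    SMILES are collected and reported together with their row indices.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    required = {"reaction_id", "acid_smiles", "amine_smiles", "product_smiles",
                "coupling_agent", "yield"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")

    records: list[ReactionRecord] = []
    row_errors: list[str] = []
    for i, row in enumerate(df.to_dict("records")):
        get = lambda col, default="": row.get(col, default)
        try:
            inter_smiles = get("intermediate_smiles")
            record = ReactionRecord(
                reaction_id=str(get("reaction_id")),
                acid=Molecule(get("acid_smiles"), "acid"),
                amine=Molecule(get("amine_smiles"), "amine"),
                product=Molecule(get("product_smiles"), "product"),
                intermediate=(
                    Molecule(inter_smiles, "intermediate") if inter_smiles else None
                ),
                coupling_agent=str(get("coupling_agent")),
                yield_percent=float(get("yield")),
                context=Context(
                    reagents=_split(get("reagents")),
                    solvents=_split(get("solvents")),
                    conditions=_split(get("conditions")),
                    temperature_c=_opt_float(get("temperature_c")),
                    time_h=_opt_float(get("time_h")),
                ),
            )
        except (ValueError, SmilesParseError) as exc:
            row_errors.append(f"row {i}: {exc}")
            continue
        records.append(record)
    if row_errors:
        raise SchemaError(
            f"{len(row_errors)} invalid rows:\n" + "\n".join(row_errors[:20])
        )
    return ReactionDataset(records)


def write_reaction_table(dataset: ReactionDataset, path: "str | Path") -> None:
    """Write *dataset* to CSV so that :func:`read_reaction_table` round-trips it.

    Missing numeric context fields are serialized as empty cells and read
    back as missing.  Multi-label fields are ';'-joined.
    """
    rows = []
    for r in dataset.records:
        rows.append(
            {
                "reaction_id": r.reaction_id,
                "acid_smiles": r.acid.smiles,
                "amine_smiles": r.amine.smiles,
                "product_smiles": r.product.smiles,
                "intermediate_smiles": r.intermediate.smiles if r.intermediate else "",
                "coupling_agent": r.coupling_agent,
                "yield": repr(r.yield_percent),
                "reagents": _join(r.context.reagents),
                "solvents": _join(r.context.solvents),
                "temperature_c": "" if r.context.temperature_c is None else repr(r.context.temperature_c),
                "time_h": "" if r.context.time_h is None else repr(r.context.time_h),
                "conditions": _join(r.context.conditions),
            }
        )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Conformer I/O
# ---------------------------------------------------------------------------

_ENERGY_PROPS = ("energy", "Energy", "E", "E_tot", "MMFF_energy")


def _parse_xyz(text: str) -> Conformer3D:
    lines = text.strip("\n").splitlines()
    if len(lines) < 2:
        raise FormatError("XYZ file too short")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"bad XYZ atom-count line: {lines[0]!r}") from exc
    body = lines[2 : 2 + n]
    if len(body) != n:
        raise FormatError(f"XYZ declares {n} atoms but lists {len(body)}")
    species, coords = [], []
    for line in body:
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"bad XYZ atom line: {line!r}")
        species.append(parts[0])
        coords.append(tuple(float(x) for x in parts[1:4]))
    energy = None
    comment = lines[1]
    for token in comment.replace("=", " ").split():
        try:
            energy = float(token)
            break
        except ValueError:
            continue
    return Conformer3D(species=species, coords=coords, energy=energy)


def read_conformer(path: "str | Path") -> Conformer3D:
    """Read a single conformer from an SDF or XYZ file.

    The energy is taken from the SDF property block (first of
    ``energy``/``Energy``/``E``/...) or from the XYZ comment line when a
    number is present; otherwise it is left missing.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        return _parse_xyz(path.read_text())
    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mol = next((m for m in supplier if m is not None), None)
        if mol is None or mol.GetNumConformers() == 0:
            raise FormatError(f"no 3D molecule found in {path}")
        conf = mol.GetConformer()
        species = [a.GetSymbol() for a in mol.GetAtoms()]
        coords = [tuple(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        energy = None
        for prop in _ENERGY_PROPS:
            if mol.HasProp(prop):
                energy = float(mol.GetProp(prop))
                break
        charge = sum(a.GetFormalCharge() for a in mol.GetAtoms())
        return Conformer3D(species=species, coords=coords, energy=energy, net_charge=charge)
    raise FormatError(f"unsupported conformer format: {path.suffix!r}")


def write_xyz(conf: Conformer3D, path: "str | Path") -> None:
    lines = [str(conf.n_atoms)]
    lines.append("" if conf.energy is None else f"energy={conf.energy!r}")
    for sym, (x, y, z) in zip(conf.species, conf.coords):
        lines.append(f"{sym} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")
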