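"""Mechanism-derived reaction augmentation.

Carbodiimide-mediated amide coupling proceeds by addition of the carboxylic
acid across the N=C=N bond of the coupling agent, giving an O-acylisourea
intermediate (the rate-determining step), which the amine then attacks to
form the amide.  This module generates those structures deterministically,
annotates reaction centers (atoms whose bond incidence changes), and
classifies amines into the three nucleophile classes used for the subset
analyses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from rdkit import Chem

from .core import (
    CARBODIIMIDE_SMILES,
    Molecule,
    SmilesParseError,
    mol_from_smiles,
)

__all__ = [
    "AmineClass",
    "ReactionCenters",
    "MechanismError",
    "classify_amine",
    "condense_product",
    "make_o_acylisourea",
    "annotate_reaction_centers",
    "find_carboxyl",
    "find_reactive_amine",
]


class MechanismError(ValueError):
    """Raised when a molecule violates a mechanistic precondition."""


class AmineClass(enum.Enum):
    PRIMARY_ALIPHATIC = "primary_aliphatic"
    PRIMARY_AROMATIC = "primary_aromatic"
    SECONDARY = "secondary"


@dataclass(frozen=True)
class ReactionCenters:
    """Atoms whose connectivity changes during the coupling.

    Indices refer to canonical atom order of the respective molecule: in the
    acid the carboxyl carbon and the departing hydroxyl oxygen, in the amine
    the nucleophilic nitrogen, in the product the amide carbon and nitrogen.
    """

    acid_atoms: frozenset[int]
    amine_atoms: frozenset[int]
    product_atoms: frozenset[int]
    #: convenience handles into the sets above
    acid_carbon: int = -1
    amine_nitrogen: int = -1


_CARBOXYL = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")
# sp3 or aryl-attached N with at least one H, not an amide/sulfonamide N,
# not aromatic itself (ring N like pyridine/pyrrole cannot couple here).
_REACTIVE_AMINE = Chem.MolFromSmarts(
    "[NX3;H1,H2,H3;!$(N[C,S]=[O,S,N]);!$(N=*);!$([N]~[!#6]);!n]"
)


def find_carboxyl(mol: Chem.Mol) -> tuple[int, int, int]:
    """Return (carboxyl C, carbonyl O, hydroxyl O) indices of the unique COOH."""
    matches = mol.GetSubstructMatches(_CARBOXYL)
    if len(matches) != 1:
        raise MechanismError(
            f"expected exactly one carboxylic acid group, found {len(matches)} "
            f"in {Chem.MolToSmiles(mol)}"
        )
    return matches[0]


def find_reactive_amine(mol: Chem.Mol) -> int:
    """Return the index of the unique reactive N-H amine nitrogen.

    Amide/sulfonamide nitrogens and aromatic ring nitrogens are not reactive
    sites; a tertiary nitrogen cannot couple and is rejected.
    """
    matches = {m[0] for m in mol.GetSubstructMatches(_REACTIVE_AMINE)}
    if not matches:
        raise MechanismError(
            f"no reactive amine nitrogen in {Chem.MolToSmiles(mol)}"
        )
    if len(matches) > 1:
        # symmetry-equivalent nitrogens (e.g. a symmetric diamine) are one
        # site chemically; inequivalent candidates are a genuine ambiguity
        ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
        if len({ranks[i] for i in matches}) > 1:
            raise MechanismError(
                f"multiple candidate amine nitrogens in {Chem.MolToSmiles(mol)}"
            )
    return min(matches)


def classify_amine(amine: "Molecule | str") -> AmineClass:
    """Classify the reactive amine as primary aliphatic/aromatic or secondary."""
    mol = mol_from_smiles(amine.smiles if isinstance(amine, Molecule) else amine)
    n_idx = find_reactive_amine(mol)
    atom = mol.GetAtomWithIdx(n_idx)
    carbons = [nb for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 6]
    n_h = atom.GetTotalNumHs()
    if len(carbons) == 1 and n_h >= 2:
        if carbons[0].GetIsAromatic():
            return AmineClass.PRIMARY_AROMATIC
        return AmineClass.PRIMARY_ALIPHATIC
    if len(carbons) == 2 and n_h == 1:
        return AmineClass.SECONDARY
    raise MechanismError(
        f"amine nitrogen with {len(carbons)} carbon substituents and {n_h} H "
        f"cannot couple: {Chem.MolToSmiles(mol)}"
    )


def _combine_tracked(a: Chem.Mol, b: Chem.Mol) -> tuple[Chem.RWMol, int]:
    """Combine two molecules; returns RWMol and the index offset of *b*."""
    return Chem.RWMol(Chem.CombineMols(a, b)), a.GetNumAtoms()


def _condense_indices(
    acid: Chem.Mol, amine: Chem.Mol
) -> tuple[Chem.Mol, int, int]:
    """Build the amide product; return (product mol, amide C idx, amide N idx)."""
    c_idx, _o_dbl, o_h = find_carboxyl(acid)
    n_idx = find_reactive_amine(amine)
    rw, offset = _combine_tracked(acid, amine)
    rw.AddBond(c_idx, offset + n_idx, Chem.BondType.SINGLE)
    rw.RemoveAtom(o_h)  # hydroxyl O departs with the water

    def shift(i: int) -> int:
        return i - 1 if i > o_h else i

    product = rw.GetMol()
    Chem.SanitizeMol(product)
    return product, shift(c_idx), shift(offset + n_idx)


def condense_product(acid: "Molecule | str", amine: "Molecule | str") -> Molecule:
    """Form the amide from one COOH and one reactive N-H amine (losing water)."""
    acid_s = acid.smiles if isinstance(acid, Molecule) else acid
    amine_s = amine.smiles if isinstance(amine, Molecule) else amine
    product, _, _ = _condense_indices(mol_from_smiles(acid_s), mol_from_smiles(amine_s))
    return Molecule(Chem.MolToSmiles(product), "product")


_NCN = Chem.MolFromSmarts("[NX2]=[CX2]=[NX2]")


def _substituent_size(mol: Chem.Mol, n_idx: int, central_c: int) -> int:
    """Heavy-atom count of the substituent on nitrogen *n_idx* (excluding N, C)."""
    seen = {n_idx, central_c}
    stack = [
        nb.GetIdx()
        for nb in mol.GetAtomWithIdx(n_idx).GetNeighbors()
        if nb.GetIdx() != central_c
    ]
    count = 0
    while stack:
        i = stack.pop()
        if i in seen:
            continue
        seen.add(i)
        count += 1
        stack.extend(
            nb.GetIdx() for nb in mol.GetAtomWithIdx(i).GetNeighbors()
            if nb.GetIdx() not in seen
        )
    return count


def make_o_acylisourea(
    acid: "Molecule | str", coupling_agent: str
) -> Molecule:
    """Add the acid across the carbodiimide N=C=N to give the O-acylisourea.

    The acyl oxygen bonds to the central carbodiimide carbon and the carboxyl
    proton moves to one nitrogen, giving R-C(=O)-O-C(=N-R')(NH-R'').  For an
    asymmetric carbodiimide (EDC) the proton goes to the nitrogen whose
    substituent has the smaller heavy-atom count (ties broken by canonical
    rank), which makes the output deterministic.
    """
    if coupling_agent not in CARBODIIMIDE_SMILES:
        raise MechanismError(f"unknown coupling agent: {coupling_agent!r}")
    acid_s = acid.smiles if isinstance(acid, Molecule) else acid
    acid_mol = mol_from_smiles(acid_s)
    agent = mol_from_smiles(CARBODIIMIDE_SMILES[coupling_agent])

    c_idx, _o_dbl, o_h = find_carboxyl(acid_mol)
    (n1, cc, n2), *extra = agent.GetSubstructMatches(_NCN)
    if extra:
        raise MechanismError("coupling agent has multiple carbodiimide groups")

    sizes = (
        _substituent_size(agent, n1, cc),
        _substituent_size(agent, n2, cc),
    )
    if sizes[0] != sizes[1]:
        proton_n = n1 if sizes[0] < sizes[1] else n2
    else:
        ranks = list(Chem.CanonicalRankAtoms(agent, breakTies=True))
        proton_n = n1 if ranks[n1] < ranks[n2] else n2

    rw, offset = _combine_tracked(acid_mol, agent)
    rw.AddBond(o_h, offset + cc, Chem.BondType.SINGLE)
    bond = rw.GetBondBetweenAtoms(offset + cc, offset + proton_n)
    bond.SetBondType(Chem.BondType.SINGLE)
    # implicit valence bookkeeping: O loses its H (2 bonds now), N gains one H
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Molecule(Chem.MolToSmiles(mol), "intermediate")


def annotate_reaction_centers(
    acid: "Molecule | str", amine: "Molecule | str", product: "Molecule | str"
) -> ReactionCenters:
    """Find the atoms whose bond incidence differs between the two sides.

    The constructed condensation product is matched onto the supplied product
    to transfer the amide C/N indices; failure to find a correspondence (the
    supplied product is not the condensation amide) is an annotation error.
    Output is invariant to atom renumbering of the inputs because all sites
    are located by substructure matching, not by positional convention.
    """
    acid_mol = mol_from_smiles(acid.smiles if isinstance(acid, Molecule) else acid)
    amine_mol = mol_from_smiles(amine.smiles if isinstance(amine, Molecule) else amine)
    given = mol_from_smiles(
        product.smiles if isinstance(product, Molecule) else product
    )
    c_idx, _o_dbl, o_h = find_carboxyl(acid_mol)
    n_idx = find_reactive_amine(amine_mol)
    built, amide_c, amide_n = _condense_indices(acid_mol, amine_mol)
    match = given.GetSubstructMatch(built)
    if not match or given.GetNumAtoms() != built.GetNumAtoms():
        raise MechanismError(
            "product does not correspond to the condensation of the given "
            "acid and amine"
        )
    return ReactionCenters(
        acid_atoms=frozenset({c_idx, o_h}),
        amine_atoms=frozenset({n_idx}),
        product_atoms=frozenset({match[amide_c], match[amide_n]}),
        acid_carbon=c_idx,
        amine_nitrogen=n_idx,
    )
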