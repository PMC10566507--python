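"""Geometry-derived descriptors: conformers, AEVs, buried volume, QM features.

Atomic environment vectors (AEVs) are smooth-cutoff symmetry functions of the
radial and angular neighbor distribution around each atom:

* radial, per element channel X and shell center Rs:
  ``G = sum_{j in X} exp(-eta (R_ij - Rs)^2) * fc(R_ij)``
* angular, per unordered element pair (X, Y), shell center Rs and angle
  center theta_s:
  ``G = 2^(1-zeta) * sum_{j<k} (1 + cos(theta_ijk - theta_s))^zeta
  * exp(-eta_a ((R_ij + R_ik)/2 - Rs)^2) * fc(R_ij) * fc(R_ik)``

with the smooth cosine cutoff ``fc(R) = 0.5 cos(pi R / Rc) + 0.5`` for
``R < Rc`` and 0 beyond.  Both are invariant to rigid motion and to
permutation of identical atoms; summing atom AEVs gives a molecule vector.

QM-style reactivity features (electronic energies, charges, Fukui indices,
IP/EA) come from a pluggable provider.  The default in the test pipeline is
the synthetic-data oracle, which returns the generator's latent values; a
small additive group-contribution provider is included for demos on real
SMILES.  The electronic reaction energy is
``dE_rxn = E(product) + E(water) - E(acid) - E(amine)``.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .core import Conformer3D, Molecule, mol_from_smiles
from .mechanism import ReactionCenters

__all__ = [
    "AEVParams",
    "StericParams",
    "QMRecord",
    "QMProvider",
    "HeuristicQMProvider",
    "CoverageError",
    "EmbeddingError",
    "SUPPORTED_ELEMENTS",
    "embed_conformer",
    "compute_aev",
    "pool_aev",
    "aev_for_molecule",
    "buried_volume",
    "qm_features",
    "delta_e_rxn",
    "derive_reaction_qm",
    "REACTION_QM_NAMES",
    "BONDI_RADII",
]

#: Element coverage of the QM provider contract.
SUPPORTED_ELEMENTS = frozenset({"H", "C", "N", "O", "F", "Si", "P", "S", "Cl"})


class CoverageError(ValueError):
    """Molecule contains an element outside the provider's coverage."""


class EmbeddingError(RuntimeError):
    """3D embedding failed after retries."""


# ---------------------------------------------------------------------------
# Conformer embedding
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=50_000)
def _embed_cached(smiles: str, seed: int, n_tries: int, max_atoms: int) -> Conformer3D:
    mol = Chem.AddHs(mol_from_smiles(smiles))
    if mol.GetNumAtoms() > max_atoms:
        raise EmbeddingError(f"molecule exceeds atom limit ({max_atoms}): {smiles}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise EmbeddingError(f"disconnected molecule cannot be embedded: {smiles}")
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_tries, params=params)
    if not conf_ids:
        raise EmbeddingError(f"embedding failed for {smiles}")
    results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
    best, best_e = None, math.inf
    for cid, (converged, energy) in zip(conf_ids, results):
        if energy < best_e:
            best, best_e = cid, energy
    conf = mol.GetConformer(best)
    species = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = [tuple(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
    return Conformer3D(species=species, coords=coords, energy=best_e)


def embed_conformer(
    mol: "Molecule | str", seed: int = 0, n_tries: int = 10, max_atoms: int = 200
) -> Conformer3D:
    """Distance-geometry embedding + MMFF minimization, best of *n_tries*.

    Deterministic under a fixed seed.  The minimized force-field energy is
    stored as the conformer's surrogate energy.
    """
    smiles = mol.smiles if isinstance(mol, Molecule) else Molecule(mol).smiles
    return _embed_cached(smiles, seed, n_tries, max_atoms)


# ---------------------------------------------------------------------------
# Atomic environment vectors
# ---------------------------------------------------------------------------

DEFAULT_ELEMENTS = ("H", "C", "N", "O", "F", "Si", "P", "S", "Cl")


def _default_radial_centers() -> tuple[float, ...]:
    return tuple(np.linspace(0.9, 5.2, 16, endpoint=False))


def _default_angular_centers() -> tuple[float, ...]:
    return tuple(np.linspace(0.9, 3.5, 4, endpoint=False))


def _default_theta_centers() -> tuple[float, ...]:
    return tuple((np.arange(8) + 0.5) * np.pi / 8)


@dataclass(frozen=True)
class AEVParams:
    """Symmetry-function preset (all lengths in Angstrom, eta in 1/A^2)."""

    radial_cutoff: float = 5.2
    radial_eta: float = 16.0
    radial_centers: tuple[float, ...] = field(default_factory=_default_radial_centers)
    angular_cutoff: float = 3.5
    angular_eta: float = 8.0
    angular_centers: tuple[float, ...] = field(default_factory=_default_angular_centers)
    theta_centers: tuple[float, ...] = field(default_factory=_default_theta_centers)
    zeta: float = 32.0
    elements: tuple[str, ...] = DEFAULT_ELEMENTS

    def __post_init__(self) -> None:
        if self.radial_cutoff <= 0 or self.angular_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if max(self.radial_centers) >= self.radial_cutoff:
            raise ValueError("radial shell centers must lie below the cutoff")
        if max(self.angular_centers) >= self.angular_cutoff:
            raise ValueError("angular shell centers must lie below the cutoff")

    @property
    def n_radial(self) -> int:
        return len(self.elements) * len(self.radial_centers)

    @property
    def n_angular(self) -> int:
        n_el = len(self.elements)
        n_pairs = n_el * (n_el + 1) // 2
        return n_pairs * len(self.angular_centers) * len(self.theta_centers)

    @property
    def length(self) -> int:
        return self.n_radial + self.n_angular


def _cutoff(r: np.ndarray, rc: float) -> np.ndarray:
    out = np.zeros_like(r)
    mask = r < rc
    out[mask] = 0.5 * np.cos(np.pi * r[mask] / rc) + 0.5
    return out


def compute_aev(conf: Conformer3D, params: AEVParams | None = None) -> np.ndarray:
    """Per-atom AEVs for one conformer; shape (n_atoms, params.length).

    Invariant to rigid rotation/translation and to permutation of
    identical atoms.  Raises when a species is absent from the element
    channel list.
    """
    params = params or AEVParams()
    missing = set(conf.species) - set(params.elements)
    if missing:
        raise CoverageError(f"species outside AEV channel list: {sorted(missing)}")

    coords = np.asarray(conf.coords, dtype=np.float64)
    n = len(conf.species)
    el_index = {el: k for k, el in enumerate(params.elements)}
    species_idx = np.array([el_index[s] for s in conf.species])
    n_el = len(params.elements)
    pair_index = {}
    for a in range(n_el):
        for b in range(a, n_el):
            pair_index[(a, b)] = len(pair_index)
    n_pairs = len(pair_index)

    rs_r = np.asarray(params.radial_centers)
    rs_a = np.asarray(params.angular_centers)
    th_s = np.asarray(params.theta_centers)
    out = np.zeros((n, params.length), dtype=np.float64)
    if n == 1:
        return out

    diff = coords[None, :, :] - coords[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)

    # radial part
    fc_r = _cutoff(dist, params.radial_cutoff)
    for i in range(n):
        neigh = np.where(fc_r[i] > 0)[0]
        if neigh.size == 0:
            continue
        terms = (
            np.exp(-params.radial_eta * (dist[i, neigh, None] - rs_r[None, :]) ** 2)
            * fc_r[i, neigh, None]
        )  # (n_neigh, n_shells)
        for j_local, j in enumerate(neigh):
            ch = species_idx[j]
            start = ch * len(rs_r)
            out[i, start : start + len(rs_r)] += terms[j_local]

    # angular part
    zeta = params.zeta
    pref = 2.0 ** (1.0 - zeta)
    fc_a = _cutoff(dist, params.angular_cutoff)
    n_shell = len(rs_a)
    n_theta = len(th_s)
    sect = n_shell * n_theta
    for i in range(n):
        neigh = np.where(fc_a[i] > 0)[0]
        if neigh.size < 2:
            continue
        vi = diff[i, neigh]  # vectors i -> j
        di = dist[i, neigh]
        fci = fc_a[i, neigh]
        for a in range(len(neigh)):
            for b in range(a + 1, len(neigh)):
                cos_t = np.dot(vi[a], vi[b]) / (di[a] * di[b])
                theta = math.acos(min(1.0, max(-1.0, cos_t)))
                r_mean = 0.5 * (di[a] + di[b])
                ang = (1.0 + np.cos(theta - th_s)) ** zeta  # (n_theta,)
                rad = np.exp(-params.angular_eta * (r_mean - rs_a) ** 2)  # (n_shell,)
                term = pref * (rad[:, None] * ang[None, :]).ravel() * fci[a] * fci[b]
                ea, eb = sorted((species_idx[neigh[a]], species_idx[neigh[b]]))
                p = pair_index[(ea, eb)]
                start = params.n_radial + p * sect
                out[i, start : start + sect] += term
    return out


def pool_aev(per_atom: np.ndarray) -> np.ndarray:
    """Sum-pool per-atom AEVs into a molecule vector."""
    per_atom = np.asarray(per_atom, dtype=np.float64)
    if per_atom.ndim != 2 or per_atom.shape[0] == 0:
        raise ValueError("need a non-empty (n_atoms, n_features) array")
    return per_atom.sum(axis=0)


@functools.lru_cache(maxsize=50_000)
def _aev_molecule_cached(smiles: str, params: AEVParams, seed: int) -> np.ndarray:
    conf = _embed_cached(smiles, seed, 10, 200)
    vec = pool_aev(compute_aev(conf, params))
    vec.setflags(write=False)
    return vec


def aev_for_molecule(
    mol: "Molecule | str", params: AEVParams | None = None, seed: int = 0
) -> np.ndarray:
    """Embed (cached) and sum-pool the AEV for one molecule."""
    smiles = mol.smiles if isinstance(mol, Molecule) else Molecule(mol).smiles
    return _aev_molecule_cached(smiles, params or AEVParams(), seed)


# ---------------------------------------------------------------------------
# Buried volume
# ---------------------------------------------------------------------------

#: Bondi van der Waals radii (Angstrom).
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}


@dataclass(frozen=True)
class StericParams:
    """Probe-sphere grid integration settings for %V_bur."""

    probe_radius: float = 3.5
    grid_spacing: float = 0.1
    include_hydrogens: bool = True
    radii: "dict[str, float] | None" = None

    def __post_init__(self) -> None:
        if self.grid_spacing >= self.probe_radius:
            raise ValueError("grid spacing must be smaller than the probe radius")


def buried_volume(
    conf: Conformer3D, center_atom: int, params: StericParams | None = None
) -> float:
    """Percent buried volume of the probe sphere centered on *center_atom*.

    %V_bur = 100 x (fraction of grid points within the probe sphere that lie
    inside the van der Waals sphere of any atom).  The center atom itself
    counts as an occluder, so an isolated atom of vdW radius r gives
    approximately 100 (r/R)^3.
    """
    params = params or StericParams()
    radii = params.radii or BONDI_RADII
    if not (0 <= center_atom < conf.n_atoms):
        raise IndexError(f"center atom {center_atom} out of range")
    missing = set(conf.species) - set(radii)
    if missing:
        raise ValueError(f"no vdW radius for: {sorted(missing)}")

    coords = np.asarray(conf.coords, dtype=np.float64)
    species = list(conf.species)
    if not params.include_hydrogens:
        keep = [i for i, s in enumerate(species) if s != "H" or i == center_atom]
        coords = coords[keep]
        species = [species[i] for i in keep]
        center_atom = keep.index(center_atom)

    center = coords[center_atom]
    R = params.probe_radius
    h = params.grid_spacing
    axis = np.arange(-R + h / 2, R, h)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    inside_probe = (pts**2).sum(axis=1) <= R * R
    pts = pts[inside_probe] + center

    occupied = np.zeros(len(pts), dtype=bool)
    for xyz, sym in zip(coords, species):
        r = radii[sym]
        # skip atoms that cannot reach the probe sphere
        if np.linalg.norm(xyz - center) > R + r:
            continue
        d2 = ((pts - xyz) ** 2).sum(axis=1)
        occupied |= d2 <= r * r
    return 100.0 * occupied.mean()


# ---------------------------------------------------------------------------
# QM provider contract and reaction-level QM features
# ---------------------------------------------------------------------------


@dataclass
class QMRecord:
    """Surrogate QM quantities for one molecule (provider units)."""

    energy: float
    charges: np.ndarray
    fukui_plus: np.ndarray
    fukui_minus: np.ndarray
    ionization_potential: float
    electron_affinity: float

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=np.float64)
        self.fukui_plus = np.asarray(self.fukui_plus, dtype=np.float64)
        self.fukui_minus = np.asarray(self.fukui_minus, dtype=np.float64)
        n = len(self.charges)
        if len(self.fukui_plus) != n or len(self.fukui_minus) != n:
            raise ValueError("per-atom arrays must have equal lengths")
        if not math.isfinite(self.energy):
            raise ValueError("energy must be finite")


class QMProvider(Protocol):
    """Anything that maps a canonical SMILES to a :class:`QMRecord`."""

    name: str

    def compute(self, smiles: str) -> QMRecord: ...


def _check_coverage(smiles: str) -> Chem.Mol:
    mol = mol_from_smiles(smiles)
    bad = {a.GetSymbol() for a in mol.GetAtoms()} - SUPPORTED_ELEMENTS
    if bad:
        raise CoverageError(
            f"elements outside provider coverage {sorted(bad)} in {smiles}"
        )
    return mol


class HeuristicQMProvider:
    """Additive group-contribution surrogate for demos on real SMILES.

    Energies are sums of per-element increments plus a bond-count term;
    charges come from Gasteiger partial charges; Fukui indices are crude
    functions of the local electronegativity environment.  Deterministic,
    fast, and chemically plausible in trend only.
    """

    name = "heuristic"

    _E_ATOM = {
        "H": -0.5, "C": -37.8, "N": -54.6, "O": -75.1, "F": -99.7,
        "Si": -289.4, "P": -341.3, "S": -398.1, "Cl": -460.1,
    }

    def compute(self, smiles: str) -> QMRecord:
        mol = _check_coverage(smiles)
        molh = Chem.AddHs(mol)
        energy = sum(self._E_ATOM[a.GetSymbol()] for a in molh.GetAtoms())
        energy -= 0.05 * molh.GetNumBonds()
        from rdkit.Chem import rdPartialCharges

        rdPartialCharges.ComputeGasteigerCharges(mol)
        charges = np.array(
            [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()]
        )
        charges = np.nan_to_num(charges)
        # crude reactivity proxies: electron-poor atoms are electrophilic
        fplus = np.clip(0.1 + charges, 0, None)
        fminus = np.clip(0.1 - charges, 0, None)
        ip = 9.0 + 0.02 * float(charges.sum())
        ea = 1.0 - 0.02 * float(charges.sum())
        return QMRecord(energy, charges, fplus, fminus, ip, ea)


def qm_features(mol: "Molecule | str", provider: QMProvider) -> QMRecord:
    """Compute the provider's QM record after checking element coverage."""
    smiles = mol.smiles if isinstance(mol, Molecule) else Molecule(mol).smiles
    _check_coverage(smiles)
    rec = provider.compute(smiles)
    n_atoms = mol_from_smiles(smiles).GetNumAtoms()
    if len(rec.charges) != n_atoms:
        raise ValueError(
            f"provider returned {len(rec.charges)} per-atom values for "
            f"{n_atoms}-atom molecule {smiles}"
        )
    return rec


def delta_e_rxn(
    e_product: float, e_water: float, e_acid: float, e_amine: float
) -> float:
    """Electronic reaction energy: E(product) + E(water) - E(acid) - E(amine)."""
    return e_product + e_water - e_acid - e_amine


REACTION_QM_NAMES = [
    "delta_e_rxn",
    "delta_f_rxn",
    "charge_acid_c",
    "charge_amine_n",
    "fukui_plus_acid_c",
    "fukui_minus_amine_n",
    "ip_acid",
    "ea_acid",
    "ip_amine",
    "ea_amine",
]


def derive_reaction_qm(
    acid_qm: QMRecord,
    amine_qm: QMRecord,
    product_qm: QMRecord,
    centers: ReactionCenters,
    e_water: float,
    intermediate_qm: QMRecord | None = None,
) -> np.ndarray:
    """Reaction-level QM vector (columns named by :data:`REACTION_QM_NAMES`).

    ``delta_f_rxn`` is signed acid-minus-amine: the electrophilic Fukui index
    at the acid's carboxyl carbon minus the nucleophilic index at the amine
    nitrogen.  Center indices come from :func:`annotate_reaction_centers`.
    """
    if not centers.acid_atoms or not centers.amine_atoms:
        raise ValueError("reaction centers missing; annotate before deriving")
    acid_c = centers.acid_carbon if centers.acid_carbon >= 0 else min(centers.acid_atoms)
    amine_n = (
        centers.amine_nitrogen
        if centers.amine_nitrogen >= 0
        else next(iter(centers.amine_atoms))
    )
    for idx, rec, what in (
        (acid_c, acid_qm, "acid"),
        (amine_n, amine_qm, "amine"),
    ):
        if idx >= len(rec.charges):
            raise ValueError(f"center index {idx} out of range for {what} QM record")
    d_e = delta_e_rxn(product_qm.energy, e_water, acid_qm.energy, amine_qm.energy)
    d_f = float(acid_qm.fukui_plus[acid_c] - amine_qm.fukui_minus[amine_n])
    return np.array(
        [
            d_e,
            d_f,
            float(acid_qm.charges[acid_c]),
            float(amine_qm.charges[amine_n]),
            float(acid_qm.fukui_plus[acid_c]),
            float(amine_qm.fukui_minus[amine_n]),
            acid_qm.ionization_potential,
            acid_qm.electron_affinity,
            amine_qm.ionization_potential,
            amine_qm.electron_affinity,
        ],
        dtype=np.float64,
    )
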