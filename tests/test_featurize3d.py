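"""Geometry descriptors: AEV symmetry functions, buried volume, QM features."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from amidebench.core import Conformer3D
from amidebench.featurize3d import (
    AEVParams,
    CoverageError,
    EmbeddingError,
    HeuristicQMProvider,
    QMRecord,
    REACTION_QM_NAMES,
    StericParams,
    buried_volume,
    compute_aev,
    delta_e_rxn,
    derive_reaction_qm,
    embed_conformer,
    pool_aev,
    qm_features,
)
from amidebench.mechanism import annotate_reaction_centers


def random_conformer(seed: int, species=("C", "H", "O", "N", "H")) -> Conformer3D:
    rng = np.random.default_rng(seed)
    coords = rng.normal(scale=1.5, size=(len(species), 3))
    return Conformer3D(list(species), [tuple(r) for r in coords])


class TestAEV:
    def test_single_atom_is_all_zero(self):
        conf = Conformer3D(["C"], [(0.0, 0.0, 0.0)])
        assert compute_aev(conf).sum() == 0.0

    def test_atoms_beyond_cutoff_are_all_zero(self):
        conf = Conformer3D(["C", "C"], [(0.0, 0.0, 0.0), (9.0, 0.0, 0.0)])
        assert compute_aev(conf).sum() == 0.0

    def test_diatomic_radial_term_matches_closed_form(self):
        params = AEVParams(
            radial_centers=(1.0,),
            angular_centers=(0.9,),
            theta_centers=(0.5,),
            elements=("H",),
        )
        conf = Conformer3D(["H", "H"], [(0.0, 0.0, 0.0), (1.0, 0.0, 0.0)])
        aev = compute_aev(conf, params)
        expected = math.exp(-16.0 * 0.0) * (0.5 * math.cos(math.pi * 1.0 / 5.2) + 0.5)
        assert aev[0, 0] == pytest.approx(expected, abs=1e-12)
        assert aev[1, 0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_rigid_motion_invariance(self, seed):
        conf = random_conformer(seed)
        coords = np.asarray(conf.coords)
        rot = Rotation.random(random_state=seed).as_matrix()
        shift = np.random.default_rng(seed).normal(scale=4.0, size=3)
        moved = Conformer3D(conf.species, [tuple(r) for r in coords @ rot.T + shift])
        assert np.abs(compute_aev(conf) - compute_aev(moved)).max() < 1e-8

    def test_permutation_invariance_for_identical_elements(self):
        conf = Conformer3D(
            ["H", "H", "O"], [(0.96, 0.0, 0.0), (-0.24, 0.93, 0.0), (0.0, 0.0, 0.0)]
        )
        swapped = Conformer3D(
            ["H", "H", "O"], [(-0.24, 0.93, 0.0), (0.96, 0.0, 0.0), (0.0, 0.0, 0.0)]
        )
        a, b = compute_aev(conf), compute_aev(swapped)
        assert np.allclose(a[2], b[2], atol=1e-12)  # oxygen AEV unchanged
        assert np.allclose(np.sort(a[:2], axis=0), np.sort(b[:2], axis=0), atol=1e-12)

    def test_species_outside_channels_rejected(self):
        conf = Conformer3D(["Br", "H"], [(0.0, 0.0, 0.0), (1.4, 0.0, 0.0)])
        with pytest.raises(CoverageError, match="Br"):
            compute_aev(conf)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="below the cutoff"):
            AEVParams(radial_centers=(6.0,))


class TestPoolAEV:
    def test_single_atom_pooling_is_identity(self):
        per_atom = np.array([[1.0, 2.0, 3.0]])
        assert np.array_equal(pool_aev(per_atom), per_atom[0])

    def test_duplicating_atoms_doubles_the_pool(self):
        rng = np.random.default_rng(0)
        per_atom = rng.normal(size=(4, 6))
        doubled = np.vstack([per_atom, per_atom])
        assert np.allclose(pool_aev(doubled), 2 * pool_aev(per_atom))

    def test_order_invariant(self):
        rng = np.random.default_rng(1)
        per_atom = rng.normal(size=(5, 7))
        assert np.allclose(pool_aev(per_atom), pool_aev(per_atom[::-1]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_aev(np.empty((0, 4)))


class TestEmbedConformer:
    def test_deterministic_under_seed(self):
        a = embed_conformer("CCO", seed=7)
        b = embed_conformer("CCO", seed=7)
        assert np.array_equal(np.asarray(a.coords), np.asarray(b.coords))

    def test_methane_geometry(self):
        conf = embed_conformer("C", seed=3)
        assert conf.n_atoms == 5
        coords = np.asarray(conf.coords)
        d = np.linalg.norm(coords[1:] - coords[0], axis=1)
        assert ((d > 1.0) & (d < 1.2)).all()

    def test_disconnected_molecule_rejected(self):
        with pytest.raises(EmbeddingError, match="disconnected"):
            embed_conformer("C.C", seed=0)


class TestBuriedVolume:
    def test_single_atom_matches_sphere_ratio(self):
        conf = Conformer3D(["C"], [(0.0, 0.0, 0.0)])
        params = StericParams(probe_radius=3.5, grid_spacing=0.1)
        expected = 100.0 * (1.70 / 3.5) ** 3
        assert buried_volume(conf, 0, params) == pytest.approx(expected, abs=2.0)

    def test_distant_atoms_do_not_occlude(self):
        near = Conformer3D(["C"], [(0.0, 0.0, 0.0)])
        far = Conformer3D(["C", "C"], [(0.0, 0.0, 0.0), (20.0, 0.0, 0.0)])
        params = StericParams(probe_radius=3.5, grid_spacing=0.2)
        assert buried_volume(near, 0, params) == buried_volume(far, 0, params)

    def test_added_occluder_never_decreases(self):
        params = StericParams(probe_radius=3.5, grid_spacing=0.2)
        base = Conformer3D(["C"], [(0.0, 0.0, 0.0)])
        v0 = buried_volume(base, 0, params)
        for pos in [(1.5, 0, 0), (0, 2.0, 0), (1.0, 1.0, 1.0)]:
            grown = Conformer3D(["C", "C"], [(0.0, 0.0, 0.0), pos])
            assert buried_volume(grown, 0, params) >= v0

    def test_grid_convergence(self):
        # halving the spacing moves the estimate by < 0.5 percentage points
        molecules = ["C", "CC", "CCO", "CC(C)C", "c1ccccc1", "CN", "CO",
                     "CC(=O)O", "CCN", "CCC"]
        for i, smiles in enumerate(molecules):
            conf = embed_conformer(smiles, seed=i)
            coarse = buried_volume(conf, 0, StericParams(grid_spacing=0.2))
            fine = buried_volume(conf, 0, StericParams(grid_spacing=0.1))
            assert abs(coarse - fine) < 0.5

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            StericParams(probe_radius=1.0, grid_spacing=1.5)


class TestDeltaERxn:
    def test_printed_equation(self):
        assert delta_e_rxn(-100, -76, -120, -55) == -1

    def test_cancellation(self):
        assert delta_e_rxn(3.5, -2.5, 3.5, -2.5) == 0.0

    def test_linearity(self):
        args = (-100.0, -76.0, -120.0, -55.0)
        assert delta_e_rxn(*(3 * a for a in args)) == pytest.approx(
            3 * delta_e_rxn(*args)
        )


class TestQMFeatures:
    def test_bromine_outside_coverage(self):
        with pytest.raises(CoverageError, match="Br"):
            qm_features("CBr", HeuristicQMProvider())

    def test_heuristic_per_atom_lengths(self):
        rec = qm_features("CC(=O)O", HeuristicQMProvider())
        assert len(rec.charges) == 4
        assert len(rec.fukui_plus) == len(rec.fukui_minus) == 4

    def test_oracle_provider_returns_latents_exactly(self, small_truth, small_dataset):
        provider = small_truth.qm_provider()
        rec = small_dataset.records[0]
        qm = provider.compute(rec.acid.smiles)
        assert qm.energy == small_truth.molecule_energy[rec.acid.smiles]

    def test_mismatched_array_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal lengths"):
            QMRecord(
                energy=-1.0,
                charges=np.zeros(3),
                fukui_plus=np.zeros(2),
                fukui_minus=np.zeros(3),
                ionization_potential=9.0,
                electron_affinity=1.0,
            )


class TestDeriveReactionQM:
    @pytest.fixture()
    def parts(self):
        acid, amine = "CC(=O)O", "CN"
        product = "CNC(C)=O"
        centers = annotate_reaction_centers(acid, amine, product)
        provider = HeuristicQMProvider()
        return (
            provider.compute(acid),
            provider.compute(amine),
            provider.compute(product),
            centers,
        )

    def test_schema_length_and_names(self, parts):
        acid_qm, amine_qm, product_qm, centers = parts
        vec = derive_reaction_qm(acid_qm, amine_qm, product_qm, centers, -76.4)
        assert len(vec) == len(REACTION_QM_NAMES) == 10

    def test_delta_e_column_consistent(self, parts):
        acid_qm, amine_qm, product_qm, centers = parts
        vec = derive_reaction_qm(acid_qm, amine_qm, product_qm, centers, -76.4)
        expected = delta_e_rxn(product_qm.energy, -76.4, acid_qm.energy, amine_qm.energy)
        assert vec[REACTION_QM_NAMES.index("delta_e_rxn")] == pytest.approx(expected)

    def test_identical_fukui_values_give_zero_difference(self, parts):
        acid_qm, amine_qm, product_qm, centers = parts
        amine_qm.fukui_minus[centers.amine_nitrogen] = acid_qm.fukui_plus[
            centers.acid_carbon
        ]
        vec = derive_reaction_qm(acid_qm, amine_qm, product_qm, centers, -76.4)
        assert vec[REACTION_QM_NAMES.index("delta_f_rxn")] == 0.0
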