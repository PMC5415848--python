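"""Hydrogen-bond detection, helicity assignment, profiles, and classification."""

import numpy as np
import pytest

from conftest import as_mdtraj, random_rotation
from helixread.chain import Residue, build_backbone
from helixread.structure import (
    HBOND_ENERGY_CUTOFF, KS_COUPLING, NH_BOND_LENGTH,
    assign_helicity, backbone_hbond_set, classify_conformation,
    compare_helicity, detect_hbonds, hbond_contact_map, helicity_profile,
)
from helixread.synthetic import make_ensemble, make_ideal_chain


def brute_force_bonds(chain):
    """Independent evaluation of the electrostatic criterion over all pairs."""
    res = chain.residues
    bonds = set()
    for di, donor in enumerate(res):
        if di == 0 or donor.name == "PRO":
            continue
        prev = res[di - 1]
        u = prev["C"] - prev["O"]
        h = donor["N"] + NH_BOND_LENGTH * u / np.linalg.norm(u)
        for acceptor in res:
            if abs(acceptor.index - donor.index) < 2:
                continue
            e = KS_COUPLING * (
                1 / np.linalg.norm(acceptor["O"] - donor["N"])
                + 1 / np.linalg.norm(acceptor["C"] - h)
                - 1 / np.linalg.norm(acceptor["O"] - h)
                - 1 / np.linalg.norm(acceptor["C"] - donor["N"])
            )
            if e < HBOND_ENERGY_CUTOFF:
                bonds.add((donor.index, acceptor.index))
    return bonds


class TestDetectHbonds:
    def test_ideal_helix_has_i_to_i4_ladder(self, helix_chain):
        assert backbone_hbond_set(helix_chain) == {(i + 4, i) for i in range(1, 7)}

    def test_extended_chain_has_no_bonds(self, extended_chain):
        assert backbone_hbond_set(extended_chain) == set()

    def test_matches_reference_kabsch_sander(self, helix_chain):
        import mdtraj as md

        traj = as_mdtraj(helix_chain)
        e = md.kabsch_sander(traj)[0].todense()
        ref = {(j + 1, i + 1) for i, j in zip(*np.nonzero(e < -0.5))}
        assert backbone_hbond_set(helix_chain) == ref

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_brute_force_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        phi_psi = [(rng.uniform(-180, 0), rng.uniform(-90, 180)) for _ in range(n)]
        chain = build_backbone("A" * n, phi_psi)
        assert backbone_hbond_set(chain) == brute_force_bonds(chain)

    def test_rigid_body_invariance(self, helix_chain):
        rng = np.random.default_rng(7)
        moved = helix_chain.transformed(random_rotation(rng), rng.normal(size=3) * 10)
        orig = {(b.donor_index, b.acceptor_index): b.energy
                for b in detect_hbonds(helix_chain)}
        new = {(b.donor_index, b.acceptor_index): b.energy
               for b in detect_hbonds(moved)}
        assert orig.keys() == new.keys()
        for k in orig:
            assert new[k] == pytest.approx(orig[k], abs=1e-9)

    def test_sidechain_hydroxyl_to_amide(self, helix_chain):
        # plant a Thr OG1 3.0 A from the residue-6 amide nitrogen
        chain = helix_chain.transformed(np.eye(3), np.zeros(3))
        n6 = chain.residue(6)["N"]
        direction = n6 - chain.residue(6)["CA"]
        chain.residue(3).atoms["OG1"] = n6 + 3.0 * direction / np.linalg.norm(direction)
        bonds = [b for b in detect_hbonds(chain, include_sidechain=True)
                 if b.kind == "sidechain-backbone"]
        assert any(b.donor_atom == "OG1" or b.acceptor_atom == "OG1" for b in bonds)

    def test_single_residue_rejected(self):
        chain = build_backbone("AR", [(-57, -47)] * 2)
        short = type(chain)([Residue(1, "ALA", chain[0].atoms)])
        with pytest.raises(ValueError):
            detect_hbonds(short)


class TestAssignHelicity:
    def test_ideal_helix_interior(self, helix_chain):
        flags = assign_helicity(helix_chain)
        assert list(np.flatnonzero(flags) + 1) == list(range(2, 10))

    def test_matches_reference_dssp(self, helix_chain, extended_chain):
        import mdtraj as md

        for chain in (helix_chain, extended_chain):
            ref = md.compute_dssp(as_mdtraj(chain), simplified=False)[0]
            mine = assign_helicity(chain)
            assert list(mine) == [c in "HGI" for c in ref]

    def test_extended_all_false(self, extended_chain):
        assert not assign_helicity(extended_chain).any()

    def test_short_chain_all_false(self):
        chain = make_ideal_chain("ART", -57, -47)
        assert not assign_helicity(chain).any()


class TestHelicityProfile:
    def test_all_helix_interior_one(self):
        ens = make_ensemble("ARTKQTARKS", 1.0, 20, n_replicas=4)
        prof = helicity_profile(ens, burn_in_fraction=0.0)
        assert np.allclose(prof.pooled[1:-1], 1.0)
        assert np.allclose(prof.iqr, 0.0)

    def test_planted_fraction_recovered_exactly(self):
        ens = make_ensemble("ARTKQTARKS", 0.4, 100)
        prof = helicity_profile(ens, burn_in_fraction=0.0)
        assert np.allclose(prof.pooled[1:-1], 0.40)

    def test_burn_in_preserves_interleaved_fraction(self):
        # helical frames are interleaved, so discarding the first quarter
        # (75 retained, 0.4 * 75 = 30 helical) still yields the planted value
        ens = make_ensemble("ARTKQTARKS", 0.4, 100)
        prof = helicity_profile(ens, burn_in_fraction=0.25)
        assert np.allclose(prof.pooled[1:-1], 0.40)

    def test_pooled_is_frame_weighted_mean(self):
        ens = make_ensemble("ARTKQTARKS", 0.3, 30, n_replicas=3)
        prof = helicity_profile(ens, burn_in_fraction=0.2)
        reps = ens.replicas()
        kept = {r: len(f) - int(np.floor(0.2 * len(f))) for r, f in reps.items()}
        w = np.array([kept[r] for r in sorted(kept)], dtype=float)
        stack = np.stack([prof.per_replica[r] for r in sorted(kept)])
        assert np.allclose(prof.pooled, (stack * w[:, None]).sum(0) / w.sum())

    def test_full_burn_in_rejected(self):
        ens = make_ensemble("ARTKQTARKS", 1.0, 4)
        with pytest.raises(ValueError):
            helicity_profile(ens, burn_in_fraction=1.0)


class TestCompareHelicity:
    def test_fully_separated_exact_p(self):
        a = np.array([0.60, 0.62, 0.65, 0.61])
        b = np.array([0.20, 0.25, 0.22, 0.24])
        assert compare_helicity(a, b) == pytest.approx(2 / 70)

    def test_identical_samples_p_one(self):
        a = np.array([0.60, 0.62, 0.65, 0.61])
        assert compare_helicity(a, a.copy()) == pytest.approx(1.0)

    def test_per_residue_vector(self):
        a = np.tile([[0.6], [0.62], [0.65], [0.61]], (1, 3))
        b = np.tile([[0.2], [0.25], [0.22], [0.24]], (1, 3))
        p = compare_helicity(a, b)
        assert p.shape == (3,) and np.allclose(p, 2 / 70)

    def test_single_replica_rejected(self):
        with pytest.raises(ValueError):
            compare_helicity(np.array([0.6]), np.array([0.2, 0.3]))


class TestContactMap:
    def test_all_helix_diagonal(self):
        ens = make_ensemble("ARTKQTARKS", 1.0, 10)
        occ = hbond_contact_map(ens, burn_in_fraction=0.0)
        for d in range(5, 11):
            assert occ.loc[d, d - 4] == 1.0
        assert occ.to_numpy().sum() == pytest.approx(6.0)

    def test_planted_fraction_on_diagonal(self):
        ens = make_ensemble("ARTKQTARKS", 0.4, 100)
        occ = hbond_contact_map(ens, burn_in_fraction=0.0)
        assert occ.loc[8, 4] == pytest.approx(0.40)

    def test_single_frame_binary(self, helix_chain):
        from helixread.chain import ConformerEnsemble

        occ = hbond_contact_map(ConformerEnsemble([helix_chain]), 0.0)
        assert set(np.unique(occ.to_numpy())) <= {0.0, 1.0}


class TestClassifyConformation:
    def test_helix_segment_is_helical(self, helix_chain):
        cc = classify_conformation(helix_chain, (4, 8), anchor=(1, 3))
        assert cc.label == "helical"
        assert cc.helical_residues >= 3

    def test_extended_chain_is_extended(self, extended_chain):
        cc = classify_conformation(extended_chain, (1, 10))
        assert cc.label == "extended"
        assert cc.end_to_end_ratio >= 0.8

    def test_kinked_chain_is_bent(self):
        phi_psi = [(-139.0, 135.0)] * 10
        phi_psi[4] = (-90.0, 0.0)
        phi_psi[5] = (-90.0, 0.0)
        chain = build_backbone("ARTKQTARKS", phi_psi)
        cc = classify_conformation(chain, (1, 10))
        assert cc.label == "bent"
        assert cc.end_to_end_ratio < 0.8

    def test_short_segment_rejected(self, helix_chain):
        with pytest.raises(ValueError):
            classify_conformation(helix_chain, (4, 6))

    def test_overlapping_anchor_rejected(self, helix_chain):
        with pytest.raises(ValueError):
            classify_conformation(helix_chain, (4, 8), anchor=(3, 5))
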