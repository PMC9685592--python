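"""Salt bridges, KDE CCS distributions, superposition and clustering."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from ciukit.ensemble import (
    ccsd_modes,
    ccsd_overlap,
    cluster_ensemble,
    detect_salt_bridges,
    ensemble_ccsd,
    superpose,
)
from ciukit.structures import Atom, Structure
from ciukit.synthetic import build_ideal_peptide, make_unfolding_ensemble, FixtureSpec


def glu_lys_pair(distance: float, glu_seq: int = 1, lys_seq: int = 2):
    """Minimal Glu/Lys pair with OE1-NZ at the requested distance."""
    atoms = [
        Atom("N", "N", 0, 0, 0, "GLY", 0),  # N-term lives on a spacer glycine
        Atom("C", "CA", 1.5, 0, 0, "GLY", 0),
        Atom("C", "C", 2.2, 1.2, 0, "GLY", 0),
        Atom("C", "CD", 10.0, 0.0, 0.0, "GLU", glu_seq),
        Atom("O", "OE1", 11.0, 0.0, 0.0, "GLU", glu_seq),
        Atom("N", "NZ", 11.0 + distance, 0.0, 0.0, "LYS", lys_seq),
        Atom("C", "C", 30.0, 0.0, 0.0, "GLY", 99),
        Atom("O", "O", 31.0, 0.0, 0.0, "GLY", 99),
    ]
    atoms.sort(key=lambda a: a.res_seq)
    return Structure(atoms)


class TestSaltBridges:
    def test_cutoff_boundary_inclusive(self):
        within = [
            b
            for b in detect_salt_bridges(glu_lys_pair(3.99))
            if b.acidic_res.startswith("GLU")
            and b.basic_res.startswith("LYS")
        ]
        assert len(within) == 1
        assert within[0].distance == pytest.approx(3.99)
        beyond = [
            b
            for b in detect_salt_bridges(glu_lys_pair(4.01))
            if b.acidic_res.startswith("GLU")
            and b.basic_res.startswith("LYS")
        ]
        assert beyond == []

    def test_unfolded_state_contact_labelled_e38_k2(self):
        # geometry mimicking the diagnostic Glu38-Lys2 contact of an
        # extended charge-driven unfolding intermediate
        s = glu_lys_pair(3.2, glu_seq=38, lys_seq=2)
        pairs = {(b.acidic_res, b.basic_res) for b in detect_salt_bridges(s)}
        assert ("GLU38", "LYS2") in pairs

    def test_detection_invariant_under_rotation(self):
        s = glu_lys_pair(3.5)
        theta = 1.1
        R = np.array(
            [
                [math.cos(theta), 0, math.sin(theta)],
                [0, 1, 0],
                [-math.sin(theta), 0, math.cos(theta)],
            ]
        )
        a = detect_salt_bridges(s)
        b = detect_salt_bridges(s.rotated(R))
        assert len(a) == len(b)
        assert {(x.acidic_res, x.basic_res) for x in a} == {
            (x.acidic_res, x.basic_res) for x in b
        }

    def test_reported_once_oriented_acidic_to_basic(self):
        bridges = detect_salt_bridges(glu_lys_pair(3.0))
        keys = [(b.acidic_res, b.basic_res) for b in bridges]
        assert len(keys) == len(set(keys))
        for acidic, basic in keys:
            assert acidic[:3] in {"GLU", "ASP", "GLY"}  # GLY = C-term carboxylate
            assert basic[:3] in {"LYS", "ARG", "HIS", "GLY"}  # GLY = N-term amine


class TestEnsembleCCSD:
    def test_near_point_mass_unimodal_at_value(self):
        e = ensemble_ccsd([1000.0, 1000.0001])
        modes = ccsd_modes(e)
        assert len(modes) == 1
        assert modes[0] == pytest.approx(1000.0, abs=1.0)

    def test_density_normalized(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            e = ensemble_ccsd(rng.normal(1000.0, 50.0, 40))
            assert e.integral == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_mode_recovery(self):
        rng = np.random.default_rng(42)
        draws = np.concatenate(
            [rng.normal(850.0, 20.0, 50), rng.normal(1300.0, 20.0, 50)]
        )
        modes = sorted(ccsd_modes(ensemble_ccsd(draws))[:2])
        assert abs(modes[0] - 850.0) <= 15.0
        assert abs(modes[1] - 1300.0) <= 15.0

    def test_degenerate_values_fall_back_to_floor_bandwidth(self):
        e = ensemble_ccsd([1000.0, 1000.0, 1000.0])
        assert e.bandwidth == pytest.approx(1.0)
        assert e.integral == pytest.approx(1.0, abs=1e-3)


class TestOverlap:
    def test_identical_distributions_give_one(self):
        e = ensemble_ccsd([900.0, 950.0, 1000.0, 1100.0])
        assert ccsd_overlap(e, e) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_supports_give_zero(self):
        a = ensemble_ccsd([100.0, 110.0], bandwidth=1.0)
        b = ensemble_ccsd([5000.0, 5010.0], bandwidth=1.0)
        assert ccsd_overlap(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_two_sigma_apart_gaussians_match_closed_form(self):
        grid = np.linspace(-8.0, 10.0, 4000)
        p = norm.pdf(grid, 0.0, 1.0)
        q = norm.pdf(grid, 2.0, 1.0)
        expected = 2 * norm.cdf(-1.0)  # ~0.3173
        assert ccsd_overlap((grid, p), (grid, q)) == pytest.approx(
            expected, abs=1e-3
        )

    def test_symmetric_and_bounded(self):
        a = ensemble_ccsd([900.0, 1000.0, 1050.0])
        b = ensemble_ccsd([980.0, 1150.0, 1200.0])
        ab, ba = ccsd_overlap(a, b), ccsd_overlap(b, a)
        assert ab == pytest.approx(ba, abs=1e-9)
        assert 0.0 < ab < 1.0


class TestSuperpose:
    def test_identical_structures_zero_rmsd(self):
        s = build_ideal_peptide("AAAAA", "helical")
        _, _, rmsd = superpose(s, s)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_isometry_removed(self):
        s = build_ideal_peptide("AKDGE", "extended")
        theta = 0.9
        R = np.array(
            [
                [1, 0, 0],
                [0, math.cos(theta), -math.sin(theta)],
                [0, math.sin(theta), math.cos(theta)],
            ]
        )
        moved = s.rotated(R).translated([5.0, -3.0, 12.0])
        rot, trans, rmsd = superpose(s, moved)
        assert rmsd < 1e-9
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_known_single_atom_displacement(self):
        # one of 10 atoms displaced 1 A radially (so the rotation refit
        # cannot absorb it): RMSD = d * sqrt(n-1) / n exactly
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 500.0, (10, 3))
        u = coords[0] - coords.mean(axis=0)
        u /= np.linalg.norm(u)
        coords_b = coords.copy()
        coords_b[0] += u
        atoms_a = [
            Atom("C", "CA", *map(float, xyz), "ALA", i + 1)
            for i, xyz in enumerate(coords)
        ]
        atoms_b = [
            Atom("C", "CA", *map(float, xyz), "ALA", i + 1)
            for i, xyz in enumerate(coords_b)
        ]
        _, _, rmsd = superpose(Structure(atoms_a), Structure(atoms_b))
        expected = math.sqrt(1.0 * (10 - 1)) / 10
        assert rmsd == pytest.approx(expected, rel=1e-6)

    def test_underdetermined_rejected(self):
        a = Structure([Atom("C", "CA", 0, 0, 0, "ALA", 1),
                       Atom("C", "CA", 1, 0, 0, "ALA", 2)])
        with pytest.raises(ValueError, match="underdetermined"):
            superpose(a, a)


class TestClustering:
    def test_identical_copies_form_one_cluster(self):
        s = build_ideal_peptide("AAAAAA", "helical")
        assignment = cluster_ensemble([s] * 5, rmsd_cutoff=1.0)
        assert assignment.labels == (0,) * 5
        assert assignment.sizes == (5,)

    def test_two_families_separate(self):
        spec = FixtureSpec(sequence="A" * 12, amplitude=2.0, seed=3,
                           n_conformers=4)
        compact = make_unfolding_ensemble(spec, t_range=(0.0, 0.02))
        extended = make_unfolding_ensemble(spec, t_range=(0.98, 1.0))
        frames = compact + extended
        assignment = cluster_ensemble(frames, rmsd_cutoff=5.0)
        first, second = assignment.labels[:4], assignment.labels[4:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert set(first) != set(second)

    def test_singletons_beyond_cutoff_stay_unique(self):
        s1 = build_ideal_peptide("A" * 10, "helical")
        s2 = build_ideal_peptide("A" * 10, "extended")
        s3 = build_ideal_peptide("A" * 10, "compact-random", seed=7)
        assignment = cluster_ensemble([s1, s2, s3], rmsd_cutoff=0.5)
        assert sorted(assignment.sizes) == [1, 1, 1]

    def test_frame_order_invariance_up_to_relabeling(self):
        spec = FixtureSpec(sequence="A" * 12, amplitude=2.0, seed=5,
                           n_conformers=6)
        frames = make_unfolding_ensemble(spec)
        a = cluster_ensemble(frames, rmsd_cutoff=3.0)
        perm = [3, 0, 5, 1, 4, 2]
        b = cluster_ensemble([frames[i] for i in perm], rmsd_cutoff=3.0)
        # partition structure is identical after permutation
        def partition(labels):
            groups = {}
            for i, lab in enumerate(labels):
                groups.setdefault(lab, set()).add(i)
            return {frozenset(g) for g in groups.values()}
        remapped = {
            frozenset(perm.index(i) for i in group)
            for group in partition(a.labels)
        }
        assert partition(b.labels) == remapped
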