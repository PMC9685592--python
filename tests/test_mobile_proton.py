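"""Mobile-proton energy model, assignment search, and schedules."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ciukit.errors import EmptyInputError, InfeasibleChargeError
from ciukit.mobile_proton import (
    COULOMB_CONSTANT,
    ChargeConfiguration,
    EnergyModel,
    assign_protons,
    brute_force_assign,
    configuration_energy,
    coulombic_schedule,
    enumerate_configurations,
    net_charge,
    reassign_over_trajectory,
    thermal_schedule,
)
from ciukit.structures import IonizableSite, SiteKind, find_ionizable_sites
from ciukit.synthetic import build_ideal_peptide

from conftest import random_site_system


def make_sites(kinds):
    return [IonizableSite(i, k, i + 1, "A", i) for i, k in enumerate(kinds)]


class TestConfigurationEnergy:
    def test_all_neutral_has_zero_coulomb_term(self):
        sites = make_sites([SiteKind.LYS, SiteKind.ASP, SiteKind.GLU])
        coords = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0]], float)
        cfg = ChargeConfiguration(states=(False, True, True), z=0)
        assert configuration_energy(sites, cfg, coords) == 0.0

    def test_two_unit_charges_match_pairwise_sum(self):
        # no intrinsic term: zero out the basicity table
        model = EnergyModel(basicity={})
        for r in (2.0, 5.0, 17.5):
            sites = make_sites([SiteKind.LYS, SiteKind.LYS])
            coords = np.array([[0, 0, 0], [r, 0, 0]], float)
            cfg = ChargeConfiguration(states=(True, True), z=2)
            expected = COULOMB_CONSTANT / r  # brute-force single pair
            assert configuration_energy(sites, cfg, coords, model) == pytest.approx(
                expected, rel=1e-12
            )

    def test_many_charge_brute_force_pair_sum(self):
        rng = np.random.default_rng(3)
        sites = make_sites([SiteKind.LYS] * 6)
        coords = rng.uniform(0, 20, (6, 3))
        cfg = ChargeConfiguration(states=(True,) * 6, z=6)
        model = EnergyModel(basicity={})
        expected = sum(
            COULOMB_CONSTANT / np.linalg.norm(coords[i] - coords[j])
            for i, j in itertools.combinations(range(6), 2)
        )
        assert configuration_energy(sites, cfg, coords, model) == pytest.approx(
            expected, rel=1e-12
        )

    def test_site_relabeling_leaves_energy_unchanged(self):
        sites, coords, z = random_site_system(7)
        cfg = brute_force_assign(sites, z, coords)
        e1 = configuration_energy(sites, cfg, coords)
        perm = np.random.default_rng(0).permutation(len(sites))
        sites_p = [
            IonizableSite(i, sites[j].kind, sites[j].res_seq, "A", i)
            for i, j in enumerate(perm)
        ]
        cfg_p = ChargeConfiguration(
            states=tuple(cfg.states[j] for j in perm), z=cfg.z
        )
        e2 = configuration_energy(sites_p, cfg_p, coords[perm])
        assert e2 == pytest.approx(e1, rel=1e-12)

    def test_monotone_repulsion_with_separation(self):
        model = EnergyModel(basicity={})
        sites = make_sites([SiteKind.LYS, SiteKind.LYS])
        cfg = ChargeConfiguration(states=(True, True), z=2)
        energies = [
            configuration_energy(
                sites, cfg, np.array([[0, 0, 0], [r, 0, 0]], float), model
            )
            for r in np.linspace(1.5, 40.0, 25)
        ]
        assert all(b < a for a, b in zip(energies, energies[1:]))


class TestBruteForce:
    def test_single_basic_site_forced(self):
        sites = make_sites([SiteKind.LYS])
        cfg = brute_force_assign(sites, 1, np.zeros((1, 3)))
        assert cfg.states == (True,)

    def test_higher_basicity_site_wins_at_equal_distance(self):
        sites = make_sites([SiteKind.LYS, SiteKind.ARG])
        coords = np.array([[0, 0, 0], [10, 0, 0]], float)
        cfg = brute_force_assign(sites, 1, coords)
        assert cfg.states == (False, True)  # Arg outranks Lys

    @pytest.mark.parametrize("n,k", [(6, 2), (8, 3), (5, 5), (7, 0)])
    def test_enumeration_count_is_binomial(self, n, k):
        sites = make_sites([SiteKind.LYS] * n)
        configs = enumerate_configurations(sites, k)
        assert len(configs) == math.comb(n, k)
        assert all(sum(c) == k for c in configs)

    def test_infeasible_charge_raises(self):
        sites = make_sites([SiteKind.LYS, SiteKind.ASP])
        with pytest.raises(InfeasibleChargeError):
            brute_force_assign(sites, 3, np.zeros((2, 3)))


class TestAssignProtons:
    def test_full_protonation_forced_without_acids(self):
        sites = make_sites([SiteKind.LYS, SiteKind.ARG, SiteKind.NTERM])
        coords = np.random.default_rng(1).uniform(0, 10, (3, 3))
        cfg = assign_protons(sites, 3, coords, seed=0)
        assert cfg.states == (True, True, True)

    def test_neutral_charge_matches_oracle(self):
        sites, coords, _ = random_site_system(21)
        bf = brute_force_assign(sites, 0, coords)
        sp = assign_protons(sites, 0, coords, seed=4)
        assert sp.energy == pytest.approx(bf.energy, rel=1e-12)

    @pytest.mark.parametrize("seed", range(0, 20))
    def test_oracle_equivalence_random_systems(self, seed):
        sites, coords, z = random_site_system(seed)
        bf = brute_force_assign(sites, z, coords)
        sp = assign_protons(sites, z, coords, seed=seed)
        assert sp.energy == pytest.approx(bf.energy, rel=1e-9)
        assert net_charge(sites, sp.states) == z

    def test_seed_determinism_bitwise(self):
        sites, coords, z = random_site_system(13)
        a = assign_protons(sites, z, coords, seed=99)
        b = assign_protons(sites, z, coords, seed=99)
        assert a.states == b.states and a.energy == b.energy

    def test_charge_conservation_everywhere(self):
        for seed in range(15):
            sites, coords, z = random_site_system(seed, n_sites=10)
            cfg = assign_protons(sites, z, coords, seed=seed)
            assert net_charge(sites, cfg.states) == cfg.z == z


class TestTrajectoryReassignment:
    def test_identical_frames_identical_configurations(self):
        frame = build_ideal_peptide("KDVKGKGKK", "helical")
        cfgs = reassign_over_trajectory([frame, frame, frame], z=3, seed=8)
        assert cfgs[0].states == cfgs[1].states == cfgs[2].states

    def test_every_configuration_conserves_charge(self):
        frames = [
            build_ideal_peptide("KDKAEKR", "extended"),
            build_ideal_peptide("KDKAEKR", "helical"),
        ]
        sites = find_ionizable_sites(frames[0])
        for cfg in reassign_over_trajectory(frames, z=2, seed=0):
            assert net_charge(sites, cfg.states) == 2

    def test_proton_relocates_under_compression(self):
        # three basic sites: when two sites approach, Coulomb repulsion
        # overcomes the basicity gap and the proton moves to the distal site
        kinds = [SiteKind.ARG, SiteKind.ARG, SiteKind.LYS]
        sites = make_sites(kinds)
        far = np.array([[0, 0, 0], [50, 0, 0], [100, 0, 0]], float)
        near = np.array([[0, 0, 0], [2.0, 0, 0], [100, 0, 0]], float)
        bf_far = brute_force_assign(sites, 2, far)
        bf_near = brute_force_assign(sites, 2, near)
        assert bf_far.states == (True, True, False)  # two Arg protonated
        assert bf_near.states[2]  # distal Lys takes a proton when compressed
        for coords, expect in ((far, bf_far), (near, bf_near)):
            sp = assign_protons(sites, 2, coords, seed=0)
            assert sp.states == expect.states

    def test_empty_frame_list_rejected(self):
        with pytest.raises(EmptyInputError):
            reassign_over_trajectory([], z=1)


class TestSchedules:
    def test_thermal_ramp_reaches_400K_in_third_segment(self):
        sched = thermal_schedule(300.0, 50.0, 4.0, 20.0)
        assert len(sched.segments) == 5
        # the segment covering 8-12 ns sits at 400 K
        assert sched.temperature_at(8.0) == 400.0
        assert sched.temperature_at(11.999) == 400.0
        assert sched.temperature_at(0.0) == 300.0
        assert sched.temperature_at(19.9) == 500.0

    def test_single_segment_ramp(self):
        sched = thermal_schedule(300.0, 50.0, 4.0, 4.0)
        assert sched.segments == ((0.0, 4.0, 300.0),)

    def test_non_divisible_total_rejected(self):
        with pytest.raises(ValueError):
            thermal_schedule(300.0, 50.0, 3.0, 20.0)

    def test_coulombic_schedule_defaults(self):
        sched = coulombic_schedule()
        assert sched.segments == ((0.0, 100.0, 300.0),)
        assert sched.ccs_cadence_ps == 10.0
        assert sched.rearrangement_period_ps == 20.0
        assert sched.n_rearrangements == 5000

    @given(
        hst.integers(min_value=1, max_value=10),
        hst.integers(min_value=1, max_value=6),
        hst.floats(min_value=100.0, max_value=500.0),
        hst.floats(min_value=-50.0, max_value=100.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_segments_cover_total_without_gaps(self, n_seg, seg_len, t0, dt):
        sched = thermal_schedule(t0, dt, float(seg_len), float(n_seg * seg_len))
        assert sched.segments[0][0] == 0.0
        assert sched.segments[-1][1] == pytest.approx(n_seg * seg_len)
        for (a0, a1, _), (b0, b1, _) in zip(
            sched.segments, sched.segments[1:]
        ):
            assert a1 == pytest.approx(b0)
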