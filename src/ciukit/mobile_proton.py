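"""Mobile proton algorithm: distribute z protons over ionizable sites.

A protein ion at net charge z carries its protons on basic sites (N-terminus,
Lys, Arg, His) and may additionally lose protons from acidic sites (Asp, Glu,
C-terminus), whose deprotonated forms carry −1.  The energy of a protonation
state balances the intrinsic gas-phase basicity gained by protonating a basic
site against the Coulomb repulsion between all charged sites:

    E(state) = − Σ_{protonated basic} B(kind)
               + Σ_{i<j} k_e · q_i q_j / (ε_r · max(r_ij, r_min))

with B in kJ/mol, k_e = 1389.35 kJ·mol⁻¹·Å·e⁻², distances in Å and charges in
elementary units.  ``assign_protons`` minimizes E by random-restart descent on
single-proton moves; ``brute_force_assign`` is the exhaustive oracle for small
site inventories.  Along a trajectory the protons are redistributed at fixed
intervals (20 ps by default), each frame independently of the last.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from ciukit.errors import ConfigMismatchError, EmptyInputError, InfeasibleChargeError
from ciukit.structures import IonizableSite, SiteKind, Structure

__all__ = [
    "ChargeConfiguration",
    "EnergyModel",
    "Schedule",
    "DEFAULT_BASICITY",
    "COULOMB_CONSTANT",
    "net_charge",
    "site_charges",
    "configuration_energy",
    "enumerate_configurations",
    "brute_force_assign",
    "assign_protons",
    "reassign_over_trajectory",
    "thermal_schedule",
    "coulombic_schedule",
]

#: Coulomb constant in kJ·mol⁻¹·Å·e⁻².
COULOMB_CONSTANT = 1389.35

#: Intrinsic basicity per basic site kind, kJ/mol.  Values follow the
#: gas-phase-basicity ordering Arg > His > Lys > backbone amine; the table is
#: an editable input, not a fixed constant of the method.
DEFAULT_BASICITY: dict[SiteKind, float] = {
    SiteKind.ARG: 1006.6,
    SiteKind.HIS: 950.2,
    SiteKind.LYS: 918.0,
    SiteKind.NTERM: 886.6,
}


@dataclass(frozen=True)
class ChargeConfiguration:
    """Per-site protonation flags realizing net charge z.

    ``states[i]`` is True when the site with ``site_id == i`` is protonated.
    Basic sites contribute +1 when protonated; acidic sites contribute −1
    when deprotonated.  ``energy`` is in kJ/mol under the EnergyModel that
    produced the configuration (None when unknown).
    """

    states: tuple[bool, ...]
    z: int
    energy: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(bool(s) for s in self.states))


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the mobile-proton energy functional."""

    basicity: dict[SiteKind, float] = field(
        default_factory=lambda: dict(DEFAULT_BASICITY)
    )
    k_e: float = COULOMB_CONSTANT
    epsilon_r: float = 1.0
    min_distance: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon_r < 1.0:
            raise ValueError("relative dielectric must be >= 1")
        if self.min_distance <= 0.0:
            raise ValueError("min_distance must be positive")
        if not all(math.isfinite(v) for v in self.basicity.values()):
            raise ValueError("non-finite basicity value")


def site_charges(sites: list[IonizableSite], states) -> np.ndarray:
    """Elementary charge per site for a protonation-state vector."""
    states = np.asarray(states, dtype=bool)
    if states.shape[-1] != len(sites):
        raise ConfigMismatchError(
            f"{states.shape[-1]} states for {len(sites)} sites"
        )
    basic = np.array([s.is_basic for s in sites])
    q = np.where(basic, states.astype(int), states.astype(int) - 1)
    return q


def net_charge(sites: list[IonizableSite], states) -> int:
    return int(site_charges(sites, states).sum())


def _check_anchor_coords(sites: list[IonizableSite], coords) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(sites), 3):
        raise ConfigMismatchError(
            f"anchor coordinates {coords.shape} do not match {len(sites)} sites"
        )
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite anchor coordinate")
    return coords


def _pair_matrix(coords: np.ndarray, model: EnergyModel) -> np.ndarray:
    """k_e / (ε_r · max(r_ij, r_min)) with zero diagonal."""
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff**2).sum(-1))
    r = np.maximum(r, model.min_distance)
    K = model.k_e / (model.epsilon_r * r)
    np.fill_diagonal(K, 0.0)
    return K


def _batch_energies(
    sites: list[IonizableSite],
    state_matrix: np.ndarray,
    coords: np.ndarray,
    model: EnergyModel,
) -> np.ndarray:
    """Energies for a (n_configs, n_sites) boolean state matrix."""
    K = _pair_matrix(coords, model)
    B = np.array(
        [model.basicity.get(s.kind, 0.0) if s.is_basic else 0.0 for s in sites]
    )
    q = site_charges(sites, state_matrix).astype(float)
    basic = np.array([s.is_basic for s in sites])
    intrinsic = -(state_matrix[:, basic] * B[basic]).sum(axis=1)
    coulomb = 0.5 * np.einsum("si,ij,sj->s", q, K, q)
    return intrinsic + coulomb


def configuration_energy(
    sites: list[IonizableSite],
    cfg: ChargeConfiguration,
    anchor_coords,
    model: EnergyModel | None = None,
) -> float:
    """Energy (kJ/mol) of one protonation state; deterministic."""
    model = model or EnergyModel()
    coords = _check_anchor_coords(sites, anchor_coords)
    states = np.asarray(cfg.states, dtype=bool)[None, :]
    if net_charge(sites, cfg.states) != cfg.z:
        raise ConfigMismatchError("configuration net charge != declared z")
    return float(_batch_energies(sites, states, coords, model)[0])


def _proton_partitions(n_basic: int, n_acidic: int, z: int) -> list[tuple[int, int]]:
    """Feasible (protonated-basic count, deprotonated-acidic count) pairs."""
    out = []
    for p in range(n_basic + 1):
        d = p - z
        if 0 <= d <= n_acidic:
            out.append((p, d))
    return out


def _feasible_or_raise(sites: list[IonizableSite], z: int) -> tuple[list[int], list[int]]:
    basic_idx = [i for i, s in enumerate(sites) if s.is_basic]
    acidic_idx = [i for i, s in enumerate(sites) if not s.is_basic]
    if not _proton_partitions(len(basic_idx), len(acidic_idx), z):
        raise InfeasibleChargeError(
            f"net charge {z} infeasible for {len(basic_idx)} basic / "
            f"{len(acidic_idx)} acidic sites"
        )
    return basic_idx, acidic_idx


def enumerate_configurations(
    sites: list[IonizableSite], z: int
) -> list[tuple[bool, ...]]:
    """All protonation-state vectors realizing net charge z.

    For k protons over n basic sites (no acidic sites) this enumerates
    exactly C(n, k) states.
    """
    basic_idx, acidic_idx = _feasible_or_raise(sites, z)
    configs: list[tuple[bool, ...]] = []
    for p, d in _proton_partitions(len(basic_idx), len(acidic_idx), z):
        for prot_b in itertools.combinations(basic_idx, p):
            for deprot_a in itertools.combinations(acidic_idx, d):
                state = np.zeros(len(sites), dtype=bool)
                state[list(prot_b)] = True
                state[acidic_idx] = True
                state[list(deprot_a)] = False
                configs.append(tuple(bool(x) for x in state))
    return configs


def brute_force_assign(
    sites: list[IonizableSite],
    z: int,
    anchor_coords,
    model: EnergyModel | None = None,
) -> ChargeConfiguration:
    """Exhaustively enumerate all states at net charge z; return the global
    minimum, ties broken by lexicographically smallest state vector.

    Enumeration bound: at most 20 sites.
    """
    if len(sites) > 20:
        raise ValueError("brute-force enumeration limited to 20 sites")
    model = model or EnergyModel()
    coords = _check_anchor_coords(sites, anchor_coords)
    matrix = np.array(enumerate_configurations(sites, z), dtype=bool)
    energies = _batch_energies(sites, matrix, coords, model)
    emin = energies.min()
    tol = 1e-9 * max(1.0, abs(emin))
    tied = [tuple(matrix[i]) for i in np.flatnonzero(energies <= emin + tol)]
    best = min(tied)
    idx = next(i for i in range(len(matrix)) if tuple(matrix[i]) == best)
    return ChargeConfiguration(states=best, z=z, energy=float(energies[idx]))


def _candidate_moves(
    state: np.ndarray, basic_idx: list[int], acidic_idx: list[int]
) -> np.ndarray:
    """All z-preserving single-proton moves from a state."""
    prot_b = [i for i in basic_idx if state[i]]
    unprot_b = [i for i in basic_idx if not state[i]]
    prot_a = [i for i in acidic_idx if state[i]]
    deprot_a = [i for i in acidic_idx if not state[i]]
    moves = []
    # relocate a proton between basic sites
    moves += [(i, j) for i in prot_b for j in unprot_b]
    # relocate the charge hole between acidic sites
    moves += [(j, i) for i in deprot_a for j in prot_a]
    # toggle an acid/base pair in either direction
    moves += [(i, j) for i in prot_b for j in deprot_a]
    moves += [(j, i) for i in prot_a for j in unprot_b]
    if not moves:
        return np.empty((0, len(state)), dtype=bool)
    out = np.broadcast_to(state, (len(moves), len(state))).copy()
    for k, (off, on) in enumerate(moves):
        out[k, off] = False
        out[k, on] = True
    return out


def _random_state(
    rng: np.random.Generator,
    n_sites: int,
    basic_idx: list[int],
    acidic_idx: list[int],
    z: int,
    partition: tuple[int, int] | None = None,
) -> np.ndarray:
    if partition is None:
        partitions = _proton_partitions(len(basic_idx), len(acidic_idx), z)
        partition = partitions[rng.integers(len(partitions))]
    p, d = partition
    state = np.zeros(n_sites, dtype=bool)
    state[rng.choice(basic_idx, size=p, replace=False).astype(int)] = True
    state[acidic_idx] = True
    if d:
        state[rng.choice(acidic_idx, size=d, replace=False).astype(int)] = False
    return state


def assign_protons(
    sites: list[IonizableSite],
    z: int,
    anchor_coords,
    model: EnergyModel | None = None,
    seed: int | None = None,
    n_restarts: int = 20,
) -> ChargeConfiguration:
    """Distribute z protons by random-restart steepest descent.

    From each random start, the best energy-lowering single-proton move
    (relocation within a polarity class, or an acid/base pair toggle) is
    applied until no move lowers the energy; when no single move helps, a
    two-move lookahead can step through one uphill intermediate.  Restarts
    are stratified over the feasible proton-count partitions so every
    basic/acidic split is explored.  Ties are broken by the lexicographically
    smallest state vector; identical seeds give bit-identical results.
    """
    model = model or EnergyModel()
    coords = _check_anchor_coords(sites, anchor_coords)
    basic_idx, acidic_idx = _feasible_or_raise(sites, z)
    partitions = _proton_partitions(len(basic_idx), len(acidic_idx), z)
    rng = np.random.default_rng(seed)
    best_state: tuple[bool, ...] | None = None
    best_energy = np.inf
    for restart in range(max(n_restarts, len(partitions))):
        state = _random_state(
            rng, len(sites), basic_idx, acidic_idx, z,
            partition=partitions[restart % len(partitions)],
        )
        energy = float(_batch_energies(sites, state[None, :], coords, model)[0])
        while True:
            cands = _candidate_moves(state, basic_idx, acidic_idx)
            if cands.shape[0] == 0:
                break
            cand_e = _batch_energies(sites, cands, coords, model)
            k = int(cand_e.argmin())
            emin = float(cand_e[k])
            if emin >= energy - 1e-12:
                # two-move lookahead through the best uphill intermediates
                stepped = False
                order = np.argsort(cand_e)[: min(len(cand_e), 12)]
                for ki in order:
                    nxt = _candidate_moves(cands[ki], basic_idx, acidic_idx)
                    if nxt.shape[0] == 0:
                        continue
                    nxt_e = _batch_energies(sites, nxt, coords, model)
                    kj = int(nxt_e.argmin())
                    if float(nxt_e[kj]) < energy - 1e-12:
                        state = nxt[kj]
                        energy = float(nxt_e[kj])
                        stepped = True
                        break
                if not stepped:
                    break
                continue
            tol = 1e-9 * max(1.0, abs(emin))
            tied = np.flatnonzero(cand_e <= emin + tol)
            k = min(tied, key=lambda i: tuple(cands[i]))
            state = cands[k]
            energy = float(cand_e[k])
        key = tuple(bool(x) for x in state)
        tol = 1e-9 * max(1.0, abs(best_energy))
        if energy < best_energy - tol or (
            abs(energy - best_energy) <= tol
            and (best_state is None or key < best_state)
        ):
            best_state, best_energy = key, energy
    assert best_state is not None
    return ChargeConfiguration(states=best_state, z=z, energy=best_energy)


@dataclass(frozen=True)
class Schedule:
    """Thermostat schedule with proton-rearrangement and CCS cadences.

    ``segments`` are contiguous (t_start, t_end, temperature) triples in ns
    and K.  The rearrangement period (default 20 ps) is the interval at which
    protons are redistributed; ``ccs_cadence_ps`` is the interval at which
    theoretical CCS values are computed along the trajectory.
    """

    segments: tuple[tuple[float, float, float], ...]
    rearrangement_period_ps: float = 20.0
    ccs_cadence_ps: float = 2.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        if self.rearrangement_period_ps <= 0 or self.ccs_cadence_ps <= 0:
            raise ValueError("cadences must be positive")
        prev_end = self.segments[0][0]
        for t0, t1, _T in self.segments:
            if t1 <= t0:
                raise ValueError("segment with non-positive duration")
            if not math.isclose(t0, prev_end, abs_tol=1e-9):
                raise ValueError("segments must be contiguous and ordered")
            dur_ps = (t1 - t0) * 1000.0
            ratio = dur_ps / self.rearrangement_period_ps
            if not math.isclose(ratio, round(ratio), abs_tol=1e-6):
                raise ValueError(
                    "rearrangement period must divide each segment duration"
                )
            prev_end = t1

    @property
    def total_ns(self) -> float:
        return self.segments[-1][1] - self.segments[0][0]

    @property
    def n_rearrangements(self) -> int:
        return round(self.total_ns * 1000.0 / self.rearrangement_period_ps)

    def temperature_at(self, t_ns: float) -> float:
        """Thermostat temperature at time t (ns); right-continuous."""
        for t0, t1, T in self.segments:
            if t0 <= t_ns < t1:
                return T
        if math.isclose(t_ns, self.segments[-1][1], abs_tol=1e-9):
            return self.segments[-1][2]
        raise ValueError(f"t={t_ns} ns outside schedule [0, {self.total_ns}]")


def thermal_schedule(
    t0_kelvin: float,
    dt_kelvin: float,
    segment_ns: float,
    total_ns: float,
    rearrangement_period_ps: float = 20.0,
    ccs_cadence_ps: float = 2.0,
) -> Schedule:
    """Stepped heating ramp: T0, T0+dT, ... in contiguous equal segments."""
    ratio = total_ns / segment_ns
    n = round(ratio)
    if not math.isclose(ratio, n, abs_tol=1e-9) or n < 1:
        raise ValueError("segment length must divide the total time")
    segments = tuple(
        (i * segment_ns, (i + 1) * segment_ns, t0_kelvin + i * dt_kelvin)
        for i in range(n)
    )
    return Schedule(segments, rearrangement_period_ps, ccs_cadence_ps)


def coulombic_schedule(
    temperature: float = 300.0,
    total_ns: float = 100.0,
    rearrangement_period_ps: float = 20.0,
    ccs_cadence_ps: float = 10.0,
) -> Schedule:
    """Single steady-temperature segment for charge-driven unfolding runs."""
    return Schedule(
        ((0.0, total_ns, temperature),),
        rearrangement_period_ps,
        ccs_cadence_ps,
    )


def reassign_over_trajectory(
    frames: list[Structure],
    z: int,
    model: EnergyModel | None = None,
    schedule: Schedule | None = None,
    seed: int | None = None,
    sites: list[IonizableSite] | None = None,
) -> list[ChargeConfiguration]:
    """Redistribute the protons at every frame, independently of history.

    Each frame is treated with the same search seed, so identical frames
    yield identical configurations; the configuration at frame i depends only
    on frame i geometry.  ``sites`` defaults to the sites of the first frame
    (trajectories share topology).
    """
    from ciukit.structures import find_ionizable_sites

    if not frames:
        raise EmptyInputError("empty frame list")
    if sites is None:
        sites = find_ionizable_sites(frames[0])
    child_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    out = []
    for frame in frames:
        coords = frame.coords[[s.anchor_atom for s in sites]]
        out.append(assign_protons(sites, z, coords, model, seed=child_seed))
    return out
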