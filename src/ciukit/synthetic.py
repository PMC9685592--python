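"""Synthetic fixtures: idealized peptides, unfolding ensembles, ATDs, calibrants.

Everything downstream — ionizable-site discovery, proton assignment, CCS,
calibration, ensemble statistics — can be exercised on inputs generated here,
with no external files.  Peptides are built from idealized backbone internal
coordinates (NeRF chain extension) with a minimal side-chain representation:
only the atoms that anchor ionizable sites or participate in salt-bridge
detection are placed, on an idealized extended side-chain axis.  That is
deliberately not a rotamer library; fixtures emulate chain topology and
compactness, not real side-chain packing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ciukit.calibration import (
    MASS_HELIUM,
    ArrivalTimeDistribution,
    CalibrantRecord,
    reduced_ccs,
)
from ciukit.structures import Atom, Structure

__all__ = [
    "FixtureSpec",
    "DEFAULT_TEST_SEQUENCE",
    "build_ideal_peptide",
    "build_peptide_from_dihedrals",
    "make_unfolding_ensemble",
    "radius_of_gyration",
    "synth_atd",
    "synth_calibrants",
]

#: Default NTL9-like test sequence: the lysine-rich loop (KDVKGKGKK, placed at
#: residues 7–15) and the C-terminal KQKEQR tail embedded in poly-Ala linkers,
#: 56 residues total.
DEFAULT_TEST_SEQUENCE = "A" * 6 + "KDVKGKGKK" + "A" * 35 + "KQKEQR"

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Idealized backbone geometry (Å, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

PRESET_DIHEDRALS = {
    "extended": (-135.0, 135.0),
    "helical": (-57.0, -47.0),
}

# Distances (Å) from CB along the extended side-chain axis for the minimal
# anchor/salt-bridge atoms of ionizable residues.
_SIDECHAIN_AXIS_ATOMS: dict[str, list[tuple[str, float, float]]] = {
    # (atom name, along-axis distance from CB, perpendicular offset)
    "LYS": [("NZ", 4.9, 0.0)],
    "ARG": [("NE", 3.2, 0.0), ("CZ", 4.4, 0.0), ("NH1", 5.7, 0.0),
            ("NH2", 4.9, 1.1)],
    "HIS": [("ND1", 2.2, 0.9), ("NE2", 3.3, 0.0)],
    "ASP": [("CG", 1.52, 0.0), ("OD1", 2.7, 0.0), ("OD2", 2.0, 1.1)],
    "GLU": [("CG", 1.52, 0.0), ("CD", 2.9, 0.0), ("OE1", 4.1, 0.0),
            ("OE2", 3.4, 1.1)],
}


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement of atom D from chain A-B-C with internal coordinates."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            bond * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + np.column_stack([bc_hat, m_hat, n_hat]) @ d_local


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a perturbed conformer ensemble."""

    sequence: str = DEFAULT_TEST_SEQUENCE
    preset: str = "extended"
    amplitude: float = 0.0  # dihedral noise, degrees
    seed: int | None = None
    n_conformers: int = 2

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = [c for c in self.sequence if c not in ONE_TO_THREE]
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(set(bad))}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.n_conformers < 2:
            raise ValueError("ensemble needs >= 2 conformers")


def build_peptide_from_dihedrals(
    sequence: str, phi: np.ndarray, psi: np.ndarray
) -> Structure:
    """Build a peptide from per-residue (φ, ψ) with idealized bond geometry.

    Each residue gets N, CA, C, O plus CB and the minimal ionizable-site /
    salt-bridge atoms; the final residue also gets OXT.
    """
    n_res = len(sequence)
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    if phi.shape != (n_res,) or psi.shape != (n_res,):
        raise ValueError("phi/psi must have one value per residue")
    atoms: list[Atom] = []
    # seed the chain in the xy-plane
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbone = [(N, CA, C)]
    for i in range(1, n_res):
        Np, CAp, Cp = backbone[-1]
        N_i = _place_atom(Np, CAp, Cp, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA_i = _place_atom(CAp, Cp, N_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C_i = _place_atom(Cp, N_i, CA_i, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        backbone.append((N_i, CA_i, C_i))

    def add(name: str, pos, element: str, res_name: str, res_seq: int) -> None:
        atoms.append(
            Atom(
                element=element,
                name=name,
                x=float(pos[0]),
                y=float(pos[1]),
                z=float(pos[2]),
                res_name=res_name,
                res_seq=res_seq,
            )
        )

    for i, letter in enumerate(sequence):
        res_name = ONE_TO_THREE[letter]
        res_seq = i + 1
        N_i, CA_i, C_i = backbone[i]
        add("N", N_i, "N", res_name, res_seq)
        add("CA", CA_i, "C", res_name, res_seq)
        add("C", C_i, "C", res_name, res_seq)
        # carbonyl O opposite the next amide nitrogen
        o_torsion = (psi[i] + 180.0) if i < n_res - 1 else psi[i] + 180.0
        O_i = _place_atom(N_i, CA_i, C_i, BOND_C_O, ANGLE_CA_C_O, o_torsion)
        add("O", O_i, "O", res_name, res_seq)
        if i == n_res - 1:
            OXT = _place_atom(N_i, CA_i, C_i, 1.25, ANGLE_CA_C_O, psi[i])
            add("OXT", OXT, "O", res_name, res_seq)
        if letter != "G":
            CB = _place_atom(C_i, N_i, CA_i, 1.53, 110.5, 122.5)
            add("CB", CB, "C", res_name, res_seq)
            if res_name in _SIDECHAIN_AXIS_ATOMS:
                u = CB - CA_i
                u /= np.linalg.norm(u)
                ref = np.array([1.0, 0.0, 0.0])
                if abs(u @ ref) > 0.9:
                    ref = np.array([0.0, 1.0, 0.0])
                perp = np.cross(u, ref)
                perp /= np.linalg.norm(perp)
                for name, along, off in _SIDECHAIN_AXIS_ATOMS[res_name]:
                    pos = CB + along * u + off * perp
                    add(name, pos, name[0], res_name, res_seq)
    return Structure(atoms)


def _preset_dihedrals(
    sequence: str, preset: str, rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray]:
    n = len(sequence)
    if preset in PRESET_DIHEDRALS:
        phi0, psi0 = PRESET_DIHEDRALS[preset]
        return np.full(n, phi0), np.full(n, psi0)
    if preset == "compact-random":
        # jittered helical basin: compact but irregular
        rng = rng if rng is not None else np.random.default_rng(0)
        phi = rng.normal(-60.0, 20.0, n)
        psi = rng.normal(-45.0, 20.0, n)
        return phi, psi
    raise ValueError(f"unknown conformation preset {preset!r}")


def build_ideal_peptide(
    sequence: str, preset: str = "extended", seed: int | None = None
) -> Structure:
    """Idealized peptide in a named conformation.

    Presets: ``extended`` (φ,ψ)=(−135°,135°), ``helical`` (−57°,−47°),
    ``compact-random`` (seeded dihedrals in a compact basin).
    """
    FixtureSpec(sequence=sequence)  # validates the sequence
    rng = np.random.default_rng(seed) if preset == "compact-random" else None
    phi, psi = _preset_dihedrals(sequence, preset, rng)
    return build_peptide_from_dihedrals(sequence, phi, psi)


def radius_of_gyration(s: Structure) -> float:
    c = s.coords
    return float(np.sqrt(((c - c.mean(axis=0)) ** 2).sum(axis=1).mean()))


def make_unfolding_ensemble(
    spec: FixtureSpec, t_range: tuple[float, float] = (0.0, 1.0)
) -> list[Structure]:
    """Conformer series interpolating compact-random → extended dihedrals.

    Frame k sits at interpolation parameter t_k (linearly spaced over
    ``t_range``; t=0 is the compact start, t=1 fully extended), with seeded
    Gaussian dihedral noise of the spec's amplitude.  At amplitude 0 the
    compact start is re-jittered deterministically, if needed, until the
    radius of gyration is non-decreasing along the series, so the ensemble is
    ordered compact → extended by construction.
    """
    rng = np.random.default_rng(spec.seed)
    phi_ext, psi_ext = _preset_dihedrals(spec.sequence, "extended", None)
    ts = np.linspace(t_range[0], t_range[1], spec.n_conformers)
    for _attempt in range(30):
        phi_c, psi_c = _preset_dihedrals(spec.sequence, "compact-random", rng)
        frames = []
        for k, t in enumerate(ts):
            phi = (1 - t) * phi_c + t * phi_ext
            psi = (1 - t) * psi_c + t * psi_ext
            if spec.amplitude > 0:
                phi = phi + rng.normal(0.0, spec.amplitude, phi.size)
                psi = psi + rng.normal(0.0, spec.amplitude, psi.size)
            s = build_peptide_from_dihedrals(spec.sequence, phi, psi)
            s.frame_id = k
            frames.append(s)
        if spec.amplitude > 0:
            return frames
        rg = [radius_of_gyration(f) for f in frames]
        if all(b >= a - 1e-9 for a, b in zip(rg, rg[1:])):
            return frames
    return frames  # best effort; extremely unlikely to be reached


def synth_atd(
    components: list[tuple[float, float, float]],
    axis,
    axis_unit: str = "ms",
) -> ArrivalTimeDistribution:
    """Gaussian-mixture arrival-time distribution sampled on an axis.

    ``components`` are (center, sigma, amplitude) triples; closed-form
    moments of the mixture are available for metric tests.
    """
    if not components:
        raise ValueError("need at least one mixture component")
    axis = np.asarray(axis, float)
    intensity = np.zeros_like(axis)
    for center, sigma, amplitude in components:
        if sigma <= 0:
            raise ValueError("component sigma must be positive")
        intensity += amplitude * np.exp(-0.5 * ((axis - center) / sigma) ** 2)
    return ArrivalTimeDistribution(
        times=tuple(map(float, axis)),
        intensities=tuple(map(float, intensity)),
        axis_unit=axis_unit,
    )


def synth_calibrants(
    true_scale: float,
    true_exponent: float,
    edc_coefficient: float,
    records: list[tuple[float, int, float]],
    noise: float = 0.0,
    seed: int | None = None,
    reference_gas_mass: float = MASS_HELIUM,
) -> list[CalibrantRecord]:
    """Calibrant table generated by inverting the power-law calibration.

    ``records`` are (ion mass Da, charge, literature CCS Å²) triples; arrival
    times satisfy Ω′ = A·t′^x exactly, then receive optional multiplicative
    Gaussian noise of relative width ``noise``.
    """
    if true_scale <= 0 or true_exponent <= 0:
        raise ValueError("scale and exponent must be positive")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i, (mass, z, ccs_lit) in enumerate(records):
        omega_prime = reduced_ccs(ccs_lit, z, mass, reference_gas_mass)
        t_prime = (omega_prime / true_scale) ** (1.0 / true_exponent)
        t = t_prime + edc_coefficient * math.sqrt(mass / z) / 1000.0
        if noise > 0:
            t *= 1.0 + rng.normal(0.0, noise)
        out.append(
            CalibrantRecord(
                name=f"cal{i}", mass=mass, z=z, ccs_lit=ccs_lit, drift_time=t
            )
        )
    return out
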