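"""Conformer-ensemble analysis: salt bridges, CCS distributions, clustering.

Gas-phase unfolding intermediates are stabilized by electrostatic contacts;
a salt bridge is scored whenever any oxygen of an acidic group comes within a
cutoff (4 Å by default, inclusive) of any nitrogen of a basic group.  A
theoretical CCS distribution (CCSD) is built from an ensemble of per-model
CCS values by Gaussian kernel density estimation and compared with an
experimental CCSD through the overlapping coefficient ∫ min(p, q).  Conformer
families are found by average-linkage hierarchical clustering on the pairwise
Cα RMSD after optimal (Kabsch) superposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import find_peaks
from scipy.spatial.distance import cdist, squareform
from scipy.stats import gaussian_kde

from ciukit.structures import Structure

__all__ = [
    "SaltBridge",
    "EnsembleCCSD",
    "ClusterAssignment",
    "detect_salt_bridges",
    "ensemble_ccsd",
    "ccsd_modes",
    "ccsd_overlap",
    "superpose",
    "cluster_ensemble",
]

# Atom-name sets realizing the "oxygen of an acidic residue / nitrogen of a
# basic residue" rule; termini contribute their carboxylate O and amine N.
ACIDIC_O_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_N_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
CTERM_O_ATOMS = ("O", "OXT")
NTERM_N_ATOM = "N"


@dataclass(frozen=True)
class SaltBridge:
    """An acidic→basic electrostatic contact within the distance cutoff."""

    acidic_res: str  # e.g. "GLU38"
    basic_res: str  # e.g. "LYS2"
    distance: float  # minimum O–N distance, Å
    frame_id: int = 0


@dataclass(frozen=True)
class EnsembleCCSD:
    """A KDE-based theoretical CCS distribution on a support grid (Å²)."""

    grid: tuple[float, ...]
    density: tuple[float, ...]
    bandwidth: float
    n_models: int

    def __post_init__(self) -> None:
        d = np.asarray(self.density)
        if np.any(d < 0):
            raise ValueError("negative density")

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster labels per frame, contiguous from 0, ordered by family size."""

    labels: tuple[int, ...]
    rmsd_cutoff: float
    sizes: tuple[int, ...]


def _residue_atom_coords(
    s: Structure,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Group acidic-O and basic-N coordinates by residue label."""
    by_chain = s._residues_by_chain()
    nterm = {(ch, rr[0][0], rr[0][1]) for ch, rr in by_chain.items()}
    cterm = {(ch, rr[-1][0], rr[-1][1]) for ch, rr in by_chain.items()}
    acidic: dict[str, list] = {}
    basic: dict[str, list] = {}
    for a in s.atoms:
        label = f"{a.res_name}{a.res_key}"
        key = (a.chain_id, a.res_seq, a.icode)
        if a.res_name in ACIDIC_O_ATOMS and a.name in ACIDIC_O_ATOMS[a.res_name]:
            acidic.setdefault(label, []).append([a.x, a.y, a.z])
        if key in cterm and a.name in CTERM_O_ATOMS:
            acidic.setdefault(label, []).append([a.x, a.y, a.z])
        if a.res_name in BASIC_N_ATOMS and a.name in BASIC_N_ATOMS[a.res_name]:
            basic.setdefault(label, []).append([a.x, a.y, a.z])
        if key in nterm and a.name == NTERM_N_ATOM:
            basic.setdefault(label, []).append([a.x, a.y, a.z])
    return (
        {k: np.asarray(v, float) for k, v in acidic.items()},
        {k: np.asarray(v, float) for k, v in basic.items()},
    )


def detect_salt_bridges(s: Structure, cutoff: float = 4.0) -> list[SaltBridge]:
    """All acidic/basic residue pairs with minimum O–N distance ≤ cutoff.

    Each pair is reported once, oriented acidic→basic; same-residue pairs
    (e.g. an N-terminal aspartate against its own amine) are skipped.  An
    empty list is a valid result.
    """
    acidic, basic = _residue_atom_coords(s)
    bridges: list[SaltBridge] = []
    for a_label, a_xyz in acidic.items():
        for b_label, b_xyz in basic.items():
            if a_label == b_label:
                continue
            d = float(cdist(a_xyz, b_xyz).min())
            if d <= cutoff:
                bridges.append(
                    SaltBridge(
                        acidic_res=a_label,
                        basic_res=b_label,
                        distance=d,
                        frame_id=s.frame_id,
                    )
                )
    bridges.sort(key=lambda b: (b.acidic_res, b.basic_res))
    return bridges


#: Floor bandwidth (Å²) used when the sample is degenerate (all values equal).
MIN_BANDWIDTH = 1.0


def ensemble_ccsd(
    ccs_values, bandwidth: float | None = None, grid_size: int = 512
) -> EnsembleCCSD:
    """Gaussian-KDE CCS distribution over an ensemble of model CCS values.

    The bandwidth defaults to Silverman's rule; for degenerate samples it
    falls back to :data:`MIN_BANDWIDTH`.  The density is evaluated on a
    ``grid_size``-point grid spanning [min − 3h, max + 3h] and renormalized
    so its trapezoid integral is exactly 1.
    """
    values = np.asarray(ccs_values, float)
    if values.size < 2:
        raise ValueError("need at least 2 CCS values for a distribution")
    if bandwidth is None:
        std = values.std(ddof=1)
        if std < 1e-12:
            h = MIN_BANDWIDTH
        else:
            h = float(gaussian_kde(values, bw_method="silverman").factor * std)
            h = max(h, 1e-12)
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        h = float(bandwidth)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_size)
    # mean of Gaussian kernels; explicit form also covers degenerate samples
    u = (grid[None, :] - values[:, None]) / h
    density = np.exp(-0.5 * u**2).sum(axis=0) / (
        values.size * h * math.sqrt(2 * math.pi)
    )
    density /= np.trapezoid(density, grid)
    return EnsembleCCSD(
        grid=tuple(map(float, grid)),
        density=tuple(map(float, density)),
        bandwidth=h,
        n_models=int(values.size),
    )


def ccsd_modes(e: EnsembleCCSD, min_prominence: float = 0.05) -> list[float]:
    """Positions (Å²) of local density maxima, most prominent first.

    ``min_prominence`` is relative to the global density maximum.
    """
    density = np.asarray(e.density)
    grid = np.asarray(e.grid)
    peaks, props = find_peaks(density, prominence=min_prominence * density.max())
    order = np.argsort(props["prominences"])[::-1]
    return [float(grid[peaks[i]]) for i in order]


def _as_grid_density(obj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, EnsembleCCSD):
        return np.asarray(obj.grid), np.asarray(obj.density)
    grid, density = obj
    return np.asarray(grid, float), np.asarray(density, float)


def ccsd_overlap(theory, experiment, grid_size: int = 2048) -> float:
    """Overlapping coefficient ∫ min(p, q) dx between two CCSDs, in [0, 1].

    Both inputs (an :class:`EnsembleCCSD` or a ``(grid, density)`` pair) are
    resampled on a common grid and renormalized before comparison.  Disjoint
    supports give 0; identical distributions give 1.
    """
    g1, d1 = _as_grid_density(theory)
    g2, d2 = _as_grid_density(experiment)
    lo = min(g1.min(), g2.min())
    hi = max(g1.max(), g2.max())
    grid = np.linspace(lo, hi, grid_size)
    p = np.interp(grid, g1, d1, left=0.0, right=0.0)
    q = np.interp(grid, g2, d2, left=0.0, right=0.0)
    ip = np.trapezoid(p, grid)
    iq = np.trapezoid(q, grid)
    if ip <= 0 or iq <= 0:
        return 0.0
    overlap = float(np.trapezoid(np.minimum(p / ip, q / iq), grid))
    return min(max(overlap, 0.0), 1.0)


def _ca_coords(s: Structure) -> np.ndarray:
    ca = np.array([[a.x, a.y, a.z] for a in s.atoms if a.name == "CA"])
    if ca.size == 0:
        return s.coords
    return ca


def superpose(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of b onto a over Cα atoms (Kabsch).

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``b_coords @ rotation.T + translation ≈ a_coords``.
    Falls back to all atoms when no Cα atoms are present.
    """
    xa = _ca_coords(a)
    xb = _ca_coords(b)
    if xa.shape != xb.shape:
        raise ValueError(f"atom count mismatch: {xa.shape[0]} vs {xb.shape[0]}")
    if xa.shape[0] < 3:
        raise ValueError("superposition underdetermined with < 3 atoms")
    ca_mean, cb_mean = xa.mean(axis=0), xb.mean(axis=0)
    A = xa - ca_mean
    B = xb - cb_mean
    H = B.T @ A
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca_mean - cb_mean @ R.T
    diff = B @ R.T - A
    rmsd = float(np.sqrt((diff**2).sum() / xa.shape[0]))
    return R, t, rmsd


def cluster_ensemble(frames: list[Structure], rmsd_cutoff: float) -> ClusterAssignment:
    """Average-linkage hierarchical clustering on pairwise superposed RMSD.

    The dendrogram is cut at ``rmsd_cutoff`` (Å); labels are contiguous from
    0 and ordered by decreasing cluster size, ties by first-member index.
    Structures farther than the cutoff from every family stay singletons.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to cluster")
    n = len(frames)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = superpose(frames[i], frames[j])
            dm[i, j] = dm[j, i] = rmsd
    Z = linkage(squareform(dm, checks=False), method="average")
    raw = fcluster(Z, t=rmsd_cutoff, criterion="distance")
    order = sorted(
        set(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    remap = {c: k for k, c in enumerate(order)}
    labels = tuple(remap[c] for c in raw)
    sizes = tuple(labels.count(k) for k in range(len(order)))
    return ClusterAssignment(labels=labels, rmsd_cutoff=rmsd_cutoff, sizes=sizes)
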