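"""Theoretical collision cross sections by the projection approximation.

The projection approximation (PA) treats the ion as a union of hard spheres
(one per atom, radius = element radius + buffer-gas probe radius) and takes
the CCS as the projected area of that union averaged over all orientations.
``pa_ccs`` estimates it by Monte Carlo: uniformly random rotations, and for
each rotation a uniform hit-or-miss sample over the bounding box of the
projected disks.  The between-rotation spread gives the standard error.
``grid_reference_ccs`` is a slower deterministic pixel-quadrature reference
with a near-uniform direction set, useful for cross-checks.

PA neglects multiple scattering and long-range interactions; it is the
compact-ion limit of trajectory-method CCS.  An optional multiplicative
``scale_factor`` is provided for users applying an empirical PA-to-TM
correction; the default is 1 (no correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ciukit.errors import EmptyInputError, UnknownElementError
from ciukit.structures import Structure

__all__ = [
    "DEFAULT_RADII",
    "PROBE_RADIUS_HELIUM",
    "PROBE_RADIUS_NITROGEN",
    "CCSResult",
    "CCSSeries",
    "pa_ccs",
    "grid_reference_ccs",
    "trajectory_ccs",
    "moving_mean_smooth",
]

#: Hard-sphere radii per element, Å.  User-replaceable.
DEFAULT_RADII: dict[str, float] = {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
}

#: Default probe radii (Å) for the two common buffer gases.
PROBE_RADIUS_HELIUM = 1.0
PROBE_RADIUS_NITROGEN = 1.6


@dataclass(frozen=True)
class CCSResult:
    """A PA CCS estimate with its Monte-Carlo uncertainty (both Å²).

    ``ccs`` already includes ``scale_factor``.
    """

    ccs: float
    standard_error: float
    n_rotations: int
    n_samples_per_rotation: int
    probe_radius: float
    radii_table_id: str = "default"
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.ccs <= 0 or self.standard_error < 0:
            raise ValueError("invalid CCS result")


@dataclass(frozen=True)
class CCSSeries:
    """A time series of per-frame CCS values along a trajectory."""

    times: tuple[float, ...]  # ps
    values: tuple[float, ...]  # Å²
    errors: tuple[float, ...]  # Å² standard errors
    cadence: float  # ps

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")


def _sphere_radii(
    s: Structure, probe_radius: float, radii: dict[str, float]
) -> np.ndarray:
    out = np.empty(len(s.atoms))
    for i, el in enumerate(s.elements):
        if el not in radii:
            raise UnknownElementError(f"element {el!r} not in radii table")
        out[i] = radii[el] + probe_radius
    return out


def _rotation_matrix_from_quat(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _projected_area_mc(
    centers_xy: np.ndarray,
    radii: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
) -> float:
    """Hit-or-miss union-of-disks area over the disk bounding box."""
    lo = (centers_xy - radii[:, None]).min(axis=0)
    hi = (centers_xy + radii[:, None]).max(axis=0)
    box_area = float(np.prod(hi - lo))
    pts = rng.uniform(lo, hi, size=(n_samples, 2))
    d2 = ((pts[:, None, :] - centers_xy[None, :, :]) ** 2).sum(axis=-1)
    hits = (d2 <= (radii**2)[None, :]).any(axis=1)
    return box_area * float(hits.mean())


def pa_ccs(
    s: Structure,
    probe_radius: float = PROBE_RADIUS_HELIUM,
    n_rotations: int = 300,
    n_samples: int = 3000,
    seed: int | None = None,
    radii: dict[str, float] | None = None,
    radii_table_id: str = "default",
    scale_factor: float = 1.0,
) -> CCSResult:
    """Monte-Carlo projection-approximation CCS of one conformer.

    The estimator is unbiased: each rotation contributes an unbiased
    union-area estimate, and the mean over uniformly random rotations is the
    orientation average.  The standard error comes from the between-rotation
    sample variance (which includes the within-rotation sampling noise).
    """
    if n_rotations < 2:
        raise ValueError("n_rotations must be >= 2 (variance undefined below)")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    table = DEFAULT_RADII if radii is None else radii
    r = _sphere_radii(s, probe_radius, table)
    coords = s.coords
    rng = np.random.default_rng(seed)
    areas = np.empty(n_rotations)
    for k in range(n_rotations):
        R = _rotation_matrix_from_quat(rng.standard_normal(4))
        xy = coords @ R.T[:, :2]
        areas[k] = _projected_area_mc(xy, r, n_samples, rng)
    ccs = float(areas.mean()) * scale_factor
    se = float(areas.std(ddof=1) / math.sqrt(n_rotations)) * scale_factor
    return CCSResult(
        ccs=ccs,
        standard_error=se,
        n_rotations=n_rotations,
        n_samples_per_rotation=n_samples,
        probe_radius=probe_radius,
        radii_table_id=radii_table_id,
        scale_factor=scale_factor,
    )


def _fibonacci_directions(n: int) -> np.ndarray:
    """Near-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    cos_t = 1.0 - 2.0 * i / n
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def grid_reference_ccs(
    s: Structure,
    probe_radius: float = PROBE_RADIUS_HELIUM,
    n_directions: int = 400,
    grid_points: int = 400,
    radii: dict[str, float] | None = None,
) -> float:
    """Deterministic PA CCS by pixel quadrature over a direction lattice.

    For each projection direction the union-of-disks area is integrated on a
    regular pixel grid; directions come from a golden-spiral lattice, so the
    result is reproducible and free of Monte-Carlo noise.  Slower than
    :func:`pa_ccs`; intended as an independent reference.
    """
    table = DEFAULT_RADII if radii is None else radii
    r = _sphere_radii(s, probe_radius, table)
    coords = s.coords
    total = 0.0
    for u in _fibonacci_directions(n_directions):
        # orthonormal basis of the projection plane
        a = np.array([1.0, 0.0, 0.0])
        if abs(u @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        xy = coords @ np.column_stack([e1, e2])
        lo = (xy - r[:, None]).min(axis=0)
        hi = (xy + r[:, None]).max(axis=0)
        xs = np.linspace(lo[0], hi[0], grid_points)
        ys = np.linspace(lo[1], hi[1], grid_points)
        cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel()])
        d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1)
        covered = (d2 <= (r**2)[None, :]).any(axis=1)
        total += covered.sum() * cell
    return total / n_directions


def trajectory_ccs(
    frames: list[Structure],
    cadence: float = 2.0,
    frame_spacing: float | None = None,
    probe_radius: float = PROBE_RADIUS_HELIUM,
    n_rotations: int = 100,
    n_samples: int = 1000,
    seed: int | None = None,
    radii: dict[str, float] | None = None,
    scale_factor: float = 1.0,
) -> CCSSeries:
    """Per-frame PA CCS along a trajectory at a fixed time cadence (ps).

    ``frame_spacing`` is the time between consecutive input frames (ps);
    it defaults to the cadence, i.e. every frame retained.  The cadence must
    be an integer multiple of the spacing.  Per-frame seeds are spawned
    deterministically from the master seed.
    """
    if not frames:
        raise EmptyInputError("empty trajectory")
    spacing = cadence if frame_spacing is None else frame_spacing
    ratio = cadence / spacing
    stride = round(ratio)
    if not math.isclose(ratio, stride, abs_tol=1e-9) or stride < 1:
        raise ValueError("cadence must be a positive multiple of frame spacing")
    kept = frames[::stride]
    seeds = np.random.SeedSequence(seed).generate_state(len(kept)) % (2**31)
    times, values, errors = [], [], []
    for i, frame in enumerate(kept):
        res = pa_ccs(
            frame,
            probe_radius=probe_radius,
            n_rotations=n_rotations,
            n_samples=n_samples,
            seed=int(seeds[i]),
            radii=radii,
            scale_factor=scale_factor,
        )
        times.append(i * cadence)
        values.append(res.ccs)
        errors.append(res.standard_error)
    return CCSSeries(
        times=tuple(times),
        values=tuple(values),
        errors=tuple(errors),
        cadence=cadence,
    )


def moving_mean_smooth(series, window: int, passes: int = 1) -> np.ndarray:
    """Centered moving-mean smoothing with shrinking windows at the edges.

    ``window`` must be odd so the window is symmetric about each point; the
    output has the same length as the input.  ``passes`` repeats the filter.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    x = np.asarray(series, dtype=float)
    half = window // 2
    n = x.size
    for _ in range(passes):
        csum = np.concatenate([[0.0], np.cumsum(x)])
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        x = (csum[hi] - csum[lo]) / (hi - lo)
    return x
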