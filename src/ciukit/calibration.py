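"""Travelling-wave ion-mobility CCS calibration and CCSD summary metrics.

Travelling-wave drift times have no first-principles relation to CCS, so the
instrument is calibrated against ions of known (literature) CCS.  Following
the standard protocol:

1. the measured arrival time is corrected for the mass-dependent transit
   time outside the mobility cell, t′ = t − C·√(m/z)/1000, with C the
   instrument's enhanced-duty-cycle (EDC) delay coefficient — always a user
   input, never guessed;
2. the literature CCS is reduced by charge and reduced mass,
   Ω′ = Ω / (z·√(1/m_ion + 1/m_gas));
3. a power law Ω′ = A·t′^x is fitted as a straight line in (ln t′, ln Ω′).

Unknowns are then read off as Ω = A·t′^x·z·√(1/m + 1/m_gas).  The reduced-mass
term uses the reference-gas mass (helium by default) so values calibrated in
N₂ against He literature numbers come out on the He scale; the drift-gas mass
is recorded for bookkeeping.

An arrival-time (or CCS) distribution is summarized by its intensity-weighted
mean and standard deviation:

    IWM  = Σ I_i·t_i / Σ I_i
    IWSD = √( Σ I_i·(t_i − IWM)² / Σ I_i )

Both accept any monotone axis (ms or Å²); the weighting is population-style
(divide by Σ I, no n−1 correction).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ciukit.errors import CalibrationDomainError, EmptyInputError, ParseError

__all__ = [
    "MASS_HELIUM",
    "MASS_NITROGEN",
    "CalibrantRecord",
    "CalibrationModel",
    "ArrivalTimeDistribution",
    "CCSDMetrics",
    "correct_drift_time",
    "reduced_ccs",
    "fit_calibration",
    "apply_calibration",
    "ccsd_metrics",
    "read_calibrant_table",
    "read_atd",
]

MASS_HELIUM = 4.002602  # Da
MASS_NITROGEN = 28.0134  # Da


@dataclass(frozen=True)
class CalibrantRecord:
    """One calibrant ion: identity, mass, charge, literature CCS, drift time."""

    name: str
    mass: float  # Da
    z: int
    ccs_lit: float  # Å², reference gas
    drift_time: float  # ms, measured arrival time

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.ccs_lit <= 0 or self.drift_time <= 0:
            raise ValueError(f"non-positive field in calibrant {self.name!r}")
        if int(self.z) != self.z or self.z < 1:
            raise ValueError(f"charge must be a positive integer ({self.name!r})")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted power-law t′→CCS mapping with diagnostics."""

    exponent: float  # x
    scale: float  # A
    edc_coefficient: float  # C
    drift_gas_mass: float = MASS_NITROGEN
    reference_gas_mass: float = MASS_HELIUM
    r_squared: float = float("nan")
    residuals: tuple[float, ...] = ()
    t_prime_range: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.exponent <= 0 or self.scale <= 0:
            raise ValueError("exponent and scale must be positive")


@dataclass(frozen=True)
class ArrivalTimeDistribution:
    """Sampled intensity vs. arrival time (or any monotone axis)."""

    times: tuple[float, ...]
    intensities: tuple[float, ...]
    axis_unit: str = "ms"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        i = np.asarray(self.intensities, float)
        if t.size == 0 or t.size != i.size:
            raise ValueError("times/intensities must be equal-length, non-empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("axis must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("negative intensity")
        if not np.any(i > 0):
            raise ValueError("at least one intensity must be positive")


@dataclass(frozen=True)
class CCSDMetrics:
    iwm: float
    iwsd: float
    axis_unit: str = "ms"


def correct_drift_time(t: float, mz: float, edc_coefficient: float) -> float:
    """EDC-corrected drift time t′ = t − C·√(m/z)/1000 (ms)."""
    if t <= 0:
        raise CalibrationDomainError("drift time must be positive")
    t_prime = t - edc_coefficient * math.sqrt(mz) / 1000.0
    if t_prime <= 0:
        raise CalibrationDomainError(
            f"corrected drift time non-positive (t={t}, m/z={mz}, C={edc_coefficient})"
        )
    return t_prime


def reduced_ccs(ccs_lit: float, z: int, ion_mass: float, gas_mass: float) -> float:
    """Charge- and reduced-mass-normalized CCS, Ω′ = Ω/(z·√(1/m + 1/M))."""
    if ion_mass <= 0 or gas_mass <= 0:
        raise ValueError("masses must be positive")
    if z < 1:
        raise ValueError("charge must be >= 1")
    return ccs_lit / (z * math.sqrt(1.0 / ion_mass + 1.0 / gas_mass))


def fit_calibration(
    records: list[CalibrantRecord],
    edc_coefficient: float,
    drift_gas_mass: float = MASS_NITROGEN,
    reference_gas_mass: float = MASS_HELIUM,
) -> CalibrationModel:
    """Least-squares power-law fit of reduced CCS against corrected drift time.

    Fits ln Ω′ = x·ln t′ + ln A over the calibrant set.  Requires at least two
    records with distinct corrected times.
    """
    if len(records) < 2:
        raise ValueError("calibration needs at least 2 calibrants")
    t_prime = np.array(
        [
            correct_drift_time(r.drift_time, r.mass / r.z, edc_coefficient)
            for r in records
        ]
    )
    if np.ptp(t_prime) < 1e-12:
        raise ValueError("coincident corrected drift times: singular fit")
    omega_prime = np.array(
        [reduced_ccs(r.ccs_lit, r.z, r.mass, reference_gas_mass) for r in records]
    )
    ln_t, ln_o = np.log(t_prime), np.log(omega_prime)
    slope, intercept = np.polyfit(ln_t, ln_o, 1)
    pred = slope * ln_t + intercept
    resid = ln_o - pred
    ss_tot = float(((ln_o - ln_o.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return CalibrationModel(
        exponent=float(slope),
        scale=float(math.exp(intercept)),
        edc_coefficient=edc_coefficient,
        drift_gas_mass=drift_gas_mass,
        reference_gas_mass=reference_gas_mass,
        r_squared=min(max(r2, 0.0), 1.0),
        residuals=tuple(float(r) for r in resid),
        t_prime_range=(float(t_prime.min()), float(t_prime.max())),
    )


def apply_calibration(
    model: CalibrationModel, t: float, z: int, ion_mass: float
) -> float:
    """CCS (Å², reference-gas scale) of an unknown from its arrival time."""
    t_prime = correct_drift_time(t, ion_mass / z, model.edc_coefficient)
    lo, hi = model.t_prime_range
    if not (lo <= t_prime <= hi):
        warnings.warn(
            f"corrected drift time {t_prime:.4g} ms outside calibration "
            f"domain [{lo:.4g}, {hi:.4g}] ms",
            stacklevel=2,
        )
    return (
        model.scale
        * t_prime**model.exponent
        * z
        * math.sqrt(1.0 / ion_mass + 1.0 / model.reference_gas_mass)
    )


def ccsd_metrics(d: ArrivalTimeDistribution) -> CCSDMetrics:
    """Intensity-weighted mean and standard deviation of a distribution."""
    t = np.asarray(d.times, float)
    w = np.asarray(d.intensities, float)
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero intensities: metrics undefined")
    iwm = float((w * t).sum() / total)
    iwsd = float(math.sqrt((w * (t - iwm) ** 2).sum() / total))
    return CCSDMetrics(iwm=iwm, iwsd=iwsd, axis_unit=d.axis_unit)


CALIBRANT_COLUMNS = ["name", "mass", "z", "ccs_lit", "drift_time"]


def read_calibrant_table(text: str) -> list[CalibrantRecord]:
    """Parse a delimited calibrant table.

    Expected header: ``name,mass,z,ccs_lit,drift_time`` (comma, tab or
    whitespace separated); masses in Da, CCS in Å², drift times in ms.
    """
    try:
        df = pd.read_csv(io.StringIO(text), sep=None, engine="python")
    except Exception as exc:
        raise ParseError(f"unreadable calibrant table: {exc}") from None
    missing = [c for c in CALIBRANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"calibrant table missing columns: {missing}")
    if df.empty:
        raise EmptyInputError("calibrant table has no rows")
    return [
        CalibrantRecord(
            name=str(row["name"]),
            mass=float(row["mass"]),
            z=int(row["z"]),
            ccs_lit=float(row["ccs_lit"]),
            drift_time=float(row["drift_time"]),
        )
        for _, row in df.iterrows()
    ]


def read_atd(text: str, axis_unit: str = "ms") -> ArrivalTimeDistribution:
    """Parse a two-column (time, intensity) text distribution."""
    times, intensities = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ParseError(f"malformed ATD record at line {lineno}")
        times.append(float(parts[0]))
        intensities.append(float(parts[1]))
    if not times:
        raise EmptyInputError("empty arrival-time distribution")
    return ArrivalTimeDistribution(
        times=tuple(times), intensities=tuple(intensities), axis_unit=axis_unit
    )
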