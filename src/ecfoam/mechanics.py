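"""Compressive modulus extraction and Gibson-Ashby foam inversion.

The apparent modulus is the least-squares slope over the sliding strain
window that maximizes R^2 — an automated reading of "the linear region of
the curve". The inherent modulus of the strut material (the hydrogel between
bubbles) follows from the open-cell Gibson-Ashby scaling

    E_apparent = C * E_inherent * (rho_rel)^n,    rho_rel = 1 - phi_air

with the standard open-cell constants C = 1, n = 2 by default. The air
volume fraction phi_air comes from gravimetry: the mass deficit of the foam
relative to a bulk casting of the same mold volume, divided by hydrogel
density times mold volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class StressStrainCurve:
    """Paired compression data: dimensionless strain (ascending, in [0, 1])
    and stress in kPa."""

    strain: np.ndarray
    stress_kpa: np.ndarray

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress_kpa = np.asarray(self.stress_kpa, dtype=float)
        if self.strain.shape != self.stress_kpa.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be equal-length 1-D arrays")
        if len(self.strain) < 10:
            raise ValueError("need at least 10 points")
        if np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be strictly increasing")
        if self.strain[0] < 0 or self.strain[-1] > 1:
            raise ValueError("strain must lie within [0, 1]")


@dataclass
class ModulusResult:
    apparent_modulus_kpa: float
    fit_window: tuple[float, float]
    fit_r2: float
    inherent_modulus_kpa: float | None = None
    air_fraction: float | None = None


@dataclass
class FoamGravimetry:
    mass_bulk_g: float
    mass_foam_g: float
    hydrogel_density_g_per_ml: float
    mold_volume_ml: float
    air_fraction: float


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(max(0.0, min(1.0, r2)))


def apparent_modulus(
    curve: StressStrainCurve,
    window_width: float = 0.10,
    search_range: tuple[float, float] = (0.0, 0.3),
    min_points: int = 5,
) -> ModulusResult:
    """Slope of the best-fitting linear window of the stress-strain curve.

    Slides a window of ``window_width`` strain across ``search_range``,
    fits a line in each and keeps the window with the highest R^2 (ties go
    to the larger slope, so a flat toe never beats the elastic branch).
    Invariant to constant stress offsets.
    """
    lo, hi = search_range
    strain, stress = curve.strain, curve.stress_kpa
    in_range = (strain >= lo) & (strain <= min(hi, strain[-1]) + 1e-12)
    idx = np.flatnonzero(in_range)
    if len(idx) < min_points:
        raise ValueError("fewer points in the search range than the window needs")

    def scan(require_full_span: bool):
        # windows truncated at the range edge hold few points and can win
        # the R^2 contest by chance, so full-span windows are preferred
        best: tuple[float, float] | None = None  # (r2, slope)
        best_window = None
        for start in idx:
            stop = np.searchsorted(strain, strain[start] + window_width, side="right")
            stop = min(stop, idx[-1] + 1)
            if stop - start < min_points:
                continue
            if require_full_span and strain[stop - 1] - strain[start] < 0.9 * window_width:
                continue
            x, y = strain[start:stop], stress[start:stop]
            slope, r2 = _linfit(x, y)
            key = (round(r2, 12), slope)
            if best is None or key > best:
                best = key
                best_window = (float(x[0]), float(x[-1]))
        return best, best_window

    best, best_window = scan(require_full_span=True)
    if best is None:
        best, best_window = scan(require_full_span=False)
    if best is None:
        raise ValueError("no window with enough points; widen the search range")
    r2, slope = best
    return ModulusResult(
        apparent_modulus_kpa=slope, fit_window=best_window, fit_r2=float(r2)
    )


def gibson_ashby_inherent(
    apparent_kpa: float,
    air_fraction: float,
    prefactor: float = 1.0,
    exponent: float = 2.0,
) -> float:
    """Invert the open-cell scaling: E_inherent = E_app / (C (1 - phi)^n)."""
    if not 0 <= air_fraction < 1:
        raise ValueError("air_fraction must lie in [0, 1)")
    if apparent_kpa <= 0:
        raise ValueError("apparent modulus must be positive")
    if prefactor <= 0:
        raise ValueError("prefactor must be positive")
    return apparent_kpa / (prefactor * (1.0 - air_fraction) ** exponent)


def air_volume_fraction(
    mass_bulk_g: float,
    mass_foam_g: float,
    hydrogel_density_g_per_ml: float = 1.0,
    mold_volume_ml: float = 1.0,
) -> FoamGravimetry:
    """Air fraction from the foam/bulk mass deficit at equal mold volume."""
    if min(mass_bulk_g, mass_foam_g, hydrogel_density_g_per_ml, mold_volume_ml) <= 0:
        raise ValueError("masses, density and volume must be positive")
    if mass_foam_g > mass_bulk_g:
        raise ValueError("foam cannot outweigh the bulk casting")
    phi = (mass_bulk_g - mass_foam_g) / (hydrogel_density_g_per_ml * mold_volume_ml)
    if phi >= 1:
        raise ValueError("air fraction >= 1: inconsistent gravimetry inputs")
    return FoamGravimetry(
        mass_bulk_g=mass_bulk_g,
        mass_foam_g=mass_foam_g,
        hydrogel_density_g_per_ml=hydrogel_density_g_per_ml,
        mold_volume_ml=mold_volume_ml,
        air_fraction=phi,
    )
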