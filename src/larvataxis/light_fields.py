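"""Planar irradiance fields and spectral utilities.

The behavioural arena is a square agarose plate centred at the origin.  The
projected light patterns vary slowly enough across the plate that their
irradiance is well described by a plane,

    I(x, y) = a0 + a1x * x + a1y * y    [W/m^2, x and y in cm]

with ``a0`` the irradiance at the plate centre and ``a1x``, ``a1y`` the
slopes along the two axes.  This module constructs and fits such fields,
evaluates them, and integrates measured spectra over the blue/green band
(380-570 nm) that the larval photoreceptors Rh5 and Rh6 respond to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator

from .errors import DegenerateDesignError, NegativeIntensityError, RangeError

__all__ = [
    "LinearLightField",
    "SpectrumTable",
    "field_from_coefficients",
    "intensity_at",
    "delta_intensity",
    "mean_intensity",
    "fit_linear_field",
    "PlaneFitDiagnostics",
    "integrate_band",
]


@dataclass(frozen=True)
class LinearLightField:
    """A linear planar irradiance field over a square plate.

    Parameters
    ----------
    a0 : float
        Irradiance at the origin (W/m^2).
    a1x, a1y : float
        Slopes along x and y (W/m^2 per cm).
    plate_half_width : float
        Half the plate side length in cm (23 cm plate -> 11.5).
    theta_deg : float
        Zenith angle of the light source relative to the plate plane, in
        degrees.  90 means overhead illumination (no in-plane
        directionality).
    source_direction : tuple of float
        Unit vector in the plate plane pointing toward the light source.
        Normalised on construction.
    """

    a0: float
    a1x: float = 0.0
    a1y: float = 0.0
    plate_half_width: float = 11.5
    theta_deg: float = 40.0
    source_direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        vals = (self.a0, self.a1x, self.a1y, self.plate_half_width, self.theta_deg)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("light-field coefficients must be finite")
        if self.plate_half_width <= 0:
            raise ValueError("plate_half_width must be positive")
        if not 0.0 < self.theta_deg <= 90.0:
            raise ValueError("theta_deg must lie in (0, 90]")
        s = np.asarray(self.source_direction, dtype=float)
        if s.shape != (2,) or not np.all(np.isfinite(s)):
            raise ValueError("source_direction must be a finite 2-vector")
        norm = float(np.hypot(*s))
        if norm == 0.0:
            raise ValueError("source_direction must be non-zero")
        object.__setattr__(
            self, "source_direction", (float(s[0] / norm), float(s[1] / norm))
        )
        if self.corner_minimum < 0.0:
            raise NegativeIntensityError(
                f"field is negative on the plate (corner minimum "
                f"{self.corner_minimum:.4g} W/m^2)"
            )

    @property
    def corner_minimum(self) -> float:
        """Minimum irradiance over the four plate corners.

        For a linear field this is the minimum over the whole plate.
        """
        h = self.plate_half_width
        corners = [(sx * h, sy * h) for sx in (-1, 1) for sy in (-1, 1)]
        return min(self.a0 + self.a1x * x + self.a1y * y for x, y in corners)


def field_from_coefficients(
    a0: float,
    a1x: float = 0.0,
    a1y: float = 0.0,
    plate_half_width: float = 11.5,
    theta_deg: float = 40.0,
    source_direction: tuple[float, float] = (1.0, 0.0),
) -> LinearLightField:
    """Build a validated :class:`LinearLightField` from plane coefficients.

    Raises
    ------
    NegativeIntensityError
        If the plane dips below zero anywhere on the plate.
    ValueError
        On non-finite coefficients or an invalid geometry.
    """
    return LinearLightField(
        a0=a0,
        a1x=a1x,
        a1y=a1y,
        plate_half_width=plate_half_width,
        theta_deg=theta_deg,
        source_direction=source_direction,
    )


def intensity_at(field: LinearLightField, x_cm, y_cm):
    """Irradiance I(x, y) = a0 + a1x*x + a1y*y, vectorised over points.

    Points outside the plate trigger a warning but are still evaluated
    (the plane extends everywhere).
    """
    x = np.asarray(x_cm, dtype=float)
    y = np.asarray(y_cm, dtype=float)
    h = field.plate_half_width
    if np.any(np.abs(x) > h) or np.any(np.abs(y) > h):
        warnings.warn("evaluating light field outside the plate domain", stacklevel=2)
    out = field.a0 + field.a1x * x + field.a1y * y
    return float(out) if out.ndim == 0 else out


def delta_intensity(field: LinearLightField, r, r_prime) -> float:
    """Intensity change I(r') - I(r) for a step from ``r`` to ``r_prime``.

    Both points are (x, y) in cm.  A move toward darker regions yields a
    negative value, so it is always accepted by the Metropolis rule.
    """
    r = np.asarray(r, dtype=float)
    rp = np.asarray(r_prime, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(rp))):
        raise ValueError("step endpoints must be finite")
    d = rp - r
    return float(field.a1x * d[0] + field.a1y * d[1])


def mean_intensity(field: LinearLightField) -> float:
    """Spatial mean irradiance over the square plate.

    For a linear field the mean over a domain symmetric about the origin
    equals the value at the centre, i.e. ``a0``.
    """
    return float(field.a0)


@dataclass(frozen=True)
class PlaneFitDiagnostics:
    """Residual diagnostics from :func:`fit_linear_field`."""

    residuals: np.ndarray
    rss: float
    coefficient_se: tuple[float, float, float] | None
    n_points: int


def fit_linear_field(
    points,
    plate_half_width: float = 11.5,
    theta_deg: float = 40.0,
    source_direction: tuple[float, float] = (1.0, 0.0),
) -> tuple[LinearLightField, PlaneFitDiagnostics]:
    """Least-squares plane through measured (x_cm, y_cm, irradiance) points.

    Returns the fitted field together with residual diagnostics
    (per-point residuals, residual sum of squares, and coefficient
    standard errors when there are more than 3 points).

    Raises
    ------
    DegenerateDesignError
        With fewer than 3 points or collinear (x, y) locations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of (x, y, irradiance)")
    if pts.shape[0] < 3:
        raise DegenerateDesignError("need at least 3 points to fit a plane")
    X = np.column_stack([np.ones(len(pts)), pts[:, 0], pts[:, 1]])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateDesignError("points are collinear; plane is not identifiable")
    coef, _, _, _ = np.linalg.lstsq(X, pts[:, 2], rcond=None)
    resid = pts[:, 2] - X @ coef
    rss = float(resid @ resid)
    se = None
    dof = len(pts) - 3
    if dof > 0:
        cov = np.linalg.inv(X.T @ X) * (rss / dof)
        se = tuple(float(v) for v in np.sqrt(np.diag(cov)))
    field = LinearLightField(
        a0=float(coef[0]),
        a1x=float(coef[1]),
        a1y=float(coef[2]),
        plate_half_width=plate_half_width,
        theta_deg=theta_deg,
        source_direction=source_direction,
    )
    return field, PlaneFitDiagnostics(
        residuals=resid, rss=rss, coefficient_se=se, n_points=len(pts)
    )


@dataclass(frozen=True)
class SpectrumTable:
    """A measured spectral-irradiance table.

    ``wavelength_nm`` must be strictly increasing; ``spectral_irradiance``
    is in W/m^2/nm and must be non-negative.
    """

    wavelength_nm: np.ndarray
    spectral_irradiance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        si = np.asarray(self.spectral_irradiance, dtype=float)
        if wl.ndim != 1 or si.shape != wl.shape:
            raise ValueError("wavelengths and irradiances must be 1-D and matched")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(si < 0) or not np.all(np.isfinite(si)):
            raise ValueError("spectral irradiance must be finite and non-negative")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "spectral_irradiance", si)

    @classmethod
    def from_csv(cls, path) -> "SpectrumTable":
        """Read a 2-column CSV with header (wavelength_nm, spectral_irradiance_W_m2_nm)."""
        df = pd.read_csv(path)
        required = {"wavelength_nm", "spectral_irradiance_W_m2_nm"}
        if not required.issubset(df.columns):
            raise ValueError(f"spectrum CSV must have columns {sorted(required)}")
        return cls(
            wavelength_nm=df["wavelength_nm"].to_numpy(float),
            spectral_irradiance=df["spectral_irradiance_W_m2_nm"].to_numpy(float),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "wavelength_nm": self.wavelength_nm,
                "spectral_irradiance_W_m2_nm": self.spectral_irradiance,
            }
        ).to_csv(path, index=False, float_format="%.12g")


def integrate_band(
    spectrum: SpectrumTable, lo_nm: float = 380.0, hi_nm: float = 570.0
) -> float:
    """Total irradiance (W/m^2) in the band [lo_nm, hi_nm].

    A monotone piecewise-cubic (PCHIP) interpolant is put through the
    measured points and integrated with adaptive quadrature.  PCHIP avoids
    the oscillation a single high-order polynomial would show on noisy
    spectra while staying within the local data range, so the interpolant
    never goes negative.

    Raises
    ------
    RangeError
        If the band extends beyond the measured wavelength range.
    """
    if hi_nm <= lo_nm:
        raise ValueError("band upper edge must exceed the lower edge")
    wl = spectrum.wavelength_nm
    if lo_nm < wl[0] or hi_nm > wl[-1]:
        raise RangeError(
            f"band [{lo_nm}, {hi_nm}] nm outside measured range [{wl[0]}, {wl[-1]}] nm"
        )
    interp = PchipInterpolator(wl, spectrum.spectral_irradiance)
    total = 0.0
    # integrate knot interval by knot interval so quad sees smooth pieces
    knots = wl[(wl > lo_nm) & (wl < hi_nm)]
    edges = np.concatenate([[lo_nm], knots, [hi_nm]])
    for a, b in zip(edges[:-1], edges[1:]):
        val, _ = quad(interp, a, b, limit=200)
        total += val
    return float(total)
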