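"""Stern-Volmer quenching analysis, double-log binding fits and site-marker
competition.

The Stern-Volmer relation for collisional (dynamic) quenching,

    F0 / F = 1 + K_SV [Q] = 1 + k_q tau0 [Q],

links the ratio of unquenched to quenched fluorescence to the quencher
concentration [Q].  K_SV comes from the slope of an ordinary least-squares
line (the intercept is fitted, not forced to 1) and the bimolecular quenching
rate constant is k_q = K_SV / tau0, with tau0 the unquenched fluorophore
lifetime (default 1e-8 s, the canonical biomolecular scale).  A K_SV that
rises with temperature indicates dynamic quenching (faster diffusion, more
collisions); a falling K_SV indicates static ground-state-complex quenching.

The association constant K_a and apparent site number n come from the
double-logarithmic plot with free-ligand depletion correction:

    log10((F0 - F) / F) = n log10 K_a + n log10([L_T] - (F0 - F)[P_T]/F0)

where [L_T] and [P_T] are the total ligand and protein concentrations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import TitrationSeries, ValidationError

__all__ = [
    "QuenchingFit",
    "BindingFit",
    "MechanismCall",
    "MarkerReport",
    "FitError",
    "stern_volmer_fit",
    "classify_mechanism",
    "double_log_fit",
    "percent_quench",
    "site_marker_comparison",
    "analyze_titration",
]

logger = logging.getLogger(__name__)

DIFFUSION_LIMIT = 2e10  # M^-1 s^-1, collisional upper bound for biopolymers


class FitError(RuntimeError):
    """Raised when a regression cannot be performed (too few usable points)."""


@dataclass
class QuenchingFit:
    """Result of a Stern-Volmer regression at one temperature."""

    K_SV: float  # M^-1
    intercept: float
    k_q: float  # M^-1 s^-1
    tau0: float  # s
    r: float
    points: np.ndarray  # columns: [Q] (mol/L), F0/F
    temperature: float | None = None
    stderr_K_SV: float = float("nan")
    exceeds_diffusion_limit: bool | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)


@dataclass
class BindingFit:
    """Result of the double-log binding regression at one temperature."""

    K_a: float  # M^-1
    n: float
    r: float
    points: np.ndarray  # columns: log10(free ligand), log10((F0-F)/F)
    temperature: float | None = None
    dropped_points: int = 0
    nonpositive_slope: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)


@dataclass
class MechanismCall:
    verdict: str  # dynamic | static | indeterminate
    K_SV_by_T: list[tuple[float, float]] = field(default_factory=list)
    evidence: str = ""


@dataclass
class MarkerReport:
    divergence: dict[str, float]
    assigned_site: str
    wavelength: float
    curves: dict[str, np.ndarray] = field(default_factory=dict)


def _ols(x: np.ndarray, y: np.ndarray):
    if x.size < 2:
        raise FitError(f"need at least 2 points for a regression, got {x.size}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # r undefined for exactly collinear input
        res = stats.linregress(x, y)
    r = res.rvalue if np.isfinite(res.rvalue) else 1.0
    return res.slope, res.intercept, r, res.stderr


def stern_volmer_fit(
    F0: float,
    F_values,
    Q_values,
    tau0: float = 1e-8,
    temperature: float | None = None,
    annotate_diffusion_limit: bool = False,
) -> QuenchingFit:
    """OLS of F0/F against [Q]; slope = K_SV, k_q = K_SV / tau0.

    ``Q_values`` are the quencher-present concentrations (mol/L) matching
    ``F_values``; the ligand-free intensity enters only through F0.
    """
    F = np.asarray(F_values, dtype=float)
    Q = np.asarray(Q_values, dtype=float)
    if F.size != Q.size:
        raise ValidationError("F and Q must have the same length")
    if F0 <= 0 or np.any(F <= 0):
        raise ValidationError("fluorescence intensities must be positive")
    if tau0 <= 0:
        raise ValidationError("tau0 must be positive")
    if F.size < 3:
        raise FitError(f"Stern-Volmer fit needs >= 3 points, got {F.size}")
    ratio = F0 / F
    slope, intercept, r, stderr = _ols(Q, ratio)
    k_q = slope / tau0
    return QuenchingFit(
        K_SV=slope,
        intercept=intercept,
        k_q=k_q,
        tau0=tau0,
        r=r,
        points=np.column_stack([Q, ratio]),
        temperature=temperature,
        stderr_K_SV=stderr,
        exceeds_diffusion_limit=(k_q > DIFFUSION_LIMIT) if annotate_diffusion_limit else None,
    )


def classify_mechanism(fits: list[QuenchingFit]) -> MechanismCall:
    """Classify quenching from the temperature trend of K_SV.

    Strictly increasing K_SV with temperature -> dynamic; strictly
    decreasing -> static; anything else -> indeterminate.
    """
    if len(fits) < 2:
        raise ValidationError("need K_SV at >= 2 temperatures")
    temps = [f.temperature for f in fits]
    if any(t is None for t in temps):
        raise ValidationError("every fit must carry its temperature")
    if len(set(temps)) != len(temps):
        raise ValidationError("temperatures must be distinct")
    ordered = sorted(fits, key=lambda f: f.temperature)
    ksv = [f.K_SV for f in ordered]
    pairs = [(float(f.temperature), float(f.K_SV)) for f in ordered]
    if all(b > a for a, b in zip(ksv, ksv[1:])):
        verdict, why = "dynamic", "K_SV strictly increases with temperature"
    elif all(b < a for a, b in zip(ksv, ksv[1:])):
        verdict, why = "static", "K_SV strictly decreases with temperature"
    else:
        verdict, why = "indeterminate", "K_SV is not monotone in temperature"
    return MechanismCall(verdict=verdict, K_SV_by_T=pairs, evidence=why)


def double_log_fit(
    F0: float,
    F_values,
    L_T,
    P_T: float,
    temperature: float | None = None,
) -> BindingFit:
    """Double-log binding fit with free-ligand depletion correction.

    Points with F >= F0 (no quench or apparent enhancement) or a non-positive
    free-ligand term are dropped with a logged warning; the regression needs
    at least 3 surviving points.  slope = n, K_a = 10**(intercept / n).
    """
    F = np.asarray(F_values, dtype=float)
    L = np.asarray(L_T, dtype=float)
    if F.size != L.size:
        raise ValidationError("F and L_T must have the same length")
    if F0 <= 0:
        raise ValidationError("F0 must be positive")
    if P_T < 0:
        raise ValidationError("protein concentration must be non-negative")
    with np.errstate(invalid="ignore", divide="ignore"):
        bound = (F0 - F) / F0
        free = L - bound * P_T
        keep = (F > 0) & (F < F0) & (free > 0)
    dropped = int(F.size - keep.sum())
    if dropped:
        logger.warning("double_log_fit: dropped %d unusable point(s)", dropped)
    if keep.sum() < 3:
        raise FitError(
            f"double-log fit needs >= 3 usable points; {dropped} of {F.size} dropped "
            "(require 0 < F < F0 and positive free-ligand term)"
        )
    x = np.log10(free[keep])
    y = np.log10((F0 - F[keep]) / F[keep])
    slope, intercept, r, _ = _ols(x, y)
    nonpos = slope <= 0
    if nonpos:
        logger.warning("double_log_fit: non-positive slope %.3g", slope)
        K_a = float("nan")
    else:
        K_a = 10.0 ** (intercept / slope)
    return BindingFit(
        K_a=K_a,
        n=slope,
        r=r,
        points=np.column_stack([x, y]),
        temperature=temperature,
        dropped_points=dropped,
        nonpositive_slope=bool(nonpos),
    )


def percent_quench(F0: float, F: float) -> float:
    """Percentage loss of fluorescence relative to the ligand-free signal."""
    if F0 <= 0:
        raise ValidationError("F0 must be positive")
    return 100.0 * (F0 - F) / F0


def site_marker_comparison(
    plain: TitrationSeries,
    with_marker_a: TitrationSeries,
    with_marker_b: TitrationSeries,
    marker_a: str = "site_I",
    marker_b: str = "site_II",
    wavelength: float = 347.0,
) -> MarkerReport:
    """Compare quench curves with and without bound site markers.

    Each series is reduced to its F/F0 curve at ``wavelength``.  The
    divergence score of a marker is the mean absolute difference between its
    curve and the plain-protein curve; the ligand is assigned to the site of
    the marker whose presence perturbs the curve MORE (larger divergence),
    since competition at a shared site changes the apparent quenching most.
    """
    ladders = [plain.ligand_concs, with_marker_a.ligand_concs, with_marker_b.ligand_concs]
    if not all(l.size == ladders[0].size and np.allclose(l, ladders[0]) for l in ladders[1:]):
        raise ValidationError("all three series must share the ligand ladder")
    curves = {}
    for name, series in (("plain", plain), (marker_a, with_marker_a), (marker_b, with_marker_b)):
        F = series.intensities_at(wavelength)
        if F[0] <= 0:
            raise ValidationError(f"{name}: F0 at {wavelength} nm must be positive")
        curves[name] = F / F[0]
    div = {
        marker_a: float(np.mean(np.abs(curves[marker_a] - curves["plain"]))),
        marker_b: float(np.mean(np.abs(curves[marker_b] - curves["plain"]))),
    }
    if np.isclose(div[marker_a], div[marker_b]):
        site = "indeterminate"
    else:
        site = marker_a if div[marker_a] > div[marker_b] else marker_b
    return MarkerReport(divergence=div, assigned_site=site, wavelength=wavelength, curves=curves)


def analyze_titration(
    series: TitrationSeries,
    tau0: float = 1e-8,
    wavelength: float | None = None,
    bandwidth: float = 0.0,
) -> tuple[QuenchingFit, BindingFit]:
    """Convenience: Stern-Volmer and double-log fits for one titration.

    Intensities are read at the per-spectrum emission maximum by default or
    at a fixed wavelength when given; a positive ``bandwidth`` averages over
    ``+- bandwidth`` nm around the read position, the recommended read-out
    for noisy spectra (ratios are unaffected because all steps share the
    band shape).
    """
    F = series.intensities_at(wavelength, bandwidth=bandwidth)
    F0 = F[0]
    sv = stern_volmer_fit(
        F0, F[1:], series.ligand_concs[1:], tau0=tau0, temperature=series.temperature
    )
    dl = double_log_fit(
        F0, F[1:], series.ligand_concs[1:], series.protein_conc,
        temperature=series.temperature,
    )
    return sv, dl
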