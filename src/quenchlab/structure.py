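"""Structural probes: CD secondary structure, synchronous-fluorescence shift
tables, 3-D fluorescence (EEM) peak tables with Rayleigh masking, and
differential-pulse-voltammetry peak metrics.

Circular dichroism: observed ellipticity theta (mdeg) is normalised to mean
residue ellipticity, MRE = theta * MRW / (10 * c * l) in deg cm^2 dmol^-1
(c in mg/mL, l in cm, MRW the mean residue weight in Da, default 110).  The
alpha-helix content follows the two-point estimator at 208 nm,

    helix % = 100 * (-MRE_208 - 4000) / (33000 - 4000),

with -33,000 the reference for a fully helical chain and -4,000 the random
coil baseline.  The raw value is unbounded; reports clamp to [0, 100] but
keep the raw number.

EEM peak tables mask Rayleigh scattering ridges (first order along
em == ex, second order along em == 2 ex) before picking local maxima, since
those ridges are instrumental, not fluorophore signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import EEM, Spectrum, TitrationSeries, ValidationError

__all__ = [
    "CDRecord",
    "PeakInfo",
    "EEMPeak",
    "mre_from_ellipticity",
    "helix_fraction",
    "cd_analysis",
    "find_peak",
    "shift_and_quench_table",
    "eem_peak_table",
    "dpv_series_metrics",
]

HELIX_MRE_208 = -33000.0  # deg cm^2 dmol^-1, 100% alpha helix
COIL_MRE_208 = -4000.0  # random coil baseline


@dataclass
class PeakInfo:
    position: float  # nm or V
    height: float
    method: str  # grid_max | parabolic


@dataclass
class EEMPeak:
    excitation: float  # nm
    emission: float  # nm
    intensity: float


@dataclass
class CDRecord:
    """CD measurement reduced to MRE and helix content."""

    conc: float  # mg/mL
    path_length: float  # cm
    mean_residue_weight: float  # Da
    mre_208: float  # deg cm^2 dmol^-1
    helix_pct_raw: float
    helix_pct: float  # clamped to [0, 100]
    mre_spectrum: Spectrum | None = None


def mre_from_ellipticity(theta_obs, conc: float, path_length: float, mrw: float = 110.0):
    """Convert observed ellipticity (mdeg) to mean residue ellipticity.

    MRE = theta * MRW / (10 * c * l) with c in mg/mL and l in cm.  Accepts
    scalars or arrays.
    """
    if conc <= 0 or path_length <= 0 or mrw <= 0:
        raise ValidationError("conc, path length and MRW must be positive")
    out = np.asarray(theta_obs, dtype=float) * mrw / (10.0 * conc * path_length)
    return float(out) if out.ndim == 0 else out


def mre_from_ellipticity_molar(theta_obs, conc_molar: float, n_residues: int, path_length: float):
    """Alternate molar form: MRE = theta / (10 * c_molar * n * l), c in mol/L."""
    if conc_molar <= 0 or path_length <= 0 or n_residues <= 0:
        raise ValidationError("conc, path length and residue count must be positive")
    out = np.asarray(theta_obs, dtype=float) / (10.0 * conc_molar * n_residues * path_length)
    return float(out) if out.ndim == 0 else out


def helix_fraction(mre_208: float) -> tuple[float, float]:
    """Alpha-helix percentage from MRE at 208 nm.

    Returns ``(clamped, raw)``: the raw two-point estimate (unbounded) and
    the value clamped to [0, 100] for reporting.
    """
    if not np.isfinite(mre_208):
        raise ValidationError("MRE_208 must be finite")
    raw = 100.0 * (-mre_208 - (-COIL_MRE_208)) / ((-HELIX_MRE_208) - (-COIL_MRE_208))
    return float(np.clip(raw, 0.0, 100.0)), float(raw)


def cd_analysis(
    theta: Spectrum,
    conc: float,
    path_length: float,
    mrw: float = 110.0,
    helix_wavelength: float = 208.0,
) -> CDRecord:
    """Full CD reduction: mdeg spectrum -> MRE spectrum -> helix content."""
    mre = mre_from_ellipticity(theta.signal, conc, path_length, mrw)
    if not (theta.abscissa[0] <= helix_wavelength <= theta.abscissa[-1]):
        raise ValidationError(f"{helix_wavelength} nm outside the CD spectrum range")
    mre_208 = float(np.interp(helix_wavelength, theta.abscissa, mre))
    clamped, raw = helix_fraction(mre_208)
    return CDRecord(
        conc=conc,
        path_length=path_length,
        mean_residue_weight=mrw,
        mre_208=mre_208,
        helix_pct_raw=raw,
        helix_pct=clamped,
        mre_spectrum=Spectrum(theta.abscissa.copy(), mre, label=f"MRE {theta.label}".strip()),
    )


def find_peak(
    spectrum: Spectrum,
    window: tuple[float, float] | None = None,
    refine: bool = False,
) -> PeakInfo:
    """Locate the maximum of a spectrum within a window.

    The grid maximum is returned (ties broken to the smallest abscissa).
    With ``refine=True`` a parabola through the maximum and its two
    neighbours interpolates a sub-grid vertex — useful for broad voltammetric
    peaks sampled coarsely.
    """
    x, y = spectrum.abscissa, spectrum.signal
    if window is not None:
        lo, hi = window
        mask = (x >= lo) & (x <= hi)
        if mask.sum() == 0:
            raise ValidationError(f"window {window} contains no data points")
        if mask.sum() < 3:
            raise ValidationError(f"window {window} holds fewer than 3 points")
        x, y = x[mask], y[mask]
    i = int(np.argmax(y))  # argmax takes the first index on ties
    if not refine or i == 0 or i == y.size - 1:
        return PeakInfo(position=float(x[i]), height=float(y[i]), method="grid_max")
    x3, y3 = x[i - 1 : i + 2], y[i - 1 : i + 2]
    denom = (y3[0] - 2 * y3[1] + y3[2])
    if denom == 0:  # flat top: keep the grid point
        return PeakInfo(position=float(x[i]), height=float(y[i]), method="grid_max")
    # vertex of the parabola through three equally or unequally spaced points
    coeffs = np.polyfit(x3, y3, 2)
    xv = -coeffs[1] / (2 * coeffs[0])
    yv = np.polyval(coeffs, xv)
    xv = float(np.clip(xv, x3[0], x3[2]))
    return PeakInfo(position=xv, height=float(yv), method="parabolic")


def shift_and_quench_table(
    series: TitrationSeries | list[Spectrum],
    window: tuple[float, float] | None = None,
    refine: bool = False,
) -> list[dict]:
    """Per-step peak table for a synchronous (or any) spectral series.

    Each row carries the peak position and height plus the signed shift and
    percent height change relative to step 0.  Shift = position - position0,
    so a negative shift is a blue shift; percent change is signed
    (a quench appears as a negative change).
    """
    spectra = series.emission_spectra if isinstance(series, TitrationSeries) else list(series)
    if len(spectra) < 2:
        raise ValidationError("need at least 2 steps for a shift table")
    rows = []
    ref: PeakInfo | None = None
    for i, spec in enumerate(spectra):
        pk = find_peak(spec, window, refine=refine)
        if ref is None:
            ref = pk
        rows.append(
            {
                "step": i,
                "label": spec.label,
                "position": pk.position,
                "height": pk.height,
                "shift": pk.position - ref.position,
                "percent_change": 100.0 * (pk.height - ref.height) / ref.height
                if ref.height != 0
                else float("nan"),
            }
        )
    return rows


def eem_peak_table(eem: EEM, rayleigh_halfwidth: float = 15.0) -> list[EEMPeak]:
    """Fluorophore peaks of an EEM after masking Rayleigh scattering ridges.

    Cells with |em - ex| <= halfwidth (first order) or |em - 2 ex| <=
    halfwidth (second order) are masked.  Remaining cells that are strict
    local maxima over their unmasked 8-neighbourhood (and above zero) are
    returned ordered by descending intensity.
    """
    if rayleigh_halfwidth < 0:
        raise ValidationError("Rayleigh halfwidth must be non-negative")
    ex = eem.excitation[:, None]
    em = eem.emission[None, :]
    masked = (np.abs(em - ex) <= rayleigh_halfwidth) | (np.abs(em - 2 * ex) <= rayleigh_halfwidth)
    if masked.all():
        raise ValidationError("Rayleigh halfwidth masks every EEM cell")
    z = np.where(masked, -np.inf, eem.intensity)
    n_ex, n_em = z.shape
    peaks: list[EEMPeak] = []
    for i in range(n_ex):
        for j in range(n_em):
            v = z[i, j]
            if not np.isfinite(v) or v <= 0:
                continue
            neigh = z[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2]
            if v >= np.max(neigh) and np.sum(neigh == v) == 1:
                peaks.append(
                    EEMPeak(
                        excitation=float(eem.excitation[i]),
                        emission=float(eem.emission[j]),
                        intensity=float(v),
                    )
                )
    peaks.sort(key=lambda p: -p.intensity)
    return peaks


def dpv_series_metrics(
    voltammograms: list[Spectrum],
    window: tuple[float, float] | None = None,
    refine: bool = True,
) -> dict:
    """Peak potential / current per voltammogram plus overall shifts.

    Returns per-step (E_p, I_p), the potential shift dE_p = last - first,
    the current change dI_p = last - first, and a flag for a strictly
    decreasing peak-current sequence (the signature of progressive complex
    formation removing free ligand from solution).
    """
    if len(voltammograms) < 2:
        raise ValidationError("need at least 2 voltammograms")
    steps = []
    for i, v in enumerate(voltammograms):
        pk = find_peak(v, window, refine=refine)
        steps.append({"step": i, "label": v.label, "E_p": pk.position, "I_p": pk.height})
    Ip = [s["I_p"] for s in steps]
    return {
        "steps": steps,
        "delta_E_p": steps[-1]["E_p"] - steps[0]["E_p"],
        "delta_I_p": Ip[-1] - Ip[0],
        "I_p_strictly_decreasing": all(b < a for a, b in zip(Ip, Ip[1:])),
    }
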