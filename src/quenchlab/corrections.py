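"""Pre-analysis corrections: inner-filter effect and Beer-Lambert arithmetic.

The inner-filter effect (IFE) is the attenuation of both the excitation beam
and the emitted light by the absorbance of the sample itself.  The standard
multiplicative correction restores the fluorescence that would be observed in
an optically thin sample:

    F_cor = F_obs * 10 ** ((A_ex + A_em) / 2)

where A_ex and A_em are the solution absorbances at the excitation and
emission wavelengths.  Both are plain absorbances of each titration solution.
"""

from __future__ import annotations

import numpy as np

from .types import Spectrum, TitrationSeries, ValidationError

__all__ = [
    "correct_inner_filter",
    "absorbance_at",
    "conc_from_absorbance",
    "correct_titration",
]


def correct_inner_filter(F_obs, A_ex, A_em):
    """Apply the multiplicative inner-filter correction.

    Accepts scalars or arrays (broadcast together).  F_cor >= F_obs always,
    with equality exactly when A_ex + A_em == 0.
    """
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValidationError("absorbances must be non-negative")
    out = np.asarray(F_obs, dtype=float) * 10.0 ** ((A_ex + A_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def absorbance_at(spectrum: Spectrum, wavelength: float) -> float:
    """Absorbance at ``wavelength`` by linear interpolation; exact at grid points."""
    lo, hi = spectrum.abscissa[0], spectrum.abscissa[-1]
    if not (lo <= wavelength <= hi):
        raise ValidationError(
            f"wavelength {wavelength} nm outside absorbance range [{lo}, {hi}]"
        )
    return float(np.interp(wavelength, spectrum.abscissa, spectrum.signal))


def conc_from_absorbance(A: float, epsilon: float, path_length: float = 1.0) -> float:
    """Beer-Lambert concentration: c = A / (epsilon * l), in mol/L.

    ``epsilon`` in M^-1 cm^-1, ``path_length`` in cm.
    """
    if epsilon <= 0 or path_length <= 0:
        raise ValidationError("epsilon and path length must be positive")
    if A < 0:
        raise ValidationError("absorbance must be non-negative")
    return A / (epsilon * path_length)


def correct_titration(
    series: TitrationSeries, *, pointwise: bool = False
) -> TitrationSeries:
    """Inner-filter-correct every emission spectrum of a titration.

    A_ex is read from each step's absorbance spectrum at the excitation
    wavelength.  By default A_em is read once per step at the emission maximum
    of the F0 spectrum and applied as a scalar; with ``pointwise=True`` the
    whole spectrum is corrected with A_em evaluated at each emission
    wavelength.

    A titration with no absorbance spectra (or all-zero absorbance) passes
    through unchanged.
    """
    if series.absorbance_spectra is None:
        return series
    em_max = series.emission_spectra[0].peak_position
    corrected = []
    for spec, absorb in zip(series.emission_spectra, series.absorbance_spectra):
        A_ex = absorbance_at(absorb, series.excitation_wavelength)
        if pointwise:
            A_em = np.interp(spec.abscissa, absorb.abscissa, absorb.signal)
        else:
            A_em = absorbance_at(absorb, em_max)
        corrected.append(
            Spectrum(spec.abscissa, correct_inner_filter(spec.signal, A_ex, A_em), spec.label)
        )
    return TitrationSeries(
        temperature=series.temperature,
        protein_conc=series.protein_conc,
        ligand_concs=series.ligand_concs.copy(),
        emission_spectra=corrected,
        excitation_wavelength=series.excitation_wavelength,
        absorbance_spectra=None,
    )
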