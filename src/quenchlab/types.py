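"""Core in-memory containers for spectral and electrochemical data.

All optical abscissae are in nanometres, voltammetric abscissae in volts,
concentrations in mol/L and temperatures in kelvin.  Validation happens at
construction time so that downstream analysis code can assume well-formed
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "TitrationSeries", "EEM", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _as_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class Spectrum:
    """A single measured curve: ordered abscissa plus signal values.

    Parameters
    ----------
    abscissa:
        Strictly increasing grid — wavelength (nm) for optical spectra,
        potential (V) for voltammograms.
    signal:
        Measured values (fluorescence a.u., absorbance, or current in uA).
    label:
        Free-text identifier, typically the titration-step concentration.
    """

    abscissa: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.abscissa = _as_1d(self.abscissa, "abscissa")
        self.signal = _as_1d(self.signal, "signal")
        if self.abscissa.size != self.signal.size:
            raise ValidationError(
                f"abscissa ({self.abscissa.size}) and signal ({self.signal.size}) "
                "lengths differ"
            )
        if self.abscissa.size < 3:
            raise ValidationError("a spectrum needs at least 3 points")
        diffs = np.diff(self.abscissa)
        if not np.all(diffs > 0):
            bad = int(np.argmax(diffs <= 0)) + 1
            raise ValidationError(
                f"abscissa not strictly increasing at index {bad} "
                f"(value {self.abscissa[bad]!r} after {self.abscissa[bad - 1]!r})"
            )

    def __len__(self) -> int:
        return int(self.abscissa.size)

    @property
    def peak_index(self) -> int:
        """Index of the grid maximum (first occurrence on ties)."""
        return int(np.argmax(self.signal))

    @property
    def peak_position(self) -> float:
        return float(self.abscissa[self.peak_index])

    @property
    def peak_height(self) -> float:
        return float(self.signal[self.peak_index])


@dataclass
class TitrationSeries:
    """A fluorescence titration: one emission spectrum per ligand concentration.

    The first ladder entry must be 0 (the ligand-free F0 spectrum).  Optional
    absorbance spectra, one per step, support inner-filter correction.
    """

    temperature: float  # K
    protein_conc: float  # mol/L
    ligand_concs: np.ndarray  # mol/L, strictly increasing, starts at 0
    emission_spectra: list[Spectrum]
    excitation_wavelength: float = 280.0  # nm
    absorbance_spectra: list[Spectrum] | None = None

    def __post_init__(self) -> None:
        self.ligand_concs = _as_1d(self.ligand_concs, "ligand_concs")
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if self.ligand_concs.size == 0 or self.ligand_concs[0] != 0.0:
            raise ValidationError("ligand ladder must start at 0 (the F0 spectrum)")
        if np.any(self.ligand_concs < 0):
            raise ValidationError("ligand concentrations must be non-negative")
        if not np.all(np.diff(self.ligand_concs) > 0):
            raise ValidationError("ligand ladder must be strictly increasing")
        if len(self.emission_spectra) != self.ligand_concs.size:
            raise ValidationError(
                f"{len(self.emission_spectra)} emission spectra for "
                f"{self.ligand_concs.size} ladder steps"
            )
        if self.absorbance_spectra is not None and len(self.absorbance_spectra) != self.ligand_concs.size:
            raise ValidationError("absorbance spectra count must match ladder steps")

    def __len__(self) -> int:
        return int(self.ligand_concs.size)

    def intensities_at(
        self, wavelength: float | None = None, bandwidth: float = 0.0
    ) -> np.ndarray:
        """Per-step fluorescence read-out.

        With ``wavelength=None`` each spectrum is read at its own emission
        maximum; with a fixed wavelength (e.g. 347 nm for site-marker work)
        all spectra are interpolated at that wavelength.  A positive
        ``bandwidth`` (half-width, nm) averages the signal over
        ``center +- bandwidth`` instead of reading a single grid point —
        since every step shares the emission band shape this leaves all
        intensity ratios unchanged while suppressing point noise.
        """
        out = np.empty(len(self))
        for i, s in enumerate(self.emission_spectra):
            if wavelength is None:
                center = s.peak_position
            else:
                if not (s.abscissa[0] <= wavelength <= s.abscissa[-1]):
                    raise ValidationError(
                        f"wavelength {wavelength} nm outside spectrum range "
                        f"[{s.abscissa[0]}, {s.abscissa[-1]}]"
                    )
                center = wavelength
            if bandwidth > 0:
                mask = np.abs(s.abscissa - center) <= bandwidth
                out[i] = float(np.mean(s.signal[mask]))
            else:
                out[i] = float(np.interp(center, s.abscissa, s.signal))
        return out


@dataclass
class EEM:
    """Excitation-emission matrix: intensity indexed (excitation, emission)."""

    excitation: np.ndarray  # nm
    emission: np.ndarray  # nm
    intensity: np.ndarray = field(repr=False)  # shape (n_ex, n_em)

    def __post_init__(self) -> None:
        self.excitation = _as_1d(self.excitation, "excitation")
        self.emission = _as_1d(self.emission, "emission")
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.excitation.size < 2 or self.emission.size < 2:
            raise ValidationError("EEM needs at least 2 excitation and 2 emission points")
        for name, grid in (("excitation", self.excitation), ("emission", self.emission)):
            if not np.all(np.diff(grid) > 0):
                raise ValidationError(f"{name} grid not strictly increasing")
        if self.intensity.shape != (self.excitation.size, self.emission.size):
            raise ValidationError(
                f"intensity shape {self.intensity.shape} does not match grids "
                f"({self.excitation.size}, {self.emission.size})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (int(self.excitation.size), int(self.emission.size))
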