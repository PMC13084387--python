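"""Synthetic spectral and electrochemical data with known ground truth.

Every analysis stage in the package has a matching generator here, so that
generator/estimator round trips are testable without any instrument data.
The defaults mirror a canonical serum-albumin drug-binding titration:
3 uM protein excited at 280 nm, a tryptophan emission band near 347 nm,
ligand from 0 to 80 uM in 10 uM steps, and temperatures of 287, 298 and
307 K.

Two quenching mechanisms are available.  ``dynamic`` applies the
Stern-Volmer law directly, F(Q) = F0 / (1 + K_SV Q).  ``static_binding``
defines F implicitly through the double-log binding isotherm with
free-ligand depletion,

    log10((F0 - F)/F) = n log10 K_a + n log10(L_T - (F0 - F) P_T / F0),

solved per titration step by fixed-point iteration to 1e-12, so the
double-log estimator is exactly consistent with the generator.

Noise is Gaussian on signal values only (the abscissa stays exact),
expressed relative to the F0 amplitude; a seed fully determines the output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .structure import COIL_MRE_208, HELIX_MRE_208
from .thermo import R_GAS
from .types import EEM, Spectrum, TitrationSeries, ValidationError

__all__ = [
    "SimConfig",
    "simulate_titration",
    "simulate_vant_hoff",
    "simulate_cd",
    "simulate_eem",
    "simulate_voltammogram",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Raised when a generator fails to converge."""


DEFAULT_LADDER = tuple(np.arange(0.0, 81.0, 10.0) * 1e-6)  # 0-80 uM, mol/L


class SimConfig(BaseModel):
    """Configuration and ground truth for a titration simulation."""

    seed: int = 0
    mechanism: str = "dynamic"  # dynamic | static_binding
    true_K_SV: float = Field(3.62e4, gt=0)  # M^-1
    true_K_a: float = Field(2.76e4, gt=0)  # M^-1
    true_n: float = Field(1.0, gt=0)
    protein_conc: float = Field(3e-6, gt=0)  # mol/L
    ligand_ladder: tuple[float, ...] = DEFAULT_LADDER  # mol/L
    emission_center: float = 347.0  # nm
    emission_sigma: float = 28.0  # nm
    emission_grid: tuple[float, float, float] = (300.0, 450.0, 1.0)  # start, stop, step (nm)
    excitation_wavelength: float = 280.0  # nm
    F0_amplitude: float = 1000.0  # a.u.
    apply_ife: bool = False
    ligand_eps_ex: float = 4000.0  # M^-1 cm^-1 at the excitation wavelength
    ligand_eps_em: float = 500.0  # M^-1 cm^-1 at the emission center
    noise_sigma_rel: float = Field(0.0, ge=0)
    temperature: float = Field(298.0, gt=0)  # K

    @field_validator("mechanism")
    @classmethod
    def _check_mechanism(cls, v: str) -> str:
        if v not in ("dynamic", "static_binding"):
            raise ValueError(f"unknown mechanism {v!r}")
        return v

    @field_validator("ligand_ladder")
    @classmethod
    def _check_ladder(cls, v):
        arr = np.asarray(v, dtype=float)
        if arr.size < 2 or arr[0] != 0.0 or np.any(np.diff(arr) <= 0):
            raise ValueError("ladder must start at 0 and be strictly increasing")
        return v


def _solve_static_F(F0: float, L_T: float, P_T: float, K_a: float, n: float) -> float:
    """Fixed-point solve of the depletion-corrected binding isotherm for F."""
    if L_T == 0:
        return F0
    F = 0.5 * F0
    for _ in range(10_000):
        free = L_T - (F0 - F) * P_T / F0
        if free <= 0:
            free = 1e-30
        x = (K_a * free) ** n
        F_new = F0 / (1.0 + x)
        if abs(F_new - F) <= 1e-12 * F0:
            return F_new
        F = F_new
    raise GenerationError(
        f"static-binding fixed point did not converge at L_T={L_T:.3g} M"
    )


def simulate_titration(config: SimConfig) -> tuple[TitrationSeries, dict]:
    """Generate a fluorescence titration plus a machine-readable truth record.

    Emission spectra are Gaussian bands whose peak follows the configured
    quenching law; if ``apply_ife`` the observed intensities are attenuated
    by 10**(-(A_ex + A_em)/2) with absorbances from the ligand's molar
    absorptivities, and matching absorbance spectra are attached so
    :func:`quenchlab.corrections.correct_titration` can invert the effect
    exactly.
    """
    rng = np.random.default_rng(config.seed)
    start, stop, step = config.emission_grid
    grid = np.arange(start, stop + 0.5 * step, step)
    ladder = np.asarray(config.ligand_ladder, dtype=float)
    band = np.exp(-0.5 * ((grid - config.emission_center) / config.emission_sigma) ** 2)

    F_true = np.empty(ladder.size)
    for i, q in enumerate(ladder):
        if config.mechanism == "dynamic":
            F_true[i] = config.F0_amplitude / (1.0 + config.true_K_SV * q)
        else:
            F_true[i] = _solve_static_F(
                config.F0_amplitude, q, config.protein_conc, config.true_K_a, config.true_n
            )

    emission, absorbance = [], []
    abs_grid = np.arange(250.0, 500.0, 1.0)
    for i, q in enumerate(ladder):
        A_ex = config.ligand_eps_ex * q
        A_em = config.ligand_eps_em * q
        atten = 10.0 ** (-(A_ex + A_em) / 2.0) if config.apply_ife else 1.0
        signal = F_true[i] * atten * band
        if config.noise_sigma_rel > 0:
            signal = signal + rng.normal(
                0.0, config.noise_sigma_rel * config.F0_amplitude, size=signal.size
            )
        emission.append(Spectrum(grid.copy(), signal, label=f"{q * 1e6:g}"))
        if config.apply_ife:
            # flat absorbance interpolating between the two stated epsilons
            frac = np.clip(
                (abs_grid - config.excitation_wavelength)
                / (config.emission_center - config.excitation_wavelength),
                0.0,
                1.0,
            )
            a = A_ex + (A_em - A_ex) * frac
            absorbance.append(Spectrum(abs_grid.copy(), a, label=f"{q * 1e6:g}"))

    series = TitrationSeries(
        temperature=config.temperature,
        protein_conc=config.protein_conc,
        ligand_concs=ladder,
        emission_spectra=emission,
        excitation_wavelength=config.excitation_wavelength,
        absorbance_spectra=absorbance if config.apply_ife else None,
    )
    truth = {
        "mechanism": config.mechanism,
        "true_K_SV": config.true_K_SV,
        "true_K_a": config.true_K_a,
        "true_n": config.true_n,
        "F0_amplitude": config.F0_amplitude,
        "F_true_peak": F_true.tolist(),
        "seed": config.seed,
        "temperature": config.temperature,
    }
    return series, truth


def simulate_vant_hoff(dH: float, dS: float, temps) -> np.ndarray:
    """Association constants from the Van't Hoff closed form.

    K(T) = exp(-dH/(R T) + dS/R), the exact inverse of the linear fit.
    """
    T = np.asarray(temps, dtype=float)
    if np.any(T <= 0):
        raise ValidationError("temperatures must be positive")
    return np.exp(-dH / (R_GAS * T) + dS / R_GAS)


def simulate_cd(
    helix_fraction: float,
    conc: float = 0.1995,
    path_length: float = 0.1,
    mrw: float = 110.0,
    seed: int = 0,
    noise_mdeg: float = 0.0,
) -> Spectrum:
    """Synthetic far-UV CD spectrum (mdeg) with a configurable helix content.

    The MRE curve is a weighted sum of a helix basis (double minima at 208
    and 222 nm, depth -33,000 at 208 for a pure helix) and a coil basis
    (-4,000 at 208), then converted to observed millidegrees by the inverse
    of the MRE normalisation.  By construction, reading MRE at 208 nm and
    applying the two-point helix estimator returns the configured fraction.
    """
    if not (0.0 <= helix_fraction <= 1.0):
        raise ValidationError("helix fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    grid = np.arange(200.0, 260.0, 0.5)

    def gauss(center, sigma):
        return np.exp(-0.5 * ((grid - center) / sigma) ** 2)

    # helix basis: two negative bands; scaled so its value at 208 nm is -33000
    helix_shape = gauss(208.0, 6.0) + 0.95 * gauss(222.0, 7.0)
    helix_basis = HELIX_MRE_208 * helix_shape / np.interp(208.0, grid, helix_shape)
    # coil basis: shallow negative band near 198 nm tailing through 208
    coil_shape = gauss(200.0, 10.0)
    coil_basis = COIL_MRE_208 * coil_shape / np.interp(208.0, grid, coil_shape)
    mre = helix_fraction * helix_basis + (1.0 - helix_fraction) * coil_basis
    theta = mre * (10.0 * conc * path_length) / mrw  # inverse of MRE conversion
    if noise_mdeg > 0:
        theta = theta + rng.normal(0.0, noise_mdeg, size=theta.size)
    return Spectrum(grid, theta, label=f"helix={helix_fraction:g}")


def simulate_eem(
    peaks: list[tuple[float, float, float, float, float]] | None = None,
    rayleigh: bool = True,
    ex_grid=None,
    em_grid=None,
    rayleigh_height: float = 120.0,
    rayleigh_sigma: float = 6.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> EEM:
    """Synthetic EEM: 2-D Gaussian fluorophore peaks plus Rayleigh ridges.

    ``peaks`` rows are (ex_center, em_center, height, ex_sigma, em_sigma) in
    nm / intensity units.  First- and second-order scattering ridges run
    along em == ex and em == 2 ex.
    """
    if ex_grid is None:
        ex_grid = np.arange(220.0, 351.0, 5.0)
    if em_grid is None:
        em_grid = np.arange(220.0, 501.0, 1.0)
    ex_grid = np.asarray(ex_grid, dtype=float)
    em_grid = np.asarray(em_grid, dtype=float)
    if peaks is None:
        peaks = []
    EX = ex_grid[:, None]
    EM = em_grid[None, :]
    z = np.zeros((ex_grid.size, em_grid.size))
    for (exc, emc, height, sx, sy) in peaks:
        if not (ex_grid[0] <= exc <= ex_grid[-1] and em_grid[0] <= emc <= em_grid[-1]):
            raise ValidationError(f"peak ({exc}, {emc}) outside the EEM grids")
        z += height * np.exp(-0.5 * (((EX - exc) / sx) ** 2 + ((EM - emc) / sy) ** 2))
    if rayleigh:
        z += rayleigh_height * np.exp(-0.5 * ((EM - EX) / rayleigh_sigma) ** 2)
        z += 0.5 * rayleigh_height * np.exp(-0.5 * ((EM - 2 * EX) / rayleigh_sigma) ** 2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        z += rng.normal(0.0, noise_sigma, size=z.shape)
    return EEM(ex_grid, em_grid, z)


def simulate_voltammogram(
    E_p: float = 0.95,
    I_p: float = 10.0,
    width: float = 0.05,
    baseline_slope: float = 0.0,
    baseline_offset: float = 0.0,
    window: tuple[float, float] = (0.6, 1.3),
    step: float = 0.002,
    noise_sigma: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> Spectrum:
    """Gaussian oxidation peak on a linear baseline over a potential window."""
    if width <= 0:
        raise ValidationError("peak width must be positive")
    E = np.arange(window[0], window[1] + 0.5 * step, step)
    i = baseline_offset + baseline_slope * E + I_p * np.exp(-0.5 * ((E - E_p) / width) ** 2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sigma, size=i.size)
    return Spectrum(E, i, label=label)


def write_truth_sidecar(truth: dict, path: str | Path) -> None:
    """Write the ground-truth record beside a generated dataset."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
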