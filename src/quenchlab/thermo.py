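"""Van't Hoff thermodynamics and interaction-force classification.

The Van't Hoff relation, ln K_a = -dH/(R T) + dS/R, makes ln K_a linear in
1/T: the slope gives the binding enthalpy (dH = -R * slope) and the intercept
the entropy (dS = R * intercept).  Gibbs free energies follow from
dG = dH - T dS at each temperature.  The sign pattern of dH and dS
classifies the dominant intermolecular force (Ross-Subramanian rules):
both positive -> hydrophobic; both negative -> van der Waals / hydrogen
bonds; dH negative with dS positive, or dH near zero -> electrostatic.

All energies are in SI joules internally; reports convert to kJ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import ValidationError
from .quenching import FitError

__all__ = ["R_GAS", "ThermoResult", "vant_hoff_fit", "gibbs", "classify_forces"]

R_GAS = 8.314  # J mol^-1 K^-1


@dataclass
class ThermoResult:
    dH: float  # J/mol
    dS: float  # J/(mol K)
    dG_by_T: list[tuple[float, float]]  # (T in K, dG in J/mol)
    r: float
    force_class: str
    gas_constant: float = R_GAS
    stderr_dH: float = float("nan")
    stderr_dS: float = float("nan")
    spontaneous: bool = False  # dG < 0 at every fitted temperature
    consistency_J: list[float] = field(default_factory=list)  # |−RT lnK − (dH−TdS)|


def gibbs(dH: float, dS: float, T: float) -> float:
    """dG = dH - T dS (J/mol)."""
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")
    return dH - T * dS


def classify_forces(dH: float, dS: float, near_zero_tol: float = 4000.0) -> str:
    """Ross-Subramanian sign rules for the dominant binding force.

    ``near_zero_tol`` (J/mol, default ~RT) widens the electrostatic clause to
    enthalpies indistinguishable from zero.
    """
    if near_zero_tol < 0:
        raise ValidationError("tolerance must be non-negative")
    if abs(dH) <= near_zero_tol:
        return "electrostatic"
    if dH > 0 and dS > 0:
        return "hydrophobic"
    if dH < 0 and dS < 0:
        return "vdW_hbond"
    if dH < 0 and dS > 0:
        return "electrostatic"
    return "indeterminate"


def vant_hoff_fit(
    K_values, T_values, near_zero_tol: float = 4000.0
) -> ThermoResult:
    """Fit ln K against 1/T and derive dH, dS, per-T dG and the force class.

    dG is computed from the fitted dH and dS (dG = dH - T dS), so the
    identity dG == dH - T dS holds exactly for every reported temperature.
    The report also carries, per temperature, |-R T ln K - (dH - T dS)| as a
    consistency check on the regression residuals.
    """
    K = np.asarray(K_values, dtype=float)
    T = np.asarray(T_values, dtype=float)
    if K.size != T.size:
        raise ValidationError("K and T must have the same length")
    if np.any(K <= 0):
        raise ValidationError("association constants must be positive")
    if np.any(T <= 0):
        raise ValidationError("temperatures must be positive (kelvin)")
    if np.unique(T).size < 2:
        raise FitError("Van't Hoff fit needs >= 2 distinct temperatures")
    x = 1.0 / T
    y = np.log(K)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.linregress(x, y)
    r = res.rvalue if np.isfinite(res.rvalue) else 1.0
    dH = -R_GAS * res.slope
    dS = R_GAS * res.intercept
    dG_by_T = [(float(t), gibbs(dH, dS, float(t))) for t in T]
    consistency = [
        float(abs(-R_GAS * t * np.log(k) - dg)) for (t, dg), k in zip(dG_by_T, K)
    ]
    return ThermoResult(
        dH=dH,
        dS=dS,
        dG_by_T=dG_by_T,
        r=r,
        force_class=classify_forces(dH, dS, near_zero_tol),
        stderr_dH=R_GAS * res.stderr if np.isfinite(res.stderr) else float("nan"),
        stderr_dS=R_GAS * res.intercept_stderr if np.isfinite(res.intercept_stderr) else float("nan"),
        spontaneous=all(dg < 0 for _, dg in dG_by_T),
        consistency_J=consistency,
    )
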