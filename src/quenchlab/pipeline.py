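"""End-to-end orchestration: run every analysis a config provides inputs for
and assemble a single report.

The pipeline mirrors a complete binding-characterization study: inner-filter
correction, Stern-Volmer fits per temperature, quenching-mechanism call,
double-log binding fits, Van't Hoff thermodynamics with Gibbs energies and
force classification, CD helix content, synchronous-fluorescence shift
tables, EEM peak tables and DPV metrics.  Stages are independent where the
data allow: a failing stage is recorded as failed and the rest still run.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import corrections, io, quenching, structure, thermo
from .types import TitrationSeries

__all__ = ["RunConfig", "TitrationInput", "run_pipeline", "table1_block"]

logger = logging.getLogger(__name__)


class TitrationInput(BaseModel):
    emission_csv: str
    absorbance_csv: str | None = None
    temperature: float = Field(gt=0)


class RunConfig(BaseModel):
    """Inputs and parameters for one full pipeline run.

    Paths are CSVs in the package's fixed dialect; analyses whose inputs are
    absent are skipped, not failed.
    """

    titrations: list[TitrationInput] = []
    protein_conc: float = Field(3e-6, gt=0)  # mol/L
    tau0: float = Field(1e-8, gt=0)  # s
    excitation_wavelength: float = 280.0  # nm
    read_wavelength: float | None = None  # None = per-spectrum maximum
    # thermo-only shortcut: association constants given directly
    K_a: list[float] | None = None
    temperatures: list[float] | None = None
    # CD
    cd_csv: str | None = None
    cd_conc_mg_ml: float = 0.1995
    cd_path_cm: float = 0.1
    cd_mrw: float = 110.0
    # synchronous
    synchronous_csv: dict[str, str] = {}  # delta-lambda label -> path
    # EEM / DPV
    eem_csv: str | None = None
    rayleigh_halfwidth: float = 15.0
    dpv_csv: str | None = None
    dpv_window: tuple[float, float] | None = None
    # site markers
    marker_csvs: dict[str, str] = {}  # marker name -> emission CSV
    marker_wavelength: float = 347.0
    output_dir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        return cls.model_validate(yaml.safe_load(text))


def _load_titration(entry: TitrationInput, cfg: RunConfig) -> TitrationSeries:
    emission = io.read_spectrum_table(entry.emission_csv, kind="emission")
    ladder = np.array([io.conc_label_to_molar(s.label) for s in emission])
    absorb = (
        io.read_spectrum_table(entry.absorbance_csv, kind="absorbance")
        if entry.absorbance_csv
        else None
    )
    return TitrationSeries(
        temperature=entry.temperature,
        protein_conc=cfg.protein_conc,
        ligand_concs=ladder,
        emission_spectra=emission,
        excitation_wavelength=cfg.excitation_wavelength,
        absorbance_spectra=absorb,
    )


def table1_block(
    sv_fits: list[quenching.QuenchingFit],
    bind_fits: list[quenching.BindingFit],
    result: thermo.ThermoResult,
) -> list[dict]:
    """Per-temperature summary rows: T, K_SV, k_q, K_a, dS, dH, dG (kJ/mol)."""
    by_T = {f.temperature: f for f in sv_fits}
    bind_by_T = {f.temperature: f for f in bind_fits}
    rows = []
    for i, (T, dG) in enumerate(result.dG_by_T):
        sv = by_T.get(T)
        bf = bind_by_T.get(T)
        rows.append(
            {
                "T_K": T,
                "K_SV_per_M": sv.K_SV if sv else None,
                "k_q_per_M_s": sv.k_q if sv else None,
                "K_a_per_M": bf.K_a if bf else None,
                "dS_J_per_mol_K": result.dS if i == 0 else None,
                "dH_kJ_per_mol": result.dH / 1000.0 if i == 0 else None,
                "dG_kJ_per_mol": dG / 1000.0,
            }
        )
    return rows


def _run_stage(report: dict, name: str, fn) -> Any:
    try:
        out = fn()
        report["stages"][name] = "ok"
        return out
    except Exception as exc:  # stage isolation: keep going
        logger.error("stage %s failed: %s", name, exc)
        report["stages"][name] = f"failed: {exc}"
        report["failed"] = True
        return None


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage the config provides inputs for; return the report.

    The report is a plain JSON-serializable dict; ``report['failed']`` is
    True if any attempted stage raised.
    """
    report: dict[str, Any] = {"stages": {}, "failed": False}

    sv_fits: list[quenching.QuenchingFit] = []
    bind_fits: list[quenching.BindingFit] = []
    if config.titrations:

        def _titrations():
            out = []
            for entry in config.titrations:
                series = _load_titration(entry, config)
                series = corrections.correct_titration(series)
                sv, dl = quenching.analyze_titration(
                    series, tau0=config.tau0, wavelength=config.read_wavelength
                )
                F = series.intensities_at(config.read_wavelength)
                out.append(
                    {
                        "temperature_K": entry.temperature,
                        "K_SV_per_M": sv.K_SV,
                        "k_q_per_M_s": sv.k_q,
                        "sv_intercept": sv.intercept,
                        "sv_r": sv.r,
                        "K_a_per_M": dl.K_a,
                        "n": dl.n,
                        "bind_r": dl.r,
                        "max_percent_quench": quenching.percent_quench(F[0], F[-1]),
                    }
                )
                sv_fits.append(sv)
                bind_fits.append(dl)
            return out

        report["titrations"] = _run_stage(report, "titrations", _titrations)
        if len(sv_fits) >= 2:
            mech = _run_stage(report, "mechanism", lambda: quenching.classify_mechanism(sv_fits))
            if mech is not None:
                report["mechanism"] = {
                    "verdict": mech.verdict,
                    "K_SV_by_T": mech.K_SV_by_T,
                    "evidence": mech.evidence,
                }

    # thermodynamics: from fitted K_a or directly supplied constants
    K_for_thermo: list[float] | None = None
    T_for_thermo: list[float] | None = None
    if config.K_a and config.temperatures:
        K_for_thermo, T_for_thermo = list(config.K_a), list(config.temperatures)
    elif len(bind_fits) >= 2:
        K_for_thermo = [f.K_a for f in bind_fits]
        T_for_thermo = [f.temperature for f in bind_fits]
    if K_for_thermo is not None:
        def _thermo():
            res = thermo.vant_hoff_fit(K_for_thermo, T_for_thermo)
            return {
                "dH_J_per_mol": res.dH,
                "dS_J_per_mol_K": res.dS,
                "dG_by_T_J_per_mol": res.dG_by_T,
                "r": res.r,
                "force_class": res.force_class,
                "spontaneous": res.spontaneous,
                "consistency_J": res.consistency_J,
                "table1": table1_block(sv_fits, bind_fits, res),
            }

        report["thermodynamics"] = _run_stage(report, "thermodynamics", _thermo)

    if config.cd_csv:
        def _cd():
            spectra = io.read_spectrum_table(config.cd_csv, kind="emission")
            out = []
            for s in spectra:
                rec = structure.cd_analysis(
                    s, config.cd_conc_mg_ml, config.cd_path_cm, config.cd_mrw
                )
                out.append(
                    {
                        "label": s.label,
                        "mre_208": rec.mre_208,
                        "helix_pct": rec.helix_pct,
                        "helix_pct_raw": rec.helix_pct_raw,
                    }
                )
            return out

        report["cd"] = _run_stage(report, "cd", _cd)

    for delta, path in config.synchronous_csv.items():
        def _sync(path=path):
            spectra = io.read_spectrum_table(path, kind="synchronous")
            return structure.shift_and_quench_table(spectra)

        report.setdefault("synchronous", {})[delta] = _run_stage(
            report, f"synchronous_{delta}", _sync
        )

    if config.eem_csv:
        def _eem():
            eem = io.read_eem(config.eem_csv)
            peaks = structure.eem_peak_table(eem, config.rayleigh_halfwidth)
            return [
                {"ex_nm": p.excitation, "em_nm": p.emission, "intensity": p.intensity}
                for p in peaks
            ]

        report["eem_peaks"] = _run_stage(report, "eem", _eem)

    if config.dpv_csv:
        def _dpv():
            vg = io.read_spectrum_table(config.dpv_csv, kind="voltammogram")
            return structure.dpv_series_metrics(vg, window=config.dpv_window)

        report["dpv"] = _run_stage(report, "dpv", _dpv)

    if config.marker_csvs and config.titrations:
        def _markers():
            plain = corrections.correct_titration(
                _load_titration(config.titrations[0], config)
            )
            names = list(config.marker_csvs)
            if len(names) != 2:
                raise ValueError("site-marker comparison needs exactly 2 marker series")
            series = [
                _load_titration(
                    TitrationInput(
                        emission_csv=config.marker_csvs[n],
                        temperature=config.titrations[0].temperature,
                    ),
                    config,
                )
                for n in names
            ]
            rep = quenching.site_marker_comparison(
                plain, series[0], series[1],
                marker_a=names[0], marker_b=names[1],
                wavelength=config.marker_wavelength,
            )
            return {
                "divergence": rep.divergence,
                "assigned_site": rep.assigned_site,
                "wavelength_nm": rep.wavelength,
            }

        report["site_markers"] = _run_stage(report, "site_markers", _markers)

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_results(report, outdir / "report.json")
        _write_markdown(report, outdir / "report.md")
    return report


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# quenchlab report", ""]
    th = report.get("thermodynamics")
    if th:
        lines += [
            "## Binding characteristics",
            "",
            "| T (K) | K_SV (M^-1) | k_q (M^-1 s^-1) | K_a (M^-1) | dS (J/mol/K) | dH (kJ/mol) | dG (kJ/mol) |",
            "|---|---|---|---|---|---|---|",
        ]
        for row in th["table1"]:
            def fmt(v, spec="{:.4g}"):
                return spec.format(v) if isinstance(v, (int, float)) and v is not None else ""
            lines.append(
                "| " + " | ".join(
                    fmt(row[k]) for k in (
                        "T_K", "K_SV_per_M", "k_q_per_M_s", "K_a_per_M",
                        "dS_J_per_mol_K", "dH_kJ_per_mol", "dG_kJ_per_mol",
                    )
                ) + " |"
            )
        lines += ["", f"Dominant force: **{th['force_class']}**", ""]
    if report.get("mechanism"):
        lines += [f"Quenching mechanism: **{report['mechanism']['verdict']}** "
                  f"({report['mechanism']['evidence']})", ""]
    if report.get("eem_peaks"):
        lines += ["## EEM fluorophore peaks", "",
                  "| ex (nm) | em (nm) | intensity |", "|---|---|---|"]
        for p in report["eem_peaks"]:
            lines.append(f"| {p['ex_nm']:g} | {p['em_nm']:g} | {p['intensity']:.4g} |")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
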