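import numpy as np
import pytest

from quenchlab import Spectrum, TitrationSeries

# Table-style worked example used across thermo tests: association constants
# (M^-1) at three temperatures (K)
KA_BY_T = {287.0: 1.25e4, 298.0: 2.76e4, 307.0: 5.24e4}


@pytest.fixture
def ka_values():
    return list(KA_BY_T.values())


@pytest.fixture
def temperatures():
    return list(KA_BY_T.keys())


def make_titration(
    K_SV=1e4,
    ladder_uM=(0, 10, 20, 30, 40, 50, 60, 70, 80),
    F0=1000.0,
    temperature=298.0,
    protein_conc=3e-6,
    center=347.0,
    sigma=28.0,
):
    """Noise-free dynamic-quenching titration built directly from the
    Stern-Volmer law (independent of the simulate module)."""
    grid = np.arange(300.0, 450.0, 1.0)
    band = np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    ladder = np.asarray(ladder_uM, dtype=float) * 1e-6
    spectra = [
        Spectrum(grid.copy(), (F0 / (1 + K_SV * q)) * band, label=f"{u:g}")
        for q, u in zip(ladder, ladder_uM)
    ]
    return TitrationSeries(
        temperature=temperature,
        protein_conc=protein_conc,
        ligand_concs=ladder,
        emission_spectra=spectra,
    )


@pytest.fixture
def dynamic_titration():
    return make_titration()
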