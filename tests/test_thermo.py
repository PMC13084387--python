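"""Van't Hoff regression, Gibbs energies and force classification."""

import numpy as np
import pytest

from quenchlab import (
    R_GAS,
    ValidationError,
    classify_forces,
    gibbs,
    vant_hoff_fit,
)
from quenchlab.quenching import FitError
from quenchlab.simulate import simulate_vant_hoff


class TestVantHoff:
    def test_worked_example_enthalpy_entropy(self, ka_values, temperatures):
        res = vant_hoff_fit(ka_values, temperatures)
        # the printed K_a are 3-sig-fig roundings; recomputation lands near
        # +52.4 kJ/mol and +261 J/mol/K
        assert res.dH == pytest.approx(52630.0, rel=0.02)
        assert res.dS == pytest.approx(261.73, rel=0.02)
        assert abs(res.r) > 0.999  # slope is negative, so r is too
        assert res.force_class == "hydrophobic"
        assert res.spontaneous

    def test_flat_constants_give_zero_enthalpy(self):
        res = vant_hoff_fit([5e4, 5e4, 5e4], [287.0, 298.0, 307.0])
        assert res.dH == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_generation_recovered_exactly(self):
        temps = [280.0, 290.0, 300.0, 310.0, 320.0]
        K = np.exp(-50000.0 / (R_GAS * np.array(temps)) + 250.0 / R_GAS)
        res = vant_hoff_fit(K, temps)
        assert res.dH == pytest.approx(50000.0, rel=1e-9)
        assert res.dS == pytest.approx(250.0, rel=1e-9)

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ValidationError):
            vant_hoff_fit([1e4, -1.0], [287.0, 298.0])

    def test_single_temperature_rejected(self):
        with pytest.raises(FitError):
            vant_hoff_fit([1e4, 2e4], [298.0, 298.0])

    def test_gibbs_identity_holds_exactly(self, ka_values, temperatures):
        res = vant_hoff_fit(ka_values, temperatures)
        for T, dG in res.dG_by_T:
            assert dG == res.dH - T * res.dS  # exact identity, not approx

    def test_consistency_with_direct_rt_lnk(self, ka_values, temperatures):
        # -RT ln K agrees with dH - T dS within the regression residual
        res = vant_hoff_fit(ka_values, temperatures)
        assert all(c < 200.0 for c in res.consistency_J)  # J/mol


class TestGibbs:
    @pytest.mark.parametrize(
        "T,expected_kJ", [(287.0, -22.49), (298.0, -25.38), (307.0, -27.73)]
    )
    def test_worked_example_gibbs_chain(self, T, expected_kJ):
        dG = gibbs(52630.0, 261.73, T)
        assert dG / 1000.0 == pytest.approx(expected_kJ, rel=0.005)

    def test_zero_entropy_reduces_to_enthalpy(self):
        assert gibbs(12345.0, 0.0, 298.0) == 12345.0

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValidationError):
            gibbs(1000.0, 10.0, 0.0)


class TestForceClassification:
    @pytest.mark.parametrize(
        "dH,dS,expected",
        [
            (52630.0, 261.73, "hydrophobic"),
            (-10000.0, -50.0, "vdW_hbond"),
            (-10000.0, 50.0, "electrostatic"),
            (1000.0, 50.0, "electrostatic"),  # |dH| within the near-zero band
            (10000.0, -50.0, "indeterminate"),
        ],
    )
    def test_sign_rules(self, dH, dS, expected):
        assert classify_forces(dH, dS) == expected

    def test_near_zero_band_is_configurable(self):
        assert classify_forces(1000.0, 50.0, near_zero_tol=0.0) == "hydrophobic"


def test_simulate_vant_hoff_matches_worked_example_constants(ka_values, temperatures):
    K = simulate_vant_hoff(52630.0, 261.73, temperatures)
    np.testing.assert_allclose(K, ka_values, rtol=0.02)


def test_generator_fit_inverse_pair():
    temps = [287.0, 298.0, 307.0]
    K = simulate_vant_hoff(52630.0, 261.73, temps)
    res = vant_hoff_fit(K, temps)
    assert res.dH == pytest.approx(52630.0, rel=1e-9)
    assert res.dS == pytest.approx(261.73, rel=1e-9)
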