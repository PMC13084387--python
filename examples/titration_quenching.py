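"""Stern-Volmer and double-log binding analysis of a simulated quenching
titration.

A 3 uM protein is titrated with ligand from 0 to 80 uM; the ratio F0/F of
unquenched to quenched fluorescence grows linearly with ligand concentration
(slope = K_SV), and the double-log plot with free-ligand depletion
correction gives the association constant K_a and site number n.
"""

from quenchlab import analyze_titration, classify_mechanism, percent_quench
from quenchlab.simulate import SimConfig, simulate_titration

# one titration per temperature, K_SV rising with T (collisional quenching)
ksv_by_T = {287.0: 1.25e4, 298.0: 3.62e4, 307.0: 7.73e4}

fits = []
for T, ksv in ksv_by_T.items():
    series, truth = simulate_titration(
        SimConfig(seed=int(T), mechanism="dynamic", true_K_SV=ksv, temperature=T)
    )
    sv, dl = analyze_titration(series)
    fits.append(sv)
    F = series.intensities_at()
    print(
        f"T = {T:.0f} K:  K_SV = {sv.K_SV:.3e} M^-1  (true {truth['true_K_SV']:.3e}), "
        f"k_q = {sv.k_q:.3e} M^-1 s^-1, r = {sv.r:.4f}, "
        f"max quench = {percent_quench(F[0], F[-1]):.1f}%"
    )

call = classify_mechanism(fits)
print(f"mechanism: {call.verdict} — {call.evidence}")
# K_SV rising with temperature is the signature of dynamic (collisional)
# quenching: warmer solutions diffuse faster and collide more often.
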