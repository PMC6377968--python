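"""Blood-gas primitives: alveolar gas equation, dissociation curve, ARF typing.

Builds one admission blood gas at the synthetic cohort's central values and
walks it through the physiology layer.
"""

import oxyloop as ox

# Admission means of the emulated cohort, measured on room air (FiO2 0.21)
pao2, paco2 = 52.73, 48.48

aado2 = ox.aa_gradient(0.21, paco2, pao2)
spo2 = ox.spo2_from_pao2(pao2)
gas = ox.BloodGas(pao2=pao2, paco2=paco2, ph=ox.ph_from_paco2(paco2, 27.0),
                  spo2=spo2, fio2=0.21)

print(f"admission gas: PaO2 {pao2} mmHg, PaCO2 {paco2} mmHg, SpO2 {spo2:.1f}%")
print(f"A-a gradient on room air: {aado2:.2f} mmHg")
print(f"ARF phenotype: {ox.classify_arf(gas).value}")
# A-a gradient ~36 mmHg means gas exchange is impaired (normal is < ~15 for
# the elderly); PaCO2 > 45 puts this patient in the hypercapnic group, so the
# device will target the conservative 88-92% SpO2 band.

print()
print("dissociation curve (Severinghaus closed form):")
for p in (30, 40, 55, 70, 100):
    print(f"  PaO2 {p:>3} mmHg -> SpO2 {ox.spo2_from_pao2(p):6.2f}%")
print(f"  P50 (half saturation): {ox.pao2_from_spo2(50.0):.1f} mmHg")
# The steep 40-70 mmHg segment is where titration happens: a few mmHg of
# PaO2 move SpO2 by whole percentage points.

print()
print("nasal-cannula FiO2 model:")
for f in (0, 2, 5, 15, 30):
    print(f"  {f:>2} L/min -> FiO2 {ox.fio2_from_flow(f):.2f}")
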