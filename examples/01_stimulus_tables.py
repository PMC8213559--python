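"""Stimulus specifications: the two shipped tables and the saturation formula.

The luminance set spans 1-100 cd/m^2 around a 10 cd/m^2 reference; the red
set spans nominal saturations 15%-85% around a 50% reference.  Saturation is
derived from CIE LCh chroma and lightness.
"""

import magest

lum = magest.luminance_stimulus_table()
print(f"luminance stimuli ({len(lum.stimuli)} total, reference id {lum.reference_id}):")
for sid, y in lum.stimuli:
    mark = " <- reference (modulus rating 10)" if sid == lum.reference_id else ""
    print(f"  stimulus {sid}: {y:6.1f} cd/m^2, model scale x = {lum.normalized()[sid]:.3f}{mark}")
print(f"  {lum.n_below} darker and {lum.n_above} brighter than the reference\n")

red = magest.red_stimulus_table()
print("red stimuli (nominal fraction, measured saturation S):")
for (sid, frac), rec in zip(red.stimuli, red.colorimetry):
    mark = " <- reference" if sid == red.reference_id else ""
    print(f"  {rec.name}: nominal {frac:.2f}, S = {rec.S:5.2f}, L* = {rec.L_star:.2f}{mark}")

s = magest.saturation_from_chroma(50.0, 50.0)
print(f"\nsaturation at equal chroma and lightness: {s:.2f}%")
print("(chroma and lightness contribute equally, so S = 100/sqrt(2))")
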