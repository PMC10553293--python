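"""Why monopolar encodings report a lower liver ADC than compensated ones.

A two-compartment liver (parenchyma + ballistically flowing blood) is
imaged with each encoding at b = 50 and 800 s/mm^2.  The blood phase in a
randomly oriented vessel depends on M1, so monopolar encodings dephase
the blood pool away while velocity-compensated ones retain it — shifting
the two-point ADC from ~D_liver toward f*D_blood + (1-f)*D_liver.
"""

import diffenc as de
from diffenc.signal import LiverModel

model = LiverModel(f=0.3, d_blood=1.6, d_liver=0.95, v_blood=3.0)
print(f"liver model: f = {model.f}, D_blood = {model.d_blood}, "
      f"D_liver = {model.d_liver} um^2/ms, v_blood = {model.v_blood} mm/s")
print(f"mixed estimate f*D_blood + (1-f)*D_liver = "
      f"{de.mixed_adc_estimate(model):.3f} um^2/ms\n")

print(f"{'scheme':26s} {'S(b=50)':>8s} {'S(b=800)':>9s} {'atten@800':>10s} "
      f"{'ADC um2/ms':>11s}")
for name in ("monopolar", "velocity-compensated", "acceleration-compensated",
             "84%-compensated", "67%-compensated"):
    sig = {}
    for b in (50.0, 800.0):
        m = de.scheme_moments(de.build_all(target_b=b)[name])
        sig[b] = de.liver_signal(b, m.M1, model)
        if b == 800.0:
            att = de.ballistic_attenuation(m.M1, model.v_blood)
    est = de.adc(sig[50.0], sig[800.0])
    print(f"{name:26s} {sig[50.0]:8.4f} {sig[800.0]:9.4f} {att:10.4f} {est:11.4f}")

print(
    "\nThe monopolar ADC sits near D_liver because its M1 suppresses the "
    "blood signal\nat both b-values; compensated encodings keep the faster-"
    "diffusing blood pool\nand report a higher apparent ADC."
)
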