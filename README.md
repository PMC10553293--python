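# diffenc

Design and analysis of concomitant-field-balanced spin-echo diffusion
encodings with continuously tunable velocity (M1) and acceleration (M2)
weighting — the waveform family used for motion-robust liver
diffusion-weighted MRI at a fixed echo time.

## The problem

Liver DWI near the heart suffers signal dropout: bulk cardiac pulsation
dephases spins within a voxel. The fix is gradient moment nulling — with
the effective gradient G(t) (the played waveform with its pre-180° part
sign-flipped), the moments

    M1 = γ ∫ G(t)·t dt      (velocity sensitivity, s/mm)
    M2 = γ ∫ G(t)·t² dt     (acceleration sensitivity, s²/mm)

control the phase φ = M0·x0 + M1·v + ½·M2·a of moving spins
(γ = 2.678×10⁸ rad/s/T). Nulling M1 (and M2) removes dropout, but also
un-suppresses flowing blood, so vessels turn bright and can mimic
lesions. `diffenc` builds a one-parameter family of symmetric (hence
concomitant-field-balanced) trapezoid waveforms that interpolates between
the two extremes:

* **monopolar** — one lobe per side (M1 = M1max, M2 = M2max);
* **velocity-compensated** — four equal lobes, effective pattern
  (+,−|pause|−,+), M1 = 0 for any pause length;
* **acceleration-compensated** — per side a short lobe *a* and an
  opposite-polarity long lobe *b* (a+b fixed); *a* is root-found so that
  M1 = 0, and the odd symmetry of the effective pattern
  (+a,−b|pause|+b,−a) then forces M2 = 0 too;
* **partially compensated** — shift the timings, a → a + t_S,
  b → b − t_S, at a fixed envelope: both residual fractions |M1|/M1max
  and |M2|/M2max grow together, ≈ 0.348·t_S/ms at the default timings
  (23 ms per side, 10 ms pause, 1.3 ms ramps, 56 ms total).

All moments and b-values (b = ∫q² dt, q = γ∫G dt) are computed in closed
form from the piecewise-linear waveform — no numerical quadrature — and
every scheme is rescaled exactly to its target b-value. A small
motion/IVIM signal module explains the downstream effects: ballistic
blood attenuation |sin(M1·v)/(M1·v)|, a two-compartment liver signal,
two-point ADC estimation, trace-weighted image combination.

## Worked example

```python
import diffenc as de

for name, scheme in de.build_all(target_b=800.0).items():
    m = de.scheme_moments(scheme)
    print(f"{name:26s} |M1| = {abs(m.M1):6.4f} s/mm   |M2| = {abs(m.M2):6.4f} s2/mm")
```

prints

```
monopolar                  |M1| = 5.8162 s/mm   |M2| = 0.3257 s2/mm
velocity-compensated       |M1| = 0.0000 s/mm   |M2| = 0.1689 s2/mm
acceleration-compensated   |M1| = 0.0000 s/mm   |M2| = 0.0000 s2/mm
84%-compensated            |M1| = 0.9276 s/mm   |M2| = 0.0519 s2/mm
67%-compensated            |M1| = 1.9579 s/mm   |M2| = 0.1096 s2/mm
```

i.e. the monopolar scheme at b = 800 s/mm² carries the full velocity
weighting (5.82 s/mm ≈ 5.8 rad of phase per mm/s of motion), the
compensated schemes null it, and the t_S = 0.45/0.95 ms shifts leave 16%
and 34% residuals of both moments. The `examples/` scripts walk through
the scheme family (`build_scheme_family.py`), the t_S tuner
(`tune_compensation.py`) and the IVIM/ADC-bias mechanism
(`liver_adc_bias.py`).

A thin CLI exposes the same functionality:

```
diffenc build            # write sampled CSV + exact JSON waveforms
diffenc report --check   # moment table with rectangular-oracle check
diffenc sweep            # residual fractions vs t_S
diffenc simulate         # liver signal model per scheme
diffenc check FILE       # validate a waveform file (M0 balance, b, slew)
```

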