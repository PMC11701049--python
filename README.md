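# octi — temporal-interference electric fields in the human eye

`octi` is a volume-conductor simulation package for **temporal-interference
(TI) electrical stimulation of the retina**.  TI stimulation delivers kHz
sinusoidal currents through several extraocular electrode pairs at slightly
different frequencies; where the fields overlap, their superposition beats
at the difference frequency, and neurons respond to the low-frequency
envelope rather than the carriers.  The question the package answers is
*where on the retinal surface the envelope concentrates, how focal it is,
and how electrode placement and per-channel current ratios steer it* — in
an eye model that includes the structure most simulation studies omit: the
optic nerve, exiting 22.5° nasal of the posterior pole with strongly
anisotropic conductivity (0.5 S/m along the fibers, 0.08 S/m across).

It is intended for researchers modeling electrical neurostimulation of the
eye (retinal neurodegenerative / vascular disease therapy, optic
neuropathy) who need a reproducible, scriptable alternative to commercial
FEM workflows.

## Model

Each electrode channel's field solves the quasi-static conduction equation
∇·(σ∇φ) = 0 with unit injected current, on a labeled tetrahedral mesh of a
multi-tissue eye (cornea, anterior chamber, lens, vitreous, retina,
choroid, sclera, orbital muscle and fat, optic nerve + CSF + sheath).  The
envelope amplitude along a direction **n** for two superposed channel
fields is

```
e(n) = | |(E1 + E2)·n| − |(E1 − E2)·n| |
```

and the **maximal modulated envelope amplitude (MMEA)** is max over **n**
of e(n) — closed form for two channels, and the standard approximation
2·min(|E₁|,…,|E₄|) for four-channel (3D) montages.  Channel fields are a
superposition basis, so sweeping the current-ratio indexes
αX = I₁/(I₁+I₂), αY = I₃/(I₃+I₄) over a whole grid costs four solves.

Focality and steerability are quantified on the retinal mid-surface:
normalized MMEA maps, profiles through the convergent peak, FWHM and 80%
widths, central-peak offsets (positive = temporal/superior), 80%
iso-intensity contour closure, and overlap with the optic-nerve
cross-section.  See `docs/methods.md` for the full model description.

## Worked example

```python
from octi.geometry import MeshSpec
from octi.steering import TIExperiment, MontageConfig

# 3D montage: stimulating electrodes at 30 deg, returns at 170 deg,
# equal currents (1 mA per channel)
exp = TIExperiment(mesh_spec=MeshSpec.preset("test"))
case = exp.run_case(MontageConfig(30, 170, 30, 170, "3D"))
st = case.stats
for d in ("horizontal", "vertical"):
    print(d, "FWHM", round(st.fwhm[d].width, 2),
          "80% width", round(st.width80[d].width, 2),
          "peak offset", round(st.central_peak_offset[d], 2))
print("contour closed:", st.contour_closed,
      "| nerve overlap:", st.nerve_overlap)
```

prints (test-scale mesh):

```
horizontal FWHM 8.79 80% width 3.39 peak offset 0.25
vertical FWHM 9.47 80% width 4.26 peak offset -1.0
contour closed: True | nerve overlap: none
```

Read: with the return electrodes 10° from the posterior pole, the envelope
converges on the macula — full width at half maximum ≈ 9° of eccentricity
(≈ 1.7 mm of retinal arc), the 80% super-level region spans ≈ 3.5–4.3°,
the peak sits within 1° of the fovea, and the 80% iso-intensity contour is
closed and clear of the optic-nerve cross-section.  On the fine
posterior-pole mesh (`MeshSpec.preset("macular")`) the 80% widths sharpen
to ≈ 2.3° / 2.7°.  Lowering αX steers the peak nasally, raising it steers
temporally:

```python
from octi.steering import CurrentRatios
case = exp.run_case(MontageConfig(30, 170, 30, 170, "3D"),
                    CurrentRatios(alphaX=0.3))
```

A thin CLI wraps the same pipeline: `octi build`, `octi sweep`,
`octi balance`, `octi reproduce table3` (see `octi --help`).

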