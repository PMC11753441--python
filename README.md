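# ovopet

Quantitative accuracy of *in ovo* PET/MRI, end to end on a desk: `ovopet`
generates digital chicken-egg and chick-embryo phantoms together with the
MRI hardware that sits in a preclinical PET field of view, simulates
attenuated Poisson sinograms, reconstructs them with MLEM under four
attenuation-correction (AC) configurations, and quantifies the resulting
biases. It is aimed at preclinical imaging scientists who want to study —
without scanner time — how object self-attenuation, animal bed and MRI coil
attenuation, and the choice of dose normalisation propagate into PET
quantification of fertilised chicken eggs (the HET-CAM / CAM-xenograft
model).

## The problem and the model

A fertilised chicken egg (~5 cm of water-equivalent material) attenuates a
substantial fraction of 511 keV annihilation photons; the cylindrical MRI
coils and the animal bed of a hybrid PET/MRI add more. Along each line of
response (LOR) the survival probability is

    acf(LOR) = exp( − ∫ μ(x) dl ),    μ in cm⁻¹ at 511 keV,

and reconstruction corrects for it by using A′ = diag(acf)·A as the system
model in the MLEM iteration

    x⁽ᵏ⁺¹⁾ = x⁽ᵏ⁾ / (A′ᵀ 1) ⊙ A′ᵀ ( y / A′ x⁽ᵏ⁾ ),

run for exactly 12 iterations (uniform phantom protocol) or 16 (*in ovo*
protocol). Four AC configurations are compared: **NO-AC** (acf ≡ 1),
**AC-1** (egg only, from an air/tissue segmentation of a simulated MR
volume, tissue set to 0.1023 cm⁻¹), **AC-2** (+ bed template, CT-derived
via bilinear HU→μ scaling) and **AC-3** (+ coil template). Tissue uptake is
reported as percent injected dose per cc,

    %ID/cc = 100 · C_tissue / A_injected ,

with `A_injected` taken either from the dose calibrator (dispensed −
residual syringe activity) or from the image itself (total activity in a
30-mm sphere around the egg). The image normalisation is exactly invariant
under any global multiplicative reconstruction bias — which is why it is
robust when hardware attenuation templates are unavailable — while the
calibrator normalisation is biased by any activity that left the egg
unmeasured (e.g. blood dabbed off after injection of a CAM vessel; the
package's bleeding-loss model emulates this).

## Worked example

Uniform saline egg (61.4 kBq/cc) on the animal bed inside the 86-mm
PET-optimised coil, one 5·10⁶-count acquisition, MLEM with 12 iterations
under each AC configuration:

```python
from ovopet import ACMode
from ovopet.quantify import percent_deviation, voi_mean
from ovopet.study import (StudyConfig, phantom_vois, prepare_phantom_setup,
                          reconstruct_acquisition, simulate_acquisition)

cfg = StudyConfig(seed=1)
setup = prepare_phantom_setup("HC-5", cfg)          # egg + bed + 86 mm coil
sino = simulate_acquisition(setup, cfg, seed=42)    # 5e6 true counts
for mode in (ACMode.NO_AC, ACMode.AC1, ACMode.AC2, ACMode.AC3):
    recon = reconstruct_acquisition(setup, sino, mode, cfg, cfg.iterations_phantom)
    cells = []
    for name, voi in phantom_vois().items():
        m = voi_mean(recon, voi, labels=setup.labels)
        cells.append(f"{name} {m:5.1f} kBq/cc ({percent_deviation(m, 61.4):+5.1f} %)")
    print(f"{mode.value:>4}: " + "  ".join(cells))
```

prints

```
none: whole_egg  36.2 kBq/cc (-41.0 %)  center  31.4 kBq/cc (-48.9 %)  shell  36.7 kBq/cc (-40.2 %)
 ac1: whole_egg  51.7 kBq/cc (-15.8 %)  center  55.9 kBq/cc ( -9.0 %)  shell  53.1 kBq/cc (-13.5 %)
 ac2: whole_egg  53.6 kBq/cc (-12.7 %)  center  57.6 kBq/cc ( -6.2 %)  shell  53.8 kBq/cc (-12.4 %)
 ac3: whole_egg  60.6 kBq/cc ( -1.2 %)  center  64.5 kBq/cc ( +5.1 %)  shell  61.0 kBq/cc ( -0.6 %)
```

Reading this: with no AC the egg's self-attenuation plus hardware hides
~41% of the signal, worst in the egg's centre where photon paths are
longest. Correcting the egg alone (AC-1) leaves the ~15% hardware loss;
adding bed and coil templates (AC-3) recovers the activity to about −1%
globally. The slight centre overshoot comes from the deliberate use of the
standard rodent tissue coefficient (0.1023 cm⁻¹) for a water filling
(0.096 cm⁻¹).

The same pipeline is scriptable from the shell:

```sh
ovopet study --experiment phantom --seed 1 --out results/phantom
ovopet study --experiment inovo   --seed 1 --out results/inovo
```

which writes tidy CSV/JSON tables (per hardware configuration × AC × VOI
for the phantom sweep; per egg / per organ %ID/cc under both
normalisations for the *in ovo* emulation), line profiles and
percent-difference NIfTI images.

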