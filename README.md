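# lungdose

Regional nanoparticle-dose mapping, airway-tree morphometry and
segmentation evaluation for 3D light-sheet microscopy of mouse lungs —
with a fully ground-truthed synthetic lung phantom so that every stage is
verifiable without microscope data.

## The problem

Pulmonary drug delivery studies need to know *where* in the lung an
inhaled or instilled dose ends up: how much lines the conducting airways
(bronchial compartment) versus the gas-exchange region (acinar
compartment), and how evenly it spreads.  Light-sheet fluorescence
microscopy (LSFM) of optically cleared lungs produces whole-organ 3D
stacks of nanoparticle (NP) fluorescence and tissue autofluorescence;
combined with a binary airway segmentation, those stacks support a full
regional dosimetry readout.  `lungdose` implements that quantification for
researchers in inhalation toxicology and pulmonary drug delivery:

* **dose fractions** — with bronchial and acinar signals `S_B`, `S_A`
  (above-threshold fluorescence inside the lung, split at the airway
  mask):

  `f_X = S_X / (S_B + S_A)`,  `B/A = S_B / S_A`

* **absolute regional doses** `dose_X = f_X · total` when the total lung
  dose (µg, from external dosimetry) is known;
* **agglomeration state** — apparent NP-positive volume per dose
  (µm³ µg⁻¹), the inverse packing density of the deposited particles;
* **C/P ratio** — central-to-peripheral signal ratio on a
  maximum-intensity projection, central being the inner half of the
  projected lung area; the classical 2D uniformity surrogate;
* **airway morphometry** — centerline extraction from the airway mask
  with per-generation branch counts, lengths, diameters and branching
  angles (Weibel numbering);
* **segmentation scores** — volumetric Dice and centerline Dice (clDice)
  for airway masks;
* **artifact augmentations** — the LSFM-specific transforms (slice
  illumination, dark lung center, local blur/halo, blank rectangles) plus
  the standard set, and the patch-sampling / Gaussian-weighted
  sliding-window machinery of patch-based segmentation inference;
* **synthetic phantoms** — seeded monopodial airway trees in an organ-like
  hull with acinar tessellation, four delivery-route deposition presets
  (INLA, ITLI, VAAD, NOAI) plus an idealized uniform preset, rendered NP
  and autofluorescence channels, and exact event-level ground truth.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate an intratracheal-instillation phantom and profile it:

```python
from lungdose.phantom import generate_phantom, spec_from_preset
from lungdose.profiling import profile_lung

ph = generate_phantom(spec_from_preset("itli", seed=1))
prof = profile_lung(ph.np_stack, ph.airway, ph.lung,
                    threshold=0.0, total_lung_dose_ug=10.0)
print(f"truth bronchial fraction {ph.truth.bronchial_fraction:.3f}")
print(f"recovered fraction       {prof.bronchial_fraction:.3f}")
print(f"B/A ratio                {prof.ba_ratio:.3f}")
print(f"C/P ratio                {prof.cp_ratio:.3f}")
print(f"bronchial dose           {prof.bronchial_dose_ug:.2f} ug")
```

prints

```
truth bronchial fraction 0.190
recovered fraction       0.191
B/A ratio                0.237
C/P ratio                1.886
bronchial dose           1.91 ug
```

The generator placed 19.0% of the deposited events in the airway lumen;
the profiler recovers 19.1% from the rendered image — the 0.001 gap is
optical blur carrying mass across the airway wall.  A B/A of 0.237 and a
C/P of 1.89 are the central-deposition signature typical of bulk-liquid
instillation; an aerosol-route phantom (`"noai"`) profiles near B/A ≈ 0.09
and C/P ≈ 1.3, and the idealized `"uniform"` preset reads C/P ≈ 1.02.

The same pipeline runs from the shell on real data (multi-page TIFFs, one
per channel, plus 0/1 airway and lung masks):

```bash
lungdose phantom --preset itli --seed 1 --out ph/
lungdose profile --np ph/np.tif --airway ph/airway.tif --lung ph/lung.tif \
                 --spacing 12,12,12 --threshold 0 --out profile.json
lungdose evaluate --pred ph/airway.tif --gt ph/airway.tif --out scores.json
lungdose morpho   --airway ph/airway.tif --spacing 12,12,12 --out tree.json
```

Every run writes a `manifest.json` with the resolved configuration, seed
and input digests.

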