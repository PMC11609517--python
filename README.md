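# octaplex

Retinal vascular **plexus segmentation from OCT angiography alone** — no
structural OCT boundaries at inference time — with the full training
pipeline runnable on synthetic phantom volumes.

OCTA volumes resolve three depth-ordered vascular compartments: the
**superficial** plexus (large bright vessels), the **deep** plexus (fine
capillary mesh), and the **avascular** outer retina. Classical pipelines
segment plexuses by projecting the OCTA cube between retinal layer
boundaries found on the co-registered structural OCT — which fails exactly
where disease distorts the layers. This package implements the
OCTA-only alternative:

1. **Weak-label dataset synthesis** — per cube, three en face slab
   projections (max in depth between boundary surfaces), each weakly
   labeled by its slab class; tail-artifact removal; percentile
   normalization (bottom 2% → 0, top 1% → 255, linear in between).
2. **Synthetic two-class blends** — a blurred random ovoid of an adjacent
   class blended into a single-class image, target = mask ≥ 50%; four
   blends per cube (eight with normalized sources).
3. **Patient-level splitting** with eye and disease balance.
4. **A 3-class encoder–decoder segmenter** (1×1 input adapter, U-Net-style
   concatenation or LinkNet-style addition merges, softmax head) trained
   with Adam (max lr 1e-4, batch 32) on per-pixel categorical
   cross-entropy, with flip/rotate-crop augmentation. The network and its
   training loop are pure NumPy — deterministic, dependency-free, sized
   for CPU.
5. **Whole-retina inference** — the volume is decomposed into overlapping
   5-voxel thin slabs spanning ILM→RPE, each slab is segmented, and
   per-voxel probability-mass voting reassembles a labeled **prediction
   cube**, sliceable as class-colored b-scan overlays.
6. **Dice evaluation** in the layout of the reference table: per-class
   Dice on single-class and two-class test images, per-set averages, and
   their combined simple average.

Since the clinical dataset (235 cubes / 33 patients) is proprietary, the
package ships a **phantom generator** producing OCTA-like cubes with known
zone textures, smooth boundary surfaces, projection "tails", and a
patients-own-cubes cohort structure — every stage above is exercised end
to end on phantoms, including the method's central comparative claim:
training with synthetic two-class blends added to the single-class images
improves held-out segmentation over single-class training alone.

## Worked example

```python
from octaplex import (build_study_data, SegmentationModel, TrainConfig,
                      as_training_pairs, evaluate_model)

# 15 phantom patients, 64x64x96 cubes, patient-level 60/20/20 split
data = build_study_data(cohort_seed=42)

config = TrainConfig(input_size=64, epochs=300, architecture="linknet_like",
                     backbone_scale="tiny", base_channels=6,
                     dataset_mix="combined", lr_schedule="one_cycle",
                     augment=False, val_interval=25, seed=0)
model = SegmentationModel(
    as_training_pairs(data.train_single, data.train_twoclass, "combined"),
    as_training_pairs(data.val_single, data.val_twoclass, "combined"),
    config,
    patient_of_cube=data.cohort.patient_of_cube(), split=data.split)
results = model.fit()
print(results.summary())
report = evaluate_model(results, data.test_single, data.test_twoclass)
print(report)
```

This prints (about three minutes on one CPU):

```
Plexus Segmentation Results
==============================================
architecture                linknet_like
backbone scale              tiny
parameters                  10695
dataset mix                 combined
train / val images          91 / 42
epochs                      300
batch size                  32
max learning rate           0.0001
seed                        0
final training loss         0.0436
best validation loss        0.0457 (epoch 299)
training time               168.0 s
==============================================
Dice report [linknet_like / combined]
  classes: superficial  deep  avascular
  single-class tests (n=18):  0.9993  1.0000  1.0000  | avg 0.9998
  two-class tests    (n=24):  0.9607  0.9422  0.9587  | avg 0.9538
  combined simple average: 0.9768
```

The per-class scores are Dice overlaps (1.0 = perfect) between the
predicted and true masks on reserved test images from patients the model
never saw; the combined simple average is the mean of the single-class-set
and two-class-set averages.

The same pipeline is scriptable from the shell:

```sh
octaplex generate-phantoms --n-patients 15 --seed 42 --out-dir cohort/
octaplex build-dataset single-class --cohort-manifest cohort/cohort.json --out-dir sc/
octaplex build-dataset two-class --single-class-manifest sc/single_class_manifest.csv --seed 1 --out-dir tc/
octaplex split --cohort-manifest cohort/cohort.json --targets 9 3 3 --seed 0 --out split.json
octaplex train --cohort-manifest cohort/cohort.json \
  --single-class-manifest sc/single_class_manifest.csv \
  --twoclass-manifest tc/twoclass_manifest.csv --split-manifest split.json \
  --mix combined --epochs 300 --out model
octaplex predict-cube --model model --cube cohort/p001_OD_c0.tif --out pred.tif
octaplex render-bscan --cube pred.tif --volume cohort/p001_OD_c0.tif --row 32 --out bscan.png
octaplex evaluate --model model --cohort-manifest cohort/cohort.json \
  --single-class-manifest sc/single_class_manifest.csv \
  --twoclass-manifest tc/twoclass_manifest.csv --split-manifest split.json --out report
```

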