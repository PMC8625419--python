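# myotype

Cell-type-specific organization analysis of cardiac co-culture micrographs.

Cardiomyocytes and fibroblasts respond differently to cyclic uniaxial
strain: in monoculture, myocytes align roughly parallel and fibroblasts
roughly perpendicular to the stretch axis. Measuring how the two
populations organize *within the same confluent co-culture* requires
per-pixel separation of the actin signal by cell type — and separating a
mature striated myocyte from a merely α-actinin-positive cell requires
recognizing sarcomeric z-line striations, not just stain presence.

`myotype` implements that pipeline for three-channel fluorescence images
(actin, α-actinin, nuclei):

1. **Texture classification** — per-pixel background/foreground labeling of
   the α-actinin channel from four texture features (local entropy, local
   standard deviation, local range, Gaussian-smoothed intensity, σ = 5)
   with a decision tree trained on balanced ~2.5% subsamples of labeled
   images.
2. **Striation classification** — the foreground is split into ~200 SLIC
   superpixels; anisotropic diffusion + white top-hat isolates thin bright
   striations; a superpixel is *Striated Myocyte* when ≥ 10% of its
   foreground lies on striation components roughly perpendicular to the
   local object axis (|dot| < 0.8 between unit axial vectors) and ≥ 5% is
   positive under a global threshold; otherwise *Other*.
3. **Orientation metrics** — per-pixel actin orientation from a
   least-mean-square (structure-tensor) gradient estimator; vectors are
   pooled by cell type (fibroblast = actin present, α-actinin background)
   and summarized by the orientational order parameter and director of the
   mean dyadic tensor T = ⟨r rᵀ⟩:
   OOP = 2λ_max(T) − 1 ∈ [0, 1], director = eigenvector of λ_max, and
   the angle to the stretch axis θ = arccos|p·q| ∈ [0°, 90°].
4. **Log-normal regression** — cardiomyocyte OOP as a function of
   cardiomyocyte actin fraction follows the 4-parameter peak curve
   y = y₀ + a·x·exp(−½ (ln(x/x₀)/b)²), fitted by unconstrained
   Levenberg–Marquardt least squares, with its extremum at x₀·exp(b²).
5. **Nucleus labeling** — externally segmented nucleus instances adopt the
   modal semantic class within their boundary when it covers ≥ 0.4 of the
   nucleus (ties unassigned).

A synthetic tissue generator (`myotype.synthetic_tissue`) renders
co-cultures of striated myocytes, fibroblasts and unstriated
α-actinin-positive cells with exact ground-truth class, orientation and
nucleus maps, so the whole pipeline is testable without microscopy data.

## Worked example

```python
import numpy as np
from myotype import texture_classifier as tc
from myotype.pipeline_cli import analyze_field, RunConfig
from myotype.synthetic_tissue import generate_wellset

# train the background/foreground texture classifier on six labeled scenes
train, _ = generate_wellset(6, 0.5, 5, base_seed=11, other_fraction=0.2)
stacks = [tc.compute_texture_features(s["alpha_actinin"].pixels) for s in train]
labels = [np.where(s["truth_class"].labels == 0, 0, 3) for s in train]
model = tc.train_pixel_classifier(
    tc.subsample_balanced(stacks, labels, fraction=0.025, seed=1), seed=1
)
print(f"training accuracy: {model.training_accuracy:.4f}")

# one co-culture well: myocytes near 25 deg, fibroblasts near 115 deg
scenes, manifest = generate_wellset(
    1, 0.5, 6, base_seed=100, myocyte_angle_deg=25, fibroblast_angle_deg=115
)
cfg = RunConfig(stretch_angle_deg=25.0)
_, rows, _ = analyze_field(
    scenes[0]["alpha_actinin"].pixels, scenes[0]["actin"].pixels, model, cfg
)
print(f"true cardiomyocyte actin fraction: {manifest[0]['true_cm_actin_fraction']:.3f}")
for r in rows:
    print(
        f"{r.cell_type:>14}: oop={r.oop:.3f} director={r.director_deg:6.2f} deg "
        f"angle_to_stretch={r.angle_to_stretch_deg:5.2f} deg "
        f"n={r.n_vectors} fraction={r.actin_fraction:.3f}"
    )
```

Output:

```
training accuracy: 0.9929
true cardiomyocyte actin fraction: 0.170
 cardiomyocyte: oop=0.856 director= 24.42 deg angle_to_stretch= 0.58 deg n=1491 fraction=0.178
    fibroblast: oop=0.923 director=117.10 deg angle_to_stretch=87.90 deg n=6861 fraction=0.817
```

The well was seeded mostly with fibroblasts (true myocyte actin fraction
0.170; measured 0.178). Both populations are recovered with the
orientations they were generated at: the cardiomyocyte director sits 0.58°
from the stretch axis (placed at 25°) and the fibroblast director 87.9°
from it, with high order parameters for both, i.e. two well-aligned but
counter-oriented populations correctly separated by the classifier.

## Command line

```sh
myotype synth    --config scene.yaml --outdir well0/        # synthetic scene + truth
myotype train    --images imgs/ --labels labs/ --fraction 0.025 --seed 1 --model m.json
myotype classify --actinin a.tif --model m.json --out class.tif
myotype organize --actin f.tif --class class.tif --stretch-angle 90 --out metrics.csv
myotype fit      --table metrics.csv --x actin_fraction --y oop --out fit.json
myotype run      --root experiment/ --model m.json          # whole directory tree
```

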