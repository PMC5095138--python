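# fppl — flexible-pattern particle labeling

Detection and counting of small bright particulate objects — calcified
particles, microspheres, stained puncta — in noisy 8-bit grayscale
micrographs such as backscattered-electron SEM images of cardiovascular
tissue. Such particles vary widely in size (a couple of pixels up to tens
of pixels), shape (round to oval) and brightness, and sit in cluttered
extracellular-matrix backgrounds where global thresholding and rigid
template matching both break down. The package provides:

* the **flexible-pattern detector**: a local-contrast discriminant with an
  ignored *gap zone*, scanned over a multi-scale image pyramid;
* the conventional baselines it is compared against: threshold-based
  particle labeling (**BPL**), the same with rolling-ball background
  subtraction (**SBP**) or Sobel edge enhancement (**FEP**) as a
  preprocessor, and multiple template matching (**MTM**);
* a point-matching **evaluator** (detection / false-negative /
  false-positive rates against manual reference dots);
* **synthetic image generators** with exact ground truth, so the whole
  validation suite runs without any external data.

## The discriminant

A square window of side `3 + 2g + 4` pixels is centred on every pixel of
the image. It is partitioned into a 3×3 core *C*, a gap ring *G* of width
*g* whose pixels are ignored, and eight peripheral blocks *P₁…P₈* (2×2
corners, 2×3 / 3×2 edges) in the outermost two-pixel band. The window
contains a particle when

```
C̄ > Th₁   and   C̄ − P̄ᵢ > Th₂  for every i = 1 … 8
```

where C̄ and P̄ᵢ are mean intensities (0–255). Because the gap pixels never
influence the decision, any compact bright object that fills the core but
stays clear of the peripheral band is accepted — regardless of its exact
size or shape within that range. The contrast condition is *local*, so the
same thresholds work on bright and dark background regions alike.

A single pattern still only accepts a band of particle sizes. The detector
therefore scans rescaled copies of the image (default 200%, 100%, 50%):
enlarged copies expose particles below the native detection resolution,
shrunken copies expose particles larger than the pattern. Per-scale hits
are merged into detections (8-connected clusters at their centroid),
mapped back to original coordinates and deduplicated across scales.
Shrinking further than 50% is deliberately avoided: large non-target
clutter collapses to pattern size and turns into false positives.

## Worked example

```python
from fppl import (build_pattern, DiscriminantParams, detect_multiscale,
                  make_sem_like_image, evaluate_detections)

fx = make_sem_like_image(n_particles=40, seed=7)   # textured 360x360 image
pattern = build_pattern(2)                          # 11x11, gap width 2
dets = detect_multiscale(fx.image, (2.0, 1.0, 0.5), pattern,
                         DiscriminantParams())      # th1=70, th2=25
res = evaluate_detections(dets, fx.reference, tolerance=5.0)
print(f"{len(dets)} detections on {fx.image.shape} image")
print(f"matched {res.n_cyan}, missed {res.n_red}, spurious {res.n_green}")
```

prints

```
39 detections on (360, 360) image
matched 39, missed 1, spurious 0
```

i.e. a 97.5 % detection rate with no false positives on this fixture: of
the 40 seeded particles (2–16 px, peaks 90–255 over a textured level-40
background), 39 are matched within the 5-px tolerance and one is missed.

The same pipeline is available from the shell, with every run writing a
config + seed sidecar that reproduces it bit-exactly:

```
fppl synth sem_like --seed 7 --out fix/
fppl detect fix/image.png --method fppl --out dets.csv
fppl evaluate dets.csv fix/reference.csv --image fix/image.png --out-prefix eval
fppl benchmark --n-images 14 --seed 100 --out bench/
```

`fppl benchmark` compares all five detectors over seeded micrograph-like
fixtures and reports mean ± SE rates per method; the pattern detector
leads the ranking (see `docs/methods.md` for the study conditions).

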