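# ecleanse

Electronic cleansing of fecal-tagged CT colonography (CTC) volumes.

In CTC with fecal tagging, residual fluid and stool are opacified with an
oral contrast agent so they read bright (≈ 200–1400 HU) instead of mimicking
soft tissue. Electronic cleansing digitally removes the tagged material and
restores an air-filled lumen so the colon can be read (or flown through)
without cathartic preparation. The hard part is the boundary: partial-volume
voxels, pseudo-enhanced soft tissue next to tagging, thin soft-tissue
structures (haustral folds, polyp surfaces) submerged in tagging, and — the
classical failure mode — thin membranes trapped between air and tagging that
naive cleansing deletes along with the fluid.

`ecleanse` implements a full pipeline:

1. **Torso preprocessing** — outside air, lungs and bones are removed by
   seeded 6-connected region growing so that only colonic structures share
   the working attenuation ranges.
2. **Lumen detection** — air (< −600 HU) and tagged material (> 200 HU)
   masks, dilated by a 3-voxel ball to capture the partial-volume shell.
3. **Ambiguous-layer classification** — layers of intermediate attenuation
   between air and tagging are classified per axial slice by a
   leaping-distance probe into horizontal vs. vertical adjacency with tagged
   pools: flat layers on pool surfaces are artifacts (removed), layers seen
   edge-on against pools are thin membranes (preserved).
4. **Material fractions** — per-voxel air / soft-tissue / tagging fractions
   from orthogonal projection onto an arch-shaped transition curve in the
   (intensity, scaled gradient) plane, for the three material pairs.
5. **Replacement** — a gradient-directional second derivative (GDSD)
   distinguishes pseudo-enhanced soft tissue (rewritten toward its tissue
   value) from genuine tagging (rewritten to air); the freshly exposed
   colonic wall is smoothed with a narrow Gaussian.

See [docs/methods.md](docs/methods.md) for the model, every default
parameter, and known limitations.

## Command-line usage

Generate a synthetic scene, cleanse it, and inspect the QC report:

```bash
ecleanse phantom --out phantom.nii.gz --scene at_layer --seed 7
ecleanse run --input phantom.nii.gz --output cleansed.nii.gz --qc-report qc.json
ecleanse qc phantom.nii.gz            # print the QC report without writing a volume
ecleanse qc phantom.nii.gz --show-config
```

On the `at_layer` scene above this prints, among other counts:

```
rewritten voxels: 22091 removal, 4185 pseudo-enhancement
counts: lumen 64575, air 20755, ftm 21696, at 1483, att 0
thetas: TA 0.878, TT 0.629, SA 0.706
```

`ecleanse run` accepts NIfTI files or DICOM series directories
(`--format dicom_dir`); output is NIfTI. `--config` takes a YAML file of
`CleanseConfig` fields (unknown keys are rejected), `--qc-report` writes a
JSON run manifest (config hash, software version, timings, warnings) plus
the per-stage report. `ecleanse phantom --scene composite` renders the
128³ scene holding every challenge at once; `--truth-out` additionally
writes the ground-truth material label map.

## Python API

```python
from ecleanse import composite_scene, run_ec

vol, truth, spec = composite_scene(seed=1)
out, report = run_ec(vol)
print(report.counts["rewritten_removal"], report.thetas)
```

## Tests

```bash
python -m pytest -q            # unit + property + acceptance tests
```

`tests/test_acceptance.py` holds the end-to-end scientific checks. Two of
them currently fail by design rather than by accident — the submerged
fold-surface preservation rate (≈ 90% measured vs. the 95% target) and the
idempotence of a second cleansing pass (≈ 1.3% of lumen voxels change vs.
the 0.1% target). Both trace to documented properties of the replacement
rules, not to bugs; see the "Limitations" section of
[docs/methods.md](docs/methods.md).

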