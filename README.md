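# ctbrain

Automated extraction of the brain-tissue region from whole-brain
unenhanced head CT, with segmentation-agreement metrics, CT-number
histogram features, and a synthetic head phantom for end-to-end
validation without patient data.

The extractor runs seven steps per axial slice (inferior→superior):

1. **Skin segmentation** — binarise at ≥ −200 HU; the rim removed by
   seven 3×3 erosions is the skin.
2. **Skin elimination** — skin pixels are overwritten with −1000 HU.
3. **Skull segmentation** — binarise at > 84 HU, then five 3×3
   dilations to close the orbital openings.
4. **Ventricle candidates** — binarise at < 22 HU.
5. **Distance map** — per pixel, the summed ray distance to the skull
   along the eight compass directions (0 where any ray exits the image).
6. **Foramen-magnum detection** — slide a 20-px-diameter circular
   template over the pixels whose distance map lies in [100, 250]; the
   most inferior slice where a placement covers > 100 such pixels
   bounds the analysis range.
7. **Extraction** — at/above that slice, pixels with a positive
   distance map that are neither skull, skin, nor ventricle candidates
   form the brain mask.

Agreement between two masks is reported as the similarity (Dice)
index `2|A∩M|/(|A|+|M|)` with false-positive/-negative rates as a
percent of the reference count. Histogram features are the mean CT
number over 22–84 HU and excess kurtosis/skewness over 22–50 HU.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` runs the full-scale (512×512×40) phantom
suite and takes a few minutes; everything else finishes in seconds.

## CLI

```sh
# generate a synthetic head phantom + ground-truth masks
ctbrain phantom --seed 1 --output phantom/

# run the extraction (DICOM directory or NIfTI volume)
ctbrain extract --input phantom/volume.nii.gz --output out/ [--save-intermediates]

# compare two masks
ctbrain evaluate --auto out/brain_mask.nii.gz --ref phantom/truth_brain.nii.gz

# masked HU histogram (optional second mask overlays a dashed curve)
ctbrain histogram --volume phantom/volume.nii.gz --mask out/brain_mask.nii.gz \
    --mask2 phantom/truth_brain.nii.gz --plot hist.png
```

`extract --config FILE` accepts a JSON/YAML file mirroring the
extraction parameters field-for-field; CLI flags override it. A
`--small` flag on `extract`/`phantom` switches to a 128×128 profile
with rescaled geometry and parameters for quick experiments (not the
reference scale).

## Layout

- `src/ctbrain/io.py` — CT volume / mask I/O (DICOM series, NIfTI, PNG)
- `src/ctbrain/extraction.py` — the seven-step pipeline and its pieces
- `src/ctbrain/metrics.py` — overlap metrics
- `src/ctbrain/histogram.py` — masked HU histogram features
- `src/ctbrain/phantom.py` — synthetic head phantom + suite generator
- `src/ctbrain/cli.py` — `ctbrain` command-line entry point
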