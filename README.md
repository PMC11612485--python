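# mitoquant

Quantitation of tandem **mCherry-GFP** mitophagy / autophagy reporter imaging
(mito-QC and auto-QC style reporters), with a calibrated synthetic-scene
simulator so every stage of the pipeline is testable without acquired data.

## The problem

Tandem-tag reporters place mCherry and GFP on the outer mitochondrial
membrane (mito-QC) or on LC3 (auto-QC). Outside lysosomes both fluorophores
emit, so mitochondria and autophagosomes appear "yellow". When cargo is
delivered to an acidified lysosome the low pH quenches GFP but not mCherry,
so mitolysosomes and autolysosomes appear as **mCherry-only ("red-not-green")
puncta**. Autophagic activity is then quantified as a ratiometric index:

```
density = N(red-only puncta) / ROI area            [puncta / µm²]
```

Structures that have fused with lysosomes but are insufficiently acidic to
quench GFP remain double-positive; with a LAMP1 marker channel these
**differentially acidified lysosomes (DALs)** are counted as
mCherry⁺GFP⁺LAMP1⁺ triple-positive objects.

`mitoquant` implements the full measurement chain:

1. **Detection** — per-channel smoothing, exact Otsu thresholding inside the
   ROI, pixelwise subtraction of the GFP mask from the mCherry mask
   (`mCherry AND NOT GFP`), connected-component segmentation with size gates,
   fragment bridging and watershed declumping, and per-ROI densities.
2. **Classification** — object-level colocalization (overlap fractions
   against GFP / marker masks) into red-only, double-positive and
   triple-positive classes; DALs are counted from *unsubtracted* mCherry
   objects so the pixel subtraction cannot erase them.
3. **Morphometry** — area, equivalent diameter, eccentricity and form factor
   (4πA/P²) per punctum.
4. **ROI handling** — import of external label masks (16-bit TIFF), hole
   filling, and an intensity-based fallback segmentation.
5. **Flux assay** — the in vitro high-content chain: nuclei → cytoplasm
   partition → per-channel LoG spot detection → red-not-green masking →
   per-cell counts normalized to the control-condition mean (bafilomycin A1
   abolishes red-only spots; deferiprone / AZD8055 induce them).
6. **Cohort statistics** — per-image → per-subject aggregation, one-way
   ANOVA with Bonferroni post hoc correction, unpaired two-tailed Student
   t tests, fold changes, percent-of-youngest standardization, box-plot
   summaries.
7. **Simulation** — seeded synthetic reporter scenes (dual-channel
   mitochondrial network, red-only and double-positive puncta as Poisson
   point processes, PSF blur, Poisson shot + Gaussian read noise) with exact
   ground truth, plus cohort presets calibrated to published group-mean
   densities and fold changes.

## Worked example

Simulate the A9 dopaminergic cohort (young vs geriatric), detect puncta in
every field, aggregate to subjects and test the age effect:

```python
import mitoquant as mq

per_image = mq.run_cohort("a9_mito", n_subjects_per_group=10,
                          images_per_subject=5, base_seed=1)
subjects = mq.aggregate_subjects(
    per_image[["group", "subject", "red_only_density"]],
    ["red_only_density"])
print(subjects.groupby("group")["red_only_density"].mean())
res = mq.one_way_anova_bonferroni(subjects, "red_only_density")
print(f"F = {res.F:.1f}, p = {res.p:.2e}")
print(mq.fold_change(subjects, "young", "geriatric", "red_only_density"))
```

prints

```
group
geriatric    0.015973
young        0.004814
Name: red_only_density, dtype: float64
F = 837.4, p = 1.51e-16
3.3179347826086967
```

i.e. the pipeline recovers the calibrated group means (0.018 and 0.005
mitolysosomes/µm²) from rendered images and finds the expected strong age
effect. The same chain is available from the shell:

```bash
mitoquant simulate --preset a9_mito --subjects 10 --images 5 --seed 1 --out scenes/
mitoquant detect --in scenes/ --out results/
mitoquant stats --in results/per_image.csv --out stats/
mitoquant flux --conditions vehicle,DFP,DFP+BafA1 --fields 4 --out flux/
```

## Layout

```
src/mitoquant/
  scenes.py    synthetic scenes, cohort presets, flux plates
  detect.py    thresholding, subtraction, segmentation, classification,
               morphometry, densities
  roi.py       label-mask import/export, hole filling, fallback segmentation
  flux.py      nuclei/cytoplasm segmentation, spot counting, normalization
  stats.py     subject aggregation, ANOVA + Bonferroni, t test, summaries
  pipeline.py  end-to-end runs (simulate/detect/stats)
  io.py        TIFF + sidecar + CSV round trips
  config.py    validated YAML run configuration
  cli.py       command-line interface
```

See `docs/methods.md` for the model, parameter choices and limitations.
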