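# octaquant

Quantification of the retinal **superficial capillary plexus (SCP)** from
en-face OCT-angiography images, with a synthetic-data path that makes every
stage testable without patient data.

## The problem

OCT angiography produces 6×6 mm en-face maps of retinal blood flow.
Clinical studies of macular disease — for example eyes with an idiopathic
epiretinal membrane (iERM) before and after vitrectomy — quantify these maps
with a semi-automated ImageJ-style chain and four metrics, computed in a
parafoveal (2.5 mm) and a perifoveal (5.5 mm) annulus around the fovea,
excluding the foveal avascular zone (FAZ):

| metric | definition | units |
|---|---|---|
| PD  | perfusion density: vessel pixels / region pixels | % |
| VLD | vessel length density: skeleton pixels / region pixels | % |
| VDI | vessel diameter index: vessel area / skeleton length × pixel pitch | µm |
| VT  | vessel tortuosity: Σ branch arc length / Σ branch chord length | — |

`octaquant` re-implements that chain as a tested, reproducible library:

1. **Quality control** — scans with signal-strength index (SSI) < 8 excluded.
2. **Dual binarization** — white top-hat background removal, then the union
   of (a) a Hessian tubeness filter thresholded globally with the
   Huang–Wang fuzzy-entropy criterion and (b) a local-median adaptive
   threshold.
3. **Skeleton analysis** — topology-preserving thinning, branch
   decomposition at junction/end nodes (arc length step-summed 1/√2,
   chords between terminal nodes), and the four metrics per region.
4. **Statistics** — Shapiro–Wilk, Mann–Whitney U, Pearson χ², Friedman,
   Wilcoxon signed-rank with Bonferroni correction, Lin's concordance
   correlation coefficient (CCC) with Fisher-z confidence interval, and
   Spearman's ρ, over long-format cohort tables.
5. **Synthetic data** — vessel phantoms with exact pre-noise ground truth
   (fill fraction, centreline fraction, caliber, arc/chord tortuosity) and
   per-eye cohort simulation from published group means ± SD via a Gaussian
   copula across visits.

## Worked example

```python
import octaquant as oq
from octaquant.roi import RegionMask

# a 6x6 mm phantom: 40 radial vessel trees, tortuosity 1.4, OCTA-like speckle
image, truth = oq.generate_phantom(oq.PhantomSpec(seed=1))

mask = oq.binarize_scp(image)                       # dual binarization
skel = oq.skeletonize_mask(mask)                    # 1-px centrelines
branches = oq.analyze_branches(oq.prune_spurs(skel, 12.0))

roi = RegionMask.full(image.grid_px)
print(f"PD  {oq.perfusion_density(mask, roi):.2f} %  "
      f"(true fill {100*truth.true_fill_fraction:.2f} %)")
print(f"VT  {oq.vessel_tortuosity(branches, roi):.3f}   "
      f"(true arc/chord {truth.true_tortuosity:.3f})")
```

prints

```
PD  12.92 %  (true fill 12.15 %)
VT  1.369   (true arc/chord 1.400)
```

i.e. the pipeline recovers the phantom's known perfusion density and its
arc/chord tortuosity within a few percent despite speckle noise.

A full simulated two-cohort study (24 iERM eyes vs 24 controls, drawn from
the published group distributions) with the complete statistical battery:

```python
report = oq.run_study_replica(seed=1)
print(report["between_group"])   # Mann-Whitney per region x metric
print(report["interobserver"])   # Lin's CCC between two simulated graders
```

## Command line

```
octaquant simulate-phantoms --seed 1 --out out/phantoms --count 5
octaquant measure --config pipeline.cfg --out out/metrics scan1.tif scan2.tif
octaquant simulate-cohort --seed 1 --out out/cohort --graders 2
octaquant stats --out out/stats out/cohort/cohort.csv
octaquant replica --seed 1 --out out/replica
```

Configuration is a flat `key = value` file (see `octaquant.PipelineConfig`
for every stage parameter and its default); each command appends a run
manifest (config hash, seed, versions) as JSON lines.

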