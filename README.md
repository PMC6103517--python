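# mtocquant

Quantitative fluorescence-image analysis of apical non-centrosomal
microtubule-organizing center (ncMTOC) assembly in the *C. elegans*
embryonic intestine — with a synthetic-microscopy generator so that every
measurement in the pipeline can be validated by parameter recovery against
known ground truth.

## The scientific problem

At the E16 (bean) stage the intestinal primordium polarizes and microtubule
organization moves from centrosomes to the shared apical surface of the two
cell tiers (the apical midline).  Assessing which proteins build this
ncMTOC requires a set of image-derived quantities:

* **Percent GFP depletion** of a ZF::GFP-tagged protein after
  intestine-specific ZIF-1-mediated degradation, comparing degraded
  ("gut(−)") embryos to their non-degraded gut(+) siblings with
  corrections for out-of-focus haze and gut autofluorescence:

      signal     = mean(G − X) − auto          per cohort
      depletion% = 100 · (1 − signal₋ / signal₊)

  where G is the mean of a 10-μm-wide gut box, X the mean of a 2-μm box
  outside the embryo, and *auto* the gut signal of no-GFP control embryos,
  all on slide-background-subtracted sum projections.
* **Apical enrichment** — mean intensity of a 2-μm apical box over a 2-μm
  cytoplasmic box, plus 1-μm-wide line profiles of intensity vs signed
  distance from the midline (cytoplasmic region 2.5–5 μm, peak region by
  the half-max rule).
* **EB1/EBP-2 comet kinetics** — comets crossing a 5-μm line laid 3 μm
  from the midline on each side within 10 s, and comet speed from the
  slope of streaks in 5-pixel-wide kymographs (speed = |slope| ·
  pixel_size / frame_interval), with per-embryo means requiring ≥ 2
  measured comets.
* **Centrosomal accumulation** (7-pixel-diameter circular ROI at the
  brightest z) and **foci / nucleus counts** by smoothed local maxima.
* **Statistics** — Welch two-sample and paired t-tests, OLS fits, and
  genotype pooling.

Raw micrographs for such experiments are rarely deposited, so the package
ships a generator (`mtocquant.synthetic`) that renders two-channel
primordium z-stacks, sibling depletion cohorts, comet time-lapse movies
(midline or centrosomal point sources, Poisson birth process calibrated to
a target crossing rate, EM-CCD noise, photobleaching) and planted
foci/nucleus images — each with its hidden `GroundTruth`.  Every stage of
the measurement pipeline is then testable by recovering those parameters.

## Worked example

```python
from mtocquant.datatypes import GroundTruth
from mtocquant.experiments import run_speed_recovery

truth = GroundTruth(comet_speed=0.558, comet_emission=5.55)  # control apical
per_embryo, summary = run_speed_recovery(truth, n_embryos=10, seed=101,
                                         min_births=3)
print(summary["mean_of_embryo_means"], summary["se"])
```

prints `0.55751 0.00022`: ten synthetic 10-s movies (0.1-s frames,
0.11 μm pixels) were tracked, one 5-pixel kymograph was laid along each
detected comet, streak slopes were fitted and the ≥ 2-comet per-embryo rule
applied — recovering the 0.558 μm/s ground truth to 0.1%.  The analysis
scripts under `analysis/` run the full set of studies; for example
`python analysis/04_comet_kinetics.py` prints

```
control_apical           truth 0.5580 -> 0.5573 ± 0.0002 (SE), 10 embryos, 248 comets
gip1_gut_minus_apical    truth 0.7210 -> 0.7208 ± 0.0001 (SE), 10 embryos, 222 comets
two_cell_centrosomal     truth 0.8884 -> 0.8882 ± 0.0005 (SE), 10 embryos, 56 comets
e8_centrosomal           truth 0.5630 -> 0.5662 ± 0.0034 (SE), 9 embryos, 42 comets
control vs GIP-1-depleted speed: t=-705.5, p=3.9e-38
```

(the e8 row shows the two-cell exclusion rule dropping an embryo with a
single measured comet), and `python analysis/02_depletion.py` prints

```
ground-truth depletion: 93.1%
recovered:              93.0% (jackknife SE 0.15)
```

Numbered scripts: `01_simulate_examples.py` (write example scenes to
disk), `02_depletion.py`, `03_enrichment_profiles.py`,
`04_comet_kinetics.py`, `05_foci_nuclei.py`.  Tables land under
`results/`, bulky TIFF examples under `scratch/`.

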