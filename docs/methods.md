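# Methods

## The synthetic primordium

A still scene is a 256×256 field at 0.11 μm/pixel (a 100× objective with a
1.5× magnifying lens on an EM-CCD; the pixel size is configuration, never a
constant) containing a straight apical midline of length 14 μm through the
field center.  With *d* the signed perpendicular distance from the midline,
the noiseless marker-channel mean of the in-focus plane is

    slide_bg + haze + [inside gut] · (auto + C · g(d))

with `g(d) = r` for |d| ≤ 1 μm, `g(d) = 1` for |d| ≥ 2.5 μm and linear
between.  The piecewise-plateau profile is chosen so the 2-μm apical and
cytoplasmic box estimator recovers the enrichment ratio *r* exactly on
noiseless images — ground truth and estimator agree by construction, so any
discrepancy under noise is attributable to the measurement.  The gut band
has half-width 5.5 μm (it must exceed 5 μm for the 10-μm gut box to fit; a
narrower primordium raises a geometry error).  Haze — out-of-focus light
from non-degraded protein in neighbouring tissues — is uniform over the
field; this means the slide-background rectangles absorb it together with
the slide background, which leaves the G − X − auto algebra exact
(verified: noiseless percent depletion equals 100·δ to 1e-9).
Autofluorescence is gut-restricted.  A 7-slice z-stack (0.5-μm steps)
scales the embryo component by a Gaussian axial weight (σ_z = 1 μm) so the
central slice is brightest; slide background and haze are z-independent.

Noise is Poisson shot noise at configurable gain plus Gaussian read noise
(defaults gain 1.0, read SD 2.0 — ~10% relative noise at the default
cytoplasmic level of 100 counts).  Setting both to zero disables noise.
Embryo-to-embryo marker expression varies with CV 5% in cohort generators.

Depletion cohorts: gut(−) embryos have their whole gut marker component
(cytoplasmic level and apical peak) scaled by (1 − δ); gut(+) siblings are
unscaled; haze is identical across the sibling cohorts because it
originates outside the intestine; no-GFP controls carry no marker and no
haze but keep the gut autofluorescence, which is exactly what the *auto*
estimate needs.

## Comet movies

Comet movies are 192×192 fields, 0.1-s frames spanning a 10-s window
inclusive of both endpoints (101 frames), so a crossing at the window edge
is observable.  Comets are isotropic Gaussian spots (σ = 0.15 μm,
amplitude 150 over a uniform background) born on each side of the midline
by a homogeneous Poisson process, uniform along the midline, moving
outward at constant speed.  Track directions splay about the outward
normal with SD 6° — microtubule tracks are not perfectly parallel, and
without splay two comets born close together would remain optically
unresolvable forever, which real data do not show.  The per-side birth
rate is calibrated as

    rate = λ · (L / 5 μm) / (window − offset/v)

so the expected number of comets crossing a 5-μm line at 3 μm offset
within the window equals the ground-truth emission λ (the uncalibrated
rate λ·L/(5·window) is used when comets are too slow to reach the line).
The splay perturbs this calibration by ≲ 2%, well inside the sampling
error of any cohort used here.  A point-source mode emits comets radially
from a centrosome at the field center for the 2-cell / E8 centrosomal
comparisons.  Whole-frame intensity decays as exp(−bleach_rate·t) before
noise; comets persist until they leave the field (no catastrophe/rescue
statistics — out of scope).

Emission defaults follow the published per-embryo crossing totals: λ =
5.55 per line (11.1 per embryo) for gip-1(+) genotypes and λ = 3.85 (7.7)
for pooled GIP-1-depleted genotypes.

## Measurement pipeline

**Stills.**  The brightest tubulin plane inside the gut box selects focus;
a 3-slice sum projection (clipped, not padded, at stack boundaries) is the
analysis image; slide background is the unweighted mean of three
rectangles outside the embryo and is subtracted without clipping negative
values (clipping would bias cohort means).  Enrichment is the ratio of
background-subtracted 2-μm box means.  Line profiles bin pixels of a
1-μm-wide band across the midline by signed perpendicular distance (one
bin per pixel; left of the directed midline is negative).  Bins are
classified by bin center, so a bin straddling a plateau edge mixes ramp
pixels — tests that assert plateau values stay one bin clear of the edges.
The cohort peak region is the connected run of bins, containing the
maximum of the cohort mean profile, at or above halfway between the
cytoplasmic mean and the maximum; a flat profile has no peak region rather
than a fabricated one.

**Comets.**  Detection is Gaussian smoothing (σ = 0.15 μm) with local
maxima above a robust median + 5·(1.4826·MAD) threshold; maxima closer
than 0.25 μm merge (this is just above the two-Gaussian fusion limit
2σ ≈ 0.3 μm, so suppression adds little loss beyond optics).  Linking is
greedy nearest-neighbour with step limit 3·v_max·frame_interval
(v_max = 1.5 μm/s) and 1-frame gap tolerance.

Crossing counts follow the trajectory rule: a crossing is a trajectory
whose |d| passes from < 3 μm to ≥ 3 μm while laterally within the 5-μm
line, once per comet per line, within the 10-s window.  A crossing spot
whose local brightness (intensity above the frame median, in units of the
cohort's median single-spot brightness) rounds to ≥ 2 is counted as that
many comets — the counterpart of a human scorer counting a double-bright
unresolved comet as two.  On noiseless movies whose comets are all
resolvable and whose crossings do not graze a counting boundary, the count
equals an independent frame-by-frame simulation of the true positions
exactly; at the densest published operating point (11.1 per embryo) truly
fused pairs still cost ~5–8% — an optical resolution floor, not a counting
defect.

Speeds: one 5-pixel-wide kymograph per detected trajectory, laid along
the trajectory's principal axis (the automated analogue of dragging the
measurement line along a comet's visible path).  The streak belonging to
that comet is read by guided per-row centroids: each trajectory frame
seeds a ±4-column window at the comet's projected path position; the
intensity-weighted centroid gives distance vs time; OLS gives the slope.
Rows are excluded when (a) another comet — interpolated across linking
gaps and extrapolated at constant velocity up to 40 frames beyond its
track, because a merged pair's partner has no track before separation —
comes within 7.7 pixels, (b) the row sits within 1 μm of the birth
structure (midline or centrosome), where newborn comets pile up
unresolved, or (c) the window would be truncated by a path end.  Two
robust passes drop residual outliers > 1.5 px.  Fits need R² ≥ 0.8, a
slope standard error ≤ 0.03 μm/s, and (in the cohort workflows) ≥ 12
clean rows (1.2 s) — shorter reads are dominated by crowding residuals.
Streaks of roughly doubled brightness (unresolved pairs, which report the
pair-mean velocity) are not measured.  Per-embryo means require ≥ 2
measured comets; intestinal embryos falling short are flagged for
reanalysis, two-cell embryos are excluded, matching the published
per-embryo rules.  Bias checks: isolated noiseless comets recover speed
essentially exactly across 0.2–1.2 μm/s; at the densest operating point
the cohort mean is within ~0.1% of truth.

**Counting.**  Foci/nuclei are smoothed local maxima above a robust
threshold computed inside a region mask (the gut band), so the
tissue/slide intensity step is not mistaken for signal; maxima closer than
the minimum separation merge, keeping the brighter.  Nuclei use a wider
preset (smooth 0.4 μm, separation 1.0 μm) and the generator lays them out
in the two tiers of the E16 intestine.

**Statistics.**  Welch t (summary-stat form with Welch–Satterthwaite df),
paired t, OLS with slope-t p-value, and two-pool genotype comparison with
within-pool pairwise checks are thin wrappers over scipy.stats; all tests
are two-tailed and no multiple-testing correction is applied (raw
p-values are reported).  Type-I error of the Welch wrapper is verified at
4,000 null simulations.

## What the generator does and does not emulate

It reproduces the intensity structure the estimators rely on (plateaued
apical profile, uniform haze, gut-restricted autofluorescence, Poisson +
read noise, photobleaching, Poisson comet traffic with splay) but not:
realistic embryo outlines, mitotic spindles, gut-granule spectra, a real
optical PSF (spots are Gaussian), comet-tail asymmetry, z-drift, or motion
of the embryo.  Passing recovery tests therefore demonstrates that the
pipeline is unbiased under this statistical structure, not that it is
robust to every artifact of real microscopy.

## Problem sizes and runtime

Recovery cohorts use 10 embryos (speeds), 15 (enrichment), 12+12+5
(depletion) and 20 movies (crossing counts) at 192–256 px fields and
101-frame movies; the full test suite runs in ~1.5 min and the acceptance
script in ~1 min on one CPU.  Crossing-count cohorts are Poisson-limited:
the sampling SD of a 20-movie mean at 7.7 crossings is ±0.62, which
dominates any pipeline error.

## Determinism

All randomness flows through numpy `SeedSequence` spawning; identical
(scene, truth, seed) give bit-identical images, movies and event logs, and
`run_pipeline` reruns reproduce identical CSV/JSON outputs.
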