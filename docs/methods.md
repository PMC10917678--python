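# Methods

`pupreact` re-implements, as tested and reusable code, the quantitative
procedures used to measure tactile reactivity across development in mouse
models of autism spectrum disorder: point-tracking displacement scoring of
neonatal air-puff responses, habituation classification, tactile
prepulse-inhibition (PPI) metrics, arena behavior indices, and confocal
synaptic puncta-proximity analysis. Because no animal data are deposited
with the original study, every analysis stage is paired with a synthetic
generator that emulates the statistical structure its assay assumes and
retains the ground truth, so that the whole pipeline can be validated by
recovery tests.

## Displacement scoring (point_tracking)

Videos are overhead grayscale recordings at 120 frames/s. Corner-like
features (Shi–Tomasi response maxima) are seeded on the animal's dorsum
and tracked frame to frame with pyramidal Lucas–Kanade optic flow (3
pyramid levels, 15-px windows, 5 Gauss–Newton iterations per level). A
point whose photometric residual exceeds 1.0 (patch mean absolute
difference over patch s.d.) or that reaches the frame border is invalid
from that frame on. The displacement trace is the mean over valid points
of each point's Euclidean distance from its mean position over the
pre-stimulus baseline window; mean-over-points is the default and the
per-point-then-max alternative is deliberately not offered, since the
trace feeds a max-in-window statistic anyway.

Peak scoring uses a half-open window (onset, onset + w]: the stimulus
frame itself reflects pre-response posture. At 120 frames/s a 500-ms
window is exactly 60 frames; non-integer window lengths round down. The
same operation scores membrane-potential traces (peak depolarization in a
10-ms window) — only the sampling rate and units change. Baseline
movement is the maximum displacement over the 10 frames preceding onset.
Fall-over trials are flagged by annotation (the event is observed, not
inferred from pixels) and scored at the 106.383-px cap, the maximal
displacement trackable before the points become occluded.

## Reactivity endpoints (reactivity_scoring)

A session is 5 ramp trials (0.10, 0.25, 0.50, 0.75, 1.0 psi; 50 ms each)
plus ten 1.0-psi repeats. Trials with baseline movement strictly above the
movement threshold (default 2 px) are discarded. Habituation is
classified per animal: H = 1 − mean(last 3 repeats)/mean(first 3 repeats),
habituated iff H > 0.25 strictly, with 0.20/0.30/0.40 re-analyses for
cutoff sensitivity. Block means use the surviving (non-excluded) trials,
at least two per block. The animal-level inclusion rule ("responded to
the first 1.0-psi presentation by more than 20% of baseline") is
grammatically ambiguous in its source; the default reading requires
first-trial peak > 1.2 × that trial's baseline movement, and the literal
reading (peak > 0.2 × baseline) is available via `rule="literal"`.
Optogenetic sessions are the mean of five capped peaks.

## Tactile PPI (startle_ppi)

%PPI = [1 − S/P] × 100 with S the mean prepulse+pulse response at the
reported 250-ms interstimulus interval and P the mean pulse-alone response
from the pseudorandomized mixed block (not the acclimation block). The
air-puff-alone response is A/P − B/P (prepulse-alone and no-stimulation
block means over the pulse-alone mean). Animals whose no-stimulation mean
exceeds 25% of P are flagged excluded; exactly 25% is included. Negative
values (facilitation) are reported, not clipped. Block means are
arithmetic means.

## Arena metrics (arena_metrics)

Open field (40 × 40 cm): center fraction is the share of samples strictly
more than 5 cm from every wall; a sample exactly at 5.0 cm is not center.
Elevated plus maze (four 30 × 5 cm arms): open/(open + closed) arm time,
center-square time excluded; boundary samples belong to the center.
Three-chamber (3 × 20 × 40 cm): both the chamber-dwell preference (used in
the headline sociability panels) and a cup-investigation preference are
computed, since the source describes both. Novel-object recognition:
investigation is presence within a radius of the object center (object
half-width + 2 cm by default — the source does not define investigation
operationally); animals that did not investigate both objects during the
learning phase are excluded. The tracked point is the body centroid.

## Puncta proximity (puncta_proximity)

Analysis is strictly 2-D per optical section (0.45–0.9 µm z-step); blobs
are never merged across planes. Each plane of the terminal channel
(VGLUT1 or VGAT) is thresholded and connected components whose equivalent
diameter (2·sqrt(area/π), in µm) does not strictly exceed the marker
minimum (0.5 µm VGLUT1, 0.1 µm VGAT) are discarded. The receptor channel
(GABRB3, GlyRα1, NLGN2, gephyrin) is smoothed at the PSF scale (matched
filter, 0.08 µm default), thresholded, declumped by watershed at intensity
maxima, and components of equivalent diameter ≥ 0.1 µm are kept. The
per-image proximity value ρ is the fraction of terminal profiles hosting
at least one counted receptor punctum, pooled over planes; per-animal
values average the images (three per animal in the source design).

Numerical choices that matter:

- **Thresholds.** The terminal channel uses pooled Otsu (foreground is a
  few percent of voxels — enough for a two-class split); pass an explicit
  threshold to hold it constant across a slide. The receptor channel is
  sparse (≪1% foreground), where Otsu splits the background noise mode
  and floods the image with single-pixel false puncta; it therefore
  defaults to a robust threshold, median + 5 × 1.4826 MAD of the smoothed
  volume, floored at 5% of the volume maximum so noiseless images do not
  threshold at zero.
- **Containment.** Default is overlap assignment — a punctum belongs to
  the terminal region it overlaps most, as in mask-intersection counting.
  This is robust at terminal borders, where two sub-resolution puncta can
  blur into a single component whose centroid falls just outside the
  terminal even though one of its constituents lies inside. Centroid,
  full-containment and ≥50%-overlap rules are switchable.
- **CLAHE** (per-plane, 64-px tiles, clip limit 0.01) is available as a
  preprocessing step; constant planes are returned unchanged with a
  warning.
- **Comparability QC** is zero-normalized spatial cross-correlation
  (Pearson over voxels) per channel pair: identical or gain-rescaled
  stacks score 1, unrelated content near 0; pairs below a floor (default
  0.5) are flagged. The original check is not described beyond its
  purpose, so this implementation is a stated stand-in.

The proximity value bounds true synaptic colocalization from above:
receptor puncta anywhere within the optical-section thickness are counted
into terminal profiles. The generator reproduces this by optionally
placing background puncta without avoiding terminal footprints
(`background_avoids_terminals=False`), emulating puncta from adjacent
tissue depth collapsing into the section; the recovery benchmark confirms
ρ̂ ≥ planted fraction in that regime.

## Statistics (cohort_stats)

Habituation outcomes are binary, so genotype comparisons of habituating
fractions use a one-sided Fisher's exact test (hypergeometric tail,
conditional on margins; direction states which genotype is hypothesized
to habituate less). Continuous comparisons are routed by Shapiro–Wilk
normality per group and Bartlett equal-variance gates, both at α = 0.05
(the gate level is not stated in the source; 0.05 is the conventional
choice): Student's t if normal with equal variances, Welch's t if normal
with unequal variances, Mann–Whitney U otherwise; one- versus two-tailed
is caller-specified. The tests themselves are executed by scipy.
Mixed-effects models and Welch-ANOVA post hocs are out of scope here; the
package only prepares their long-format input tables. Miniature-PSC event
lists are summarized to frequency and mean amplitude with a sufficiency
flag at 100 events per cell.

## Synthetic data (synthetic_cohort)

The generators define the study conditions for all recovery tests.
Randomness derives from one root seed per spec with child streams keyed by
(seed, generator, genotype, animal/object index), so outputs are
bit-identical for a spec and independent of generation order.

- **Air-puff sessions.** Evoked peak = gain (20 px/psi default) ×
  intensity × genotype multiplier (1.5 default for mutants) × geometric
  habituation decay (10% per trial for animals drawn habituating;
  Bernoulli per animal, defaults 0.8 control / 0.3 mutant — the group
  structure of the neonatal cohort comparison, at n = 16 vs 10) ×
  multiplicative lognormal noise (σ = 0.2). Baseline movement is the max
  of 10 absolute Gaussian draws (σ = 0.3 px); a contamination probability
  plants trials with gross baseline movement to exercise exclusion. The
  source reports no displacement distributions (figure axes only), so
  these magnitudes are realistic free choices, fixed once.
- **Videos.** The evoked response is a 100-ms half-sine bump whose peak
  equals the amplitude parameter (shape unspecified in the source; smooth
  and peak-exact). A textured disk translates along x by the trace under
  bilinear interpolation, plus Gaussian pixel noise.
- **Startle tables.** Pulse-alone = scale × lognormal; prepulse+pulse =
  scale × (1 − π) × lognormal (expected %PPI = 100π); prepulse-alone =
  scale × a + baseline (expected air-puff-alone = a); no-stim = baseline ×
  lognormal. All responses are positive by construction.
- **Confocal stacks.** Terminals are single-optical-section elliptical
  profiles (axis ratio ≤ 1.5) centered on integer planes — consistent
  with the strictly 2-D analysis — with a 0.6-µm same-plane gap so PSF
  blur cannot merge them. Exactly round(f × n) terminals receive one
  receptor punctum centered in the eroded footprint; background puncta
  (density 0.05/µm³) avoid terminal footprints unless the z-collapse
  stress mode is on. Channels are blurred by a Gaussian PSF (σ = 0.08 µm)
  and degraded by Poisson (100 photons/unit) + Gaussian (σ = 0.02) noise.
- **Arena trajectories.** Target occupancies are realized by a
  round-robin schedule of dwell bouts per zone, a reflected Gaussian walk
  confined to the active zone, and brief straight dashes between zones
  (through the center square in the plus maze). Ground truth is the
  actual per-sample zone bookkeeping, so downstream recovery is exact and
  agreement with the target is limited only by dash overhead (a few
  percent of a multi-minute session). Without a bias the walk is a free
  reflected walk.

What the generators do **not** emulate: posture and limb articulation,
maternal-separation stress, litter effects, non-rigid body motion,
photobleaching or depth-dependent attenuation in the stacks, and thigmotaxis
dynamics beyond planted occupancies. Passing recovery tests therefore
demonstrate correctness of the *measurement* pipeline under the stated
models, not robustness to every property of real recordings.

## Benchmark problem sizes

The validation suite (and `scripts/acceptance.py`) uses sizes chosen to
make Monte-Carlo noise small relative to each check: 1,000 randomized
sessions against the brute-force habituation oracle; 500 rational-input
draws per formula (assay-realistic magnitudes, agreement to 1e-12); all
~164k Fisher tables with margins ≤ 30 against exact integer enumeration;
100 rendered videos with planted peaks 2–50 px (tolerance max(0.5 px,
5%)); 3 stacks per colocalization fraction in {0, .25, .5, .75, 1},
noiseless and at default noise; power of the n = 16 vs 10 genotype
comparison from 2,000 simulated cohorts per root seed (the majority claim
is checked on 500), with 1,000 null cohorts for type-I behavior; and 500
cohorts for cutoff concordance.

## Known limitations

- The tracker assumes locally rigid, well-textured targets; it is not a
  pose estimator and degrades under occlusion (expressed via the validity
  mask, which the trace and peak operations respect).
- Puncta diameters are reported from thresholded areas of
  diffraction-blurred spots and are PSF-dominated near the 0.1-µm
  minimum; the minimum-diameter rule therefore acts on apparent, not
  physical, size — as in the original workflow.
- The proximity value is an upper bound on synaptic colocalization by
  design; no deconvolution or 3-D merging is attempted.
- Exact one-sided Fisher tests are conservative at these group sizes;
  null rejection rates run well below the nominal α.
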