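# Methods

## The measurement problem

Adrenergic-type neuroblastoma cells migrate the way immature neurons do:
in a two-stroke cycle in which a leading process extends first and the
nucleus then translocates forward within the cell, often past the cellular
centroid (nucleokinesis, NUC).  Mesenchymal-type cells instead glide
smoothly with the nucleus towed at a roughly constant offset behind the cell
centroid.  Given only two tracked points per cell per frame — the cellular
centroid (CC) and the nuclear centroid (NC), in micrometres — the package
distinguishes these modes and counts individual nuclear translocations.

## Transition geometry

For each pair of consecutive stored frames *n*, *n + 1*:

* **NNC/NCC angle** — the angle at vertex NC(n+1) between the vector back to
  NC(n) and the vector to CC(n+1), in [0°, 180°].  High angles mean the cell
  centroid lies ahead of a slowly advancing nucleus (process extension,
  towing); low angles mean the nucleus is moving toward or past the cell
  centroid (anterior translocation, contraction).  The angle is *undefined*
  (not an error) when either arm is shorter than 1 nm; undefined transitions
  are counted separately and never enter block frequencies.
* **Angle blocks** — LOW = [0°, 40°], HIGH = [140°, 180°], MID otherwise.
  Both boundaries are inclusive toward their block, and 0° is assigned to
  LOW: the exact boundary is a measure-zero case and a fourth in-range
  category would serve nothing.  Both bounds are configurable
  (`low_block_max_deg`, `high_block_min_deg`).
* **Signed nucleus position** — the scalar projection of (NC − CC) at frame
  *n + 1* onto the unit vector of the CC step.  Positive means the nucleus
  is ahead of the cell centroid along the instantaneous motion axis.  This
  operationalises "nucleus ahead / cell centroid ahead" as an along-axis
  ordering, the natural reading of the nucleus "surpassing" the centroid.
* **Noise correction** — displacements with magnitude below a floor `tau`
  are set to exactly 0.  The default `tau` = 0.12 µm is the pooled median
  per-frame nuclear displacement of sessile cells (median NC speed
  < 0.05 µm/min), i.e. the magnitude of apparent motion produced by
  segmentation and tracking jitter alone.  The same `tau` defines the
  NEUTRAL band of the position state (|projection| ≤ `tau`): by the noise
  argument itself, sub-noise ordering of the two centroids is unknowable.
  `estimate_noise_threshold` recomputes this calibration from any sessile
  cohort as the median of the pooled per-transition NC displacements.
* **Gaps** — manual tracking drops frames.  Transitions spanning a
  frame-index gap > 1 are computed (with `dt` from the true gap, so
  velocities stay correct) but gap-flagged, and flagged transitions are
  excluded from signature and event decoding, which are defined on truly
  consecutive frames.

## Event decoding

A **signature** is a maximal run of ≥ 2 consecutive transitions in the same
LOW or HIGH block (MID, undefined and gap-flagged transitions break runs).

A **NUC event** is decoded from adjacent transition pairs of
(block, position-state):

* pattern A, extension-then-jump: (HIGH, CC-ahead) → (LOW, NC-ahead);
* pattern B, jump-then-catch-up: (LOW, NC-ahead) → (LOW, CC-ahead).

Matches sharing a transition are merged into a single event keeping the
earlier pattern label: the two rules share the (LOW, NC-ahead) element, and
counting both would book one biological translocation twice.  The event
distance is measured in the cell frame — |Δ(NC − CC)| from the start of the
first to the end of the last spanned transition — because nucleokinesis is
nuclear movement *within* the cell; the distance is noise-corrected and
zero-distance events are discarded, so every reported event distance is
≥ `tau`.

The **NUC footprint** of a track is the weighted mean event distance, by
default weighted by each event's spanned transition count (a translocation
that unfolds over more frames contributes proportionally); uniform
weighting is available (`footprint_weighting="uniform"`).  The footprint is
not normalised by track length; `n_events / n_transitions` is reported
alongside for rate comparisons.  Per-track velocity is accumulated path
length over elapsed time, computed for the NC by default (the nucleus is
the marker actually tracked in nuclear-label movies) and for the CC on
request.

## Statistical comparisons

Cell-cycle-resolved displacement comparisons use the two-sample
Kolmogorov–Smirnov test on per-transition NC displacements pooled across
tracks (G1 vs S/G2, transitions inheriting the phase of their *from* frame),
with the asymptotic p-value by default — appropriate at the
hundreds-to-thousands of pooled timepoints these cohorts produce; an exact
option is exposed.  The velocity–footprint association across tracks is a
Pearson correlation with a two-sided p-value; zero variance in either
variable raises a degenerate-input error.  A cohort that decodes *no*
events has an all-zero footprint vector and therefore no velocity–footprint
coupling by construction; cohort-level reports treat that case as r = 0
rather than a failure.

## Morphometrics

Nuclear roundness is ImageJ-style circularity 4πA/P², clipped at 1.
Shapes come from integer-labeled masks via `skimage.measure.regionprops`;
the perimeter estimator is the 4-direction Crofton formula, which is nearly
unbiased on smooth convex shapes (a 50-px disc measures within 1% of 2πr;
the boundary-segment estimator overshoots by ≈ 4% there).  Labels under
5 px are excluded as debris and reported.  Two positioning fractions have
no field-standard operational definition, so their thresholds are explicit
parameters recorded with every output: a centrosome is *distal* when its
distance from the nucleus centroid exceeds `k` equivalent nuclear radii
(r = √(A/π); default k = 1, i.e. outside the idealised nuclear disc), and a
metaphase is *asymmetric* when the plate centroid sits more than `f`
equivalent cell radii from the cell centroid (default f = 0.25).  Both
fractions are monotone non-increasing in their threshold.

## Mis-expression and fingerprint mapping

Across two DE contrasts (perturbation vs clinical), genes in the
intersection are quadrant-classified by logFC sign with a raw p-value gate
(default p ≤ 0.05 in both tables, no logFC magnitude threshold;
`lfc_min` exposes magnitude cutoffs since some analyses use 0.2–0.3).
Discordant signs are *mis-expressed* (MIS_UP = up after perturbation, down
clinically), concordant signs CONCORDANT_*, and genes failing the gate or
with no direction (|logFC| ≤ `lfc_min`) are UNCLASSIFIED.  No
multiple-testing correction is applied inside the classification (a BH
helper is provided separately).  Fingerprint mapping ranks a profile
descending by logFC (or signed −log10 p), ties broken lexicographically by
gene id for a total, reproducible order, and reports query-gene ranks, the
median rank quantile, and a one-sided Mann–Whitney rank-sum p-value for
enrichment toward the top.

## The synthetic generator

The generator exists to make every stage verifiable without imaging data;
its defaults are the package's standard study conditions and were chosen
for decoder identifiability, not to match any measured biology.

* **NUC mode** (5-min frame interval): per cycle of `cycle_frames` = 8
  frames, the CC advances `step_um` = 1.0 µm/frame along a heading that
  turns by wrapped-Gaussian increments of SD (1 − persistence)·π/2
  (persistence 0.9 ⇒ ≈ 9°/frame) while the NC drags at `nc_drag` = 0.5 of
  the CC step; on the cycle's last frame the NC translocates in one stroke,
  landing `jump_um` = 1.5 µm ahead of the new CC position.  The drag is
  what keeps extension-phase NC motion well above jitter so extension
  transitions classify HIGH rather than noise-random; the single-frame
  stroke produces the (LOW, NC-ahead) jump transition.  One truth event is
  recorded per translocation, at generation time.
* **MES mode** (15-min interval): CC advances as above; NC is towed exactly
  `lag_um` = 2.0 µm behind the heading.  With `pause_prob` = 0.1 per frame
  the cell rests (CC holds position), mimicking the intermittent pauses of
  mesenchymal cells; during pauses both centroids show only jitter, which
  is what occasionally produces decodable (false-positive) events and keeps
  the footprint vector non-degenerate.  No truth events.
* **SESSILE mode** (15-min interval): both centroids jitter about fixed
  anchors.
* **Jitter** (all modes): `jitter_sd_um` is defined as the per-axis SD of
  the per-frame *displacement* noise; positions receive independent
  Gaussian noise of per-axis SD `jitter_sd_um`/√2, so the step-magnitude
  median is `jitter_sd_um`·√(2 ln 2) (Rayleigh).
  `jitter_for_noise_median(0.12)` inverts this to calibrate a sessile
  cohort whose pooled median displacement is the 0.12 µm noise floor.
* **Per-track heterogeneity**: each track draws a scale factor
  ~ Uniform(1 ± `track_scale_spread`, default 0.4) applied to `step_um` and
  `jump_um`.  Faster cells therefore take proportionally larger nuclear
  strokes — the within-mode coupling that makes the velocity–footprint
  correlation informative rather than pure noise.
* **Truth-event bookkeeping**: with *n* frames and cycle length *C*,
  translocations land on steps into frames C, 2C, …, giving
  ⌊(n − 1)/C⌋ events per track.
* **Seeding**: track *i* of a cohort is generated from
  `default_rng([seed, i])`, so any track is reproducible independently of
  cohort size or generation order.

DE-table pairs are generated with exact category counts (rounded from the
requested fractions), |logFC| = `effect_size` with the category's sign
pattern and p ∈ (0, 0.05] for classified genes, and p ∈ (0.05, 1] with
N(0, effect/3) logFC for the remainder — so default-threshold
classification recovers the truth exactly, by construction.

### What the generator does and does not emulate

It reproduces the *geometry* the decoder keys on (two-stroke cycles, towed
nuclei, anchored jitter), per-track speed heterogeneity, and a calibratable
noise floor.  It does not emulate cell–cell contact, division and track
splitting, drift, segmentation failure modes (merged/split labels), mode
switching within one track, or realistic event-amplitude distributions —
no quantitative event rate or amplitude for real cells is established.
Passing recovery tests therefore demonstrates the decoder is correct and
well-conditioned under its stated assumptions, not that real cohorts will
decode with the same recall.

## Numerical choices and degenerate inputs

Angles and projections are undefined (None) below a 1 nm arm length;
`classify_block` maps undefined to UNDEF and rejects out-of-range angles.
Noise correction is idempotent and odd.  Block frequencies are taken over
defined-angle transitions only and sum to 1 whenever any exists.
Correlation requires ≥ 3 tracks and non-degenerate variance.  Track tables
round-trip through TSV at 9 significant digits (read-back within 1e-6 µm).
Runs are reproducible end-to-end: CLI outputs carry a manifest (config
echo, input SHA-256, package version, no timestamps) and identical
invocations are byte-identical.

## Problem sizes

Standard verification cohorts are 100 tracks × 200 frames per mode
(~20 000 transitions, ~2 400 truth events in NUC mode), 10 × 1 000 genes
for mis-expression recovery, and exhaustive decoder validation over all
(block, state) strings of length ≤ 5 including gap-flagged and
undefined-angle symbols (15 symbols, 813 615 strings) against an
independent brute-force enumerator.

## Known limitations

Strictly 2-D; no drift correction, smoothing or interpolation (all
non-goals).  The decoder is the deterministic two-rule pattern matcher —
no probabilistic segmentation — so borderline transitions flip with `tau`
and the block bounds; both are exposed in `RunConfig`.  Whether real
analyses merged overlapping pattern matches is not established; this
implementation merges (the rules share an element), and the uniform /
duration footprint weighting switch brackets the plausible alternatives.
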