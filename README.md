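# nuctrack

Quantification of **nucleokinetic migration** from paired cell/nucleus
centroid time-lapse tracks.

Neuroblastoma cells of the adrenergic type migrate like immature neurons:
a leading process extends first, then the nucleus translocates forward
within the cell in a discrete stroke, often overtaking the cellular
centroid (nucleokinesis, *NUC*).  Mesenchymal-type cells instead glide
smoothly with the nucleus trailing at a constant offset.  `nuctrack` takes
the minimal observable — two tracked points per cell per frame, the
cellular centroid (CC) and nuclear centroid (NC) in µm — and turns it into
migration-mode diagnostics and counted translocation events.  It is aimed
at anyone analysing dual-centroid tracking exports (e.g. ImageJ Manual
Tracking on nuclear-marker movies).

## The method

For consecutive frames *n*, *n+1* each transition is characterised by:

- the **∠NCₙ/NCₙ₊₁/CCₙ₊₁ (NNC/NCC) angle** — the angle at the new nuclear
  position between the vector back to the old nuclear position and the
  vector to the new cellular centroid.  Angles in the **140–180° block**
  reflect leading-process extension / mesenchymal towing; the **0–40°
  block** reflects anterior nuclear translocation and contraction;
- the **signed NC−CC distance** — the projection of (NC − CC) onto the CC
  motion axis, noise-corrected with a floor **τ = 0.12 µm** (the pooled
  median per-frame nuclear displacement of sessile cells, median speed
  < 0.05 µm/min), giving a nucleus-ahead / cell-centroid-ahead state.

**NUC events** are decoded from adjacent transition pairs:
`[140–180°; CC ahead] → [0–40°; NC ahead]` (extension then jump) or
`[0–40°; NC ahead] → [0–40°; CC ahead]` (jump then catch-up); overlapping
matches merge into one event.  Each event's distance is |Δ(NC − CC)| across
its span, and a track's **NUC footprint** is the duration-weighted mean
event distance — which correlates with velocity in nucleokinetic cohorts
but not mesenchymal ones.  Angle-block **signatures** (≥ 2 consecutive
same-block transitions), per-track velocities, accumulated distances and
block frequencies complete the track summary.

The package also includes fixed-cell morphometrics (nuclear roundness
4πA/P², nucleus–centrosome distance, distal-centrosome and
asymmetric-metaphase fractions), the **mis-expression** procedure on paired
differential-expression tables (genes discordant between a perturbation
and a clinical contrast at p ≤ 0.05 with no logFC threshold), ranked
fingerprint mapping, and a seeded synthetic generator producing all three
migration phenotypes with ground-truth event labels.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```sh
nuctrack simulate --mode nuc --n-tracks 5 --n-frames 60 --seed 11 --out-dir sim
nuctrack decode sim/tracks.tsv --frame-interval-min 5 --out-dir decoded
nuctrack summarize sim/tracks.tsv --frame-interval-min 5 --out-dir summary
```

prints

```
simulated 5 nuc track(s) -> sim/tracks.tsv
5 track(s): 33 NUC event(s), 70 signature(s)
summarized 5 track(s) -> summary/summaries.tsv
```

`decoded/events.tsv` lists each translocation with its pattern, transition
span and in-cell-frame distance:

```
track_id  pattern         start_transition  end_transition  nuc_distance_um
nuc_0000  A_lp_then_jump  6                 7               3.05781817
nuc_0000  A_lp_then_jump  14                15              2.04115101
```

and `summary/summaries.tsv` holds one row per track:

```
track_id  velocity_um_min  freq_low  freq_high  n_events  footprint_um
nuc_0000            0.143     0.322      0.475         6         2.301
nuc_0001            0.154     0.339      0.508         6         2.540
nuc_0002            0.264     0.322      0.525         7         4.203
nuc_0003            0.275     0.356      0.492         7         4.415
nuc_0004            0.144     0.322      0.508         7         2.252
```

Each simulated track shows the nucleokinetic signature: a third of
transitions in the 0–40° block, 6–7 decoded events over 59 transitions,
and footprints tracking velocity — `summary/cohort_stats.json` reports the
velocity–footprint Pearson r = 0.999 (p = 3.8 × 10⁻⁵) for this cohort.
The same library is importable directly
(`nuctrack.transitions`, `nuctrack.decode_events`,
`nuctrack.summarize_tracks`, …).

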