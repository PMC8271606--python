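# Methods

## The scheduling model

Each fly is a triple of random times on a common recording axis whose zero
is the start of constant darkness (DD).  A fly pupariating at offset `z`
commits to the final phase of metamorphosis at

    C = z + Normal(commit_mean_h, commit_sd_h)

and needs a roughening (final-molt) duration

    R ~ Normal(rough_mean_h, rough_sd_h) truncated at 0

drawn independently of everything else.  The clock is a phase variable
`ct(t) = (t + ct0_offset_h) mod tau_h`; the gate is the half-open interval
`[gate_open_ct, gate_open_ct + gate_width_h)` of that phase — half-open so
that a completion landing exactly on gate close is deferred, which makes
every tie-break deterministic.  The three regimes are:

* **developmental** — onset `O` is the smallest time ≥ C such that `O + R`
  lies in a gate; emergence `E = O + R` (completion and emergence
  coincide; nobody waits).
* **permissive** — `O = C`; completion `C + R`; `E` is the completion if it
  falls inside a gate, else the next gate-opening instant.
* **arrhythmic** — `O = C`, `E = O + R`, no gate.

With deterministic durations both gated regimes produce identical
emergence distributions; they differ in onset distributions and in the
"ready but unemerged" fraction — `ready_fraction(schedules, t)` is the
predicted responder fraction of an ETH probe at time t, i.e. among flies
not yet emerged, the fraction whose completion is already past.  Under the
developmental regime that fraction is ~0 at all probe times (shrinking
with `rough_sd_h`), under the permissive regime it approaches 1 just
before a gate opens.

Randomness: one root seed spawns a per-fly `numpy` substream
(`SeedSequence(seed, spawn_key=(i,))`), so enlarging a cohort never
reshuffles earlier flies.  Truncation that rejects more than 1000 draws
for one fly is reported as an error rather than silently retried forever.

### Presets

The clock geometry is anchored only qualitatively by the biology (morning
emergence; ~24-h wild-type and ~20-h short-period free-running rhythms;
clock-less arrhythmicity), so the presets are nominal reconstructions, not
measurements:

| parameter | wild type | short period | clock-less |
| --- | --- | --- | --- |
| model | developmental | developmental | arrhythmic |
| tau_h | 24 | 20 | 24 (unused) |
| gate_open_ct / width | CT0 / 10 h | CT0 / 10 h | — |
| commit mean ± sd | 96 ± 2 h | 96 ± 2 h | 96 ± 2 h |
| rough mean ± sd | 13 ± 1 h | 13 ± 1 h | 13 ± 1 h |
| ct0_offset_h | 12 (DD starts at subjective lights-off) | 12 | 12 |

A `gate_dependent_duration` switch stretches the duration of deferred
flies — a falsification control for the duration-constancy analysis, off
by default because duration independence is the modeled finding.

### A selection artifact worth knowing about

Even with durations drawn independently of the gate, conditioning on
*which* gate a fly used induces a small duration difference: making the
early gate requires `C + R` below the gate close, so when `rough_sd_h` is
comparable to `commit_sd_h` the early-gate group is enriched for short
durations.  At large n an ANOVA reliably detects this artifact.  The
observed biological constancy of duration across gates therefore implies
the regime where commitment-time variation dominates; the split-gate
fixture preset encodes that regime (commit sd 2.5 h vs rough sd 0.4 h) and
the constancy test mirrors realistic group sizes (7–10 per group).

## The synthetic rig

`render_series` emulates the filming setup: a burst of `burst_size` frames
(default 10) every `cadence_h` hours (default 0.2 h = 12 min, i.e. five
disk passes per hour), each burst frame independently translated by an
integer jitter up to `jitter_px`, with additive Gaussian sensor noise and
a slow sinusoidal illumination drift.  Frames are 8-bit grayscale,
200×200 px by default, origin top-left, 0-based pixel coordinates; the
manifest stores decimal hours since DD start.

Appearance model, per frame time t:

* body: a bright ellipse centered on the frame center against a dark
  background (the centering matters: burst selection picks the frame whose
  intensity-weighted supra-Otsu centroid is nearest the frame center, and
  the fly's rest position is defined as centered);
* wing region: mean intensity ramps linearly from `wing_start_intensity`
  to `wing_end_intensity` over `wing_ramp_h`, starting
  `wing_ramp_start_h` after pupariation (darker wings → smaller values);
* head reflection: before onset a single smooth-bordered bright patch
  (border softened with a 3.5-px blur — the optical signature of molting
  fluid).  From onset to emergence the patch fragments: a continuous
  fragmentation index `kappa = 1 + (K−1)·(t−O)/(E−O)` controls patch
  count (the i-th patch fades in as kappa crosses i, so the count of
  patches at ≥ half fade equals `round(kappa)`), patch radius shrinks as
  `kappa^-0.4` (sublinear, so the fragmenting area never contracts),
  boundaries acquire low-order Fourier wobble and sharpen, and a fixed
  per-animal speckle field over the whole head footprint deepens with
  `sqrt(progress)` after an abrupt ~15% activation at onset.  The abrupt
  activation models the distinct starting moment of resorption and is
  what makes the onset a detectable change point; boundaries are
  anti-aliased so the noise-free roughness trace is smooth and strictly
  increasing during roughening;
* at emergence the scene switches to an empty puparium: the wing region
  brightens abruptly and the head patchiness disappears.

What the generator does **not** emulate: optics (no pixel scale, no
defocus), rotation or scale changes, multi-animal frames, occlusions,
biological variation in body shape, and any light-driven behavior (the
real rig films in far red precisely so there is none).  Passing the
round-trip tests therefore shows the pipeline recovers known ground truth
under the modeled noise sources, not that it is robust to every failure
mode of real video.

`generate_event_record` builds binned population records over
`[0, 24·n_days)`.  By default pupariation times are drawn uniformly over a
window sized so mean emergence covers the record — the population assay
collects pupae of every developmental age from running cultures, and a
literal daily restaggering of a few collection times in exact 24-h steps
would imprint a spurious 24-h period on clock-less records.  Passing an
explicit list of collection times instead reproduces the synchronized
imaging-cohort protocol (e.g. ZT6/ZT12/ZT18).

## Imaging

Burst selection: the frame whose intensity-weighted centroid of
above-Otsu pixels lies nearest the frame center; ties go to the lowest
burst index.  Because selection minimizes centroid-to-center distance, a
static photometric asymmetry (bright head, darkening wing) shifts which
jitter wins; this is harmless because stabilization then removes residual
translation.  Stabilization aligns each frame to its predecessor by the
integer shift (bounded by `max_shift_px`, default 5) maximizing normalized
cross-correlation, evaluated by exhaustive scan; the first frame is the
fixed reference, cumulative shifts are recorded, and a shift on the search
bound is flagged since the true displacement may exceed it.  The bound
must exceed twice the per-frame jitter (consecutive selected frames can
differ by the sum of two jitters).  Subpixel registration is deliberately
out of scope: the rig's jitter is integer-pixel by construction and
integer shifts keep the marker operators exactly translation-invariant.

## Markers

* `roughness_sd`: sum over interior ROI pixels of the population SD of the
  3×3 neighborhood (center included) — additive-offset invariant and
  homogeneous of degree 1 in intensity.  The alternative reading (SD of
  the 8 signed center-to-neighbor differences) is available as
  `mode="differences"`; the neighborhood form is the default because it is
  the standard local-SD texture operator and degenerates sanely (0 on
  constants).
* `segment_patches` / `roughness_borders`: 8-connected components of
  pixels ≥ threshold; perimeter is the crack-edge count (pixel sides
  adjoining sub-threshold or out-of-ROI pixels), which is even, ≥ 4, and
  additive under patch splitting — unlike boundary-pixel counts.  The
  threshold is Otsu on the head ROI of the first stabilized frame, frozen
  for the whole series so fragmentation is not confounded with drift.
* `highpass`: value minus centered moving average over `window_h`
  (default 6 h), window truncated at the ends.
* `detect_onset`: on the filtered trace (post-emergence part excluded
  first), baseline noise is the MAD over the first quarter of the record
  (global MAD if that is degenerate); an excursion is ≥ `min_run`
  (default 5) consecutive samples with |filtered| > `k_mad`·MAD (default
  k=4); the onset is the extremum of the first excursion.  The rule is
  two-sided and extremum-anchored for a structural reason: a centered
  moving average maps a flat-to-ramp kink to a negative lobe whose
  extremum falls exactly on the kink (on the ramp,
  `hp(u) = −s(u−w/2)²/(2w)`), so a one-sided first-crossing rule misses
  ramp-like onsets entirely.  Defaults were chosen on rendered fixtures
  and are exposed in the config.
* `detect_emergence`: the largest signed step of the channel's expected
  sign (wing up, roughness down) must exceed the median step by
  `k_jump`=6 robust SDs (1.4826·MAD of all steps); measuring the
  excursion relative to the median step makes a perfectly steady ramp
  undetectable even when its MAD is zero.
* `group_compare`: one-way fixed-effects ANOVA plus Tukey HSD at
  alpha=0.05 (scipy), with a compact-letter display built from maximal
  cliques of the not-significantly-different graph.

Times are decimal hours since DD start throughout; ZT/CT conversions
always carry an explicit offset.

## Rhythm analysis

The autocorrelogram uses the biased (divide-by-total-variance,
non-circular) estimator: its decaying peak envelope is what the RI
convention assumes, and the unbiased estimator would inflate coefficients
at long lags.  Records must have positive variance; `max_lag` may not
exceed half the record span.  Default binning 0.5 h, max lag three
expected periods.

Peak finding: local maxima of the 3-lag-smoothed correlogram, excluding
lag 0, with prominence above both a fixed floor (0.02) and a sampling-
noise floor `z/sqrt(N)` (z=2 by default; the autocorrelation of an N-bin
uncorrelated count record fluctuates at scale 1/sqrt(N), and without the
floor the first-peak period estimate locks onto noise lobes).  Each
smoothed peak is refined to the raw-coefficient argmax within its
smoothing window, because smoothing displaces a sharp correlogram spike by
one lag and both reported quantities are read off the raw correlogram.
The period is the first peak's lag; RI is the coefficient at the second
peak (configurable via `ri_peak_index`); classification is strict
(RI > 0.3 rhythmic; 0.1 ≤ RI ≤ 0.3 weakly rhythmic; RI < 0.1 arrhythmic;
fewer than two peaks → aperiodic flag and arrhythmic).

The valley criterion for records too short to support a correlogram:
smooth the counts with a 3-h moving average, mark maximal runs at or below
the 20th percentile of the smoothed values over the record's nonzero span
(at-or-below, because a strongly gated record spends more than a fifth of
its span at exactly zero), and accept iff there are at least two valleys
and the *median* spacing of consecutive valley centers lies within
`expected_period_h ± tol_h` (default tol 4 h).  Requiring the median
consecutive spacing — rather than any pair of valleys — is what keeps
irregular records from passing by combinatorial chance.

## Problem sizes

The test suite and the acceptance script use 300-fly, 7-day population
records (ten seeds) for all rhythm statistics, and a ten-animal rendered
cohort (3-frame bursts, 2-px jitter, noise SD 1.5) for the image
round-trip checks; these sizes give stable statistics while keeping a full
run around a minute.  The fixture gating preset compresses the
pupariation-to-commitment time to ~7 h so a rendered series spans about a
day of recording, exactly as the real rig only films the final day.

## Known limitations

* Gate phase and width are reconstructions; analyses that depend only on
  periodicity and classification are insensitive to them, but absolute
  emergence phases are not meaningful.
* The onset detector assumes a single onset per record and a baseline
  quarter-record of pre-onset data; series that begin mid-roughening will
  be mis-dated.
* The borders roughness index responds to fragmentation more weakly than
  the SD index under this renderer and is not used for onset scoring by
  default; the two indices are positively rank-correlated during
  roughening, which is the property the analysis relies on.
* Integer-only registration; scenes with subpixel drift would alias.
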