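# eclopy

Tools for analyzing the timing of the final day of *Drosophila*
metamorphosis from single-animal time-lapse imagery, and for scoring the
circadian rhythmicity of population eclosion records.

## The scientific problem

Adult flies do not emerge from the puparium whenever metamorphosis happens
to finish: the circadian clock restricts eclosion to recurring permitted
windows ("gates"), typically around subjective dawn.  Two mechanisms can
produce the same gated population record:

* **permissive gating** — development free-runs; animals that finish while
  the gate is closed are held, fully formed, until it reopens;
* **developmental gating** — the clock sets when each animal *initiates*
  the final steps of metamorphosis, so that it finishes inside a gate and
  emerges as soon as it is ready.

Distinguishing them requires following individual animals through the last
day of metamorphosis.  Two imaging markers make that possible through the
pupal case: the wings darken over several hours (a pure developmental
clock-independent marker), and the bright, smooth reflection of molting
fluid over the head breaks up into many small irregular patches as the
fluid is resorbed ("head roughening") — a marker with a well-defined onset
that tracks commitment to complete the molt.  The hypotheses then separate
on two observables: the distribution of roughening onsets across emergence
gates, and the fraction of "ready but unemerged" animals that an
ecdysis-triggering-hormone (ETH) probe would cause to eclose before a gate
opens.

`eclopy` implements the whole chain as a tested pipeline with an explicit
simulator for every stage, so each analysis step can be validated against
ground truth without any recorded data:

| module | role |
| --- | --- |
| `eclopy.gating` | stochastic per-fly scheduling model of the three regimes (developmental / permissive / clock-less), cohort simulation, ETH-probe responder prediction, model contrast |
| `eclopy.synthetic_data` | ground-truthed renderer of the filming rig (bursts every 12 min, jitter, noise) and of binned population eclosion records |
| `eclopy.imaging` | burst-to-series reconstruction (most-centered frame per burst) and integer-shift stabilization |
| `eclopy.markers` | wing-intensity and head-roughness traces, onset/emergence detection, ANOVA + Tukey group comparison |
| `eclopy.rhythm` | autocorrelogram, rhythmicity index, period estimate, three-way classification, valley criterion |
| `eclopy.cli` | `eclopy` command-line tool and end-to-end orchestration |

## The statistics at the core

For a binned emergence record `x_1 .. x_N` the correlogram uses the biased
sample autocorrelation

    r(l) = sum_t (x_t - x̄)(x_{t+l} - x̄) / sum_t (x_t - x̄)^2

The dominant period is the lag of the first non-zero-lag correlogram peak;
the **rhythmicity index (RI)** is the coefficient at the second peak (near
twice the period).  Records are classified *rhythmic* when RI > 0.3,
*weakly rhythmic* for RI in [0.1, 0.3], and *arrhythmic* when RI < 0.1 or
the correlogram is aperiodic.  The head-roughness index is either the sum
of local 3×3-neighborhood standard deviations over the head region
("standard deviation" algorithm) or the summed crack-edge perimeter of
supra-threshold patches ("borders" algorithm); roughening onset is the
extremum of the first sustained excursion of the high-pass-filtered trace,
and emergence is the largest abrupt step of the expected sign (brightness
jump in the wing trace, roughness collapse).

## Worked example

```sh
printf 'scene.burst_size = 3\n' > demo.cfg
eclopy demo --seed 5 --config demo.cfg --out out
```

prints

```
3 animals analyzed; population record: RI=0.70, period=24.0, classification=rhythmic; 4 figures in out/figures
```

and writes `out/traces.csv`, `out/summaries.csv`, `out/rhythm.json` and
figures.  Reading the numbers: three synthetic animals were rendered
frame-by-frame, reconstructed, stabilized and traced; their detected
roughening onsets cluster at 6.8 h after the start of constant darkness
with roughening durations of ~13 h (`summaries.csv`), matching the
generative schedule.  In parallel a 300-fly, 7-day population record was
simulated with the same wild-type clock parameters; its correlogram has its
first peak at lag 24 h (the free-running period) and a coefficient of 0.70
at the second peak — well above the 0.3 cutoff, so the record is classified
rhythmic.  Rerunning with the same seed reproduces every output file
byte-for-byte.

Other entry points: `eclopy simulate-events --preset short_period`,
`eclopy rhythm events.csv`, `eclopy gating-compare`, `eclopy trace`,
`eclopy onset`, `eclopy stabilize` — all take `--seed` and `--config`.

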