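# lymphnir

Quantification of collecting lymphatic vessel function from near-infrared
(NIR) fluorescence imaging of the rodent tail.

## The problem

Collecting lymphatic vessels pump lymph through intrinsic contractions of
their lymphangions, propelling discrete boluses ("packets") of fluid.
After an intradermal injection of a NIR tracer (indocyanine green bound to
albumin) at the tail tip, a camera placed 10 cm downstream records the two
parallel collecting vessels that drain the tail.  From those recordings,
three function metrics are measured per vessel:

- **transport time** — seconds from injection until fluorescence arrives at
  the imaging window (a sustained 20% rise above the pre-arrival baseline),
- **packet frequency** — packets per minute passing the field of view,
- **packet velocity** — mm/s of the packet fronts across the window.

Metrics are resolved in two 100-s analysis segments: the *arrival* segment
(starting 60 s after per-vessel fluorescence arrival) and the *steady-state*
segment (starting 10 min after injection).  The vessel where fluorescence
arrives first is the **dominant** vessel; in longitudinal designs the
dominance labels are fixed from the week-0 session.  The package also
tracks tracer retention at the injection site (visible while SNR =
20·log₁₀((mean − background)/σ_background) exceeds 3 dB), measures lymph
node projected 2-D area from microscopy images, and runs the study's
hypothesis tests (paired/unpaired two-tail t with Bonferroni correction,
paired one-tail t for week-k vs. week-0 comparisons, α = 0.05).

A bundled synthetic-data generator (`lymphnir.synth`) produces videos,
traces, retention series and node images with exported ground truth —
gamma-renewal packet trains advected at constant velocity over a saturating
free-flow baseline — so every estimator is testable end to end.

## Who it is for

Researchers doing NIR lymphangiography in rodent models who want a tested,
reproducible implementation of the two-vessel function-quantification
framework, and methodologists who want a ground-truthed sandbox for packet
detection and transit-time velocimetry in fluorescence time series.

## Worked example

```python
import lymphnir as ln
from lymphnir.synth import session_rois

cfg = ln.preset("healthy", seed=7, duration_s=720)
stack, truth = ln.simulate_video(cfg)
result = ln.analyze_session(stack, session_rois(cfg), animal_id="rat01")
```

Running `python examples/01_vessel_function_session.py` (which does exactly
this) prints:

```
dominant vessel: vessel_a (ground truth: vessel_a)

vessel_a (dominant)
  transport time         61.5 s   (truth 60 s)
  packet frequency      9.6 /min (arrival)  12.0 /min (steady state)
  packet velocity      2.50 mm/s (arrival)  2.50 mm/s (steady state)

vessel_b (nondominant)
  transport time         86.0 s   (truth 85 s)
  packet frequency      8.4 /min (arrival)   8.4 /min (steady state)
  packet velocity      1.88 mm/s (arrival)  1.88 mm/s (steady state)
```

The pipeline recovers the generator's arrival times within ~1.5 s, packet
rates within counting noise, and velocities within ~5%, and identifies the
earlier-arriving vessel as dominant.  The other examples cover the
dominant/non-dominant paired comparison (`02`), injection-site retention
and the 3 dB visibility window (`03`), and the week-0 → week-1 follow-up
with node enlargement (`04`).

## Command line

A thin CLI wraps the library for shell use:

```bash
lymphnir simulate --preset healthy --seed 7 --out session/
lymphnir analyze  --stack session/stack.tif --rois session/rois.json --out results.csv
lymphnir compile  --results results.csv --out table.csv
lymphnir stats    --table table.csv --design vessel_paired --out tests.csv
lymphnir retention --series retention/ --out retention.csv
lymphnir nodes     --images nodes/ --pixel-size 0.05 --out nodes.csv
```

Outputs embed the analysis-config hash; identical seeds give byte-identical
tables.

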