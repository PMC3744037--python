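# Methods

## Signal model

A collecting lymphatic vessel observed through a NIR imaging window is
modelled as the sum of three components:

1. **Free-flow baseline.** After fluorescence arrival at time `t_arr`, the
   mean intensity rises toward a plateau as
   `B(t) = b0 + P·(1 − exp(−(t − t_arr)/τ))`, with constant background `b0`
   before arrival.  Defaults: `b0 = 50`, `P = 400` (×0.8 for the
   non-dominant vessel, which runs dimmer), `τ = 30 s`.
2. **Packet pulses.** Lymphangion contractions launch discrete boluses.
   Inter-packet intervals follow a gamma renewal process with mean `60/rate`
   and shape 4 (contractions are quasi-periodic; shape 1 recovers a Poisson
   process for stress tests).  In traces each packet is a temporal Gaussian
   of amplitude 150 and sd 0.5 s; in videos it is a spatial Gaussian blob
   (axial sd 0.5 mm) translating at the vessel's packet velocity, entering
   the window at its ground-truth time.
3. **Noise.** Additive Gaussian, per-pixel sd 2 by default.

Acquisition defaults mirror the experimental timeline: 0.05-s frame
interval (50-ms exposure), 20-min sessions, imaging window 10 cm downstream
of the injection site, 0.1 mm/pixel with a 10-mm window (100 px) and two
vessel stripes 1.6 mm apart.

In videos, a blob's amplitude is modulated by a *spatial* envelope centred
on the window midpoint, sd `max(v·0.5 s, L/2)` for window length `L`.  This
makes the whole-vessel ROI trace show one unimodal pulse per packet with
amplitude calibrated to the trace model (so video→trace reduction matches
`simulate_trace` for the same seed stream), while keeping front-tracking
nearly unbiased: an amplitude profile that depends only on position shifts
the peak time at a fixed position by `−(x − L/2)·σ_eff²/(v·σ_env²)`, a
linear-in-x term that inflates measured velocity by
`σ_eff²/σ_env² ≈ 2–4%` (σ_eff combines the blob sd with the sub-ROI
averaging length).  This bias is visible in the recovery numbers (≈+4%)
and is well inside the ±10% velocity tolerance.

All generator randomness derives from the single `SimConfig.seed` through
keyed substreams; identical seeds give bit-identical traces, videos,
retention series and node images.

## Estimators

**Arrival.** The nominal criterion — a 20% intensity rise — is ill-posed
for near-zero baselines, so the working threshold is
`max(1.2·baseline, baseline + 5·σ_bg)` with the baseline taken as the
median of the first 10 s and the crossing required to hold for ≥1 s of
consecutive samples.  Background statistics (`σ_bg`, per-pixel) come from
the background ROI pooled over the first 10 s, before tracer can reach the
window.  Transport time is the arrival time in seconds since injection
(`t0_s` bookkeeping covers late-started recordings).

**Segments.** Arrival segment `[t_arr + 60, t_arr + 160]` per vessel;
steady-state segment `[600, 700]` s post-injection, anchored to the
injection rather than the arrival.  A late arrival can make the two
overlap; overlap and truncation are flagged, never silently shifted.

**Detrending.** A running-median baseline (window 30 s, evaluated on a
decimated grid and interpolated — the baseline is slow by construction) is
subtracted to isolate the pulsatile component.

**Packet detection.** Strict local maxima of the detrended trace with
prominence ≥ `max(5·σ_bg, 0.1·segment dynamic range)` and ≥1 s separation
(higher peaks win), after a 0.25-s boxcar pre-smoothing.  The smoothing sits
well below the pulse width, so amplitudes and peak times are essentially
untouched, but it prevents high noise from splitting one tall pulse into
several prominence-passing maxima — without it, raising the noise level
could *increase* counts.  The operator is a reconstruction: the tolerances
were chosen so detection is exact against generator ground truth at
high SNR (test suite, acceptance script).  Within full sessions, packets
are counted on the central sub-ROI trace (one axial cross-section): there a
pulse's width is set by the blob length, not the transit time, so slow
vessels do not merge neighbouring packets the way whole-window averages do.

**Velocity.** The vessel ROI is split into 5 equal-axial-length sub-ROIs
(spanning ≥5 mm).  For each packet detected in the middle sub-trace, front
times at the other sub-ROIs are found by walking outward: within a search
window bounded by a minimum physiological speed (0.2 mm/s), the candidate
is the *nearest* strict local maximum above 3·σ_bg — nearest, because the
farthest candidates belong to neighbouring packets.  Peak times are refined
by parabolic (three-point) interpolation for sub-frame resolution.
Velocity is the least-squares slope of axial position vs. front time;
packets with fewer than 3 usable fronts, non-monotone fronts, fit R² < 0.8,
or implied speed above 20 mm/s (infinite-velocity guard) are discarded and
counted; the per-segment value is the median over surviving packets.  A
missing velocity is NaN, never zero.

**Dominance.** Earlier detected arrival wins.  If the two arrivals fall
within one frame interval, the tie breaks on mean intensity over the first
100 s post-arrival (the dominant vessel nearly always runs brighter); an
exact tie falls back to ROI order and is flagged.  In follow-up sessions
(week > 0) labels are copied from the stored week-0 result regardless of
the current transport times.

**Retention.** Injection-site SNR per day, in amplitude dB
(`20·log10`); a `10·log10` power mode exists behind `snr_mode="power"`
since the 3 dB convention's dB flavour is ambiguous — at the 3 dB limit the
two differ only in the implied amplitude ratio (1.41 vs. 2.0).  The
generator decays the injection-site amplitude as `exp(−day/6.5 d)` from a
day-0 amplitude 20× the noise sd (26.02 dB), putting the analytic 3 dB
crossing at day 17.2 — visible for more than two weeks — sampled every
2 days.

**Node morphometry.** Binary masks are counted exactly.  Grayscale images
go through Otsu thresholding, largest connected component, hole filling —
a standard reconstruction of "projected 2-D area", accurate to <1% on the
synthetic ellipses (criterion: ≤5%).  The generator's area scales are
4.5× (week 1), 3.0× (week 2) and 1.0× (weeks 0/4) of a 1.25 × 0.9 mm
baseline ellipse, encoding the observed +350%/+200% enlargement; controls
stay at baseline.

**Statistics.** `t_test` wraps the classical t with explicit handling the
tables need: pairwise missing-value dropping (counted), Welch degrees of
freedom for unpaired tests (pooled variance behind a switch), a `p = 0`
degenerate flag for zero variance with nonzero effect, and an error (never
`p = 1`) for the 0/0 case.  `compare_design` runs one test per
metric·segment combination present in the table: dominant vs. non-dominant
is paired two-tail with Bonferroni `m` = family size; group comparisons are
unpaired two-tail with Bonferroni; week-k vs. week-0 is paired one-tail in
the direction of functional loss (transport time up, frequency and velocity
down) and uncorrected, matching the study design.  Raw and adjusted p are
always both reported because the appropriate family size is a design
choice.

## Preset scenarios

`preset(name)` encodes the study's conditions relative to the healthy
baseline (arrivals 60/85 s, rates 10/8 min⁻¹, velocities 2.4/1.8 mm/s for
dominant/non-dominant):

| preset | change vs. healthy |
|---|---|
| `gtno` | non-dominant arrival ×6 (the ~6-fold transport-time increase), dominant ×2; rates ×0.7/×0.4; velocities ×0.7/×0.5 |
| `icg_week1` | both vessels: arrival ×2.5, rate ×0.5, velocity ×0.5 |
| `icg_week2` | non-dominant only: arrival ×2, rate ×0.6, velocity ×0.6 |
| `week4`, `control` | identical to healthy |

Absolute healthy-preset rates and velocities are calibration choices —
the framework reports relative contrasts, and published collecting-vessel
values span roughly 1–10 mm/s and 5–15 packets/min; they were fixed once
and the acceptance thresholds were not adjusted around them.

## What the generator does and does not emulate

It reproduces the statistical structure the estimators assume: renewal
packet timing, constant advection, saturating baseline, earlier/brighter
dominant vessel, exponential retention decay, ellipse-like node outlines.
It does **not** model optical scattering or a realistic PSF, motion,
photobleaching, packet dispersion or amplitude decay along the vessel,
vessel curvature, heart/respiratory artefacts, or pharmacokinetics of
tracer binding.  Passing tests therefore demonstrate correctness of the
measurement chain under the assumed signal model, not robustness to every
in-vivo artefact; on real data the ROI definitions and the detection
parameters (exposed in `AnalysisConfig`) are the knobs to revisit.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale problem sizes chosen as the
smallest that exercise every code path with stable statistics: 720-s
sessions (the steady-state segment ends at 700 s) instead of the full
1200 s, 130–260-s clips for single-estimator checks, 50–100 seeds for
recovery sweeps, and n = 4 animals for the paired designs, matching the
study's group size.  Ties in peak selection are broken toward higher
peaks, then earlier indices; parabolic interpolation clamps to ±half a
frame; all file round-trips preserve dtype bit-exactly.

## Known limitations

- The packet-detection and velocimetry operators are reconstructions of
  methods the framework builds on; parameter defaults are justified by
  simulation, not by the original in-vivo recordings (which are not
  available).
- Whole-window packet counting merges packets when the transit time
  approaches the inter-packet interval; the central-cross-section counting
  used by `analyze_session` avoids this but assumes the vessel ROI can be
  subdivided axially.
- The ~4% velocity bias from the video amplitude envelope is a property of
  the synthetic videos, not of the estimator; on data without a common
  spatial amplitude profile the front regression is unbiased.
- Dominance classification assumes exactly two vessel ROIs.
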