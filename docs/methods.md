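# Methods

## Scope

`beambreak` simulates and analyses infrared beam-break recordings of a
single zooplankter (modelled on Antarctic krill, *Euphausia superba*)
swimming in a vertical column, as produced by scanned light-barrier
activity monitors.  The package covers five stages: (1) an agent-based
swimmer and a virtual beam-barrier scanner that emit synthetic logfiles,
(2) the logfile/config formats, (3) the per-module beam-break event
pipeline, (4) the upward-swimming activity metric, and (5) light-phase
statistics, group aggregation, quality screening and average-day profiles.

## Instrument model

A column holds a 75 cm water column (inner diameter 9 cm) with five
detector modules: rings of six infrared emitter/receiver pairs.  Module 1
sits 3 cm below the surface (surface swimmers still trigger it), module 5
sits 5 cm above the floor (a dead, settled animal triggers nothing), and
the modules are equally spaced in between (depths 3, 19.75, 36.5, 53.25,
70 cm).

Within a module only one beam is lit at a time; each beam is active for
10 ms, so a six-beam module completes one scan rotation every 60 ms
(16 full rotations per second).  A beam break is detected only if the
occlusion covers at least 50% of an activation slot (5 ms).  The scan is
modelled per module — modules scan concurrently and independently.  A
globally serialized scan over all 30 beams would complete only ~3.3
rotations per second, which contradicts the instrument's rotation rate,
so the per-module reading is adopted.

The firmware's latching across consecutive rotations during a long
occlusion is not documented; we assume at most one detection per beam per
activation slot, i.e. a stationary occluding body yields one record per
qualifying slot.  (Note the closed form "beams x full rotations" slightly
undercounts a trailing partial rotation: a 1000 ms occlusion qualifies in
all 100 slots, not 96.)

## Light regime

Irradiance follows a triangular profile: zero outside the photoperiod,
linear ramps from lights-on to a midday peak and back.  Defaults are the
reference deployment's settings: photoperiod 15.5 h, peak 8.8 mW m^-2,
noon at 12:00 local time.  Logfile timestamps are UTC; the experiment
config carries the local-time offset (UTC-2 for the reference deployment)
and all analysis is done in local time.

## Behavioural model (synthetic individuals)

Depth (cm below surface, clamped to the water column) evolves in 0.1 s
steps as the sum of four terms:

* **sink drift** — krill are negatively buoyant; default 0.3 cm s^-1
  downward.
* **phototaxis** — upward speed `phototaxis_gain x I(t)/I_peak x
  baseline_speed`.  Positive gain = surface-attracted, negative =
  depth-seeking; the default cohort mixes gains in [-1, 1] because real
  individuals differ strongly in their response to an artificial light
  source.
* **upward swimming bouts** — a Poisson process (default 2 h^-1) starts
  bouts during which the animal swims upward at `baseline_speed`
  (1.5 cm s^-1) for `bout_duration_s` (75 s, long enough to traverse the
  column); in darkness the bout rate is multiplied by
  `dark_activity_gain` (default 3), producing the nocturnal activity
  increase the analysis is meant to recover.
* **Gaussian jitter** — random-walk noise, 0.8 cm s^-1/2.

The speeds are within the range of routine krill swimming; they were fixed
once as plausible defaults and double as the study conditions for all
simulation-based tests.  Horizontal position is not modelled: the chance
that the body actually intersects the active beam (the beams leave gaps of
up to ~3 cm) is collapsed into a single per-slot hit probability
`beam_hit_prob` (default 0.15).  The body is a vertical band of half-height
2.5 cm (adults reach ~6 cm; a partial overlap with the detector plane is
enough to occlude a beam).

The scanner intersects occlusion intervals with the slot grid
*analytically* (integer microsecond arithmetic), so the 5 ms rule is exact
rather than sampled; surviving slots are drawn by geometric gap-sampling,
which is an exact implementation of independent per-slot thinning.
Trajectory integration runs in a single compiled (numba) pass because the
clamp at the surface/floor makes it inherently sequential.  Given a seed,
simulated logfiles are byte-identical across runs.

### What the generator does and does not emulate

It reproduces the statistical structure the pipeline assumes: bursty
per-module detections from one animal, phototaxis-dependent vertical
preference, a nocturnal excess of upward swimming, faulty channels (dead
or stuck detectors) for QC testing.  It does not emulate horizontal
movement, swimming-speed modulation, feeding state, swarming, spectral
light composition or temperature effects.  Passing tests therefore show
that the *analysis* recovers what the *model* put in — not that real krill
behave like the model.

## Event pipeline

* **1-min event rule**: a module scores one *event* per calendar minute
  containing at least one detection (saturating, so detection multiplicity
  within a minute is irrelevant).
* **Binning**: events are summed into calendar-aligned 10-min bins
  (values 0–10).  Bins are aligned to the clock, not to recording start,
  so day folding and phase labels are exact; partial first/last bins are
  kept for continuity but flagged and excluded from statistics.
* **Normalization**: min-max to [0, 1] over the whole recording, per
  module (per column for the activity metric).  A constant series maps to
  zeros.
* **Smoothing**: 6-bin centered moving average for visualisation.  For an
  even window the centre is ambiguous; we use the left-heavy convention
  (three bins before through two after) with shrinking windows at the
  edges.  Statistics always use unsmoothed bins.

## Upward-swimming activity metric

All detections of a column are merged chronologically; a detection at
module *m* is retained iff the *immediately preceding* detection (any
module) came from a module lower in the column (index > m).  Consecutive
detections at the same module break the chain and become the new
predecessor.  Records in the same millisecond are ordered
bottom-module-first (configurable), so an ascending burst within one scan
rotation counts as upward movement.  An alternative predecessor rule that
looks through same-module repeats (`previous-distinct`) is provided;
retained sets differ only when a repeat interrupts an ascent.

The retained detections (raw beam breaks, not 1-min events) are binned,
normalized per column and smoothed exactly like the event series.  The
metric is zero for any trajectory that never crosses a module boundary
upward, which separates hovering/sinking (baseline) from active ascent.

## Statistics

* **Phase labels**: a bin is lights-on iff the ramp intensity at its start
  is positive; the two bins per day containing a transition are flagged
  and excluded from tests.  Under the default regime 93 of 144 daily bins
  are lights-on.
* **Mann-Whitney U**: implemented from rank sums with midranks.  Exact
  mode enumerates all C(n_x+n_y, n_x) labelings of the pooled multiset
  (used automatically for n_x+n_y <= 12); otherwise the normal
  approximation with tie-corrected variance and continuity correction is
  used.  Two-sided p-values; a pooled sample with zero variance yields
  p = 1.  The exact mode is verified exhaustively against an independent
  reference implementation for all tie-free samples up to 4 vs 4.
* **Phase comparison**: unsmoothed normalized bins, lights-off vs
  lights-on, with significance stars at p < 0.05 / 0.01 / 0.001 and the
  direction as the sign of median(off) - median(on).  Smoothing is
  deliberately excluded from testing: it induces strong serial
  correlation.  Binned behavioural series already violate the U test's
  exchangeability assumption to some degree (bouts can straddle bin
  boundaries); no block-resampling correction is applied, to keep the
  procedure identical to standard practice, and the residual
  anticonservativeness is assessed empirically by the null-calibration
  test.
* **Group aggregation**: per-bin mean and s.e.m. (sample sd, n-1) across
  individuals on a shared calendar grid; s.e.m. is reported missing for a
  single individual.
* **Average day**: usable bins folded by time of day into 144 bins; mean,
  s.e.m. and contribution count per bin across individuals x days.
* **Quality screening**: a column is dropped when a module logged nothing
  while all other modules logged >= 10 detections (dead module), or when a
  module fired in more than 50% of its scan rotations (stuck detector).
  The thresholds are configurable; the instrument description gives no
  quantitative criterion, so conservative defaults are used.

## Numerical choices and degenerate inputs

Occlusion/slot intersection is computed in integer microseconds (no float
thresholds).  Empty trajectories produce empty record lists; empty record
sets with an explicit span produce all-zero series; a phase without usable
bins makes a comparison "not testable" instead of raising.  Seeds derive
from `numpy.random.SeedSequence`, spawned per individual and per stage
(trajectory vs thinning), so runs are reproducible and individual streams
independent.

## Problem sizes

The reference analysis uses 10 individuals x 5 days.  The replication
experiments use 9 individuals x 5 days x 50 seed batches for parameter
recovery and 200 single-individual replicates for null calibration; the
acceptance script uses 20 recovery batches.  These sizes give binomial
standard errors of a few percent on the reported rates.

## Known limitations

* The logfile schema is a synthetic stand-in: the real instrument's format
  is not public, so only the information content (timestamped detections
  per column/module/beam plus housekeeping sensor rows) is mirrored.
* The behavioural model is one-dimensional and stationary within a phase;
  it cannot reproduce masking dynamics, anticipation, or free-running
  rhythms.
* The U test on 10-min bins inherits serial correlation from behaviour
  that spans bins; the null-calibration test quantifies the effect under
  the model, but real data may be more strongly autocorrelated.
* Periodogram/rhythm-strength analysis, swimming-speed estimation and
  downward metrics are out of scope.
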