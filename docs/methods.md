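# Methods

## The elastance model

The ventricle is treated as a time-varying elastance: instantaneous chamber
stiffness `E(t)` relates pressure to volume through `P(t) = E(t)·(V(t) − V0)`,
with the zero-pressure volume `V0` fixed to 0 mL. This is a deliberate
simplification — a real ESPVR has a positive volume intercept — but it makes
the single-beat computation closed-form and treats non-invasive and invasive
loops identically. `V0` is exposed as a constant (`pvloop.noninvasive.V0_ML`)
for forward compatibility; no other value is exercised.

### Normalized elastance shape

The normalized shape `E_N(x)` on cycle fraction `x ∈ [0, 1]` is a
double-Hill product,

    E_N(x) ∝ [(x/τ1)^n1 / (1 + (x/τ1)^n1)] · [1 / (1 + (x/τ2)^n2)]

with τ1 = 0.269, n1 = 1.32 (activation) and τ2 = 0.452, n2 = 21.9
(relaxation), renormalized to unit peak. This is a widely used normalized
approximation of the human elastance waveform: a gradual sigmoid rise, peak
near 38% of the cycle, and a steep relaxation. The curve ships as a data
asset (`src/pvloop/data/default_elastance.csv`, 501 uniform samples;
regenerate with `scripts/generate_default_elastance.py`) so a user-digitized
curve — e.g. one traced from a subject-specific measurement — can be dropped
in via `Config.elastance_path` or `--elastance` without code changes. All
shape-dependent tests run against the packaged asset.

### Temporal scaling

The landmark aligned with end systole is the **middle of the elastance
downslope**, interpreted in amplitude: the first cycle fraction after the
peak where `E_N` falls to half its maximum (the temporal midpoint of the
descent is a noted alternative, not implemented). A piecewise-linear
bijection of [0, 1] maps `[0, downslope_half]` onto `[0, t_es]` and the
remainder onto `[t_es, 1]`, where `t_es` is the minimal-volume frame's cycle
fraction. Warping is invertible: composing with the inverse warp recovers
the original curve to grid resolution.

### Amplitude scaling

A pure multiplicative scale cannot match both the end-diastolic and the
peak pressure, so the scaling is affine: `E(t) = E_off + E_sc·E_N(t)` with
`E_off = EDP/EDV` (anchoring `P = EDP` at the maximal-volume sample, where
`E_N ≈ 0`) and `E_sc` solved by bisection so that
`max_t E(t)·V(t) = LVP_systole`. The peak pressure is strictly increasing
in `E_sc`, so bisection on the bracket `[0, 10·LVP_systole/ESV]` always
converges; the solver iterates to 1e-4 mmHg on the peak (well inside the
0.05 mmHg guarantee stated in the API docs) within at most 200 iterations.

One design choice deserves note: the amplitude is solved **on the delivered
100-point loop grid** (warped elastance and periodic-spline volumes are both
evaluated at the 100 uniform cycle fractions) rather than on a denser
intermediate grid followed by downsampling. Solving on an intermediate grid
and then interpolating would let the delivered peak drift below the target
by up to the local curvature times the squared grid spacing; solving on the
final grid makes the documented anchors — `max P = (2·SBP + DBP)/3 ± 0.1`
and `P(ED) = EDP ± 0.1` mmHg — hold exactly on the loop the caller receives.

### End-diastolic pressure

EDP cannot be derived from a cuff pressure, so it is a user estimate,
default 7.5 mmHg. The sensitivity sweep recomputes the full metric set over
{3, 7.5, 10, 16, 25, 40} mmHg; the 7.5 row is bit-identical to the default
pipeline because the sweep is the same pure function. EDP is anchored at the
maximal-volume frame (frame 0 under end-diastolic gating); when a curve is
not ED-gated the constructor warns and records the ED frame index rather
than re-anchoring the cycle, since the gating convention is an acquisition
property the software should surface, not silently repair.

## Volume curves

`VolumeCurve` holds one retrospectively gated cycle: frame 0 at the R-wave,
volumes in mL, heart rate defining the cycle length. Interpolation is a
periodic cubic spline (`V(T) = V(0)`), matching the closed cycle of
retrospective gating; ties on the minimal volume break to the earliest
frame. The degenerate case EDV = ESV (zero stroke volume) raises rather
than propagating zeros into ratios downstream.

## Loop metrics

All seven metrics are computed from the sampled loop polygon, identically
for both sources:

- **SW**: absolute shoelace area of the (V, P) vertex sequence. On closed
  polygons this equals the trapezoidal contour integral ∮P dV exactly.
- **E_max / ESPVR**: the discrete sample maximizing P/V (earliest index on
  ties, with a 1e-12 relative tolerance so constant-ratio loops tie-break
  deterministically); ESPVR = P_emax/V_emax with V0 = 0. Defining E_max on
  loop samples rather than on the continuous elastance keeps invasive and
  non-invasive loops on the same footing.
- **PE**: triangle ½·ESV·(ESPVR·ESV); **PVA** = SW + PE holds exactly by
  construction, and **VE** = SW/PVA.
- **E_a**: slope from the E_max point to (EDV, 0). The alternative form
  E_max-pressure/SV is dimensionally attractive but equals the slope only
  when the E_max volume coincides with ESV; the slope definition is
  implemented (the identity is verified numerically in tests for that
  special case).
- **MEP**: SW·HR/60, reported in watts (1 mmHg·mL = 1.33322e-4 J) and in
  raw mmHg·mL/min, since conventions differ across labs.
- **EPEV**: PVA/SV, with SV = EDV − ESV taken from the loop itself.

## Invasive reference pipeline

- **Filtering**: the "10 Hz filter" is realized as a 2nd-order Butterworth
  applied forward–backward (zero phase; effective 4th-order magnitude).
  Chosen for minimal ringing on pressure upstrokes; DC gain 1, ≥ 20 dB
  attenuation at twice the cutoff.
- **Offset**: the pressure registered at catheter withdrawal is subtracted
  wholesale.
- **Segmentation**: upstrokes are prominent dP/dt peaks (≥ 50% of the
  global maximum, ≥ 0.3 s apart). The beat onset — the diastolic foot just
  before isovolumic contraction — is located by the intersecting-tangent
  construction: the tangent at the dP/dt maximum is projected down to the
  diastolic baseline level. A simple dP/dt-threshold backtrack was tried
  first and sat systematically ~30 ms late (the elastance rise is gradual),
  which rotated the averaged beat against the volume curve and biased
  stroke work by roughly 20%; the tangent foot recovers generator
  ground-truth onsets to ±1 sample at 250 Hz. Automatic markers replace the
  manual check step of interactive analysis software; the detected
  `BeatSet` is a plain value object a caller can edit before averaging.
- **Ectopy**: a beat whose RR deviates from the median by more than 20% is
  ectopic; it and both neighbours are dropped. More than 25% ectopic beats
  rejects the recording outright, mirroring exclusion for high ectopic
  burden. Both thresholds are configurable; the RR criterion stands in for
  what is a manual, morphology-aware decision in practice.
- **Averaging**: each retained beat is linearly resampled to 250 points on
  its own normalized duration and averaged pointwise; the SD of per-beat
  peaks is reported as the beat-to-beat variability.
- **Loop assembly**: averaged pressures and the 250-point resampled volume
  curve are paired on the normalized beat axis, both anchored at end
  diastole (pressure beat onset ↔ maximal-volume frame), with no lag
  optimization, then reduced to the common 100-point loop. The conductance
  channel, when present, is only linearly rescaled so its maximum equals
  the CMR EDV; conductance-to-volume physics is out of scope.

## Synthetic data: what it does and does not emulate

The generator produces what the pipelines consume, with known truth:

- Volume curves: smooth two-phase shape — cosine ejection to ESV at
  `t_es`, then biphasic refill (72% of the stroke in the first 45% of
  diastole, a diastasis plateau, 28% during the atrial kick). Values chosen
  to resemble normal filling-phase partitioning; the exact split only
  matters insofar as it creates a realistic diastolic baseline for beat
  detection. `t_es` is drawn on the 25-frame grid because in cine CMR the
  end-systolic time *is* a frame time.
- Haemodynamic states: EDV 150–400 mL, EF 15–45%, HR 60–90 bpm, true peak
  pressure 90–140 mmHg — a dilated, low-EF cohort spanning distinct states
  so agreement statistics have real between-dataset variance.
- Catheter traces: concatenated copies of the true beat at 250 Hz, each
  rescaled so per-beat peaks are Gaussian with 1.96·SD = 6.1 mmHg (the
  beat-to-beat variability of real recordings), plus additive sample noise
  (SD 1 mmHg) and a withdrawal offset. Ectopics are short-coupled
  (RR × 0.6) with 30% reduced peak — simple, but sufficient to exercise the
  RR-deviation detector.
- Brachial pressure: constructed by inverting `(2·SBP + DBP)/3` around the
  true peak plus a systematic overestimation (default +11 mmHg, jittered
  25% between datasets; exactly zero when requested), with pulse pressure
  35–60 mmHg.
- Ground truth pressures come from the same elastance family the estimator
  uses (self-consistency mode); `shape_mismatch=True` jitters the
  double-Hill parameters to emulate model error.

Not emulated: respiratory modulation, Windkessel afterload coupling,
pressure-waveform morphology beyond the elastance model (no isovolumic
spikes or a-waves), conductance-volume nonlinearity, and measurement
separation between cuff and imaging. Passing tests therefore demonstrate
internal consistency and correct signal processing — that each pipeline
recovers what the generator encoded — not clinical accuracy on patients,
which requires paired human data.

## Problem sizes and numerical choices

The validation cohort is 8 datasets of 20–28 beats (~200 samples per beat
at 250 Hz), the scale at which the agreement statistics are meaningful for
this design; the Monte-Carlo averaging bound uses 100 seeds. Loops are 100
points, averaged beats 250 points. All randomness flows through
`numpy.random.default_rng` seeds; identical inputs give bit-identical
outputs everywhere (no global RNG state). Degenerate inputs — constant
volume curves, constant pressure traces, zero-variance statistics inputs —
raise typed errors from `pvloop.errors` rather than returning NaN.

## Known limitations

- The packaged elastance shape is a population-average approximation; no
  patient-specific shape fitting or V0 estimation is attempted.
- The cuff pressure is assumed concurrent with imaging; no drift
  correction for the up-to-an-hour separation typical of combined
  protocols.
- Single-beat ESPVR through the origin, not a multi-load fit; no dP/dt
  metrics.
- Central-aortic waveform reconstruction and valvular gradients are out of
  scope: in severe aortic stenosis or peripheral arterial disease the
  estimated systolic pressure will be biased.
- ICC is the single-measures form ICC(2,1); no multiple-testing correction
  is applied across the seven metrics.
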