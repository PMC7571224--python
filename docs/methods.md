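# Methods

`gaitload` measures how people adapt their trunk and pelvis movement when
carrying hand loads. The pipeline turns body-worn gyroscope recordings (80 Hz,
four sites: sixth thoracic vertebra T6, first sacral vertebra S1, right thigh,
right shank) into eleven per-gait-cycle parameters and condition-level
mixed-effects summaries. Because the human recordings this class of study
rests on are not publicly deposited, the package carries a first-class
synthetic-gait generator whose ground truth is exact by construction; every
estimator is validated against it.

## Signal model and axis convention

Sensors are mounted with the x-axis along the segment's proximal–distal axis
pointing inferiorly, which maps gyroscope axes onto anatomical planes:
x → transverse (axial rotation), y → sagittal (flexion–extension),
z → coronal (lateral bend). All angular velocity is in °/s, displacement and
phase in degrees, lengths in metres.

## Preprocessing

* **Low-pass filter.** Second-order Butterworth at 2 Hz, applied forward and
  backward (zero lag). The forward–backward pass squares the magnitude
  response, so the cutoff sits at −6 dB (|H|² = 1/2).
* **Integration.** Cumulative trapezoidal integration of filtered angular
  velocity, θ(0) = 0; exact for piecewise-linear inputs.
* **Drift control.** Gyroscope bias turns trial-level integrals into ramps.
  The default path (a) restarts the integral at every heel-strike, limiting
  any residual error to one cycle (~1 s), and (b) removes the constant bias
  estimated as the mean filtered velocity between the first and last
  heel-strike — segment angular velocity is periodic over a gait cycle, so
  its mean over an integer number of cycles is ≈ 0 and the trial mean is the
  bias. With these two steps a 1 °/s bias leaves per-cycle range of motion
  unchanged to numerical precision. An optional endpoint linear detrend per
  cycle (`preprocess.detrend_cycle`) guards against slowly varying drift; a
  least-squares detrend is deliberately avoided because a sinusoid is not
  orthogonal to a line over one period. An alternative path
  (`displacement_source: trial_highpass`) integrates the whole trial and
  applies a second-order zero-lag 0.75 Hz high-pass instead; it is kept for
  comparison because it attenuates stride-frequency (~0.95 Hz) sway by ~30%,
  which is visible in its ROM outputs.
* **Time normalization.** Cycles are resampled by linear interpolation onto a
  conventional 101-point 0–100% gait-cycle grid.

### Known, quantified filter bias

The 2 Hz low-pass attenuates sway at stride frequency (~0.94 Hz) by ~4.7%
peak-to-peak and sway at step frequency (~1.9 Hz; the sagittal plane) by
~44%. Phase-based parameters are immune (amplitude normalization), and
between-condition contrasts of ROM survive because the attenuation is a
common factor, but absolute sagittal ROM values from this pipeline are
systematically low. This is an inherent property of the published filter
choice, reported here so nobody mistakes it for an estimator defect.

## Gait events

Detection runs on the right shank's sagittal angular velocity. Mid-swing is a
prominent positive peak (prominence ≥ 40% of the trial's 95th-percentile
|ω|, with a 30 °/s floor; minimum separation 0.4 s); a polarity check flips
the signal if the sensor was mounted upside down. Heel-strike is the first
minimum after a mid-swing peak and toe-off the last minimum before it, within
±0.35 s windows. Peaks are located on the 2 Hz-filtered signal, whose heavy
smoothing is what makes the peak structure unambiguous — but the same
smoothing skews or occasionally erases the narrow heel-strike dip, so the
minima themselves are picked on a lightly filtered copy (8 Hz, config
`events.refine_cutoff_hz`). On synthetic trials at default noise this yields
heel-strike timing errors of ~3 ms median and cycle-duration RMSE ≈ 6 ms.
Cycles are delimited by consecutive heel-strikes; the analysis policy skips
the first cycle and keeps a fixed count (five by default, ten for the longer
second design) to avoid gait initiation/termination transients. A
physiological duration gate (0.4–2.5 s) flags spurious cycles.

## Stride length (double-segment model)

Thigh and shank act as an inverted double pendulum over the planted foot
during stance and a double pendulum about the hip during swing. Each
segment's rotation Δθ over a sub-phase is the integral of its sagittal
angular velocity between events; each contributes the chord
2·L·sin(|Δθ|/2) — exact for a rigid segment rotating between two postures.
Under left/right symmetry the stance advance stands in for the contralateral
step, and the stride is the sum of the stance and swing contributions.
Rotation integrals use a dedicated 4 Hz low-pass (config
`stride.lowpass_hz`): the 2 Hz event filter removes enough swing-phase energy
to bias the rotation integrals, while 4 Hz preserves them and still
suppresses noise. Rotations above 120° are flagged implausible. Against
generator truth the estimator is biased by about +1% with RMSE ≈ 1.3 cm over
cohort-like variation.

Relative speed — (stride length / cycle duration) / leg length — is the
walking-speed covariate; it is grand-mean-centered once per analysis set.

## Sway and coordination

* **ROM**: max − min of the per-cycle integrated displacement, per plane and
  site (six parameters).
* **Continuous relative phase**: within a cycle, angular velocity and
  displacement are each mapped to [−1, 1] via 2(v − min)/(max − min) − 1,
  and the per-frame phase is the four-quadrant arctangent of
  (normalized ω / normalized θ). A principal-branch arctan cannot reach the
  out-of-phase regime beyond 90°, so atan2 is the only interpretation
  consistent with mean values above 100°. The relative phase is the pelvic
  minus thoracic phase, wrapped to (−180°, 180°]; its absolute value is
  averaged over the cycle, giving the mean relative phase (MRP) in [0°, 180°]
  (0 = in-phase, 180 = anti-phase). A signed mode (`phase.absolute: false`)
  is available; phases are differenced wrapped, with unwrap-before-difference
  as a config alternative. MRP is invariant to amplitude rescaling of either
  site and to common time shifts, and recovers imposed lags over the full
  [0°, 180°] range within 0.05° at zero noise.
* **Ensemble curves**: per-frame |relative phase| time-normalized to 101
  points, averaged cycles→participant→grand (participant-first averaging is
  the contract; naive pooling differs when cycle counts are unbalanced), SE
  across participants.

## Mixed-effects stage

Cycle rows are averaged per walk trial. Each of the nine sway/coordination
parameters is fit with a linear mixed model: fixed effects for carrying mode
(side/anterior), load level (0, 4.5, 9.1, 13.6 kg), mode × load, and centered
relative speed; a random intercept and random slope on the covariate per
participant (statsmodels `MixedLM`, REML). The empty-handed reference trials
are shared between modes; for the crossed mode × load layout they are split
evenly between the mode columns per participant — the trials are exchangeable
draws from the same condition, so every no-load summary is invariant to the
labelling (tested). Singular fits fall back in order: random
intercept + slope → random intercept → OLS, with the structure recorded in
the diagnostics; a fit is accepted only if its fixed-effects covariance is
positive semidefinite.

Per-term Wald F tests use sum-coded (type-III-style) contrasts. The
denominator df is a containment-style approximation,
n_obs − rank(X) − (n_participants − 1); a Satterthwaite approximation is not
exposed by the backend, and the calibration that matters is tested directly —
over 200 null simulations at the full study size the mode term rejects at
3–5% against the nominal 5%. Estimated marginal means are cell predictions
at the covariate mean (centered value 0) with SEs from the fixed-effects
covariance; on balanced noise-free designs they equal raw cell means.
Bonferroni families follow the reporting structure: each mode-within-load
comparison is its own family (m = 1, four contrasts), the six load pairs
within a mode form one family (m = 6); adjusted p = min(1, m·p_raw).
Residual diagnostics (Shapiro–Wilk on residuals, Levene across mode × load
cells) are exported as tables.

## Synthetic gait generator

The generator is displacement-first: it constructs θ(φ) over a gait-phase
axis φ and emits the analytic derivative as angular velocity, so ROM and
phase-lag truth are exact by construction.

* **Torso/pelvis**: the trunk segments are treated as an oscillating inverted
  pendulum; per-plane displacement is sinusoidal at stride frequency
  (coronal, transverse) or step frequency (sagittal). The pelvic waveform
  lags the thoracic one by a configurable phase within each plane; the lag in
  degrees of cycle phase is the MRP ground truth. Waveform-level detail of
  real trunk signals is richer than a sinusoid; this is a modelling choice
  consistent with the inverted-pendulum framing, and it is exactly the regime
  in which the phase-portrait definition of MRP is well posed.
* **Shank**: a periodic cubic-spline template with the canonical gait shape —
  negative dips at heel-strike and toe-off, a dominant positive mid-swing
  peak (~300 °/s). The template is adjusted to zero mean (orientation is
  periodic over a cycle) and re-parameterized so its heel-strike minimum sits
  exactly at phase 0; its knots are config.
* **Thigh**: a stride-frequency sinusoid whose amplitude is solved from the
  same chord-length geometry the estimator uses, so the double-segment model
  is exercised with a known target stride. Because generator and estimator
  share the geometry, stride tests probe event timing, filtering and
  integration — not the geometric formula itself.
* **Timing**: cycle durations are drawn per cycle (SD 0.02 s within trial)
  and the phase axis is piecewise-linearly warped; half a cycle of lead-in
  and lead-out keeps edge events detectable.
* **Imperfections**: white Gaussian noise (default SD 2 °/s) plus a constant
  bias (default 0.2 °/s) on every channel. Pink noise, soft-tissue artifact
  and nonstationary drift are not modelled — passing tests therefore show
  correctness of the algorithms under the stated signal model, not robustness
  to every artifact of real skin-mounted sensors.

Default magnitudes are the unloaded-walking operating point the analysis
targets: sway half-amplitudes giving ROMs of 5.6/7.5° (coronal T6/S1),
5.6/7.4° (transverse), 2.9/3.8° (sagittal); phase lags 109.5° (coronal),
102.2° (transverse), 81.7° (sagittal); cycle duration 1.06 s; relative speed
1.09 (m/s per metre of leg length).

**Study designs.** `expt1`: 9 participants × (2 modes × 3 loads × 2 trials +
4 no-load walks) = 144 trials, 5 analyzed cycles each (720). `expt2`: 10
participants × 8 trials = 80 trials of 10 analyzed cycles with the 6th cycle
of three designated trials discarded (797; 1517 combined). Between-participant
spread: leg length N(0.94, 0.06²) m (expt2: 0.96, 0.05), relative speed
N(1.09, 0.08²) (expt2: 1.01, 0.15²), cycle duration N(1.06, 0.05²) s,
per-plane phase-lag intercepts SD 8°, trial-level lag SD 6°, amplitude SDs
0.4°/0.2°. A mild covariate link (coronal T6 amplitude −3 °, coronal lag
−15 ° per unit relative speed) exercises the covariate adjustment. The
`table3` effect preset adds condition offsets with the field-typical
signature: side carry drives coronal thoracic-pelvic coordination out of
phase with increasing load (up to +23.6° at 13.6 kg) while anterior carry
pulls it in phase (−22 to −30°); transverse coordination tightens under load;
sagittal thoracic sway is higher in side carry.

**Pendulum fixture.** A uniform rigid rod (0.46 m, released from 75°) pivoted
at one end: θ″ = −(3g/2L)·sinθ − c·θ′, integrated with DOP853 at tight
tolerances. The gyroscope-style channel is the angular velocity; the solved
displacement is the oracle. The integrate-and-filter pipeline reproduces it
to < 0.2° RMSE when both chains pass the same 2 Hz zero-lag filter (the
integration constant is unobservable from a rate gyro, so means are aligned
before comparison).

## Numerical and design choices

* PRNG: NumPy PCG64 (`default_rng`) everywhere; the same seed reproduces a
  trial bit for bit.
* Events reported both as sample index (0-based internally) and seconds.
* Zero-amplitude cycles make the phase portrait undefined; such cycles are
  flagged and excluded rather than patched.
* The high-pass (when used) is applied zero-lag like the low-pass, for phase
  fidelity.
* Problem sizes in the test-suite simulations — 100 trials for the accuracy
  studies, 200 null datasets for type-I calibration, 50 studies for
  direction recovery — were chosen to keep Monte-Carlo error comfortably
  below the decision margins while the whole suite stays desk-scale.

## Limitations

* Sinusoidal trunk sway cannot probe waveform-shape sensitivity of MRP;
  conclusions about real data rest on the phase-portrait method's established
  behaviour, not on these simulations.
* Absolute sagittal ROM is attenuated by the published filter choice (above).
* Only right-foot events and straight-line steady gait are modelled: no
  turning, no left/right asymmetry, no treadmill control.
* The stats stage models compound symmetry through the random-intercept
  structure; unstructured repeated-measures covariances are out of scope.
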