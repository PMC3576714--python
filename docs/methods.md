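# Methods

## Model structure

`lvcontrol` models the amplitude of an evoked response at each input event
as a second-order Volterra functional of the amplitude-graded impulse
train, truncated at second order throughout: every equation in the package
(forward prediction, kernel reconstruction, the inverse solve) is exact
second-order algebra, and the truncation is what makes the inverse a
quadratic root rather than a numerical search.

The present impulse's contribution is isolated from the history terms
(zero-lag isolation).  Three static terms — c₀, c₁(0)·A, c₂(0,0)·A² —
form the static input–output curve; three history terms — first-order,
second-order past×past, and present×past cross — carry the nonlinear
dynamics.  History enters through event-driven convolutions of past
amplitudes with discrete orthonormal Laguerre functions, which compresses
an M-bin kernel memory into L coefficients per order.

Conventions worth stating explicitly:

* **Basis indexing** is 0-based: orders 0..L−1.  Sums written 1..L in the
  standard notation map to this range.
* **Lag binning.** Continuous inter-event lags are binned at dt by
  round-to-nearest.  A past event lands in bin m = round(Δ/dt); events
  with m > M−1 are outside the memory window, so the effective window is
  half-open with cutoff (M−0.5)·dt — an event exactly M·dt old contributes
  nothing.
* **The present impulse is excluded from v_l.**  Its effect is carried
  entirely by the isolated zero-lag terms; including it in the convolution
  would double-count the present amplitude and destroy the quadratic-in-A
  structure the inverse relies on.
* **Kernel grid.**  Reconstructed kernels k₁, k₂ are materialized on the
  same 0..M−1 lag-bin grid as the basis, with the present-input entries
  (k₁ at zero lag, k₂ at the zero-lag pair) held as separate scalars.  The
  brute-force kernel predictor uses the identical binning, so the
  coefficient route and the kernel route agree to machine precision — an
  equality the test suite asserts rather than assumes.

## Laguerre evaluation

The direct formula for L_l(m) is an alternating binomial sum; evaluated
naively it is unstable at large m.  Production evaluation uses the
standard two-term recurrence, L_0(m) = √α·L_0(m−1) with
L_l(m) = √α·(L_l(m−1) + L_{l−1}(m)) − L_{l−1}(m−1), realized as an IIR
filter along the lag axis (the l=0 row is computed in log space).  The
direct sum with exact integer binomials is retained in the test suite as
an independent oracle; the two agree to 1e−10 relative across orders and
lags, and the tabulated basis is orthonormal to better than 1e−12 at the
default configuration.

## Default parameters

| parameter | default | meaning / rationale |
|---|---|---|
| α | 0.95 | basis decay.  With 1 ms bins, 99% of the order-2 energy lies within ~260 ms — the timescale of paired-pulse facilitation/depression and of inter-pulse intervals at a 2 Hz mean rate.  Smaller α (e.g. 0.7 at 1 ms bins) would confine the basis to ~30 ms and leave most event histories invisible. |
| L | 3 | basis functions per order; 15 free coefficients total (3 static + 3 first-order + 6 symmetric second-order + 3 cross). |
| dt | 1 ms | lag-bin width, well below the 2 ms minimum inter-pulse interval; binning error is bounded by basis smoothness over one bin. |
| μ = M·dt | 1.0 s | memory window; the basis has decayed to ~2e−9 at the window edge, so truncation is immaterial. |
| ridge | 0 | fits are ordinary least squares unless the design is deliberately degenerate. |

Amplitudes are used raw (μA or mV), not standardized; the solver
equilibrates design columns internally (coefficients are returned on the
raw scale), which removes the pure-scaling part of the conditioning (A²
columns are ~10⁴ larger than the intercept) and keeps noiseless
coefficient recovery at ~1e−13 relative.

## Estimation

One regression row per event with an observed output; trains are
independent (history resets at each train start, reflecting wash-out
periods between recordings).  The symmetric second-order coefficients are
identified by folding each (l₁,l₂)/(l₂,l₁) pair into one column 2·v_{l₁}v_{l₂};
the cross terms use columns 2·A·v_l.  The solver is SVD least squares;
rank deficiency without ridge raises an error naming the dependent columns
(a fixed-amplitude train, for instance, makes 1, A, A² exactly collinear —
which is also why the trajectory model must be fitted on *varying*
upstream amplitudes, never on the fixed stimulation intensities).
Cross-validation is leave-one-train-out: fit on all-but-one train, score
VAF/NMSE on the held-out train, select the basis configuration with the
best mean held-out VAF.

## Inverse model

Per event, with history v built from *already solved* amplitudes (true
recursion — never from any reference input):
a = c₂(0,0), b = c₁(0) + 2Σc₂(l)v_l, c = (static+history terms) − y_desired.
The default root branch is A = (−b+√(b²−4ac))/(2a); with a saturating
plant (a < 0, b > 0) this selects the ascending-limb root, and the
round-trip invert(predict(train)) = train identity holds to 1e−15
relative.  Alternative branches ("−", nearest-to-previous) are exposed as
a policy switch.

Degenerate cases are decided, not left undefined:

* |a| ≤ 1e−15 → linear solve −c/b (`linear_fallback`); if b also vanishes
  the event is genuinely unsolvable and raises with its index.
* negative discriminant (target beyond the reachable extremum) → vertex
  amplitude −b/(2a) (`no_real_root_vertex`): a control device must emit
  *something*, and the vertex is the closest-achievable stimulation.
* negative amplitude → clamped to 0 (`clamped_negative`); this occurs when
  the desired output falls below the plant's zero-stimulation floor
  (c₀ plus history), which no non-negative stimulation can undercut.

Flags are per event; `ControlResult.achieved_outputs` forward-simulates
the solved train so saturation is visible, not silent.

## Synthetic protocols and ground truth

The generators reproduce the study conditions: FARITs are 4 trains × 300
pulses with exponential (Poisson) intervals of mean 0.5 s resampled (not
clipped) into [2 ms, 5 s], fixed intensity 200 μA (within the 150–300 μA
fixed-intensity range; exposed as a parameter since it varied by
preparation); RARITs draw Gaussian amplitudes, mean 150 μA, sd 45 μA
(30% CV — the spread is not reported for the original protocol; this
value keeps >99.9% of draws positive and spans the plant's dynamic range),
truncated at >0 by redrawing.

Ground-truth plants are coefficient tables on physiological scales
(saturating static curve monotone over 0–300 μA; facilitating presets gain
~+8% at a 50 ms paired-pulse interval, depressing ~−11%, mixed is biphasic
in lag).  Two additional presets support the end-to-end scenario:
`dg_upstream` (stimulation → population-spike amplitude, ~1 mV scale)
provides the *varying* upstream signal a fixed-amplitude FARIT cannot, and
`trajectory` (upstream mV → downstream mV) generates the reference
pathway.  All preset entries are nonzero so relative parameter-recovery
checks are well defined.  Default output noise is 0.05 mV, about 25% of
the response fluctuation scale; at that level the fitted trajectory and
plant models reach mean train VAFs of ~66% and ~89% in the end-to-end
scenario — the same order as slice experiments, though that is a property
of the chosen noise level, not a reproduction of any recording.

What the generator does *not* emulate: waveform-level dynamics (only
extracted amplitudes), slow nonstationarities (electrode drift, slice
run-down), input-amplitude measurement noise on the upstream signal in the
fitting sense (it is present, and acts as errors-in-variables on the
trajectory fit), and any third-or-higher-order nonlinearity.  Passing
tests therefore demonstrate the *method* — identifiability, inversion,
and the benefit of model-based control under the model class — not
biological fidelity of any particular preset.

## End-to-end scenario and problem sizes

`run_endtoend` executes the four-step protocol (reference-pathway data →
trajectory fit; stimulation data → plant fit; trajectory prediction →
inverse plant → DARIT; DARIT delivery → comparison) with one seeded
random stream.  The non-optimal comparison arm stimulates with the mean
DARIT amplitude.  Noiseless, the controlled NMSE is ~0.01% (nonzero only
through a handful of clamped floor events); with 0.05 mV noise it is
~1.9% against ~3.4% for the fixed arm, and the controlled arm wins in
50/50 seeded replicates.

Test-suite and acceptance-script problem sizes (4×300-event batteries,
50-replicate Monte-Carlo loops, 300-event round trips) match the original
protocol's scale and run in seconds; they were chosen as the smallest
sizes at which Monte-Carlo error is comfortably below the asserted
tolerances.

## Known limitations

* The inverse optimizes each event given the *past* only (causal,
  matching the recursion); it does not anticipate future targets.
* No closed-loop error feedback: the controller is open-loop model
  inversion, so plant-model bias propagates directly into the achieved
  outputs.
* Second-order truncation: systems with strong third-order interactions
  will fold those effects into biased second-order estimates.
* VAF is offset-blind (a constant prediction error is invisible to it);
  NMSE is reported alongside for that reason.
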