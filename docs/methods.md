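# Methods

## The circuit model

The model describes motion-direction processing in a recurrent two-area
circuit. The state of each direction-tuned unit (a cortical mini-column) is
its mean membrane potential v, evolving under single-compartment shunting
dynamics, `τ dv/dt = −v + (1 − v)·I_ex − (1 + v)·I_inh`, which saturates
multiplicatively at ±1 and has the closed-form fixed point
`v* = (I_ex − I_inh)/(1 + I_ex + I_inh)`. Both areas share the membrane
time constant τ = 30 ms — deliberately slower than a single neuron, as the
unit aggregates a population.

V1 is driven by the pooled direction statistics R_θ of the stimulus,
convolved with a Gaussian direction kernel (σ_c = 45°) and multiplied by
the re-entrant feedback term `1 + λ·y_FB·[v_MT]⁺` (λ = 20): feedback does
not drive V1, it amplifies feedforward evidence that matches MT's current
estimate. MT is driven by the convolved rectified V1 output gated by the
feedforward efficacy, `y_FF·(G ∗ [v_V1]⁺)`. Inhibition in each area is the
population mean of its excitatory drive, a pool-normalization term that
makes a uniform input exactly self-cancelling (the balanced-input null: a
flat R_θ leaves every potential at zero).

Short-term synaptic depression is modelled as vesicle occupancy
y ∈ [0, 1] with `τ_syn dy/dt = α(1 − y) − β·y·[v_pre]⁺` (τ_syn = 1 s).
Under constant presynaptic drive v the efficacy relaxes exponentially to
`α/(α + β·v)` at rate `(α + β·v)/τ_syn`; with the drive off it recovers to
1 at rate `α/τ_syn`. The feedforward synapse is fast (α_FF = 1, β_FF = 10:
depletion time constants of ~100–300 ms at working drive levels, recovery
1 s), the feedback synapse slow (α_FB = 0.04, β_FB = 1.2: recovery 25 s).
Direction specificity of adaptation comes from the per-direction efficacy
vector being depleted by the same-index presynaptic rectified potential.

The decision stage weighs the rectified MT profile with two Gaussian
channels centered at ±90° (SD 45°) and passes the two channel sums through
a softmax with temperature 10⁻³ (max-subtracted exponents, so arbitrarily
small temperatures are safe). P_up is recorded deterministically per trial;
readout uses the time-averaged rectified MT response over the test
interval, which is robust to onset transients; the exact evaluation window
is otherwise a free design choice.

### Direction domain

Directions live on a full-circle grid of 37 units symmetric about 0°
(spacing 360/37 ≈ 9.73°), with wrap-around angular distances. A half-range
[−90°, +90°] grid is also provided (`DirectionGrid.half_circle()`), but it
is not the default: with σ_c = 45° a truncated-and-renormalized kernel
concentrates its boundary-row mass on the interior activity profile, and
under λ = 20 feedback that turns the ±90° endpoints into spurious
attractors — the population peak migrates to the boundary instead of
remaining at the salient stimulus direction. The circular grid has no
boundary rows; every kernel row has the same sum, so pool normalization and
the balanced-input null are exact everywhere.

### Kernel regimes

`direction_kernel` supports two conventions. The default is row-normalized
(an averaging kernel): convolution preserves mass, and the inter-area gain
is 1. The plain (unnormalized) Gaussian profile instead sums over
neighbors, giving each convolution a gain of about σ√(2π)/Δθ ≈ 11.6 on the
default grid; in this *regenerative* regime the λ-weighted feedback loop
has a loop gain above 1 for sufficiently strong inputs and actively
amplifies the winning direction.

The two regimes expose a real tension in the parameter set: feedback
disambiguation of a multimodal input requires `λ·y_FB·v_MT ≫ 1`
(v_MT well above 0.05), while the slow-feedback variant's insensitivity to
sub-second exposure requires `β_FB·v_MT` small against the session length
(v_MT well below 0.02). Since both properties run through the same λ = 20
circuitry, no single operating point yields both. The psychophysical
protocols therefore run in the mass-preserving regime, where the
fast/slow timescale dissociation, the ordering bias, and unsaturated
psychometric functions all hold; the tuning-curve demonstration of
feedback disambiguation (a strong bimodal adaptor with modes ±65°
collapsing to one coherent V1/MT peak when feedback is present, V1
remaining bimodal without it) runs in the regenerative configuration where
that phenomenon actually operates. Both are single-switch configurations
of the same equations.

### Integration

Forward Euler at dt = 1 ms (dt ≤ τ/10 enforced). Every update is checked
against the state bounds; overshoots below 10⁻⁶ are clipped, anything
larger raises. A numba-compiled kernel (optional extra `fast`) mirrors the
reference numpy step operation-for-operation; a unit test asserts the two
trajectories agree to 10⁻¹². Euler truncation error for an exponential
relaxation at rate k is ≈ k·dt/(2e) of the step size, so at the working
drive levels (I_ex ≲ 0.3, presynaptic v ≲ 0.3) trajectories match the
closed-form solutions to better than 10⁻³ sup-norm over ten time
constants, which the oracle tests verify for all five variant rate sets.

## Stimuli and the synthetic-data generator

**Skew.** The shear map (x, y) → (x + tanΨ·y, tanΨ·x + y) is applied about
the image center by inverse-map bilinear resampling (no holes), |Ψ| < 45°,
with a central crop (650/720 ≈ 0.9 of the short side at full scale).
Adapting conditions use Ψ = ±25°.

**Aperture.** Circular Hanning window w(r) = cos²(πr/N), zero beyond
r = N/2.

**Random dots.** 2,000 dots of 0.14° in a 17.7°-diameter aperture
(650 px at 0.271 mm pitch viewed from 57 cm), moving coherently at 3°/s at
elevation θ; the update is the coherent translation
x₂ = x₁ + s·cosθ·Δt, y₂ = y₁ + s·sinθ·Δt. Dots leaving the aperture are
repositioned uniformly inside it with a seeded generator.

**Surrogate movies.** The original adapting footage is not
redistributable, so `synth_movie` generates what the model actually
consumes: a periodic 1/f texture (spectral slope 1) drifting with
piecewise-coherent velocity (direction ~ N(0°, 20°), speed ~ |N(2, 0.3)|
px/frame, redrawn every 12 frames), Hanning-windowed, 130×130 px by
default. It emulates broadband spatial content and coherent local motion;
it does not emulate occlusions, depth, independent object motion, or
photometric nonstationarity — conclusions about real footage rest on the
qualitative property (horizontally dominated statistics shifted by skew),
which the front-end tests verify, not on quantitative spectra.

**Parametric direction statistics.** The recurrent stage is normally fed a
parametric surrogate of the pooled statistics: baseline 0.02 plus Gaussian
bumps — un-skewed: (0°, SD 25°, 0.1); DSK: (−50°, 20°, 0.1) + a residual
horizontal mode (0°, 20°, 0.06); USK is the exact mirror. Test stimuli map
to a Gaussian bump at the test direction with SD 15° ("width" read as a
standard deviation) and peak 0.1.

**Amplitude calibration.** Pooled motion energy has arbitrary units and no
canonical scale. The single overall amplitude (adapting dominant bump =
test peak) is the remaining free condition; it was calibrated once, by the
same observable the decision temperature was originally adjusted against:
the slope of the simulated psychometric functions. At scale 0.1 the fitted
slopes are ≈ 2° (curves rising smoothly across the ±6.6° test range, as in
human data) and the PSEs stay inside the tested range; at order-1
amplitudes the depressing synapses drive the aftereffect into saturation
(every response up/down) and no psychometric function exists. The
calibration rule and value were fixed before the variant-comparison matrix
was evaluated.

## Front-end

LGN stage: difference-of-Gaussians (center σ = 1 px, surround σ = 2 px).
Orientation stage: steerable first/second Gaussian-derivative quadrature
pair (σ = 1.5 px) steered to each detector direction. Correlation stage:
the filtered frame at t multiplies the filtered frame at t+1 shifted
backwards along the detector direction; the opponent arm swaps the delayed
and undelayed taps, so static input cancels exactly; the difference is
half-wave rectified. Two correlator shifts (1 and 2 px/frame) serve as
speed channels ρ and are integrated out before pooling — a single channel
mis-tuned to the texture speed produces oblique-biased tuning for
broadband stimuli. Center-surround normalization divides each response by
ε plus the mean response in a 9×9 px window pooled across channels
(ε = 10⁻³ of the field mean, making the uniform-field invariant exact and
the output contrast-scale invariant). Pooling averages over space, time
and ρ per direction. On half-range grids the left/right hemifields are
folded onto the elevation axis.

## Protocols and analysis

All sessions run a DSK block followed immediately by a USK block with no
state reset (carry-over is the mechanism behind the negative ΣPSE).
Experiment 1: 0.3 s top-up / 0.3 s blank / 0.3 s test; twelve directions
±0.6°…±6.6° (step 1.2°, 0° excluded — these endpoints and step admit
twelve values only without zero), five repetitions, order randomized by
seed. Experiment 2: 180 s initial adaptation per block, 15 s top-ups,
0.5 s ISI and tests, same test set. Experiment 3: timing as experiment 1,
fourteen directions −13°…13° (step 2°), four cycles, ascending for DSK and
descending for USK. The no-adaptation control reuses any schedule with the
adapt segments removed; the mirror control reverses block order and
negates the test directions (each condition keeps its own, mirrored,
statistics), which maps every P_up to P_down and must negate the fitted
PSEs exactly — a stringent end-to-end symmetry test.

Psychometric fits maximize the binomial likelihood (or weighted least
squares for real-valued model probabilities) of
`ψ(θ) = γ + (1 − 2γ)·Φ((θ − μ)/σ)` with one shared lapse rate
γ ∈ [0, 0.25], by bounded L-BFGS-B from six deterministic starts
(μ ∈ {min θ, 0, max θ} × σ ∈ {span/4, span/2}), ties broken by likelihood
then smallest |μ|. μ is the PSE. Degenerate blocks (all responses equal at
0 or 1) are rejected rather than fitted. Variant comparison scores each
(variant, experiment) cell by sign criteria — ΔPSE > 0.1° and
ΣPSE < −0.02° by default, user-suppliable numeric intervals otherwise —
and summarizes each variant by err_avg, the mean distance of its
predictions outside the reference intervals.

## Known limitations

- **Experiment-2 ordering bias.** The slowest process in the model
  recovers with τ = τ_syn/α_FB = 25 s, so the USK block's own 180-s
  adaptation erases all DSK carry-over and ΣPSE in experiment 2 is
  structurally ≈ 0 (sign set by fit noise, ~10⁻⁴ deg). A persistent
  ordering bias at the minutes timescale would require a mechanism slower
  than any parameter in the model.
- **Variant-2 separation.** The "slow feedforward" variant differs from
  the fast one only in replenishment rate (α 0.5 vs 1) and the absence of
  feedback; in the mass-preserving regime feedback changes the presynaptic
  V1 drive by ≤ 1.4×, so variant 2 depletes at nearly the fast variant's
  rate and shows a sizable sub-second aftereffect rather than none. Its
  "slow" character is not derivable from the tabulated rates in this
  implementation.
- **Sequential-protocol null.** With adaptation removed, the randomized
  protocols fit |PSE| < 0.05°, but the ascending/descending ladders of
  experiment 3 leave |PSE| ≈ 0.34° of exactly antisymmetric sign in the
  two blocks: the same fast synaptic memory that produces the intended
  hysteresis acts on the test history itself. It is a property of the
  protocol, not an asymmetry of the implementation (the mirror control is
  exact to 10⁻⁸).
- The model pools space before the recurrent stage (no retinotopy, no
  lateral intra-areal connections), has no MST/attention feedback, no
  response stochasticity beyond the optional Bernoulli sampling of P_up,
  and the exact elaborated-Reichardt wiring of the original front-end is
  reconstructed from its staged description rather than copied.
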