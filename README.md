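# skewadapt

Simulation of motion-direction adaptation aftereffects induced by
geometrically *skewed* naturalistic image sequences, as experienced by
wearers of progressive-addition lenses. The package models the underlying
cortical mechanism — direction-tuned populations in V1 and MT coupled by a
driving feedforward (FF) and a modulatory re-entrant feedback (FB) stream,
each carrying a short-term *depressing synapse* — and reproduces simulated
psychophysics end to end: stimulus generation, Reichardt motion-energy
detection, recurrent circuit dynamics, constant-stimuli experiment
protocols, and psychometric PSE analysis.

It is intended for computational-neuroscience and visual-psychophysics
researchers who want a compact, fully testable implementation of
multi-timescale synaptic adaptation in a recurrent two-area motion circuit.

## Model

Each of the n = 37 direction-tuned units (elevation θ from horizontal,
positive upward) is a mean-field mini-column with shunting dynamics

    τ dv/dt = −v + (1 − v)·I_ex − (1 + v)·I_inh ,     τ = 30 ms,

which bounds v ∈ [−1, 1]. The drives are

    I_ex^V1 = (G_σ ∗ R_θ) · (1 + λ·y_FB·[v_MT]⁺)          (FB-modulated input)
    I_ex^MT = y_FF · (G_σ ∗ [v_V1]⁺)                      (FF drive)
    I_inh   = (1/n)·Σ_θ I_ex                              (pool normalization)

with a Gaussian direction kernel G of width σ_c = 45° and feedback strength
λ = 20. Synaptic efficacies y ∈ [0, 1] model presynaptic vesicle occupancy,

    τ_syn dy/dt = α·(1 − y) − β·y·[v_pre]⁺ ,   τ_syn = 1 s,

depleting toward α/(α + β·v) under drive and recovering to 1 at rate α.
Fast FF rates (α_FF = 1, β_FF = 10) adapt within sub-second exposures; slow
FB rates (α_FB = 0.04, β_FB = 1.2) adapt and recover over tens of seconds
to minutes. A softmax over Gaussian up/down channels (centered ±90°,
SD 45°, temperature 10⁻³) converts the time-averaged rectified MT response
of each test interval into P(up), the simulated button press. Five model
variants cross circuit complexity (FF-only vs FF–FB) with synaptic rate
regimes (fast, slow, or both; variant 5 carries both).

Adapting signals R_θ are direction statistics of skewed natural image
sequences: down-skew (DSK) shifts the dominant motion energy to −50°,
up-skew (USK) to +50°. Aftereffects are measured as the point of subjective
equality (PSE) of a cumulative-Gaussian psychometric fit, summarized by
ΔPSE = PSE_USK − PSE_DSK (repulsion magnitude) and ΣPSE = PSE_USK + PSE_DSK
(DSK-first ordering bias).

## Worked example

```python
from skewadapt import (build_schedule, run_experiment, summarize_trials,
                       variant_params)

params = variant_params(5)              # FF-FB circuit, fast + slow synapses
sched = build_schedule(1, rng_seed=11)  # 0.3 s top-up / ISI / test protocol
trials = run_experiment(params, sched)  # DSK block then USK block, 120 trials
res = summarize_trials(trials)
s = res["summary"]
print(f"PSE_DSK = {s.pse_dsk:+.2f} deg, PSE_USK = {s.pse_usk:+.2f} deg")
print(f"dPSE = {s.delta_pse:+.2f} deg, sumPSE = {s.sum_pse:+.3f} deg")
```

prints

```
PSE_DSK = -2.84 deg, PSE_USK = +2.78 deg
dPSE = +5.62 deg, sumPSE = -0.056 deg
```

After down-skew adaptation a slightly downward test direction is perceived
as horizontal (PSE_DSK < 0) and vice versa — the perceived direction is
repelled away from the adaptor, so ΔPSE > 0. The small negative ΣPSE is the
carry-over of the slow feedback synapse from the DSK block into the
subsequent USK block.

The same session from a shell:

```bash
skewadapt run --variant 5 --experiment 1 --seed 11 --out trials.csv
skewadapt matrix --seed 11 --out pattern.json   # all 5 variants x 3 experiments
skewadapt stim stats --condition DSK --out dsk.csv
```

## Layout

- `skewadapt.stimgen` — shear distortion (inverse-map bilinear warp), circular Hanning aperture, coherent random-dot fields,
  1/f surrogate movies, and parametric DSK/USK/UnSK direction statistics.
- `skewadapt.frontend` — DoG "LGN" filtering, steerable odd/even
  orientation channels, delayed opponent Reichardt correlation,
  center-surround divisive normalization, pooling to R_θ.
- `skewadapt.circuit` — the recurrent V1–MT dynamics, efficacy ODEs,
  forward-Euler integrator (numba fast path), softmax readout, and
  population-response probes.
- `skewadapt.protocols` — the five model variant parameter sets, the
  three experiment schedules, full simulated sessions, and the
  variant-comparison pattern table.
- `skewadapt.psychometrics` — cumulative-Gaussian ML/least-squares fits
  with a shared lapse rate, ΔPSE/ΣPSE summaries, interval-deviation scores.

See `docs/methods.md` for modelling choices, calibration, and known
limitations.
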