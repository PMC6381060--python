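"""Recurrent V1-MT direction circuit with depressing FF/FB synapses.

Each model area is a population of n direction-tuned units (mini-columns)
whose mean membrane potential v follows shunting single-compartment dynamics

    τ dv/dt = -v + (1 - v)·I_ex - (1 + v)·I_inh,

which confines v to [-1, 1].  V1 is driven by the direction signal R_θ
convolved with a Gaussian receptive-field kernel and multiplicatively
enhanced by re-entrant MT feedback, (1 + λ·y_FB·[v_MT]⁺); MT is driven by the
convolved, FF-efficacy-gated V1 output, y_FF·(G ∗ [v_V1]⁺).  Inhibition is a
pool term equal to the mean excitatory drive across the population
(response normalization).  Synaptic efficacies y ∈ [0, 1] model presynaptic
vesicle occupancy: depleted at rate β by the rectified presynaptic potential
and replenished at a tonic rate α,

    τ_syn dy/dt = α·(1 - y) - β·y·[v_pre]⁺,

so y relaxes to α/(α + β·v) under constant drive and back to 1 when the
drive is off.  A softmax over Gaussian up/down readout channels (centered at
±90°, SD 45°) converts MT activity to a probability of an "upward" report.

Integration is forward Euler (default dt = 1 ms ≤ τ/10); a numba-compiled
fast path is used for long segments when available, with an identical
pure-numpy fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import DirectionGrid, DirectionSignal

__all__ = [
    "VariantParams",
    "CircuitState",
    "Drives",
    "ReadoutWeights",
    "SegmentResult",
    "direction_kernel",
    "compute_drives",
    "steady_state_membrane",
    "steady_state_synapse",
    "readout_weights",
    "readout",
    "step",
    "run_segment",
    "probe_tuning",
    "peak_location",
]

_BOUND_TOL = 1e-6


def _relu(v: np.ndarray) -> np.ndarray:
    return np.maximum(v, 0.0)


# --------------------------------------------------------------------------
# parameters and state
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantParams:
    """Complete parameter set of the recurrent circuit.

    Units: ``tau`` and ``tau_syn`` in seconds, ``sigma_c`` in degrees;
    the synaptic rates and the feedback strength λ are dimensionless.
    """

    lam: float
    alpha_ff: float
    beta_ff: float
    alpha_fb: float
    beta_fb: float
    temp: float
    tau: float = 0.030
    tau_syn: float = 1.0
    sigma_c: float = 45.0
    variant_id: int | str = "custom"

    def __post_init__(self) -> None:
        if min(self.lam, self.alpha_ff, self.beta_ff, self.alpha_fb, self.beta_fb) < 0:
            raise ValueError("λ and synaptic rates must be non-negative")
        if self.tau <= 0 or self.tau_syn <= 0 or self.temp <= 0:
            raise ValueError("tau, tau_syn and temp must be positive")


@dataclass
class CircuitState:
    """Membrane potentials and synaptic efficacies of both areas."""

    v_v1: np.ndarray
    v_mt: np.ndarray
    y_ff: np.ndarray
    y_fb: np.ndarray
    t: float = 0.0

    @classmethod
    def resting(cls, grid: DirectionGrid) -> "CircuitState":
        n = grid.n
        return cls(np.zeros(n), np.zeros(n), np.ones(n), np.ones(n), 0.0)

    def copy(self) -> "CircuitState":
        return CircuitState(
            self.v_v1.copy(), self.v_mt.copy(), self.y_ff.copy(), self.y_fb.copy(), self.t
        )

    def validate(self, tol: float = 0.0) -> None:
        for name, arr, lo, hi in (
            ("v_v1", self.v_v1, -1.0, 1.0),
            ("v_mt", self.v_mt, -1.0, 1.0),
            ("y_ff", self.y_ff, 0.0, 1.0),
            ("y_fb", self.y_fb, 0.0, 1.0),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} is not finite")
            if arr.min() < lo - tol or arr.max() > hi + tol:
                raise ValueError(f"{name} violates bound [{lo}, {hi}]")


@dataclass
class Drives:
    """Excitatory, modulatory and (scalar pool) inhibitory inputs."""

    i_ex_v1: np.ndarray
    i_ex_mt: np.ndarray
    i_mod_v1: np.ndarray
    i_inh_v1: float
    i_inh_mt: float


# --------------------------------------------------------------------------
# kernels, drives, equilibria
# --------------------------------------------------------------------------

def direction_kernel(
    sigma_c: float, grid: DirectionGrid, normalized: bool = True
) -> np.ndarray:
    """Gaussian receptive-field kernel over the direction grid.

    Row i holds the weights pooling input directions onto output direction i
    (wrapped angular distance on circular grids, truncated at the boundary
    otherwise).  By default rows are rescaled to unit sum, so G ∗ x is a
    mass-preserving average — the regime in which the psychophysical
    protocols are calibrated.  With ``normalized=False`` the kernel is the
    plain Gaussian weight profile with peak 1: the convolution then sums over
    neighbors with stage gain ≈ σ√(2π)/Δθ, the regenerative regime in which
    the λ-weighted feedback loop amplifies the winning direction enough to
    disambiguate a multimodal input (used by the tuning-curve
    demonstrations).  On a circular grid all rows share the same sum either
    way, so a uniform input always maps to a uniform output.
    """
    if sigma_c <= 0:
        raise ValueError("sigma_c must be positive")
    d = grid.pairwise_distance()
    k = np.exp(-(d**2) / (2.0 * sigma_c**2))
    if normalized:
        k = k / k.sum(axis=1, keepdims=True)
    return k


def compute_drives(
    state: CircuitState,
    r_theta: DirectionSignal,
    params: VariantParams,
    kernel: np.ndarray | None = None,
) -> Drives:
    """Evaluate all synaptic drives for the current state and input.

    Rectified potentials [v]⁺ are used wherever a potential acts
    presynaptically; efficacies gate element-wise per direction.
    """
    n = r_theta.grid.n
    if state.v_v1.size != n:
        raise ValueError("state and signal grids differ in size")
    k = kernel if kernel is not None else direction_kernel(params.sigma_c, r_theta.grid)
    rect_v1 = _relu(state.v_v1)
    rect_mt = _relu(state.v_mt)
    i_mod_v1 = state.y_fb * rect_mt
    i_ex_v1 = (k @ r_theta.values) * (1.0 + params.lam * i_mod_v1)
    i_ex_mt = state.y_ff * (k @ rect_v1)
    return Drives(
        i_ex_v1=i_ex_v1,
        i_ex_mt=i_ex_mt,
        i_mod_v1=i_mod_v1,
        i_inh_v1=float(i_ex_v1.sum() / n),
        i_inh_mt=float(i_ex_mt.sum() / n),
    )


def steady_state_membrane(i_ex: float, i_inh: float) -> float:
    """Fixed point of the shunting membrane equation under constant drives."""
    return (i_ex - i_inh) / (1.0 + i_ex + i_inh)


def steady_state_synapse(alpha: float, beta: float, v: float) -> float:
    """Equilibrium efficacy α/(α + β·v) under constant presynaptic drive v."""
    if alpha < 0 or beta < 0 or not 0.0 <= v <= 1.0:
        raise ValueError("need alpha, beta >= 0 and v in [0, 1]")
    denom = alpha + beta * v
    if denom == 0:
        raise ValueError("equilibrium undefined for alpha = beta·v = 0")
    return alpha / denom


# --------------------------------------------------------------------------
# decision readout
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadoutWeights:
    """Gaussian up/down decision channels over the direction grid."""

    g_up: np.ndarray
    g_down: np.ndarray


def readout_weights(grid: DirectionGrid, width: float = 45.0) -> ReadoutWeights:
    """Gaussian weights (SD ``width``) centered at +90° and -90°."""
    d_up = grid.angles - 90.0
    d_down = grid.angles + 90.0
    if grid.circular:
        d_up = (d_up + 180.0) % 360.0 - 180.0
        d_down = (d_down + 180.0) % 360.0 - 180.0
    g_up = np.exp(-(d_up**2) / (2.0 * width**2))
    g_down = np.exp(-(d_down**2) / (2.0 * width**2))
    return ReadoutWeights(g_up=g_up, g_down=g_down)


def readout(
    v_mt: np.ndarray, weights: ReadoutWeights, temp: float
) -> tuple[float, float]:
    """Softmax action selection over the up/down channels.

    Numerically stabilized for small temperatures by max subtraction in the
    exponent; returns (P_up, P_down) with P_up + P_down = 1.
    """
    if temp <= 0:
        raise ValueError("softmax temperature must be positive")
    rect = _relu(np.asarray(v_mt, dtype=float))
    i_up = float(weights.g_up @ rect)
    i_down = float(weights.g_down @ rect)
    m = max(i_up, i_down)
    e_up = np.exp((i_up - m) / temp)
    e_down = np.exp((i_down - m) / temp)
    p_up = e_up / (e_up + e_down)
    return float(p_up), float(1.0 - p_up)


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

def _check_dt(dt: float, params: VariantParams) -> None:
    if not 0.0 < dt <= params.tau / 10.0 + 1e-12:
        raise ValueError(f"dt must satisfy 0 < dt <= tau/10 = {params.tau / 10.0}")


def _clip_tracked(arr: np.ndarray, lo: float, hi: float) -> float:
    over = max(float(lo - arr.min()), float(arr.max() - hi), 0.0)
    np.clip(arr, lo, hi, out=arr)
    return over


def step(
    state: CircuitState,
    r_theta: DirectionSignal,
    dt: float,
    params: VariantParams,
    kernel: np.ndarray | None = None,
) -> CircuitState:
    """One forward-Euler update of both areas and both efficacy vectors.

    All derivatives are evaluated on the pre-step state.  If the Euler update
    overshoots the invariant bounds by more than 1e-6 the step is rejected
    (the dt is too large for the current drive magnitudes); overshoots below
    the tolerance are clipped.
    """
    _check_dt(dt, params)
    k = kernel if kernel is not None else direction_kernel(params.sigma_c, r_theta.grid)
    d = compute_drives(state, r_theta, params, kernel=k)
    rect_v1 = _relu(state.v_v1)
    rect_mt = _relu(state.v_mt)

    v_v1 = state.v_v1 + (dt / params.tau) * (
        -state.v_v1 + (1.0 - state.v_v1) * d.i_ex_v1 - (1.0 + state.v_v1) * d.i_inh_v1
    )
    v_mt = state.v_mt + (dt / params.tau) * (
        -state.v_mt + (1.0 - state.v_mt) * d.i_ex_mt - (1.0 + state.v_mt) * d.i_inh_mt
    )
    y_ff = state.y_ff + (dt / params.tau_syn) * (
        params.alpha_ff * (1.0 - state.y_ff) - params.beta_ff * state.y_ff * rect_v1
    )
    y_fb = state.y_fb + (dt / params.tau_syn) * (
        params.alpha_fb * (1.0 - state.y_fb) - params.beta_fb * state.y_fb * rect_mt
    )

    over = 0.0
    over = max(over, _clip_tracked(v_v1, -1.0, 1.0))
    over = max(over, _clip_tracked(v_mt, -1.0, 1.0))
    over = max(over, _clip_tracked(y_ff, 0.0, 1.0))
    over = max(over, _clip_tracked(y_fb, 0.0, 1.0))
    if over > _BOUND_TOL:
        raise ValueError(
            f"Euler step overshoots state bounds (v in [-1,1], y in [0,1]) "
            f"by {over:.2e} > {_BOUND_TOL}: dt too large"
        )
    return CircuitState(v_v1, v_mt, y_ff, y_fb, state.t + dt)


@dataclass
class SegmentResult:
    """Outcome of integrating one constant-signal segment."""

    state: CircuitState
    mean_rect_v1: np.ndarray
    mean_rect_mt: np.ndarray
    max_overshoot: float = 0.0
    trace: dict | None = None


def run_segment(
    state: CircuitState,
    signal: DirectionSignal,
    duration: float,
    dt: float,
    params: VariantParams,
    kernel: np.ndarray | None = None,
    record_stride: int | None = None,
    use_fast: bool = True,
) -> SegmentResult:
    """Integrate the circuit under a constant direction signal.

    Returns the final state together with the time-averaged rectified
    potentials over the segment (the decision readout uses the MT average).
    With ``record_stride`` set, the pure-numpy path records the trajectory
    every ``record_stride`` steps.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n_steps = int(round(duration / dt))
    if n_steps == 0:
        return SegmentResult(state.copy(), np.zeros(signal.grid.n), np.zeros(signal.grid.n))
    _check_dt(dt, params)
    k = kernel if kernel is not None else direction_kernel(params.sigma_c, signal.grid)

    if record_stride is None and use_fast:
        from . import _fast

        if _fast.HAVE_NUMBA:
            out = _fast.euler_run(
                state.v_v1.copy(),
                state.v_mt.copy(),
                state.y_ff.copy(),
                state.y_fb.copy(),
                k,
                np.ascontiguousarray(k @ signal.values),
                n_steps,
                dt,
                params.tau,
                params.tau_syn,
                params.lam,
                params.alpha_ff,
                params.beta_ff,
                params.alpha_fb,
                params.beta_fb,
            )
            v1, vmt, yff, yfb, acc1, accmt, over = out
            if over > _BOUND_TOL:
                raise ValueError(
                    f"Euler integration overshoots state bounds by {over:.2e}: dt too large"
                )
            new = CircuitState(v1, vmt, yff, yfb, state.t + n_steps * dt)
            return SegmentResult(new, acc1 / n_steps, accmt / n_steps, float(over))

    cur = state.copy()
    acc1 = np.zeros(signal.grid.n)
    accmt = np.zeros(signal.grid.n)
    trace = (
        {"t": [], "v_v1": [], "v_mt": [], "y_ff": [], "y_fb": []}
        if record_stride
        else None
    )
    for i in range(n_steps):
        cur = step(cur, signal, dt, params, kernel=k)
        acc1 += _relu(cur.v_v1)
        accmt += _relu(cur.v_mt)
        if trace is not None and (i % record_stride == 0 or i == n_steps - 1):
            trace["t"].append(cur.t)
            trace["v_v1"].append(cur.v_v1.copy())
            trace["v_mt"].append(cur.v_mt.copy())
            trace["y_ff"].append(cur.y_ff.copy())
            trace["y_fb"].append(cur.y_fb.copy())
    if trace is not None:
        trace = {key: np.asarray(val) for key, val in trace.items()}
    return SegmentResult(cur, acc1 / n_steps, accmt / n_steps, 0.0, trace)


# --------------------------------------------------------------------------
# population-response probes
# --------------------------------------------------------------------------

def probe_tuning(
    adapted_state: CircuitState,
    probe_thetas,
    params: VariantParams,
    probe_duration: float = 0.3,
    dt: float = 0.001,
    grid: DirectionGrid | None = None,
    test_width: float = 15.0,
    test_amplitude: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Population response curves of V1 and MT for a set of probe stimuli.

    For each probe direction a test-stimulus segment is run from a frozen
    copy of the adapted efficacies (membrane potentials reset to rest, so the
    probe measures the synaptic aftereffect only); the time-averaged [v]⁺ of
    each area is reported, max-normalized per curve.  ``adapted_state`` is
    not mutated.  Returns arrays of shape (n_probes, n_units).
    """
    from .stimgen import test_direction_signal

    if grid is None:
        grid = DirectionGrid.full_circle(adapted_state.v_v1.size)
    kernel = direction_kernel(params.sigma_c, grid)
    probes = np.atleast_1d(np.asarray(probe_thetas, dtype=float))
    curves_v1 = np.zeros((probes.size, grid.n))
    curves_mt = np.zeros((probes.size, grid.n))
    for i, th in enumerate(probes):
        start = CircuitState(
            np.zeros(grid.n),
            np.zeros(grid.n),
            adapted_state.y_ff.copy(),
            adapted_state.y_fb.copy(),
            adapted_state.t,
        )
        sig = test_direction_signal(th, grid, width=test_width, amplitude=test_amplitude)
        res = run_segment(start, sig, probe_duration, dt, params, kernel=kernel)
        curves_v1[i] = res.mean_rect_v1
        curves_mt[i] = res.mean_rect_mt
    for curves in (curves_v1, curves_mt):
        peak = curves.max(axis=1, keepdims=True)
        np.divide(curves, peak, out=curves, where=peak > 0)
    return curves_v1, curves_mt


def adaptation_response(
    params: VariantParams,
    signal: DirectionSignal,
    duration: float = 0.3,
    dt: float = 0.001,
    kernel: np.ndarray | None = None,
    state: CircuitState | None = None,
) -> tuple[np.ndarray, np.ndarray, CircuitState]:
    """Normalized V1/MT population responses at the end of an adapting segment.

    Runs the circuit from rest (or ``state``) under the adapting signal and
    returns the rectified, max-normalized response profiles of both areas
    together with the final state.
    """
    start = state or CircuitState.resting(signal.grid)
    res = run_segment(start, signal, duration, dt, params, kernel=kernel)
    curves = []
    for v in (res.state.v_v1, res.state.v_mt):
        rect = _relu(v)
        peak = rect.max()
        curves.append(rect / peak if peak > 0 else rect)
    return curves[0], curves[1], res.state


def count_modes(
    values: np.ndarray, prominence_frac: float = 0.05, circular: bool = True
) -> list[int]:
    """Indices of local maxima with prominence above a fraction of the max.

    On circular profiles the array is unrolled by half a period on both
    sides so boundary peaks are counted once.
    """
    from scipy.signal import find_peaks

    values = np.asarray(values, dtype=float)
    n = values.size
    prominence = prominence_frac * values.max() if values.max() > 0 else np.inf
    if circular:
        ext = np.concatenate([values[-(n // 2):], values, values[: n // 2]])
        peaks, _ = find_peaks(ext, prominence=prominence)
        offset = n // 2
        return sorted({int((p - offset) % n) for p in peaks if offset <= p < offset + n})
    peaks, _ = find_peaks(values, prominence=prominence)
    return sorted(int(p) for p in peaks)


def peak_location(grid: DirectionGrid, values: np.ndarray) -> float:
    """Sub-grid peak direction via parabolic interpolation around the argmax."""
    values = np.asarray(values, dtype=float)
    i = int(np.argmax(values))
    if i == 0 or i == values.size - 1:
        return float(grid.angles[i])
    y0, y1, y2 = values[i - 1 : i + 2]
    denom = y0 - 2.0 * y1 + y2
    offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(grid.angles[i] + offset * grid.spacing)
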