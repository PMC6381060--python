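"""Model variants, experiment schedules, and simulated psychophysics runs.

Three method-of-constant-stimuli protocols probe the motion aftereffect at
different adaptation timescales.  Every experiment runs a down-skew (DSK)
adaptation block followed by an up-skew (USK) block with no state reset in
between (the carry-over is what produces the negative ΣPSE ordering bias):

* experiment 1 — sub-second exposure: 0.3 s top-up / 0.3 s blank ISI /
  0.3 s test, 12 test directions (±0.6°…±6.6°, step 1.2°) × 5 repetitions,
  randomized order;
* experiment 2 — minutes exposure: 180 s initial adaptation, then 15 s
  top-ups with 0.5 s ISI and 0.5 s tests, same test set, randomized order;
* experiment 3 — hysteresis: timing as experiment 1 but 14 test directions
  (−13°…13°, step 2°) presented sequentially, ascending for DSK and
  descending for USK, 4 cycles.

Five model variants cross circuit complexity (feedforward-only vs
recurrent feedforward-feedback) with synaptic rate regimes (fast, slow, or
both); variant 5 combines the fast FF rates of variant 3 with the slow FB
rates of variant 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import circuit, stimgen
from .circuit import CircuitState, VariantParams
from .grid import DirectionGrid, DirectionSignal
from .psychometrics import AftereffectSummary, aftereffect_summary, fit_psychometric, prediction_error

__all__ = [
    "EpisodeSchedule",
    "PatternCriteria",
    "variant_params",
    "build_schedule",
    "null_schedule",
    "mirrored_schedule",
    "adapt_signals",
    "run_experiment",
    "summarize_trials",
    "evaluate_variant_pattern",
]

_VARIANT_TABLE = {
    1: dict(lam=0.0, alpha_ff=0.0005, beta_ff=9.0, alpha_fb=0.0, beta_fb=0.0, temp=0.00001),
    2: dict(lam=0.0, alpha_ff=0.5, beta_ff=10.0, alpha_fb=0.0, beta_fb=0.0, temp=0.001),
    3: dict(lam=20.0, alpha_ff=1.0, beta_ff=10.0, alpha_fb=0.0, beta_fb=0.0, temp=0.001),
    4: dict(lam=20.0, alpha_ff=0.0, beta_ff=0.0, alpha_fb=0.04, beta_fb=1.2, temp=0.001),
    5: dict(lam=20.0, alpha_ff=1.0, beta_ff=10.0, alpha_fb=0.04, beta_fb=1.2, temp=0.001),
}


def variant_params(variant_id: int) -> VariantParams:
    """Exact parameter tuple of one of the five standard model variants."""
    if variant_id not in _VARIANT_TABLE:
        raise ValueError(f"unknown variant {variant_id!r}; valid ids are 1..5")
    return VariantParams(variant_id=variant_id, **_VARIANT_TABLE[variant_id])


# --------------------------------------------------------------------------
# schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EpisodeSchedule:
    """Timed protocol of one experiment.

    ``test_orders`` maps each adapting condition to the full ordered list of
    test directions presented in that block (repetitions already unrolled).
    Zero durations mean the segment is skipped (used by the no-adaptation
    control).
    """

    experiment_id: int
    conditions: tuple[str, ...]
    initial_adapt_s: float
    topup_s: float
    isi_s: float
    test_s: float
    test_orders: dict
    test_order_kind: str
    seed: int

    def __post_init__(self) -> None:
        if min(self.initial_adapt_s, self.topup_s, self.isi_s) < 0 or self.test_s <= 0:
            raise ValueError("segment durations must be non-negative, test > 0")

    def n_trials(self, condition: str) -> int:
        return len(self.test_orders[condition])


def _exp12_thetas() -> np.ndarray:
    # ±0.6° … ±6.6° in 1.2° steps: twelve directions, 0° excluded
    half = 0.6 + 1.2 * np.arange(6)
    return np.sort(np.concatenate([-half, half]))


def _exp3_thetas() -> np.ndarray:
    return np.arange(-13.0, 13.0 + 1e-9, 2.0)


def build_schedule(experiment_id: int, rng_seed: int = 0) -> EpisodeSchedule:
    """Schedule of one of the three experiments (DSK block then USK block)."""
    rng = np.random.default_rng(rng_seed)
    if experiment_id == 1 or experiment_id == 2:
        thetas = _exp12_thetas()
        reps = 5
        orders = {
            cond: rng.permutation(np.repeat(thetas, reps)).tolist()
            for cond in ("DSK", "USK")
        }
        if experiment_id == 1:
            timing = dict(initial_adapt_s=0.0, topup_s=0.3, isi_s=0.3, test_s=0.3)
        else:
            timing = dict(initial_adapt_s=180.0, topup_s=15.0, isi_s=0.5, test_s=0.5)
        kind = "randomized"
    elif experiment_id == 3:
        thetas = _exp3_thetas()
        cycles = 4
        orders = {
            "DSK": np.tile(thetas, cycles).tolist(),
            "USK": np.tile(thetas[::-1], cycles).tolist(),
        }
        timing = dict(initial_adapt_s=0.0, topup_s=0.3, isi_s=0.3, test_s=0.3)
        kind = "sequential"
    else:
        raise ValueError(f"unknown experiment {experiment_id!r}; valid ids are 1, 2, 3")
    return EpisodeSchedule(
        experiment_id=experiment_id,
        conditions=("DSK", "USK"),
        test_orders=orders,
        test_order_kind=kind,
        seed=rng_seed,
        **timing,
    )


def null_schedule(experiment_id: int, rng_seed: int = 0) -> EpisodeSchedule:
    """Same protocol with all adaptation segments removed (symmetry control)."""
    sched = build_schedule(experiment_id, rng_seed)
    return replace(sched, initial_adapt_s=0.0, topup_s=0.0)


def mirrored_schedule(schedule: EpisodeSchedule) -> EpisodeSchedule:
    """The up/down mirror image of a session.

    Reflecting the whole experiment about the horizontal maps the DSK-first
    session onto a USK-first session with negated test directions (each
    condition keeps its own statistics, which are mirror images by
    construction); every trial's P_up maps to P_down, so the fitted PSEs of
    corresponding blocks negate exactly.
    """
    orders = {
        cond: [-th for th in schedule.test_orders[other]]
        for cond, other in (("USK", "DSK"), ("DSK", "USK"))
    }
    return replace(
        schedule, conditions=tuple(reversed(schedule.conditions)), test_orders=orders
    )


# --------------------------------------------------------------------------
# running a session
# --------------------------------------------------------------------------

def adapt_signals(grid: DirectionGrid) -> dict:
    """Default DSK/USK adapting direction statistics on a grid."""
    dsk = stimgen.direction_stats_signal(stimgen.DirectionStatsModel.for_condition("DSK"), grid)
    usk = stimgen.direction_stats_signal(stimgen.DirectionStatsModel.for_condition("USK"), grid)
    return {"DSK": dsk, "USK": usk}


def run_experiment(
    params: VariantParams,
    schedule: EpisodeSchedule,
    grid: DirectionGrid | None = None,
    signals: dict | None = None,
    dt: float = 0.001,
    test_width: float = 15.0,
    test_amplitude: float = 0.1,
    state: CircuitState | None = None,
) -> pd.DataFrame:
    """Simulate one full session and return the trial table.

    The circuit state persists across all trials and across the two adapting
    blocks (no reset), as in the human sessions.  Each trial runs top-up →
    ISI → test; P_up is the softmax readout of the time-averaged rectified
    MT response over the test segment.
    """
    grid = grid or DirectionGrid.default()
    signals = signals or adapt_signals(grid)
    kernel = circuit.direction_kernel(params.sigma_c, grid)
    weights = circuit.readout_weights(grid)
    blank = DirectionSignal.zeros(grid)
    state = state or CircuitState.resting(grid)

    rows = []
    trial_idx = 0
    for cond in schedule.conditions:
        adapt = signals[cond]
        if schedule.initial_adapt_s > 0:
            state = circuit.run_segment(
                state, adapt, schedule.initial_adapt_s, dt, params, kernel=kernel
            ).state
        for theta in schedule.test_orders[cond]:
            if schedule.topup_s > 0:
                state = circuit.run_segment(
                    state, adapt, schedule.topup_s, dt, params, kernel=kernel
                ).state
            if schedule.isi_s > 0:
                state = circuit.run_segment(
                    state, blank, schedule.isi_s, dt, params, kernel=kernel
                ).state
            test_sig = stimgen.test_direction_signal(
                theta, grid, width=test_width, amplitude=test_amplitude
            )
            res = circuit.run_segment(
                state, test_sig, schedule.test_s, dt, params, kernel=kernel
            )
            state = res.state
            p_up, _ = circuit.readout(res.mean_rect_mt, weights, params.temp)
            rows.append(
                dict(
                    trial=trial_idx,
                    adapt_condition=cond,
                    theta_deg=float(theta),
                    p_up=p_up,
                    t_model_s=state.t,
                    seed=schedule.seed,
                )
            )
            trial_idx += 1
    return pd.DataFrame(rows)


def summarize_trials(trials: pd.DataFrame) -> dict:
    """Per-condition psychometric fits and the aftereffect summary.

    Returns ``{"fits": {cond: PsychometricFit|None}, "summary":
    AftereffectSummary|None}``; a degenerate or unconverged block leaves its
    fit as None and the summary as None.
    """
    fits = {}
    for cond, block in trials.groupby("adapt_condition"):
        try:
            fits[cond] = fit_psychometric(
                block["theta_deg"].to_numpy(), p_up=block["p_up"].to_numpy()
            )
        except ValueError:
            fits[cond] = None
    summary = None
    if fits.get("USK") and fits.get("DSK"):
        try:
            summary = aftereffect_summary(fits["USK"], fits["DSK"])
        except ValueError:
            summary = None
    return {"fits": fits, "summary": summary}


# --------------------------------------------------------------------------
# variant-comparison pattern
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternCriteria:
    """Sign-based pass criteria for one experiment cell.

    A cell passes when ΔPSE > ``delta_pse_min`` and ΣPSE < ``sum_pse_max``.
    Users with measured psychophysical intervals can supply them via
    ``reference_intervals`` as {(experiment, "delta_pse"|"sum_pse"):
    (lo, hi)}, which then also drive err_avg.
    """

    delta_pse_min: float = 0.1
    sum_pse_max: float = -0.02
    reference_intervals: dict | None = None

    def intervals(self, experiments) -> dict:
        if self.reference_intervals is not None:
            return self.reference_intervals
        out = {}
        for e in experiments:
            out[(e, "delta_pse")] = (self.delta_pse_min, None)
            out[(e, "sum_pse")] = (None, self.sum_pse_max)
        return out


def evaluate_variant_pattern(
    results: dict, criteria: PatternCriteria | None = None
) -> tuple[pd.DataFrame, dict]:
    """Score every (variant, experiment) cell against the pass criteria.

    ``results`` maps (variant_id, experiment_id) to an
    :class:`AftereffectSummary` (or None for a degenerate session, which
    fails its cell).  Returns the pattern table and per-variant err_avg.
    Missing cells are rejected.
    """
    criteria = criteria or PatternCriteria()
    variants = sorted({v for v, _ in results})
    experiments = sorted({e for _, e in results})
    for v in variants:
        for e in experiments:
            if (v, e) not in results:
                raise ValueError(f"missing result cell for variant {v}, experiment {e}")

    rows = []
    err_avg = {}
    intervals = criteria.intervals(experiments)
    for v in variants:
        predictions = {}
        for e in experiments:
            s = results[(v, e)]
            if s is None:
                d_pse, s_pse, ok = np.nan, np.nan, False
                # a degenerate block counts as the largest observed miss later
            else:
                d_pse, s_pse = s.delta_pse, s.sum_pse
                ok = d_pse > criteria.delta_pse_min and s_pse < criteria.sum_pse_max
                predictions[(e, "delta_pse")] = d_pse
                predictions[(e, "sum_pse")] = s_pse
            rows.append(
                dict(variant=v, experiment=e, delta_pse=d_pse, sum_pse=s_pse, passed=ok)
            )
        if predictions and len(predictions) == 2 * len(experiments):
            err_avg[v] = prediction_error(predictions, intervals).err_avg
        else:
            err_avg[v] = np.inf
    table = pd.DataFrame(rows).set_index(["variant", "experiment"])
    return table, err_avg
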