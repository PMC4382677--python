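"""The motion-categorization task: stimuli, trial protocol, decision
readout, training loop and frozen-weight evaluation.

A trial is a 200-ms pre-stimulus period (no external input), a 1-s motion
stimulus, and a 500-ms intertrial interval.  During the stimulus, sensory
units receive a periodic-Gaussian input current centred on the motion
direction, and both decision populations receive a small nonselective
gating current that puts the decision circuit in its winner-take-all
regime; during the first 300 ms of the intertrial interval a negative
reset current returns the decision circuit to the spontaneous state.  The
choice is read from the decision rates over the last 25 ms of the
stimulus: valid iff exactly one population is above 20 Hz and neither
crossed threshold before stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import (_ZIG_FN, _ZIG_KN, _ZIG_WN, build_rate_lut,
                       make_noise_state, ring_kernel_2n, run_trial_kernel)
from .circuit import preferred_directions, ring_coupling_matrix, wrapped_angle_diff
from .datasets import RateDataset
from .params import NetworkParams, TaskSpec
from .plasticity import (PlasticWeights, RewardExpectation, end_of_trial_update,
                         init_weights)

__all__ = [
    "VARIANTS",
    "TrialRecord",
    "TrainResult",
    "stimulus_current",
    "assign_category",
    "read_decision",
    "CircuitSimulator",
    "run_trial",
    "train",
    "frozen_evaluation",
    "psychometric",
    "percent_correct",
]

#: Network variants: ``feedback`` is the full model; ``no_feedback`` removes
#: the decision->association pathway; ``fixed_tuning`` additionally freezes
#: the sensory->association weights (a classical two-layer model).
VARIANTS = ("feedback", "no_feedback", "fixed_tuning")


def stimulus_current(theta_pref, theta_s, g_s: float, sigma_s: float):
    """Stimulus-evoked input current (nA) to a sensory unit."""
    delta = wrapped_angle_diff(theta_pref, theta_s)
    return g_s * np.exp(-np.square(delta) / (2.0 * sigma_s**2))


def assign_category(theta_deg: float, boundary_deg: float) -> str:
    """C1 for directions counterclockwise of the boundary axis, C2 otherwise."""
    rel = (theta_deg - boundary_deg) % 360.0
    if rel % 180.0 == 0.0:
        raise ValueError(f"direction {theta_deg} deg lies on the category boundary")
    return "C1" if 0.0 < rel < 180.0 else "C2"


def _decide(win1: float, win2: float, pre_max: float, threshold: float) -> str:
    if pre_max >= threshold:
        return "invalid"
    above1, above2 = win1 >= threshold, win2 >= threshold
    if above1 == above2:  # both or neither
        return "invalid"
    return "C1" if above1 else "C2"


def read_decision(r_c1, r_c2, n_prestim: int, n_window: int,
                  threshold: float = 20.0) -> str:
    """Choice from decision-population rate traces covering the pre-stimulus
    and stimulus periods.  The choice is the unique population whose mean
    rate over the last ``n_window`` samples exceeds ``threshold``; the trial
    is invalid if both or neither do, or if either crossed threshold during
    the first ``n_prestim`` samples."""
    r_c1 = np.asarray(r_c1, dtype=float)
    r_c2 = np.asarray(r_c2, dtype=float)
    if r_c1.shape != r_c2.shape or r_c1.ndim != 1:
        raise ValueError("rate traces must be 1-D and of equal length")
    if len(r_c1) < n_prestim + n_window:
        raise ValueError("rate traces must cover pre-stimulus and stimulus periods")
    pre_max = max(r_c1[:n_prestim].max(initial=0.0), r_c2[:n_prestim].max(initial=0.0))
    return _decide(r_c1[-n_window:].mean(), r_c2[-n_window:].mean(), pre_max, threshold)


@dataclass
class TrialRecord:
    trial: int
    theta_deg: float
    category: str
    choice: str                 # "C1" | "C2" | "invalid"
    valid: bool
    reward: float               # defined only on valid trials
    reward_expectation: float   # <R|theta> before this trial's update
    r_sensory: np.ndarray = field(repr=False, default=None)
    r_assoc: np.ndarray = field(repr=False, default=None)
    r_dec: np.ndarray = field(repr=False, default=None)


@dataclass
class TrainResult:
    trials: pd.DataFrame
    snapshots: dict            # trial index -> PlasticWeights
    weights: PlasticWeights
    tracker: RewardExpectation


class CircuitSimulator:
    """Stateful simulator binding parameters, task, weights and RNG.

    Gating and noise state persist across trials (as in a continuous
    session); weights change only through :meth:`learn_trial` /
    :meth:`train`.
    """

    def __init__(self, params: NetworkParams | None = None,
                 task: TaskSpec | None = None,
                 variant: str = "feedback",
                 weights: PlasticWeights | None = None,
                 rng: np.random.Generator | int | None = None):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        self.params = params or NetworkParams()
        self.task = task or TaskSpec()
        self.variant = variant
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.weights = weights.copy() if weights is not None else \
            init_weights(self.params, self.rng)
        self.tracker = RewardExpectation(tau_R=self.params.tau_R)
        self.trial_index = 0

        p, t = self.params, self.task
        G_ss = ring_coupling_matrix(p.n_sensory, p.J_plus_sens, p.J_minus_sens,
                                    p.sigma_conn)
        G_aa = ring_coupling_matrix(p.n_assoc, p.J_plus_assoc, p.J_minus_assoc,
                                    p.sigma_conn)
        self._c2_ss = ring_kernel_2n(G_ss[0])
        self._c2_aa = ring_kernel_2n(G_aa[0])
        # worst-case positive recurrent current per unit (fast-forward bound)
        self._bnd_ss = float(np.clip(G_ss[0], 0.0, None).sum() / p.n_sensory)
        self._bnd_aa = float(np.clip(G_aa[0], 0.0, None).sum() / p.n_assoc)
        self._lut, self._i_cut, self._inv_h = build_rate_lut(p.a, p.b, p.d)
        self._i_hi = 1.6
        self._pref_s = preferred_directions(p.n_sensory)
        self._stim_cache = {
            th: np.asarray(stimulus_current(self._pref_s, th, t.g_s, t.sigma_s),
                           dtype=np.float32)
            for th in t.directions_deg
        }
        self._n_pre = int(round(t.t_prestim / p.dt))
        self._n_stim = int(round(t.t_stim / p.dt))
        self._n_iti = int(round(t.t_intertrial / p.dt))
        self._n_reset = int(round(t.t_reset / p.dt))
        self._n_win = int(round(t.t_decision_window / p.dt))
        self._alpha = float(np.exp(-p.dt / p.tau_n))
        self._beta = p.sigma_n * float(np.sqrt(1.0 - self._alpha**2))
        # in-kernel bit-generator state for the high-volume noise stream,
        # seeded from the simulator's main generator
        self._noise_state = make_noise_state(self.rng)
        # gating / noise state (float32, matching the trial kernel)
        f32 = np.float32
        self._s = [np.zeros(p.n_sensory, f32), np.zeros(p.n_assoc, f32),
                   np.zeros(2, f32)]
        self._noise = [np.zeros(p.n_sensory, f32), np.zeros(p.n_assoc, f32),
                       np.zeros(2, f32)]

    # pathway presence/plasticity per variant
    @property
    def has_feedback(self) -> bool:
        return self.variant == "feedback"

    @property
    def plastic_sa(self) -> bool:
        return self.variant != "fixed_tuning"

    def _scaled_weights(self):
        p = self.params
        f32 = np.float32
        w_sa = ((p.g_max_sa / p.n_sensory) * self.weights.c_sa).astype(f32)
        w_ad = ((p.g_max_ad / p.n_assoc) * self.weights.c_ad).astype(f32)
        if self.has_feedback:
            w_da = ((p.g_max_da / 2.0) * self.weights.c_da).astype(f32)
        else:
            w_da = np.zeros((p.n_assoc, 2), f32)
        return w_sa, w_ad, w_da

    def run_trial(self, theta_s: float) -> TrialRecord:
        """Integrate one trial (no plasticity applied here)."""
        p, t = self.params, self.task
        w_sa, w_ad, w_da = self._scaled_weights()
        i_stim = self._stim_cache.get(theta_s)
        if i_stim is None:
            i_stim = stimulus_current(self._pref_s, theta_s, t.g_s, t.sigma_s)
        bounds = np.array([
            self._bnd_ss, self._bnd_aa,
            w_sa.sum(axis=1).max(), w_da.sum(axis=1).max(),
            w_ad.sum(axis=1).max(),
        ], dtype=np.float32)
        r_s = np.empty(p.n_sensory)
        r_a = np.empty(p.n_assoc)
        r_d = np.empty(2)
        win = np.empty(2)
        pre_max = run_trial_kernel(
            self._s[0], self._s[1], self._s[2],
            self._noise[0], self._noise[1], self._noise[2],
            self._c2_ss, self._c2_aa, p.J_dec_self, p.J_dec_cross,
            w_sa, w_ad, w_da,
            np.asarray(i_stim, dtype=np.float32), t.i_gate, t.i_reset,
            p.i_bg_sens, p.i_bg_assoc, p.i_bg_dec,
            self._n_pre, self._n_stim, self._n_iti, self._n_reset, self._n_win,
            self._alpha, self._beta, self._noise_state,
            _ZIG_KN, _ZIG_WN, _ZIG_FN, bounds,
            self._lut, self._i_cut, self._inv_h, self._i_hi,
            p.a, p.b, p.gamma, p.tau_s, p.dt,
            r_s, r_a, r_d, win,
        )
        if pre_max < 0.0:
            raise FloatingPointError(
                f"non-finite network state in trial {self.trial_index} "
                f"(theta={theta_s} deg); couplings may be unstable"
            )
        choice = _decide(win[0], win[1], pre_max, t.decision_threshold)
        category = assign_category(theta_s, t.boundary_deg)
        valid = choice != "invalid"
        reward = float(choice == category) if valid else np.nan
        rec = TrialRecord(
            trial=self.trial_index, theta_deg=theta_s, category=category,
            choice=choice, valid=valid, reward=reward,
            reward_expectation=self.tracker.expected(theta_s),
            r_sensory=r_s, r_assoc=r_a, r_dec=r_d,
        )
        self.trial_index += 1
        return rec

    def learn_trial(self, theta_s: float) -> TrialRecord:
        """One trial followed by the end-of-trial plasticity update."""
        rec = self.run_trial(theta_s)
        end_of_trial_update(
            self.weights, (rec.r_sensory, rec.r_assoc, rec.r_dec),
            rec.reward if rec.valid else 0.0, self.tracker, theta_s,
            self.params.q, rec.valid,
            plastic_sa=self.plastic_sa, plastic_ad=True,
            plastic_da=self.has_feedback,
        )
        return rec

    def train(self, n_trials: int, snapshot_schedule=() ,
              progress: bool = False) -> TrainResult:
        """Training loop: i.i.d. uniform stimulus per trial over the 12
        directions, trial integration, end-of-trial plasticity."""
        directions = np.asarray(self.task.directions_deg)
        schedule = set(int(k) for k in snapshot_schedule)
        snapshots: dict[int, PlasticWeights] = {}
        rows = []
        for k in range(n_trials):
            if self.trial_index in schedule:
                snapshots[self.trial_index] = self.weights.copy()
            theta = float(directions[self.rng.integers(len(directions))])
            rec = self.learn_trial(theta)
            rows.append((rec.trial, rec.theta_deg, rec.category, rec.choice,
                         rec.valid, rec.reward, rec.reward_expectation))
        if self.trial_index in schedule:
            snapshots[self.trial_index] = self.weights.copy()
        trials = pd.DataFrame(
            rows, columns=["trial", "theta_deg", "category", "choice", "valid",
                           "reward", "reward_expectation"])
        return TrainResult(trials=trials, snapshots=snapshots,
                           weights=self.weights, tracker=self.tracker)

    def frozen_evaluation(self, n_trials: int) -> RateDataset:
        """Trials with plasticity disabled; emits the trial x neuron rate
        table (sensory, association and decision units) with task labels."""
        p = self.params
        directions = np.asarray(self.task.directions_deg)
        n_neurons = p.n_sensory + p.n_assoc + 2
        rates = np.empty((n_trials, n_neurons))
        rows = []
        for k in range(n_trials):
            theta = float(directions[self.rng.integers(len(directions))])
            rec = self.run_trial(theta)
            rates[k] = np.concatenate([rec.r_sensory, rec.r_assoc, rec.r_dec])
            rows.append((rec.theta_deg, rec.category, rec.choice,
                         rec.choice == rec.category if rec.valid else False,
                         rec.valid))
        trials = pd.DataFrame(rows, columns=["theta_deg", "category", "choice",
                                             "correct", "valid"])
        neurons = pd.DataFrame({
            "population": (["sensory"] * p.n_sensory + ["assoc"] * p.n_assoc
                           + ["decision"] * 2),
            "pref_deg": np.concatenate([
                preferred_directions(p.n_sensory),
                preferred_directions(p.n_assoc),
                [np.nan, np.nan],
            ]),
        })
        return RateDataset(rates, trials, neurons)


# ---------------------------------------------------------------------------
# functional wrappers


def run_trial(weights: PlasticWeights, theta_s: float,
              params: NetworkParams | None = None, task: TaskSpec | None = None,
              rng=None, variant: str = "feedback") -> TrialRecord:
    sim = CircuitSimulator(params, task, variant, weights, rng)
    return sim.run_trial(theta_s)


def train(variant: str, n_trials: int, params: NetworkParams | None = None,
          task: TaskSpec | None = None, rng=None,
          snapshot_schedule=()) -> TrainResult:
    sim = CircuitSimulator(params, task, variant, None, rng)
    return sim.train(n_trials, snapshot_schedule)


def frozen_evaluation(weights: PlasticWeights, n_trials: int,
                      params: NetworkParams | None = None,
                      task: TaskSpec | None = None, rng=None,
                      variant: str = "feedback") -> RateDataset:
    sim = CircuitSimulator(params, task, variant, weights, rng)
    return sim.frozen_evaluation(n_trials)


# ---------------------------------------------------------------------------
# behavioural summaries


def percent_correct(trials: pd.DataFrame) -> float:
    """Percent correct among valid trials (NaN if no valid trial)."""
    valid = trials[trials["valid"].astype(bool)]
    if len(valid) == 0:
        return float("nan")
    return 100.0 * float(valid["reward"].mean())


def psychometric(trials: pd.DataFrame, task: TaskSpec | None = None,
                 epoch: slice | None = None) -> dict:
    """Percent correct by boundary distance (15/45/75 deg) and overall,
    over an epoch of the trial log.  Invalid trials are excluded from the
    denominators; an empty bin yields NaN."""
    task = task or TaskSpec()
    df = trials.iloc[epoch] if epoch is not None else trials
    out = {"overall": percent_correct(df)}
    dist = df["theta_deg"].map(task.boundary_distance)
    for d in (15.0, 45.0, 75.0):
        out[d] = percent_correct(df[np.isclose(dist, d)])
    return out
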