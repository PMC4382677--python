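"""Reward-prediction-error-modulated Hebbian plasticity.

At the end of every valid trial each plastic synapse is updated as

    c' = clip(c + q * (R - <R|theta>) * r_pre * r_post, 0, 1)

where ``r_pre``/``r_post`` are trial-averaged stimulus-period rates, R is the
binary reward and <R|theta> the stimulus-specific reward expectation, tracked
as a first-order running average with time constant ``tau_R`` trials.  The
RPE factor (R - <R|theta>) is shared by all synapses within a trial, and the
expectation tracker is updated only after the weight update, so the RPE uses
the pre-trial expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import preferred_directions, wrapped_angle_diff
from .params import NetworkParams

__all__ = [
    "PlasticWeights",
    "RewardExpectation",
    "hebbian_update",
    "update_reward_expectation",
    "init_weights",
    "end_of_trial_update",
]


@dataclass
class PlasticWeights:
    """The three plastic pathways, entrywise in [0, 1].

    c_sa: (n_assoc, n_sensory) sensory -> association
    c_ad: (2, n_assoc) association -> decision
    c_da: (n_assoc, 2) decision -> association feedback
    """

    c_sa: np.ndarray
    c_ad: np.ndarray
    c_da: np.ndarray

    def copy(self) -> "PlasticWeights":
        return PlasticWeights(self.c_sa.copy(), self.c_ad.copy(), self.c_da.copy())

    def check(self) -> None:
        for name in ("c_sa", "c_ad", "c_da"):
            c = getattr(self, name)
            if np.any(c < 0.0) or np.any(c > 1.0):
                raise ValueError(f"plastic weights {name} out of [0, 1]")


class RewardExpectation:
    """Per-stimulus running average of reward history.

    E' = E + (R - E) / tau_R, one independent tracker per distinct stimulus,
    initialized at 0.5 (chance reward in a two-category task) when a stimulus
    is first seen.
    """

    def __init__(self, tau_R: float = 5.0, initial: float = 0.5):
        if tau_R < 1.0:
            raise ValueError("tau_R must be >= 1 trial")
        self.tau_R = float(tau_R)
        self.initial = float(initial)
        self._table: dict[float, float] = {}

    def expected(self, theta) -> float:
        return self._table.get(float(theta), self.initial)

    def update(self, theta, R: float) -> float:
        e = self.expected(theta)
        e = min(1.0, max(0.0, e + (R - e) / self.tau_R))
        self._table[float(theta)] = e
        return e

    def as_dict(self) -> dict[float, float]:
        return dict(self._table)


def hebbian_update(c, r_pre, r_post, R: float, R_expected: float, q: float):
    """One reward-modulated Hebbian step; supports scalars or an outer
    product of rate vectors (r_post as column, r_pre as row)."""
    if q <= 0:
        raise ValueError("learning rate q must be positive")
    c = np.asarray(c, dtype=float)
    rpe = R - R_expected
    hebb = np.multiply.outer(np.asarray(r_post, dtype=float),
                             np.asarray(r_pre, dtype=float)) if c.ndim == 2 else \
        np.asarray(r_post, dtype=float) * np.asarray(r_pre, dtype=float)
    out = np.clip(c + q * rpe * hebb, 0.0, 1.0)
    return out if out.ndim else float(out)


def update_reward_expectation(tracker: RewardExpectation, theta, R: float) -> float:
    if R not in (0, 1, 0.0, 1.0):
        raise ValueError("reward must be binary")
    return tracker.update(theta, R)


def init_weights(params: NetworkParams, rng: np.random.Generator) -> PlasticWeights:
    """Initial plastic weights.

    The sensory->association pathway carries the periodic Gaussian profile
    over the preferred-direction difference (peak 1 on the diagonal), so
    association neurons start out direction-tuned like naive parietal
    neurons; the pathways to and from the decision circuit start
    unstructured, i.i.d. uniform on [0.25, 0.75].
    """
    th_a = preferred_directions(params.n_assoc)
    th_s = preferred_directions(params.n_sensory)
    delta = wrapped_angle_diff(th_a[:, None], th_s[None, :])
    c_sa = np.exp(-np.square(delta) / (2.0 * params.sigma_sa_init**2))
    c_ad = rng.uniform(0.25, 0.75, size=(2, params.n_assoc))
    c_da = rng.uniform(0.25, 0.75, size=(params.n_assoc, 2))
    return PlasticWeights(c_sa=c_sa, c_ad=c_ad, c_da=c_da)


def end_of_trial_update(weights: PlasticWeights, trial_rates, R: float,
                        tracker: RewardExpectation, theta, q: float,
                        valid: bool, *, plastic_sa: bool = True,
                        plastic_ad: bool = True, plastic_da: bool = True) -> None:
    """Apply the Hebbian rule to every plastic pathway after one trial.

    ``trial_rates`` is the triple (r_sensory, r_assoc, r_dec) of
    stimulus-period mean rates.  All pathways use pre-update rates and the
    shared RPE, so update order within the trial is immaterial.  On invalid
    trials nothing changes, including the reward-expectation tracker.
    Pathway flags implement the network variants (absent/frozen pathways).
    """
    if not valid:
        return
    r_s, r_a, r_d = trial_rates
    rpe_args = dict(R=R, R_expected=tracker.expected(theta), q=q)
    if plastic_sa:
        weights.c_sa = hebbian_update(weights.c_sa, r_s, r_a, **rpe_args)
    if plastic_ad:
        weights.c_ad = hebbian_update(weights.c_ad, r_a, r_d, **rpe_args)
    if plastic_da:
        weights.c_da = hebbian_update(weights.c_da, r_d, r_a, **rpe_args)
    tracker.update(theta, R)
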