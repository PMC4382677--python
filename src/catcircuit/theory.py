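"""Analytical core of the learning rule.

The reward-modulated Hebbian rule produces an expected per-trial weight
change proportional to the covariance between reward and neural activity,

    <dc | theta> = q Cov[R, N | theta],      N = r_pre r_post.

Conditioning on the (discrete) choice gives the general decomposition

    Cov[R, N | theta] = sum_i P_i R_i N_i - (sum_i P_i R_i)(sum_i P_i N_i)

which for two-choice tasks collapses to

    Cov[R, N | theta] = P_1 P_2 (R_1 - R_2)(N_1 - N_2).

The factor (N_1 - N_2) is monotonically related to choice probability (CP),
the ROC area between the choice-conditioned rate distributions; for two
equal-variance Gaussians CP = Phi((N_1 - N_2) / (sqrt(2) sd)).  The
toy-model neuron demonstrates the consequence directly: a single synapse
updated by the Hebbian rule drifts at a rate set by the sign and magnitude
of CP - 0.5, and performs an unbiased random walk when CP = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .plasticity import RewardExpectation, hebbian_update

__all__ = [
    "ChoiceConditionedSpec",
    "ToyNeuronSpec",
    "covariance_decomposition",
    "mc_covariance_oracle",
    "cp_gaussian",
    "toy_neuron_run",
    "expected_toy_drift",
]


@dataclass
class ChoiceConditionedSpec:
    """Choice-conditioned expectations for one stimulus.

    probs: P_i, choice probabilities (sum to 1); rewards: R_i = <R|C_i>;
    activities: N_i = <N|C_i>.
    """

    probs: np.ndarray
    rewards: np.ndarray
    activities: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.rewards = np.asarray(self.rewards, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if not (self.probs.shape == self.rewards.shape == self.activities.shape):
            raise ValueError("probs, rewards and activities must have equal length")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("choice probabilities must be nonnegative and sum to 1")


def covariance_decomposition(spec: ChoiceConditionedSpec) -> float:
    """Cov[R, N | theta] from choice-conditioned expectations.

    Evaluates the general n-choice form; for n = 2 the product form
    P1 P2 (R1 - R2)(N1 - N2) is evaluated as well and asserted equal
    (they are algebraically identical).
    """
    P, R, N = spec.probs, spec.rewards, spec.activities
    general = float(np.sum(P * R * N) - np.sum(P * R) * np.sum(P * N))
    if len(P) == 2:
        two = float(P[0] * P[1] * (R[0] - R[1]) * (N[0] - N[1]))
        if abs(general - two) > 1e-10 * max(1.0, abs(general)):
            raise AssertionError("two-choice factorization mismatch "
                                 f"({general} vs {two})")
    return general


def mc_covariance_oracle(spec: ChoiceConditionedSpec, n_samples: int,
                         rng: np.random.Generator,
                         reward_sd: float = 0.0,
                         activity_sd: float = 0.0,
                         return_se: bool = False):
    """Brute-force Monte-Carlo estimate of Cov[R, N | theta].

    Samples a choice per trial, then reward and activity around their
    choice-conditioned means (optionally with independent Gaussian spread,
    which leaves the covariance unchanged), and returns the sample
    covariance; with ``return_se`` also its standard error, estimated from
    the spread of the centered cross products.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    choice = rng.choice(len(spec.probs), size=n_samples, p=spec.probs)
    R = spec.rewards[choice]
    N = spec.activities[choice]
    if reward_sd > 0:
        R = R + reward_sd * rng.standard_normal(n_samples)
    if activity_sd > 0:
        N = N + activity_sd * rng.standard_normal(n_samples)
    prod = (R - R.mean()) * (N - N.mean())
    cov = float(prod.sum() / (n_samples - 1))
    if not return_se:
        return cov
    se = float(prod.std(ddof=1) / np.sqrt(n_samples))
    return cov, se


def cp_gaussian(N1: float, N2: float, sd: float) -> float:
    """Choice probability for two equal-variance Gaussian rate distributions.

    The ROC area between N(N1, sd^2) (choice C1 trials) and N(N2, sd^2)
    (choice C2 trials): CP = Phi((N1 - N2) / (sqrt(2) sd)).  CP > 0.5 means
    the neuron fires more before C1 choices.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    return float(norm.cdf((N1 - N2) / (np.sqrt(2.0) * sd)))


@dataclass
class ToyNeuronSpec:
    """Single neuron whose rate is choice-correlated; C1 choices rewarded.

    Rates are Gaussian with choice-dependent mean (N1, N2) and common
    spread ``sd`` (5 Hz default; the choice-conditioned dispersion is
    specified as a standard deviation).  Both choices are equally likely,
    the partner rate is fixed at 1, and the synapse starts at 0.5.
    """

    N1: float = 55.0
    N2: float = 50.0
    sd: float = 5.0
    p_choice1: float = 0.5
    q: float = 3.0e-5
    tau_R: float = 5.0
    c0: float = 0.5
    partner_rate: float = 1.0

    @property
    def cp(self) -> float:
        return cp_gaussian(self.N1, self.N2, self.sd)


def toy_neuron_run(spec: ToyNeuronSpec, n_trials: int, seed=None) -> np.ndarray:
    """Weight trajectory of the toy-model synapse over ``n_trials``.

    Per trial: draw the choice (P(C1) = p_choice1), draw the rate from the
    choice-conditioned Gaussian, reward iff C1, apply the RPE-modulated
    Hebbian update with the running-average reward expectation (a single
    tracker: there is one implicit stimulus).  Returns the weight after
    each trial (length n_trials + 1 including the initial value).
    """
    rng = np.random.default_rng(seed)
    tracker = RewardExpectation(tau_R=spec.tau_R)
    theta = 0.0
    c = spec.c0
    out = np.empty(n_trials + 1)
    out[0] = c
    choices = rng.random(n_trials) < spec.p_choice1
    zs = rng.standard_normal(n_trials)
    for k in range(n_trials):
        is_c1 = choices[k]
        rate = (spec.N1 if is_c1 else spec.N2) + spec.sd * zs[k]
        R = 1.0 if is_c1 else 0.0
        c = hebbian_update(c, spec.partner_rate, rate, R,
                           tracker.expected(theta), spec.q)
        tracker.update(theta, R)
        out[k + 1] = c
    return out


def expected_toy_drift(spec: ToyNeuronSpec) -> float:
    """Predicted mean per-trial weight drift q P1 P2 (R1 - R2)(N1 - N2),
    valid once the reward expectation has settled at P(C1) and away from
    the weight bounds."""
    dec = covariance_decomposition(ChoiceConditionedSpec(
        probs=[spec.p_choice1, 1.0 - spec.p_choice1],
        rewards=[1.0, 0.0],
        activities=[spec.N1 * spec.partner_rate, spec.N2 * spec.partner_rate],
    ))
    return spec.q * dec
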