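"""Mean-field population dynamics of the three-circuit model.

Each excitatory population is summarized by a single gating variable ``s``
(the fraction of activated NMDA-receptor conductance) obeying

    ds/dt = -s / tau_s + (1 - s) * gamma * r(I),

with the firing rate given by the f-I curve

    r(I) = (a I - b) / (1 - exp(-d (a I - b))).

Sensory and association circuits are rings of ``n`` units with periodic
Gaussian recurrent coupling; the decision circuit is two scalar populations
with self-excitation and cross-inhibition (winner-take-all).  Background
synaptic input is an Ornstein-Uhlenbeck current per unit.

These are the reference (pure NumPy) implementations; the trial-level fast
path in :mod:`catcircuit._kernels` is cross-checked against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import NetworkParams

__all__ = [
    "transfer_rate",
    "wrapped_angle_diff",
    "gaussian_coupling",
    "ring_coupling_matrix",
    "recurrent_current",
    "ou_noise_step",
    "gating_step",
    "NetworkState",
    "step_network",
    "preferred_directions",
]

# below this value of d*(aI-b) the closed form is evaluated by series
_SERIES_CUTOFF = 1e-6


def transfer_rate(I, params: NetworkParams | None = None, *, a=None, b=None, d=None):
    """Firing rate (Hz) as a function of total synaptic current (nA).

    The singularity at a*I - b = 0 is removable; the limit is 1/d.  Near it
    the ratio u / (1 - exp(-u)) is evaluated by its series 1 + u/2 + u^2/12.
    """
    if params is not None:
        a, b, d = params.a, params.b, params.d
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("transfer_rate: input current must be finite")
    x = a * I - b
    u = d * x
    with np.errstate(over="ignore", invalid="ignore"):
        r = np.where(
            np.abs(u) < _SERIES_CUTOFF,
            (1.0 + 0.5 * u + u * u / 12.0) / d,
            x / (1.0 - np.exp(-u)),
        )
    return r if r.ndim else float(r)


def wrapped_angle_diff(theta_i, theta_j):
    """Angular difference wrapped to [0, 180] degrees."""
    delta = np.abs((np.asarray(theta_i, dtype=float) - theta_j + 180.0) % 360.0 - 180.0)
    return delta if np.ndim(delta) else float(delta)


def gaussian_coupling(theta_i, theta_j, J_plus, J_minus, sigma_conn):
    """Periodic Gaussian coupling profile (nA) between two preferred directions."""
    delta = wrapped_angle_diff(theta_i, theta_j)
    return J_minus + (J_plus - J_minus) * np.exp(-np.square(delta) / (2.0 * sigma_conn**2))


def preferred_directions(n: int) -> np.ndarray:
    """Equally spaced preferred directions on [0, 360) degrees."""
    return np.arange(n) * (360.0 / n)


def ring_coupling_matrix(n: int, J_plus: float, J_minus: float, sigma_conn: float) -> np.ndarray:
    """Full n x n recurrent coupling matrix of a ring circuit (nA)."""
    theta = preferred_directions(n)
    return gaussian_coupling(theta[:, None], theta[None, :], J_plus, J_minus, sigma_conn)


def recurrent_current(s_pre: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Recurrent input current per postsynaptic unit, normalized by the
    number of presynaptic units: I_i = (1/N_pre) sum_j g_ij s_j."""
    s_pre = np.asarray(s_pre, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] != s_pre.shape[0]:
        raise ValueError(
            f"recurrent_current: coupling matrix {G.shape} incompatible "
            f"with presynaptic vector of length {s_pre.shape[0]}"
        )
    return G @ s_pre / s_pre.shape[0]


def ou_noise_step(I_noise, dt: float, tau_n: float, sigma_n: float, rng: np.random.Generator):
    """Exact one-step update of the Ornstein-Uhlenbeck background current.

    I' = I e^(-dt/tau_n) + sigma_n sqrt(1 - e^(-2 dt/tau_n)) z,  z ~ N(0,1).

    Zero mean, stationary SD ``sigma_n``, correlation time ``tau_n`` hold
    exactly for any ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    I_noise = np.asarray(I_noise, dtype=float)
    alpha = np.exp(-dt / tau_n)
    beta = sigma_n * np.sqrt(1.0 - alpha * alpha)
    return alpha * I_noise + beta * rng.standard_normal(I_noise.shape)


def _ds_dt(s, r, gamma, tau_s):
    # r in Hz -> 1/ms
    return -s / tau_s + (1.0 - s) * gamma * (r / 1000.0)


def gating_step(s, r, dt: float, params: NetworkParams):
    """Heun (predictor-corrector) update of the gating variable for a rate
    held fixed over the step.  The result is clipped to [0, 1]; for rates
    r >= 0 and dt well below tau_s the update stays inside on its own."""
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    k1 = _ds_dt(s, r, params.gamma, params.tau_s)
    s_pred = s + dt * k1
    k2 = _ds_dt(s_pred, r, params.gamma, params.tau_s)
    out = np.clip(s + 0.5 * dt * (k1 + k2), 0.0, 1.0)
    return out if out.ndim else float(out)


@dataclass
class NetworkState:
    """Instantaneous state of all populations at one time step."""

    s_sensory: np.ndarray       # (n_sensory,), gating fractions in [0, 1]
    s_assoc: np.ndarray         # (n_assoc,)
    s_dec: np.ndarray           # (2,)
    noise_sensory: np.ndarray   # OU currents, nA
    noise_assoc: np.ndarray
    noise_dec: np.ndarray
    r_sensory: np.ndarray = field(default=None)  # rates from the last step, Hz
    r_assoc: np.ndarray = field(default=None)
    r_dec: np.ndarray = field(default=None)

    @classmethod
    def zeros(cls, params: NetworkParams) -> "NetworkState":
        ns, na = params.n_sensory, params.n_assoc
        return cls(
            s_sensory=np.zeros(ns), s_assoc=np.zeros(na), s_dec=np.zeros(2),
            noise_sensory=np.zeros(ns), noise_assoc=np.zeros(na), noise_dec=np.zeros(2),
            r_sensory=np.zeros(ns), r_assoc=np.zeros(na), r_dec=np.zeros(2),
        )


def _total_currents(state_s, state_a, state_d, noise, ext, G_ss, G_aa, J_dec,
                    W_sa, W_ad, W_da, i_bg):
    """Total synaptic current per population given gating vectors.

    ``W_*`` are the plastic pathway matrices already scaled by g_max and
    normalized by their presynaptic counts; ``i_bg`` is the per-circuit
    constant background drive.
    """
    I_s = G_ss @ state_s / state_s.shape[0] + noise[0] + ext[0] + i_bg[0]
    I_a = (G_aa @ state_a / state_a.shape[0] + W_sa @ state_s + W_da @ state_d
           + noise[1] + ext[1] + i_bg[1])
    I_d = J_dec @ state_d + W_ad @ state_a + noise[2] + ext[2] + i_bg[2]
    return I_s, I_a, I_d


def step_network(state: NetworkState, weights, external_currents, params: NetworkParams,
                 rng: np.random.Generator | None = None) -> NetworkState:
    """Advance the full network by one integration step ``dt`` (Heun scheme).

    ``weights`` is a :class:`catcircuit.plasticity.PlasticWeights`;
    ``external_currents`` is a triple of per-population external input
    arrays (sensory, association, decision), in nA.  The OU noise is
    updated once per step and held fixed across the two Heun stages.
    With ``rng=None`` the noise currents are left unchanged (deterministic).
    """
    p = params
    G_ss = ring_coupling_matrix(p.n_sensory, p.J_plus_sens, p.J_minus_sens, p.sigma_conn)
    G_aa = ring_coupling_matrix(p.n_assoc, p.J_plus_assoc, p.J_minus_assoc, p.sigma_conn)
    J_dec = np.array([[p.J_dec_self, p.J_dec_cross], [p.J_dec_cross, p.J_dec_self]])
    W_sa = p.g_max_sa * weights.c_sa / p.n_sensory
    W_ad = p.g_max_ad * weights.c_ad / p.n_assoc
    W_da = p.g_max_da * weights.c_da / 2.0

    if rng is not None:
        noise = (
            ou_noise_step(state.noise_sensory, p.dt, p.tau_n, p.sigma_n, rng),
            ou_noise_step(state.noise_assoc, p.dt, p.tau_n, p.sigma_n, rng),
            ou_noise_step(state.noise_dec, p.dt, p.tau_n, p.sigma_n, rng),
        )
    else:
        noise = (state.noise_sensory, state.noise_assoc, state.noise_dec)

    i_bg = (p.i_bg_sens, p.i_bg_assoc, p.i_bg_dec)

    def deriv(ss, sa, sd):
        I_s, I_a, I_d = _total_currents(ss, sa, sd, noise, external_currents,
                                        G_ss, G_aa, J_dec, W_sa, W_ad, W_da, i_bg)
        r_s, r_a, r_d = transfer_rate(I_s, p), transfer_rate(I_a, p), transfer_rate(I_d, p)
        return (_ds_dt(ss, r_s, p.gamma, p.tau_s),
                _ds_dt(sa, r_a, p.gamma, p.tau_s),
                _ds_dt(sd, r_d, p.gamma, p.tau_s)), (r_s, r_a, r_d)

    k1, rates = deriv(state.s_sensory, state.s_assoc, state.s_dec)
    pred = tuple(np.clip(s + p.dt * k, 0.0, 1.0)
                 for s, k in zip((state.s_sensory, state.s_assoc, state.s_dec), k1))
    k2, _ = deriv(*pred)
    new_s = tuple(
        np.clip(s + 0.5 * p.dt * (a + b), 0.0, 1.0)
        for s, a, b in zip((state.s_sensory, state.s_assoc, state.s_dec), k1, k2)
    )
    for arr in new_s:
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(
                "step_network: non-finite gating variable encountered; "
                "check couplings and external currents"
            )
    return NetworkState(
        s_sensory=new_s[0], s_assoc=new_s[1], s_dec=new_s[2],
        noise_sensory=noise[0], noise_assoc=noise[1], noise_dec=noise[2],
        r_sensory=rates[0], r_assoc=rates[1], r_dec=rates[2],
    )
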