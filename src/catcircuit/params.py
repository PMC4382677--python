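"""Parameter containers for the three-circuit category-learning model.

Units convention: time in ms, rates in Hz, currents in nA, angles in degrees.
The single place where mixed units meet is the gating equation
``ds/dt = -s/tau_s + (1 - s) * gamma * r``, where ``r`` (Hz = 1/s) is
converted to 1/ms so that ``dt`` in ms can be used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass
class NetworkParams:
    """All circuit, coupling, noise and plasticity constants.

    The f-I curve, gating kinetics, noise process and decision-circuit
    recurrent couplings follow the standard reduced mean-field model of
    NMDA-dominated cortical populations.  The ring-circuit recurrent
    couplings (``J_plus``/``J_minus`` per circuit) and the maximal plastic
    strengths ``g_max_*`` were set by the calibration scan shipped in
    ``catcircuit.calibrate`` (see docs/calibration.md).
    """

    # gating kinetics
    gamma: float = 0.641           # dimensionless kinetic factor
    tau_s: float = 60.0            # gating time constant, ms

    # f-I transfer function r(I) = (a I - b) / (1 - exp(-d (a I - b)))
    a: float = 270.0               # gain, Hz/nA
    b: float = 108.0               # offset, Hz
    d: float = 0.154               # curvature, s

    # ring connectivity (sensory and association circuits)
    sigma_conn: float = 43.2       # Gaussian footprint width, deg
    J_plus_sens: float = 2.4       # peak recurrent coupling, nA (calibrated)
    J_minus_sens: float = -2.0     # baseline recurrent coupling, nA (calibrated)
    J_plus_assoc: float = 0.2      # (calibrated)
    J_minus_assoc: float = -0.5    # (calibrated)

    # background noise (Ornstein-Uhlenbeck current per unit)
    tau_n: float = 2.0             # noise time constant, ms
    sigma_n: float = 0.009         # stationary noise SD, nA

    # constant background current per circuit, nA (calibrated).  The f-I
    # offset b = 108 Hz puts the firing threshold near 0.4 nA of total
    # current, so each unit needs a tonic depolarizing drive (the I0 of the
    # reduced mean-field model family) for the 0.1-nA stimulus to ignite
    # recurrent activity; defaults keep the spontaneous state quiescent.
    i_bg_sens: float = 0.25
    i_bg_assoc: float = 0.255
    i_bg_dec: float = 0.33

    # decision circuit (two scalar populations, no ring structure)
    J_dec_self: float = 0.3725     # nA
    J_dec_cross: float = -0.1137   # nA

    # plastic pathway maximal strengths, nA (calibrated)
    g_max_sa: float = 1.15         # sensory -> association
    g_max_ad: float = 0.45         # association -> decision
    g_max_da: float = 0.10         # decision -> association (feedback)
    # width of the initial Gaussian profile of the sensory->association
    # weights, deg (calibrated; sets how broad association tuning starts)
    sigma_sa_init: float = 70.0

    # plasticity
    q: float = 3.0e-5              # learning rate
    tau_R: float = 5.0             # reward-expectation time constant, trials

    # geometry / integration
    n_sensory: int = 128
    n_assoc: int = 128
    dt: float = 1.0                # integration step, ms

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_s <= 0 or self.tau_n <= 0:
            raise ValueError("time constants must be positive")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be nonnegative")
        if self.J_minus_sens >= self.J_plus_sens:
            raise ValueError("sensory circuit requires J_minus < J_plus")
        if self.J_minus_assoc >= self.J_plus_assoc:
            raise ValueError("association circuit requires J_minus < J_plus")
        if self.n_sensory < 2 or self.n_assoc < 2:
            raise ValueError("need at least two units per ring circuit")

    def replace(self, **kw) -> "NetworkParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown NetworkParams keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TaskSpec:
    """Motion-categorization task protocol.

    Twelve directions at +-15, +-45, +-75 degrees around each side of the
    category boundary axis; no direction lies on the boundary itself.
    """

    boundary_deg: float = 0.0          # category boundary axis, deg
    # trial timing, ms
    t_prestim: float = 200.0
    t_stim: float = 1000.0
    t_intertrial: float = 500.0
    t_reset: float = 300.0             # reset-current window at ITI start
    # external currents
    g_s: float = 0.1                   # stimulus peak current, nA
    sigma_s: float = 43.2              # stimulus tuning width, deg
    i_gate: float = 0.01               # nonselective gating to decision, nA
    i_reset: float = -0.08             # reset current to decision, nA
    # decision readout
    decision_threshold: float = 20.0   # Hz
    t_decision_window: float = 25.0    # last part of stimulus, ms

    def __post_init__(self) -> None:
        for name in ("t_prestim", "t_stim", "t_intertrial", "t_reset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.t_reset > self.t_intertrial:
            raise ValueError("reset window cannot exceed the intertrial interval")
        if self.t_decision_window > self.t_stim:
            raise ValueError("decision window cannot exceed the stimulus period")

    @property
    def directions_deg(self) -> list[float]:
        offsets = (15.0, 45.0, 75.0, 105.0, 135.0, 165.0,
                   195.0, 225.0, 255.0, 285.0, 315.0, 345.0)
        return [(self.boundary_deg + o) % 360.0 for o in offsets]

    def boundary_distance(self, theta_deg: float) -> float:
        """Angular distance (deg) from a direction to the boundary axis."""
        delta = (theta_deg - self.boundary_deg) % 180.0
        return min(delta, 180.0 - delta)

    def replace(self, **kw) -> "TaskSpec":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TaskSpec keys: {sorted(unknown)}")
        return cls(**d)
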