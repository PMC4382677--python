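"""Numba-compiled trial integrator (fast path).

Runs one full trial (pre-stimulus, stimulus, intertrial) of the three-circuit
model at ``dt`` resolution.  Semantics match
:func:`catcircuit.circuit.step_network` (Heun scheme, OU noise updated once
per step and frozen across the two Heun stages, rates recorded at the
step-start state); a cross-check test enforces agreement with the NumPy
reference.

Performance choices (documented in docs/methods.md; the induced errors are
far below the background-noise scale of the dynamics):

* float32 state and matrices;
* the f-I curve is evaluated from a dense lookup table with linear
  interpolation (absolute error < 2e-3 Hz); rates are truncated to zero
  below 0.36 Hz (u = d(aI-b) <= -4), so the spontaneous state is silent;
* the fixed ring couplings are circulant and applied as sliding dots
  against a length-2N kernel vector;
* the plastic sensory->association matrix is traversed once per step,
  producing the feedforward currents of both Heun stages together;
* the OU noise innovations come from an in-kernel ziggurat normal sampler
  driven by a small counter-based generator (seeded per simulator from
  the user's seed; validated against SciPy in the test suite);
* silent stretches of the pre-stimulus, reset and post-reset intertrial
  windows are advanced in closed form (exponential gating decay, exact OU
  jump) once a conservative current bound certifies every rate stays 0.

The integrator is deliberately split into small compiled helpers: numba
generates much better machine code for short, single-purpose loops than
for one monolithic function.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["run_trial_kernel", "ring_kernel_2n", "build_rate_lut",
           "make_noise_state", "normal_fill", "RATE_U_CUTOFF"]

F32 = np.float32

#: rates with u = d*(a*I-b) at or below this value are truncated to zero
RATE_U_CUTOFF = -4.0


def ring_kernel_2n(G_row0: np.ndarray) -> np.ndarray:
    """Doubled circulant kernel (already normalized by N) for sliding dots.

    ``G_row0`` is row 0 of the ring coupling matrix; row i is the same
    vector rotated, so I = G s / N becomes I_i = dot(c2[N-i:2N-i], s) with
    c2 the doubled, N-normalized kernel.
    """
    k = np.asarray(G_row0, dtype=np.float64) / G_row0.shape[0]
    return np.concatenate([k, k]).astype(F32)


def build_rate_lut(a: float, b: float, d: float, n: int = 4096,
                   i_hi: float = 1.6):
    """Tabulate r(I) on [I_cut, i_hi] for linear interpolation.

    Below I_cut (where u = RATE_U_CUTOFF) the rate is truncated to 0; above
    ``i_hi`` the curve is numerically exactly a*I - b.  Returns
    (lut, i_cut, inv_h).
    """
    i_cut = (b + RATE_U_CUTOFF / d) / a
    grid = np.linspace(i_cut, i_hi, n)
    x = a * grid - b
    u = d * x
    with np.errstate(over="ignore"):
        vals = np.where(np.abs(u) < 1e-9, 1.0 / d, x / (1.0 - np.exp(-u)))
    inv_h = (n - 1) / (i_hi - i_cut)
    return vals.astype(F32), float(i_cut), float(inv_h)


# ---------------------------------------------------------------------------
# in-kernel normal sampler: SFC64 bit generator + Marsaglia-Tsang ziggurat

def _build_ziggurat():
    m = 2147483648.0  # 2^31
    dn = 3.442619855899
    tn = dn
    vn = 9.91256303526217e-3
    kn = np.zeros(128, dtype=np.int64)
    wn = np.zeros(128)
    fn = np.zeros(128)
    q = vn / math.exp(-0.5 * dn * dn)
    kn[0] = int((dn / q) * m)
    kn[1] = 0
    wn[0] = q / m
    wn[127] = dn / m
    fn[0] = 1.0
    fn[127] = math.exp(-0.5 * dn * dn)
    for i in range(126, 0, -1):
        dn = math.sqrt(-2.0 * math.log(vn / dn + math.exp(-0.5 * dn * dn)))
        kn[i + 1] = int((dn / tn) * m)
        tn = dn
        fn[i] = math.exp(-0.5 * dn * dn)
        wn[i] = dn / m
    return kn, wn, fn


_ZIG_KN, _ZIG_WN, _ZIG_FN = _build_ziggurat()
_ZIG_R = 3.442619855899


def make_noise_state(seed_source) -> np.ndarray:
    """Fresh state for the in-kernel bit generator.

    ``seed_source`` is a numpy Generator (or an int); the four 64-bit words
    are drawn from it, so the whole run remains reproducible from one seed.
    """
    rng = seed_source if isinstance(seed_source, np.random.Generator) \
        else np.random.default_rng(seed_source)
    state = rng.integers(1, 2**63 - 1, size=4, dtype=np.uint64)
    for _ in range(12):  # warm up so poor seeds decorrelate
        _next_u64(state)
    return state


@njit(cache=True, inline="always")
def _next_u64(st):
    """SFC64 step on a 4-word uint64 state array."""
    t = st[0] + st[1] + st[3]
    st[3] += np.uint64(1)
    st[0] = st[1] ^ (st[1] >> np.uint64(11))
    st[1] = st[2] + (st[2] << np.uint64(3))
    st[2] = ((st[2] << np.uint64(24)) | (st[2] >> np.uint64(40))) + t
    return t


@njit(cache=True, inline="never")
def _znorm_slow(st, kn, wn, fn, j, i):
    """Ziggurat wedge/tail handling after a fast-path rejection at (j, i);
    loops over fresh draws until acceptance."""
    while True:
        if i == 0:
            # tail beyond r
            while True:
                u1 = np.float64(_next_u64(st) >> np.uint64(11)) * 1.1102230246251565e-16
                u2 = np.float64(_next_u64(st) >> np.uint64(11)) * 1.1102230246251565e-16
                x = -math.log(u1 + 1e-300) / _ZIG_R
                y = -math.log(u2 + 1e-300)
                if y + y > x * x:
                    return _ZIG_R + x if j > 0 else -(_ZIG_R + x)
        else:
            x = j * wn[i]
            u3 = np.float64(_next_u64(st) >> np.uint64(11)) * 1.1102230246251565e-16
            if fn[i] + u3 * (fn[i - 1] - fn[i]) < math.exp(-0.5 * x * x):
                return x
        u = _next_u64(st)
        j = np.int64(u & np.uint64(0xFFFFFFFF))
        if j >= 2147483648:
            j -= 4294967296
        i = np.int64(u >> np.uint64(32)) & 127
        ja = j if j >= 0 else -j
        if ja < kn[i]:
            return j * wn[i]


@njit(cache=True)
def normal_fill(st, kn, wn, fn, out):
    """Fill ``out`` with standard normals (the fast accept path is written
    out inline so the loop stays branch-predictable and register-resident)."""
    for k in range(out.shape[0]):
        u = _next_u64(st)
        j = np.int64(u & np.uint64(0xFFFFFFFF))
        if j >= 2147483648:
            j -= 4294967296
        i = np.int64(u >> np.uint64(32)) & 127
        ja = j if j >= 0 else -j
        if ja < kn[i]:
            out[k] = j * wn[i]
        else:
            out[k] = _znorm_slow(st, kn, wn, fn, j, i)


@njit(cache=True, fastmath=True)
def _ou_step(st, kn, wn, fn, noise, af, bf):
    """One exact OU update of a noise-current array."""
    for k in range(noise.shape[0]):
        u = _next_u64(st)
        j = np.int64(u & np.uint64(0xFFFFFFFF))
        if j >= 2147483648:
            j -= 4294967296
        i = np.int64(u >> np.uint64(32)) & 127
        ja = j if j >= 0 else -j
        if ja < kn[i]:
            z = j * wn[i]
        else:
            z = _znorm_slow(st, kn, wn, fn, j, i)
        noise[k] = af * noise[k] + bf * F32(z)


@njit(cache=True, fastmath=True)
def _ou_jump(st, kn, wn, fn, noise, s, a_T, b_T, dec_T):
    """Closed-form T-step advance of silent units: gating decays, noise
    takes one exact OU jump."""
    for k in range(noise.shape[0]):
        u = _next_u64(st)
        j = np.int64(u & np.uint64(0xFFFFFFFF))
        if j >= 2147483648:
            j -= 4294967296
        i = np.int64(u >> np.uint64(32)) & 127
        ja = j if j >= 0 else -j
        if ja < kn[i]:
            z = j * wn[i]
        else:
            z = _znorm_slow(st, kn, wn, fn, j, i)
        noise[k] = a_T * noise[k] + b_T * F32(z)
        v = s[k] * dec_T
        # flush to zero before float32 denormal territory
        s[k] = v if v > F32(1e-12) else F32(0.0)


# ---------------------------------------------------------------------------
# per-step helpers

@njit(cache=True, fastmath=True)
def _conv_ring(c2, s, out):
    n = s.shape[0]
    for i in range(n):
        base = n - i
        acc = F32(0.0)
        for j in range(n):
            acc += c2[base + j] * s[j]
        out[i] = acc


@njit(cache=True, fastmath=True)
def _fused_ff(W, s, sp, W_da, sd0, sd1, f1, f2):
    """Association extra input in one traversal of W: f1 = W @ s plus the
    stage-1 feedback from the decision pair; f2 = W @ sp (the stage-2
    feedback is added later, once the decision predictor exists)."""
    for i in range(W.shape[0]):
        a1 = F32(0.0)
        a2 = F32(0.0)
        Wi = W[i]
        for j in range(W.shape[1]):
            a1 += Wi[j] * s[j]
            a2 += Wi[j] * sp[j]
        f1[i] = a1 + W_da[i, 0] * sd0 + W_da[i, 1] * sd1
        f2[i] = a2


@njit(cache=True, fastmath=True)
def _add_feedback(f, W_da, sd0, sd1):
    for i in range(f.shape[0]):
        f[i] += W_da[i, 0] * sd0 + W_da[i, 1] * sd1


@njit(cache=True, fastmath=True)
def _lut_rates(I, lut, i_cut, inv_h, a, b, i_hi, r):
    ic = F32(i_cut)
    ih = F32(i_hi)
    iv = F32(inv_h)
    af = F32(a)
    bf = F32(b)
    for i in range(I.shape[0]):
        x = I[i]
        if x <= ic:
            r[i] = F32(0.0)
        elif x >= ih:
            r[i] = af * x - bf
        else:
            p = (x - ic) * iv
            k = int(p)
            w = p - F32(k)
            r[i] = lut[k] * (F32(1.0) - w) + lut[k + 1] * w


@njit(cache=True, fastmath=True)
def _heun_predict(s, r, gam, inv_tau, dtf, ds1, sp):
    """Stage 1: ds1 = f(s, r); sp = clip(s + dt ds1)."""
    for i in range(s.shape[0]):
        d = -s[i] * inv_tau + (F32(1.0) - s[i]) * gam * r[i]
        ds1[i] = d
        v = s[i] + dtf * d
        if v < F32(1e-12):   # clip at 0, flushing float32 denormals
            v = F32(0.0)
        elif v > F32(1.0):
            v = F32(1.0)
        sp[i] = v


@njit(cache=True, fastmath=True)
def _heun_correct(s, sp, r2, ds1, gam, inv_tau, half):
    """Stage 2: s = clip(s + dt/2 (ds1 + f(sp, r2)))."""
    for i in range(s.shape[0]):
        d2 = -sp[i] * inv_tau + (F32(1.0) - sp[i]) * gam * r2[i]
        v = s[i] + half * (ds1[i] + d2)
        if v < F32(1e-12):   # clip at 0, flushing float32 denormals
            v = F32(0.0)
        elif v > F32(1.0):
            v = F32(1.0)
        s[i] = v


@njit(cache=True, fastmath=True)
def _stage1(conv, extra, noise, i_bg, stim, use_stim, lut, i_cut, inv_h,
            a, b, i_hi, s, r_out, ds1, sp, gam, inv_tau, dtf):
    """Fused stage-1 pass: current assembly, rate lookup, Heun predictor.

    ``extra`` holds per-unit additional synaptic input (feedforward and
    feedback terms); pass a zero-length array to skip it.
    """
    ic = F32(i_cut)
    ih = F32(i_hi)
    iv = F32(inv_h)
    af = F32(a)
    bf = F32(b)
    ibg = F32(i_bg)
    has_extra = extra.shape[0] == s.shape[0]
    for i in range(s.shape[0]):
        x = conv[i] + noise[i] + ibg
        if has_extra:
            x += extra[i]
        if use_stim:
            x += stim[i]
        if x <= ic:
            r = F32(0.0)
        elif x >= ih:
            r = af * x - bf
        else:
            p = (x - ic) * iv
            k = int(p)
            w = p - F32(k)
            r = lut[k] * (F32(1.0) - w) + lut[k + 1] * w
        r_out[i] = r
        d = -s[i] * inv_tau + (F32(1.0) - s[i]) * gam * r
        ds1[i] = d
        v = s[i] + dtf * d
        if v < F32(1e-12):
            v = F32(0.0)
        elif v > F32(1.0):
            v = F32(1.0)
        sp[i] = v


@njit(cache=True, fastmath=True)
def _stage2(conv, extra, noise, i_bg, stim, use_stim, lut, i_cut, inv_h,
            a, b, i_hi, s, sp, ds1, gam, inv_tau, half):
    """Fused stage-2 pass at the predictor state: assembly, rate lookup,
    Heun corrector writing the new gating into ``s``."""
    ic = F32(i_cut)
    ih = F32(i_hi)
    iv = F32(inv_h)
    af = F32(a)
    bf = F32(b)
    ibg = F32(i_bg)
    has_extra = extra.shape[0] == s.shape[0]
    for i in range(s.shape[0]):
        x = conv[i] + noise[i] + ibg
        if has_extra:
            x += extra[i]
        if use_stim:
            x += stim[i]
        if x <= ic:
            r = F32(0.0)
        elif x >= ih:
            r = af * x - bf
        else:
            p = (x - ic) * iv
            k = int(p)
            w = p - F32(k)
            r = lut[k] * (F32(1.0) - w) + lut[k + 1] * w
        d2 = -sp[i] * inv_tau + (F32(1.0) - sp[i]) * gam * r
        v = s[i] + half * (ds1[i] + d2)
        if v < F32(1e-12):
            v = F32(0.0)
        elif v > F32(1.0):
            v = F32(1.0)
        s[i] = v


@njit(cache=True, fastmath=True)
def _accum(dst, src):
    for i in range(src.shape[0]):
        dst[i] += src[i]


# ---------------------------------------------------------------------------
# trial integrator

@njit(cache=True, fastmath=True)
def run_trial_kernel(s_s, s_a, s_d, n_s, n_a, n_d,
                     c2_ss, c2_aa, Jds, Jdx, W_sa, W_ad, W_da,
                     I_stim, i_gate, i_reset, i_bg_s, i_bg_a, i_bg_d,
                     n_pre, n_stim, n_iti, n_reset, n_win,
                     alpha, beta, rng_state, zkn, zwn, zfn,
                     bounds, lut, i_cut, inv_h, i_hi,
                     a, b, gamma, tau_s, dt,
                     r_s_mean, r_a_mean, r_d_mean, dec_win_mean):
    """Integrate one trial; gating/noise/rng state arrays update in place.

    Array arguments are float32 except the float64 output means and the
    uint64 ``rng_state``.  ``bounds`` holds worst-case current coefficients
    (bnd_ss, bnd_aa, bnd_sa, bnd_da, bnd_ad) for the silent fast-forward
    test.  Returns the maximum decision rate seen during the pre-stimulus
    period, or -1.0 on a non-finite state.
    """
    Ns = s_s.shape[0]
    Na = s_a.shape[0]
    n_steps = n_pre + n_stim + n_iti
    t_stim_on = n_pre
    t_stim_off = n_pre + n_stim
    t_reset_off = t_stim_off + n_reset

    gam = F32(gamma * 1e-3)
    inv_tau = F32(1.0 / tau_s)
    dtf = F32(dt)
    half = F32(0.5 * dt)
    af = F32(alpha)
    bf = F32(beta)
    # one Heun step of pure decay (r = 0): s *= 1 - dt/tau + dt^2/(2 tau^2)
    decay_h = 1.0 - dt / tau_s + dt * dt / (2.0 * tau_s * tau_s)
    sigma_n = beta / math.sqrt(max(1.0 - alpha * alpha, 1e-30))
    noise_margin = F32(4.0 * sigma_n)

    f1 = np.empty(Na, dtype=F32)
    f2 = np.empty(Na, dtype=F32)
    conv_s = np.empty(Ns, dtype=F32)
    conv_a = np.empty(Na, dtype=F32)
    I_d = np.empty(2, dtype=F32)
    empty_extra = np.empty(0, dtype=F32)
    rec_s = np.empty(Ns, dtype=F32)
    rec_a = np.empty(Na, dtype=F32)
    rec_d = np.empty(2, dtype=F32)
    r2_d = np.empty(2, dtype=F32)
    ds1_s = np.empty(Ns, dtype=F32)
    ds1_a = np.empty(Na, dtype=F32)
    ds1_d = np.empty(2, dtype=F32)
    sp_s = np.empty(Ns, dtype=F32)
    sp_a = np.empty(Na, dtype=F32)
    sp_d = np.empty(2, dtype=F32)

    for i in range(Ns):
        r_s_mean[i] = 0.0
    for i in range(Na):
        r_a_mean[i] = 0.0
    for k in range(2):
        r_d_mean[k] = 0.0
        dec_win_mean[k] = 0.0
    pre_max = 0.0

    t = 0
    while t < n_steps:
        stim_on = t_stim_on <= t < t_stim_off
        in_reset = t_stim_off <= t < t_reset_off
        gate = F32(i_gate) if stim_on else (F32(i_reset) if in_reset else F32(0.0))

        # ---- ring fast-forward over external-input-free stretches --------
        # Both rings must be certifiably silent (rates pinned at 0); the
        # two decision units keep integrating exactly, with the association
        # feedforward input decaying in closed form alongside the silent
        # association gating.  The reset current is part of ``gate``.
        if not stim_on:
            if t < t_stim_on:
                t_end = t_stim_on
            elif in_reset:
                t_end = t_reset_off
            else:
                t_end = n_steps
            if t_end - t > 1:
                smax = F32(0.0)
                amax = F32(0.0)
                dmax = F32(0.0)
                for i in range(Ns):
                    if s_s[i] > smax:
                        smax = s_s[i]
                for i in range(Na):
                    if s_a[i] > amax:
                        amax = s_a[i]
                for k in range(2):
                    if s_d[k] > dmax:
                        dmax = s_d[k]
                i_sb = F32(i_bg_s) + bounds[0] * smax + noise_margin
                i_ab = (F32(i_bg_a) + bounds[1] * amax + bounds[2] * smax
                        + bounds[3] * dmax + noise_margin)
                icut = F32(i_cut)
                if i_sb < icut and i_ab < icut:
                    ff0 = F32(0.0)
                    ff1 = F32(0.0)
                    for j in range(Na):
                        ff0 += W_ad[0, j] * s_a[j]
                        ff1 += W_ad[1, j] * s_a[j]
                    dec_1 = F32(decay_h)
                    T = 0
                    while t + T < t_end:
                        # decision-pair step (rings silent), same Heun
                        # scheme and noise ordering as the full path
                        _ou_step(rng_state, zkn, zwn, zfn, n_d, af, bf)
                        I_d[0] = (F32(Jds) * s_d[0] + F32(Jdx) * s_d[1]
                                  + ff0 + n_d[0] + gate + F32(i_bg_d))
                        I_d[1] = (F32(Jds) * s_d[1] + F32(Jdx) * s_d[0]
                                  + ff1 + n_d[1] + gate + F32(i_bg_d))
                        _lut_rates(I_d, lut, i_cut, inv_h, a, b, i_hi, rec_d)
                        _heun_predict(s_d, rec_d, gam, inv_tau, dtf, ds1_d, sp_d)
                        I_d[0] = (F32(Jds) * sp_d[0] + F32(Jdx) * sp_d[1]
                                  + ff0 + n_d[0] + gate + F32(i_bg_d))
                        I_d[1] = (F32(Jds) * sp_d[1] + F32(Jdx) * sp_d[0]
                                  + ff1 + n_d[1] + gate + F32(i_bg_d))
                        _lut_rates(I_d, lut, i_cut, inv_h, a, b, i_hi, r2_d)
                        _heun_correct(s_d, sp_d, r2_d, ds1_d, gam, inv_tau, half)
                        if t + T < t_stim_on:
                            if rec_d[0] > pre_max:
                                pre_max = rec_d[0]
                            if rec_d[1] > pre_max:
                                pre_max = rec_d[1]
                        ff0 *= dec_1
                        ff1 *= dec_1
                        amax *= dec_1
                        smax *= dec_1
                        T += 1
                        # decision growth can reopen the association bound
                        dmax = s_d[0] if s_d[0] > s_d[1] else s_d[1]
                        i_ab = (F32(i_bg_a) + bounds[1] * amax
                                + bounds[2] * smax + bounds[3] * dmax
                                + noise_margin)
                        if i_ab >= icut:
                            break
                    if T > 0:
                        dec_T = F32(decay_h ** T)
                        a_T = F32(alpha ** T)
                        b_T = F32(sigma_n * math.sqrt(1.0 - alpha ** (2 * T)))
                        _ou_jump(rng_state, zkn, zwn, zfn, n_s, s_s, a_T, b_T, dec_T)
                        _ou_jump(rng_state, zkn, zwn, zfn, n_a, s_a, a_T, b_T, dec_T)
                        t += T
                        continue

        # ---- OU noise: exact update, once per step -----------------------
        _ou_step(rng_state, zkn, zwn, zfn, n_s, af, bf)
        _ou_step(rng_state, zkn, zwn, zfn, n_a, af, bf)
        _ou_step(rng_state, zkn, zwn, zfn, n_d, af, bf)

        # ---- stage 1 -----------------------------------------------------
        _conv_ring(c2_ss, s_s, conv_s)
        _stage1(conv_s, empty_extra, n_s, i_bg_s, I_stim, stim_on,
                lut, i_cut, inv_h, a, b, i_hi,
                s_s, rec_s, ds1_s, sp_s, gam, inv_tau, dtf)

        _fused_ff(W_sa, s_s, sp_s, W_da, s_d[0], s_d[1], f1, f2)

        _conv_ring(c2_aa, s_a, conv_a)
        _stage1(conv_a, f1, n_a, i_bg_a, I_stim, False,
                lut, i_cut, inv_h, a, b, i_hi,
                s_a, rec_a, ds1_a, sp_a, gam, inv_tau, dtf)

        for k in range(2):
            acc = F32(0.0)
            Wk = W_ad[k]
            for j in range(Na):
                acc += Wk[j] * s_a[j]
            I_d[k] = (F32(Jds) * s_d[k] + F32(Jdx) * s_d[1 - k] + acc
                      + n_d[k] + gate + F32(i_bg_d))
        _lut_rates(I_d, lut, i_cut, inv_h, a, b, i_hi, rec_d)
        _heun_predict(s_d, rec_d, gam, inv_tau, dtf, ds1_d, sp_d)

        # ---- stage 2 at the predictor state ------------------------------
        _conv_ring(c2_ss, sp_s, conv_s)
        _stage2(conv_s, empty_extra, n_s, i_bg_s, I_stim, stim_on,
                lut, i_cut, inv_h, a, b, i_hi,
                s_s, sp_s, ds1_s, gam, inv_tau, half)

        _add_feedback(f2, W_da, sp_d[0], sp_d[1])
        _conv_ring(c2_aa, sp_a, conv_a)
        _stage2(conv_a, f2, n_a, i_bg_a, I_stim, False,
                lut, i_cut, inv_h, a, b, i_hi,
                s_a, sp_a, ds1_a, gam, inv_tau, half)

        for k in range(2):
            acc = F32(0.0)
            Wk = W_ad[k]
            for j in range(Na):
                acc += Wk[j] * sp_a[j]
            I_d[k] = (F32(Jds) * sp_d[k] + F32(Jdx) * sp_d[1 - k] + acc
                      + n_d[k] + gate + F32(i_bg_d))
        _lut_rates(I_d, lut, i_cut, inv_h, a, b, i_hi, r2_d)
        _heun_correct(s_d, sp_d, r2_d, ds1_d, gam, inv_tau, half)

        # ---- recording (rates at the step-start state) -------------------
        if t < t_stim_on:
            if rec_d[0] > pre_max:
                pre_max = rec_d[0]
            if rec_d[1] > pre_max:
                pre_max = rec_d[1]
        elif stim_on:
            _accum(r_s_mean, rec_s)
            _accum(r_a_mean, rec_a)
            for k in range(2):
                r_d_mean[k] += rec_d[k]
            if t >= t_stim_off - n_win:
                for k in range(2):
                    dec_win_mean[k] += rec_d[k]
        t += 1

    inv = 1.0 / n_stim
    for i in range(Ns):
        r_s_mean[i] *= inv
    for i in range(Na):
        r_a_mean[i] *= inv
    for k in range(2):
        r_d_mean[k] *= inv
        dec_win_mean[k] /= n_win
    ok = True
    for i in range(Ns):
        if not np.isfinite(s_s[i]):
            ok = False
    for i in range(Na):
        if not np.isfinite(s_a[i]):
            ok = False
    for k in range(2):
        if not np.isfinite(s_d[k]):
            ok = False
    if not ok:
        return -1.0
    return pre_max
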