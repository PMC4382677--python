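"""Neural-data statistics for trial x neuron firing-rate tables.

All estimators operate on a :class:`~catcircuit.datasets.RateDataset` and
are agnostic about whether the rates came from the circuit model, the
synthetic-fixture generator, or (z-scored) experimental recordings:

* ROC area (rank-sum formulation with half-credit ties);
* category-tuning index (CTI): contrast of between- vs within-category
  mean-rate differences over direction pairs;
* category sensitivity (CS): ROC area separating correct-trial rates of
  the two categories;
* choice probability (CP): per-stimulus ROC area between rates preceding
  C1 and C2 choices, averaged over stimuli passing the trial-count rule,
  with a within-stimulus shuffle test;
* direction (exponential-cosine) and category (step) tuning fits and the
  ridge-GLM classification of tuning into direction/category/mixed/none;
* noise correlations (per-stimulus Pearson on correct trials, averaged);
* Hartigan's dip test for bimodality of preferred directions;
* classical (Torgerson) multidimensional scaling of the population
  representation of the stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import RateDataset
from .task import assign_category

__all__ = [
    "roc_area",
    "cti",
    "tuning_curve_cti",
    "category_sensitivity",
    "choice_probability",
    "cp_shuffle_test",
    "infer_choice_from_match",
    "noise_correlations",
    "TuningFit",
    "fit_direction_tuning",
    "fit_category_tuning",
    "width_constraint_band",
    "glm_classify",
    "dip_statistic",
    "dip_test",
    "classical_mds",
    "analyze_neurons",
]


# ---------------------------------------------------------------------------
# ROC / CP / CS

def roc_area(x, y) -> float:
    """P(x > y) + 0.5 P(x = y) over all pairs (area under the ROC curve).

    Computed from the Mann-Whitney U statistic, which implements exactly
    the rank-sum-with-half-ties convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("roc_area: both samples must be nonempty")
    u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    return float(u) / (x.size * y.size)


def category_sensitivity(ds: RateDataset, neuron: int) -> float:
    """ROC area between correct-trial rates for category C1 vs C2.

    1 means strong C1 preference, 0 strong C2 preference, 0.5 none.
    NaN when either category lacks correct trials.
    """
    t = ds.trials
    correct = t["correct"].to_numpy(dtype=bool) & t["valid"].to_numpy(dtype=bool)
    cat = t["category"].to_numpy()
    x = ds.rates[correct & (cat == "C1"), neuron]
    y = ds.rates[correct & (cat == "C2"), neuron]
    if x.size == 0 or y.size == 0:
        return float("nan")
    return roc_area(x, y)


def _cp_per_stimulus(rates, theta, choice, valid, min_trials):
    """(stimulus, CP) pairs for stimuli passing the trial-count rule."""
    out = {}
    for th in np.unique(theta[valid]):
        m = valid & (theta == th)
        x = rates[m & (choice == "C1")]
        y = rates[m & (choice == "C2")]
        if x.size >= min_trials and y.size >= min_trials:
            out[float(th)] = roc_area(x, y)
    return out


def choice_probability(ds: RateDataset, neuron: int, min_trials: int = 3,
                       return_details: bool = False):
    """Neuron-level choice probability.

    Per qualifying stimulus (at least ``min_trials`` valid trials for each
    choice), the ROC area between rates on C1-choice and C2-choice trials;
    the neuron's CP is the unweighted mean over qualifying stimuli.
    CP > 0.5 means higher rates precede C1 choices.  Returns NaN unless the
    neuron has a valid per-stimulus CP for at least one stimulus in each
    category (the inclusion rule).
    """
    t = ds.trials
    theta = t["theta_deg"].to_numpy(dtype=float)
    choice = t["choice"].to_numpy()
    valid = t["valid"].to_numpy(dtype=bool)
    cat = t["category"].to_numpy()
    per = _cp_per_stimulus(ds.rates[:, neuron], theta, choice, valid, min_trials)
    cats = {str(cat[np.argmax(theta == th)]) for th in per}
    ok = {"C1", "C2"} <= cats
    cp = float(np.mean(list(per.values()))) if (per and ok) else float("nan")
    if return_details:
        return cp, per
    return cp


def cp_shuffle_test(ds: RateDataset, neuron: int, n_shuffles: int = 1000,
                    rng=None, min_trials: int = 3) -> tuple[float, float]:
    """Shuffle test for a neuron's CP.

    Choice labels are permuted within each stimulus (trial counts
    preserved) and the neuron CP recomputed ``n_shuffles`` times.  The
    observed CP is compared against the null sample with a t-statistic
    (observed minus null mean over null SD); the two-sided p-value uses the
    null sample's t distribution.  Returns (cp, p).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t = ds.trials
    theta = t["theta_deg"].to_numpy(dtype=float)
    choice = t["choice"].to_numpy().copy()
    valid = t["valid"].to_numpy(dtype=bool)
    rates = ds.rates[:, neuron]
    cp = choice_probability(ds, neuron, min_trials)
    if np.isnan(cp):
        return cp, float("nan")
    null = np.empty(n_shuffles)
    shuffled = choice.copy()
    for k in range(n_shuffles):
        for th in np.unique(theta[valid]):
            m = np.flatnonzero(valid & (theta == th))
            shuffled[m] = choice[m][rng.permutation(m.size)]
        per = _cp_per_stimulus(rates, theta, shuffled, valid, min_trials)
        null[k] = np.mean(list(per.values())) if per else 0.5
    sd = null.std(ddof=1)
    if sd == 0:
        return cp, float(cp == null.mean())
    z = (cp - null.mean()) / sd
    p = 2.0 * stats.t.sf(abs(z), df=n_shuffles - 1)
    return cp, float(p)


def infer_choice_from_match(test_category: str, response: str,
                            test_distance_deg: float) -> str | None:
    """Infer the subject's sample-category decision in a match-to-category
    design.  Only trials whose test stimulus was far from the boundary
    (45 or 75 deg) qualify; a match response implies the test's category,
    a nonmatch response the other one.  Returns None for excluded trials.
    """
    if response not in ("match", "nonmatch"):
        raise ValueError(f"unknown response {response!r}")
    if test_category not in ("C1", "C2"):
        raise ValueError(f"unknown category {test_category!r}")
    if not np.isclose(test_distance_deg, 45.0) and not np.isclose(test_distance_deg, 75.0):
        return None
    other = "C2" if test_category == "C1" else "C1"
    return test_category if response == "match" else other


# ---------------------------------------------------------------------------
# CTI

def tuning_curve_cti(mean_rates, categories, directions_deg=None) -> float:
    """CTI from per-direction mean rates and their category labels.

    (BCD - WCD) / (BCD + WCD), where BCD/WCD are the mean absolute rate
    differences over between-/within-category direction pairs.  Pairs are
    compared at matched angular separations (mean within each separation,
    then averaged over the separations at which both pair types exist);
    without this matching any unimodal tuning curve would score ~+0.2
    simply because between-category pairs are farther apart on average.
    +1 means purely categorical tuning, 0 no categorical structure (or a
    flat curve, by convention).
    """
    r = np.asarray(mean_rates, dtype=float)
    cats = np.asarray(categories)
    if r.shape != cats.shape:
        raise ValueError("rates and category labels must align")
    n = r.size
    if directions_deg is None:
        directions_deg = np.arange(n) * 360.0 / n  # equally spaced
    th = np.asarray(directions_deg, dtype=float)
    by_sep: dict = {}
    for i in range(n):
        for j in range(i + 1, n):
            sep = abs(th[i] - th[j]) % 360.0
            sep = round(min(sep, 360.0 - sep), 6)
            slot = by_sep.setdefault(sep, ([], []))
            slot[0 if cats[i] == cats[j] else 1].append(abs(r[i] - r[j]))
    wcd_list, bcd_list = [], []
    for sep, (within, between) in by_sep.items():
        if within and between:
            wcd_list.append(np.mean(within))
            bcd_list.append(np.mean(between))
    if not wcd_list:
        raise ValueError("no separation has both within- and between-category pairs")
    bcd = float(np.mean(bcd_list))
    wcd = float(np.mean(wcd_list))
    if bcd + wcd == 0:
        return 0.0
    return (bcd - wcd) / (bcd + wcd)


def cti(ds: RateDataset, neuron: int, boundary_deg: float = 0.0) -> float:
    """Category-tuning index of one neuron from all its valid trials."""
    curve = ds.tuning_curve(neuron)
    cats = [assign_category(th, boundary_deg) for th in curve.index]
    return tuning_curve_cti(curve.to_numpy(), np.asarray(cats),
                            curve.index.to_numpy())


# ---------------------------------------------------------------------------
# noise correlations

def noise_correlations(ds: RateDataset) -> np.ndarray:
    """Pairwise noise-correlation matrix.

    Pearson correlation of rates across correct trials within each
    stimulus, averaged over stimuli; diagonal 1.  Stimuli where either
    neuron has zero variance are skipped for that pair; a pair with no
    usable stimulus gets NaN.
    """
    t = ds.trials
    ok = t["correct"].to_numpy(dtype=bool) & t["valid"].to_numpy(dtype=bool)
    theta = t["theta_deg"].to_numpy(dtype=float)
    n = ds.n_neurons
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n), dtype=int)
    for th in np.unique(theta[ok]):
        m = ok & (theta == th)
        if m.sum() < 2:
            continue
        block = ds.rates[m]
        sd = block.std(axis=0)
        good = sd > 0
        if good.sum() < 2:
            continue
        c = np.corrcoef(block[:, good], rowvar=False)
        idx = np.flatnonzero(good)
        acc[np.ix_(idx, idx)] += c
        cnt[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        out = acc / cnt
    np.fill_diagonal(out, 1.0)
    return out


# ---------------------------------------------------------------------------
# tuning fits and GLM classification

@dataclass
class TuningFit:
    """Fitted tuning profiles and GLM classification for one neuron."""

    r0: float = np.nan          # baseline of the direction fit
    rmax: float = np.nan        # amplitude of the direction fit
    w_deg: float = np.nan       # tuning width (deg, as fitted)
    theta0_deg: float = np.nan  # preferred direction (deg)
    cat_means: tuple = (np.nan, np.nan)   # step profile (C1, C2 mean rate)
    beta: tuple = (np.nan, np.nan, np.nan)  # (direction, category, baseline)
    p_beta: tuple = (np.nan, np.nan)         # shuffle p-values (dir, cat)
    ridge_lambda: float = np.nan
    label: str = "nonselective"  # direction | category | mixed | nonselective
    converged: bool = True


def _dir_profile(theta_deg, r0, rmax, w_deg, theta0_deg):
    w_rad = np.deg2rad(w_deg)
    return r0 + rmax * np.exp((np.cos(np.deg2rad(theta_deg - theta0_deg)) - 1.0)
                              / w_rad**2)


def fit_direction_tuning(theta_deg, rates, w_bounds=(10.0, 360.0)) -> TuningFit:
    """Least-squares fit of the exponential-cosine direction profile

        r(theta) = r0 + rmax exp((cos(theta - theta0) - 1) / w_rad^2)

    with ``w`` expressed in degrees (converted to radians inside the
    exponent).  ``w_bounds`` optionally box-constrains the width (used by
    the population two-pass procedure).  A non-convergent or degenerate
    fit is returned flagged with ``converged=False``.
    """
    theta_deg = np.asarray(theta_deg, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if theta_deg.size < 4:
        raise ValueError("need at least 4 directions for a direction fit")
    # moment-based initialization
    rad = np.deg2rad(theta_deg)
    shifted = rates - rates.min()
    vec = np.sum(shifted * np.exp(1j * rad))
    th0 = float(np.rad2deg(np.angle(vec))) % 360.0
    p0 = [float(rates.min()), float(np.ptp(rates)) or 1.0,
          float(np.clip(90.0, *w_bounds)), th0]
    lo = [-np.inf, 0.0, w_bounds[0], -360.0]
    hi = [np.inf, np.inf, w_bounds[1], 720.0]

    def resid(p):
        return _dir_profile(theta_deg, *p) - rates

    try:
        sol = optimize.least_squares(resid, p0, bounds=(lo, hi), max_nfev=2000)
        ok = sol.success
        r0, rmax, w, th = sol.x
    except Exception:
        ok = False
        r0, rmax, w, th = p0
    th = th % 360.0
    flat = np.ptp(rates) < 1e-12 or rmax < 1e-9 * max(1.0, abs(r0))
    return TuningFit(r0=float(r0), rmax=float(rmax), w_deg=float(w),
                     theta0_deg=float(th), converged=bool(ok and not flat))


def fit_category_tuning(theta_deg, rates, boundary_deg: float = 0.0) -> tuple[float, float]:
    """Step profile: mean rate over C1 directions and over C2 directions."""
    theta_deg = np.asarray(theta_deg, dtype=float)
    rates = np.asarray(rates, dtype=float)
    cats = np.asarray([assign_category(th, boundary_deg) for th in theta_deg])
    if not {"C1", "C2"} <= set(cats):
        raise ValueError("both categories must be represented")
    return (float(rates[cats == "C1"].mean()), float(rates[cats == "C2"].mean()))


def width_constraint_band(widths, percentile: float = 10.0) -> tuple[float, float]:
    """Population width-constraint band: the ``percentile`` range around the
    median of the unconstrained widths (median -/+ percentile/2 on the
    empirical distribution), used for the second, constrained fitting pass."""
    w = np.asarray(widths, dtype=float)
    w = w[np.isfinite(w)]
    if w.size == 0:
        raise ValueError("no finite widths")
    return (float(np.percentile(w, 50.0 - percentile / 2)),
            float(np.percentile(w, 50.0 + percentile / 2)))


def _ridge_loo_lambda(X, y, lambdas):
    """Exact leave-one-out MSE over a lambda grid via the leverage identity:
    e_loo_i = e_i / (1 - h_ii)."""
    best = (np.inf, lambdas[0])
    XtX = X.T @ X
    Xty = X.T @ y
    eye = np.eye(X.shape[1])
    for lam in lambdas:
        A = np.linalg.solve(XtX + lam * eye, np.column_stack([Xty, X.T]))
        beta, H_part = A[:, 0], A[:, 1:]
        h = np.einsum("ij,ji->i", X, H_part)
        e = y - X @ beta
        denom = np.clip(1.0 - h, 1e-8, None)
        mse = float(np.mean((e / denom) ** 2))
        if mse < best[0]:
            best = (mse, lam)
    return best[1]


def glm_classify(ds: RateDataset, neuron: int, boundary_deg: float = 0.0,
                 n_shuffles: int = 1000, rng=None,
                 lambdas=None, w_bounds=(10.0, 360.0),
                 dir_fit: TuningFit | None = None) -> TuningFit:
    """Ridge-GLM classification of a neuron's tuning.

    The design matrix holds the neuron's own fitted direction profile, the
    category step profile and a constant; beta = (X'X + lambda I)^-1 X'r
    with lambda chosen by exact leave-one-trial-out CV on a log grid.
    Significance of the direction and category coefficients is assessed
    against betas refitted after shuffling the trial order (P < 0.05,
    two-sided, t-statistic against the shuffle distribution); the label is
    direction/category/mixed/nonselective accordingly.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if lambdas is None:
        lambdas = np.logspace(-4, 2, 13)
    t = ds.trials
    valid = t["valid"].to_numpy(dtype=bool)
    theta = t["theta_deg"].to_numpy(dtype=float)[valid]
    y = ds.rates[valid, neuron]
    curve = ds.tuning_curve(neuron)
    fit = dir_fit if dir_fit is not None else \
        fit_direction_tuning(curve.index.to_numpy(), curve.to_numpy(), w_bounds)
    c1m, c2m = fit_category_tuning(curve.index.to_numpy(), curve.to_numpy(),
                                   boundary_deg)
    dir_reg = _dir_profile(theta, 0.0, 1.0, fit.w_deg, fit.theta0_deg)
    cats = np.asarray([assign_category(th, boundary_deg) for th in theta])
    cat_reg = np.where(cats == "C1", 1.0, -1.0)
    # center and scale the profile regressors so the betas are comparable
    for reg in (dir_reg, cat_reg):
        reg -= reg.mean()
    sd_d = dir_reg.std() or 1.0
    sd_c = cat_reg.std() or 1.0
    X = np.column_stack([dir_reg / sd_d, cat_reg / sd_c, np.ones_like(y)])

    lam = _ridge_loo_lambda(X, y, lambdas)
    A = np.linalg.solve(X.T @ X + lam * np.eye(3), X.T)
    beta = A @ y
    null = np.empty((n_shuffles, 2))
    for k in range(n_shuffles):
        null[k] = (A @ y[rng.permutation(y.size)])[:2]
    sd = null.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    z = (beta[:2] - null.mean(axis=0)) / sd
    p = 2.0 * stats.t.sf(np.abs(z), df=n_shuffles - 1)
    sig_dir = bool(p[0] < 0.05) and fit.converged
    sig_cat = bool(p[1] < 0.05)
    label = ("mixed" if (sig_dir and sig_cat) else
             "direction" if sig_dir else
             "category" if sig_cat else "nonselective")
    return TuningFit(r0=fit.r0, rmax=fit.rmax, w_deg=fit.w_deg,
                     theta0_deg=fit.theta0_deg, cat_means=(c1m, c2m),
                     beta=tuple(float(v) for v in beta),
                     p_beta=(float(p[0]), float(p[1])),
                     ridge_lambda=float(lam), label=label,
                     converged=fit.converged)


# ---------------------------------------------------------------------------
# Hartigan's dip test

def _lower_hull(x, y, lo, hi):
    """Touch-point indices of the greatest convex minorant of the points
    (x_i, y_i), i in [lo, hi]."""
    pts = [lo]
    for i in range(lo + 1, hi + 1):
        while len(pts) >= 2:
            a, b = pts[-2], pts[-1]
            # drop b if it lies on or above the chord a->i
            if (y[b] - y[a]) * (x[i] - x[a]) >= (y[i] - y[a]) * (x[b] - x[a]):
                pts.pop()
            else:
                break
        pts.append(i)
    return np.asarray(pts)


def dip_statistic(values) -> float:
    """Hartigan & Hartigan's dip statistic of a 1-D sample.

    The dip is the smallest sup-distance between the empirical CDF and any
    unimodal CDF.  It is computed by the classic iterative search: the
    greatest convex minorant (through the lower ECDF corners) and least
    concave majorant (upper corners) are intersected over a shrinking
    modal interval; the dip is half the largest of the envelope separation
    outside the modal interval and the ECDF deviations from the envelopes
    in the tails.  Ties are broken by an infinitesimal deterministic
    spread.  A 50/50 two-point sample attains the maximal dip 0.25; large
    unimodal samples give values near 0.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("dip statistic needs at least 4 observations")
    if x[0] == x[-1]:
        return 0.0
    # break exact ties (the hull construction assumes distinct abscissae)
    span = x[-1] - x[0]
    x = x + np.arange(n) * (span * 1e-12)
    y_low = np.arange(n, dtype=float)        # lower ECDF corners (counts)
    y_high = y_low + 1.0                     # upper corners

    lo, hi = 0, n - 1
    D = 0.0
    for _ in range(n):
        g = _lower_hull(x, y_low, lo, hi)
        l_ = _lower_hull(x, -y_high, lo, hi)   # concave majorant via reflection
        idx = np.arange(lo, hi + 1)
        g_env = np.interp(x[idx], x[g], y_low[g])
        l_env = np.interp(x[idx], x[l_], y_high[l_])
        sep = l_env - g_env
        d = sep.max() / n
        if d <= D or hi - lo < 2:
            break
        m = idx[int(np.argmax(sep))]
        new_lo = int(g[g <= m].max(initial=lo))
        new_hi = int(l_[l_ >= m].min(initial=hi))
        # ECDF deviation from the envelopes in the excluded tails
        left = np.arange(lo, new_lo + 1)
        right = np.arange(new_hi, hi + 1)
        dl = float((y_high[left] - np.interp(x[left], x[g], y_low[g])).max()) / n
        du = float((np.interp(x[right], x[l_], y_high[l_]) - y_low[right]).max()) / n
        D = max(D, dl, du)
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return float(max(D, 2.0 / n) / 2.0)


def dip_test(values, n_boot: int = 2000, rng=None,
              boundary_deg: float | None = None) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against a uniform null.

    When ``boundary_deg`` is given, ``values`` are treated as preferred
    directions (deg) and unwrapped to (-180, 180] relative to the boundary
    axis before testing (the dip is computed on the linearized axis).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x = np.asarray(values, dtype=float)
    if boundary_deg is not None:
        x = (x - boundary_deg + 180.0) % 360.0 - 180.0
    if x.size < 8:
        raise ValueError("dip test needs at least 8 values")
    d = dip_statistic(x)
    n = x.size
    null = np.empty(n_boot)
    for k in range(n_boot):
        null[k] = dip_statistic(rng.random(n))
    p = float((null >= d).mean())
    return d, p


# ---------------------------------------------------------------------------
# classical MDS

def classical_mds(M: np.ndarray, n_components: int = 2):
    """Classical (Torgerson) multidimensional scaling.

    ``M`` is a stimuli x neurons matrix of mean rates.  Squared Euclidean
    distances between stimulus vectors are double-centered; coordinates
    come from the top eigenvectors scaled by sqrt(eigenvalue).  Returns
    (coords, eigenvalues); eigenvalues are the full descending spectrum,
    and fewer than ``n_components`` positive eigenvalues flags a
    degenerate embedding via a trailing zero coordinate.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 3:
        raise ValueError("classical MDS needs at least 3 stimuli")
    sq = ((M[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(M.shape[0]) - 1.0 / M.shape[0]
    B = -0.5 * J @ sq @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    coords = evecs[:, :n_components] * np.sqrt(np.clip(evals[:n_components], 0.0, None))
    return coords, evals


# ---------------------------------------------------------------------------
# population pipeline

def analyze_neurons(ds: RateDataset, boundary_deg: float = 0.0,
                    neurons=None, n_shuffles: int = 200, rng=None,
                    cp_min_trials: int = 3,
                    width_percentile: float = 10.0,
                    cp_shuffles: int = 0) -> pd.DataFrame:
    """Per-neuron summary: two-pass tuning fit, GLM label, CTI, CS, CP.

    Pass 1 fits the direction profile unconstrained for every neuron; the
    population's ``width_percentile`` band around the median width then
    constrains pass 2, which feeds the GLM classification.  With
    ``cp_shuffles`` > 0 the CP shuffle test runs per neuron (costly) and
    fills the ``cp_p`` column; otherwise it is NaN.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if neurons is None:
        neurons = range(ds.n_neurons)
    neurons = list(neurons)
    curves = {j: ds.tuning_curve(j) for j in neurons}
    pass1 = {}
    for j in neurons:
        c = curves[j]
        pass1[j] = fit_direction_tuning(c.index.to_numpy(), c.to_numpy())
    widths = [f.w_deg for f in pass1.values() if f.converged]
    try:
        band = width_constraint_band(widths, width_percentile)
    except ValueError:
        band = (10.0, 360.0)
    rows = []
    for j in neurons:
        c = curves[j]
        fit2 = fit_direction_tuning(c.index.to_numpy(), c.to_numpy(), band)
        g = glm_classify(ds, j, boundary_deg, n_shuffles, rng, dir_fit=fit2)
        if cp_shuffles > 0:
            cp, cp_p = cp_shuffle_test(ds, j, cp_shuffles, rng, cp_min_trials)
        else:
            cp = choice_probability(ds, j, cp_min_trials)
            cp_p = float("nan")
        rows.append({
            "neuron": j,
            "label": g.label,
            "theta0_deg": g.theta0_deg,
            "w_deg": g.w_deg,
            "r0": g.r0, "rmax": g.rmax,
            "beta_dir": g.beta[0], "beta_cat": g.beta[1],
            "p_dir": g.p_beta[0], "p_cat": g.p_beta[1],
            "ridge_lambda": g.ridge_lambda,
            "cti": cti(ds, j, boundary_deg),
            "cs": category_sensitivity(ds, j),
            "cp": cp,
            "cp_p": cp_p,
        })
    return pd.DataFrame(rows)


def pairwise_table(ds: RateDataset, neurons=None) -> pd.DataFrame:
    """Noise correlation per neuron pair with the CS difference and the
    pair's CS strength (|CS_i - 0.5| + |CS_j - 0.5|) / 2."""
    if neurons is None:
        neurons = list(range(ds.n_neurons))
    neurons = list(neurons)
    nc = noise_correlations(ds)[np.ix_(neurons, neurons)]
    cs = np.array([category_sensitivity(ds, j) for j in neurons])
    rows = []
    for a in range(len(neurons)):
        for b in range(a + 1, len(neurons)):
            rows.append({
                "neuron_i": neurons[a], "neuron_j": neurons[b],
                "noise_corr": nc[a, b],
                "dcs": abs(cs[a] - cs[b]),
                "cs_strength": (abs(cs[a] - 0.5) + abs(cs[b] - 0.5)) / 2,
            })
    return pd.DataFrame(rows)
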