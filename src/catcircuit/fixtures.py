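"""Synthetic rate datasets with known ground truth.

Generates trial x neuron tables that satisfy the RateDataset schema and
carry analytically known tuning, choice-probability and noise-correlation
structure, so every analysis estimator can be validated for parameter
recovery without running the circuit simulator:

    rate = tuning(theta) + choice shift + shared gain + private noise

* tuning: exponential-cosine (direction), step (category), their sum
  (mixed), or flat;
* the choice-dependent shift is chosen from the inverse of the Gaussian
  ROC relation, so each neuron has a prescribed ground-truth CP;
* a shared Gaussian gain factor induces uniform noise correlations of
  known magnitude;
* choices follow a logistic psychometric rule in the signed boundary
  distance, so error trials occur at every distance (required by the CP
  trial-count rules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datasets import RateDataset
from .params import TaskSpec
from .task import assign_category

__all__ = ["NeuronSpec", "FixtureSpec", "generate_dataset", "ground_truth_report"]

_KINDS = ("direction", "category", "mixed", "flat")


@dataclass
class NeuronSpec:
    """Ground-truth generative parameters of one synthetic neuron."""

    kind: str = "direction"       # direction | category | mixed | flat
    r0: float = 5.0               # baseline rate, Hz
    rmax: float = 10.0            # direction-tuning amplitude, Hz
    w_deg: float = 120.0          # direction-tuning width, deg
    theta0_deg: float = 90.0      # preferred direction, deg
    cat_step: float = 4.0         # C1-minus-C2 step amplitude, Hz
    cp: float = 0.5               # target choice probability

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown tuning kind {self.kind!r}")
        if not 0.0 < self.cp < 1.0:
            raise ValueError("cp must be in (0, 1)")


@dataclass
class FixtureSpec:
    """Specification of a synthetic dataset."""

    neurons: list                     # list of NeuronSpec
    trials_per_stimulus: int = 40
    task: TaskSpec = field(default_factory=TaskSpec)
    noise_sd: float = 2.0             # private rate noise, Hz
    shared_gain_sd: float = 0.0       # shared multiplicative gain spread
    # choice model: shallow logistic with a lapse floor so that error
    # trials occur at every boundary distance (the CP inclusion rules need
    # at least 3 trials per choice per stimulus)
    psychometric_slope: float = 0.02  # logistic slope per deg of boundary distance
    lapse: float = 0.06               # floor error rate at any distance
    seed: int | None = None


def _tuning(spec: NeuronSpec, theta_deg: np.ndarray, category: np.ndarray) -> np.ndarray:
    out = np.full(theta_deg.shape, spec.r0, dtype=float)
    if spec.kind in ("direction", "mixed"):
        w_rad = np.deg2rad(spec.w_deg)
        out = out + spec.rmax * np.exp(
            (np.cos(np.deg2rad(theta_deg - spec.theta0_deg)) - 1.0) / w_rad**2)
    if spec.kind in ("category", "mixed"):
        out = out + np.where(category == "C1", 0.5, -0.5) * spec.cat_step
    return out


def choice_shift(cp: float, noise_sd: float) -> float:
    """Rate difference between C1- and C2-choice trials that yields the
    target CP under the Gaussian ROC relation: delta = sqrt(2) sd Phi^-1(CP)."""
    return float(np.sqrt(2.0) * noise_sd * norm.ppf(cp))


def generate_dataset(spec: FixtureSpec) -> tuple[RateDataset, pd.DataFrame]:
    """Synthesize a RateDataset plus its ground-truth table.

    The ground truth holds, per neuron, the generative parameters, the
    target CP and the analytic CTI of the noiseless tuning curve; the
    analysis code never reads it.
    """
    rng = np.random.default_rng(spec.seed)
    task = spec.task
    dirs = np.asarray(task.directions_deg)
    theta = np.repeat(dirs, spec.trials_per_stimulus)
    rng.shuffle(theta)
    n_trials = theta.size
    category = np.asarray([assign_category(th, task.boundary_deg) for th in theta])

    # logistic psychometric rule in signed boundary distance
    signed = np.where(category == "C1", 1.0, -1.0) * \
        np.asarray([task.boundary_distance(th) for th in theta])
    p_c1 = spec.lapse + (1.0 - 2.0 * spec.lapse) / (
        1.0 + np.exp(-spec.psychometric_slope * signed * 4.0))
    choice = np.where(rng.random(n_trials) < p_c1, "C1", "C2")
    correct = choice == category

    shared = spec.shared_gain_sd * rng.standard_normal(n_trials)
    rates = np.empty((n_trials, len(spec.neurons)))
    truth_rows = []
    for j, ns in enumerate(spec.neurons):
        base = _tuning(ns, theta, category)
        delta = choice_shift(ns.cp, spec.noise_sd)
        shift = np.where(choice == "C1", 0.5, -0.5) * delta
        rates[:, j] = (base + shift + shared * max(base.mean(), 1.0)
                       + spec.noise_sd * rng.standard_normal(n_trials))
        curve = np.array([_tuning(ns, np.array([th]), np.array([assign_category(th, task.boundary_deg)]))[0]
                          for th in dirs])
        truth_rows.append({
            "neuron": j, "kind": ns.kind, "r0": ns.r0, "rmax": ns.rmax,
            "w_deg": ns.w_deg, "theta0_deg": ns.theta0_deg,
            "cat_step": ns.cat_step, "cp": ns.cp,
            "cti": _noiseless_cti(curve, dirs, task.boundary_deg),
        })

    trials = pd.DataFrame({
        "theta_deg": theta, "category": category, "choice": choice,
        "correct": correct, "valid": np.ones(n_trials, dtype=bool),
    })
    neurons = pd.DataFrame({
        "population": ["synthetic"] * len(spec.neurons),
        "pref_deg": [ns.theta0_deg if ns.kind in ("direction", "mixed") else np.nan
                     for ns in spec.neurons],
    })
    return RateDataset(rates, trials, neurons), pd.DataFrame(truth_rows)


def _noiseless_cti(curve: np.ndarray, dirs: np.ndarray, boundary: float) -> float:
    from .analysis import tuning_curve_cti
    cats = np.asarray([assign_category(th, boundary) for th in dirs])
    return tuning_curve_cti(curve, cats)


def ground_truth_report(truth: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    """Bias/RMSE of the recovered quantities against the ground truth and
    the label-confusion table for the GLM classification.

    ``results`` is the output of :func:`catcircuit.analysis.analyze_neurons`
    on the fixture dataset (aligned by neuron index).
    """
    quantities = ("cp", "cti", "theta0_deg")
    t_ren = truth.rename(columns={q: f"{q}_true" for q in quantities})
    e_ren = results.rename(columns={q: f"{q}_est" for q in quantities})
    merged = t_ren.merge(e_ren, on="neuron")
    rows = []
    for name in quantities:
        t = merged[f"{name}_true"].to_numpy(dtype=float)
        e = merged[f"{name}_est"].to_numpy(dtype=float)
        if name == "theta0_deg":
            keep = merged["kind"].isin(["direction", "mixed"]).to_numpy()
            t, e = t[keep], e[keep]
            err = (e - t + 180.0) % 360.0 - 180.0
        else:
            err = e - t
        err = err[np.isfinite(err)]
        rows.append({"quantity": name, "bias": float(err.mean()),
                     "rmse": float(np.sqrt(np.mean(err**2))), "n": int(err.size)})
    report = pd.DataFrame(rows)
    expected = {"direction": "direction", "category": "category",
                "mixed": "mixed", "flat": "nonselective"}
    confusion = pd.crosstab(merged["kind"].map(expected), merged["label"])
    report.attrs["confusion"] = confusion
    return report
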