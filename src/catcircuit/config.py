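"""Run configuration: YAML serialization, validation, and the end-to-end
pipeline (train -> frozen evaluations -> analysis -> summary tables).

A run is fully reproducible from the configuration plus its seed; every
output directory carries the configuration and its hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import NetworkParams, TaskSpec
from .task import CircuitSimulator, VARIANTS, percent_correct, psychometric

__all__ = ["RunConfig", "load_config", "save_config", "run_pipeline",
           "default_snapshot_schedule"]


def default_snapshot_schedule(n_trials: int) -> list[int]:
    """Geometric-plus-fixed snapshot schedule including the standard
    learning landmarks (0; 500; 1,000; 6,000; 65,000; 420,000) up to the
    run length."""
    marks = {0, n_trials}
    marks.update(m for m in (500, 1000, 6000, 65_000, 420_000) if m <= n_trials)
    g = 250
    while g < n_trials:
        marks.add(g)
        g *= 4
    return sorted(marks)


@dataclass
class RunConfig:
    network: NetworkParams = field(default_factory=NetworkParams)
    task: TaskSpec = field(default_factory=TaskSpec)
    variant: str = "feedback"
    n_trials: int = 6000
    seeds: tuple = (1, 2, 3, 4, 5)
    snapshot_schedule: tuple = ()    # empty -> default schedule
    eval_trials: int = 2000          # frozen-evaluation trials per snapshot
    analysis_shuffles: int = 200
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        if not self.seeds:
            raise ValueError("need at least one seed")

    def to_dict(self) -> dict:
        return {
            "network": self.network.to_dict(),
            "task": self.task.to_dict(),
            "variant": self.variant,
            "n_trials": self.n_trials,
            "seeds": list(self.seeds),
            "snapshot_schedule": list(self.snapshot_schedule),
            "eval_trials": self.eval_trials,
            "analysis_shuffles": self.analysis_shuffles,
            "out_dir": self.out_dir,
        }

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


_TOP_KEYS = {"network", "task", "variant", "n_trials", "seeds",
             "snapshot_schedule", "eval_trials", "analysis_shuffles", "out_dir"}


def load_config(path) -> RunConfig:
    """Read a YAML config; missing keys fall back to documented defaults,
    unknown keys are rejected with a list of offenders."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    kwargs["network"] = NetworkParams.from_dict(raw.get("network", {}) or {})
    kwargs["task"] = TaskSpec.from_dict(raw.get("task", {}) or {})
    if "seeds" in kwargs:
        kwargs["seeds"] = tuple(kwargs["seeds"])
    if "snapshot_schedule" in kwargs:
        kwargs["snapshot_schedule"] = tuple(kwargs["snapshot_schedule"])
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def run_pipeline(cfg: RunConfig, seed: int | None = None,
                 analyze: bool = True) -> Path:
    """Execute one seed of the configured run end to end.

    Writes, under ``out_dir/<variant>-seed<seed>/``: the resolved config,
    ``trials.csv``, ``snapshots.h5`` (one dataset per snapshot and
    pathway), per-snapshot ``rates_eval_<trial>.csv`` frozen evaluations,
    per-snapshot ``neurons_<trial>.csv`` analyses, and ``summary.json``
    (learning curve, psychometric functions, CTI trajectory).
    """
    import h5py

    from .analysis import analyze_neurons

    seed = int(cfg.seeds[0] if seed is None else seed)
    out = Path(cfg.out_dir) / f"{cfg.variant}-seed{seed}"
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")

    schedule = list(cfg.snapshot_schedule) or default_snapshot_schedule(cfg.n_trials)
    sim = CircuitSimulator(cfg.network, cfg.task, cfg.variant, rng=seed)
    result = sim.train(cfg.n_trials, snapshot_schedule=schedule)
    result.trials.to_csv(out / "trials.csv", index=False)

    with h5py.File(out / "snapshots.h5", "w") as h5:
        h5.attrs["config_hash"] = cfg.hash
        for trial, w in result.snapshots.items():
            grp = h5.create_group(f"trial_{trial:07d}")
            grp.create_dataset("c_sa", data=w.c_sa)
            grp.create_dataset("c_ad", data=w.c_ad)
            grp.create_dataset("c_da", data=w.c_da)

    summary = {"config_hash": cfg.hash, "seed": seed, "variant": cfg.variant,
               "percent_correct_by_1000": [], "snapshots": {},
               "weight_change_norms": {}}
    tr = result.trials
    for lo in range(0, cfg.n_trials, 1000):
        summary["percent_correct_by_1000"].append(
            percent_correct(tr.iloc[lo:lo + 1000]))
    if 0 in result.snapshots:
        w0 = result.snapshots[0]
        for trial, w in result.snapshots.items():
            summary["weight_change_norms"][str(trial)] = {
                name: float(np.linalg.norm(getattr(w, name) - getattr(w0, name)))
                for name in ("c_sa", "c_ad", "c_da")
            }
    summary["psychometric_final"] = {
        str(k): v for k, v in
        psychometric(tr, cfg.task, slice(max(0, cfg.n_trials - 1000),
                                         cfg.n_trials)).items()}

    if analyze:
        from .analysis import classical_mds, pairwise_table

        for trial, w in result.snapshots.items():
            ev = CircuitSimulator(cfg.network, cfg.task, cfg.variant, w,
                                  rng=seed + 100_000 + trial)
            ds = ev.frozen_evaluation(cfg.eval_trials)
            ds.to_csv(out / f"rates_eval_{trial:07d}.csv")
            assoc = [j for j, p in enumerate(ds.neurons["population"])
                     if p == "assoc"]
            res = analyze_neurons(ds, cfg.task.boundary_deg, assoc,
                                  n_shuffles=cfg.analysis_shuffles,
                                  rng=np.random.default_rng(seed + trial))
            res.to_csv(out / f"neurons_{trial:07d}.csv", index=False)
            pairwise_table(ds, assoc).to_csv(out / f"pairs_{trial:07d}.csv",
                                             index=False)
            # population representation of the 12 stimuli (association ring)
            valid = ds.valid_subset()
            mean_rates = pd.DataFrame(valid.rates[:, assoc]) \
                .groupby(valid.trials["theta_deg"].to_numpy()).mean()
            coords, evals = classical_mds(mean_rates.to_numpy())
            pd.DataFrame({"theta_deg": mean_rates.index,
                          "x": coords[:, 0], "y": coords[:, 1]}) \
                .to_csv(out / f"mds_{trial:07d}.csv", index=False)
            summary["snapshots"][str(trial)] = {
                "mean_cti": float(np.nanmean(res["cti"])),
                "mean_cp": float(np.nanmean(res["cp"])),
                "mean_cs": float(np.nanmean(res["cs"])),
                "valid_fraction": float(ds.trials["valid"].mean()),
                "mds_eigenvalues": [float(v) for v in evals[:4]],
            }
        (out / "analysis_params.json").write_text(json.dumps({
            "boundary_deg": cfg.task.boundary_deg,
            "eval_trials": cfg.eval_trials,
            "n_shuffles": cfg.analysis_shuffles,
            "seed": seed,
        }, indent=2))

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
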