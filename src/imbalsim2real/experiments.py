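"""Named experiment manifests and the reproduction harness.

Each manifest describes one summary table of the reference protocol:

* ``table2``   — supervised vs proposed total validation score, groups A/B/C;
* ``table5``   — group A architectural ablation (proposed, supervised,
  fake-provided CycleGAN, original CycleGAN), paired/unpaired/total scores;
* ``table6``   — group B pairing-ratio sensitivity (0:30 vs 10:20), multi-run
  mean/variance and convergence-success index;
* ``table3-synthetic`` — sim2real success rates per stiffness on the
  synthetic actuator, for each transfer method;
* ``table4-synthetic`` — stiffness self-sensing estimation per method.

Every run is fully determined by (manifest, seed); ``scale`` multiplies the
epoch budgets for quick runs and is recorded in the summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmarks import ActuatorSpec, build_stiffness_dataset, generate_benchmark, simulate_angle
from .evaluation import (
    convergence_success_index,
    multi_run_stats,
    success_rate,
    validation_score,
)
from .pipeline import run_framework, transfer_all
from .training import (
    SelfSensingConfig,
    TrainingConfig,
    TrainingVariant,
    train,
    train_supervised,
)

EXPERIMENTS = ("table2", "table5", "table6", "table3-synthetic", "table4-synthetic")

#: reference protocol for the numerical benchmarks
BENCHMARK_CONFIG = TrainingConfig()


@dataclass(frozen=True)
class ExperimentManifest:
    name: str
    seeds: tuple[int, ...]
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.name!r}; valid names: {', '.join(EXPERIMENTS)}"
            )


def reproduce(
    experiment_name: str,
    seeds=(0,),
    scale: float = 1.0,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run a named experiment and return its summary table.

    With ``out_dir`` set, writes ``summary.csv`` and ``summary.json`` (the
    JSON carries the manifest: name, seeds, scale, epoch budgets).
    """
    manifest = ExperimentManifest(experiment_name, tuple(int(s) for s in seeds), scale)
    runner = {
        "table2": _table2,
        "table5": _table5,
        "table6": _table6,
        "table3-synthetic": _table3,
        "table4-synthetic": _table4,
    }[manifest.name]
    summary = runner(manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "experiment": manifest.name,
                    "seeds": list(manifest.seeds),
                    "scale": manifest.scale,
                    "rows": summary.to_dict(orient="records"),
                },
                indent=2,
            )
        )
    return summary


def _bench_config(manifest: ExperimentManifest, **kw) -> TrainingConfig:
    return replace(BENCHMARK_CONFIG.scaled(manifest.scale), **kw)


def _table2(manifest: ExperimentManifest) -> pd.DataFrame:
    rows = []
    for group in ("A", "B", "C"):
        sup_scores, prop_scores = [], []
        for seed in manifest.seeds:
            ds, spec = generate_benchmark(group, seed=seed)
            cfg = _bench_config(manifest, seed=seed)
            prop = train(ds, cfg).validation_report(spec.f2).score_total
            sup = validation_score(
                train_supervised(ds, cfg).predict, ds, spec.f2
            ).score_total
            prop_scores.append(prop)
            sup_scores.append(sup)
        sup_m, prop_m = float(np.mean(sup_scores)), float(np.mean(prop_scores))
        rows.append(
            {
                "group": group,
                "supervised": sup_m,
                "proposed": prop_m,
                "supervised/proposed": sup_m / prop_m,
            }
        )
    return pd.DataFrame(rows)


_TABLE5_VARIANTS = {
    "proposed": TrainingVariant.proposed(),
    "fake_provided_cyclegan": TrainingVariant.fake_provided_cyclegan(),
    "original_cyclegan": TrainingVariant.original_cyclegan(),
}


def _table5(manifest: ExperimentManifest) -> pd.DataFrame:
    acc: dict[str, list] = {k: [] for k in ("proposed", "supervised", *(_TABLE5_VARIANTS))}
    for seed in manifest.seeds:
        ds, spec = generate_benchmark("A", seed=seed)
        for name, variant in _TABLE5_VARIANTS.items():
            cfg = _bench_config(manifest, seed=seed, variant=variant)
            rep = train(ds, cfg).validation_report(spec.f2)
            acc[name].append(rep)
        cfg = _bench_config(manifest, seed=seed)
        rep = validation_score(train_supervised(ds, cfg).predict, ds, spec.f2)
        acc["supervised"].append(rep)
    rows = []
    for name in ("proposed", "supervised", "fake_provided_cyclegan", "original_cyclegan"):
        reps = acc[name]
        rows.append(
            {
                "method": name,
                "mse_unpaired": float(np.mean([r.score_unpaired for r in reps])),
                "mse_paired": float(np.mean([r.score_paired for r in reps])),
                "total": float(np.mean([r.score_total for r in reps])),
            }
        )
    return pd.DataFrame(rows)


#: the pairing-ratio study trains one 10,000-epoch phase at lr 1e-4
PAIRING_STUDY_CONFIG = TrainingConfig(epochs_phase1=10_000, epochs_phase2=0)


def _table6(manifest: ExperimentManifest) -> pd.DataFrame:
    rows = []
    for n_paired, label in ((0, "0:30"), (10, "10:20")):
        scores = []
        for seed in manifest.seeds:
            ds, spec = generate_benchmark("B", seed=seed, n_paired=n_paired)
            cfg = replace(PAIRING_STUDY_CONFIG.scaled(manifest.scale), seed=seed)
            scores.append(train(ds, cfg).validation_report(spec.f2).score_total)
        mean, var = (
            multi_run_stats(scores) if len(scores) >= 2 else (float(scores[0]), float("nan"))
        )
        rows.append(
            {
                "paired:unpaired": label,
                "mean": mean,
                "variance": var,
                "convergence_success_index": convergence_success_index(scores),
            }
        )
    return pd.DataFrame(rows)


def _actuator_success_rates(manifest: ExperimentManifest, seed: int) -> list[dict]:
    """Success rates of sim2real angle transfer per training stiffness."""
    from .pipeline import ACTUATOR_TRANSFER_CONFIG

    spec = ActuatorSpec()
    ds, _ = build_stiffness_dataset(spec, seed=seed)
    cfg = replace(ACTUATOR_TRANSFER_CONFIG.scaled(manifest.scale), seed=seed)
    methods = {
        "proposed": replace(cfg, variant=TrainingVariant.proposed()),
        "cyclegan": replace(cfg, variant=TrainingVariant.original_cyclegan()),
    }
    P = np.asarray(spec.pressures, dtype=float)
    P = P[P > 0]
    eval_stiffness = tuple(spec.real_stiffness)
    per_method: dict[str, dict] = {}
    for name, mcfg in methods.items():
        res = train(ds, mcfg)
        rates = {}
        for k in eval_stiffness:
            true = np.asarray([simulate_angle(p, k, "real", spec) for p in P])
            sim = np.asarray([simulate_angle(p, k, "sim", spec) for p in P])
            pred = res.predict_s2r(np.column_stack([P, np.full(P.shape, k)]), sim)
            rates[k] = success_rate(pred, true)
        per_method[name] = rates
    sup = train_supervised(ds, cfg)
    rates = {}
    for k in eval_stiffness:
        true = np.asarray([simulate_angle(p, k, "real", spec) for p in P])
        sim = np.asarray([simulate_angle(p, k, "sim", spec) for p in P])
        pred = sup.predict(np.column_stack([P, np.full(P.shape, k)]), sim)
        rates[k] = success_rate(pred, true)
    per_method["supervised"] = rates
    per_method["no_transfer"] = {
        k: success_rate(
            np.asarray([simulate_angle(p, k, "sim", spec) for p in P]),
            np.asarray([simulate_angle(p, k, "real", spec) for p in P]),
        )
        for k in eval_stiffness
    }
    rows = []
    for name, rates in per_method.items():
        row = {"method": name}
        row.update({f"k={k}": v for k, v in rates.items()})
        row["total"] = float(np.mean(list(rates.values())))
        rows.append(row)
    return rows


def _table3(manifest: ExperimentManifest) -> pd.DataFrame:
    all_rows = []
    for seed in manifest.seeds:
        for row in _actuator_success_rates(manifest, seed):
            row["seed"] = seed
            all_rows.append(row)
    df = pd.DataFrame(all_rows)
    return df.groupby("method", sort=False).mean(numeric_only=True).drop(columns="seed").reset_index()


def _table4(manifest: ExperimentManifest) -> pd.DataFrame:
    from .pipeline import ACTUATOR_TRANSFER_CONFIG

    transfer_cfg = ACTUATOR_TRANSFER_CONFIG.scaled(manifest.scale)
    sensing_epochs = max(1, int(10_000 * manifest.scale))
    rows = []
    for method in ("supervised_real_only", "cyclegan", "proposed"):
        totals, averages = [], []
        per_k_acc: dict[float, list] = {}
        for seed in manifest.seeds:
            result = run_framework(
                method=method,
                transfer_config=transfer_cfg,
                sensing_config=SelfSensingConfig(epochs=sensing_epochs, seed=seed),
                seed=seed,
            )
            totals.append(result.report["total_mse"])
            averages.append(result.report["average_mse"])
            for k, (m, s) in result.report["per_stiffness"].items():
                per_k_acc.setdefault(k, []).append((m, s))
        row = {"method": method}
        for k, pairs in per_k_acc.items():
            m = float(np.mean([p[0] for p in pairs]))
            s = float(np.mean([p[1] for p in pairs]))
            row[f"k={k}"] = f"{m:.2f}+-{s:.2f}"
        row["total_mse"] = float(np.mean(totals))
        row["average_mse"] = float(np.mean(averages))
        rows.append(row)
    return pd.DataFrame(rows)
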