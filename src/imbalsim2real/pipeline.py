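"""End-to-end joint-stiffness self-sensing framework.

The framework chains three stages on the synthetic actuator:

1. fit the sim2real transfer scheme on the imbalanced angle dataset
   (abundant simulation grid, scarce real-world training stiffness values);
2. push *every* simulation sample through the trained sim->real generator
   to obtain "regressed real-world" angle data over the full grid;
3. train the stiffness self-sensing MLP on the regressed data and evaluate
   it on withheld real-world validation stiffness values.

Baselines swap stage 1 for the original CycleGAN or drop stages 1-2 and
train the self-sensing net directly on the scarce real-world data.

Zero-pressure rows are excluded from self-sensing training and evaluation:
at zero pressure every stiffness produces a zero angle, so stiffness is
unidentifiable there.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .benchmarks import ActuatorSpec, build_stiffness_dataset, simulate_angle
from .data import ImbalancedDataset
from .evaluation import stiffness_report
from .training import (
    ImbalSim2Real,
    SelfSensingConfig,
    Sim2RealResults,
    StiffnessEstimator,
    TrainingConfig,
    TrainingVariant,
    train_self_sensing,
)

Method = Literal["proposed", "cyclegan", "supervised_real_only"]

#: default transfer protocol for the actuator application; covariates here
#: span very different scales (pressure 0-100 kPa vs stiffness ~0.1-2), so
#: the transfer trains in z-scored units
ACTUATOR_TRANSFER_CONFIG = TrainingConfig(
    epochs_phase1=17_000, epochs_phase2=17_000, lr_phase1=1e-4, lr_phase2=1e-5,
    normalize=True,
)


def transfer_all(results: Sim2RealResults, dataset: ImbalancedDataset) -> pd.DataFrame:
    """Regressed real-world data: g_s2r applied to every simulation sample.

    Covariates (pressure, stiffness) pass through untouched; only the
    response is replaced by the generated real-world angle.
    """
    src = dataset.source_samples()
    if not src:
        raise ValueError("dataset has no simulation samples to transfer")
    cov = np.array([s.covariates for s in src])
    y1 = np.array([s.response for s in src])
    regressed = results.predict_s2r(cov, y1)
    return pd.DataFrame(
        {"pressure": cov[:, 0], "stiffness": cov[:, 1], "angle": regressed}
    )


@dataclass
class FrameworkResult:
    method: str
    estimator: StiffnessEstimator
    report: dict
    regressed: pd.DataFrame | None
    transfer_results: Sim2RealResults | None


def run_framework(
    spec: ActuatorSpec | None = None,
    method: Method = "proposed",
    transfer_config: TrainingConfig | None = None,
    sensing_config: SelfSensingConfig | None = None,
    seed: int = 0,
) -> FrameworkResult:
    """Run the full self-sensing framework with one of the three methods.

    Evaluation covers the withheld validation stiffness values and the
    training stiffness grids (noiseless real-world angles as inputs),
    reporting per-stiffness prediction mean/STD plus total and average MSE.
    """
    if method not in ("proposed", "cyclegan", "supervised_real_only"):
        raise ValueError(f"unknown method {method!r}")
    spec = spec or ActuatorSpec()
    transfer_config = transfer_config or ACTUATOR_TRANSFER_CONFIG
    sensing_config = sensing_config or SelfSensingConfig(seed=seed)
    ds, validation = build_stiffness_dataset(spec, seed=seed)

    transfer_results: Sim2RealResults | None = None
    regressed: pd.DataFrame | None = None
    if method == "supervised_real_only":
        tgt = ds.target_samples()
        P = np.array([s.covariates[0] for s in tgt])
        k = np.array([s.covariates[1] for s in tgt])
        theta = np.array([s.response for s in tgt])
        keep = P > 0
        estimator = train_self_sensing(P[keep], theta[keep], k[keep], sensing_config)
    else:
        variant = (
            TrainingVariant.proposed()
            if method == "proposed"
            else TrainingVariant.original_cyclegan()
        )
        cfg = replace(transfer_config, variant=variant, seed=seed)
        transfer_results = ImbalSim2Real(ds, cfg).fit()
        regressed = transfer_all(transfer_results, ds)
        keep = regressed["pressure"].to_numpy() > 0
        estimator = train_self_sensing(
            regressed["pressure"].to_numpy()[keep],
            regressed["angle"].to_numpy()[keep],
            regressed["stiffness"].to_numpy()[keep],
            sensing_config,
        )

    eval_sets = _evaluation_sets(spec)
    report = stiffness_report(estimator.predict, eval_sets)
    return FrameworkResult(method, estimator, report, regressed, transfer_results)


def _evaluation_sets(spec: ActuatorSpec) -> dict[float, dict[str, np.ndarray]]:
    """Noiseless real-world grids at validation + training stiffness values,
    zero-pressure rows excluded."""
    P = np.asarray(spec.pressures, dtype=float)
    P = P[P > 0]
    sets: dict[float, dict[str, np.ndarray]] = {}
    for k in tuple(spec.validation_stiffness) + tuple(spec.train_stiffness):
        sets[float(k)] = {
            "pressure": P.copy(),
            "angle_real": np.asarray([simulate_angle(p, k, "real", spec) for p in P]),
        }
    return sets


def oracle_transfer_recovery(
    spec: ActuatorSpec | None = None,
    sensing_config: SelfSensingConfig | None = None,
) -> float:
    """Upper-bound check: self-sensing RMSE with a perfect transfer stage.

    The true real-world angle function stands in for the trained generator
    (noise off); returns the stiffness RMSE over the withheld validation
    grids.  This bounds what any transfer quality can achieve downstream.
    """
    spec = spec or ActuatorSpec()
    sensing_config = sensing_config or SelfSensingConfig()
    P = np.asarray(spec.pressures, dtype=float)
    P = P[P > 0]
    rows_P, rows_th, rows_k = [], [], []
    for k in spec.sim_stiffness:
        theta = np.asarray([simulate_angle(p, k, "real", spec) for p in P])
        rows_P.append(P)
        rows_th.append(theta)
        rows_k.append(np.full(P.shape, k))
    estimator = train_self_sensing(
        np.concatenate(rows_P),
        np.concatenate(rows_th),
        np.concatenate(rows_k),
        sensing_config,
    )
    sq, n = 0.0, 0
    for k in spec.validation_stiffness:
        theta = np.asarray([simulate_angle(p, k, "real", spec) for p in P])
        pred = estimator.predict(P, theta)
        sq += float(np.sum((pred - k) ** 2))
        n += pred.size
    return float(np.sqrt(sq / n))
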