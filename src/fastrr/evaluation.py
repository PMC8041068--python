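"""Replicated Monte-Carlo experiments: power, false positive rate, accuracy.

One experiment repeats (simulate genotypes + phenotype -> run FastRR) over
independent replicates and summarizes, per QTN,

* power (%)   — fraction of replicates in which the QTN's exact simulated
  marker position is called significant (simulated markers are independent,
  so no window matching is needed);
* effect (SD) — mean and standard deviation of the deshrunk (DRR) effect at
  the true position over the replicates where it was detected;
* MSE         — the *sum* over detecting replicates of the squared error
  (estimate - truth)^2;

and, over all replicates, the false positive rate: significant markers at
zero-effect positions divided by (replicates x zero-effect markers),
reported per mille.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .pipeline import FastrrConfig, run_fastrr
from .simulate import SimConfig, generate_genotypes, generate_phenotype

__all__ = [
    "ReplicateResult",
    "ExperimentSummary",
    "run_replicate",
    "run_experiment",
    "false_positive_rate",
    "effect_accuracy",
]


@dataclass
class ReplicateResult:
    """Detections of a single simulated replicate."""

    seed: int
    detected_positions: np.ndarray              # 1-based
    detected_effects: np.ndarray                # gamma_DRR at those positions
    n_selected: int
    lambda_g: float


@dataclass
class ExperimentSummary:
    """Per-QTN power/accuracy plus the overall false positive rate."""

    scenario: str
    n_replicates: int
    n_markers: int
    qtn_table: pd.DataFrame        # position, true_effect, power_pct, mean/sd/mse
    fpr_per_mille: float
    replicates: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = self.qtn_table.copy()
        df.insert(0, "scenario", self.scenario)
        return df

    def detections_frame(self) -> pd.DataFrame:
        """Raw per-replicate detections (one row per detected marker)."""
        rows = []
        for i, rep in enumerate(self.replicates):
            for p, g in zip(rep.detected_positions, rep.detected_effects):
                rows.append({"replicate": i, "seed": rep.seed,
                             "position": int(p), "gamma_drr": g})
        return pd.DataFrame(rows, columns=["replicate", "seed", "position",
                                           "gamma_drr"])


def run_replicate(config: SimConfig, seed: int,
                  fastrr_config: FastrrConfig | None = None) -> ReplicateResult:
    """Simulate one dataset and run the full pipeline on it.

    Genotype and phenotype draws use independent streams spawned from the
    replicate seed, so a replicate is fully reproducible from (config, seed).
    """
    gs, ps = np.random.SeedSequence(int(seed)).spawn(2)
    geno = generate_genotypes(config, np.random.default_rng(gs))
    y, _ = generate_phenotype(geno, None, config, np.random.default_rng(ps))
    res = run_fastrr(geno, y, config=fastrr_config)
    det = res.table[res.table["significant"]] if not res.table.empty else res.table
    return ReplicateResult(
        seed=int(seed),
        detected_positions=det["position"].to_numpy(dtype=np.int64)
        if not det.empty else np.array([], dtype=np.int64),
        detected_effects=det["gamma_drr"].to_numpy(dtype=float)
        if not det.empty else np.array([], dtype=float),
        n_selected=res.n_selected,
        lambda_g=res.lambda_g,
    )


def _truth_match(positions, truth_positions, window):
    """Boolean mask: which detected positions hit a true QTN.

    ``window = 0`` (the default) demands the exact simulated marker index —
    appropriate for independent markers.  A positive window matches any
    position within +/- window of a QTN, for data carrying linkage
    disequilibrium.
    """
    positions = np.asarray(positions, dtype=int)
    truth_positions = np.asarray(truth_positions, dtype=int)
    if positions.size == 0 or truth_positions.size == 0:
        return np.zeros(positions.shape, dtype=bool)
    if window == 0:
        return np.isin(positions, truth_positions)
    dist = np.abs(positions[:, None] - truth_positions[None, :])
    return (dist <= window).any(axis=1)


def false_positive_rate(detections, truth_positions, n_reps, n_markers,
                        window: int = 0) -> float:
    """FPR in per mille: false-positive calls over total zero-effect markers.

    ``detections`` is an iterable of per-replicate detected-position arrays.
    """
    truth = np.asarray(truth_positions, dtype=int).ravel()
    n_zero = n_markers - len(set(truth.tolist()))
    if n_reps <= 0 or n_zero <= 0:
        raise ZeroDivisionError("no zero-effect markers or no replicates")
    fp = sum(int(np.sum(~_truth_match(d, truth, window))) for d in detections)
    return 1000.0 * fp / (n_reps * n_zero)


def effect_accuracy(detections, truth_positions, truth_effects,
                    window: int = 0) -> pd.DataFrame:
    """Mean, SD and summed squared error of detected effects per QTN.

    ``detections`` is an iterable of (positions, effects) pairs per
    replicate.  Effect statistics are conditioned on detection; QTNs never
    detected get NaN statistics (missing, not zero).  With a positive
    ``window`` a detection is credited to the nearest QTN within range
    (at most one credit per QTN per replicate, strongest Wald first is not
    needed because positions are unique per replicate).
    """
    truth_positions = np.asarray(truth_positions, dtype=int)
    truth_effects = np.asarray(truth_effects, dtype=float)
    per_qtn = {int(p): [] for p in truth_positions}
    for pos, eff in detections:
        pos = np.asarray(pos, dtype=int)
        eff = np.asarray(eff, dtype=float)
        credited = set()
        for p, g in zip(pos, eff):
            if window == 0:
                target = int(p) if int(p) in per_qtn else None
            else:
                dist = np.abs(truth_positions - int(p))
                j = int(np.argmin(dist))
                target = int(truth_positions[j]) if dist[j] <= window else None
            if target is not None and target not in credited:
                per_qtn[target].append(g)
                credited.add(target)
    rows = []
    for p, g_true in zip(truth_positions, truth_effects):
        est = np.asarray(per_qtn[int(p)], dtype=float)
        if est.size:
            rows.append({
                "position": int(p),
                "true_effect": g_true,
                "n_detected": est.size,
                "mean_effect": est.mean(),
                "sd_effect": est.std(ddof=1) if est.size > 1 else 0.0,
                "mse": float(np.sum((est - g_true) ** 2)),
            })
        else:
            rows.append({
                "position": int(p),
                "true_effect": g_true,
                "n_detected": 0,
                "mean_effect": np.nan,
                "sd_effect": np.nan,
                "mse": np.nan,
            })
    return pd.DataFrame(rows)


def run_experiment(config: SimConfig, n_reps: int | None = None,
                   seed: int | None = None,
                   fastrr_config: FastrrConfig | None = None,
                   n_jobs: int = 1,
                   scenario: str | None = None,
                   window: int = 0) -> ExperimentSummary:
    """Run a replicated simulation experiment and summarize it.

    Replicate ``i`` uses seed ``base + i`` (base = ``seed`` if given, else
    ``config.base_seed``); replicates are independent, so the summary does
    not depend on execution order or ``n_jobs``.
    """
    config.validate()
    n_reps = config.n_replicates if n_reps is None else int(n_reps)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = config.base_seed if seed is None else int(seed)
    seeds = [base + i for i in range(n_reps)]
    if n_jobs == 1:
        reps = [run_replicate(config, s, fastrr_config) for s in seeds]
    else:
        reps = Parallel(n_jobs=n_jobs)(
            delayed(run_replicate)(config, s, fastrr_config) for s in seeds
        )

    truth_pos = np.asarray(config.qtn_positions, dtype=int)
    truth_eff = np.asarray(config.qtn_effects, dtype=float)
    acc = effect_accuracy(
        [(r.detected_positions, r.detected_effects) for r in reps],
        truth_pos, truth_eff, window=window,
    )
    acc.insert(3, "power_pct", 100.0 * acc["n_detected"] / n_reps)
    fpr = false_positive_rate(
        [r.detected_positions for r in reps], truth_pos, n_reps,
        config.n_markers, window=window,
    )
    label = scenario or f"{config.polygenic_multiplier:g}K"
    return ExperimentSummary(
        scenario=label,
        n_replicates=n_reps,
        n_markers=config.n_markers,
        qtn_table=acc,
        fpr_per_mille=fpr,
        replicates=reps,
    )
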