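"""Replicated benchmarking of harmonization strategies.

Each replicate draws a fresh multi-study collection, runs every strategy on
the identical draw (paired design), fits the outcome lasso and records the
validation root mean square error.  Strategies are then compared by paired
two-sided Wilcoxon signed-rank tests with Bonferroni correction across the
method pairs, by log-RMSE ratios against a baseline, and by the proportion
of replicates in which each method attains the smallest RMSE.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .imputers import LearnerSpec
from .simulate import SimulationConfig, generate_collection
from .strategies import Method, run_method

__all__ = [
    "ExperimentResult",
    "rmse",
    "log_rmse_ratio",
    "wilcoxon_signed_rank",
    "wilcoxon_matrix",
    "proportion_best",
    "run_experiment",
]

SEED_MOD = 2**31


@dataclass
class ExperimentResult:
    """Per-replicate, per-method validation RMSE plus provenance.

    ``rmse`` is a replicates x methods DataFrame whose columns are method
    labels; all methods within a row were scored on the identical
    validation draw.
    """

    rmse: pd.DataFrame
    methods: tuple[Method, ...]
    replicate_seeds: tuple[int, ...]
    config_fingerprint: str

    def medians(self) -> pd.Series:
        return self.rmse.median(axis=0)


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Root mean square error of a prediction vector."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if len(pred) == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def log_rmse_ratio(method_rmse: np.ndarray, baseline_rmse: np.ndarray) -> np.ndarray:
    """Element-wise log(method RMSE / baseline RMSE); negative favors the method."""
    m = np.asarray(method_rmse, dtype=float)
    b = np.asarray(baseline_rmse, dtype=float)
    if m.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if np.any(m <= 0) or np.any(b <= 0):
        raise ValueError("RMSE entries must be positive to take log ratios")
    return np.log(m / b)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Paired two-sided Wilcoxon signed-rank p-value.

    Zero differences are dropped.  The exact null distribution is used for
    n <= 25 without ties in |differences|; otherwise the normal
    approximation with continuity correction.  Returns ``(p, degenerate)``
    where ``degenerate`` flags an all-zero difference vector (p reported
    as 1).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0, True
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not ties) else "approx"
    if method == "exact":
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                             method="exact")
    else:
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                             method="approx", correction=True)
    return float(res.pvalue), False


def wilcoxon_matrix(result: ExperimentResult | pd.DataFrame,
                    alpha_levels: tuple[float, float] = (0.01, 0.05)) -> pd.DataFrame:
    """All-pairs paired Wilcoxon tests on per-replicate RMSE.

    Returns one row per unordered method pair with the raw and
    Bonferroni-adjusted p-value (multiplied by the number of pairs, capped
    at 1), the direction (which method has the smaller median RMSE) and a
    significance band mirroring the usual red/green/blue encoding:
    ``"<0.01"``, ``"0.01-0.05"`` or ``">0.05"`` on the adjusted p-value.
    """
    table = result.rmse if isinstance(result, ExperimentResult) else result
    methods = list(table.columns)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    if table.shape[0] < 6:
        raise ValueError("need at least 6 replicates for a meaningful signed-rank test")
    lo, hi = alpha_levels
    pairs = list(combinations(methods, 2))
    rows = []
    for a, b in pairs:
        p_raw, degenerate = wilcoxon_signed_rank(table[a].to_numpy(), table[b].to_numpy())
        p_adj = min(1.0, p_raw * len(pairs))
        med_a, med_b = table[a].median(), table[b].median()
        if degenerate or med_a == med_b:
            direction = "tie"
        else:
            direction = a if med_a < med_b else b
        band = f"<{lo}" if p_adj < lo else (f"{lo}-{hi}" if p_adj < hi else f">{hi}")
        rows.append({
            "method_a": a, "method_b": b, "p_raw": p_raw, "p_adjusted": p_adj,
            "smaller_median": direction, "band": band, "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def proportion_best(result: ExperimentResult | pd.DataFrame) -> pd.Series:
    """Per method, the share of replicates in which it attains the smallest
    RMSE; replicate ties are split equally among the tied methods, so the
    proportions always sum to 1."""
    table = result.rmse if isinstance(result, ExperimentResult) else result
    if table.shape[0] == 0:
        raise ValueError("no replicates")
    wins = pd.Series(0.0, index=table.columns)
    for _, row in table.iterrows():
        best = row[row == row.min()].index
        wins[best] += 1.0 / len(best)
    return wins / table.shape[0]


def _replicate_seed(base_seed: int, index: int) -> int:
    return (int(base_seed) + int(index)) % SEED_MOD


def _config_fingerprint(config: SimulationConfig, methods: Sequence[Method]) -> str:
    payload = json.dumps(
        {"config": config.to_dict(),
         "methods": [{"name": m.name, "k": m.k, "q": m.q,
                      "learner": m.learner.to_dict()} for m in methods]},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _one_replicate(config: SimulationConfig, methods: Sequence[Method],
                   seed: int) -> list[float]:
    cfg = dataclasses.replace(config, seed=seed)
    training, validation, _ = generate_collection(cfg)
    y_true = validation.outcome
    scores = []
    for m in methods:
        learner = LearnerSpec(**{**m.learner.to_dict(), "seed": seed})
        method = Method(m.name, learner, m.k, m.q)
        outcome_spec = LearnerSpec(seed=seed)
        try:
            pred = run_method(method, training, validation, outcome_spec=outcome_spec)
        except Exception as exc:
            raise RuntimeError(
                f"method {method.label!r} failed on replicate seed {seed}: {exc}"
            ) from exc
        scores.append(rmse(pred, y_true))
    return scores


def run_experiment(config: SimulationConfig, methods: Sequence[Method],
                   replicates: int, base_seed: int,
                   n_jobs: int = 1) -> ExperimentResult:
    """Run every method on ``replicates`` fresh collections.

    Replicate seeds are ``(base_seed + index) mod 2^31``, so any subset of
    replicates is reproducible in isolation, and serial and parallel
    execution give identical results.  Each method's learner and the
    outcome model are re-seeded with the replicate seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    labels = [m.label for m in methods]
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate method labels: {labels}")
    seeds = [_replicate_seed(base_seed, i) for i in range(replicates)]
    if n_jobs == 1:
        rows = [_one_replicate(config, methods, s) for s in seeds]
    else:
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(config, methods, s) for s in seeds
        )
    table = pd.DataFrame(rows, columns=labels)
    return ExperimentResult(
        rmse=table,
        methods=tuple(methods),
        replicate_seeds=tuple(seeds),
        config_fingerprint=_config_fingerprint(config, methods),
    )
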