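"""Synthetic multi-study generators with structural missingness.

Three benchmark mechanisms are provided.  In each, every study draws its
samples independently from the same joint law (unless cross-study
heterogeneity is switched on), the outcome is a linear form in the genes
plus Gaussian noise, and missingness is structural: whole gene columns are
dropped per study.

* ``eq1`` — 10 predictive genes (X1..X5 and their partners Xs1..Xs5) drawn
  jointly multivariate normal with mean 0.1, unit variance and pairwise
  covariance 0.5.  X1, X2 are anchored (never masked); the remaining eight
  genes are maskable across training studies.  The validation study is
  complete.
* ``eq2`` — eq1 plus ten irrelevant genes Z1..Z10 (mean 0.1, unit variance,
  correlation 0.2, zero coefficients), which may also go missing.
* ``eq3`` — a sparse-signal design: 20 common predictive genes X1..X20,
  20 partner genes Xs1..Xs20 and 120 irrelevant genes Z1..Z120 (mean 0,
  unit variance, correlation 0.2, zero coefficients).  Per study —
  including the validation study — 10 of the Xs genes and 50 of the Z genes
  are masked, leaving 100 observed genes per study.
* ``nonlinear`` — like eq1 but the partner genes are a sine/cosine map of
  the X block; the exact functional form is a package choice and is
  documented as non-canonical.

Cross-study heterogeneity: with ``tau > 0``, eq1-style mechanisms replace
the joint draw of the partner block by study-specific random slopes
(Xs_j = X @ gamma_kj with gamma_kj ~ N(gamma_k, I) and gamma_k ~ N(0, tau^2)),
and eq2/eq3 shift the Z-block mean by a study-specific mu_k ~ N(0, tau^2).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import Study, TRAINING, VALIDATION

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "eq1_config",
    "eq2_config",
    "eq3_config",
    "nonlinear_config",
    "generate_collection",
    "apply_heterogeneity",
    "design_missingness",
    "outcome_variance",
]

MECHANISMS = ("eq1", "eq2", "eq3", "nonlinear")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic multi-study collection.

    ``beta`` maps gene ID to outcome coefficient (genes absent from the map
    have coefficient 0).  ``missing_design`` is one of:

    * ``{"kind": "proportion", "proportion": p}`` — per training study,
      mask ``round(p * |pool|)`` genes drawn without replacement from the
      maskable pool (all non-protected genes); the validation study stays
      complete.  Draws are redrawn (seeded) if a gene would end up masked
      in every training study, which would leave nothing to impute from.
    * ``{"kind": "blocks", "blocks": [{"pool": [...], "count": n}, ...],
      "mask_validation": true}`` — per study (validation included when
      flagged), mask ``count`` genes from each pool.
    * ``{"kind": "explicit", "per_study": {study_id: [genes...]}}`` — a
      fixed pattern; validated, not redrawn.
    """

    mechanism: str = "eq1"
    n_per_study: int = 100
    n_training: int = 4
    beta: tuple[tuple[str, float], ...] = ()
    sigma_eps: float = 1.0
    mvn_mean: float = 0.1
    mvn_cov: float = 0.5
    z_mean: float = 0.1
    z_corr: float = 0.2
    missing_design: tuple = ()
    protected: tuple[str, ...] = ()
    tau: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.n_per_study < 2 or self.n_training < 1:
            raise ValueError("n_per_study >= 2 and n_training >= 1 required")
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        design = dict(self._design())
        if design.get("kind") == "proportion":
            p = design["proportion"]
            if not 0 <= p <= 1:
                raise ValueError(f"missing proportion must be in [0, 1], got {p}")

    def _design(self) -> dict:
        return _tuples_to_dict(self.missing_design)

    @property
    def beta_map(self) -> dict[str, float]:
        return dict(self.beta)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta"] = dict(self.beta)
        d["missing_design"] = self._design()
        d["protected"] = list(self.protected)
        return d


def _dict_to_tuples(d: dict) -> tuple:
    """Recursively freeze a dict into sorted tuples (hashable config field)."""
    out = []
    for k in sorted(d):
        v = d[k]
        if isinstance(v, dict):
            v = _dict_to_tuples(v)
        elif isinstance(v, (list, tuple)):
            v = tuple(_dict_to_tuples(x) if isinstance(x, dict) else
                      (tuple(x) if isinstance(x, (list, tuple)) else x) for x in v)
        out.append((k, v))
    return tuple(out)


def _tuples_to_dict(t: tuple) -> dict:
    out = {}
    for k, v in t:
        if isinstance(v, tuple) and v and all(
                isinstance(x, tuple) and len(x) == 2 and isinstance(x[0], str) for x in v):
            v = _tuples_to_dict(v)
        elif isinstance(v, tuple):
            v = [_tuples_to_dict(x) if (isinstance(x, tuple) and x and all(
                isinstance(y, tuple) and len(y) == 2 and isinstance(y[0], str) for y in x))
                else list(x) if isinstance(x, tuple) else x for x in v]
        out[k] = v
    return out


def _gene_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(1, n + 1)]


def eq1_config(missing_proportion: float = 0.3, n_training: int = 4,
               n_per_study: int = 100, sigma_eps: float = 1.0, tau: float = 0.0,
               seed: int = 0, beta_value: float = 1.0) -> SimulationConfig:
    """Ten correlated predictive genes; X1, X2 anchored; validation complete."""
    genes = _gene_names("X", 5) + _gene_names("Xs", 5)
    beta = tuple((g, beta_value) for g in genes)
    design = _dict_to_tuples({"kind": "proportion", "proportion": missing_proportion})
    return SimulationConfig(
        mechanism="eq1", n_per_study=n_per_study, n_training=n_training,
        beta=beta, sigma_eps=sigma_eps, missing_design=design,
        protected=("X1", "X2"), tau=tau, seed=seed,
    )


def eq2_config(missing_proportion: float = 0.3, n_training: int = 4,
               n_per_study: int = 100, sigma_eps: float = 1.0, tau: float = 0.0,
               seed: int = 0, beta_value: float = 1.0) -> SimulationConfig:
    """eq1 plus ten zero-coefficient Z genes (mean 0.1, correlation 0.2)."""
    genes = _gene_names("X", 5) + _gene_names("Xs", 5)
    beta = tuple((g, beta_value) for g in genes)  # Z coefficients are 0
    design = _dict_to_tuples({"kind": "proportion", "proportion": missing_proportion})
    return SimulationConfig(
        mechanism="eq2", n_per_study=n_per_study, n_training=n_training,
        beta=beta, sigma_eps=sigma_eps, z_mean=0.1, z_corr=0.2,
        missing_design=design, protected=("X1", "X2"), tau=tau, seed=seed,
    )


def eq3_config(preset: str = "xstar_strong", n_training: int = 2,
               n_per_study: int = 100, sigma_eps: float = 1.0, tau: float = 0.0,
               seed: int = 0) -> SimulationConfig:
    """Sparse-signal design: 40 predictive + 120 irrelevant genes.

    ``preset="xstar_strong"`` sets beta(X1..X20)=5 and beta(Xs1..Xs10)=10;
    ``preset="x_strong"`` sets beta(X1..X20)=10 and beta(Xs1..Xs20)=5.
    Per study (validation included), 10 of the 20 Xs genes and 50 of the
    120 Z genes are masked: 100 observed genes per study.
    """
    if preset == "xstar_strong":
        beta = tuple((g, 5.0) for g in _gene_names("X", 20)) + \
               tuple((f"Xs{i}", 10.0) for i in range(1, 11))
    elif preset == "x_strong":
        beta = tuple((g, 10.0) for g in _gene_names("X", 20)) + \
               tuple((g, 5.0) for g in _gene_names("Xs", 20))
    else:
        raise ValueError(f"unknown preset {preset!r}")
    design = _dict_to_tuples({
        "kind": "blocks", "mask_validation": True,
        "blocks": [
            {"pool": _gene_names("Xs", 20), "count": 10},
            {"pool": _gene_names("Z", 120), "count": 50},
        ],
    })
    return SimulationConfig(
        mechanism="eq3", n_per_study=n_per_study, n_training=n_training,
        beta=beta, sigma_eps=sigma_eps, z_mean=0.0, z_corr=0.2,
        missing_design=design, protected=tuple(_gene_names("X", 20)),
        tau=tau, seed=seed,
    )


def nonlinear_config(missing_proportion: float = 0.3, n_training: int = 4,
                     n_per_study: int = 100, sigma_eps: float = 1.0,
                     seed: int = 0, beta_value: float = 1.0) -> SimulationConfig:
    """eq1 layout with partner genes built from sine/cosine maps of X.

    Non-canonical: the exact published functional form is unavailable, so
    this mechanism uses Xs_j = sin(X w_j) + cos(X v_j) with fixed random
    projection weights drawn once per collection.
    """
    genes = _gene_names("X", 5) + _gene_names("Xs", 5)
    beta = tuple((g, beta_value) for g in genes)
    design = _dict_to_tuples({"kind": "proportion", "proportion": missing_proportion})
    return SimulationConfig(
        mechanism="nonlinear", n_per_study=n_per_study, n_training=n_training,
        beta=beta, sigma_eps=sigma_eps, missing_design=design,
        protected=("X1", "X2"), seed=seed,
    )


@dataclass
class TruthRecord:
    """Pre-masking matrices, masks and outcomes for scoring imputations."""

    full: dict[str, pd.DataFrame]
    masks: dict[str, tuple[str, ...]]
    outcomes: dict[str, np.ndarray]
    heterogeneity: dict[str, np.ndarray]
    config: SimulationConfig


def _equicorr_cov(p: int, var: float, cov: float) -> np.ndarray:
    sigma = np.full((p, p), cov)
    np.fill_diagonal(sigma, var)
    return sigma


def _mechanism_layout(mechanism: str) -> dict[str, list[str]]:
    if mechanism in ("eq1", "nonlinear"):
        return {"x": _gene_names("X", 5), "xs": _gene_names("Xs", 5), "z": []}
    if mechanism == "eq2":
        return {"x": _gene_names("X", 5), "xs": _gene_names("Xs", 5),
                "z": _gene_names("Z", 10)}
    return {"x": _gene_names("X", 20), "xs": _gene_names("Xs", 20),
            "z": _gene_names("Z", 120)}


def apply_heterogeneity(X: np.ndarray, n_targets: int, tau: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw one study's random-slope partner block.

    A study-level mean slope gamma_k ~ N(0, tau^2) is drawn, then per
    target gene j a slope vector gamma_kj ~ N(gamma_k, I) over the columns
    of ``X``; the partner block is the noiseless linear map X @ gamma_kj.
    Returns ``(Xs, slopes)`` with ``slopes`` of shape (n_targets, n_sources).
    Larger tau spreads the slope vectors further apart across studies.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    gamma_k = rng.normal(0.0, tau) if tau > 0 else 0.0
    slopes = rng.normal(gamma_k, 1.0, size=(n_targets, X.shape[1]))
    return X @ slopes.T, slopes


def design_missingness(gene_pool: Sequence[str], proportion: float, n_studies: int,
                       protected: Sequence[str], seed: int,
                       max_redraws: int = 1000) -> list[list[str]]:
    """Per-study random masks: ``round(proportion * |pool|)`` genes each.

    Protected genes are excluded from the maskable pool.  Draws are without
    replacement and seeded.  A pattern that masks some gene in every study
    is redrawn (bounded, seeded) when a valid pattern is feasible; at high
    proportions — where almost every pattern retires some gene from all
    studies, the regime the benchmark sweeps deliberately visit — the last
    draw is returned and fully masked genes simply drop out of the
    collection's training union.  ``proportion = 1`` is an error: every
    maskable gene would be gone from every study.
    """
    if not 0 <= proportion <= 1:
        raise ValueError("proportion must be in [0, 1]")
    pool = sorted(set(gene_pool) - set(protected))
    if proportion > 0 and not pool:
        raise ValueError("proportion > 0 but the maskable pool is empty")
    count = round(proportion * len(pool))
    if count == 0:
        return [[] for _ in range(n_studies)]
    if count >= len(pool):
        raise ValueError(
            "every maskable gene would be masked in every study; no study "
            "would retain it to train an imputation model"
        )
    rng = np.random.default_rng(seed)
    masks: list[list[str]] = []
    for _ in range(max_redraws):
        masks = [sorted(map(str, rng.choice(pool, size=count, replace=False)))
                 for _ in range(n_studies)]
        if not set(pool).intersection(*map(set, masks)):
            break
    return masks


def _resolve_masks(config: SimulationConfig, study_ids: list[str],
                   validation_id: str, genes: list[str],
                   rng: np.random.Generator) -> dict[str, list[str]]:
    design = config._design()
    kind = design.get("kind", "proportion") if design else "proportion"
    training_ids = [s for s in study_ids if s != validation_id]
    masks: dict[str, list[str]] = {sid: [] for sid in study_ids}
    if kind == "proportion":
        prop = design.get("proportion", 0.0) if design else 0.0
        pool = [g for g in genes if g not in config.protected]
        if prop > 0:
            drawn = design_missingness(pool, prop, len(training_ids),
                                       config.protected,
                                       seed=int(rng.integers(2**31)))
            for sid, m in zip(training_ids, drawn):
                masks[sid] = m
    elif kind == "blocks":
        mask_validation = bool(design.get("mask_validation", False))
        targets = study_ids if mask_validation else training_ids
        for sid in targets:
            combined: list[str] = []
            for block in design["blocks"]:
                pool = sorted(set(block["pool"]) - set(config.protected))
                count = int(block["count"])
                if count > len(pool):
                    raise ValueError(f"block count {count} exceeds pool size {len(pool)}")
                combined.extend(sorted(map(str, rng.choice(pool, size=count, replace=False))))
            masks[sid] = sorted(combined)
    elif kind == "explicit":
        per_study = design["per_study"]
        unknown = set(per_study) - set(study_ids)
        if unknown:
            raise ValueError(f"explicit missing_design names unknown studies {sorted(unknown)}")
        for sid, genes_m in per_study.items():
            bad = set(genes_m) & set(config.protected)
            if bad:
                raise ValueError(f"cannot mask protected genes {sorted(bad)}")
            absent = set(genes_m) - set(genes)
            if absent:
                raise ValueError(f"missing_design names unknown genes {sorted(absent)}")
            masks[sid] = sorted(genes_m)
        fully = set(genes).intersection(*(set(masks[sid]) for sid in training_ids))
        if fully:
            raise ValueError(
                f"genes {sorted(fully)} are masked in every training study; "
                "nothing to train their imputation models on"
            )
    else:
        raise ValueError(f"unknown missing_design kind {kind!r}")
    return masks


def generate_collection(config: SimulationConfig
                        ) -> tuple[list[Study], Study, TruthRecord]:
    """Draw one multi-study collection: training studies, validation, truth.

    Every study draws ``n_per_study`` independent samples; the outcome is
    the configured linear form plus N(0, sigma_eps^2) noise.  The truth
    record keeps each study's complete pre-masking matrix, the applied
    masks, every outcome (including the validation study's) and any
    heterogeneity slopes, so imputation error can be scored exactly.
    """
    layout = _mechanism_layout(config.mechanism)
    x_genes, xs_genes, z_genes = layout["x"], layout["xs"], layout["z"]
    genes = x_genes + xs_genes + z_genes
    beta = config.beta_map
    beta_vec = np.array([beta.get(g, 0.0) for g in genes])

    rng = np.random.default_rng(config.seed)
    study_ids = [f"T{i}" for i in range(1, config.n_training + 1)] + ["V"]
    n = config.n_per_study

    slope_het = config.tau > 0 and config.mechanism in ("eq1", "nonlinear")
    mean_het = config.tau > 0 and config.mechanism in ("eq2", "eq3")

    full: dict[str, pd.DataFrame] = {}
    outcomes: dict[str, np.ndarray] = {}
    het: dict[str, np.ndarray] = {}
    for sid in study_ids:
        if config.mechanism == "nonlinear":
            cov_x = _equicorr_cov(len(x_genes), 1.0, config.mvn_cov)
            X = rng.multivariate_normal(np.full(len(x_genes), config.mvn_mean),
                                        cov_x, size=n, method="cholesky")
            W = rng.normal(size=(len(xs_genes), len(x_genes)))
            Vw = rng.normal(size=(len(xs_genes), len(x_genes)))
            Xs = np.sin(X @ W.T) + np.cos(X @ Vw.T)
        elif slope_het:
            cov_x = _equicorr_cov(len(x_genes), 1.0, config.mvn_cov)
            X = rng.multivariate_normal(np.full(len(x_genes), config.mvn_mean),
                                        cov_x, size=n, method="cholesky")
            Xs, slopes = apply_heterogeneity(X, len(xs_genes), config.tau, rng)
            het[sid] = slopes
        else:
            p_pred = len(x_genes) + len(xs_genes)
            cov = _equicorr_cov(p_pred, 1.0, config.mvn_cov)
            block = rng.multivariate_normal(np.full(p_pred, config.mvn_mean),
                                            cov, size=n, method="cholesky")
            X, Xs = block[:, :len(x_genes)], block[:, len(x_genes):]
        parts = [X, Xs]
        if z_genes:
            z_mean = config.z_mean
            if mean_het:
                z_mean = z_mean + rng.normal(0.0, config.tau)
            cov_z = _equicorr_cov(len(z_genes), 1.0, config.z_corr)
            parts.append(rng.multivariate_normal(np.full(len(z_genes), z_mean),
                                                 cov_z, size=n, method="cholesky"))
        G = np.hstack(parts)
        eps = rng.normal(0.0, config.sigma_eps, size=n)
        y = G @ beta_vec + eps
        index = [f"{sid}_s{i}" for i in range(1, n + 1)]
        full[sid] = pd.DataFrame(G, columns=genes, index=index)
        outcomes[sid] = y

    masks = _resolve_masks(config, study_ids, "V", genes, rng)

    training: list[Study] = []
    for sid in study_ids[:-1]:
        kept = [g for g in genes if g not in masks[sid]]
        training.append(Study(sid, full[sid].loc[:, kept], outcomes[sid], TRAINING))
    kept_v = [g for g in genes if g not in masks["V"]]
    validation = Study("V", full["V"].loc[:, kept_v], outcomes["V"], VALIDATION)

    truth = TruthRecord(
        full=full,
        masks={sid: tuple(masks[sid]) for sid in study_ids},
        outcomes=outcomes,
        heterogeneity=het,
        config=config,
    )
    return training, validation, truth


def outcome_variance(config: SimulationConfig) -> float:
    """Closed-form Var(Y) = beta' Sigma beta + sigma_eps^2 (homogeneous case)."""
    layout = _mechanism_layout(config.mechanism)
    x_genes, xs_genes, z_genes = layout["x"], layout["xs"], layout["z"]
    genes = x_genes + xs_genes + z_genes
    beta = config.beta_map
    p_pred = len(x_genes) + len(xs_genes)
    sigma = np.zeros((len(genes), len(genes)))
    sigma[:p_pred, :p_pred] = _equicorr_cov(p_pred, 1.0, config.mvn_cov)
    if z_genes:
        sigma[p_pred:, p_pred:] = _equicorr_cov(len(z_genes), 1.0, config.z_corr)
    b = np.array([beta.get(g, 0.0) for g in genes])
    return float(b @ sigma @ b + config.sigma_eps**2)
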