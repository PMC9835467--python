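"""Cross-study feature-harmonization strategies.

Given S studies measuring overlapping gene panels, the strategies here
produce a collection on a common panel that a single outcome model can be
trained on:

* **omit** — keep only the global gene intersection (the conventional
  baseline; discards every study-specific gene).
* **pairwise** — for each of the ``C(S, 2)`` study pairs, impute each gene
  unique to one member into the other using the *pair* intersection as the
  feature pool; genes imputed by several pairs are averaged.  The pair
  intersection is never smaller than the global intersection, so each
  imputation model sees at least as many features as the merged approach.
* **merged** — pool all studies and impute every missing gene from the
  global intersection with a single model per gene.
* **subset-of-k** — the generalization imputing within every ``C(S, k)``
  study subset using the subset intersection; ``k=2`` is pairwise and
  ``k=S`` is merged.
* **Core / All pairwise** — the variants for an incomplete external
  validation study V without outcome: each training study is first screened
  to its top-q outcome-predictive genes; missing screened genes are imputed
  using either H1 (screened genes shared by both training sets and V —
  Core) or H_int (all genes shared by both training sets and V — All).

Averaging across pairs is unweighted, and every fit consumes its inputs in
lexicographic study/gene order, so all strategies are invariant to the order
in which studies are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, lasso_path
from sklearn.model_selection import KFold

from .datamodel import (
    CoreAllSets,
    Study,
    build_core_all_sets,
    partition_genes,
    validate_collection,
)
from .imputers import FittedImputer, LearnerSpec, fit_imputer, predict_imputer

__all__ = [
    "ImputationLedger",
    "Method",
    "METHOD_NAMES",
    "impute_omit",
    "impute_pairwise",
    "impute_merged",
    "impute_subset_k",
    "screen_top_q",
    "impute_core",
    "impute_all",
    "run_core_all_multi",
    "fit_outcome_model",
    "predict_outcome",
    "run_method",
]

METHOD_NAMES = ("omit", "pairwise", "merged", "subset_k", "core_pairwise", "all_pairwise")


@dataclass(frozen=True)
class Method:
    """A named harmonization strategy plus its parameters.

    ``k`` is required for ``subset_k``; ``q`` (screening size) for the
    Core/All variants.  ``learner`` is the imputation learner; the outcome
    model is always a cross-validated lasso on the harmonized panel.
    """

    name: str
    learner: LearnerSpec = LearnerSpec()
    k: Optional[int] = None
    q: Optional[int] = None

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValueError(f"unknown method {self.name!r}; choose from {METHOD_NAMES}")
        if self.name == "subset_k" and (self.k is None or self.k < 2):
            raise ValueError("subset_k requires k >= 2")
        if self.name in ("core_pairwise", "all_pairwise") and (self.q is None or self.q < 1):
            raise ValueError(f"{self.name} requires screening size q >= 1")

    @property
    def label(self) -> str:
        if self.name == "subset_k":
            return f"subset_{self.k}"
        return self.name


class ImputationLedger:
    """Accumulates per-pair imputed vectors for each structurally missing
    (study, gene) cell and finalizes them by unweighted averaging.

    Entries are averaged in sorted source order, so the finalized values do
    not depend on the order in which pairs were processed.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], dict[str, np.ndarray]] = {}

    def add(self, study_id: str, gene: str, source: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        key = (study_id, gene)
        bucket = self._entries.setdefault(key, {})
        if source in bucket:
            raise ValueError(f"duplicate ledger entry {key} from source {source!r}")
        if bucket:
            first = next(iter(bucket.values()))
            if len(first) != len(values):
                raise ValueError(f"inconsistent vector length for {key}")
        bucket[source] = values

    def __len__(self) -> int:
        return len(self._entries)

    def n_sources(self, study_id: str, gene: str) -> int:
        return len(self._entries.get((study_id, gene), {}))

    def finalize(self) -> dict[tuple[str, str], np.ndarray]:
        """Element-wise mean of each cell's entries, in sorted-source order."""
        out = {}
        for key, bucket in self._entries.items():
            stacked = np.vstack([bucket[src] for src in sorted(bucket)])
            out[key] = stacked.mean(axis=0)
        return out

    def report(self) -> pd.DataFrame:
        """One row per imputed (study, gene): contributing source count and list."""
        rows = [
            {"study_id": sid, "gene": g, "n_sources": len(bucket),
             "sources": ";".join(sorted(bucket))}
            for (sid, g), bucket in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows, columns=["study_id", "gene", "n_sources", "sources"])


def _sorted_studies(studies: Sequence[Study]) -> list[Study]:
    return sorted(studies, key=lambda s: s.study_id)


def _assemble(studies: Sequence[Study], columns: Sequence[str],
              finalized: dict[tuple[str, str], np.ndarray]) -> list[Study]:
    """Rebuild each study on ``columns``: observed values verbatim,
    ledger-finalized values for structurally missing genes."""
    out = []
    for s in studies:
        data = {}
        for g in columns:
            if g in s.expression.columns:
                data[g] = s.expression[g].to_numpy(dtype=float)
            elif (s.study_id, g) in finalized:
                data[g] = finalized[(s.study_id, g)]
            else:
                raise ValueError(
                    f"gene {g!r} is missing from study {s.study_id!r} and was "
                    "imputed by no pair/subset"
                )
        df = pd.DataFrame(data, index=s.expression.index, columns=list(columns))
        out.append(s.with_expression(df))
    return out


# ---------------------------------------------------------------------------
# generic strategies (all studies carry the training role)


def impute_omit(studies: Sequence[Study]) -> list[Study]:
    """Restrict every study to the global gene intersection (no imputation)."""
    validate_collection(studies)
    common = frozenset.intersection(*(s.gene_set for s in studies))
    if not common:
        raise ValueError("global gene intersection is empty")
    cols = sorted(common)
    return [s.with_expression(s.subset(cols)) for s in studies]


def impute_pairwise(studies: Sequence[Study], spec: LearnerSpec,
                    with_ledger: bool = False):
    """Impute within every study pair using the pair intersection, then average.

    For each unordered pair (s, j): one lasso per gene unique to s, trained
    on s with the pair's shared genes as features, predicts that gene in j
    (and symmetrically).  Genes imputed by several pairs are averaged.
    With ``with_ledger=True`` the (studies, ledger) pair is returned.
    """
    validate_collection(studies)
    ordered = _sorted_studies(studies)
    ledger = ImputationLedger()
    for a, b in combinations(ordered, 2):
        part = partition_genes(a.gene_set, b.gene_set)
        feats = list(part.shared)
        source = f"pair:{a.study_id}|{b.study_id}"
        for holder, receiver, unique in ((a, b, part.only_s), (b, a, part.only_j)):
            X_recv = receiver.subset(feats)
            for g in unique:
                model = fit_imputer(holder.subset(feats), holder.expression[g].to_numpy(),
                                    spec, target_gene=g)
                ledger.add(receiver.study_id, g, source, predict_imputer(model, X_recv))
    union = sorted(frozenset().union(*(s.gene_set for s in studies)))
    out = _match_input_order(studies, _assemble(ordered, union, ledger.finalize()))
    return (out, ledger) if with_ledger else out


def impute_merged(studies: Sequence[Study], spec: LearnerSpec,
                  with_ledger: bool = False):
    """Pool all studies; impute each missing gene from the global intersection.

    One model per missing gene, trained on the row-concatenation of every
    study observing the gene, with the global intersection as features.
    """
    validate_collection(studies)
    ordered = _sorted_studies(studies)
    common = sorted(frozenset.intersection(*(s.gene_set for s in studies)))
    if not common:
        raise ValueError("global gene intersection is empty")
    union = sorted(frozenset().union(*(s.gene_set for s in studies)))
    ledger = ImputationLedger()
    for g in union:
        holders = [s for s in ordered if g in s.expression.columns]
        receivers = [s for s in ordered if g not in s.expression.columns]
        if not receivers:
            continue
        train_X = pd.concat([s.subset(common) for s in holders], axis=0, ignore_index=True)
        train_y = np.concatenate([s.expression[g].to_numpy(dtype=float) for s in holders])
        model = fit_imputer(train_X, train_y, spec, target_gene=g)
        for r in receivers:
            ledger.add(r.study_id, g, "merged", predict_imputer(model, r.subset(common)))
    out = _match_input_order(studies, _assemble(ordered, union, ledger.finalize()))
    return (out, ledger) if with_ledger else out


def impute_subset_k(studies: Sequence[Study], k: int, spec: LearnerSpec,
                    with_ledger: bool = False):
    """Impute within every size-k study subset using the subset intersection.

    ``k=2`` reproduces :func:`impute_pairwise` exactly and ``k=S`` reproduces
    :func:`impute_merged` exactly (same fits, same averaging).  A subset with
    an empty gene intersection is skipped with a warning; it is an error only
    if some missing gene ends up covered by no usable subset.
    """
    S = len(studies)
    if not 2 <= k <= S:
        raise ValueError(f"k must satisfy 2 <= k <= {S}, got {k}")
    validate_collection(studies)
    ordered = _sorted_studies(studies)
    ledger = ImputationLedger()
    for subset in combinations(ordered, k):
        inter = frozenset.intersection(*(s.gene_set for s in subset))
        sub_ids = "|".join(s.study_id for s in subset)
        if not inter:
            warnings.warn(f"subset {sub_ids} shares no genes; skipped", stacklevel=2)
            continue
        feats = sorted(inter)
        sub_union = frozenset().union(*(s.gene_set for s in subset))
        source = f"subset:{sub_ids}"
        for g in sorted(sub_union - inter):
            holders = [s for s in subset if g in s.expression.columns]
            receivers = [s for s in subset if g not in s.expression.columns]
            train_X = pd.concat([s.subset(feats) for s in holders], axis=0, ignore_index=True)
            train_y = np.concatenate([s.expression[g].to_numpy(dtype=float) for s in holders])
            model = fit_imputer(train_X, train_y, spec, target_gene=g)
            for r in receivers:
                ledger.add(r.study_id, g, source, predict_imputer(model, r.subset(feats)))
    union = sorted(frozenset().union(*(s.gene_set for s in studies)))
    out = _match_input_order(studies, _assemble(ordered, union, ledger.finalize()))
    return (out, ledger) if with_ledger else out


def _match_input_order(inputs: Sequence[Study], outputs: list[Study]) -> list[Study]:
    by_id = {s.study_id: s for s in outputs}
    return [by_id[s.study_id] for s in inputs]


# ---------------------------------------------------------------------------
# screening and the Core / All pairwise variants


def screen_top_q(study: Study, q: int, seed: int, cv_folds: int = 10,
                 n_alphas: int = 50) -> list[str]:
    """Select the top-q genes by magnitude of lasso coefficient on the outcome.

    A cross-validated lasso of the outcome on all of the study's genes is
    fitted first.  If it retains at least ``min(q, p)`` genes, the q largest
    |coefficient| genes are returned.  Otherwise the penalization path is
    descended to the largest penalty admitting at least q nonzero
    coefficients and the ranking is taken there.  Ties break
    lexicographically by gene ID; if no penalty yields any signal (e.g. a
    zero-variance outcome) the fallback ranking is absolute marginal
    correlation with the outcome, again with lexicographic ties.
    """
    if study.outcome is None:
        raise ValueError(f"study {study.study_id!r} has no outcome; cannot screen")
    if q < 1:
        raise ValueError("q must be >= 1")
    genes = sorted(study.gene_ids)
    target = min(q, len(genes))
    X = study.subset(genes).to_numpy(dtype=float)
    y = np.asarray(study.outcome, dtype=float)
    x_sd = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / np.where(x_sd > 0, x_sd, 1.0)
    y_sd = y.std()
    if y_sd == 0:
        return genes[:target]
    ys = (y - y.mean()) / y_sd

    folds = min(cv_folds, len(y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv_model = LassoCV(cv=kf, fit_intercept=False, alphas=n_alphas, max_iter=50_000)
        cv_model.fit(Xs, ys)
    coef = cv_model.coef_
    if np.count_nonzero(coef) < target:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alphas, coefs, _ = lasso_path(Xs, ys, alphas=n_alphas, max_iter=50_000)
        nnz = np.count_nonzero(coefs, axis=0)  # alphas descend along the path
        rich = np.flatnonzero(nnz >= target)
        coef = coefs[:, rich[0]] if rich.size else coefs[:, -1]
    if not np.any(coef):
        corr = np.abs([np.corrcoef(Xs[:, j], ys)[0, 1] if x_sd[j] > 0 else 0.0
                       for j in range(len(genes))])
        order = sorted(range(len(genes)), key=lambda j: (-corr[j], genes[j]))
        return [genes[j] for j in order[:target]]
    nonzero = [j for j in range(len(genes)) if coef[j] != 0]
    order = sorted(nonzero, key=lambda j: (-abs(coef[j]), genes[j]))
    return [genes[j] for j in order[:target]]


def _core_all_pair(T_i: Study, T_j: Study, V: Study, q: int, spec: LearnerSpec,
                   ledger: ImputationLedger, variant: str,
                   q_i: Optional[Sequence[str]] = None,
                   q_j: Optional[Sequence[str]] = None) -> CoreAllSets:
    if T_i.outcome is None or T_j.outcome is None:
        raise ValueError("training studies must carry outcomes for screening")
    if q_i is None:
        q_i = screen_top_q(T_i, q, spec.seed, cv_folds=spec.cv_folds, n_alphas=spec.n_alphas)
    if q_j is None:
        q_j = screen_top_q(T_j, q, spec.seed, cv_folds=spec.cv_folds, n_alphas=spec.n_alphas)
    sets = build_core_all_sets(q_i, q_j, V.gene_set, T_i.gene_set, T_j.gene_set)
    if variant == "core":
        feats = [g for g in sets.h1]
        if not feats:
            raise ValueError(
                f"Core strategy: H1 empty for pair ({T_i.study_id}, {T_j.study_id}) — "
                "no screened gene is shared by both training sets and the validation set"
            )
    elif variant == "all":
        feats = [g for g in sets.h_int]
        if not feats:
            raise ValueError(
                f"All strategy: H_int empty for pair ({T_i.study_id}, {T_j.study_id})"
            )
    else:
        raise ValueError(f"variant must be 'core' or 'all', got {variant!r}")

    source = f"{variant}:{T_i.study_id}|{T_j.study_id}"
    for g in sets.h2:
        if variant == "core":
            # holders are the training sets that *screened* g
            holders = [t for t, flag in ((T_i, g in sets.q_i), (T_j, g in sets.q_j)) if flag]
        else:
            # holders are the training sets measuring g at all
            holders = [t for t in (T_i, T_j) if g in t.expression.columns]
        assert holders, f"gene {g!r} in H2 but held by neither training set"
        # targets: training sets structurally lacking g, plus V unless V observes g
        targets = [t for t in (T_i, T_j) if g not in t.expression.columns]
        if g not in sets.q_v:
            targets.append(V)
        if not targets:
            continue  # everyone measuring g uses original values
        feats_g = [f for f in feats if f != g]
        train_X = pd.concat([t.subset(feats_g) for t in holders], axis=0, ignore_index=True)
        train_y = np.concatenate([t.expression[g].to_numpy(dtype=float) for t in holders])
        model = fit_imputer(train_X, train_y, spec, target_gene=g)
        for t in targets:
            ledger.add(t.study_id, g, source, predict_imputer(model, t.subset(feats_g)))
    return sets


def impute_core(T_i: Study, T_j: Study, V: Study, q: int, spec: LearnerSpec,
                ledger: ImputationLedger, q_i: Optional[Sequence[str]] = None,
                q_j: Optional[Sequence[str]] = None) -> CoreAllSets:
    """Core pairwise imputation for one training pair plus validation study.

    Targets are the genes in H2 (screened by one or both training sets but
    not observed everywhere); the feature pool is H1, the screened genes
    common to T_i, T_j and V.  A gene screened by exactly one training set
    is imputed into whichever of the other training set / V structurally
    lacks it (a study that measures the gene keeps its original values); a
    gene screened by both training sets but absent from V is imputed into V
    from a single model fitted on the pooled pair.
    """
    return _core_all_pair(T_i, T_j, V, q, spec, ledger, "core", q_i, q_j)


def impute_all(T_i: Study, T_j: Study, V: Study, q: int, spec: LearnerSpec,
               ledger: ImputationLedger, q_i: Optional[Sequence[str]] = None,
               q_j: Optional[Sequence[str]] = None) -> CoreAllSets:
    """All pairwise imputation: same H2 targets as Core, feature pool H_int.

    H_int is the intersection of *all* available genes (screened or not)
    across T_i, T_j and V, so H1 is always a subset of H_int.  A gene present
    but unscreened in a study keeps its original values there; imputation
    happens only where the gene is structurally absent (and in V when V
    lacks it).
    """
    return _core_all_pair(T_i, T_j, V, q, spec, ledger, "all", q_i, q_j)


def run_core_all_multi(training: Sequence[Study], V: Study, q: int, variant: str,
                       spec: LearnerSpec, with_ledger: bool = False):
    """Run the Core or All variant over all training pairs and finalize.

    Screening is computed once per training study (it depends only on the
    study), every pair shares one ledger, multiply-imputed genes are
    averaged, and the returned studies — training and validation alike —
    carry the union of all screened gene panels.
    """
    if len(training) < 2:
        raise ValueError("need at least two training studies")
    ordered = _sorted_studies(training)
    screened = {
        s.study_id: screen_top_q(s, q, spec.seed, cv_folds=spec.cv_folds,
                                 n_alphas=spec.n_alphas)
        for s in ordered
    }
    ledger = ImputationLedger()
    for a, b in combinations(ordered, 2):
        _core_all_pair(a, b, V, q, spec, ledger, variant,
                       q_i=screened[a.study_id], q_j=screened[b.study_id])
    finalized = ledger.finalize()
    h_all = sorted(frozenset().union(*(frozenset(v) for v in screened.values())))
    out_training = _assemble(ordered, h_all, finalized)
    out_v = _assemble([V], h_all, finalized)[0]
    result = (_match_input_order(training, out_training), out_v)
    return (*result, ledger) if with_ledger else result


# ---------------------------------------------------------------------------
# downstream outcome model


def fit_outcome_model(training: Sequence[Study], spec: LearnerSpec) -> FittedImputer:
    """Fit the final outcome lasso on the row-concatenation of the studies.

    All training studies must share an identical gene panel (the output of
    any strategy above) and carry outcomes.
    """
    if not training:
        raise ValueError("no training studies")
    panels = [s.gene_set for s in training]
    if any(p != panels[0] for p in panels[1:]):
        diff = sorted(frozenset().union(*panels) - frozenset.intersection(*panels))
        raise ValueError(f"training studies disagree on gene panels; differing genes: {diff}")
    if any(s.outcome is None for s in training):
        raise ValueError("every training study needs an outcome")
    cols = sorted(panels[0])
    ordered = _sorted_studies(training)
    X = pd.concat([s.subset(cols) for s in ordered], axis=0, ignore_index=True)
    y = np.concatenate([s.outcome for s in ordered])
    return fit_imputer(X, y, spec, target_gene="__outcome__")


def predict_outcome(model: FittedImputer, V: Study) -> np.ndarray:
    """Predict the outcome for a validation study on the model's gene panel."""
    missing = [g for g in model.feature_genes if g not in V.expression.columns]
    extra = [g for g in V.gene_ids if g not in model.feature_genes]
    if missing:
        raise ValueError(
            f"validation study {V.study_id!r} lacks model genes {sorted(missing)}; "
            f"genes outside the model panel: {sorted(extra)}"
        )
    return predict_imputer(model, V.expression)


def run_method(method: Method, training: Sequence[Study], V: Study,
               outcome_spec: Optional[LearnerSpec] = None) -> np.ndarray:
    """Harmonize with ``method``, fit the outcome lasso, predict V.

    The validation outcome is never consulted; V participates only through
    its expression matrix (and, for Core/All, its available gene panel).
    Returns the predicted outcome vector for V's samples.
    """
    outcome_spec = outcome_spec or LearnerSpec(seed=method.learner.seed)
    V_blind = Study(V.study_id, V.expression, None, role="validation")
    if method.name == "omit":
        restricted = impute_omit([*training, V_blind])
        train_r, v_r = restricted[:-1], restricted[-1]
    elif method.name in ("pairwise", "merged", "subset_k"):
        if method.name == "pairwise":
            train_r = impute_pairwise(training, method.learner)
        elif method.name == "merged":
            train_r = impute_merged(training, method.learner)
        else:
            train_r = impute_subset_k(training, method.k, method.learner)
        cols = sorted(train_r[0].gene_set)
        v_r = V_blind.with_expression(V_blind.subset(cols))
    else:
        variant = "core" if method.name == "core_pairwise" else "all"
        train_r, v_r = run_core_all_multi(training, V_blind, method.q, variant,
                                          method.learner)
    model = fit_outcome_model(train_r, outcome_spec)
    return predict_outcome(model, v_r)
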