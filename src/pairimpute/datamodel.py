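"""Core data types and gene-set algebra for multi-study expression collections.

A *collection* is a set of studies measuring overlapping but non-identical
gene panels on disjoint patient cohorts.  Missingness is structural: a gene
is either measured for every sample in a study or absent from the study
entirely, so a study is fully described by a dense samples x genes matrix
plus the list of gene identifiers it measures.

Gene identity is exact string match on gene IDs; no probe-to-gene mapping or
symbol aliasing is attempted.  All derived gene sets are returned in
lexicographic order so that every downstream computation is reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Study",
    "GenePartition",
    "CoreAllSets",
    "partition_genes",
    "build_core_all_sets",
    "validate_collection",
    "read_study",
    "write_study",
]

TRAINING = "training"
VALIDATION = "validation"


@dataclass
class Study:
    """One cohort: a dense samples x genes expression matrix plus metadata.

    Parameters
    ----------
    study_id
        Unique identifier of the cohort.
    expression
        DataFrame with one row per sample and one column per gene; the
        column labels are the gene IDs, the index holds sample IDs.
    outcome
        Continuous response vector, one entry per sample.  May be ``None``
        for a validation study whose outcome is withheld.
    role
        ``"training"`` or ``"validation"``.
    """

    study_id: str
    expression: pd.DataFrame
    outcome: Optional[np.ndarray] = None
    role: str = TRAINING

    def __post_init__(self) -> None:
        if self.role not in (TRAINING, VALIDATION):
            raise ValueError(f"role must be 'training' or 'validation', got {self.role!r}")
        cols = list(self.expression.columns)
        if len(cols) != len(set(cols)):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"study {self.study_id!r} has duplicate gene IDs: {dupes}")
        if self.expression.isna().any().any():
            raise ValueError(
                f"study {self.study_id!r} contains missing entries; missingness "
                "must be structural (whole columns absent), not in-matrix NaNs"
            )
        if self.outcome is not None:
            self.outcome = np.asarray(self.outcome, dtype=float)
            if self.outcome.ndim != 1 or len(self.outcome) != self.n_samples:
                raise ValueError(
                    f"study {self.study_id!r}: outcome length {len(self.outcome)} "
                    f"does not match sample count {self.n_samples}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [str(c) for c in self.expression.columns]

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def subset(self, genes: Sequence[str]) -> pd.DataFrame:
        """Expression restricted to ``genes`` in the given order."""
        missing = [g for g in genes if g not in self.expression.columns]
        if missing:
            raise KeyError(f"study {self.study_id!r} lacks genes {sorted(missing)}")
        return self.expression.loc[:, list(genes)]

    def with_expression(self, expression: pd.DataFrame) -> "Study":
        return Study(self.study_id, expression, self.outcome, self.role)


@dataclass(frozen=True)
class GenePartition:
    """Three-way split of two studies' gene panels.

    ``shared`` is the pair intersection, ``only_s``/``only_j`` the genes
    unique to each study.  All three are disjoint, lexicographically sorted
    tuples.
    """

    shared: tuple[str, ...]
    only_s: tuple[str, ...]
    only_j: tuple[str, ...]

    @property
    def p_shared(self) -> int:
        return len(self.shared)


def partition_genes(genes_s: Iterable[str], genes_j: Iterable[str]) -> GenePartition:
    """Split two gene sets into shared / unique-to-s / unique-to-j.

    Raises
    ------
    ValueError
        If either set is empty or the intersection is empty: every study
        pair is assumed to share at least one gene.
    """
    set_s, set_j = frozenset(genes_s), frozenset(genes_j)
    if not set_s or not set_j:
        raise ValueError("gene sets must be non-empty")
    shared = set_s & set_j
    if not shared:
        raise ValueError("no shared genes between the two studies")
    return GenePartition(
        shared=tuple(sorted(shared)),
        only_s=tuple(sorted(set_s - set_j)),
        only_j=tuple(sorted(set_j - set_s)),
    )


@dataclass(frozen=True)
class CoreAllSets:
    """Gene sets driving the Core/All imputation variants for one study pair.

    ``q_i``/``q_j`` are the screened (outcome-predictive) genes of the two
    training sets, ``q_v`` every gene available in the validation study.
    ``h = q_i | q_j`` is the candidate prediction panel, ``h1`` its subset
    observed everywhere (the Core feature pool), ``h2 = h - h1`` the genes
    requiring imputation somewhere.  ``qc_i``/``qc_j`` are each training
    set's unscreened genes, and ``h_int`` the intersection of *all* available
    genes across the three studies (the All feature pool).
    """

    q_i: frozenset[str]
    q_j: frozenset[str]
    q_v: frozenset[str]
    qc_i: frozenset[str]
    qc_j: frozenset[str]
    h: tuple[str, ...]
    h1: tuple[str, ...]
    h2: tuple[str, ...]
    hc: tuple[str, ...]
    h_int: tuple[str, ...]


def build_core_all_sets(
    q_i: Iterable[str],
    q_j: Iterable[str],
    q_v: Iterable[str],
    full_i: Iterable[str],
    full_j: Iterable[str],
) -> CoreAllSets:
    """Derive the Core/All gene sets from screened and full gene panels.

    ``full_i``/``full_j`` are the complete gene panels of the two training
    studies; the screened sets must be subsets of them.
    """
    q_i, q_j, q_v = frozenset(q_i), frozenset(q_j), frozenset(q_v)
    full_i, full_j = frozenset(full_i), frozenset(full_j)
    for name, s in (("q_i", q_i), ("q_j", q_j), ("q_v", q_v),
                    ("full_i", full_i), ("full_j", full_j)):
        if not s:
            raise ValueError(f"{name} must be non-empty")
    if not q_i <= full_i:
        raise ValueError(f"screened genes not in study i's panel: {sorted(q_i - full_i)}")
    if not q_j <= full_j:
        raise ValueError(f"screened genes not in study j's panel: {sorted(q_j - full_j)}")
    qc_i = full_i - q_i
    qc_j = full_j - q_j
    h = q_i | q_j
    h1 = q_i & q_j & q_v
    h2 = h - h1
    hc = qc_i | qc_j
    h_int = full_i & full_j & q_v
    return CoreAllSets(
        q_i=q_i, q_j=q_j, q_v=q_v, qc_i=frozenset(qc_i), qc_j=frozenset(qc_j),
        h=tuple(sorted(h)), h1=tuple(sorted(h1)), h2=tuple(sorted(h2)),
        hc=tuple(sorted(hc)), h_int=tuple(sorted(h_int)),
    )


def validate_collection(studies: Sequence[Study]) -> dict:
    """Diagnostics for a multi-study collection.

    Returns a report with pairwise intersection sizes, the global
    intersection, and per-study counts of union genes the study lacks.
    Raises on duplicate study IDs or on a study pair sharing no genes.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    ids = [s.study_id for s in studies]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate study IDs: {sorted({i for i in ids if ids.count(i) > 1})}")
    gene_sets = {s.study_id: s.gene_set for s in studies}
    union = frozenset().union(*gene_sets.values())
    global_int = frozenset.intersection(*gene_sets.values())
    pairwise: dict[tuple[str, str], int] = {}
    for a, b in _sorted_pairs(ids):
        inter = gene_sets[a] & gene_sets[b]
        if not inter:
            raise ValueError(f"studies {a!r} and {b!r} share no genes")
        pairwise[(a, b)] = len(inter)
    return {
        "n_studies": len(studies),
        "union_size": len(union),
        "global_intersection": tuple(sorted(global_int)),
        "global_intersection_size": len(global_int),
        "pairwise_intersection_sizes": pairwise,
        "missing_per_study": {sid: len(union - gs) for sid, gs in gene_sets.items()},
    }


def _sorted_pairs(ids: Sequence[str]) -> list[tuple[str, str]]:
    ordered = sorted(ids)
    return [(a, b) for i, a in enumerate(ordered) for b in ordered[i + 1:]]


# ---------------------------------------------------------------------------
# delimited-text I/O
#
# Layout: first column = sample IDs (index), header row = gene IDs, and an
# optional outcome column identified by name.  Values round-trip losslessly
# because pandas writes shortest-repr floats.


def read_study(
    path: str | Path,
    study_id: Optional[str] = None,
    outcome_column: str = "outcome",
    role: str = TRAINING,
    sep: Optional[str] = None,
) -> Study:
    """Read a study matrix from CSV/TSV.

    ``sep=None`` infers the delimiter from the file suffix (``.tsv`` -> tab,
    otherwise comma).  A column named ``outcome_column`` is split off as the
    response; its absence simply yields ``outcome=None``.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))[1:]
    if len(header) != len(set(header)):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"{path}: duplicate gene columns {dupes}; collapse probes upstream")
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    outcome = None
    if outcome_column in df.columns:
        outcome = df[outcome_column].to_numpy(dtype=float)
        df = df.drop(columns=[outcome_column])
    return Study(
        study_id=study_id or path.stem,
        expression=df.astype(float),
        outcome=outcome,
        role=role,
    )


def write_study(study: Study, path: str | Path, outcome_column: str = "outcome",
                sep: Optional[str] = None) -> None:
    """Write a study to CSV/TSV in the dialect accepted by :func:`read_study`."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = study.expression.copy()
    if study.outcome is not None:
        if outcome_column in df.columns:
            raise ValueError(f"gene column clashes with outcome column {outcome_column!r}")
        df[outcome_column] = study.outcome
    df.to_csv(path, sep=sep, index=True)
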