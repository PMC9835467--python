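import numpy as np
import pandas as pd
import pytest

from pairimpute import Study


def make_study(study_id, genes, X, outcome=None, role="training"):
    X = np.asarray(X, dtype=float)
    df = pd.DataFrame(X, columns=list(genes),
                      index=[f"{study_id}_s{i}" for i in range(X.shape[0])])
    return Study(study_id, df, outcome, role)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def noiseless_collection(rng):
    """Three studies sharing genes A-D; genes E and F are exact linear
    functions of the shared genes and each is structurally missing from one
    study.  Returns (studies, truth) where truth maps (study_id, gene) to
    the withheld column."""
    shared = ["A", "B", "C", "D"]
    w_e = np.array([2.0, -1.0, 0.5, 0.0])
    w_f = np.array([0.0, 1.5, -0.5, 1.0])
    studies, truth = [], {}
    for sid, drop in [("s1", "E"), ("s2", "F"), ("s3", None)]:
        X = rng.normal(size=(40, 4))
        E = X @ w_e + 0.7
        F = X @ w_f - 0.3
        full = np.column_stack([X, E, F])
        genes = shared + ["E", "F"]
        y = full[:, :4].sum(axis=1)
        if drop is not None:
            keep = [g for g in genes if g != drop]
            idx = [genes.index(g) for g in keep]
            truth[(sid, drop)] = full[:, genes.index(drop)].copy()
            studies.append(make_study(sid, keep, full[:, idx], outcome=y))
        else:
            studies.append(make_study(sid, genes, full, outcome=y))
    return studies, truth
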