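import numpy as np
import pandas as pd
import pytest

from pairimpute import (
    ImputationLedger,
    LearnerSpec,
    Method,
    fit_outcome_model,
    impute_all,
    impute_core,
    impute_merged,
    impute_omit,
    impute_pairwise,
    impute_subset_k,
    predict_outcome,
    run_core_all_multi,
    screen_top_q,
)
from conftest import make_study

OLS = LearnerSpec(lambda_policy="fixed", lambda_value=0.0)


def assert_studies_equal(a, b):
    assert [s.study_id for s in a] == [s.study_id for s in b]
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x.expression, y.expression)


class TestLedger:
    def test_finalized_is_unweighted_mean(self):
        led = ImputationLedger()
        led.add("s1", "g", "p1", [1.0, 1.0])
        led.add("s1", "g", "p2", [2.0, 4.0])
        led.add("s1", "g", "p3", [3.0, 1.0])
        np.testing.assert_array_equal(led.finalize()[("s1", "g")], [2.0, 2.0])

    def test_entry_order_does_not_matter(self):
        v1, v2 = [0.1, 0.2], [0.3, 0.5]
        a, b = ImputationLedger(), ImputationLedger()
        a.add("s", "g", "p1", v1); a.add("s", "g", "p2", v2)
        b.add("s", "g", "p2", v2); b.add("s", "g", "p1", v1)
        np.testing.assert_array_equal(a.finalize()[("s", "g")],
                                      b.finalize()[("s", "g")])

    def test_duplicate_source_rejected(self):
        led = ImputationLedger()
        led.add("s", "g", "p1", [1.0])
        with pytest.raises(ValueError, match="duplicate ledger entry"):
            led.add("s", "g", "p1", [2.0])

    def test_report_counts_sources(self):
        led = ImputationLedger()
        led.add("s1", "g", "p1", [1.0]); led.add("s1", "g", "p2", [1.0])
        led.add("s2", "h", "p1", [1.0])
        report = led.report()
        assert set(report["n_sources"]) == {1, 2}
        assert len(report) == 2


class TestOmit:
    def test_restricts_to_global_intersection(self, rng):
        s1 = make_study("s1", ["A", "B", "C"], rng.normal(size=(4, 3)))
        s2 = make_study("s2", ["B", "C", "D"], rng.normal(size=(4, 3)))
        out = impute_omit([s1, s2])
        assert out[0].gene_ids == ["B", "C"] and out[1].gene_ids == ["B", "C"]
        pd.testing.assert_frame_equal(out[0].expression, s1.expression[["B", "C"]])

    def test_identical_panels_unchanged_up_to_order(self, rng):
        s1 = make_study("s1", ["B", "A"], rng.normal(size=(3, 2)))
        s2 = make_study("s2", ["A", "B"], rng.normal(size=(3, 2)))
        out = impute_omit([s1, s2])
        assert out[0].gene_ids == ["A", "B"]
        pd.testing.assert_frame_equal(out[0].expression, s1.expression[["A", "B"]])

    def test_single_common_gene(self, rng):
        studies = [make_study(f"s{i}", genes, rng.normal(size=(3, 3)))
                   for i, genes in enumerate([["A", "B", "C"], ["B", "C", "D"],
                                              ["C", "D", "E"]])]
        out = impute_omit(studies)
        assert all(s.gene_ids == ["C"] for s in out)


class TestPairwise:
    def test_noiseless_linear_recovery(self, noiseless_collection):
        studies, truth = noiseless_collection
        out = impute_pairwise(studies, OLS)
        for (sid, gene), values in truth.items():
            got = next(s for s in out if s.study_id == sid).expression[gene]
            np.testing.assert_allclose(got, values, atol=1e-6)

    def test_average_of_per_pair_predictions(self, noiseless_collection):
        # gene E missing only in s1, observed in s2 and s3: finalized value
        # is the mean of the two per-pair predictions
        studies, truth = noiseless_collection
        out, ledger = impute_pairwise(studies, OLS, with_ledger=True)
        assert ledger.n_sources("s1", "E") == 2
        entries = ledger._entries[("s1", "E")]
        mean = np.vstack(list(entries.values())).mean(axis=0)
        got = next(s for s in out if s.study_id == "s1").expression["E"]
        np.testing.assert_array_equal(got.to_numpy(), mean)

    def test_study_order_invariance(self, noiseless_collection):
        studies, _ = noiseless_collection
        spec = LearnerSpec(seed=7)
        out_a = impute_pairwise(studies, spec)
        out_b = impute_pairwise(studies[::-1], spec)
        assert_studies_equal(sorted(out_a, key=lambda s: s.study_id),
                             sorted(out_b, key=lambda s: s.study_id))

    def test_observed_values_untouched(self, noiseless_collection):
        studies, _ = noiseless_collection
        out = impute_pairwise(studies, LearnerSpec(seed=1))
        for before, after in zip(studies, out):
            for g in before.gene_ids:
                np.testing.assert_array_equal(after.expression[g], before.expression[g])

    def test_two_studies_equals_merged(self, noiseless_collection):
        studies, _ = noiseless_collection
        pair = studies[:2]
        spec = LearnerSpec(seed=5)
        assert_studies_equal(impute_pairwise(pair, spec), impute_merged(pair, spec))


class TestMerged:
    def test_training_rows_pool_observing_studies(self, noiseless_collection):
        studies, _ = noiseless_collection
        _, ledger = impute_merged(studies, OLS, with_ledger=True)
        # each missing gene imputed once, from the single merged model
        assert all(n == 1 for n in
                   (len(b) for b in ledger._entries.values()))

    def test_complete_collection_is_identity(self, rng):
        studies = [make_study(f"s{i}", ["A", "B"], rng.normal(size=(4, 2)))
                   for i in range(3)]
        out = impute_merged(studies, OLS)
        assert_studies_equal(out, [s.with_expression(s.subset(["A", "B"]))
                                   for s in studies])

    def test_merged_feature_pool_is_global_intersection(self, noiseless_collection):
        studies, _ = noiseless_collection
        common = frozenset.intersection(*(s.gene_set for s in studies))
        # every pairwise intersection contains the global one
        for i, a in enumerate(studies):
            for b in studies[i + 1:]:
                assert common <= (a.gene_set & b.gene_set)


class TestSubsetK:
    def test_k2_equals_pairwise(self, noiseless_collection):
        studies, _ = noiseless_collection
        spec = LearnerSpec(seed=2)
        assert_studies_equal(impute_subset_k(studies, 2, spec),
                             impute_pairwise(studies, spec))

    def test_k_equals_s_equals_merged(self, noiseless_collection):
        studies, _ = noiseless_collection
        spec = LearnerSpec(seed=2)
        assert_studies_equal(impute_subset_k(studies, len(studies), spec),
                             impute_merged(studies, spec))

    def test_entry_counts_on_four_studies(self, rng):
        # 4 studies; gene E observed in three of them, missing in s0: with
        # k=3 the subsets containing s0 plus >=1 observer all contribute
        genes_full = ["A", "B", "E"]
        studies = [make_study("s0", ["A", "B"], rng.normal(size=(10, 2)))]
        for i in range(1, 4):
            studies.append(make_study(f"s{i}", genes_full, rng.normal(size=(10, 3))))
        _, ledger = impute_subset_k(studies, 3, OLS, with_ledger=True)
        assert ledger.n_sources("s0", "E") == 3  # C(3,2) subsets contain s0

    def test_k_bounds(self, noiseless_collection):
        studies, _ = noiseless_collection
        with pytest.raises(ValueError, match="k must satisfy"):
            impute_subset_k(studies, 1, OLS)
        with pytest.raises(ValueError, match="k must satisfy"):
            impute_subset_k(studies, 4, OLS)


class TestScreening:
    def test_q_saturates_at_panel_size(self, rng):
        X = rng.normal(size=(30, 4))
        y = X[:, 0] + rng.normal(scale=0.1, size=30)
        s = make_study("s", ["a", "b", "c", "d"], X, outcome=y)
        assert sorted(screen_top_q(s, 99, seed=0)) == ["a", "b", "c", "d"]

    def test_outcome_required(self, rng):
        s = make_study("s", ["a"], rng.normal(size=(5, 1)))
        with pytest.raises(ValueError, match="no outcome"):
            screen_top_q(s, 1, seed=0)

    def test_strong_signals_recovered(self):
        # outcome driven by g01, g02 with large coefficients among 10 noise
        # genes: the pair should be screened in >= 95% of replicates
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            X = r.normal(size=(60, 12))
            y = 5.0 * X[:, 0] + 5.0 * X[:, 1] + r.normal(size=60)
            genes = [f"g{i:02d}" for i in range(1, 13)]
            s = make_study("s", genes, X, outcome=y)
            if set(screen_top_q(s, 2, seed=rep)) == {"g01", "g02"}:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_zero_variance_outcome_deterministic_fallback(self, rng):
        X = rng.normal(size=(20, 3))
        s = make_study("s", ["c", "a", "b"], X, outcome=np.zeros(20))
        assert screen_top_q(s, 2, seed=0) == ["a", "b"]


def _core_all_fixture(rng):
    """Hand-built pair + validation with controlled screened sets.

    T_i genes: c1, c2, gi (gi unique to T_i); T_j genes: c1, c2, gj, gu
    (gj unique to T_j, gu unscreened); V genes: c1, c2, gv_extra.
    """
    n = 25
    def study(sid, genes, role="training"):
        X = rng.normal(size=(n, len(genes)))
        y = X[:, 0] + rng.normal(size=n) if role == "training" else None
        return make_study(sid, genes, X, outcome=y, role=role)
    T_i = study("Ti", ["c1", "c2", "gi", "both"])
    T_j = study("Tj", ["c1", "c2", "gj", "gu", "both"])
    V = study("V", ["c1", "c2", "gj"], role="validation")
    return T_i, T_j, V


class TestCoreScenarios:
    def test_gene_screened_in_one_set_absent_from_v(self, rng):
        # scenario (i): imputed into the other training set and V
        T_i, T_j, V = _core_all_fixture(rng)
        led = ImputationLedger()
        impute_core(T_i, T_j, V, q=3, spec=OLS, ledger=led,
                    q_i=["c1", "c2", "gi"], q_j=["c1", "c2"])
        assert led.n_sources("Tj", "gi") == 1 and led.n_sources("V", "gi") == 1

    def test_gene_screened_in_one_set_present_in_v(self, rng):
        # scenario (ii): V keeps its original values
        T_i, T_j, V = _core_all_fixture(rng)
        led = ImputationLedger()
        impute_core(T_i, T_j, V, q=3, spec=OLS, ledger=led,
                    q_i=["c1", "c2"], q_j=["c1", "c2", "gj"])
        assert led.n_sources("Ti", "gj") == 1
        assert led.n_sources("V", "gj") == 0

    def test_gene_screened_in_both_sets_absent_from_v(self, rng):
        # scenario (iii): single pooled model, imputed into V only
        T_i, T_j, V = _core_all_fixture(rng)
        led = ImputationLedger()
        impute_core(T_i, T_j, V, q=4, spec=OLS, ledger=led,
                    q_i=["c1", "c2", "both"], q_j=["c1", "c2", "both"])
        assert led.n_sources("V", "both") == 1
        assert led.n_sources("Ti", "both") == 0 and led.n_sources("Tj", "both") == 0

    def test_empty_h1_rejected(self, rng):
        T_i, T_j, V = _core_all_fixture(rng)
        led = ImputationLedger()
        with pytest.raises(ValueError, match="H1 empty"):
            impute_core(T_i, T_j, V, q=1, spec=OLS, ledger=led,
                        q_i=["gi"], q_j=["gj"])


class TestAllScenarios:
    def test_unscreened_gene_present_in_v_is_noop(self, rng):
        # scenario (iv): gene in Hc and in V -> everyone keeps originals
        T_i, T_j, V = _core_all_fixture(rng)
        led = ImputationLedger()
        impute_all(T_i, T_j, V, q=2, spec=OLS, ledger=led,
                   q_i=["c1", "c2"], q_j=["c1", "gj"])
        # gj is screened in Tj and observed in V -> no V entry; but Ti lacks
        # gj so it is imputed there; gu never enters H at all
        assert led.n_sources("V", "gj") == 0
        assert all(g != "gu" for (_, g) in led._entries)

    def test_feature_pool_is_h_int(self, rng):
        T_i, T_j, V = _core_all_fixture(rng)
        led = ImputationLedger()
        sets = impute_all(T_i, T_j, V, q=3, spec=OLS, ledger=led,
                          q_i=["c1", "c2", "gi"], q_j=["c1", "c2"])
        # gj is only in T_j and V, gu only in T_j, "both" absent from V
        assert set(sets.h_int) == {"c1", "c2"}
        assert set(sets.h1) <= set(sets.h_int)

    def test_core_pool_never_exceeds_all_pool(self, rng):
        T_i, T_j, V = _core_all_fixture(rng)
        led = ImputationLedger()
        sets = impute_core(T_i, T_j, V, q=3, spec=OLS, ledger=led,
                           q_i=["c1", "c2", "gi"], q_j=["c1", "c2", "gj"])
        assert len(sets.h1) <= len(sets.h_int)


class TestRunCoreAllMulti:
    def _collection(self, rng, n_train=3):
        n = 30
        studies = []
        for i in range(n_train):
            genes = ["c1", "c2", "c3", f"u{i}"]
            X = rng.normal(size=(n, 4))
            y = 2 * X[:, 0] - X[:, 1] + 0.5 * X[:, 3] + rng.normal(scale=0.2, size=n)
            studies.append(make_study(f"T{i}", genes, X, outcome=y))
        V = make_study("V", ["c1", "c2", "c3"], rng.normal(size=(n, 3)),
                       role="validation")
        return studies, V

    def test_single_pair_average_is_raw_prediction(self, rng):
        studies, V = self._collection(rng, n_train=2)
        spec = LearnerSpec(seed=0)
        out_tr, out_v, ledger = run_core_all_multi(studies[:2], V, q=4, variant="core",
                                                   spec=spec, with_ledger=True)
        for (sid, g), bucket in ledger._entries.items():
            assert len(bucket) == 1
            target = out_v if sid == "V" else next(s for s in out_tr if s.study_id == sid)
            np.testing.assert_array_equal(target.expression[g].to_numpy(),
                                          next(iter(bucket.values())))

    @pytest.mark.parametrize("variant", ["core", "all"])
    def test_training_order_invariance(self, rng, variant):
        studies, V = self._collection(rng)
        spec = LearnerSpec(seed=4)
        tr_a, v_a = run_core_all_multi(studies, V, 4, variant, spec)
        tr_b, v_b = run_core_all_multi(studies[::-1], V, 4, variant, spec)
        assert_studies_equal(sorted(tr_a, key=lambda s: s.study_id),
                             sorted(tr_b, key=lambda s: s.study_id))
        pd.testing.assert_frame_equal(v_a.expression, v_b.expression)

    def test_common_panel_out(self, rng):
        studies, V = self._collection(rng)
        tr, v = run_core_all_multi(studies, V, 4, "all", LearnerSpec(seed=1))
        panels = {tuple(s.gene_ids) for s in tr} | {tuple(v.gene_ids)}
        assert len(panels) == 1


class TestOutcomeModel:
    def test_noiseless_linear_validation_error(self, rng):
        genes = ["a", "b", "c"]
        w = np.array([1.0, -2.0, 0.5])
        studies = []
        for i in range(2):
            X = rng.normal(size=(40, 3))
            studies.append(make_study(f"s{i}", genes, X, outcome=X @ w + 1.0))
        Xv = rng.normal(size=(20, 3))
        V = make_study("V", genes, Xv, role="validation")
        model = fit_outcome_model(studies, OLS)
        pred = predict_outcome(model, V)
        np.testing.assert_allclose(pred, Xv @ w + 1.0, atol=1e-6)

    def test_constant_outcome(self, rng):
        s = make_study("s", ["a"], rng.normal(size=(10, 1)), outcome=np.full(10, 2.0))
        model = fit_outcome_model([s], OLS)
        np.testing.assert_array_equal(
            predict_outcome(model, make_study("V", ["a"], rng.normal(size=(4, 1)),
                                              role="validation")),
            np.full(4, 2.0))

    def test_panel_mismatch_lists_difference(self, rng):
        s1 = make_study("s1", ["a", "b"], rng.normal(size=(5, 2)), outcome=np.ones(5))
        s2 = make_study("s2", ["a", "c"], rng.normal(size=(5, 2)), outcome=np.ones(5))
        with pytest.raises(ValueError, match="'b', 'c'"):
            fit_outcome_model([s1, s2], OLS)

    def test_validation_missing_genes_listed(self, rng):
        s = make_study("s", ["a", "b"], rng.normal(size=(10, 2)),
                       outcome=rng.normal(size=10))
        model = fit_outcome_model([s], OLS)
        V = make_study("V", ["a"], rng.normal(size=(3, 1)), role="validation")
        with pytest.raises(ValueError, match="lacks model genes"):
            predict_outcome(model, V)


class TestMethodValidation:
    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            Method("stacking")

    def test_subset_requires_k(self):
        with pytest.raises(ValueError, match="k >= 2"):
            Method("subset_k")

    def test_core_requires_q(self):
        with pytest.raises(ValueError, match="q >= 1"):
            Method("core_pairwise")
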