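"""Stratified splits, LOSO protocol, confusion-matrix metrics."""

import pickle

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aclgait import evaluate

# published confusion matrices and derived metrics of the six classifiers;
# metric values kept as strings to preserve their printed precision
PRINTED = [
    # family,   tp,   fn,   fp,   tn,   sens,   spec,    prec,    f1,  kappa
    ("knn", 2345, 743, 975, 2161, "75.93", "68.9", "70.63", "73.19", "0.448"),
    ("nb", 2222, 866, 853, 2283, "71.95", "72.8", "72.26", "72.1", "0.447"),
    ("svm", 2097, 991, 799, 2337, "67.9", "74.5", "72.4", "70.08", "0.424"),
    ("xgb", 2526, 562, 1158, 1978, "81.8", "63.07", "68.56", "74.6", "0.448"),
    ("mlp", 2409, 679, 994, 2142, "78.01", "68.3", "70.79", "74.22", "0.462"),
    ("stacking", 2396, 692, 995, 2141, "77.59", "68.27", "70.65", "73.96", "0.458"),
]


def printed(value: str):
    """Parse a printed number and its one-unit-in-the-last-digit tolerance."""
    decimals = len(value.split(".")[1]) if "." in value else 0
    return float(value), 10.0 ** -decimals + 1e-9


class TestMetricsFromConfusion:
    @pytest.mark.parametrize(
        "family,tp,fn,fp,tn,sens,spec,prec,f1,kappa",
        PRINTED, ids=[row[0] for row in PRINTED])
    def test_printed_model_metrics(self, family, tp, fn, fp, tn,
                                   sens, spec, prec, f1, kappa):
        m = evaluate.metrics_from_confusion(evaluate.ConfusionMatrix(tp, fn, fp, tn))
        for key, exp in [("sensitivity", sens), ("specificity", spec),
                         ("precision", prec), ("f1", f1), ("kappa", kappa)]:
            target, tol = printed(exp)
            assert m[key] == pytest.approx(target, abs=tol), key

    def test_perfect_classifier(self):
        m = evaluate.metrics_from_confusion(evaluate.ConfusionMatrix(10, 0, 0, 10))
        for key in ("sensitivity", "specificity", "precision", "f1", "accuracy"):
            assert m[key] == 100.0
        assert m["kappa"] == 1.0

    def test_marginally_independent_kappa_zero(self):
        # P(pred=+|y) identical for both classes -> kappa exactly 0
        m = evaluate.metrics_from_confusion(evaluate.ConfusionMatrix(30, 30, 20, 20))
        assert m["kappa"] == pytest.approx(0.0, abs=1e-12)

    def test_kappa_bounded(self, rng):
        for _ in range(50):
            tp, fn, fp, tn = rng.integers(0, 40, 4)
            if tp + fn + fp + tn == 0:
                continue
            m = evaluate.metrics_from_confusion(
                evaluate.ConfusionMatrix(int(tp), int(fn), int(fp), int(tn)))
            if np.isfinite(m["kappa"]):
                assert -1.0 - 1e-12 <= m["kappa"] <= 1.0 + 1e-12

    def test_zero_denominator_flagged(self):
        m = evaluate.metrics_from_confusion(evaluate.ConfusionMatrix(0, 0, 0, 5))
        assert np.isnan(m["sensitivity"]) and np.isnan(m["precision"])
        assert m["specificity"] == 100.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            evaluate.ConfusionMatrix(-1, 0, 0, 0)


def _cohorts(n_per=6):
    out = {}
    for c in ("healthy", "acl"):
        for i in range(n_per):
            out[f"{c}_{i:02d}"] = c
    return out


class TestStratifiedSplit:
    def test_six_plus_six_partition(self):
        plan = evaluate.stratified_split(_cohorts(), seed=0)
        for role, size in (("train", 6), ("validation", 2), ("test", 4)):
            members = plan.subjects(role)
            assert len(members) == size
            acl = sum(1 for s in members if s.startswith("acl"))
            assert acl == size // 2  # equal cohort counts

    def test_deterministic_under_seed(self):
        a = evaluate.stratified_split(_cohorts(), seed=5)
        b = evaluate.stratified_split(_cohorts(), seed=5)
        assert a.assignment == b.assignment

    @pytest.mark.parametrize("seed", range(10))
    def test_many_seeds_all_valid(self, seed):
        plan = evaluate.stratified_split(_cohorts(), seed=seed)
        roles = list(plan.assignment.values())
        assert sorted(roles).count("train") == 6
        assert sorted(roles).count("validation") == 2
        assert sorted(roles).count("test") == 4

    def test_unstratifiable_cohorts_rejected(self):
        cohorts = {f"s{i}": ("acl" if i < 5 else "healthy") for i in range(12)}
        with pytest.raises(ValueError, match="stratifiable"):
            evaluate.stratified_split(cohorts, seed=0)


def _blob_dataset(rng, separation=3.0, n_subj_per=6, reps=10, n_feat=20):
    """Feature matrix with subject-level clusters; group mean shift on
    the first three features controls separability."""
    rows, meta = [], []
    for c, sign in (("healthy", -1), ("acl", 1)):
        for s in range(n_subj_per):
            center = rng.normal(0, 1.0, n_feat)
            center[:3] += sign * separation / 2
            for r in range(reps):
                rows.append(center + rng.normal(0, 1.0, n_feat))
                meta.append({"subject": f"{c}_{s:02d}", "cohort": c, "trial": r})
    X = pd.DataFrame(rows, columns=[f"f{i}" for i in range(n_feat)])
    return X, pd.DataFrame(meta)


class TestLosoGridSearch:
    def test_single_grid_point_returned(self, rng):
        X, meta = _blob_dataset(rng)
        grid = evaluate.ModelGrid("knn", {"n_neighbors": [3]}, k_grid=[5])
        res = evaluate.loso_grid_search(X, meta["cohort"].to_numpy(),
                                        meta["subject"].to_numpy(), grid, seed=0)
        assert res.best_params == {"n_neighbors": 3}
        assert res.best_k == 5
        assert res.n_points == 1
        assert len(res.selected_features) == 5

    def test_separable_cohorts_above_90(self, rng):
        X, meta = _blob_dataset(rng, separation=4.0)
        grid = evaluate.ModelGrid("knn", {"n_neighbors": [3, 5]}, k_grid=[3, 5])
        res = evaluate.loso_grid_search(X, meta["cohort"].to_numpy(),
                                        meta["subject"].to_numpy(), grid, seed=0)
        assert res.mean_accuracy > 90.0

    def test_uninformative_features_at_chance(self, rng):
        """With no group structure in the features, subject-wise label
        shuffling leaves LOSO accuracy inside the binomial 95% band of
        50% — the leakage-free pipeline cannot manufacture signal."""
        X, meta = _blob_dataset(rng, separation=0.0)
        subj_order = meta["subject"].unique()
        shuffled = meta.groupby("subject")["cohort"].first().to_numpy()
        rng.shuffle(shuffled)
        relabel = dict(zip(subj_order, shuffled))
        y = meta["subject"].map(relabel).to_numpy()
        grid = evaluate.ModelGrid("knn", {"n_neighbors": [5]}, k_grid=[5])
        res = evaluate.loso_grid_search(X, y, meta["subject"].to_numpy(), grid, seed=0)
        n = len(meta)
        correct = int(round(res.mean_accuracy / 100 * n))
        p = sps.binomtest(correct, n, 0.5).pvalue
        assert p > 0.05

    def test_k_cap_enforced(self):
        with pytest.raises(ValueError, match="K"):
            evaluate.ModelGrid("knn", {}, k_grid=[11])

    def test_non_finite_feature_named(self, rng):
        X, meta = _blob_dataset(rng)
        X.loc[3, "f7"] = np.nan
        grid = evaluate.ModelGrid("knn", {}, k_grid=[2])
        with pytest.raises(ValueError, match="f7"):
            evaluate.loso_grid_search(X, meta["cohort"].to_numpy(),
                                      meta["subject"].to_numpy(), grid, seed=0)


class TestProtocol:
    def test_single_permutation_reproducible(self, rng):
        X, meta = _blob_dataset(rng, separation=2.0)
        grid = evaluate.ModelGrid("knn", {"n_neighbors": [3]}, k_grid=[3])
        a = evaluate.evaluate_protocol(X, meta, grid, n_permutations=1, seed=9)
        b = evaluate.evaluate_protocol(X, meta, grid, n_permutations=1, seed=9)
        assert a.per_subject_accuracy == b.per_subject_accuracy
        assert a.confusion.as_dict() == b.confusion.as_dict()
        assert a.permutation_seeds == b.permutation_seeds

    def test_pooled_total_counts_scored_repetitions(self, rng):
        X, meta = _blob_dataset(rng, reps=7)
        grid = evaluate.ModelGrid("knn", {"n_neighbors": [3]}, k_grid=[3])
        rep = evaluate.evaluate_protocol(X, meta, grid, n_permutations=3, seed=1)
        # 4 test subjects x 7 repetitions x 3 permutations
        assert rep.confusion.total == 4 * 7 * 3
        assert len(rep.per_subject_accuracy) == 12
        accs = np.array([a for _, a in rep.per_subject_accuracy])
        assert rep.se_accuracy == pytest.approx(
            accs.std(ddof=1) / np.sqrt(len(accs)), abs=1e-9)

    def test_fitted_state_independent_of_test_rows(self, rng):
        """Deleting the held-out subjects' rows leaves the fitted model
        byte-identical: fitting never touches them."""
        X, meta = _blob_dataset(rng)
        plan = evaluate.stratified_split(
            dict(meta.drop_duplicates("subject").set_index("subject")["cohort"]),
            seed=3)
        train = plan.subjects("train") + plan.subjects("validation")
        mask = meta["subject"].isin(train).to_numpy()
        arr = X.to_numpy()
        y = (meta["cohort"] == "acl").to_numpy()

        pipe_full = evaluate.make_pipeline("knn", {"n_neighbors": 3}, 4, seed=0)
        pipe_full.fit(arr[mask], y[mask])

        arr_del = np.delete(arr, np.nonzero(~mask)[0], axis=0)
        y_del = np.delete(y, np.nonzero(~mask)[0])
        pipe_del = evaluate.make_pipeline("knn", {"n_neighbors": 3}, 4, seed=0)
        pipe_del.fit(arr_del, y_del)
        assert pickle.dumps(pipe_full) == pickle.dumps(pipe_del)

    def test_leakage_guard_trips(self, rng):
        X, meta = _blob_dataset(rng)
        with pytest.raises(evaluate.LeakageError):
            evaluate.loso_accuracy(
                X.to_numpy(), (meta["cohort"] == "acl").to_numpy().astype(int),
                meta["subject"].to_numpy(), "knn", {}, 3, 0,
                forbidden_subjects=["acl_00"])

    @pytest.mark.parametrize("family", ["nb", "svm", "xgb"])
    def test_other_model_families_run(self, rng, family):
        X, meta = _blob_dataset(rng, separation=4.0, reps=4)
        grid = evaluate.ModelGrid(family, {}, k_grid=[3])
        rep = evaluate.evaluate_protocol(X, meta, grid, n_permutations=1, seed=2)
        assert rep.mean_accuracy > 70.0
        assert rep.confusion.total == 4 * 4
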