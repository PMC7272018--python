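"""Clinical encoding, SVM-RFE feature selection and cross-validated SVM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from pathrisk import FeatureTable, encode_clinical, pathway_features, rfe_select, svm_cv


def make_features(rng, n_features, n_per_group, informative=(), shift=2.0):
    cols = [f"c{i}" for i in range(n_per_group)] + [f"t{i}" for i in range(n_per_group)]
    values = rng.normal(size=(n_features, 2 * n_per_group))
    idx = [f"f{i}" for i in range(n_features)]
    df = pd.DataFrame(values, index=idx, columns=cols)
    for f in informative:
        df.loc[f, df.columns[n_per_group:]] += shift
    labels = pd.Series(["control"] * n_per_group + ["case"] * n_per_group, index=cols)
    return FeatureTable(df, pd.Series("pathway", index=idx)), labels


def auc_pair_counting(y, scores):
    """Mann–Whitney oracle: P(case score > control score), ties 1/2."""
    pos = [s for s, yi in zip(scores, y) if yi == 1]
    neg = [s for s, yi in zip(scores, y) if yi == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


class TestEncodeClinical:
    def test_eleven_feature_setting(self, small_cohort):
        """5 pathway features + 6 clinical covariates -> 11 rows."""
        ann = small_cohort.annotations
        rng = np.random.default_rng(0)
        pathway = pathway_features(
            pd.DataFrame(rng.normal(size=(5, len(ann))),
                         index=[f"T{i}" for i in range(5)], columns=ann.index)
        )
        clinical = encode_clinical(ann)
        assert clinical.values.shape[0] == 6
        combined = pathway.append(clinical)
        assert combined.values.shape == (11, len(ann))
        assert (combined.provenance == "clinical").sum() == 6
        assert (combined.provenance == "pathway").sum() == 5

    def test_deterministic(self, small_cohort):
        a = encode_clinical(small_cohort.annotations)
        b = encode_clinical(small_cohort.annotations)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_binary_fields_are_01(self, small_cohort):
        block = encode_clinical(small_cohort.annotations)
        for f in ("gender", "lymphadenopathy"):
            assert set(block.values.loc[f].unique()) <= {0.0, 1.0}

    def test_missing_value_names_sample_and_field(self, small_cohort):
        ann = small_cohort.annotations.copy()
        ann.loc[ann.index[3], "age"] = np.nan
        with pytest.raises(ValueError, match="age"):
            encode_clinical(ann)

    def test_string_gender_encoded(self, small_cohort):
        ann = small_cohort.annotations.copy()
        ann["gender"] = np.where(ann["gender"] == 1, "Male", "Female")
        block = encode_clinical(ann)
        assert set(block.values.loc["gender"].unique()) <= {0.0, 1.0}


class TestRFE:
    def test_curve_length_bookkeeping(self):
        rng = np.random.default_rng(0)
        feats, labels = make_features(rng, 7, 15)
        curve = rfe_select(feats, labels, step=1, seed=0)
        assert curve.sizes == [7, 6, 5, 4, 3, 2, 1]
        curve2 = rfe_select(feats, labels, step=2, seed=0)
        assert curve2.sizes == [7, 5, 3, 1]

    def test_step_too_large_raises(self):
        rng = np.random.default_rng(0)
        feats, labels = make_features(rng, 4, 10)
        with pytest.raises(ValueError):
            rfe_select(feats, labels, step=4)

    def test_informative_feature_survives(self):
        """1 strong feature among 9 noise features stays in the optimum set."""
        kept = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            feats, labels = make_features(rng, 10, 20, informative=["f0"], shift=2.0)
            curve = rfe_select(feats, labels, seed=seed)
            kept += "f0" in curve.optimum_features
        assert kept >= 18  # >= 90% of seeds

    def test_optimum_ties_break_toward_fewer(self):
        rng = np.random.default_rng(5)
        feats, labels = make_features(rng, 5, 25, informative=["f0"], shift=5.0)
        curve = rfe_select(feats, labels, seed=1)
        best = max(curve.accuracies)
        tied_sizes = [s for s, a in zip(curve.sizes, curve.accuracies)
                      if abs(a - best) < 1e-12]
        assert curve.optimum_size == min(tied_sizes)

    def test_matches_exhaustive_subset_search(self):
        """Greedy RFE finds the brute-force best subset in most seeds."""

        def subset_cv_accuracy(X, y, subset, seed):
            skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
            accs = []
            for tr, te in skf.split(X, y):
                mu = X[tr][:, subset].mean(0)
                sd = X[tr][:, subset].std(0)
                sd[sd == 0] = 1.0
                clf = SVC(kernel="linear", C=1.0)
                clf.fit((X[tr][:, subset] - mu) / sd, y[tr])
                accs.append((clf.predict((X[te][:, subset] - mu) / sd) == y[te]).mean())
            return np.mean(accs)

        agree = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            feats, labels = make_features(
                rng, 4, 15, informative=["f0", "f1", "f2"], shift=3.0
            )
            X = feats.values.to_numpy().T
            y = (labels.values == "case").astype(int)
            best_subset, best_acc = None, -1.0
            for r in range(1, 5):
                for subset in itertools.combinations(range(4), r):
                    acc = subset_cv_accuracy(X, y, list(subset), seed)
                    if acc > best_acc + 1e-12:
                        best_acc, best_subset = acc, subset
            curve = rfe_select(feats, labels, seed=seed)
            rfe_set = {int(f[1:]) for f in curve.optimum_features}
            agree += rfe_set == set(best_subset) or abs(
                best_acc - max(curve.accuracies)
            ) < 1e-9
        assert agree >= 16  # >= 80% of seeds


class TestSvmCV:
    def test_separable_features_auc_one(self):
        rng = np.random.default_rng(0)
        feats, labels = make_features(rng, 3, 20, informative=["f0"], shift=10.0)
        report = svm_cv(feats, labels, seed=0)
        assert all(a == pytest.approx(1.0) for a in report.fold_aucs)
        assert report.mean_auc == pytest.approx(1.0)

    def test_null_features_auc_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            feats, labels = make_features(rng, 5, 15)
            aucs.append(svm_cv(feats, labels, seed=seed).mean_auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_each_sample_predicted_exactly_once(self):
        rng = np.random.default_rng(1)
        feats, labels = make_features(rng, 4, 10)
        report = svm_cv(feats, labels, seed=3)
        assert not report.predictions.isna().any()
        assert len(report.predictions) == 20

    def test_auc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        feats, labels = make_features(rng, 3, 12, informative=["f1"], shift=1.0)
        report = svm_cv(feats, labels, folds=4, seed=2)
        y = (labels.values == "case").astype(int)
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=2)
        X = feats.values.to_numpy().T
        for (tr, te), fold_auc in zip(skf.split(X, y), report.fold_aucs):
            oracle = auc_pair_counting(y[te], report.predictions.iloc[te].values)
            assert fold_auc == pytest.approx(oracle, abs=1e-12)

    def test_duplicated_feature_keeps_separable_auc(self):
        rng = np.random.default_rng(4)
        feats, labels = make_features(rng, 2, 15, informative=["f0"], shift=10.0)
        dup = FeatureTable(
            pd.concat([feats.values, feats.values.loc[["f0"]].rename(index={"f0": "f0_copy"})]),
            pd.concat([feats.provenance, pd.Series({"f0_copy": "pathway"})]),
        )
        assert svm_cv(dup, labels, seed=0).mean_auc == pytest.approx(1.0)

    def test_roc_endpoints(self):
        rng = np.random.default_rng(9)
        feats, labels = make_features(rng, 3, 10, informative=["f0"], shift=1.5)
        report = svm_cv(feats, labels, seed=1)
        for fpr, tpr in report.fold_rocs:
            assert fpr[0] == 0 and tpr[0] == 0
            assert fpr[-1] == 1 and tpr[-1] == 1

    def test_too_many_folds_raises(self):
        rng = np.random.default_rng(0)
        feats, labels = make_features(rng, 3, 4)
        with pytest.raises(ValueError, match="folds"):
            svm_cv(feats, labels, folds=5)

    def test_zero_variance_feature_handled(self):
        rng = np.random.default_rng(0)
        feats, labels = make_features(rng, 3, 10, informative=["f0"], shift=5.0)
        feats.values.loc["f2"] = 1.0  # constant
        report = svm_cv(feats, labels, seed=0)
        assert np.isfinite(report.mean_auc)
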