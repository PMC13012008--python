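import numpy as np
import pandas as pd
import pytest

from napy import (
    ClassifierModel,
    DerivationConfig,
    ExpressionMatrix,
    TFProgram,
    TrainingConfig,
    evaluate,
    nested_cv,
    predict_series,
    stratified_split,
    train_model,
)
from napy.errors import ContractError, MissingGeneError


def two_feature_matrix(points, samples):
    """Matrix with two 'genes' (features) and given per-sample coordinates."""
    df = pd.DataFrame(np.asarray(points, float).T,
                      index=["F1", "F2"], columns=samples)
    return ExpressionMatrix(df, "log2_tpm1")


TOY_PROGRAMS = {"T1": TFProgram("T1", ["F1"]), "T2": TFProgram("T2", ["F2"])}


class TestStratifiedSplit:
    def test_proportions_preserved(self):
        y = pd.Series(["A"] * 40 + ["N"] * 30 + ["P"] * 20 + ["Y"] * 10,
                      index=[f"s{i}" for i in range(100)])
        train, hold = stratified_split(y, 0.2, seed=3)
        assert len(hold) == 20
        assert y.loc[hold].value_counts().to_dict() == {"A": 8, "N": 6, "P": 4, "Y": 2}
        assert set(train) | set(hold) == set(y.index)
        assert not set(train) & set(hold)

    def test_deterministic_under_seed(self):
        y = pd.Series(["A", "N"] * 10, index=[f"s{i}" for i in range(20)])
        assert stratified_split(y, 0.2, 7) == stratified_split(y, 0.2, 7)

    def test_zero_fraction_rejected(self):
        y = pd.Series(["A", "A", "N", "N"])
        with pytest.raises(ContractError):
            stratified_split(y, 0.0, 1)


class TestTrainPredict:
    def test_separable_two_point_boundary(self):
        # classes at (-1,0) and (1,0): the max-margin boundary is F1 = 0
        samples = ["a1", "a2", "b1", "b2"]
        m = two_feature_matrix([(-1, 0), (-1, 0.1), (1, 0), (1, -0.1)], samples)
        y = pd.Series(["L", "L", "R", "R"], index=samples)
        model = train_model(m, y, TOY_PROGRAMS, cost=1000.0, class_order=("L", "R"))
        assert list(predict_series(model, m)) == list(y)
        probe = two_feature_matrix([(-2, 0)], ["probe"])
        assert predict_series(model, probe)["probe"] == "L"

    def test_missing_class_named(self):
        samples = ["a", "b", "c", "d"]
        m = two_feature_matrix([(-1, 0), (1, 0), (0, 1), (0, -1)], samples)
        y = pd.Series(["A", "N", "Y", "Y"], index=samples)
        with pytest.raises(ContractError, match="P"):
            train_model(m, y, TOY_PROGRAMS, cost=1.0)

    def test_duplicate_sample_predicts_identically(self, small_cohort, strict_labels):
        from napy import derive_programs, LabelingConfig
        y = strict_labels
        m = small_cohort.expression.subset_samples(y.index)
        programs = derive_programs(m, LabelingConfig().tf_genes, DerivationConfig(k=5))
        model = train_model(m, y, programs, cost=0.031)
        pred = predict_series(model, m)
        dup = m.subset_samples([y.index[0]])
        assert predict_series(model, dup).iloc[0] == pred.iloc[0]

    def test_missing_feature_gene_rejected(self):
        samples = ["a1", "a2", "b1", "b2"]
        m = two_feature_matrix([(-1, 0), (-1, 1), (1, 0), (1, 1)], samples)
        y = pd.Series(["L", "L", "R", "R"], index=samples)
        model = train_model(m, y, TOY_PROGRAMS, cost=1.0, class_order=("L", "R"))
        bad = ExpressionMatrix(m.values.drop(index=["F2"]), "log2_tpm1")
        with pytest.raises(MissingGeneError, match="F2"):
            predict_series(model, bad)

    def test_json_round_trip(self):
        samples = ["a1", "a2", "b1", "b2"]
        m = two_feature_matrix([(-1, 0), (-1, 1), (1, 0), (1, 1)], samples)
        y = pd.Series(["L", "L", "R", "R"], index=samples)
        model = train_model(m, y, TOY_PROGRAMS, cost=0.5, class_order=("L", "R"))
        clone = ClassifierModel.from_json(model.to_json())
        assert list(predict_series(clone, m)) == list(predict_series(model, m))
        assert clone.cost == model.cost


def brute_force_report(conf):
    """Independent per-class metric computation from a confusion matrix."""
    conf = np.asarray(conf)
    total = conf.sum()
    out = {}
    for i in range(conf.shape[0]):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        ppv = tp / (tp + fp) if tp + fp else np.nan
        npv = tn / (tn + fn) if tn + fn else np.nan
        f = (2 * ppv * sens / (ppv + sens)
             if np.isfinite(ppv) and np.isfinite(sens) and ppv + sens > 0 else np.nan)
        out[i] = dict(sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
                      f_measure=f, balanced_accuracy=(sens + spec) / 2)
    return out


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(list("ANPY") * 3)
        rep = evaluate(y, y)
        assert rep.accuracy == 1.0
        assert (rep.per_class == 1.0).all().all()
        assert np.trace(rep.confusion.to_numpy()) == 12

    def test_degenerate_all_one_class(self):
        truth = np.array(["A"] * 5 + ["N"] * 5)
        pred = np.array(["A"] * 10)
        with pytest.warns(UserWarning):
            rep = evaluate(pred, truth)
        assert rep.per_class.loc["A", "sensitivity"] == 1.0
        assert rep.per_class.loc["A", "specificity"] == 0.0
        assert rep.per_class.loc["A", "balanced_accuracy"] == 0.5

    def test_matches_brute_force_on_random_confusions(self):
        rng = np.random.default_rng(5)
        classes = list("ANPY")
        for _ in range(50):
            conf = rng.integers(0, 10, size=(4, 4))
            if conf.sum() == 0:
                continue
            truth, pred = [], []
            for i in range(4):
                for j in range(4):
                    truth += [classes[i]] * conf[i, j]
                    pred += [classes[j]] * conf[i, j]
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = evaluate(np.array(pred), np.array(truth))
            oracle = brute_force_report(conf)
            for i, cls in enumerate(classes):
                for metric, val in oracle[i].items():
                    got = rep.per_class.loc[cls, metric]
                    assert (np.isnan(val) and np.isnan(got)) or got == pytest.approx(val)
            assert rep.accuracy == pytest.approx(np.trace(conf) / conf.sum())

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        truth = rng.choice(list("ANPY"), 40)
        pred = rng.choice(list("ANPY"), 40)
        perm = rng.permutation(40)
        r1 = evaluate(pred, truth)
        r2 = evaluate(pred[perm], truth[perm])
        pd.testing.assert_frame_equal(r1.per_class, r2.per_class)

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            evaluate(np.array(["A"]), np.array(["A", "N"]))


@pytest.fixture(scope="module")
def strict_labels(small_cohort):
    from napy import calls_to_series, label_cohort
    calls = calls_to_series(label_cohort(small_cohort.expression))
    return calls[calls != "unassigned"]


@pytest.fixture(scope="module")
def small_cv(small_cohort, strict_labels):
    """One small nested CV shared by the structural tests below."""
    m = small_cohort.expression.subset_samples(strict_labels.index)
    cfg = TrainingConfig(outer_repeats=1, seed=4, cost_grid=(0.01, 1.0))
    return nested_cv(m, strict_labels, DerivationConfig(k=5), cfg), cfg


class TestNestedCV:
    def test_run_count_and_per_run_features(self, small_cv):
        res, cfg = small_cv
        assert len(res.runs) == cfg.n_runs == 4
        for run in res.runs:
            from napy import program_feature_genes
            assert len(program_feature_genes(run.programs)) == 20  # 4 x k

    def test_outer_test_fold_sizes_partition(self, small_cv, strict_labels):
        res, _ = small_cv
        ids = [s for run in res.runs for s in run.test_ids]
        assert sorted(ids) == sorted(strict_labels.index)

    def test_no_leakage_from_test_samples(self, small_cohort, strict_labels):
        """Corrupting outer-test expression must not change features or cost."""
        m = small_cohort.expression.subset_samples(strict_labels.index)
        cfg = TrainingConfig(outer_repeats=1, seed=4, cost_grid=(0.01, 1.0))
        res1 = nested_cv(m, strict_labels, DerivationConfig(k=5), cfg)
        target = res1.runs[0]
        vals = m.values.copy()
        rng = np.random.default_rng(0)
        vals[target.test_ids] = rng.uniform(0, 8, size=(len(vals), len(target.test_ids)))
        res2 = nested_cv(ExpressionMatrix(vals, "log2_tpm1"), strict_labels,
                         DerivationConfig(k=5), cfg)
        r1, r2 = res1.runs[0], res2.runs[0]
        assert r1.best_cost == r2.best_cost
        for tf in r1.programs:
            assert r1.programs[tf].genes == r2.programs[tf].genes
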