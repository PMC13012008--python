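import numpy as np
import pandas as pd
import pytest
from scipy import stats

from napy import (
    ExpressionMatrix,
    GeneSignature,
    anova_f,
    coherence_score,
    differential_by_subtype,
    read_gmt,
    score_signature,
    select_representative,
    top_fraction_composition,
    write_gmt,
    zscore_matrix,
)
from napy.errors import ContractError, CoverageError, DomainError, InsufficientDataError
from conftest import golden


def zmat(rows, samples=None):
    df = pd.DataFrame(rows).T.astype(float)
    df.columns = samples or [f"S{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df, "zscore")


class TestScoreSignature:
    def test_single_present_gene_passthrough(self):
        z = zmat({"G1": (1.0, -2.0), "G2": (0.0, 0.0)})
        sig = GeneSignature("s", ["G1", "GX"])  # GX absent, 1/2 = min_present
        scores = score_signature(z, sig)
        assert scores.to_numpy() == pytest.approx([1.0, -2.0])

    def test_mean_of_three_genes(self):
        z = zmat({"G1": (1, -1), "G2": (0, 2), "G3": (2, 0)})
        scores = score_signature(z, GeneSignature("s", ["G1", "G2", "G3"]))
        assert scores.to_numpy() == pytest.approx([1.0, 1 / 3])

    def test_coverage_error_names_missing(self):
        z = zmat({"G1": (1, 2)})
        with pytest.raises(CoverageError, match="GX"):
            score_signature(z, GeneSignature("s", ["G1", "GX", "GY"]))

    def test_linearity_over_disjoint_sets(self):
        rng = np.random.default_rng(4)
        z = zmat({f"G{i}": tuple(rng.normal(size=5)) for i in range(6)})
        a = GeneSignature("a", ["G0", "G1"])
        b = GeneSignature("b", ["G2", "G3", "G4", "G5"])
        both = GeneSignature("ab", a.genes + b.genes)
        expected = (2 * score_signature(z, a) + 4 * score_signature(z, b)) / 6
        assert score_signature(z, both).to_numpy() == pytest.approx(
            expected.to_numpy())


class TestCoherence:
    def test_identical_genes(self):
        m = zmat({"G1": (1, 2, 3), "G2": (1, 2, 3)})
        assert coherence_score(m, GeneSignature("s", ["G1", "G2"])) == pytest.approx(1.0)

    def test_reflected_gene(self):
        m = zmat({"G1": (1, 2, 3), "G2": (3, 2, 1)})
        assert coherence_score(m, GeneSignature("s", ["G1", "G2"])) == pytest.approx(-1.0)

    def test_mean_of_pairwise_correlations(self, toy_matrix):
        genes = toy_matrix.gene_ids[:3]
        sig = GeneSignature("s", genes)
        rs = [stats.pearsonr(toy_matrix.values.loc[a], toy_matrix.values.loc[b])[0]
              for i, a in enumerate(genes) for b in genes[i + 1:]]
        assert coherence_score(toy_matrix, sig) == pytest.approx(np.mean(rs))

    def test_affine_rescaling_invariance(self, toy_matrix):
        genes = toy_matrix.gene_ids[:3]
        sig = GeneSignature("s", genes)
        before = coherence_score(toy_matrix, sig)
        vals = toy_matrix.values.copy()
        vals.loc[genes[0]] = 3.0 * vals.loc[genes[0]] + 7.0
        after = coherence_score(ExpressionMatrix(vals, "log2_tpm1"), sig)
        assert after == pytest.approx(before)


def labeled_scores(rng, shift_group=None, shift=0.0, n_per=30):
    labels, vals = [], []
    for c in "ANPY":
        x = rng.normal(size=n_per)
        if c == shift_group:
            x = x + shift
        labels += [c] * n_per
        vals.append(x)
    ids = [f"s{i}" for i in range(4 * n_per)]
    return (pd.Series(np.concatenate(vals), index=ids),
            pd.Series(labels, index=ids))


class TestDifferential:
    def test_null_distributions_not_retained(self):
        scores, labels = labeled_scores(np.random.default_rng(0))
        table, n_sig, retained = differential_by_subtype(scores, labels)
        assert n_sig == 0 and not retained

    def test_planted_shift_retained(self):
        scores, labels = labeled_scores(np.random.default_rng(1),
                                        shift_group="Y", shift=3.0)
        table, n_sig, retained = differential_by_subtype(scores, labels)
        assert n_sig >= 3 and retained

    def test_bonferroni_dominates_raw(self):
        scores, labels = labeled_scores(np.random.default_rng(2),
                                        shift_group="P", shift=1.0)
        table, _, _ = differential_by_subtype(scores, labels)
        assert (table["p_adj"] >= table["p_raw"]).all()
        assert (table["p_adj"] <= 1.0).all()

    def test_single_class_rejected(self):
        ids = [f"s{i}" for i in range(10)]
        with pytest.raises(InsufficientDataError):
            differential_by_subtype(pd.Series(np.arange(10.0), index=ids),
                                    pd.Series(["A"] * 10, index=ids))

    def test_wilcoxon_matches_scipy_per_pair(self):
        scores, labels = labeled_scores(np.random.default_rng(3),
                                        shift_group="N", shift=0.8)
        table, _, _ = differential_by_subtype(scores, labels)
        a = scores[labels == "A"].to_numpy()
        n = scores[labels == "N"].to_numpy()
        expected = stats.mannwhitneyu(a, n, alternative="two-sided",
                                      method="asymptotic").pvalue
        got = table.loc[table["pair"] == "A-N", "p_raw"].iloc[0]
        assert got == pytest.approx(expected)


class TestRepresentativeAndTopScores:
    def test_single_candidate_returned(self):
        scores, labels = labeled_scores(np.random.default_rng(4))
        assert select_representative({"only": scores}, labels) == "only"

    def test_separated_candidate_wins(self):
        rng = np.random.default_rng(5)
        flat, labels = labeled_scores(rng)
        sep, _ = labeled_scores(rng, shift_group="Y", shift=3.0)
        assert select_representative({"flat": flat, "sep": sep}, labels) == "sep"

    def test_anova_f_matches_closed_form(self):
        rng = np.random.default_rng(6)
        scores, labels = labeled_scores(rng, shift_group="P", shift=1.0, n_per=10)
        groups = [scores[labels == c].to_numpy() for c in "ANPY"]
        assert anova_f(scores, labels) == pytest.approx(
            stats.f_oneway(*groups).statistic)

    def test_top_fraction_forced_composition(self):
        rng = np.random.default_rng(7)
        scores, labels = labeled_scores(rng, n_per=25)
        top5 = scores.sort_values(ascending=False).index[:5]
        shares = top_fraction_composition(scores, labels, fraction=0.05)
        assert shares.sum() == pytest.approx(100.0)
        expected = labels.loc[top5].value_counts()
        for c in "ANPY":
            assert shares[c] == pytest.approx(100 * expected.get(c, 0) / 5)

    def test_too_few_samples_rejected(self):
        ids = [f"s{i}" for i in range(10)]
        with pytest.raises(ContractError):
            top_fraction_composition(pd.Series(np.arange(10.0), index=ids),
                                     pd.Series(["A"] * 10, index=ids), 0.05)

    def test_planted_y_high_signature_top_scores(self, small_cohort):
        z = zscore_matrix(small_cohort.expression)
        sig = GeneSignature("ysig", small_cohort.programs["YAP1"].genes)
        scores = score_signature(z, sig)
        shares = top_fraction_composition(scores, small_cohort.labels, 0.05)
        assert shares.idxmax() == "Y"


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        sigs = [GeneSignature("a", ["G1", "G2"], "src"),
                GeneSignature("b", ["G3", "G4", "G5"], "src2")]
        p = tmp_path / "sets.gmt"
        write_gmt(sigs, p)
        back = read_gmt(p)
        assert [s.name for s in back] == ["a", "b"]
        assert back[1].genes == ["G3", "G4", "G5"]

    def test_worked_example_ysig_scores_golden(self, worked_example):
        z = zscore_matrix(worked_example.expression)
        scores = score_signature(z, GeneSignature("Y_sig", ["YSIG1", "YSIG2"]))
        expected = golden("worked_example_ysig_scores.tsv", index_col=0)["Y_sig"]
        assert scores.to_numpy() == pytest.approx(expected.to_numpy(), abs=1e-6)
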