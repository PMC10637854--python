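"""Labels, APOE score, risk-model fitting, and classification metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from adors.models import (
    APOEWeights,
    SingleClassError,
    adors_score,
    apoe_score,
    assign_labels,
    auprc,
    auroc,
    fit_risk_model,
    parse_apoe,
    phenotype_association,
    stratified_split,
    task_labels,
)
from adors.models import RiskModel


class TestAssignLabels:
    @pytest.mark.parametrize(
        "visits,expected",
        [
            (("CN", "CN", "CN"), "CN"),
            (("LMCI", "LMCI", "AD"), "MCI_c"),
            (("EMCI", "LMCI", "EMCI"), "MCI_nc"),
            (("AD", "AD"), "AD"),
            (("EMCI", "AD", "LMCI"), "excluded"),  # relapse after AD
            (("CN", "EMCI", "CN"), "excluded"),
        ],
    )
    def test_text_policy_cases(self, visits, expected):
        assert assign_labels(visits, "text") == expected

    def test_cn_first_converter_differs_between_policies(self):
        visits = ("CN", "LMCI", "AD")
        assert assign_labels(visits, "text") == "excluded"
        assert assign_labels(visits, "table1") == "AD"

    def test_policies_agree_everywhere_else(self):
        states = ("CN", "EMCI", "LMCI", "AD")
        for length in (1, 2, 3, 4):
            for visits in itertools.product(states, repeat=length):
                text = assign_labels(visits, "text")
                table1 = assign_labels(visits, "table1")
                if text != table1:
                    assert visits[0] == "CN" and visits[-1] == "AD"

    def test_empty_or_unknown_tokens_rejected(self):
        with pytest.raises(ValueError):
            assign_labels((), "text")
        with pytest.raises(ValueError):
            assign_labels(("CN", "SMC"), "text")

    def test_task_label_mapping(self):
        labels = pd.Series(
            ["CN", "AD", "MCI_c", "MCI_nc", "excluded"],
            index=list("abcde"),
        )
        cnad_text = task_labels(labels, "CNAD", "text")
        assert dict(cnad_text) == {"a": 0, "b": 1, "c": 1}
        cnad_t1 = task_labels(labels, "CNAD", "table1")
        assert dict(cnad_t1) == {"a": 0, "b": 1}
        mci = task_labels(labels, "MCI_CP")
        assert dict(mci) == {"c": 1, "d": 0}


class TestApoeScore:
    def test_reference_genotype_scores_zero(self):
        assert apoe_score("e3e3") == 0.0

    def test_weighted_allele_sums(self):
        assert apoe_score("e2e4") == pytest.approx(-0.47 + 1.12)
        assert apoe_score("e4e4") == pytest.approx(2 * 1.12)
        assert apoe_score("ε2ε2") == pytest.approx(-0.94)

    def test_unparseable_genotype_rejected(self):
        with pytest.raises(ValueError):
            parse_apoe("e3")
        with pytest.raises(ValueError):
            parse_apoe("e1e3")


def auroc_oracle(scores, labels):
    """Exhaustive pair counting with half-credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
        assert auprc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auroc(np.ones(10), [0, 1] * 5) == pytest.approx(0.5)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(41)
        for _ in range(25):
            labels = rng.integers(0, 2, size=60)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 8, size=60).astype(float)  # heavy ties
            assert auroc(scores, labels) == pytest.approx(
                auroc_oracle(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance_and_negation(self):
        rng = np.random.default_rng(42)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        scores = rng.normal(size=100)
        a = auroc(scores, labels)
        assert auroc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
        assert auroc(-scores, labels) == pytest.approx(1.0 - a, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            auroc([1.0, 2.0], [1, 1])


class TestAdorsScore:
    def _model(self, weights):
        return RiskModel(
            task="CNAD", intercept=0.3, gene_weights=weights, covariate_weights={}
        )

    def test_zero_weights_zero_scores(self):
        burdens = pd.DataFrame({"G1": [1.0, 2.0]}, index=["a", "b"])
        st = adors_score(self._model({"G1": 0.0}), burdens)
        assert (st["score"] == 0.0).all()

    def test_single_gene_arithmetic(self):
        burdens = pd.DataFrame({"G1": [4.0]}, index=["a"])
        st = adors_score(self._model({"G1": 0.5}), burdens)
        assert st["score"].iloc[0] == 2.0
        assert st["linear_predictor"].iloc[0] == pytest.approx(2.3)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(43)
        genes = [f"G{j}" for j in range(37)]
        burdens = pd.DataFrame(
            rng.normal(size=(50, 37)), index=[f"s{i}" for i in range(50)], columns=genes
        )
        weights = {g: float(w) for g, w in zip(genes, rng.normal(size=37))}
        st = adors_score(self._model(weights), burdens)
        for i, s in enumerate(burdens.index):
            expected = sum(weights[g] * burdens.loc[s, g] for g in genes)
            assert st["score"].iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_linearity_in_weights(self):
        burdens = pd.DataFrame({"G1": [1.0, 3.0], "G2": [2.0, 0.0]}, index=["a", "b"])
        s1 = adors_score(self._model({"G1": 0.2, "G2": -0.4}), burdens)["score"]
        s2 = adors_score(self._model({"G1": 0.6, "G2": -1.2}), burdens)["score"]
        np.testing.assert_allclose(3 * s1, s2, atol=1e-12)

    def test_missing_gene_column_names_the_gene(self):
        burdens = pd.DataFrame({"G1": [1.0]}, index=["a"])
        with pytest.raises(KeyError, match="G2"):
            adors_score(self._model({"G1": 0.1, "G2": 0.1}), burdens)


def _cohort_features(rng, n, p):
    idx = [f"s{i}" for i in range(n)]
    X = pd.DataFrame(rng.normal(size=(n, p)), index=idx,
                     columns=[f"f{j}" for j in range(p)])
    return idx, X


class TestFitRiskModel:
    def test_null_features_give_chance_level_auroc(self):
        rng = np.random.default_rng(44)
        idx, X = _cohort_features(rng, 1000, 10)
        y = pd.Series(rng.integers(0, 2, size=1000), index=idx)
        _, report = fit_risk_model(X, y, seed=0)
        assert 0.35 <= report.test_auroc <= 0.65

    def test_near_noiseless_feature_gives_high_auroc(self):
        rng = np.random.default_rng(45)
        idx, X = _cohort_features(rng, 500, 3)
        liability = X["f0"] + 0.01 * rng.normal(size=500)
        y = pd.Series((liability > liability.median()).astype(int), index=idx)
        _, report = fit_risk_model(X, y, seed=0)
        assert report.test_auroc >= 0.95

    def test_duplicated_feature_columns_leave_ml_predictor_unchanged(self):
        rng = np.random.default_rng(46)
        idx, X = _cohort_features(rng, 400, 3)
        lp = 0.8 * X["f0"] - 0.5 * X["f1"]
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-lp))), index=idx)
        m1, _ = fit_risk_model(X, y, seed=0)
        X_dup = X.copy()
        X_dup["f0_copy"] = X["f0"]
        m2, _ = fit_risk_model(X_dup, y, seed=0)
        lp1 = m1.linear_predictor(X_dup.assign(f0_copy=X["f0"]))
        lp2 = m2.linear_predictor(X_dup)
        assert not m1.ridge_used and not m2.ridge_used
        np.testing.assert_allclose(lp1, lp2, atol=1e-6)

    def test_separation_triggers_ridge_fallback(self):
        rng = np.random.default_rng(47)
        idx, X = _cohort_features(rng, 200, 2)
        y = pd.Series((X["f0"] > 0).astype(int), index=idx)  # perfectly separable
        with pytest.warns(UserWarning, match="separation"):
            model, report = fit_risk_model(X, y, seed=0)
        assert model.ridge_used
        assert np.isfinite(list(model.gene_weights.values())).all()
        assert report.test_auroc > 0.9

    def test_stratified_folds_partition_train_and_balance_classes(self):
        rng = np.random.default_rng(48)
        idx, X = _cohort_features(rng, 500, 4)
        y = pd.Series((rng.random(500) < 0.3).astype(int), index=idx)
        model, _ = fit_risk_model(X, y, seed=3)
        folds = pd.Series(model.fold_assignments)
        train = set(model.train_samples)
        assert set(folds.index) == train  # folds partition the training split
        global_ratio = y.loc[model.train_samples].mean()
        for f in range(10):
            members = folds[folds == f].index
            n_pos = y.loc[members].sum()
            assert abs(n_pos - global_ratio * len(members)) <= 1.0

    def test_split_is_stratified_and_reproducible(self):
        rng = np.random.default_rng(49)
        y = pd.Series((rng.random(200) < 0.4).astype(int),
                      index=[f"s{i}" for i in range(200)])
        tr1, te1 = stratified_split(y, seed=5)
        tr2, te2 = stratified_split(y, seed=5)
        assert tr1 == tr2 and te1 == te2
        assert abs(y.loc[te1].mean() - y.mean()) < 0.05


class TestPhenotypeAssociation:
    def test_score_identical_to_assessment_gives_r_one(self):
        rng = np.random.default_rng(50)
        idx = [f"s{i}" for i in range(30)]
        vals = rng.normal(size=30)
        pheno = pd.DataFrame(
            {t: rng.normal(size=30) for t in ("CDRSB", "FAQ", "MMSE", "RAVLT")},
            index=idx,
        )
        pheno["ADAS13"] = vals
        table = phenotype_association(pd.Series(vals, index=idx), pheno)
        r_adas = table.set_index("test").loc["ADAS13", "r"]
        assert r_adas == pytest.approx(1.0)

    def test_permuted_scores_have_negligible_correlation(self):
        rng = np.random.default_rng(51)
        idx = [f"s{i}" for i in range(1000)]
        liability = rng.normal(size=1000)
        pheno = pd.DataFrame(
            {t: liability + rng.normal(size=1000) for t in
             ("ADAS13", "CDRSB", "FAQ", "MMSE", "RAVLT")},
            index=idx,
        )
        permuted = pd.Series(rng.permutation(liability), index=idx)
        table = phenotype_association(permuted, pheno)
        assert (table["r"].abs() < 0.1).all()

    def test_samples_missing_all_scores_excluded(self):
        idx = ["a", "b", "c", "d", "e"]
        pheno = pd.DataFrame(
            {t: [1.0, 2.0, 3.0, 4.0, np.nan] for t in
             ("ADAS13", "CDRSB", "FAQ", "MMSE", "RAVLT")},
            index=idx,
        )
        table = phenotype_association(
            pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=idx), pheno
        )
        assert (table["n"] == 4).all()
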