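"""L1 logistic path, 1-SE selection, signature extraction, scoring, persistence."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import pairsig as ps
from pairsig.signature import _fit_path_arrays, _lambda_max, binomial_deviance
from conftest import make_dataset


def _toy_design(seed=0, n=40, p=6):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < 0.5).astype(float)
    logits = 1.5 * X[:, 0] - 2.0 * X[:, 1] + 0.3
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(np.int64)
    # ensure both classes present
    y[0], y[1] = 0, 1
    return X, y


class TestSolver:
    def test_all_zero_at_lambda_max(self):
        X, y = _toy_design()
        lam_max = _lambda_max(X, y)
        coefs, intercepts = _fit_path_arrays(X, y, np.array([lam_max * 1.5, lam_max]))
        assert np.all(coefs == 0)
        # intercept-only optimum is the log-odds of the base rate
        ybar = y.mean()
        assert intercepts[1] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-6)

    def test_unpenalized_limit_matches_statsmodels(self):
        """At vanishing λ the solution approaches the plain logistic MLE."""
        X, y = _toy_design(seed=3, n=60, p=3)
        lam_max = _lambda_max(X, y)
        lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-8), 30)
        coefs, intercepts = _fit_path_arrays(X, y, lambdas)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert intercepts[-1] == pytest.approx(mle.params[0], abs=1e-3)
        assert np.allclose(coefs[-1], mle.params[1:], atol=1e-3)

    def test_kkt_conditions_along_path(self):
        X, y = _toy_design(seed=5, n=80, p=10)
        lam_max = _lambda_max(X, y)
        lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-3), 25)
        coefs, intercepts = _fit_path_arrays(X, y, lambdas)
        for k, lam in enumerate(lambdas):
            viol = ps.kkt_violation(X, y, coefs[k], intercepts[k], lam)
            assert viol < 1e-6, f"KKT violation {viol:.2e} at λ={lam:.3g}"

    def test_support_weakly_decreases_toward_lambda_max(self):
        X, y = _toy_design(seed=7, n=100, p=12)
        path = ps.fit_lasso_logistic(X, y, nfolds=2, seed=0, n_lambda=40)
        nz = path.n_nonzero()
        # grid is descending in λ: larger penalty (smaller index), no larger support
        assert nz[0] == 0  # first grid point is λ_max itself
        assert all(nz[i] <= nz[j] for i in range(len(nz)) for j in range(i, len(nz)))

    def test_path_determinism(self):
        X, y = _toy_design(seed=11)
        a = ps.fit_lasso_logistic(X, y, nfolds=3, seed=4)
        b = ps.fit_lasso_logistic(X, y, nfolds=3, seed=4)
        assert np.array_equal(a.coefs, b.coefs)
        assert np.array_equal(a.cv_mean, b.cv_mean)
        assert np.array_equal(a.fold_ids, b.fold_ids)

    def test_nonbinary_labels_rejected(self):
        X, _ = _toy_design()
        with pytest.raises(ValueError, match="binary"):
            ps.fit_lasso_logistic(X, np.arange(len(X)))

    def test_too_few_samples_per_class_for_folds(self):
        X, y = _toy_design()
        y = np.zeros(len(X), dtype=np.int64)
        y[:3] = 1
        with pytest.raises(ValueError, match="stratified"):
            ps.fit_lasso_logistic(X, y, nfolds=10)


class TestLambdaSelection:
    @staticmethod
    def _path(cv_mean, cv_se, lambdas=None):
        n = len(cv_mean)
        lambdas = np.logspace(0, -2, n) if lambdas is None else lambdas
        return ps.LassoPath(
            lambdas=lambdas,
            coefs=np.zeros((n, 1)),
            intercepts=np.zeros(n),
            cv_mean=np.asarray(cv_mean, dtype=float),
            cv_se=np.asarray(cv_se, dtype=float),
            feature_names=["A__B"],
            fold_ids=np.zeros(1, dtype=np.int64),
            nfolds=10,
            seed=0,
        )

    def test_flat_curve_selects_largest_lambda(self):
        path = self._path([1.0] * 8, [0.1] * 8)
        assert ps.select_lambda_1se(path) == path.lambdas[0]

    def test_zero_se_decreasing_curve_selects_minimum(self):
        path = self._path([5, 4, 3, 2, 1], [0] * 5)
        assert ps.select_lambda_1se(path) == path.lambdas[-1]
        assert ps.select_lambda_min(path) == path.lambdas[-1]

    def test_agrees_with_bruteforce_scan(self):
        rng = np.random.default_rng(31)
        for _ in range(300):
            n = rng.integers(3, 40)
            cv_mean = rng.uniform(0.5, 2.0, n)
            cv_se = rng.uniform(0.0, 0.3, n)
            path = self._path(cv_mean, cv_se)
            # brute force: scan every grid point, keep the largest qualifying λ
            k_min = int(np.argmin(cv_mean))
            bound = cv_mean[k_min] + cv_se[k_min]
            best = max(
                (lam for lam, m in zip(path.lambdas, cv_mean) if m <= bound)
            )
            assert ps.select_lambda_1se(path) == best


class TestSignatureModel:
    def test_empty_signature_at_lambda_max(self):
        X, y = _toy_design()
        path = ps.fit_lasso_logistic(X, y, nfolds=2, seed=0, n_lambda=10)
        with pytest.warns(RuntimeWarning, match="empty"):
            sig = ps.extract_signature(path, float(path.lambdas[0]))
        assert len(sig) == 0

    def test_off_grid_lambda_rejected(self):
        X, y = _toy_design()
        path = ps.fit_lasso_logistic(X, y, nfolds=2, seed=0, n_lambda=10)
        with pytest.raises(ValueError, match="not on the fitted grid"):
            ps.extract_signature(path, 0.123456789)

    def test_planted_pair_recovery(self):
        """5 strongly informative pairs are found in the λ_1SE support."""
        rng = np.random.default_rng(41)
        n_per = 60
        genes = [f"G{i:02d}" for i in range(12)]
        planted = [ps.GenePair(genes[2 * k], genes[2 * k + 1]) for k in range(5)]
        values = np.empty((12, 2 * n_per))
        labels = ["tumor"] * n_per + ["nontumor"] * n_per
        for k in range(5):
            lo, hi = 6.0, 8.0
            # tumor: first gene above second; nontumor: reversed
            values[2 * k, :n_per] = rng.normal(hi, 0.4, n_per)
            values[2 * k + 1, :n_per] = rng.normal(lo, 0.4, n_per)
            values[2 * k, n_per:] = rng.normal(lo, 0.4, n_per)
            values[2 * k + 1, n_per:] = rng.normal(hi, 0.4, n_per)
        values[10:] = rng.normal(7.0, 1.0, size=(2, 2 * n_per))
        ds = make_dataset(values, genes, [f"s{i}" for i in range(2 * n_per)], labels)
        pm = ps.build_pair_matrix(ds, ps.enumerate_pairs(genes))
        path = ps.fit_lasso_logistic(pm, nfolds=10, seed=2)
        sig = ps.extract_signature(path, ps.select_lambda_1se(path))
        support = {p.id for p in sig.pairs}
        assert sum(p.id in support for p in planted) >= 4

    def test_score_single_pair_examples(self):
        sig = ps.SignatureModel(entries=[(ps.GenePair("GA", "GB"), 0.5)], intercept=0.0)
        ds = make_dataset(
            np.array([[2.0, 1.0], [1.0, 2.0]]), ["GA", "GB"], ["s1", "s2"],
            ["tumor", "nontumor"],
        )
        scores = ps.score_samples(sig, ds)
        assert scores["s1"] == pytest.approx(0.5)  # indicator 1
        assert scores["s2"] == pytest.approx(0.0)  # indicator 0 -> intercept

    def test_all_zero_indicators_give_intercept(self):
        sig = ps.SignatureModel(
            entries=[(ps.GenePair("GA", "GB"), 0.7)], intercept=-1.25
        )
        ds = make_dataset(
            np.array([[1.0], [2.0]]), ["GA", "GB"], ["s1"], ["tumor"]
        )
        assert ps.score_samples(sig, ds)["s1"] == pytest.approx(-1.25)
        assert ps.score_samples(sig, ds, include_intercept=False)["s1"] == 0.0

    def test_score_invariance_under_distortion(self, signature_demo_dataset):
        sig = ps.load_default_signature()
        base = ps.score_samples(sig, signature_demo_dataset)
        distorted = ps.apply_sample_distortion(signature_demo_dataset, "affine", seed=3)
        pd.testing.assert_series_equal(base, ps.score_samples(sig, distorted))

    def test_missing_signature_gene_errors(self, signature_demo_dataset):
        trimmed = signature_demo_dataset.expr.drop(index=["TPO"])
        ds = ps.ExpressionDataset(trimmed, signature_demo_dataset.meta)
        with pytest.raises(KeyError, match="TPO"):
            ps.score_samples(ps.load_default_signature(), ds)


class TestPersistence:
    def test_roundtrip(self, tmp_path):
        sig = ps.SignatureModel(
            entries=[(ps.GenePair("CA4", "CDH3"), -0.25), (ps.GenePair("GLUL", "TFF3"), 1.5)],
            intercept=0.75,
            provenance="unit test",
        )
        path = tmp_path / "sig.tsv"
        ps.save_signature(sig, path)
        back = ps.load_signature(path)
        assert back.entries == sig.entries
        assert back.intercept == sig.intercept
        assert back.provenance == sig.provenance

    def test_packaged_signature_roundtrip(self, tmp_path):
        sig = ps.load_default_signature()
        path = tmp_path / "sig.tsv"
        ps.save_signature(sig, path)
        back = ps.load_signature(path)
        assert back.entries == sig.entries
        assert back.intercept == sig.intercept

    def test_noncanonical_pair_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "gene_first\tgene_second\tcoefficient\nCDH3\tCA4\t-0.34\n"
        )
        with pytest.raises(ValueError, match="canonical"):
            ps.load_signature(path)

    def test_duplicate_pair_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "gene_first\tgene_second\tcoefficient\nCA4\tCDH3\t-0.3\nCA4\tCDH3\t0.2\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            ps.load_signature(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("geneA\tgeneB\tbeta\nCA4\tCDH3\t-0.3\n")
        with pytest.raises(ValueError, match="header"):
            ps.load_signature(path)
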