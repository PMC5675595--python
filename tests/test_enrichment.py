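import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retscan.accessibility import uniform_provider
from retscan.enrichment import (
    EnrichmentResult,
    LassoLogisticCV,
    MotifEnrichmentLRT,
    fit_lasso_cv,
    nested_lrt,
    results_frame,
    scan_collection,
    evaluate_motif,
)
from retscan.gene_models import RegionKind
from retscan.motif import FeatureTable, IUPACMotif, build_feature_table


def _table(features: pd.DataFrame, labels) -> FeatureTable:
    return FeatureTable(
        "m", RegionKind.THREE_PRIME_UTR, features,
        pd.Series(np.asarray(labels), index=features.index, name="label"),
    )


def _signal_table(seed, n=80, noise=1.0):
    """motif_score separates the classes; controls are pure noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    score = np.where(y == 1, 3.0, 0.0) + noise * rng.normal(size=n).round(3)
    X = pd.DataFrame({
        "motif_score": score,
        "GG": rng.integers(0, 10, size=n),
        "UG": rng.integers(0, 10, size=n),
        "region_length": rng.integers(100, 400, size=n),
    })
    return _table(X, y)


class TestLassoLogisticCV:
    def test_all_zero_features_select_nothing(self):
        X = pd.DataFrame(np.zeros((20, 3)), columns=["motif_score", "GG", "region_length"])
        y = np.repeat([1, 0], 10)
        lam, selected, coef = fit_lasso_cv(_table(X, y), folds=5, seed=0)
        assert selected == []
        assert np.all(coef == 0)

    def test_separating_score_selected_across_seeds(self):
        hits = sum(
            "motif_score" in fit_lasso_cv(_signal_table(seed), folds=5, seed=seed)[1]
            for seed in range(20)
        )
        assert hits >= 19

    def test_permuted_labels_rarely_select_motif(self):
        rng = np.random.default_rng(99)
        table = _signal_table(0)
        hits = 0
        for seed in range(50):
            y_perm = rng.permutation(table.labels.to_numpy())
            perm = _table(table.features, y_perm)
            if "motif_score" in fit_lasso_cv(perm, folds=5, seed=seed)[1]:
                hits += 1
        assert hits <= 10  # <= 20% of 50 null runs

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError):
            LassoLogisticCV().fit(X, np.ones(10))

    def test_fewer_rows_than_folds_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError):
            LassoLogisticCV(cv=5).fit(X, [0, 1, 0, 1])

    def test_path_shape_and_monotone_lambda(self):
        est = LassoLogisticCV(random_state=0).fit(
            _signal_table(1).features, _signal_table(1).labels
        )
        assert len(est.lambda_path_) == 100
        assert np.all(np.diff(est.lambda_path_) < 0)
        # glmnet default for n > p
        assert est.lambda_path_[-1] == pytest.approx(est.lambda_path_[0] * 1e-4)

    def test_sklearn_params_roundtrip(self):
        est = LassoLogisticCV(cv=3, random_state=7)
        assert LassoLogisticCV(**est.get_params()).get_params() == est.get_params()

    def test_matches_glmnet_lambda_max(self, tmp_path):
        """Independent cross-check of the penalty path start against glmnet."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        table = _signal_table(3)
        X, y = table.features, table.labels.to_numpy()
        xfile, yfile = tmp_path / "x.csv", tmp_path / "y.csv"
        X.to_csv(xfile, index=False)
        np.savetxt(yfile, y)
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(glmnet))\n"
            f"x <- as.matrix(read.csv('{xfile}'))\n"
            f"y <- scan('{yfile}', quiet=TRUE)\n"
            "fit <- glmnet(x, y, family='binomial', standardize=TRUE)\n"
            "cat(max(fit$lambda), '\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        glmnet_lambda_max = float(out.stdout.strip().split()[-1])
        est = LassoLogisticCV(random_state=0).fit(X, y)
        assert est.lambda_path_[0] == pytest.approx(glmnet_lambda_max, rel=1e-4)


class TestNestedLRT:
    def test_motif_not_selected_gives_p_one(self):
        table = _signal_table(0)
        res = nested_lrt(table, ["GG", "region_length"])
        assert res.p_value == 1.0 and res.df == 0 and not res.motif_selected

    def test_equal_likelihoods_give_zero_statistic(self):
        # motif_score duplicated as a control: the full model adds nothing
        rng = np.random.default_rng(4)
        score = rng.normal(size=40)
        X = pd.DataFrame({"motif_score": score, "GG": score})
        y = (score + rng.normal(scale=2, size=40) > 0).astype(int)
        res = nested_lrt(_table(X, y), ["motif_score", "GG"])
        assert res.lrt_statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_chi_square_reference_value(self):
        # independent oracle for the printed textbook pair (10.83, 1) ~ 0.001
        assert stats.chi2.sf(10.83, df=1) == pytest.approx(0.001, rel=0.01)
        table = _signal_table(0, noise=2.5)
        res = nested_lrt(table, ["motif_score", "GG"])
        assert res.p_value == pytest.approx(
            stats.chi2.sf(res.lrt_statistic, df=1), rel=1e-12
        )
        assert res.df == 1

    def test_perfect_separation_flagged(self):
        table = _signal_table(0, noise=0.0)
        res = nested_lrt(table, ["motif_score"])
        assert res.separation
        assert res.lrt_statistic > 20
        assert res.p_value < 1e-5


class TestMotifEnrichmentLRT:
    def test_planted_signal_detected(self, planted_dataset, srsf1):
        by_id, partition, _ = planted_dataset
        table = build_feature_table(
            partition, by_id, RegionKind.THREE_PRIME_UTR, srsf1, uniform_provider
        )
        est = MotifEnrichmentLRT(random_state=1).fit(table.features, table.labels)
        assert est.motif_selected_
        assert est.p_value_ < 1e-10
        assert est.df_ == 1

    def test_estimator_deterministic(self, planted_dataset, srsf1):
        by_id, partition, _ = planted_dataset
        table = build_feature_table(
            partition, by_id, RegionKind.THREE_PRIME_UTR, srsf1, uniform_provider
        )
        a = MotifEnrichmentLRT(random_state=5).fit(table.features, table.labels)
        b = MotifEnrichmentLRT(random_state=5).fit(table.features, table.labels)
        assert a.p_value_ == b.p_value_
        assert a.lambda_selected_ == b.lambda_selected_
        assert a.selected_features_ == b.selected_features_


class TestScanCollection:
    def test_single_motif_matches_direct_run(self, planted_dataset, srsf1):
        by_id, partition, _ = planted_dataset
        table = build_feature_table(
            partition, by_id, RegionKind.THREE_PRIME_UTR, srsf1, uniform_provider
        )
        direct = evaluate_motif(table, folds=5, seed=1)
        [res] = scan_collection(
            [srsf1], partition, by_id, RegionKind.THREE_PRIME_UTR,
            uniform_provider, seed=1,
        )
        assert res.p_value == direct.p_value
        assert res.q_value == pytest.approx(direct.p_value)

    def test_planted_motif_ranks_first_among_decoys(self, planted_dataset, srsf1):
        by_id, partition, _ = planted_dataset
        decoys = [
            IUPACMotif(f"D{i}", f"decoy{i}", p)
            for i, p in enumerate(
                ["UUUUAUU", "RCGCGY", "AUWUAUA", "GCAUGM", "YACAYAC",
                 "CUKCUUC", "ACGUACG", "WGGACWG", "UCAYUCA"]
            )
        ]
        results = scan_collection(
            [srsf1] + decoys, partition, by_id, RegionKind.THREE_PRIME_UTR,
            uniform_provider, seed=1,
        )
        assert results[0].motif_id == "SRSF1_1"
        assert results[0].p_value < min(r.p_value for r in results[1:])
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)

    def test_identical_sequences_give_p_one(self, srsf1):
        from retscan.compartment import GeneSetPartition
        from retscan.gene_models import TranscriptRecord

        seq = "A" * 20 + "GGAAGGAGGAAGGAACGUACGU"
        ids = [f"X{i}" for i in range(10)]
        records = {t: TranscriptRecord(t, t, seq, 10, 20) for t in ids}
        partition = GeneSetPartition(ids[:5], ids[5:])
        [res] = scan_collection(
            [srsf1], partition, records, RegionKind.THREE_PRIME_UTR,
            uniform_provider, seed=1,
        )
        assert res.p_value == 1.0 and not res.motif_selected

    def test_failing_motif_recorded_not_raised(self, planted_dataset, srsf1):
        by_id, partition, _ = planted_dataset

        def broken_provider(tid, length):
            raise OSError("no track")

        results = scan_collection(
            [srsf1], partition, by_id, RegionKind.THREE_PRIME_UTR,
            broken_provider, seed=1,
        )
        assert results[0].error is not None
        assert np.isnan(results[0].p_value)

    def test_results_frame_columns(self, planted_dataset, srsf1):
        by_id, partition, _ = planted_dataset
        results = scan_collection(
            [srsf1], partition, by_id, RegionKind.THREE_PRIME_UTR,
            uniform_provider, seed=1,
        )
        df = results_frame(results)
        assert list(df["motif_id"]) == ["SRSF1_1"]
        assert {"p_value", "q_value", "lrt_statistic", "selected_features"} <= set(df.columns)
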