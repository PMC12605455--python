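"""Interest-area filtering, DV derivation, model table, effect checks."""

import math

import numpy as np
import pandas as pd
import pytest

from wordinfo import eyetrack as et
from wordinfo.errors import (
    ParseError,
    RankDeficiencyError,
    SchemaError,
    UndefinedStatisticError,
)
from wordinfo.synth import SynthConfig, make_corpus, make_eye_data, make_scores


def toy_ia(rows):
    base = {"subject": "S1", "language": "L1", "trial": "t1", "word": "word"}
    return pd.DataFrame([{**base, "ia_index": i, **r} for i, r in enumerate(rows)])


def build_table(cfg: SynthConfig) -> tuple[et.ModelTable, dict]:
    corpus = make_corpus(cfg)
    scores = make_scores(cfg, corpus)
    ia, skills, truth = make_eye_data(cfg, scores)
    kept, _ = et.filter_ia(ia)
    kept = et.derive_dvs(kept)
    sk, _ = et.composite_skill(skills)
    keys = ["language", "trial", "ia_index"]
    table = et.build_model_table(
        kept, scores[keys + ["informativeness", "outlier"]],
        zipf=scores[keys + ["zipf"]],
        predictability=scores[keys + ["predictability"]],
        skills=sk)
    return table, truth


class TestReadIaReport:
    def test_toy_csv(self, tmp_path):
        p = tmp_path / "ia.csv"
        p.write_text("subject,language,trial,ia_index,word,ffd,gaze,tfd\n"
                     "S1,L1,t1,0,cat,200,250,300\n"
                     "S1,L1,t1,1,sat,NA,NA,NA\n"
                     "S1,L1,t1,2,mat,150,150,150\n")
        df = et.read_ia_report(p)
        assert len(df) == 3
        assert df.loc[1, "tfd"] != df.loc[1, "tfd"]  # NaN

    def test_missing_column_schema_error(self, tmp_path):
        p = tmp_path / "ia.csv"
        p.write_text("subject,language,trial,ia_index,word,ffd,gaze\nS1,L1,t1,0,cat,1,2\n")
        with pytest.raises(SchemaError, match="tfd"):
            et.read_ia_report(p)

    def test_non_numeric_duration_parse_error(self, tmp_path):
        p = tmp_path / "ia.csv"
        p.write_text("subject,language,trial,ia_index,word,ffd,gaze,tfd\n"
                     "S1,L1,t1,0,cat,200,250,300\n"
                     "S1,L1,t1,1,sat,abc,250,300\n")
        with pytest.raises(ParseError, match="row 2"):
            et.read_ia_report(p)


class TestFilterIa:
    def test_strict_boundaries(self):
        df = toy_ia([
            {"ffd": 79, "gaze": 79, "tfd": 79},       # removed: tfd < 80
            {"ffd": 80, "gaze": 80, "tfd": 80},       # kept: boundary
            {"ffd": 100, "gaze": 100, "tfd": 2000},   # kept: boundary
            {"ffd": 100, "gaze": 100, "tfd": 2001},   # removed: tfd > 2000
            {"ffd": 801, "gaze": 900, "tfd": 1000},   # removed: ffd > 800
            {"ffd": 800, "gaze": 1000, "tfd": 1500},  # kept: both boundaries
            {"ffd": 500, "gaze": 1001, "tfd": 1500},  # removed: gaze > 1000
        ])
        kept, log = et.filter_ia(df)
        assert sorted(kept["ia_index"]) == [1, 2, 5]
        assert log["n_removed"] == 4
        assert log["tfd_below_min"] == 1 and log["ffd_above_max"] == 1

    def test_ffd_rule_applies_even_with_ok_tfd(self):
        df = toy_ia([{"ffd": 900, "gaze": 950, "tfd": 1800}])
        kept, log = et.filter_ia(df)
        assert kept.empty and log["ffd_above_max"] == 1

    def test_skipped_words_retained(self):
        df = toy_ia([{"ffd": np.nan, "gaze": np.nan, "tfd": np.nan}])
        kept, log = et.filter_ia(df)
        assert len(kept) == 1 and log["n_removed"] == 0

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = toy_ia([{"ffd": float(f), "gaze": float(g), "tfd": float(t)}
                     for f, g, t in zip(rng.integers(10, 900, 200),
                                        rng.integers(10, 1200, 200),
                                        rng.integers(10, 2500, 200))])
        once, _ = et.filter_ia(df)
        twice, log2 = et.filter_ia(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log2["n_removed"] == 0


class TestDeriveDvs:
    def test_no_rereading(self):
        df = et.derive_dvs(toy_ia([{"ffd": 200.0, "gaze": 200.0, "tfd": 200.0}]))
        assert df.loc[0, "reread"] == 0
        assert df.loc[0, "log_tfd"] == pytest.approx(math.log(200), abs=1e-4)
        assert df.loc[0, "skip"] == 0

    def test_rereading(self):
        df = et.derive_dvs(toy_ia([{"ffd": 200.0, "gaze": 250.0, "tfd": 520.0}]))
        assert df.loc[0, "reread"] == 1

    def test_skipped_word(self):
        df = et.derive_dvs(toy_ia([{"ffd": np.nan, "gaze": np.nan, "tfd": np.nan}]))
        assert df.loc[0, "skip"] == 1
        assert np.isnan(df.loc[0, "log_tfd"]) and np.isnan(df.loc[0, "reread"])

    def test_first_pass_skip_with_later_fixation(self):
        df = et.derive_dvs(toy_ia([{"ffd": np.nan, "gaze": np.nan, "tfd": 300.0}]))
        assert df.loc[0, "skip"] == 1 and df.loc[0, "reread"] == 1

    def test_reread_consistency_on_simulated_data(self):
        cfg = SynthConfig(seed=5, n_subjects=5, n_passages=4)
        corpus = make_corpus(cfg)
        ia, _, _ = make_eye_data(cfg, make_scores(cfg, corpus))
        kept, _ = et.filter_ia(ia)
        df = et.derive_dvs(kept)
        fix = df[df["tfd"].notna() & df["gaze"].notna()]
        np.testing.assert_array_equal(fix["reread"].to_numpy(),
                                      (fix["tfd"] > fix["gaze"]).astype(float))


class TestCompositeSkill:
    def _scores(self, matrix):
        cols = list(et.SKILL_TESTS)
        return pd.DataFrame([{"subject": f"S{i}",
                              **dict(zip(cols, row))} for i, row in enumerate(matrix)])

    def test_subject_at_mean_scores_zero(self):
        df, _ = et.composite_skill(self._scores([[10, 10, 10, 10, 10],
                                                 [20, 20, 20, 20, 20],
                                                 [15, 15, 15, 15, 15]]))
        assert df.loc[2, "composite"] == pytest.approx(0.0)

    def test_all_z_one(self):
        df, _ = et.composite_skill(self._scores([[10, 10, 10, 10, 10],
                                                 [20, 20, 20, 20, 20]]))
        assert df.loc[1, "composite"] == pytest.approx(1.0)

    def test_matches_numpy_zscore_oracle(self):
        rng = np.random.default_rng(3)
        matrix = rng.normal(50, 10, size=(12, 5))
        out, _ = et.composite_skill(self._scores(matrix))
        z = (matrix - matrix.mean(axis=0)) / matrix.std(axis=0)
        np.testing.assert_allclose(out["composite"], z.mean(axis=1), atol=1e-12)

    def test_opposite_deviations_cancel(self):
        # one subject +z on a test and -z on another, at the mean elsewhere
        matrix = np.array([[10.0, 20.0, 5.0, 5.0, 5.0],
                           [20.0, 10.0, 5.0, 7.0, 9.0],
                           [15.0, 15.0, 5.0, 3.0, 1.0]])
        out, log = et.composite_skill(self._scores(matrix))
        assert "towre_nonword" not in log["undefined_tests"]
        assert out.loc[0, "z_towre_word"] == pytest.approx(-out.loc[0, "z_towre_nonword"])

    def test_constant_test_flagged_undefined(self):
        df, log = et.composite_skill(self._scores([[1, 5, 5, 1, 1], [2, 5, 6, 2, 2]]))
        assert log["undefined_tests"] == ["towre_nonword"]
        assert df["z_towre_nonword"].isna().all()

    def test_single_subject_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            et.composite_skill(self._scores([[1, 2, 3, 4, 5]]))

    def test_missing_test_dropped_from_mean(self):
        df = self._scores([[10, 10, 10, 10, 10], [20, 20, 20, 20, 20]])
        df.loc[0, "vocabulary"] = np.nan
        out, _ = et.composite_skill(df)
        assert out.loc[0, "n_tests_used"] == 4


@pytest.fixture(scope="module")
def table_truth():
    return build_table(SynthConfig(seed=11))


class TestBuildModelTable:
    def test_scaled_covariates_standardized(self, table_truth):
        table, _ = table_truth
        for col in ("informativeness", "length", "zipf", "composite"):
            assert table.data[col].mean() == pytest.approx(0.0, abs=1e-8)
            assert table.data[col].std(ddof=0) == pytest.approx(1.0, abs=1e-8)
            assert col in table.scaling

    def test_unmatched_rows_absent(self):
        ia = et.derive_dvs(toy_ia([{"ffd": 200.0, "gaze": 200.0, "tfd": 250.0},
                                   {"ffd": 180.0, "gaze": 180.0, "tfd": 180.0}]))
        info = pd.DataFrame({"language": ["L1"], "trial": ["t1"], "ia_index": [0],
                             "informativeness": [-3.0]})
        out = et.build_model_table(ia, info)
        assert len(out.data) == 1 and out.data["ia_index"].iloc[0] == 0

    def test_outlier_informativeness_rows_dropped(self):
        ia = et.derive_dvs(toy_ia([{"ffd": 200.0, "gaze": 200.0, "tfd": 250.0},
                                   {"ffd": 180.0, "gaze": 180.0, "tfd": 180.0},
                                   {"ffd": 150.0, "gaze": 150.0, "tfd": 150.0}]))
        info = pd.DataFrame({"language": "L1", "trial": "t1",
                             "ia_index": [0, 1, 2],
                             "informativeness": [-3.0, -11.0, -4.0]})
        out = et.build_model_table(ia, info)
        assert out.n_dropped_outliers == 1
        assert sorted(out.data["ia_index"]) == [0, 2]

    def test_duplicate_join_keys_rejected(self):
        ia = et.derive_dvs(toy_ia([{"ffd": 200.0, "gaze": 200.0, "tfd": 250.0}]))
        info = pd.DataFrame({"language": ["L1", "L1"], "trial": ["t1", "t1"],
                             "ia_index": [0, 0], "informativeness": [-3.0, -4.0]})
        with pytest.raises(ValueError, match="duplicate"):
            et.build_model_table(ia, info)

    def test_join_conservation(self, table_truth):
        table, _ = table_truth
        keys = ["subject", "language", "trial", "ia_index"]
        assert not table.data.duplicated(subset=keys).any()


class TestFitEffectCheck:
    def test_recovers_planted_duration_effect(self, table_truth):
        table, truth = table_truth
        est = {e.term: e for e in et.fit_effect_check(
            table, "log_tfd",
            ["informativeness", "length", "zipf", "predictability"])}
        e = est["informativeness"]
        assert abs(e.beta - truth["b_info"]) < 1.96 * e.se

    def test_recovers_planted_signs(self, table_truth):
        table, truth = table_truth
        est = {e.term: e for e in et.fit_effect_check(
            table, "log_tfd",
            ["informativeness", "length", "zipf", "predictability"])}
        for term, key in (("informativeness", "b_info"), ("length", "b_len"),
                          ("zipf", "b_zipf")):
            assert math.copysign(1, est[term].beta) == math.copysign(1, truth[key])

    def test_skip_logistic_recovers_negative_signs(self, table_truth):
        table, truth = table_truth
        est = {e.term: e for e in et.fit_effect_check(
            table, "skip", ["informativeness", "length"])}
        assert est["informativeness"].beta < 0 and truth["skip_b_info"] < 0
        assert est["length"].beta < 0 and truth["skip_b_len"] < 0

    def test_negative_skill_interaction_sign_recovered(self, table_truth):
        table, truth = table_truth
        est = {e.term: e for e in et.fit_effect_check(
            table, "log_tfd",
            ["informativeness", "length", "zipf", "predictability",
             "composite", "composite:informativeness"])}
        assert truth["b_skill_info"] < 0
        assert est["composite:informativeness"].beta < 0

    def test_null_effect_type_one_control(self):
        """With b_info = 0 planted, |beta| < 2 se in at least 90% of replicates."""
        hits = 0
        n_reps = 50
        for rep in range(n_reps):
            cfg = SynthConfig(seed=1000 + rep, b_info=0.0, b_skill_info=0.0,
                              n_subjects=10, n_passages=5, tokens_per_passage=30,
                              vocabulary_size=80)
            table, _ = build_table(cfg)
            est = {e.term: e for e in et.fit_effect_check(
                table, "log_tfd", ["informativeness", "length", "zipf"])}
            e = est["informativeness"]
            hits += abs(e.beta) < 2 * e.se
        assert hits >= 0.9 * n_reps

    def test_collinear_terms_rejected(self, table_truth):
        table, _ = table_truth
        df = table.data.copy()
        df["info2"] = df["informativeness"]
        with pytest.raises(RankDeficiencyError):
            et.fit_effect_check(et.ModelTable(data=df), "log_tfd",
                                ["informativeness", "info2"])

    def test_too_few_rows_rejected(self, table_truth):
        table, _ = table_truth
        small = et.ModelTable(data=table.data.head(10))
        with pytest.raises(ValueError):
            et.fit_effect_check(small, "log_tfd", ["informativeness"])

    def test_ols_route_matches_statsmodels_oracle(self, table_truth):
        """Unpenalized fit agrees with statsmodels OLS on the same design."""
        import statsmodels.api as sm

        table, _ = table_truth
        sub = table.data.dropna(subset=["log_tfd"]).head(2000)
        X = np.column_stack([np.ones(len(sub)),
                             sub["informativeness"], sub["length"]])
        y = sub["log_tfd"].to_numpy()
        from wordinfo.eyetrack import _fit_ols

        beta, cov = _fit_ols(X, y, np.zeros(3))
        fit = sm.OLS(y, X).fit()
        np.testing.assert_allclose(beta, fit.params, atol=1e-8)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)), fit.bse, atol=1e-8)
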