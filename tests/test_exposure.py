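"""Negative-binomial exposure models and sensitivity summaries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from coreclades.exposure import (
    ExposureDesign,
    SensitivityRecord,
    fit_nb_glm,
    sensitivity_scan,
    summarize_sensitivity,
)


def nb_draw(rng, mu, size, n):
    lam = rng.gamma(shape=size, scale=mu / size, size=n)
    return rng.poisson(lam)


def two_arm_design(n_control, n_exposed, label="tox", study="study1"):
    ids = [f"s{i}" for i in range(n_control + n_exposed)]
    levels = pd.Series(
        ["control"] * n_control + [label] * n_exposed, index=ids
    )
    return ExposureDesign(study=study, levels=levels)


class TestExposureDesign:
    def test_missing_control_raises(self):
        levels = pd.Series(["tox"] * 4, index=list("abcd"))
        with pytest.raises(ValueError, match="control"):
            ExposureDesign(study="s", levels=levels)

    def test_single_sample_level_raises(self):
        levels = pd.Series(
            ["control", "control", "tox"], index=list("abc")
        )
        with pytest.raises(ValueError, match="<2 samples"):
            ExposureDesign(study="s", levels=levels)


class TestFitNbGlm:
    def test_null_effect_unbiased(self, rng):
        betas, ses = [], []
        design = two_arm_design(100, 100)
        for _ in range(30):
            y = nb_draw(rng, 20, 2, 200)
            fit = fit_nb_glm(y, design)
            b, se, _ = fit.coef["tox"]
            betas.append(b)
            ses.append(se)
        mean_se = np.mean(ses) / np.sqrt(len(betas))
        assert abs(np.mean(betas)) < 3 * mean_se

    def test_recovers_log2_fold_change(self, rng):
        design = two_arm_design(100, 100)
        betas = []
        for _ in range(50):
            y = np.concatenate(
                [nb_draw(rng, 20, 2, 100), nb_draw(rng, 40, 2, 100)]
            )
            betas.append(fit_nb_glm(y, design).coef["tox"][0])
        assert abs(np.mean(betas) - np.log(2)) < 0.1

    def test_poisson_limit_matches_poisson_glm(self, rng):
        y = rng.poisson(20, size=200)
        design = two_arm_design(100, 100)
        fit = fit_nb_glm(y, design)
        X = np.column_stack(
            [np.ones(200), np.r_[np.zeros(100), np.ones(100)]]
        )
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert abs(fit.coef["tox"][0] - pois.params[1]) < 1e-4
        assert abs(fit.intercept - pois.params[0]) < 1e-4

    def test_dispersion_estimate_in_range(self, rng):
        design = two_arm_design(150, 150)
        sizes = [
            fit_nb_glm(nb_draw(rng, 30, 2, 300), design).dispersion
            for _ in range(20)
        ]
        assert 1 < np.median(sizes) < 4

    def test_all_zero_response_degenerate(self):
        design = two_arm_design(5, 5)
        fit = fit_nb_glm(np.zeros(10, dtype=int), design)
        assert fit.status == "degenerate"
        assert np.isnan(fit.coef["tox"][0])

    def test_mostly_zero_response_skipped(self):
        design = two_arm_design(50, 50)
        y = np.zeros(100, dtype=int)
        y[0] = 3
        fit = fit_nb_glm(y, design)
        assert fit.status == "insufficient_signal"

    def test_negative_counts_raise(self):
        design = two_arm_design(3, 3)
        with pytest.raises(ValueError):
            fit_nb_glm(np.array([-1, 0, 1, 2, 3, 4]), design)


def scan_inputs(rng, n_clades=6, n_per_arm=30, lfc=0.0, study="study1"):
    ids = [f"{study}_s{i}" for i in range(2 * n_per_arm)]
    meta = pd.DataFrame(
        {
            "study": study,
            "exposure": ["control"] * n_per_arm + ["tox"] * n_per_arm,
        },
        index=ids,
    )
    rows = []
    for _ in range(n_clades):
        mu = 20.0
        y = np.concatenate(
            [
                nb_draw(rng, mu, 2, n_per_arm),
                nb_draw(rng, mu * np.exp(lfc), 2, n_per_arm),
            ]
        )
        rows.append(y)
    matrix = pd.DataFrame(
        rows, index=[f"node{i}" for i in range(n_clades)], columns=ids
    )
    return matrix, meta


class TestSensitivityScan:
    def test_null_false_call_rate_controlled(self, rng):
        flagged, total = 0, 0
        for _ in range(15):
            matrix, meta = scan_inputs(rng, n_clades=8, lfc=0.0)
            recs = sensitivity_scan(matrix, meta, fdr=0.1)
            flagged += sum(r.sensitive for r in recs)
            total += len(recs)
        assert flagged / total <= 0.1

    def test_strong_effects_detected(self, rng):
        detected = []
        for _ in range(5):
            matrix, meta = scan_inputs(rng, n_clades=10, n_per_arm=50, lfc=np.log(4))
            recs = sensitivity_scan(matrix, meta, fdr=0.1)
            detected.append(np.mean([r.sensitive for r in recs]))
        assert np.mean(detected) >= 0.9

    def test_control_only_study_skipped_with_warning(self, rng):
        matrix, meta = scan_inputs(rng, n_clades=3)
        meta_ctrl = meta.copy()
        meta_ctrl["exposure"] = "control"
        with pytest.warns(UserWarning, match="skipped"):
            recs = sensitivity_scan(matrix, meta_ctrl)
        assert recs == []

    def test_sample_order_within_study_irrelevant(self, rng):
        matrix, meta = scan_inputs(rng, n_clades=4, lfc=np.log(2))
        recs1 = sensitivity_scan(matrix, meta)
        perm = rng.permutation(len(meta))
        meta2 = meta.iloc[perm]
        matrix2 = matrix[meta2.index]
        recs2 = sensitivity_scan(matrix2, meta2)
        key = lambda r: (r.study, r.clade_id, r.exposure_level)
        d1 = {key(r): (r.beta, r.se, r.p) for r in recs1}
        d2 = {key(r): (r.beta, r.se, r.p) for r in recs2}
        assert d1.keys() == d2.keys()
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], abs=1e-10)

    def test_fdr_within_study_by_default(self, rng):
        # two studies: one with huge effects, one null; per-study FDR means
        # the null study's q-values are not diluted by the other's signal
        m1, meta1 = scan_inputs(rng, n_clades=5, lfc=np.log(8), study="study1")
        m2, meta2 = scan_inputs(rng, n_clades=5, lfc=0.0, study="study2")
        matrix = pd.concat([m1, m2.set_axis([f"x{i}" for i in range(5)])])
        matrix = matrix.fillna(0).astype(int)
        meta = pd.concat([meta1, meta2])
        recs = sensitivity_scan(matrix, meta, fdr=0.1)
        null_flags = [
            r.sensitive
            for r in recs
            if r.study == "study2" and r.clade_id.startswith("x")
        ]
        assert np.mean(null_flags) <= 0.2


class TestSummarize:
    def make_records(self):
        mk = lambda st, cid, lev, sens: SensitivityRecord(
            study=st,
            clade_id=cid,
            exposure_level=lev,
            beta=0.5,
            se=0.1,
            p=0.01,
            q=0.05 if sens else 0.9,
            sensitive=sens,
        )
        return [
            mk("study1", "nodeA", "X", True),
            mk("study1", "nodeA", "Y", True),
            mk("study2", "nodeA", "Z", True),
            mk("study1", "nodeB", "X", False),
            mk("study1", "nodeB", "Y", False),
            mk("study2", "nodeB", "Z", False),
        ]

    def test_counts_distinct_exposures_per_clade(self):
        summary = summarize_sensitivity(self.make_records())
        assert summary.per_clade.loc["nodeA", "n_sensitive_exposures"] == 3
        assert summary.per_clade.loc["nodeB", "n_sensitive_exposures"] == 0

    def test_robust_set_when_nothing_sensitive(self):
        recs = [
            SensitivityRecord(
                study="s1",
                clade_id=c,
                exposure_level="X",
                beta=0.0,
                se=0.1,
                p=0.9,
                q=0.95,
                sensitive=False,
            )
            for c in ["n1", "n2"]
        ]
        summary = summarize_sensitivity(recs)
        assert summary.robust_clades == {"n1", "n2"}

    def test_per_exposure_clade_counts(self):
        summary = summarize_sensitivity(self.make_records())
        assert summary.per_exposure.loc[("study1", "X"), "n_sensitive_clades"] == 1
        assert summary.per_exposure.loc[("study2", "Z"), "n_sensitive_clades"] == 1

    def test_empty_records(self):
        summary = summarize_sensitivity([])
        assert summary.per_clade.empty
        assert summary.robust_clades == set()
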