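"""Tests for residualization, ComBat, z-scoring and outlier removal."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import zsustain as zs
from zsustain.harmonize import CovariateDesign


def _frame(X, prefix="roi"):
    return pd.DataFrame(X, columns=[f"{prefix}{i}" for i in range(X.shape[1])])


class TestResidualize:
    def _design(self, n, rng, constant_tiv=False):
        df = pd.DataFrame(
            {
                "age": rng.normal(35, 10, n),
                "sex": rng.integers(0, 2, n),
                "site": np.repeat(["s1", "s2"], n // 2),
                "tiv": np.full(n, 1500.0) if constant_tiv else rng.normal(1500, 100, n),
            }
        )
        return df, CovariateDesign.from_frame(df)

    def test_null_covariates_leave_centered_volumes(self, rng):
        n = 600
        df, design = self._design(n, rng)
        Y = _frame(rng.normal(5.0, 1.0, (n, 3)))  # independent of covariates
        resid, _ = zs.residualize(Y, design, np.ones(n, bool))
        centered = Y - Y.mean()
        # residuals differ from centred volumes only by OLS sampling error
        assert float((resid - centered).abs().mean().mean()) < 0.15
        np.testing.assert_allclose(resid.mean(), 0.0, atol=1e-10)

    def test_recovers_planted_age_slope(self, rng):
        # independent oracle: statsmodels OLS gives the same slope and its SE
        import statsmodels.api as sm

        n, b = 500, 0.08
        df, design = self._design(n, rng)
        y = 3.0 + b * df["age"].to_numpy() + rng.normal(0, 1, n)
        _, coef = zs.residualize(_frame(y[:, None]), design, np.ones(n, bool))
        fitted = sm.OLS(y, design.matrix).fit()
        age_ix = design.columns.index("age")
        assert coef.loc["age", "roi0"] == pytest.approx(fitted.params[age_ix], abs=1e-10)
        assert abs(coef.loc["age", "roi0"] - b) < 3 * fitted.bse[age_ix]

    def test_constant_column_is_named_in_error(self, rng):
        df, design = self._design(100, rng, constant_tiv=True)
        with pytest.raises(ValueError, match="tiv"):
            zs.residualize(_frame(rng.normal(0, 1, (100, 2))), design, np.ones(100, bool))

    def test_control_only_mode_uses_control_coefficients(self, rng):
        n = 400
        df, design = self._design(n, rng)
        ctrl = np.zeros(n, bool)
        ctrl[: n // 2] = True
        y = 1.0 + 0.1 * df["age"].to_numpy() + rng.normal(0, 1, n)
        y[~ctrl] -= 2.0  # patient offset must not bias control-only fit
        _, coef_pooled = zs.residualize(_frame(y[:, None]), design, ctrl)
        _, coef_ctrl = zs.residualize(_frame(y[:, None]), design, ctrl, control_only=True)
        import statsmodels.api as sm

        ref = sm.OLS(y[ctrl], design.matrix[ctrl]).fit().params
        np.testing.assert_allclose(coef_ctrl["roi0"].to_numpy(), ref, atol=1e-10)
        assert not np.allclose(coef_pooled["roi0"], coef_ctrl["roi0"])


class TestCombat:
    def test_single_batch_is_identity(self, rng):
        X = _frame(rng.normal(0, 1, (50, 4)))
        out = zs.combat(X, np.repeat("one", 50))
        np.testing.assert_allclose(out.to_numpy(), X.to_numpy(), atol=1e-12)

    def test_removes_planted_additive_shift(self, rng):
        n = 400
        X = np.vstack(
            [rng.normal(0, 1, (n, 17)), rng.normal(0.5, 1, (n, 17))]
        )
        batch = np.repeat(["a", "b"], n)
        out = zs.combat(_frame(X), batch).to_numpy()
        gap = np.abs(out[:n].mean(axis=0) - out[n:].mean(axis=0))
        # table-level residual shift well under 0.05 SD; every feature keeps
        # at most a small remnant of the planted 0.5 (matches sva::ComBat,
        # whose EB shrinkage leaves the same per-feature wobble)
        assert gap.mean() < 0.05
        assert gap.max() < 0.15

    def test_removes_planted_scale_ratio(self, rng):
        n = 400
        X = np.vstack(
            [rng.normal(0, 1.0, (n, 5)), rng.normal(0, 1.5, (n, 5))]
        )
        batch = np.repeat(["a", "b"], n)
        out = zs.combat(_frame(X), batch).to_numpy()
        ratio = out[n:].std(axis=0) / out[:n].std(axis=0)
        assert np.all((ratio > 0.95) & (ratio < 1.05))

    def test_zero_variance_batch_rejected(self, rng):
        X = rng.normal(0, 1, (40, 3))
        X[:20, 1] = 7.0
        with pytest.raises(ValueError, match="zero within-batch variance"):
            zs.combat(_frame(X), np.repeat(["a", "b"], 20))

    def test_matches_reference_combat_from_sva(self, tmp_path):
        # independent oracle: Bioconductor sva::ComBat on the same table
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; the reference ComBat check cannot run")
        rng = np.random.default_rng(42)
        n1, n2, F = 25, 35, 5
        X = np.vstack(
            [rng.normal(0.0, 1.0, (n1, F)) + 0.4, rng.normal(0.0, 1.4, (n2, F)) - 0.2]
        )
        batch = np.array(["a"] * n1 + ["b"] * n2)
        ours = zs.combat(_frame(X), batch).to_numpy()
        csv_in = tmp_path / "in.csv"
        csv_out = tmp_path / "out.csv"
        pd.DataFrame(X).to_csv(csv_in, index=False)
        script = f"""
        suppressMessages(library(sva))
        X <- t(as.matrix(read.csv("{csv_in}")))
        batch <- c(rep("a", {n1}), rep("b", {n2}))
        out <- ComBat(dat=X, batch=batch, par.prior=TRUE)
        write.csv(t(out), "{csv_out}", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(csv_out).to_numpy()
        np.testing.assert_allclose(ours, ref, atol=1e-5)


class TestZScores:
    def test_control_moments_and_sign_flip(self, rng):
        n = 100
        X = _frame(rng.normal(10, 2, (n, 3)))
        ctrl = np.zeros(n, bool)
        ctrl[:60] = True
        z = zs.to_zscores(X, ctrl)
        np.testing.assert_allclose(z.controls.mean(), 0.0, atol=1e-8)
        np.testing.assert_allclose(z.controls.std(ddof=1), 1.0, atol=1e-8)

    def test_sign_convention_examples(self):
        # controls at 9/10/11 -> mean 10, sd 1
        vals = pd.DataFrame({"roi": [9.0, 10.0, 11.0, 10.0, 9.0, 12.0]})
        ctrl = np.array([True, True, True, True, False, False])
        z = zs.to_zscores(vals, ctrl)
        sd = np.std([9, 10, 11, 10], ddof=1)
        assert z.values.iloc[3, 0] == pytest.approx(0.0)  # control at mean
        assert z.values.iloc[4, 0] == pytest.approx(1.0 / sd)  # one unit below -> +z
        assert z.values.iloc[5, 0] == pytest.approx(-2.0 / sd)  # above mean -> -z

    def test_zero_control_sd_rejected(self):
        vals = pd.DataFrame({"roi": [1.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="zero control SD"):
            zs.to_zscores(vals, np.array([True, True, False]))

    def test_needs_two_controls(self):
        vals = pd.DataFrame({"roi": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 2 controls"):
            zs.to_zscores(vals, np.array([True, False]))


class TestRemoveOutliers:
    def _table(self, X):
        n = len(X)
        return zs.ZScoreTable(values=_frame(np.asarray(X, float)), control_mask=np.zeros(n, bool))

    def test_all_within_threshold_is_identity(self):
        z = self._table([[1.0, -4.9], [0.0, 3.0]])
        out, report = zs.remove_outliers(z)
        assert len(out.values) == 2 and report.removed_ids == []

    def test_single_violator_removed(self):
        z = self._table([[1.0, 6.0], [0.0, 3.0]])
        out, report = zs.remove_outliers(z)
        assert report.removed_ids == [0]
        assert report.offending[0] == ["roi1"]
        assert len(out.values) == 1

    def test_hand_built_ten_subject_table(self):
        X = np.zeros((10, 2))
        X[3, 0] = 5.5
        X[7, 1] = -5.2  # two-sided rule
        out, report = zs.remove_outliers(self._table(X))
        assert sorted(report.removed_ids) == [3, 7]
        assert len(out.values) == 8
        assert report.threshold == 5.0


class TestFullChain:
    def test_idempotent_on_single_site_controls(self):
        # re-harmonizing an already loss-oriented z-table (direction -1)
        # reproduces it; exact only for a single batch, where the EB step
        # is the identity
        cfg = zs.SimulationConfig(
            n_patients=2, n_controls=300, seed=21,
            n_sites=1, site_shifts=(0.0,), site_scales=(1.0,),
        )
        cohort = zs.generate_cohort(cfg)
        ctrl = cohort[cohort.group == "control"].reset_index(drop=True)
        z1, _, _ = zs.harmonize_cohort(ctrl)
        again = ctrl.copy()
        again[list(zs.DEFAULT_ATLAS.names)] = z1.values.to_numpy()
        flipped = zs.ROIAtlas(
            names=zs.DEFAULT_ATLAS.names, loss_direction=(-1,) * 17
        )
        z2, _, _ = zs.harmonize_cohort(again, atlas=flipped)
        np.testing.assert_allclose(
            z2.values.to_numpy(), z1.values.to_numpy(), atol=1e-6
        )

    def test_truth_columns_do_not_influence_output(self, small_cohort):
        cohort, _ = small_cohort
        z1, _, _ = zs.harmonize_cohort(cohort)
        scrambled = cohort.copy()
        scrambled["true_stage"] = scrambled["true_stage"].sample(
            frac=1.0, random_state=0
        ).to_numpy()
        scrambled["true_subtype"] = 0
        z2, _, _ = zs.harmonize_cohort(scrambled)
        pd.testing.assert_frame_equal(z1.values, z2.values)
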