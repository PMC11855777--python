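import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import methimmune as mi
from methimmune.data_io import ValidationError
from methimmune.deconvolution import (
    apply_threshold,
    compare_groups,
    deconvolve_matrix,
    deconvolve_sample,
    solve_fractions,
)
from methimmune.synthetic import generate_mixtures

from conftest import make_fraction_cohort


def grid_oracle(y, X, step=0.001):
    """Exhaustive search over the 2-type simplex {a1, a2 >= 0, a1+a2 <= 1}."""
    grid = np.arange(0.0, 1.0 + step / 2, step)
    best, best_obj = None, np.inf
    for a1 in grid:
        a2s = grid[grid <= 1 - a1 + 1e-12]
        R = y[:, None] - np.outer(X[:, 0], np.full(len(a2s), a1)) - np.outer(X[:, 1], a2s)
        obj = (R ** 2).sum(axis=0)
        j = int(obj.argmin())
        if obj[j] < best_obj:
            best, best_obj = np.array([a1, a2s[j]]), obj[j]
    return best, best_obj


def slsqp_oracle(y, X):
    """Independent constrained solver as a cross-check."""
    J = X.shape[1]
    res = minimize(lambda a: float(((y - X @ a) ** 2).sum()),
                   np.full(J, 1 / (2 * J)), method="SLSQP",
                   bounds=[(0, 1)] * J,
                   constraints=[{"type": "ineq", "fun": lambda a: 1 - a.sum()}],
                   options={"maxiter": 500, "ftol": 1e-14})
    return res.x


class TestQPSolver:
    def test_pure_sample_recovers_unit_vector(self, signature):
        X = signature.means.to_numpy()
        a, diag = deconvolve_sample(X[:, 2], signature)
        expected = np.zeros(7)
        expected[2] = 1.0
        assert np.allclose(a, expected, atol=1e-8)
        assert diag["rss"] == pytest.approx(0.0, abs=1e-14)

    def test_two_component_mixture_recovered(self, signature):
        X = signature.means.to_numpy()
        y = 0.5 * X[:, 1] + 0.3 * X[:, 2]
        a, _ = deconvolve_sample(y, signature)
        expected = np.zeros(7)
        expected[1], expected[2] = 0.5, 0.3
        assert np.allclose(a, expected, atol=1e-6)

    def test_matches_grid_oracle_small_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X = rng.uniform(0, 1, (5, 2))
            y = rng.uniform(0, 1, 5)
            a, resid = solve_fractions(y, X)
            a_grid, obj_grid = grid_oracle(y, X)
            assert np.all(np.abs(a - a_grid) <= 0.002)
            assert float(resid @ resid) <= obj_grid + 1e-12

    def test_matches_slsqp_on_seven_types(self, signature):
        rng = np.random.default_rng(4)
        X = signature.means.to_numpy()
        for _ in range(5):
            y = np.clip(X @ rng.dirichlet(np.ones(7)) * 0.8
                        + rng.normal(0, 0.05, X.shape[0]), 0, 1)
            a, _ = solve_fractions(y, X)
            a_ref = slsqp_oracle(y, X)
            assert np.all(np.abs(a - a_ref) < 1e-4)

    def test_scale_consistency_noiseless(self, signature):
        rng = np.random.default_rng(5)
        X = signature.means.to_numpy()
        for _ in range(5):
            truth = rng.dirichlet(np.ones(7)) * rng.uniform(0.3, 0.95)
            a, _ = solve_fractions(X @ truth, X)
            assert np.all(np.abs(a - truth) < 1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="dimension"):
            solve_fractions(np.ones(4), np.ones((5, 2)))

    def test_rank_deficient_warns_but_solves(self):
        X = np.column_stack([np.linspace(0.1, 0.9, 6)] * 2)  # duplicated column
        y = 0.5 * X[:, 0]
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            a, diag = deconvolve_sample(y, X)
        assert diag["rss"] == pytest.approx(0.0, abs=1e-12)
        assert a.sum() == pytest.approx(0.5, abs=1e-6)


class TestThreshold:
    def test_small_fractions_zeroed(self):
        raw = pd.DataFrame([[0.005, 0.3, 0.009, 0.011]],
                           columns=list("abcd"))
        out = apply_threshold(raw, 0.01)
        assert out.to_numpy().tolist() == [[0.0, 0.3, 0.0, 0.011]]

    def test_zero_threshold_is_identity(self):
        raw = pd.DataFrame(np.random.default_rng(0).uniform(0, 0.3, (4, 7)))
        assert apply_threshold(raw, 0.0).equals(raw)

    def test_idempotent_and_never_increases(self):
        raw = pd.DataFrame(np.random.default_rng(1).uniform(0, 0.2, (10, 7)))
        once = apply_threshold(raw, 0.01)
        twice = apply_threshold(once, 0.01)
        assert once.equals(twice)
        assert (once.to_numpy() <= raw.to_numpy() + 1e-15).all()
        assert (once.sum(axis=1) <= raw.sum(axis=1) + 1e-15).all()


class TestDeconvolveMatrix:
    def test_missing_marker_genes_listed(self, ref_panel, signature):
        panel, _, truth = ref_panel
        beta, _ = generate_mixtures(truth.profiles, 3, seed=0)
        clipped = mi.BetaMatrix(beta.values.drop(index=signature.genes[:2]))
        with pytest.raises(ValidationError) as err:
            deconvolve_matrix(clipped, signature)
        assert signature.genes[0] in str(err.value)

    def test_recovery_error_monotone_in_noise(self, ref_panel, signature):
        profiles = ref_panel[2].profiles
        maes = []
        for sd in (0.0, 0.02, 0.05, 0.1):
            beta, truth = generate_mixtures(profiles, 40, noise_sd=sd,
                                            nonimmune_mass=0.0, seed=17)
            fr = deconvolve_matrix(beta, signature, threshold=0.0)
            maes.append(float((fr.raw - truth.true_fractions).abs().mean().mean()))
        assert all(a <= b + 1e-6 for a, b in zip(maes, maes[1:]))

    def test_reported_matrix_respects_threshold_invariant(self, pipeline_result):
        fr = pipeline_result.fractions
        nonzero = fr.fractions.to_numpy()[fr.fractions.to_numpy() > 0]
        assert nonzero.min() >= fr.threshold


class TestCompareGroups:
    @staticmethod
    def _fraction_matrix(df):
        return mi.FractionMatrix(fractions=df, raw=df,
                                 rss=pd.Series(0.0, index=df.index),
                                 threshold=0.0)

    def test_null_distributions_mostly_nochange(self):
        rng = np.random.default_rng(8)
        df, sheet, _ = make_fraction_cohort(rng, n_tumor=60, n_normal=60)
        gc = compare_groups(self._fraction_matrix(df), sheet)
        rate = (gc.tumor_vs_normal["direction"] != "nochange").mean()
        assert rate <= 0.15  # 7 tests, alpha 0.05 after BH

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(9)
        df, sheet, _ = make_fraction_cohort(rng, n_tumor=100, n_normal=50,
                                            shift_cell_type="CD8", shift=0.15)
        gc = compare_groups(self._fraction_matrix(df), sheet)
        row = gc.tumor_vs_normal.set_index("cell_type").loc["CD8"]
        assert row["direction"] == "increase" and row["q_value"] < 0.05

    def test_cross_cancer_anova_detects_distinct_means(self):
        rng = np.random.default_rng(10)
        frames, sheets = [], []
        for i, ct in enumerate(["CD4", "CD8", "CD56"]):
            df, sheet, _ = make_fraction_cohort(rng, n_tumor=60, n_normal=10,
                                                shift_cell_type=ct, shift=0.15)
            df.index = [f"c{i}_{s}" for s in df.index]
            tab = sheet.table.reset_index(drop=True).copy()
            tab["sample_id"] = [f"c{i}_{s}" for s in tab["sample_id"]]
            tab["cancer_type"] = f"CANC{i}"
            frames.append(df)
            sheets.append(tab)
        frac = self._fraction_matrix(pd.concat(frames))
        sheet = mi.SampleSheet(pd.concat(sheets, ignore_index=True))
        gc = compare_groups(frac, sheet)
        an = gc.across_cancers.set_index("cell_type")
        assert (an.loc[["CD4", "CD8", "CD56"], "q_value"] < 0.05).all()

    def test_small_groups_flagged_skipped(self):
        rng = np.random.default_rng(11)
        df, sheet, _ = make_fraction_cohort(rng, n_tumor=5, n_normal=1)
        gc = compare_groups(self._fraction_matrix(df), sheet)
        assert (gc.tumor_vs_normal["flag"] == "skipped").all()
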