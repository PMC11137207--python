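"""Control-anchored empirical-Bayes co-normalization."""

import numpy as np
import pandas as pd
import pytest

from infantsep import conorm
from infantsep.io import ExpressionMatrix, Group, MergedCohort, SampleMetadata
from infantsep.synth import SynthConfig, generate_cohort


def _cohort_from_blocks(blocks: dict[str, np.ndarray], genes, groups=None):
    """blocks: platform -> genes x samples array."""
    cols, meta = {}, []
    for p, arr in blocks.items():
        for j in range(arr.shape[1]):
            sid = f"{p}_s{j}"
            cols[sid] = arr[:, j]
            grp = Group.HEALTHY_CONTROL if groups is None else groups[p][j]
            meta.append(SampleMetadata(sid, p, p, grp))
    return MergedCohort(ExpressionMatrix(pd.DataFrame(cols, index=genes)), meta)


class TestEstimateParams:
    def test_duplicated_platform_is_near_identity(self, rng):
        base = rng.normal(8, 1.5, size=(30, 100)) + rng.normal(0, 0.4, size=(30, 100))
        cohort = _cohort_from_blocks(
            {"A": base, "B": base.copy()}, [f"g{i}" for i in range(30)]
        )
        params = conorm.estimate_params(cohort)
        assert np.abs(params.gamma_star.to_numpy()).max() < 0.05
        assert np.abs(params.delta_star.to_numpy() - 1.0).max() < 0.05

    def test_recovers_injected_shift_and_scale(self):
        cfg = SynthConfig(
            n_platforms=2, n_controls=50, n_bacteremia=0, n_shock=0, n_genes=300,
            batch_gamma=(0.0, 1.5), batch_delta=(1.0, 2.0), noise_sd=0.3, seed=21,
        )
        cohort, _ = generate_cohort(cfg)
        params = conorm.estimate_params(cohort)
        shift = (
            params.destandardized_shift("PL2") - params.destandardized_shift("PL1")
        ).mean()
        assert abs(shift - 1.5) / 1.5 < 0.10
        # scale: sd ratio between platforms
        sd2 = np.sqrt(params.delta_star.loc["PL2"].to_numpy()).mean()
        sd1 = np.sqrt(params.delta_star.loc["PL1"].to_numpy()).mean()
        assert abs(sd2 / sd1 - 2.0) / 2.0 < 0.15

    def test_fixed_point_matches_grid_substitution_oracle(self, rng):
        # one platform's EB equations solved independently by substitution +
        # dense grid over gamma, on a 3-gene toy
        Z = rng.normal(size=(3, 8)) + np.array([[0.5], [-0.2], [0.1]])
        n = Z.shape[1]
        g_hat = Z.mean(axis=1)
        d_hat = Z.var(axis=1, ddof=1)
        gamma_bar, tau2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        g_star, d_star = conorm._fixed_point(
            Z, g_hat, d_hat, gamma_bar, tau2, a_prior, b_prior, tol=1e-10
        )
        for gi in range(3):
            grid = np.linspace(g_hat[gi] - 2, g_hat[gi] + 2, 40001)
            d_of_g = (0.5 * ((Z[gi] - grid[:, None]) ** 2).sum(axis=1) + b_prior) / (
                n / 2 + a_prior - 1
            )
            resid = np.abs(
                grid
                - (n * tau2 * g_hat[gi] + d_of_g * gamma_bar) / (n * tau2 + d_of_g)
            )
            best = np.argmin(resid)
            assert g_star[gi] == pytest.approx(grid[best], abs=1e-3)
            assert d_star[gi] == pytest.approx(d_of_g[best], abs=1e-3)

    def test_single_control_platform_rejected(self, rng):
        cohort = _cohort_from_blocks(
            {"A": rng.normal(size=(5, 10)), "B": rng.normal(size=(5, 1))},
            [f"g{i}" for i in range(5)],
        )
        with pytest.raises(ValueError, match="platform B"):
            conorm.estimate_params(cohort)

    def test_zero_variance_gene_passes_through(self, rng):
        a = rng.normal(size=(3, 10))
        b = rng.normal(size=(3, 10)) + 1.0
        a[0] = 5.0
        b[0] = 5.0
        cohort = _cohort_from_blocks({"A": a, "B": b}, ["flat", "g1", "g2"])
        params = conorm.estimate_params(cohort)
        assert params.unadjusted_genes == ["flat"]
        post = conorm.apply(cohort, params)
        np.testing.assert_array_equal(
            post.expr.values.loc["flat"].to_numpy(),
            cohort.expr.values.loc["flat"].to_numpy(),
        )

    def test_cases_do_not_influence_estimation(self, default_cohort):
        cohort, _ = default_cohort
        params = conorm.estimate_params(cohort)
        # drop all case samples
        ctrl = cohort.control_ids()
        sub = MergedCohort(
            ExpressionMatrix(cohort.expr.values[ctrl], "log2"),
            [m for m in cohort.meta if m.is_control],
        )
        params2 = conorm.estimate_params(sub)
        np.testing.assert_array_equal(
            params.gamma_star.to_numpy(), params2.gamma_star.to_numpy()
        )
        np.testing.assert_array_equal(
            params.delta_star.to_numpy(), params2.delta_star.to_numpy()
        )


class TestApply:
    def test_zero_shift_params_are_identity(self, rng):
        cohort = _cohort_from_blocks(
            {"A": rng.normal(size=(10, 6)), "B": rng.normal(size=(10, 6))},
            [f"g{i}" for i in range(10)],
        )
        params = conorm.estimate_params(cohort)
        params.gamma_star.iloc[:, :] = 0.0
        params.delta_star.iloc[:, :] = 1.0
        post = conorm.apply(cohort, params)
        np.testing.assert_allclose(
            post.expr.values.to_numpy(), cohort.expr.values.to_numpy(), atol=1e-12
        )

    def test_missing_platform_rejected(self, rng):
        cohort = _cohort_from_blocks(
            {"A": rng.normal(size=(4, 5)), "B": rng.normal(size=(4, 5))},
            [f"g{i}" for i in range(4)],
        )
        params = conorm.estimate_params(cohort)
        params.gamma_star = params.gamma_star.drop(index="B")
        with pytest.raises(ValueError, match="absent"):
            conorm.apply(cohort, params)

    def test_control_means_harmonized_within_2sem(self, conormalized):
        cohort, _, params, post = conormalized
        ctrl = set(cohort.control_ids())
        grand = post.expr.values[list(ctrl)].mean(axis=1)
        for p in params.platforms:
            ids = [s for s in cohort.sample_ids_of_platform(p) if s in ctrl]
            block = post.expr.values[ids]
            sem = block.std(axis=1, ddof=1) / np.sqrt(len(ids))
            frac_within = ((block.mean(axis=1) - grand).abs() <= 2 * sem).mean()
            assert frac_within > 0.9

    def test_contrast_preserved_on_unit_scale_platform(self, conormalized):
        cohort, _, params, post = conormalized
        meta = cohort.meta_by_id
        ids = cohort.sample_ids_of_platform("PL1")  # delta = 1 platform
        c = [s for s in ids if meta[s].is_control]
        k = [s for s in ids if not meta[s].is_control]
        pre = (cohort.expr.values[k].mean(axis=1) - cohort.expr.values[c].mean(axis=1))
        po = (post.expr.values[k].mean(axis=1) - post.expr.values[c].mean(axis=1))
        assert np.corrcoef(pre, po)[0, 1] >= 0.99

    def test_monotone_within_platform_gene(self, conormalized):
        cohort, _, params, post = conormalized
        ids = cohort.sample_ids_of_platform("PL2")
        pre = cohort.expr.values.loc[cohort.expr.gene_ids[13], ids].to_numpy()
        po = post.expr.values.loc[cohort.expr.gene_ids[13], ids].to_numpy()
        np.testing.assert_array_equal(np.argsort(pre), np.argsort(po))

    def test_idempotent_after_one_pass(self):
        # tolerance 0.05 holds at 100 controls per platform
        cfg = SynthConfig(
            n_platforms=3, n_controls=100, n_bacteremia=10, n_shock=5, n_genes=400,
            batch_gamma=(0.0, 1.5, -1.0), batch_delta=(1.0, 2.0, 0.7),
            noise_sd=0.3, seed=33,
        )
        cohort, _ = generate_cohort(cfg)
        post = conorm.apply(cohort, conorm.estimate_params(cohort))
        params2 = conorm.estimate_params(post)
        assert np.abs(params2.gamma_star.to_numpy()).max() < 0.05
        assert np.abs(params2.delta_star.to_numpy() - 1.0).max() < 0.05


class TestValidate:
    def test_identity_report(self, default_cohort):
        cohort, truth = default_cohort
        hk = list(truth.housekeeping_genes[:2])
        mk = [truth.modules["hemostasis_up"].genes[0], truth.modules["tcell_down"].genes[0]]
        rep = conorm.validate(cohort, cohort, hk, mk)
        assert rep.pearson_r_pre_post == pytest.approx(1.0)
        ratios = (
            rep.housekeeping["control_variance_post"]
            / rep.housekeeping["control_variance_pre"]
        )
        np.testing.assert_allclose(ratios.to_numpy(), 1.0)

    def test_housekeeping_variance_drops_markers_stay(self, conormalized):
        cohort, truth, _, post = conormalized
        hk = list(truth.housekeeping_genes)
        mk = [truth.modules["hemostasis_up"].genes[0], truth.modules["tcell_down"].genes[0]]
        rep = conorm.validate(cohort, post, hk, mk)
        assert (
            rep.housekeeping["control_variance_post"]
            < rep.housekeeping["control_variance_pre"]
        ).all()
        assert (rep.markers["p_post"] < 0.05).all()
        assert (rep.ecdf_distance["ks_post"] <= rep.ecdf_distance["ks_pre"]).all()

    def test_missing_panel_gene_warns_and_skips(self, default_cohort):
        cohort, truth = default_cohort
        with pytest.warns(UserWarning, match="NOPE"):
            rep = conorm.validate(
                cohort, cohort, ["NOPE", truth.housekeeping_genes[0]],
                [truth.modules["hemostasis_up"].genes[0]],
            )
        assert rep.skipped_panel_genes == ["NOPE"]
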