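"""Behaviour of the hierarchical allometric regression machinery."""

import numpy as np
import pandas as pd
import pytest

import forceallometry as fa
from _helpers import point_fit
from forceallometry.allometry import batch_mcse, split_rhat


class TestLogCenter:
    def test_equal_to_scale_gives_zero(self):
        assert np.allclose(fa.log_center([7.0, 7.0, 7.0], 7.0), 0.0)

    def test_exact_logs(self):
        assert np.allclose(fa.log_center([1.0, 10.0, 100.0], 10.0),
                           [-1.0, 0.0, 1.0])

    def test_geometric_mean_centres_exactly(self):
        v = np.array([0.3, 2.0, 11.0, 0.07])
        out = fa.log_center(v, "geometric_mean")
        assert out.mean() == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_rejected_with_position(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            fa.log_center([1.0, -2.0, 3.0])


class TestPhyloCovariance:
    def test_lambda_zero_is_identity(self, five_tip_tree):
        c = fa.phylo_covariance(five_tip_tree, 0.0)
        assert np.allclose(c, np.eye(5))

    def test_sister_tips_share_half_path(self, three_tip_pair):
        t1, _ = three_tip_pair   # ((A:1,B:1):1,C:2)
        c = fa.phylo_covariance(t1, 1.0, species=["A", "B", "C"])
        assert c[0, 1] == pytest.approx(0.5)
        assert c[0, 2] == pytest.approx(0.0)
        assert np.allclose(np.diag(c), 1.0)

    @pytest.mark.parametrize("lam", [0.0, 0.25, 0.5, 0.9, 1.0])
    def test_positive_definite(self, five_tip_tree, lam):
        c = fa.phylo_covariance(five_tip_tree, lam)
        assert np.all(np.linalg.eigvalsh(c) > 0)
        assert np.allclose(c, c.T)

    def test_unmapped_species_listed(self, five_tip_tree):
        with pytest.raises(ValueError, match="Zeta"):
            fa.phylo_covariance(five_tip_tree, 0.5, species=["A", "Zeta"])


class TestSummaries:
    def test_quantile_rule_on_integer_draws(self):
        draws = np.arange(1.0, 101.0)
        fit = point_fit(draws)
        s = fa.summarize_fit(fit)
        assert s.loc["b", "mean"] == pytest.approx(50.5)
        assert s.loc["b", "ci_low"] == pytest.approx(3.475)
        assert s.loc["b", "ci_high"] == pytest.approx(97.525)

    def test_degenerate_draws(self):
        fit = point_fit(np.full(200, 2.5))
        lo, hi = fit.slope_ci
        assert lo == hi == 2.5

    def test_reference_overlap_flag(self):
        fit = point_fit(np.linspace(0.4, 0.6, 500))
        s = fa.summarize_fit(fit, references=(0.0, 0.5, 1.0))
        assert not s.loc["b", "overlaps_0"]
        assert s.loc["b", "overlaps_0.5"]
        assert not s.loc["b", "overlaps_1"]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            fa.summarize_fit(point_fit(np.ones(50)))

    def test_split_rhat_detects_disagreement(self):
        rng = np.random.default_rng(0)
        same = rng.standard_normal((4, 500))
        apart = same + np.array([[0.0], [0.0], [5.0], [5.0]])
        assert split_rhat(same) < 1.05
        assert split_rhat(apart) > 1.5




@pytest.fixture(scope="module")
def small_tree_ensemble(request):
    import dendropy
    tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1.5,D:1.5):0.5,E:2);",
                             schema="newick", rooting="default-rooted")
    return fa.TreeEnsemble([tree])


class TestInterspecificFit:
    def test_exact_linear_data_recovers_slope(self, small_tree_ensemble):
        rng = np.random.default_rng(1)
        sp = np.array(["A", "B", "C", "D", "E"])
        x = 10 ** rng.normal(0, 0.4, 5)
        y = x ** 2.0
        cfg = fa.AllometryConfig(n_chains=2, n_iter=3000, burn_in=1500,
                                 fix_within_cov=np.eye(2) * 1e-8, seed=3)
        fit = fa.fit_interspecific(x, y, sp, small_tree_ensemble, cfg)
        assert fit.slope_mean == pytest.approx(2.0, abs=3 * max(
            fit.mcse(), 1e-3))

    @pytest.mark.parametrize("lam", [0.0, 1.0])
    def test_fixed_lambda_limits_match_matrix_oracles(
            self, small_tree_ensemble, lam):
        """lambda=0 reduces to OLS, lambda=1 to phylogenetic GLS."""
        rng = np.random.default_rng(0)
        sp = np.array(["A", "B", "C", "D", "E"])
        x = 10 ** rng.normal(0, 0.4, 5)
        y = 10 ** (0.7 * np.log10(x) + rng.normal(0, 0.08, 5))
        lx = np.log10(x) - np.log10(x).mean()
        ly = np.log10(y) - np.log10(y).mean()
        X = np.column_stack([np.ones(5), lx])
        if lam == 0.0:
            oracle = np.linalg.lstsq(X, ly, rcond=None)[0][1]
        else:
            si = np.linalg.inv(fa.phylo_covariance(
                small_tree_ensemble.trees[0], 1.0, species=sp))
            oracle = np.linalg.solve(X.T @ si @ X, X.T @ si @ ly)[1]
        cfg = fa.AllometryConfig(seed=2, fix_lambda=lam,
                                 fix_within_cov=np.eye(2) * 1e-6,
                                 n_iter=4000, burn_in=2000)
        fit = fa.fit_interspecific(x, y, sp, small_tree_ensemble, cfg)
        assert abs(fit.slope_mean - oracle) < 2 * fit.mcse()

    def test_needs_three_species(self, small_tree_ensemble, fast_config):
        with pytest.raises(ValueError, match="3 species"):
            fa.fit_interspecific([1, 2], [1, 2], ["A", "B"],
                                 small_tree_ensemble, fast_config)

    def test_permutation_invariance(self, among_dataset, fast_config):
        ds, d = among_dataset
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(d))
        f1 = fa.fit_interspecific(d["weight"], d["wing_area_S"],
                                  d["species"], ds.trees, fast_config)
        f2 = fa.fit_interspecific(d["weight"].iloc[perm].to_numpy(),
                                  d["wing_area_S"].iloc[perm].to_numpy(),
                                  d["species"].iloc[perm].to_numpy(),
                                  ds.trees, fast_config)
        tol = 4 * max(f1.mcse(), f2.mcse())
        assert abs(f1.slope_mean - f2.slope_mean) < tol

    def test_tree_assignment_modes_agree(self, among_dataset):
        """Per-draw vs per-chain tree sampling shift the posterior little."""
        ds, d = among_dataset
        fits = {}
        for mode in ("draw", "chain"):
            cfg = fa.AllometryConfig(n_chains=4, n_iter=2000, burn_in=1000,
                                     tree_assignment=mode, seed=6)
            fits[mode] = fa.fit_interspecific(
                d["weight"], d["wing_area_S"], d["species"], ds.trees, cfg)
        tol = 4 * max(fits["draw"].mcse(), fits["chain"].mcse())
        assert abs(fits["draw"].slope_mean
                   - fits["chain"].slope_mean) < max(tol, 0.02)

    def test_measurement_error_attenuation_is_corrected(self):
        """x-noise attenuates naive OLS but not the latent-mean model."""
        rng = np.random.default_rng(8)
        cfg_gen = fa.GeneratorConfig(n_species=30, n_trees=1, seed=8,
                                     branch_jitter_sd=0.0,
                                     measurement_noise=0.0)
        ds = fa.simulate_records(cfg_gen)
        d = fa.derive_table(ds.records)
        x = d["weight"].to_numpy()
        y = d["wing_area_S"].to_numpy()
        # inject hefty x measurement noise (sd 20% of value)
        x_noisy = x * np.clip(1 + 0.2 * rng.standard_normal(len(x)), 0.2, None)
        sp = d["species"].to_numpy()
        # naive per-individual OLS attenuates
        b_naive = np.polyfit(np.log10(x_noisy), np.log10(y), 1)[0]
        cfg = fa.AllometryConfig(n_chains=2, n_iter=3000, burn_in=1500, seed=9)
        fit = fa.fit_interspecific(x_noisy, y, sp, ds.trees, cfg)
        assert b_naive < 0.95 * 1.01
        assert abs(fit.slope_mean - 1.01) < abs(b_naive - 1.01)


class TestIntraspecificFit:
    def test_centring_removes_species_offsets(self, fast_config):
        x = np.concatenate([10 ** np.linspace(0, 1, 6),
                            10 ** np.linspace(2, 3, 6)])
        y = np.concatenate([3.0 * (10 ** np.linspace(0, 1, 6)) ** 0.5,
                            50.0 * (10 ** np.linspace(2, 3, 6)) ** 0.5])
        sp = np.array(["u"] * 6 + ["v"] * 6)
        fit = fa.fit_intraspecific(x, y, sp, fast_config)
        assert fit.slope_mean == pytest.approx(0.5, abs=1e-3)

    def test_matches_centred_ols(self, within_dataset, fast_config):
        ds, d = within_dataset
        lx = np.log10(d["weight"])
        ly = np.log10(d["wing_area_S"])
        frame = pd.DataFrame(dict(sp=d["species"], x=lx, y=ly))
        cx = frame.groupby("sp")["x"].transform(lambda v: v - v.mean())
        cy = frame.groupby("sp")["y"].transform(lambda v: v - v.mean())
        oracle = np.polyfit(cx, cy, 1)[0]
        fit = fa.fit_intraspecific(d["weight"], d["wing_area_S"],
                                   d["species"], fast_config)
        assert abs(fit.slope_mean - oracle) < 2 * fit.mcse()

    def test_singletons_rejected_when_nothing_usable(self, fast_config):
        with pytest.raises(ValueError, match=">= 2 individuals"):
            fa.fit_intraspecific([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                 ["a", "b", "c"], fast_config)

    def test_calibration_coverage(self):
        """CIs cover the generating within-species exponent in most runs."""
        cfg = fa.AllometryConfig(n_chains=2, n_iter=2000, burn_in=1000, seed=0)
        hits = 0
        n_rep = 12
        for rep in range(n_rep):
            ds = fa.simulate_records(fa.make_preset("within", seed=300 + rep))
            d = fa.derive_table(ds.records)
            fit = fa.fit_intraspecific(d["weight"], d["wing_area_S"],
                                       d["species"], cfg)
            lo, hi = fit.slope_ci
            hits += lo <= 0.42 <= hi
        assert hits >= int(0.75 * n_rep)


class TestCladeFit:
    def test_divergent_clade_detected(self, small_tree_ensemble):
        """A clade generated with slope 0.4 excludes the global value 1.0."""
        rng = np.random.default_rng(3)
        species = [f"s{i}" for i in range(8)]
        clades = ["low"] * 4 + ["high"] * 4
        rows_x, rows_y, rows_sp, rows_cl = [], [], [], []
        for sp, cl in zip(species, clades):
            slope = 0.4 if cl == "low" else 1.0
            lx = rng.uniform(-0.5, 0.5)
            for _ in range(5):
                xi = lx + rng.normal(0, 0.02)
                yi = slope * xi + rng.normal(0, 0.01)
                rows_x.append(10 ** xi)
                rows_y.append(10 ** yi)
                rows_sp.append(sp)
                rows_cl.append(cl)
        cfg = fa.AllometryConfig(n_chains=2, n_iter=3000, burn_in=1500, seed=2)
        fits = fa.fit_clade(rows_x, rows_y, rows_sp, rows_cl, trees=None,
                            config=cfg, slope_prior_mean=1.0, reference=1.0)
        lo, hi = fits["low"].slope_ci
        assert hi < 1.0
        assert fits["low"].diagnostics["excludes_reference"]
        lo, hi = fits["high"].slope_ci
        assert lo <= 1.0 <= hi

    def test_small_clades_skipped(self, fast_config):
        x = [1.0, 2.0, 4.0, 1.0, 2.0, 4.0]
        sp = ["a", "b", "c", "a", "b", "c"]
        clades = ["big"] * 6
        fits = fa.fit_clade(x, x, sp, ["tiny"] + clades[1:], config=fast_config)
        assert "tiny" not in fits


def test_batch_mcse_scales_with_sample_size():
    rng = np.random.default_rng(0)
    small = batch_mcse(rng.standard_normal(400))
    large = batch_mcse(rng.standard_normal(40000))
    assert large < small
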