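"""Covariate balancing: binning, matching, iterative refinement."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from connectoscramble import balancing


def make_table(**columns):
    n = len(next(iter(columns.values())))
    base = {"subject_id": [f"s{i}" for i in range(n)]}
    base.update(columns)
    return pd.DataFrame(base)


class TestDiscretize:
    def test_equal_width_split(self):
        table = make_table(sex=[0, 0, 1, 1], icv=[0.0, 1.0, 2.0, 3.0])
        scheme = balancing.BinningScheme.fit(table, ["icv"], [2])
        assert np.allclose(scheme.edges[0], [0.0, 1.5, 3.0])
        assert balancing.discretize(table, scheme)[:, 0].tolist() == [0, 0, 1, 1]

    def test_constant_covariate_single_bin(self):
        table = make_table(sex=[0, 1, 0], icv=[10.0, 10.0, 10.0])
        scheme = balancing.BinningScheme.fit(table, ["icv"], [5])
        assert balancing.discretize(table, scheme)[:, 0].tolist() == [0, 0, 0]

    def test_multivariate_bin_product(self):
        table = make_table(sex=[0, 1], a=[0.0, 1.0], b=[0.0, 1.0])
        scheme = balancing.BinningScheme.fit(table, ["a", "b"], [2, 3])
        bins = balancing.discretize(table, scheme)
        assert bins.shape == (2, 2)
        # 2 x 3 = 6 possible multivariate bins
        assert scheme.bin_counts == (2, 3)

    def test_maximum_falls_in_top_bin(self):
        table = make_table(sex=[0, 1], x=[0.0, 10.0])
        scheme = balancing.BinningScheme.fit(table, ["x"], [4])
        assert balancing.discretize(table, scheme)[1, 0] == 3


class TestMatching:
    def test_hand_run_of_matching_rule(self):
        # class A ICV {10,10,20}, class B {10,20,20}, 2 bins
        # -> bin 10: 1 of each; bin 20: 1 of each; 2 retained per class
        table = make_table(sex=[0, 0, 0, 1, 1, 1],
                           icv=[10.0, 10.0, 20.0, 10.0, 20.0, 20.0])
        scheme = balancing.BinningScheme.fit(table, ["icv"], [2])
        cfg = balancing.BalanceConfig(covariates=("icv",), seed=0)
        kept = balancing.match_within_bins(table, scheme, cfg, "sex")
        sub = table.loc[kept]
        assert len(sub) == 4
        assert (sub["sex"] == 0).sum() == 2
        assert (sub["sex"] == 1).sum() == 2
        for icv_val in (10.0, 20.0):
            cell = sub[sub["icv"] == icv_val]
            assert (cell["sex"] == 0).sum() == (cell["sex"] == 1).sum() == 1

    def test_identical_multisets_fully_retained(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        table = make_table(sex=[0] * 4 + [1] * 4, icv=vals + vals)
        scheme = balancing.BinningScheme.fit(table, ["icv"], [4])
        cfg = balancing.BalanceConfig(covariates=("icv",), seed=1)
        kept = balancing.match_within_bins(table, scheme, cfg, "sex")
        assert len(kept) == 8

    def test_disjoint_supports_empty(self):
        table = make_table(sex=[0, 0, 1, 1], icv=[1.0, 2.0, 9.0, 10.0])
        scheme = balancing.BinningScheme.fit(table, ["icv"], [4])
        cfg = balancing.BalanceConfig(covariates=("icv",), seed=0)
        assert len(balancing.match_within_bins(table, scheme, cfg, "sex")) == 0


class TestBalance:
    def test_identical_distributions_pass_at_one_bin(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 100)
        table = make_table(sex=np.repeat([0, 1], 100),
                           icv=np.concatenate([vals, vals]))
        cfg = balancing.BalanceConfig(covariates=("icv",), seed=0)
        kept, cert = balancing.balance(table, cfg)
        assert cert.success
        assert cert.bin_counts == {"icv": 1}
        assert cert.p_values["icv"] > 0.95

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_forced_ratio_exact_for_any_seed(self, seed, confounded_phenotypes):
        cfg = balancing.BalanceConfig(seed=seed)
        kept, cert = balancing.balance(confounded_phenotypes, cfg, "sex")
        sub = confounded_phenotypes.loc[kept]
        assert cert.success
        assert (sub["sex"] == 0).sum() == (sub["sex"] == 1).sum()
        # retained set is a subset, no duplicates
        assert kept.is_unique
        assert kept.isin(confounded_phenotypes.index).all()

    def test_certificate_pvalues_recompute_independently(self, confounded_phenotypes):
        cfg = balancing.BalanceConfig(seed=3)
        kept, cert = balancing.balance(confounded_phenotypes, cfg, "sex")
        sub = confounded_phenotypes.loc[kept]
        for cov, reported in cert.p_values.items():
            a = sub[sub["sex"] == 0][cov]
            b = sub[sub["sex"] == 1][cov]
            independent = mannwhitneyu(a, b, alternative="two-sided").pvalue
            assert reported == pytest.approx(independent, rel=1e-9)
            assert reported > cfg.p_threshold

    def test_one_class_empty_fails(self):
        table = make_table(sex=[0, 0, 0], icv=[1.0, 2.0, 3.0])
        cfg = balancing.BalanceConfig(covariates=("icv",))
        kept, cert = balancing.balance(table, cfg)
        assert not cert.success
        assert len(kept) == 0

    def test_unbalanceable_cohort_reports_failure(self):
        # disjoint ICV supports can never be matched
        table = make_table(sex=np.repeat([0, 1], 50),
                           icv=np.concatenate([np.linspace(0, 1, 50),
                                               np.linspace(10, 11, 50)]))
        cfg = balancing.BalanceConfig(covariates=("icv",),
                                      max_bins_per_covariate=8)
        kept, cert = balancing.balance(table, cfg)
        assert not cert.success
        assert "icv" in cert.failing_covariates or len(kept) == 0

    def test_bin_refinement_shrinks_span(self, confounded_phenotypes):
        # doubling bins never increases within-bin covariate span
        for k in (1, 2, 4, 8):
            scheme = balancing.BinningScheme.fit(
                confounded_phenotypes, ["icv"], [k])
            widths = np.diff(scheme.edges[0])
            if k > 1:
                assert widths.max() <= prev_max + 1e-9
            prev_max = widths.max()


class TestTwoFactor:
    def test_four_divisions_all_balanced(self, confounded_phenotypes):
        cfg = balancing.BalanceConfig(seed=5)
        kept, certs = balancing.balance_two_factor(confounded_phenotypes, cfg)
        assert certs["sex"].success and certs["condition"].success
        sub = confounded_phenotypes.loc[kept]
        # all 5 covariates x both factors pass independently recomputed tests
        for factor in ("sex", "condition"):
            for cov in cfg.covariates:
                a = sub[sub[factor] == 0][cov]
                b = sub[sub[factor] == 1][cov]
                assert mannwhitneyu(a, b, alternative="two-sided").pvalue > 0.10

    def test_stage_one_ratio_approximately_preserved(self, confounded_phenotypes):
        cfg = balancing.BalanceConfig(seed=5)
        kept, _ = balancing.balance_two_factor(confounded_phenotypes, cfg)
        sub = confounded_phenotypes.loc[kept]
        counts = sub["sex"].value_counts()
        assert abs(counts[0] - counts[1]) / counts.sum() < 0.05
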