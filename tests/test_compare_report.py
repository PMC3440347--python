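import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cytoquant as cq
from cytoquant.errors import ValidationError
from tests.conftest import make_noiseless_scenario


def _permutation_p(a, b):
    """Exact two-sided permutation test on the difference of means."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), len(a)):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        diff = abs(pooled[mask].mean() - pooled[~mask].mean())
        count += diff >= observed - 1e-12
        total += 1
    return count / total


class TestAnovaTukey:
    def test_identical_groups_not_significant(self):
        res = cq.anova_tukey({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert all(not p.significant for p in res.pairwise)

    def test_separated_groups_all_significant(self):
        res = cq.anova_tukey({"lo": [0.0, 0.1, -0.1], "hi": [100.0, 100.1, 99.9]})
        assert res.anova_p < 1e-6
        assert all(p.significant for p in res.pairwise)
        assert res.pairwise[0].mean_difference == pytest.approx(-100.0)

    def test_classification_agrees_with_permutation_oracle(self, rng):
        groups = {"a": rng.normal(0, 1, 5), "b": rng.normal(0.2, 1, 5),
                  "c": rng.normal(10, 1, 5)}
        res = cq.anova_tukey(groups, alpha=0.05)
        for pc in res.pairwise:
            p_perm = _permutation_p(groups[pc.pair[0]], groups[pc.pair[1]])
            # both tests must classify clear-cut pairs identically
            if p_perm <= 0.01:
                assert pc.significant
            if p_perm > 0.2:
                assert not pc.significant

    def test_tukey_adjustment_is_conservative(self):
        # adjusted p >= the unadjusted pairwise p computed from the same
        # pooled error variance (Fisher LSD), over random instances
        for seed in range(10):
            r = np.random.default_rng(seed)
            groups = {k: r.normal(r.uniform(0, 2), 1, 6) for k in "abc"}
            arrays = list(groups.values())
            df = sum(len(a) - 1 for a in arrays)
            mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
            res = cq.anova_tukey(groups)
            for pc in res.pairwise:
                a, b = (groups[k] for k in pc.pair)
                t = abs(a.mean() - b.mean()) / np.sqrt(mse * (1 / len(a) + 1 / len(b)))
                lsd_p = 2 * stats.t.sf(t, df)
                assert pc.adjusted_p >= lsd_p - 1e-12

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            cq.anova_tukey({"a": [1.0], "b": [1.0, 2.0]})

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            cq.anova_tukey({"a": [1.0, 2.0]})


class TestRunScenario:
    def test_deterministic_under_fixed_seed(self):
        cfg = make_noiseless_scenario(n_cells=300)
        a, b = cq.run_scenario(cfg), cq.run_scenario(cfg)
        assert a.ensemble == b.ensemble
        assert a.summary == b.summary
        np.testing.assert_array_equal(a.pooled.values, b.pooled.values)

    def test_seed_changes_output(self):
        a = cq.run_scenario(make_noiseless_scenario(n_cells=300, seed=1))
        b = cq.run_scenario(make_noiseless_scenario(n_cells=300, seed=2))
        assert a.ensemble.mean != b.ensemble.mean

    def test_noiseless_ensemble_mean_equals_drawn_sample_mean(self):
        cfg = make_noiseless_scenario(n_cells=400, autofluor_pe=300.0, gain=2.0,
                                      n_replicates=2)
        noop = cq.PipelineConfig(scatter_gate=(0.0, np.inf, 0.0, np.inf),
                                 fl1_rule="fixed", fl1_threshold=0.0)
        res = cq.run_scenario(cfg, noop)
        # with all noise off, recovered counts are the drawn counts, so the
        # replicate means are exactly the means of the drawn samples
        for rep, sample in enumerate(res.samples):
            seeds = np.random.SeedSequence([cfg.seed, rep]).spawn(3)
            truth = cq.generate_cell_events(cfg, labeled=True,
                                            seed=np.random.default_rng(seeds[1]))
            assert sample.per_cell.mean() == pytest.approx(
                truth.data["true_receptors"].mean(), rel=1e-9)

    def test_gating_report_covers_all_replicates(self, small_scenario):
        res = cq.run_scenario(small_scenario)
        assert len(res.gating_report) == small_scenario.n_replicates
        assert (res.gating_report["fl1_positive"] <= res.gating_report["singlets"]).all()


class TestBuildReport:
    def test_single_condition_single_row(self):
        res = cq.run_scenario(make_noiseless_scenario(n_cells=300))
        table = cq.build_report([res])
        assert len(table) == 1
        assert list(table.columns) == ["condition", "n", "mean", "sem", "n_cells",
                                       "median", "cv_percent", "skewness", "kurtosis"]

    def test_rows_mirror_published_table_structure(self):
        results = [cq.run_scenario(cq.load_scenario(name, n_cells=800, n_replicates=2))
                   for name in ("c57bl6_gastrocnemius_vegfr1",
                                "c57bl6_gastrocnemius_vegfr2")]
        table = cq.build_report(results)
        assert len(table) == 2
        assert (table["mean"] % 100 == 0).all()  # report-layer rounding

    def test_report_regeneration_is_identical(self):
        res = cq.run_scenario(make_noiseless_scenario(n_cells=300))
        pd.testing.assert_frame_equal(cq.build_report([res]), cq.build_report([res]))

    def test_histogram_frame_matches_summary(self):
        res = cq.run_scenario(make_noiseless_scenario(n_cells=300))
        hf = cq.histogram_frame(res.summary)
        assert hf["count"].sum() == res.summary.n_cells
        assert (hf["bin_hi"] - hf["bin_lo"] == 500.0).all()
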