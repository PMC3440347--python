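import numpy as np
import pandas as pd
import pytest

import cytoquant as cq
from cytoquant.errors import CalibrationInputError, ConfigurationError, ValidationError


class TestScatterGate:
    def test_full_range_gate_is_identity(self, event_table):
        gate = cq.ScatterGate()
        out = cq.gate_singlets(event_table, gate)
        assert len(out) == len(event_table)
        pd.testing.assert_frame_equal(out.data, event_table.data)

    def test_empty_table_passes_through_empty(self):
        t = cq.EventTable(pd.DataFrame({c: [] for c in ("fsc", "ssc", "fl1", "fl2")}))
        assert len(cq.gate_singlets(t, cq.ScatterGate())) == 0

    @pytest.mark.parametrize("kwargs", [
        {"fsc_min": 5, "fsc_max": 5},
        {"ssc_min": 10, "ssc_max": 2},
        {"polygon": ((0, 0), (1, 1), (2, 2))},
    ])
    def test_degenerate_gate_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            cq.ScatterGate(**kwargs)

    def test_polygon_gate_contains(self):
        gate = cq.ScatterGate(polygon=((0, 0), (10, 0), (10, 10), (0, 10)))
        inside = gate.contains(np.array([5.0, 15.0]), np.array([5.0, 5.0]))
        assert inside.tolist() == [True, False]

    def test_auto_gate_retains_singlet_cells(self, small_scenario):
        t = cq.generate_cell_events(small_scenario, labeled=True, seed=1)
        gate = cq.fit_scatter_gate(t)
        kept = cq.gate_singlets(t, gate)
        labels = kept.data["population_label"]
        assert labels.isin(["target", "contaminant"]).mean() >= 0.95

    def test_gating_is_pure_filter(self, small_scenario):
        t = cq.generate_cell_events(small_scenario, labeled=True, seed=2)
        kept = cq.gate_singlets(t, cq.fit_scatter_gate(t))
        # output rows are a subset of input rows, order preserved, unmodified
        merged = t.data.merge(kept.data, how="inner")
        assert len(merged) == len(kept)


class TestFl1Gate:
    def test_zero_fixed_threshold_keeps_positive_fl1(self, event_table):
        out = cq.gate_fl1_positive(event_table, cq.Fl1Threshold(rule="fixed", threshold=0.0))
        assert len(out) == (event_table.channel("fl1") > 0).sum()

    def test_quantile_rule_requires_reference(self, event_table):
        with pytest.raises(ConfigurationError):
            cq.gate_fl1_positive(event_table, cq.Fl1Threshold())

    def test_quantile_rule_selects_true_targets(self, small_scenario):
        labeled = cq.generate_cell_events(small_scenario, labeled=True, seed=3)
        unlabeled = cq.generate_cell_events(small_scenario, labeled=False, seed=4)
        gate = cq.fit_scatter_gate(labeled)
        cells = cq.gate_singlets(labeled, gate)
        ref = cq.gate_singlets(unlabeled, gate)
        out = cq.gate_fl1_positive(cells, cq.Fl1Threshold(), unlabeled_reference=ref)
        assert (out.data["population_label"] == "target").mean() >= 0.99
        assert out.metadata["fl1_threshold_resolved"] > 0

    def test_pre_enrichment_retained_fraction_five_percent(self):
        cfg = cq.pre_enrichment_scenario(n_cells=40000, seed=12)
        labeled = cq.generate_cell_events(cfg, labeled=True, seed=12)
        unlabeled = cq.generate_cell_events(cfg, labeled=False, seed=13)
        gate = cq.fit_scatter_gate(labeled)
        cells = cq.gate_singlets(labeled, gate)
        ref = cq.gate_singlets(unlabeled, gate)
        out = cq.gate_fl1_positive(cells, cq.Fl1Threshold(), unlabeled_reference=ref)
        assert len(out) / len(labeled) == pytest.approx(0.05, abs=0.015)

    def test_composition_order_equals_intersection(self, small_scenario):
        t = cq.generate_cell_events(small_scenario, labeled=True, seed=5)
        gate = cq.fit_scatter_gate(t)
        thr = cq.Fl1Threshold(rule="fixed", threshold=50.0)
        a = cq.gate_fl1_positive(cq.gate_singlets(t, gate), thr)
        mask = gate.contains(t.channel("fsc"), t.channel("ssc")) & (t.channel("fl1") > 50.0)
        b = t.subset(mask)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestBeadLevelIdentification:
    def test_noiseless_spikes_assigned_exactly(self, noiseless_scenario):
        beads = cq.generate_bead_events(noiseless_scenario, seed=1)
        by_level = cq.identify_bead_levels(beads, cq.BeadLevelSet())
        for k, level in enumerate(cq.QUANTIBRITE_PE_LEVELS):
            labels = by_level[level].data["population_label"]
            assert (labels == f"bead_level_{k}").all()

    def test_noisy_assignment_accuracy(self):
        from cytoquant.synthetic_cytometry import BeadConfig

        cfg = cq.ScenarioConfig(bead=BeadConfig(n_per_level=10_000, noise_cv=0.05))
        beads = cq.generate_bead_events(cfg, seed=2)
        by_level = cq.identify_bead_levels(beads, cq.BeadLevelSet())
        correct = total = 0
        for k, level in enumerate(cq.QUANTIBRITE_PE_LEVELS):
            labels = by_level[level].data["population_label"]
            correct += (labels == f"bead_level_{k}").sum()
            total += len(labels)
        assert correct / total >= 0.999

    def test_fewer_events_than_levels_rejected(self):
        t = cq.EventTable(pd.DataFrame({
            "fsc": [1.0] * 3, "ssc": [1.0] * 3, "fl1": [1.0] * 3,
            "fl2": [10.0, 100.0, 1000.0]}))
        with pytest.raises(CalibrationInputError):
            cq.identify_bead_levels(t, cq.BeadLevelSet())

    def test_overlapping_clusters_rejected(self, rng):
        # two barely separated smears cannot support four levels
        fl2 = np.exp(rng.normal(5.0, 1.0, 2000))
        t = cq.EventTable(pd.DataFrame({"fsc": np.ones(2000), "ssc": np.ones(2000),
                                        "fl1": np.ones(2000), "fl2": fl2}))
        with pytest.raises(CalibrationInputError):
            cq.identify_bead_levels(t, cq.BeadLevelSet())

    def test_assignment_monotone_in_fl2(self):
        from cytoquant.synthetic_cytometry import BeadConfig

        cfg = cq.ScenarioConfig(bead=BeadConfig(n_per_level=500, noise_cv=0.05))
        beads = cq.generate_bead_events(cfg, seed=3)
        by_level = cq.identify_bead_levels(beads, cq.BeadLevelSet())
        maxima = [by_level[lv].channel("fl2").max() for lv in cq.QUANTIBRITE_PE_LEVELS]
        minima = [by_level[lv].channel("fl2").min() for lv in cq.QUANTIBRITE_PE_LEVELS]
        for lo_max, hi_min in zip(maxima[:-1], minima[1:]):
            assert lo_max <= hi_min
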