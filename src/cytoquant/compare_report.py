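"""Group comparison (one-way ANOVA with Tukey HSD), the end-to-end
scenario runner, and report assembly.

The ANOVA/Tukey comparison operates on replicate means (the ensemble
level, where the published n is the replicate count); the K-S test in
:mod:`cytoquant.distribution_stats` operates on pooled single cells.
Both levels are exposed deliberately: ensemble differences between
conditions can be non-significant while the pooled cell-level
distributions differ decisively, because the cell-level n is orders of
magnitude larger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationCurve, calibrate_from_beads
from .distribution_stats import DistributionSummary, PooledSample, pool_and_exclude, summarize
from .errors import ValidationError
from .events_io import PipelineConfig
from .gating import Fl1Threshold, ScatterGate, fit_scatter_gate, gate_fl1_positive, gate_singlets
from .quantify import (EnsembleResult, ReceptorSample, background_pe,
                       ensemble_summary, receptors_per_cell, round_reported)
from .synthetic_cytometry import ScenarioConfig, generate_bead_events, generate_cell_events


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple
    mean_difference: float
    adjusted_p: float
    significant: bool


@dataclass(frozen=True)
class ComparisonResult:
    groups: tuple
    anova_p: float
    pairwise: tuple
    alpha: float = 0.05


def anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.05,
                ) -> ComparisonResult:
    """One-way ANOVA F-test plus Tukey HSD pairwise comparisons.

    ``groups`` maps a condition label to its replicate means.  Adjusted
    pairwise p-values come from the studentized-range distribution;
    a pair is significant when its adjusted p falls below ``alpha``.
    """
    labels = tuple(groups)
    if len(labels) < 2:
        raise ValidationError("ANOVA requires >=2 groups")
    arrays = []
    for lab in labels:
        a = np.asarray(groups[lab], dtype=float)
        if len(a) < 2:
            raise ValidationError(f"group {lab!r} has n < 2")
        arrays.append(a)
    anova_p = float(stats.f_oneway(*arrays).pvalue)
    hsd = stats.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p_adj = float(hsd.pvalue[i, j])
            pairwise.append(PairwiseComparison(
                pair=(labels[i], labels[j]),
                mean_difference=float(arrays[i].mean() - arrays[j].mean()),
                adjusted_p=p_adj,
                significant=p_adj < alpha,
            ))
    return ComparisonResult(groups=labels, anova_p=anova_p,
                            pairwise=tuple(pairwise), alpha=alpha)


@dataclass
class ScenarioResult:
    """Everything one end-to-end scenario run produces."""

    name: str
    ensemble: EnsembleResult
    summary: DistributionSummary
    pooled: PooledSample
    samples: tuple = ()
    curves: tuple = ()
    backgrounds: tuple = ()
    gating_report: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def clamp_fraction(self) -> float:
        n = sum(len(s) + s.n_excluded for s in self.samples)
        clamped = sum(s.n_clamped for s in self.samples)
        return clamped / n if n else 0.0


def run_scenario(scenario: ScenarioConfig,
                 pipeline: Optional[PipelineConfig] = None) -> ScenarioResult:
    """Simulate and analyze one condition end to end.

    Per replicate: generate bead, unlabeled and labeled tubes; fit the
    bead calibration for that session; fit/apply the scatter gate and
    the FL1 threshold (resolved on the unlabeled tube); convert gated
    events to receptors/cell with background subtraction.  Replicates
    then feed the ensemble summary, and the pooled cells (after k-SD
    exclusion) feed the cell-by-cell summary.  Deterministic given the
    scenario seed.
    """
    pipeline = pipeline or PipelineConfig()
    samples, curves, backgrounds, gate_rows = [], [], [], []
    for rep in range(scenario.n_replicates):
        seeds = np.random.SeedSequence([int(scenario.seed), rep]).spawn(3)
        beads = generate_bead_events(scenario, seed=np.random.default_rng(seeds[0]))
        labeled = generate_cell_events(scenario, labeled=True,
                                       seed=np.random.default_rng(seeds[1]))
        unlabeled = generate_cell_events(scenario, labeled=False,
                                         seed=np.random.default_rng(seeds[2]))
        labeled.metadata["replicate"] = rep
        curve, _ = calibrate_from_beads(beads, pipeline.bead_levels)

        if pipeline.scatter_gate is not None:
            gate = ScatterGate(*pipeline.scatter_gate)
        else:
            gate = fit_scatter_gate(labeled)
        unl_gated = gate_singlets(unlabeled, gate)
        cells = gate_singlets(labeled, gate)
        thr = Fl1Threshold(rule=pipeline.fl1_rule,
                           threshold=pipeline.fl1_threshold or 0.0,
                           quantile=pipeline.fl1_quantile)
        positive = gate_fl1_positive(cells, thr, unlabeled_reference=unl_gated)
        bg = background_pe(unl_gated, curve)
        sample = receptors_per_cell(
            positive, curve, bg,
            subtract_per_cell=pipeline.subtract_background_per_cell)
        samples.append(sample)
        curves.append(curve)
        backgrounds.append(bg)
        gate_rows.append({
            "replicate": rep, "events": len(labeled),
            "singlets": len(cells), "fl1_positive": len(positive),
            "fl1_threshold": positive.metadata["fl1_threshold_resolved"],
            "background_pe": bg, "m": curve.m, "b": curve.b, "r2": curve.r_squared,
        })

    ensemble = ensemble_summary(samples)
    pooled = pool_and_exclude(samples, k=pipeline.outlier_k)
    summary = summarize(pooled.values, bin_width=pipeline.bin_width,
                        n_excluded=pooled.n_excluded,
                        excess=pipeline.excess_kurtosis,
                        bias_corrected=pipeline.bias_corrected)
    return ScenarioResult(name=scenario.name, ensemble=ensemble, summary=summary,
                          pooled=pooled, samples=tuple(samples),
                          curves=tuple(curves), backgrounds=tuple(backgrounds),
                          gating_report=pd.DataFrame(gate_rows))


def build_report(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Assemble the condition summary table (ensemble + cell-by-cell
    columns).  Means and SEMs are rounded to the nearest 100
    receptors/cell here, at the report layer only; every stored value
    stays full precision."""
    if len(results) == 0:
        raise ValidationError("report requires >=1 condition result")
    rows = []
    for r in results:
        rows.append({
            "condition": r.name,
            "n": r.ensemble.n,
            "mean": round_reported(r.ensemble.mean, 100),
            "sem": round_reported(r.ensemble.sem, 100),
            "n_cells": r.summary.n_cells,
            "median": round(r.summary.median),
            "cv_percent": round(r.summary.cv_percent),
            "skewness": round(r.summary.skewness, 1),
            "kurtosis": round(r.summary.excess_kurtosis, 1),
        })
    return pd.DataFrame(rows)


def histogram_frame(summary: DistributionSummary) -> pd.DataFrame:
    """Histogram as (bin_lo, bin_hi, count) rows, ready for re-plotting."""
    edges = np.asarray(summary.bin_edges)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                         "count": summary.counts})


def plot_histogram(summary: DistributionSummary, ax=None, **kwargs):
    """Receptor-distribution histogram (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    edges = np.asarray(summary.bin_edges)
    ax.stairs(summary.counts, edges, fill=True, **kwargs)
    ax.set_xlabel("receptors/cell")
    ax.set_ylabel("number of cells")
    return ax


def plot_calibration(curve: CalibrationCurve, ax=None):
    """Bead calibration points and fitted line (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = np.asarray(curve.points)
    ax.plot(pts[:, 0], pts[:, 1], "o", label="bead levels")
    xs = np.linspace(pts[:, 0].min() - 0.2, pts[:, 0].max() + 0.2, 50)
    ax.plot(xs, curve.m * xs + curve.b, "-",
            label=f"y = {curve.m:.3f}x + {curve.b:.3f} (r$^2$={curve.r_squared:.4f})")
    ax.set_xlabel("log10(PE molecules/bead)")
    ax.set_ylabel("log10(FL2 geometric mean)")
    ax.legend()
    return ax
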