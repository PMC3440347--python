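"""Event selection: scatter (singlet) gating, FL1/CD34 positivity,
and bead subpopulation identification.

Gating is a pure filter — output events are a subset of input events,
in order, with no intensity modified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import CalibrationInputError, ConfigurationError, ValidationError
from .events_io import BeadLevelSet, EventTable


@dataclass(frozen=True)
class ScatterGate:
    """Region in linear (fsc, ssc) space.

    A rectangle is given by its bounds; alternatively a convex polygon
    may be supplied as an (n, 2) vertex array, which takes precedence.
    """

    fsc_min: float = 0.0
    fsc_max: float = np.inf
    ssc_min: float = 0.0
    ssc_max: float = np.inf
    polygon: Optional[tuple] = None

    def __post_init__(self):
        if self.polygon is not None:
            poly = np.asarray(self.polygon, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
                raise ValidationError("polygon must be an (n>=3, 2) vertex array")
            # shoelace area; degenerate polygons rejected
            x, y = poly[:, 0], poly[:, 1]
            area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
            if area <= 0:
                raise ValidationError("degenerate scatter gate: zero polygon area")
            object.__setattr__(self, "polygon", tuple(map(tuple, poly)))
        else:
            if not (self.fsc_max > self.fsc_min and self.ssc_max > self.ssc_min):
                raise ValidationError("degenerate scatter gate: empty rectangle")

    def contains(self, fsc: np.ndarray, ssc: np.ndarray) -> np.ndarray:
        fsc = np.asarray(fsc, dtype=float)
        ssc = np.asarray(ssc, dtype=float)
        if self.polygon is not None:
            from matplotlib.path import Path as MplPath

            pts = np.column_stack([fsc, ssc])
            return MplPath(np.asarray(self.polygon)).contains_points(pts)
        return ((fsc >= self.fsc_min) & (fsc <= self.fsc_max)
                & (ssc >= self.ssc_min) & (ssc <= self.ssc_max))


@dataclass(frozen=True)
class Fl1Threshold:
    """FL1 positivity rule: a fixed cutoff, or a quantile of the
    unlabeled reference sample (default: its 99.9th percentile, a
    specificity-anchored substitute for a manual gate)."""

    rule: str = "quantile_of_unlabeled"
    threshold: float = 0.0
    quantile: float = 0.999

    def __post_init__(self):
        if self.rule not in ("fixed", "quantile_of_unlabeled"):
            raise ValidationError(f"unknown fl1 rule: {self.rule!r}")
        if self.rule == "fixed" and self.threshold < 0:
            raise ValidationError("fixed fl1 threshold must be >= 0")
        if self.rule == "quantile_of_unlabeled" and not (0 < self.quantile < 1):
            raise ValidationError("fl1 quantile must be in (0, 1)")


def fit_scatter_gate(table: EventTable, n_sigma: float = 3.0) -> ScatterGate:
    """Fit a +/- n_sigma box around the densest (fsc, ssc) cluster.

    Uses the median as a robust center and 1.4826*MAD as a robust
    scale per axis, so minority debris/doublet clusters do not drag
    the box.  Intended as an unattended default for the manual singlet
    gate of an interactive analysis.
    """
    if len(table) == 0:
        raise ValidationError("cannot fit a scatter gate to an empty table")
    fsc, ssc = table.channel("fsc"), table.channel("ssc")
    bounds = []
    for v in (fsc, ssc):
        center = np.median(v)
        scale = 1.4826 * np.median(np.abs(v - center))
        if scale == 0:
            scale = max(1e-9, 0.01 * abs(center))
        bounds.append((center - n_sigma * scale, center + n_sigma * scale))
    return ScatterGate(fsc_min=max(0.0, bounds[0][0]), fsc_max=bounds[0][1],
                       ssc_min=max(0.0, bounds[1][0]), ssc_max=bounds[1][1])


def gate_singlets(table: EventTable, gate: ScatterGate) -> EventTable:
    """Select events whose (fsc, ssc) lie inside the scatter gate."""
    mask = gate.contains(table.channel("fsc"), table.channel("ssc"))
    return table.subset(mask, scatter_gate_kept=int(mask.sum()),
                        scatter_gate_total=len(table))


def gate_fl1_positive(table: EventTable, thr: Fl1Threshold,
                      unlabeled_reference: Optional[EventTable] = None) -> EventTable:
    """Select FL1(CD34-FITC)-positive events.

    With the quantile rule the threshold is resolved against the FL1
    distribution of the unlabeled reference tube; the resolved value is
    recorded in the result metadata.
    """
    if thr.rule == "quantile_of_unlabeled":
        if unlabeled_reference is None or len(unlabeled_reference) == 0:
            raise ConfigurationError(
                "fl1 quantile rule requires a non-empty unlabeled reference table")
        resolved = float(np.quantile(unlabeled_reference.channel("fl1"), thr.quantile))
    else:
        resolved = float(thr.threshold)
    mask = table.channel("fl1") > resolved
    return table.subset(mask, fl1_threshold_resolved=resolved,
                        fl1_gate_kept=int(mask.sum()), fl1_gate_total=len(table))


def identify_bead_levels(beads: EventTable, levels: BeadLevelSet,
                         min_separation: float = 4.0) -> Mapping[float, EventTable]:
    """Assign bead events to the PE-level subpopulations.

    1-D k-means on log10(fl2) with k = number of levels, initialized at
    evenly spaced quantiles of the data, then matched to levels by rank
    (higher fl2 cluster -> higher PE level), mirroring how the
    subpopulations are read off the bead histogram.

    Raises
    ------
    CalibrationInputError
        If there are fewer positive-fl2 events than levels, if any
        cluster ends up empty, or if adjacent cluster centers are
        separated by less than ``min_separation`` pooled within-cluster
        standard deviations.
    """
    k = len(levels)
    fl2 = beads.channel("fl2")
    positive = fl2 > 0
    if int(positive.sum()) < k:
        raise CalibrationInputError(
            f"need at least {k} positive-fl2 bead events, got {int(positive.sum())}")
    x = np.log10(fl2[positive])

    from sklearn.cluster import KMeans

    init = np.quantile(x, (np.arange(k) + 0.5) / k).reshape(-1, 1)
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300)
    labels = km.fit_predict(x.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)

    # separation diagnostic: adjacent centers vs pooled within-cluster spread
    spreads = []
    for j in range(k):
        xs = x[labels == j]
        if len(xs) == 0:
            raise CalibrationInputError("empty bead cluster: levels unresolvable")
        spreads.append(xs.std())
    spreads = np.array(spreads)[order]
    gaps = np.diff(centers[order])
    pooled = (spreads[:-1] + spreads[1:]) / 2
    with np.errstate(invalid="ignore"):
        bad = gaps < min_separation * pooled
    if bad.any():
        raise CalibrationInputError(
            "bead subpopulations overlap: cluster separation below threshold")

    # map back onto the full table (non-positive fl2 events are dropped)
    full_labels = np.full(len(beads), -1)
    full_labels[np.flatnonzero(positive)] = labels
    out = {}
    for rank, j in enumerate(order):
        level = levels.levels[rank]
        out[level] = beads.subset(full_labels == j, bead_level=level)
    return out
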