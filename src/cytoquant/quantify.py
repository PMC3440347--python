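"""Receptor quantification: background subtraction, per-cell
conversion, ensemble (replicate-level) summaries and compartment
arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .calibration import CalibrationCurve, fluorescence_to_pe, geometric_mean
from .errors import ComputationError, ValidationError
from .events_io import EventTable


@dataclass
class ReceptorSample:
    """Per-cell receptor counts for one replicate of one condition."""

    per_cell: np.ndarray
    condition: str = ""
    replicate_id: Optional[str] = None
    background_pe: float = 0.0
    n_excluded: int = 0  # non-positive fl2, no log-domain image
    n_clamped: int = 0   # below background, floored at 0

    def __post_init__(self):
        self.per_cell = np.asarray(self.per_cell, dtype=float)
        if (self.per_cell < 0).any():
            raise ValidationError("receptor counts must be >= 0")
        if self.background_pe < 0:
            raise ValidationError("background_pe must be >= 0")

    def __len__(self):
        return len(self.per_cell)

    @property
    def clamp_fraction(self) -> float:
        n = len(self.per_cell)
        return self.n_clamped / n if n else 0.0


@dataclass(frozen=True)
class EnsembleResult:
    """Replicate-level summary: mean +/- SEM across replicate means."""

    n: int
    mean: float
    sem: float
    replicate_means: tuple = ()


@dataclass(frozen=True)
class CompartmentEstimate:
    """Whole-cell receptor budget inferred from the surface count and a
    literature surface fraction."""

    surface: float
    surface_fraction: float
    total: float
    intracellular: float
    recycled: Optional[float] = None
    recycled_fraction_of_intracellular: Optional[float] = None


def background_pe(unlabeled: EventTable, curve: CalibrationCurve) -> float:
    """Endogenous fluorescence of unlabeled cells in PE-equivalents.

    Geometric mean of the unlabeled FL2 signal, converted through the
    bead calibration.  A tube with no positive FL2 signal has zero
    measurable endogenous fluorescence.
    """
    if len(unlabeled) == 0:
        raise ComputationError("background requires a non-empty unlabeled table")
    fl2 = unlabeled.channel("fl2")
    if not (fl2 > 0).any():
        warnings.warn("unlabeled tube has no positive FL2 signal; background = 0",
                      stacklevel=2)
        return 0.0
    gm = geometric_mean(fl2)
    return float(fluorescence_to_pe(gm.value, curve))


def receptors_per_cell(cells: EventTable, curve: CalibrationCurve,
                       background: float = 0.0,
                       subtract_per_cell: bool = True) -> ReceptorSample:
    """Convert gated, labeled cell events to receptors/cell.

    Per event: ``max(0, PE(fl2) - background)`` with 1 PE molecule
    identified with 1 bound receptor.  Events with non-positive fl2
    are excluded (counted); values below background are clamped to 0
    (counted) since receptor counts are physical.  ``subtract_per_cell
    =False`` keeps the raw converted values, for probing how much the
    background rule matters.
    """
    if len(cells) == 0:
        warnings.warn("empty input: returning empty receptor sample", stacklevel=2)
        return ReceptorSample(per_cell=np.empty(0),
                              condition=cells.metadata.get("condition", ""),
                              background_pe=background)
    pe = fluorescence_to_pe(cells.channel("fl2"), curve)
    ok = np.isfinite(pe)
    n_excluded = int((~ok).sum())
    pe = pe[ok]
    if subtract_per_cell:
        shifted = pe - background
        n_clamped = int((shifted < 0).sum())
        values = np.maximum(shifted, 0.0)
    else:
        n_clamped = 0
        values = pe
    return ReceptorSample(
        per_cell=values,
        condition=cells.metadata.get("condition", ""),
        replicate_id=cells.metadata.get("replicate"),
        background_pe=float(background),
        n_excluded=n_excluded,
        n_clamped=n_clamped,
    )


def ensemble_summary(replicate_samples: Sequence[ReceptorSample]) -> EnsembleResult:
    """Mean +/- SEM across replicates.

    Each replicate contributes the mean of its per-cell values; the
    ensemble mean is the unweighted mean of those replicate means and
    the SEM is their sample standard deviation divided by sqrt(n).
    """
    if len(replicate_samples) == 0:
        raise ComputationError("ensemble summary requires >=1 replicate")
    means = []
    for s in replicate_samples:
        if len(s) == 0:
            raise ComputationError("replicate with no cells cannot contribute a mean")
        means.append(float(np.mean(s.per_cell)))
    means = np.array(means)
    n = len(means)
    sem = float(np.std(means, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return EnsembleResult(n=n, mean=float(means.mean()), sem=sem,
                          replicate_means=tuple(means))


def compile_conditions(results: Sequence[tuple]) -> float:
    """n-weighted average across conditions.

    ``results`` is a sequence of (EnsembleResult-or-mean, n) pairs; the
    compiled mean weights each condition mean by its replicate count.
    With equal weights this reduces to the plain average.  Rounding to
    the nearest 100 receptors/cell happens only at the report layer.
    """
    if len(results) == 0:
        raise ComputationError("compile_conditions requires >=1 condition")
    means, weights = [], []
    for res, n in results:
        means.append(res.mean if isinstance(res, EnsembleResult) else float(res))
        weights.append(float(n))
    return float(np.average(means, weights=weights))


def compartment_estimate(surface: float, surface_fraction: float,
                         recycled_fraction: Optional[float] = None,
                         ) -> CompartmentEstimate:
    """Partition the whole-cell receptor pool from its surface count.

    total = surface / surface_fraction; intracellular = total - surface;
    recycled = recycled_fraction * intracellular (when given).
    """
    if not (0.0 < surface_fraction <= 1.0):
        raise ValidationError("surface_fraction must be in (0, 1]")
    if surface < 0:
        raise ValidationError("surface count must be >= 0")
    total = surface / surface_fraction
    intracellular = total - surface
    recycled = None
    if recycled_fraction is not None:
        if not (0.0 <= recycled_fraction <= 1.0):
            raise ValidationError("recycled_fraction must be in [0, 1]")
        recycled = recycled_fraction * intracellular
    return CompartmentEstimate(surface=float(surface),
                               surface_fraction=float(surface_fraction),
                               total=float(total),
                               intracellular=float(intracellular),
                               recycled=recycled,
                               recycled_fraction_of_intracellular=recycled_fraction)


def round_reported(value: float, nearest: float = 100.0) -> float:
    """Report-layer rounding (means to the nearest 100 receptors/cell,
    compartment estimates to the nearest 1,000 or 100)."""
    return float(nearest * round(value / nearest))
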