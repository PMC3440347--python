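"""PE-bead calibration: fluorescence -> absolute PE-molecule counts.

The calibration curve is an ordinary least-squares fit of
log10(per-level FL2 geometric mean) on log10(PE molecules/bead):
``y = m x + b``.  Inverting it converts any FL2 intensity to PE
molecules: ``PE = 10**((log10 fl2 - b) / m)``; with 1 PE per antibody
and 1 antibody per receptor, PE molecules equal receptors bound.
The curve is applied by extrapolation outside the bead range (cell
signals below the lowest bead level are routine); results carry a flag
when extrapolation occurred.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
from scipy import stats

from .errors import CalibrationInputError, ComputationError
from .events_io import BeadLevelSet, EventTable

GeometricMean = namedtuple("GeometricMean", ["value", "n_excluded"])


def geometric_mean(values) -> GeometricMean:
    """exp(mean(ln v)) over the strictly positive values.

    Non-positive values cannot enter the log domain; they are excluded
    (not offset-shifted) and their count is reported.
    """
    v = np.asarray(values, dtype=float)
    positive = v > 0
    n_excluded = int(v.size - positive.sum())
    if not positive.any():
        raise ComputationError("geometric mean undefined: no strictly positive values")
    return GeometricMean(float(np.exp(np.mean(np.log(v[positive])))), n_excluded)


@dataclass(frozen=True)
class CalibrationCurve:
    """y = m x + b with x = log10(PE/bead), y = log10(FL2 geomean)."""

    m: float
    b: float
    r_squared: float
    points: tuple = ()  # ((log10 PE, log10 geomean), ...)
    monotone_ok: bool = True

    def __post_init__(self):
        if len(self.points) < 2:
            raise CalibrationInputError("calibration curve needs >=2 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise CalibrationInputError("r_squared outside [0, 1]")


def fit_calibration(bead_geomeans: Mapping[float, float],
                    levels: BeadLevelSet = None) -> CalibrationCurve:
    """OLS fit of log10(geomean FL2) on log10(PE/bead).

    ``bead_geomeans`` maps PE level -> FL2 geometric mean.  The fit is
    invariant to the order the levels are supplied in.  A non-positive
    slope is physically implausible (response must increase with PE
    load) and is flagged rather than rejected.
    """
    if levels is not None:
        missing = [lv for lv in levels if lv not in bead_geomeans]
        if missing:
            raise CalibrationInputError(f"no geomean for bead level(s) {missing}")
        items = [(lv, bead_geomeans[lv]) for lv in levels]
    else:
        items = sorted(bead_geomeans.items())
    usable = [(lv, gm) for lv, gm in items if lv > 0 and gm > 0]
    if len(usable) < 2:
        raise CalibrationInputError("calibration needs >=2 levels with positive geomeans")
    x = np.log10([lv for lv, _ in usable])
    y = np.log10([gm for _, gm in usable])
    fit = stats.linregress(x, y)
    m, b = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    monotone_ok = m > 0
    if not monotone_ok:
        warnings.warn("calibration slope m <= 0: non-monotone bead response",
                      stacklevel=2)
    return CalibrationCurve(m=m, b=b, r_squared=r2,
                            points=tuple(zip(x.tolist(), y.tolist())),
                            monotone_ok=monotone_ok)


def fluorescence_to_pe(fl2: Union[float, np.ndarray],
                       curve: CalibrationCurve) -> Union[float, np.ndarray]:
    """Invert the calibration: PE = 10**((log10 fl2 - b) / m).

    Monotone increasing in fl2 (for m > 0).  Non-positive fl2 has no
    log-domain image and maps to NaN; callers exclude and count those
    events.
    """
    scalar = np.isscalar(fl2)
    v = np.asarray(fl2, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = v > 0
    out[ok] = 10.0 ** ((np.log10(v[ok]) - curve.b) / curve.m)
    return float(out) if scalar else out


def calibrate_from_beads(bead_table: EventTable, levels: BeadLevelSet = None,
                         ) -> tuple:
    """Convenience: identify bead levels, take per-level FL2 geometric
    means, fit the curve.  Returns (curve, geomeans dict)."""
    from .gating import identify_bead_levels

    levels = levels if levels is not None else BeadLevelSet()
    by_level = identify_bead_levels(bead_table, levels)
    geomeans = {lv: geometric_mean(t.channel("fl2")).value for lv, t in by_level.items()}
    return fit_calibration(geomeans, levels), geomeans
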