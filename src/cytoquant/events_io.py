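"""Event tables, bead metadata and pipeline configuration.

The canonical on-disk format is a delimited text file with a one-line
header and four linear channel columns (``fsc``, ``ssc``, ``fl1``,
``fl2``), optionally followed by ground-truth columns that only a
synthetic generator can supply (``true_receptors``,
``population_label``).  FCS 3.0/3.1 files can be ingested read-only
through :func:`read_event_table` with ``dialect="fcs"``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

#: Required channel columns, in canonical order.  All values are linear
#: (no log-amplifier transform), in arbitrary instrument units.
CHANNELS = ("fsc", "ssc", "fl1", "fl2")

#: Optional per-event annotations carried only by synthetic data.
GROUND_TRUTH_COLUMNS = ("true_receptors", "population_label")

#: Quantibrite-style PE bead calibration standard: number of
#: phycoerythrin molecules per bead for the low, medium-low,
#: medium-high and high subpopulations.
QUANTIBRITE_PE_LEVELS = (515.0, 5956.0, 26653.0, 69045.0)


@dataclass(frozen=True)
class BeadLevelSet:
    """Ordered PE-molecule loadings of the bead calibration standard."""

    levels: tuple = QUANTIBRITE_PE_LEVELS

    def __post_init__(self):
        levels = tuple(float(v) for v in self.levels)
        if len(levels) < 2:
            raise ValidationError("bead level set needs >=2 levels for a regression")
        if any(v <= 0 for v in levels):
            raise ValidationError("bead PE levels must be positive")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValidationError("bead PE levels must be strictly increasing")
        object.__setattr__(self, "levels", levels)

    def __len__(self):
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)


@dataclass
class EventTable:
    """Per-event channel intensities with optional ground truth.

    Parameters
    ----------
    data
        One row per event.  Must contain the four channel columns; may
        additionally contain the ground-truth columns.  Row order is
        meaningful and preserved by every operation.
    metadata
        Free-form sample annotations (``sample_id``, ``condition``,
        ``replicate``, ``labeled`` ...) plus records appended by
        pipeline stages (gating counts, resolved thresholds).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        for col in CHANNELS:
            if col not in self.data.columns:
                raise FormatError(f"missing required channel column: {col!r}")
        ch = self.data[list(CHANNELS)].to_numpy(dtype=float)
        if ch.size:
            if not np.isfinite(ch).all():
                raise ValidationError("channel intensities must be finite")
            if (ch < 0).any():
                raise ValidationError("channel intensities must be non-negative")

    def __len__(self):
        return len(self.data)

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def has_ground_truth(self) -> bool:
        return all(c in self.data.columns for c in GROUND_TRUTH_COLUMNS)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def subset(self, mask, **metadata_updates) -> "EventTable":
        """Pure filter: returns the rows where ``mask`` is true, order
        preserved, intensities untouched, metadata carried over."""
        data = self.data.loc[np.asarray(mask)].reset_index(drop=True)
        meta = {**self.metadata, **metadata_updates}
        return EventTable(data=data, metadata=meta)


def read_event_table(path, dialect: str = "tabular") -> EventTable:
    """Read an event table from ``path``.

    ``dialect="tabular"`` reads the canonical delimited text format;
    ``dialect="fcs"`` reads an FCS 3.0/3.1 file, mapping the first four
    detector parameters (or ``$PnN`` names matching FSC/SSC/FL1/FL2)
    onto the canonical channel names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tabular":
        data = pd.read_csv(path)
        meta = {}
        return EventTable(data=data, metadata=meta)
    if dialect == "fcs":
        from ._fcs import read_fcs

        data = read_fcs(path)
        return EventTable(data=data, metadata={"source": str(path), "dialect": "fcs"})
    raise ValidationError(f"unknown dialect: {dialect!r}")


def write_event_table(table: EventTable, path) -> Path:
    """Write ``table`` in the canonical delimited text format.

    Channel values are written with 9 significant digits so a
    write/read round trip preserves them to well under 1e-6 relative.
    """
    path = Path(path)
    table.data.to_csv(path, index=False, float_format="%.9g")
    return path


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Analysis-stage constants.

    Defaults reproduce the published protocol: single-pass exclusion of
    values more than 3 standard deviations from the pooled mean,
    histograms with 500-receptor bins, significance at alpha=0.05 and
    the four-level Quantibrite PE bead standard.
    """

    scatter_gate: Optional[tuple] = None  # (fsc_min, fsc_max, ssc_min, ssc_max); None = auto-fit
    fl1_rule: str = "quantile_of_unlabeled"
    fl1_threshold: Optional[float] = None  # used when fl1_rule == "fixed"
    fl1_quantile: float = 0.999
    bead_levels: BeadLevelSet = field(default_factory=BeadLevelSet)
    outlier_k: float = 3.0
    bin_width: float = 500.0
    alpha: float = 0.05
    seed: Optional[int] = None
    subtract_background_per_cell: bool = True
    excess_kurtosis: bool = True
    bias_corrected: bool = False

    def __post_init__(self):
        if self.outlier_k <= 0:
            raise ValidationError("outlier_k: must be > 0")
        if self.bin_width <= 0:
            raise ValidationError("bin_width: must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha: must be in (0, 1)")
        if not (0.0 < self.fl1_quantile < 1.0):
            raise ValidationError("fl1_quantile: must be in (0, 1)")
        if self.fl1_rule not in ("fixed", "quantile_of_unlabeled"):
            raise ValidationError(f"fl1_rule: unknown rule {self.fl1_rule!r}")
        if not isinstance(self.bead_levels, BeadLevelSet):
            self.bead_levels = BeadLevelSet(tuple(self.bead_levels))


def load_config(path) -> Union[PipelineConfig, "ScenarioConfig"]:
    """Load a pipeline or scenario configuration from a YAML/JSON file.

    The document kind is inferred from its keys: anything defining a
    ``receptor_distribution`` is a scenario; everything else is a
    pipeline configuration.  Absent fields take their defaults.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: config document must be a mapping")
    if "receptor_distribution" in doc or doc.get("kind") == "scenario":
        from .synthetic_cytometry import ScenarioConfig

        doc.pop("kind", None)
        return ScenarioConfig.from_dict(doc)
    doc.pop("kind", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValidationError(f"unknown config fields: {sorted(unknown)}")
    if "bead_levels" in doc:
        doc["bead_levels"] = BeadLevelSet(tuple(doc["bead_levels"]))
    return PipelineConfig(**doc)


def dump_config(config, path) -> Path:
    """Serialize a PipelineConfig back to YAML (inverse of load_config)."""
    doc = dataclasses.asdict(config)
    doc["bead_levels"] = list(config.bead_levels.levels)
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path
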