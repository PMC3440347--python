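"""Forward model of cytometry events with known ground truth.

The generator emulates the statistical structure the downstream
analysis assumes:

* heavy-tailed per-cell receptor counts (log-normal, or a log-normal
  mixture for populations with a distinct low-expressing mode),
* saturating 1:1 antibody:receptor labeling with ~1 PE per antibody,
  so the number of bound PE molecules equals the surface receptor count,
* a linear FL2 detector response (``gain`` a.u. per PE molecule) with
  multiplicative log-normal instrument noise and additive
  autofluorescence,
* non-target event classes — CD34-negative contaminant cells, debris
  and doublets — occupying their own scatter/FL1 clusters, and
* a four-subpopulation PE bead standard for calibration.

Every event carries its ground truth (``true_receptors``,
``population_label``) so gating and quantification can be scored
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .events_io import BeadLevelSet, EventTable

RngLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def lognormal_params(median: float, cv: float) -> tuple:
    """(mu, sigma) of a log-normal with the given population median and CV.

    mu = ln(median); sigma^2 = ln(1 + cv^2).
    """
    if median <= 0 or cv <= 0:
        raise ValidationError("median and cv must be positive")
    return float(np.log(median)), float(np.sqrt(np.log1p(cv * cv)))


def lognormal_skewness(cv: float) -> float:
    """Closed-form skewness of a log-normal distribution: cv^3 + 3 cv."""
    return cv**3 + 3 * cv


@dataclass(frozen=True)
class MixtureComponent:
    """One log-normal component: mixing weight, median, log-scale sigma."""

    weight: float
    median: float
    sigma: float


@dataclass
class ReceptorDistribution:
    """Per-cell surface receptor count model for the target population.

    ``family="lognormal"`` is parameterized by (median, cv) — the two
    heterogeneity statistics reported per condition.  ``family=
    "lognormal_mixture"`` takes explicit components, used by the
    packaged scenarios where a single log-normal cannot jointly match
    the reported mean, median and CV.
    """

    family: str = "lognormal"
    median: float = 2000.0
    cv: float = 1.0
    components: Optional[tuple] = None

    def __post_init__(self):
        if self.family not in ("lognormal", "lognormal_mixture"):
            raise ConfigurationError(f"unsupported distribution family: {self.family!r}")
        if self.family == "lognormal":
            if self.median <= 0:
                raise ValidationError("median: must be > 0")
            if self.cv <= 0:
                raise ValidationError("cv: must be > 0")
        else:
            if not self.components:
                raise ConfigurationError("lognormal_mixture requires components")
            comps = tuple(
                c if isinstance(c, MixtureComponent) else MixtureComponent(*c)
                for c in self.components
            )
            w = np.array([c.weight for c in comps])
            if (w <= 0).any() or abs(w.sum() - 1.0) > 1e-3:
                raise ValidationError("mixture weights must be positive and sum to 1")
            if any(c.median <= 0 or c.sigma <= 0 for c in comps):
                raise ValidationError("mixture medians and sigmas must be positive")
            # renormalize away rounding slack in stored weights
            self.components = tuple(
                MixtureComponent(c.weight / w.sum(), c.median, c.sigma) for c in comps)


@dataclass
class Instrument:
    """FL2 detector model.

    gain
        a.u. of FL2 per PE molecule (linear response).
    noise_cv
        CV of the multiplicative log-normal measurement noise on FL2
        (unit arithmetic mean, so the mean signal is unbiased).
    autofluor_pe / autofluor_cv
        Endogenous cell fluorescence on FL2, expressed as the
        arithmetic-mean PE-equivalent molecule count; contributes
        ``gain * autofluor`` a.u. additively, for labeled and unlabeled
        cells alike.
    """

    gain: float = 2.0
    noise_cv: float = 0.15
    autofluor_pe: float = 300.0
    autofluor_cv: float = 0.30

    def __post_init__(self):
        if self.gain <= 0:
            raise ValidationError("gain: must be > 0")
        if self.noise_cv < 0 or self.autofluor_cv < 0 or self.autofluor_pe < 0:
            raise ValidationError("instrument noise parameters must be >= 0")


@dataclass
class Populations:
    """Event-class composition of a cell tube (fractions of all events)."""

    contaminant_fraction: float = 0.10
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.03

    def __post_init__(self):
        f = (self.contaminant_fraction, self.debris_fraction, self.doublet_fraction)
        if any(x < 0 or x >= 1 for x in f):
            raise ValidationError("population fractions must be in [0, 1)")
        if sum(f) >= 1:
            raise ValidationError("population fractions must sum to < 1")

    @property
    def target_fraction(self) -> float:
        return 1.0 - self.contaminant_fraction - self.debris_fraction - self.doublet_fraction


@dataclass
class Fl1Model:
    """CD34-FITC channel: positive (target) vs negative populations."""

    positive_mean: float = 500.0
    negative_mean: float = 5.0
    cv: float = 0.35

    def __post_init__(self):
        if self.positive_mean <= self.negative_mean:
            raise ValidationError("fl1 positive_mean must exceed negative_mean")


@dataclass(frozen=True)
class ScatterCluster:
    """Normal (fsc, ssc) cluster, clipped at zero; sd = mean * cv."""

    fsc_mean: float
    ssc_mean: float
    cv: float = 0.12


DEFAULT_SCATTER = {
    "target": ScatterCluster(500.0, 300.0, 0.12),
    "contaminant": ScatterCluster(480.0, 320.0, 0.16),
    "debris": ScatterCluster(80.0, 40.0, 0.35),
    "bead": ScatterCluster(200.0, 150.0, 0.08),
}


@dataclass
class BeadConfig:
    levels: BeadLevelSet = field(default_factory=BeadLevelSet)
    n_per_level: int = 2500
    noise_cv: float = 0.05

    def __post_init__(self):
        if not isinstance(self.levels, BeadLevelSet):
            self.levels = BeadLevelSet(tuple(self.levels))
        if self.n_per_level <= 0:
            raise ValidationError("n_per_level: must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("bead noise_cv: must be >= 0")


@dataclass
class ScenarioConfig:
    """All generator parameters for one simulated condition."""

    name: str = "scenario"
    receptor_distribution: ReceptorDistribution = field(default_factory=ReceptorDistribution)
    n_cells: int = 10000
    n_replicates: int = 6
    instrument: Instrument = field(default_factory=Instrument)
    populations: Populations = field(default_factory=Populations)
    fl1: Fl1Model = field(default_factory=Fl1Model)
    scatter: dict = field(default_factory=lambda: dict(DEFAULT_SCATTER))
    bead: BeadConfig = field(default_factory=BeadConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ValidationError("n_cells: must be > 0")
        if self.n_replicates <= 0:
            raise ValidationError("n_replicates: must be > 0")
        for key in ("target", "contaminant", "debris", "bead"):
            if key not in self.scatter:
                self.scatter[key] = DEFAULT_SCATTER[key]
            c = self.scatter[key]
            if not isinstance(c, ScatterCluster):
                self.scatter[key] = ScatterCluster(**c) if isinstance(c, dict) else ScatterCluster(*c)

    @classmethod
    def from_dict(cls, doc: dict) -> "ScenarioConfig":
        doc = dict(doc)
        rd = doc.get("receptor_distribution", {})
        if isinstance(rd, dict):
            doc["receptor_distribution"] = ReceptorDistribution(**rd)
        for key, typ in (("instrument", Instrument), ("populations", Populations),
                         ("fl1", Fl1Model), ("bead", BeadConfig)):
            if isinstance(doc.get(key), dict):
                doc[key] = typ(**doc[key])
        if "scatter" in doc and isinstance(doc["scatter"], dict):
            doc["scatter"] = {
                k: (v if isinstance(v, ScatterCluster) else ScatterCluster(**v))
                for k, v in doc["scatter"].items()
            }
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown scenario fields: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# draws


def draw_receptor_counts(cfg: ScenarioConfig, n: int, seed: RngLike = None) -> np.ndarray:
    """Draw ``n`` per-cell receptor counts from the scenario's distribution."""
    rng = _rng(seed if seed is not None else cfg.seed)
    dist = cfg.receptor_distribution
    if n == 0:
        return np.empty(0)
    if dist.family == "lognormal":
        mu, sigma = lognormal_params(dist.median, dist.cv)
        return np.exp(mu + sigma * rng.standard_normal(n))
    comps = dist.components
    w = np.array([c.weight for c in comps])
    idx = rng.choice(len(comps), size=n, p=w / w.sum())
    mus = np.log([c.median for c in comps])
    sigmas = np.array([c.sigma for c in comps])
    return np.exp(mus[idx] + sigmas[idx] * rng.standard_normal(n))


def _mult_noise(rng, n, cv):
    """Multiplicative log-normal factor with arithmetic mean exactly 1."""
    if cv == 0:
        return np.ones(n)
    s = np.sqrt(np.log1p(cv * cv))
    return np.exp(s * rng.standard_normal(n) - s * s / 2)


def _autofluor(rng, n, inst: Instrument):
    """Additive FL2 autofluorescence in a.u. (arithmetic mean gain*autofluor_pe)."""
    base = inst.gain * inst.autofluor_pe
    if base == 0:
        return np.zeros(n)
    return base * _mult_noise(rng, n, inst.autofluor_cv)


def _scatter(rng, n, cluster: ScatterCluster):
    fsc = cluster.fsc_mean * (1 + cluster.cv * rng.standard_normal(n))
    ssc = cluster.ssc_mean * (1 + cluster.cv * rng.standard_normal(n))
    return np.clip(fsc, 0, None), np.clip(ssc, 0, None)


def _fl1(rng, n, mean, cv):
    if n == 0:
        return np.empty(0)
    mu, sigma = lognormal_params(mean, max(cv, 1e-9))
    return np.exp(mu + sigma * rng.standard_normal(n))


def generate_cell_events(cfg: ScenarioConfig, labeled: bool = True,
                         seed: RngLike = None) -> EventTable:
    """Simulate one cell tube (labeled or unlabeled control).

    For labeled target cells ``fl2 = gain * R * eps + A`` where ``R``
    is the true receptor count (1 bound PE per receptor under
    saturating labeling), ``eps`` is unit-mean log-normal instrument
    noise and ``A`` is the autofluorescence draw.  Unlabeled cells and
    receptor-free contaminants contribute ``fl2 = A`` only.  Doublets
    are sums of two target singlet events in every channel.
    """
    rng = _rng(seed if seed is not None else cfg.seed)
    inst, pops = cfg.instrument, cfg.populations
    n = cfg.n_cells
    probs = [pops.target_fraction, pops.contaminant_fraction,
             pops.debris_fraction, pops.doublet_fraction]
    n_tgt, n_cont, n_deb, n_dbl = rng.multinomial(n, probs)

    parts = []

    def emit(label, fsc, ssc, fl1, fl2, true_r):
        parts.append(pd.DataFrame({
            "fsc": fsc, "ssc": ssc, "fl1": fl1, "fl2": np.clip(fl2, 0, None),
            "true_receptors": true_r, "population_label": label,
        }))

    # target singlets
    r = draw_receptor_counts(cfg, n_tgt, rng)
    fsc, ssc = _scatter(rng, n_tgt, cfg.scatter["target"])
    a = _autofluor(rng, n_tgt, inst)
    if labeled:
        fl2 = inst.gain * r * _mult_noise(rng, n_tgt, inst.noise_cv) + a
        fl1 = _fl1(rng, n_tgt, cfg.fl1.positive_mean, cfg.fl1.cv)
    else:
        fl2 = a
        fl1 = _fl1(rng, n_tgt, cfg.fl1.negative_mean, cfg.fl1.cv)
    emit("target", fsc, ssc, fl1, fl2, r)

    # CD34-negative contaminant cells: no receptor, autofluorescence only
    fsc, ssc = _scatter(rng, n_cont, cfg.scatter["contaminant"])
    emit("contaminant", fsc, ssc, _fl1(rng, n_cont, cfg.fl1.negative_mean, cfg.fl1.cv),
         _autofluor(rng, n_cont, inst), np.zeros(n_cont))

    # debris: small scatter, dim
    fsc, ssc = _scatter(rng, n_deb, cfg.scatter["debris"])
    emit("debris", fsc, ssc, _fl1(rng, n_deb, cfg.fl1.negative_mean, cfg.fl1.cv),
         0.3 * _autofluor(rng, n_deb, inst), np.zeros(n_deb))

    # doublets: sums of two target singlets in every channel
    r2 = draw_receptor_counts(cfg, 2 * n_dbl, rng).reshape(2, -1) if n_dbl else np.zeros((2, 0))
    f1, s1 = _scatter(rng, n_dbl, cfg.scatter["target"])
    f2, s2 = _scatter(rng, n_dbl, cfg.scatter["target"])
    a2 = _autofluor(rng, n_dbl, inst) + _autofluor(rng, n_dbl, inst)
    if labeled:
        eps = _mult_noise(rng, n_dbl, inst.noise_cv)
        fl2 = inst.gain * r2.sum(axis=0) * eps + a2
        fl1 = _fl1(rng, n_dbl, cfg.fl1.positive_mean, cfg.fl1.cv) * 2
    else:
        fl2 = a2
        fl1 = _fl1(rng, n_dbl, cfg.fl1.negative_mean, cfg.fl1.cv) * 2
    emit("doublet", f1 + f2, s1 + s2, fl1, fl2, r2.sum(axis=0))

    data = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["fsc", "ssc", "fl1", "fl2", "true_receptors", "population_label"])
    # shuffle so event order carries no population information
    order = rng.permutation(len(data))
    data = data.iloc[order].reset_index(drop=True)
    meta = {"condition": cfg.name, "labeled": bool(labeled), "n_events": len(data)}
    return EventTable(data=data, metadata=meta)


def generate_bead_events(cfg: ScenarioConfig, seed: RngLike = None) -> EventTable:
    """Simulate the PE bead calibration tube.

    Per level: ``fl2 = gain * PE_level * eps_bead`` with ``eps_bead``
    unit-median log-normal (so the per-level geometric mean of FL2 is
    exactly ``gain * PE_level`` in expectation, matching the log-domain
    calibration fit).  The bead scatter cluster is distinct from cells.
    """
    rng = _rng(seed if seed is not None else cfg.seed)
    inst, bead = cfg.instrument, cfg.bead
    parts = []
    for k, level in enumerate(bead.levels):
        npl = bead.n_per_level
        if bead.noise_cv > 0:
            s = np.sqrt(np.log1p(bead.noise_cv**2))
            eps = np.exp(s * rng.standard_normal(npl))  # unit median
        else:
            eps = np.ones(npl)
        fsc, ssc = _scatter(rng, npl, cfg.scatter["bead"])
        parts.append(pd.DataFrame({
            "fsc": fsc, "ssc": ssc,
            "fl1": _fl1(rng, npl, cfg.fl1.negative_mean, cfg.fl1.cv),
            "fl2": inst.gain * level * eps,
            "true_receptors": np.full(npl, np.nan),
            "population_label": f"bead_level_{k}",
        }))
    data = pd.concat(parts, ignore_index=True)
    meta = {"condition": cfg.name, "kind": "beads",
            "levels": tuple(bead.levels.levels)}
    return EventTable(data=data, metadata=meta)
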