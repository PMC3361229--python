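"""Synthetic three-class NIR spectrum generator with ground-truth outliers.

Emulates diffuse-reflectance absorbance spectra of ground plant material on
the 4000-12000 cm^-1 grid at 8 cm^-1 spacing: a handful of smooth shared
absorbance bands, a class-sensitive band near 7200 cm^-1, per-sample additive
baseline (offset + linear tilt), multiplicative scatter, and channel noise
that grows above 10000 cm^-1.  Outlying samples of the two kinds a
score/orthogonal-distance diagnosis distinguishes — orthogonal outliers (an
extra band off the common subspace) and leverage points (a grossly scaled
spectrum) — can be injected explicitly, and every injection is recorded in
the returned ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import SpectraSet

DEFAULT_CLASSES = ("parent", "transgenic", "hybrid")

#: Smooth shared absorbance bands (center cm^-1, width cm^-1, amplitude AU),
#: loosely placed at common C-H / O-H / N-H overtone and combination regions.
DEFAULT_SHARED_BANDS = (
    (4350.0, 180.0, 0.45),
    (4750.0, 220.0, 0.30),
    (5200.0, 260.0, 0.38),
    (5800.0, 240.0, 0.25),
    (6900.0, 150.0, 0.20),
    (8400.0, 300.0, 0.10),
)

#: Class-sensitive bands (center cm^-1, width cm^-1, common amplitude AU).
#: Every class shares the bands; the per-class amplitude offsets differ.
#: Two bands with non-proportional offsets keep the three class means
#: non-collinear in feature space — a genotype changes the composition of
#: several constituents, not one constituent along a single dose axis.
DEFAULT_CLASS_BANDS = ((7200.0, 110.0, 0.06), (6400.0, 130.0, 0.04))

#: Per-class amplitude offsets (AU) on the class-sensitive bands, one row
#: per class, one column per band.
DEFAULT_CLASS_EFFECT = ((0.0, 0.0), (0.05, 0.012), (0.10, 0.045))

ORTHOGONAL_BAND_CENTER = 9000.0
ORTHOGONAL_BAND_WIDTH = 60.0

OUTLIER_KINDS = ("orthogonal", "leverage")


@dataclass(frozen=True)
class OutlierSpec:
    """One injected outlier: class, kind, 1-based index within the class,
    and magnitude (band height in AU for orthogonal, scale factor for
    leverage)."""

    class_name: str
    kind: str
    index_in_class: int
    magnitude: float


#: Default contamination pattern: a few orthogonal outliers per class plus
#: one leverage point in the first class, echoing typical screening yields
#: of a few percent per group.
DEFAULT_OUTLIERS = (
    OutlierSpec("parent", "orthogonal", 16, 0.4),
    OutlierSpec("parent", "orthogonal", 19, 0.4),
    OutlierSpec("parent", "leverage", 1, 5.0),
    OutlierSpec("transgenic", "orthogonal", 13, 0.4),
    OutlierSpec("transgenic", "orthogonal", 21, 0.4),
    OutlierSpec("transgenic", "orthogonal", 30, 0.4),
    OutlierSpec("transgenic", "orthogonal", 33, 0.4),
    OutlierSpec("hybrid", "orthogonal", 14, 0.4),
    OutlierSpec("hybrid", "orthogonal", 19, 0.4),
    OutlierSpec("hybrid", "orthogonal", 25, 0.4),
)

DEFAULT_ORTHOGONAL_MAGNITUDE = 0.4


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the study conditions used
    throughout the test-suite and the worked examples."""

    n_per_class: Sequence[int] = (41, 40, 40)
    class_names: Sequence[str] = DEFAULT_CLASSES
    grid: tuple[float, float, float] = (4000.0, 12000.0, 8.0)
    shared_bands: Sequence[tuple[float, float, float]] = DEFAULT_SHARED_BANDS
    class_bands: Sequence[tuple[float, float, float]] = DEFAULT_CLASS_BANDS
    class_effect: Sequence[Sequence[float]] = DEFAULT_CLASS_EFFECT
    baseline_mean: float = 0.05
    baseline_sd: float = 0.02
    tilt_sd: float = 0.01
    drift_sd: float = 0.06
    drift_terms: int = 16
    scatter_sd: float = 0.05
    noise_sd: float = 0.0005
    highband_noise_factor: float = 6.0
    outliers: Sequence[OutlierSpec] = DEFAULT_OUTLIERS
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_class) != len(self.class_names):
            raise ValueError("n_per_class and class_names lengths differ")
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("class counts must be >= 0")
        start, stop, step = self.grid
        if step <= 0 or stop <= start:
            raise ValueError("grid must satisfy stop > start, step > 0")
        for s in (self.baseline_sd, self.tilt_sd, self.drift_sd,
                  self.scatter_sd, self.noise_sd):
            if s < 0:
                raise ValueError("spread parameters must be >= 0")
        if len(self.class_effect) != len(self.class_names):
            raise ValueError("class_effect must give one amplitude-offset "
                             "row per class")
        for row in self.class_effect:
            if np.ndim(row) != 1 or len(row) != len(self.class_bands):
                raise ValueError("each class_effect row must give one "
                                 "offset per class band")
        counts = dict(zip(self.class_names, self.n_per_class))
        for out in self.outliers:
            if out.kind not in OUTLIER_KINDS:
                raise ValueError(f"unknown outlier kind {out.kind!r}; "
                                 f"expected one of {OUTLIER_KINDS}")
            if counts.get(out.class_name, 0) == 0:
                raise ValueError(
                    f"outlier requested in empty/unknown class "
                    f"{out.class_name!r}")
            if not 1 <= out.index_in_class <= counts[out.class_name]:
                raise ValueError(
                    f"outlier index {out.index_in_class} outside class "
                    f"{out.class_name!r} of size {counts[out.class_name]}")


@dataclass
class GroundTruth:
    """Per-sample generation record: true class and injected-outlier kind."""

    class_of: dict
    outlier_of: dict = field(default_factory=dict)

    def outlier_ids(self, kind: Optional[str] = None) -> list:
        return [s for s, k in self.outlier_of.items()
                if kind is None or k == kind]


def _gaussian(w: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - center) / width) ** 2)


def wavenumber_grid(cfg: SynthConfig) -> np.ndarray:
    start, stop, step = cfg.grid
    p = int(np.floor((stop - start) / step)) + 1
    return start + step * np.arange(p)


def generate_spectra(cfg: SynthConfig = SynthConfig()) -> tuple[SpectraSet, GroundTruth]:
    """Draw a full synthetic spectra set plus its ground truth.

    Each clean spectrum is ``scatter * (sum of bands + class effect +
    baseline) + noise``; the noise standard deviation is multiplied by
    ``highband_noise_factor`` above 10000 cm^-1.  The same seed yields
    bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    w = wavenumber_grid(cfg)
    p = len(w)
    n_total = int(sum(cfg.n_per_class))

    shared = np.zeros(p)
    for center, width, amp in cfg.shared_bands:
        shared += amp * _gaussian(w, center, width)
    class_band_shapes = [_gaussian(w, c, wd) for c, wd, _ in cfg.class_bands]
    class_band_amps = [a for _, _, a in cfg.class_bands]

    noise_scale = np.where(w > 10000.0, cfg.highband_noise_factor, 1.0)
    tilt_shape = (w - w.mean()) / (w[-1] - w[0])
    # smooth baseline drift basis: low-frequency cosines over the grid;
    # random per-sample phases make the drift effectively high-rank across
    # samples while staying far too smooth to survive a second derivative
    frac = (w - w[0]) / (w[-1] - w[0])
    drift_j = np.arange(1, cfg.drift_terms + 1)

    X = np.empty((n_total, p))
    labels = np.empty(n_total, dtype=object)
    row = 0
    for cls, n_c, effect in zip(cfg.class_names, cfg.n_per_class,
                                cfg.class_effect):
        if n_c == 0:
            raise ValueError(f"class {cls!r} has no samples")
        base = shared.copy()
        for shape, amp, off in zip(class_band_shapes, class_band_amps,
                                   effect):
            base += (amp + off) * shape
        for _ in range(n_c):
            offset = rng.normal(cfg.baseline_mean, cfg.baseline_sd)
            tilt = rng.normal(0.0, cfg.tilt_sd)
            scatter = rng.normal(1.0, cfg.scatter_sd)
            if cfg.drift_terms > 0 and cfg.drift_sd > 0:
                amps = rng.normal(0.0, cfg.drift_sd / np.sqrt(cfg.drift_terms),
                                  size=cfg.drift_terms)
                phases = rng.uniform(0.0, 2 * np.pi, size=cfg.drift_terms)
                drift = (amps[:, None]
                         * np.cos(np.pi * drift_j[:, None] * frac + phases[:, None])
                         ).sum(axis=0)
            else:
                drift = 0.0
            noise = rng.normal(0.0, cfg.noise_sd, size=p) * noise_scale
            X[row] = (scatter * (base + offset + tilt * tilt_shape + drift)
                      + noise)
            labels[row] = cls
            row += 1

    sample_ids = np.arange(1, n_total + 1)
    data = SpectraSet(w, X, labels.astype(str), sample_ids,
                      {"source": "synthetic", "history": ["raw"]})
    truth = GroundTruth({int(s): str(l) for s, l in zip(sample_ids, labels)})

    # explicit, logged contamination
    for out in cfg.outliers:
        sid = _global_id(cfg, out.class_name, out.index_in_class)
        if out.kind == "orthogonal":
            data = inject_orthogonal_outlier(data, sid, out.magnitude)
        else:
            data = inject_leverage_sample(data, sid, out.magnitude)
        truth.outlier_of[sid] = out.kind
    return data, truth


def _global_id(cfg: SynthConfig, class_name: str, index_in_class: int) -> int:
    offset = 0
    for cls, n_c in zip(cfg.class_names, cfg.n_per_class):
        if cls == class_name:
            return offset + index_in_class
        offset += n_c
    raise KeyError(f"unknown class {class_name!r}")


def _row_of(data: SpectraSet, sample_id) -> int:
    hits = np.flatnonzero(data.sample_ids == sample_id)
    if len(hits) == 0:
        raise KeyError(f"unknown sample_id {sample_id!r}")
    return int(hits[0])


def inject_orthogonal_outlier(data: SpectraSet, sample_id,
                              magnitude: float,
                              center: float = ORTHOGONAL_BAND_CENTER,
                              width: float = ORTHOGONAL_BAND_WIDTH) -> SpectraSet:
    """Add a spurious band (default at 9000 cm^-1) to one sample.

    The band lies off the subspace spanned by the shared bands, so the
    modified sample acquires a large orthogonal distance while its score
    distance stays small.
    """
    i = _row_of(data, sample_id)
    X = data.absorbance.copy()
    X[i] = X[i] + magnitude * _gaussian(data.wavenumbers, center, width)
    return data.with_absorbance(
        X, f"inject_orthogonal(id={sample_id}, magnitude={magnitude:g})")


def inject_leverage_sample(data: SpectraSet, sample_id,
                           factor: float) -> SpectraSet:
    """Scale one spectrum by ``factor`` — an extreme within-subspace
    excursion producing a large score distance."""
    if not factor > 0:
        raise ValueError(f"leverage factor must be > 0, got {factor}")
    i = _row_of(data, sample_id)
    X = data.absorbance.copy()
    X[i] = factor * X[i]
    return data.with_absorbance(
        X, f"inject_leverage(id={sample_id}, factor={factor:g})")
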