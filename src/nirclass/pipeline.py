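"""End-to-end orchestration: simulate (or load) -> per-class robust-PCA
outlier removal -> per-class Kennard-Stone split -> per-variant PLSDA
training and evaluation -> report.

Stage order is fixed: the wavenumber range is restricted first, the outlier
diagnosis runs per class on the raw restricted spectra, excluded samples
never reach the split, the Kennard-Stone split is computed once on the
cleaned raw spectra and shared across all preprocessing variants, and model
selection sees training rows only.  One global seed governs synthesis,
projection directions and MCCV resampling, so a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import SpectraSet, read_spectra_csv, write_spectra_csv, diagnosis_frame
from .preprocessing import PreprocessSpec, restrict_range
from .robust_pca import RPCASettings, diagnose_class
from .sample_split import SplitResult, split_per_class
from .synthetic_data import SynthConfig, generate_spectra
from .evaluation import EvaluationReport, evaluate_variants

log = logging.getLogger(__name__)

DEFAULT_VARIANTS = (
    PreprocessSpec("raw"),
    PreprocessSpec("smooth"),
    PreprocessSpec("second_derivative"),
    PreprocessSpec("snv"),
)


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults mirror the reference workflow
    (significance 0.05, coverage 0.75, 25 training samples per class,
    100 MCCV splits, leave-out 0.3, F-test alpha 0.25)."""

    synth: Optional[SynthConfig] = None
    input_csv: Optional[str] = None
    variants: Sequence[PreprocessSpec] = DEFAULT_VARIANTS
    keep_range: tuple[float, float] = (4000.0, 10000.0)
    rpca: RPCASettings = field(default_factory=RPCASettings)
    train_per_class: int = 25
    k_max: int = 15
    mccv_splits: int = 100
    leave_out_fraction: float = 0.3
    f_alpha: float = 0.25
    seed: int = 0
    outdir: Optional[str] = None

    def validate(self) -> None:
        if self.synth is None and self.input_csv is None:
            raise ValueError("either a synthetic config or an input CSV is "
                             "required")
        if not self.variants:
            raise ValueError("at least one preprocessing variant is required")
        if self.mccv_splits < 1:
            raise ValueError("mccv_splits must be >= 1")
        if self.train_per_class < 2:
            raise ValueError("train_per_class must be >= 2")
        if not 0 < self.leave_out_fraction <= 0.5:
            raise ValueError("leave_out_fraction must lie in (0, 0.5]")
        if self.synth is not None:
            self.synth.validate()


@dataclass
class PipelineResult:
    data: SpectraSet
    clean: SpectraSet
    diagnoses: dict          # class -> RobustPCADiagnosis
    excluded_ids: np.ndarray
    split: SplitResult
    report: EvaluationReport


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    cfg.validate()
    out = Path(cfg.outdir) if cfg.outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # 1. acquire
    if cfg.input_csv is not None:
        data = read_spectra_csv(cfg.input_csv)
    else:
        synth = cfg.synth
        if synth.seed != cfg.seed:
            from dataclasses import replace
            synth = replace(synth, seed=cfg.seed)
        data, _truth = generate_spectra(synth)
    log.info("loaded %d spectra x %d channels", data.n_samples,
             data.n_channels)
    if out:
        write_spectra_csv(data, out / "spectra.csv")

    # 2. range restriction (noisy high-wavenumber region dropped)
    restricted = restrict_range(data, *cfg.keep_range)

    # 3. per-class robust-PCA diagnosis on raw restricted spectra
    diagnoses = {}
    frames = []
    excluded: list = []
    classes = list(dict.fromkeys(restricted.labels.tolist()))
    for ci, cls in enumerate(classes):
        settings = RPCASettings(
            significance=cfg.rpca.significance,
            alpha_coverage=cfg.rpca.alpha_coverage,
            k=cfg.rpca.k, k_max=cfg.rpca.k_max,
            press_folds=cfg.rpca.press_folds,
            press_tol=cfg.rpca.press_tol,
            n_directions=cfg.rpca.n_directions,
            seed=(cfg.seed * 10007 + 101 + ci) % (2 ** 31))
        diag = diagnose_class(restricted, cls, settings)
        diagnoses[cls] = diag
        excluded.extend(diag.excluded_ids.tolist())
        frame = diagnosis_frame(diag)
        frame.insert(1, "class", cls)
        frames.append(frame)
        log.info("class %s: %d samples, %d excluded (k=%d)", cls,
                 len(diag.sample_ids), int(diag.excluded.sum()),
                 diag.model.k)
    if out:
        pd.concat(frames).to_csv(out / "diag.tsv", sep="\t", index=False,
                                 float_format="%.8g")

    # 4. exclusion
    keep_mask = ~np.isin(restricted.sample_ids, excluded)
    clean = restricted.select_samples(keep_mask)
    if out:
        write_spectra_csv(clean, out / "clean.csv")

    # 5. per-class Kennard-Stone split on cleaned raw restricted spectra
    split = split_per_class(clean, cfg.train_per_class)
    train = clean.select_samples(split.train_ids)
    test = clean.select_samples(split.test_ids)
    log.info("split: train %d / test %d (%s)", len(split.train_ids),
             len(split.test_ids), split.per_class)
    if out:
        write_spectra_csv(train, out / "train.csv")
        write_spectra_csv(test, out / "test.csv")

    # 6. per-variant PLSDA training and evaluation
    report = evaluate_variants(
        train, test, cfg.variants, k_max=cfg.k_max,
        leave_out_fraction=cfg.leave_out_fraction,
        n_splits=cfg.mccv_splits, f_alpha=cfg.f_alpha,
        seed=(cfg.seed * 10007 + 777) % (2 ** 31))
    if out:
        report.to_tsv(out / "report.tsv")
        for r in report.rows:
            r.model.save(out / f"model_{r.spec.method}.json")

    return PipelineResult(data=data, clean=clean, diagnoses=diagnoses,
                          excluded_ids=np.array(sorted(excluded)),
                          split=split, report=report)
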