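"""Spectra containers and plain-text readers/writers.

The universal currency between pipeline stages is :class:`SpectraSet`, an
N x p absorbance matrix with a wavenumber axis, class labels and sample ids.
Spectra travel as wide CSV (one row per sample, one column per wavenumber);
outlier-diagnosis tables travel as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file or container violates the spectra-table contract."""


@dataclass
class SpectraSet:
    """A set of absorbance spectra on a common wavenumber grid.

    Parameters
    ----------
    wavenumbers
        Channel positions in cm^-1, strictly monotone increasing, length p.
    absorbance
        N x p matrix of absorbance units.
    labels
        N class names.
    sample_ids
        N unique identifiers (1-based integers by default).
    meta
        Free-form provenance; ``meta["history"]`` records the preprocessing
        chain applied so far.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.labels = np.asarray(self.labels)
        self.sample_ids = np.asarray(self.sample_ids)
        self.meta = dict(self.meta)
        self.meta.setdefault("history", [])
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, p = self.absorbance.shape
        if self.wavenumbers.ndim != 1 or len(self.wavenumbers) != p:
            raise FormatError(
                f"wavenumber axis has {len(self.wavenumbers)} entries but the "
                f"absorbance matrix has {p} columns"
            )
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise FormatError(
                f"{n} spectra but {len(self.labels)} labels / "
                f"{len(self.sample_ids)} sample ids"
            )
        if p > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise FormatError("wavenumbers must be strictly increasing")
        ids, counts = np.unique(self.sample_ids, return_counts=True)
        if np.any(counts > 1):
            dup = ids[counts > 1][0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        if not np.all(np.isfinite(self.absorbance)):
            i, j = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise FormatError(
                f"non-finite absorbance at sample {self.sample_ids[i]!r}, "
                f"wavenumber {self.wavenumbers[j]:g}"
            )

    # -- conveniences ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Unique class labels in sorted order."""
        return np.unique(self.labels)

    def history(self) -> list[str]:
        return list(self.meta.get("history", []))

    def with_absorbance(self, absorbance: np.ndarray, step: str) -> "SpectraSet":
        """Copy with a replaced matrix and a history entry appended."""
        meta = dict(self.meta)
        meta["history"] = self.history() + [step]
        return SpectraSet(self.wavenumbers.copy(), np.asarray(absorbance, float),
                          self.labels.copy(), self.sample_ids.copy(), meta)

    def select_samples(self, mask_or_ids: Iterable) -> "SpectraSet":
        """Row subset by boolean mask or by a collection of sample ids."""
        arr = np.asarray(list(mask_or_ids) if not isinstance(mask_or_ids, np.ndarray)
                         else mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            wanted = set(arr.tolist())
            idx = np.array([i for i, s in enumerate(self.sample_ids)
                            if s in wanted], dtype=int)
            if len(idx) != len(wanted):
                missing = wanted - set(self.sample_ids.tolist())
                raise KeyError(f"unknown sample ids: {sorted(missing)!r}")
        return SpectraSet(self.wavenumbers.copy(), self.absorbance[idx],
                          self.labels[idx], self.sample_ids[idx], dict(self.meta))

    def class_subset(self, label: str) -> "SpectraSet":
        if label not in self.labels:
            raise KeyError(f"unknown class {label!r}")
        return self.select_samples(self.labels == label)


def read_spectra_csv(path) -> SpectraSet:
    """Read a wide spectra CSV (``sample_id,label,<w1>,<w2>,...``)."""
    df = pd.read_csv(path, dtype={0: str, 1: str})
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise FormatError(
            f"{path}: header must start with 'sample_id,label', "
            f"got {list(df.columns[:2])!r}"
        )
    try:
        wavenumbers = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavenumber column header "
                          f"({exc})") from None
    if len(wavenumbers) == 0:
        raise FormatError(f"{path}: no wavenumber columns")
    sample_ids = _coerce_int_ids(df["sample_id"].to_numpy())
    labels = df["label"].to_numpy()
    absorbance = df.iloc[:, 2:].to_numpy(dtype=float)
    if np.any(pd.isna(absorbance)):
        i, j = np.argwhere(pd.isna(absorbance))[0]
        raise FormatError(f"{path}: missing value at sample {sample_ids[i]!r}, "
                          f"wavenumber column {df.columns[2 + j]}")
    data = SpectraSet(wavenumbers, absorbance, labels, sample_ids,
                      {"source": str(path), "history": ["raw"]})
    return data


def _coerce_int_ids(ids: np.ndarray) -> np.ndarray:
    """Sample ids are integers when they look like integers, else strings."""
    try:
        return np.array([int(s) for s in ids])
    except (TypeError, ValueError):
        return np.asarray(ids)


def write_spectra_csv(data: SpectraSet, path) -> None:
    """Write a SpectraSet as wide CSV; round-trips to >= 12 significant digits."""
    data.validate()
    if data.n_samples == 0:
        raise FormatError("refusing to write an empty (N=0) spectra table")
    cols = [f"{w:.10g}" for w in data.wavenumbers]
    df = pd.DataFrame(data.absorbance, columns=cols)
    df.insert(0, "label", data.labels)
    df.insert(0, "sample_id", data.sample_ids)
    df.to_csv(path, index=False, float_format="%.14g")


def write_diagnosis_table(diag, path) -> None:
    """Export a per-sample outlier diagnosis as TSV.

    Columns: ``sample_id  SD  OD  group  excluded`` — the data behind the
    usual score-distance / orthogonal-distance diagnostic plot.
    """
    df = diagnosis_frame(diag)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def diagnosis_frame(diag) -> pd.DataFrame:
    from .robust_pca import GROUPS  # local import to avoid a cycle

    bad = set(diag.group) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown diagnosis group names: {sorted(bad)!r}")
    return pd.DataFrame({
        "sample_id": diag.sample_ids,
        "SD": diag.sd,
        "OD": diag.od,
        "group": diag.group,
        "excluded": diag.excluded,
    })
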