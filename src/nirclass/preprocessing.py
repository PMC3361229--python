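"""Spectral preprocessing: range restriction, Savitzky-Golay smoothing and
second derivative, and standard normal variate (SNV).

The four variants compared downstream are alternatives, not a chain:
``raw`` (range restriction only), ``smooth``, ``second_derivative`` and
``snv``, each applied after restricting to the informative 4000-10000 cm^-1
window (the 10000-12000 cm^-1 region carries mostly detector noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .io import SpectraSet

METHODS = ("raw", "smooth", "second_derivative", "snv")

_DEFAULT_WINDOW = {"smooth": 11, "second_derivative": 15}
_DEFAULT_POLYORDER = {"smooth": 2, "second_derivative": 3}


@dataclass(frozen=True)
class PreprocessSpec:
    """One preprocessing variant.

    window/polyorder defaults depend on the method: 11/2 for smoothing,
    15/3 for the second derivative (standard NIR practice; the comparison
    between variants is qualitative, not sensitive to these).
    """

    method: str = "raw"
    window: int | None = None
    polyorder: int | None = None
    keep_range: tuple[float, float] = (4000.0, 10000.0)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; "
                             f"expected one of {METHODS}")
        lo, hi = self.keep_range
        if not lo < hi:
            raise ValueError(f"keep_range must satisfy lo < hi, got {lo}:{hi}")
        w, o = self.resolved()
        if w is not None:
            if w % 2 == 0:
                raise ValueError(f"window must be odd, got {w}")
            if not w > o:
                raise ValueError(f"window {w} must exceed polyorder {o}")

    def resolved(self) -> tuple[int | None, int | None]:
        """(window, polyorder) with method-specific defaults filled in."""
        if self.method not in _DEFAULT_WINDOW:
            return None, None
        w = self.window if self.window is not None else _DEFAULT_WINDOW[self.method]
        o = (self.polyorder if self.polyorder is not None
             else _DEFAULT_POLYORDER[self.method])
        return w, o


def restrict_range(data: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep channels with lo <= wavenumber <= hi (order preserved)."""
    mask = (data.wavenumbers >= lo) & (data.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"no channels inside [{lo:g}, {hi:g}] cm^-1")
    meta = dict(data.meta)
    meta["history"] = data.history() + [f"restrict_range({lo:g},{hi:g})"]
    return SpectraSet(data.wavenumbers[mask], data.absorbance[:, mask],
                      data.labels.copy(), data.sample_ids.copy(), meta)


def _check_window(window: int, polyorder: int, p: int) -> None:
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > p:
        raise ValueError(f"window {window} exceeds channel count {p}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")


def sg_smooth(data: SpectraSet, window: int = 11, polyorder: int = 2) -> SpectraSet:
    """Per-row Savitzky-Golay smoothing; edges use one-sided polynomial fits."""
    _check_window(window, polyorder, data.n_channels)
    sm = savgol_filter(data.absorbance, window, polyorder, axis=1, mode="interp")
    return data.with_absorbance(sm, f"sg_smooth(w={window},o={polyorder})")


def sg_second_derivative(data: SpectraSet, window: int = 15,
                         polyorder: int = 3) -> SpectraSet:
    """Per-row Savitzky-Golay second derivative in AU * cm^2.

    Requires a uniform wavenumber grid (the derivative step is the channel
    spacing) and polyorder >= 2, since a lower order carries no curvature.
    """
    if polyorder < 2:
        raise ValueError("second derivative needs polyorder >= 2")
    _check_window(window, polyorder, data.n_channels)
    dw = np.diff(data.wavenumbers)
    step = dw.mean()
    if np.any(np.abs(dw - step) > 1e-6 * abs(step)):
        raise ValueError("wavenumber grid is not uniform; cannot take a "
                         "finite-difference derivative")
    d2 = savgol_filter(data.absorbance, window, polyorder, deriv=2,
                       delta=step, axis=1, mode="interp")
    return data.with_absorbance(d2, f"sg_d2(w={window},o={polyorder})")


def snv(data: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-spectrum centering and unit scaling.

    Uses the sample standard deviation (n-1 denominator).  Removes additive
    baseline and multiplicative scatter; every output row has mean 0 and
    standard deviation 1.
    """
    X = data.absorbance
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if len(flat):
        raise ValueError(
            f"constant spectrum (zero variance) for sample "
            f"{data.sample_ids[flat[0]]!r}; SNV undefined")
    return data.with_absorbance((X - mean) / sd, "snv")


def apply_preprocess(data: SpectraSet, spec: PreprocessSpec) -> SpectraSet:
    """Range restriction followed by the chosen row-wise transform."""
    out = restrict_range(data, *spec.keep_range)
    window, polyorder = spec.resolved()
    if spec.method == "raw":
        return out
    if spec.method == "smooth":
        return sg_smooth(out, window, polyorder)
    if spec.method == "second_derivative":
        return sg_second_derivative(out, window, polyorder)
    return snv(out)
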