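"""Spectral preprocessing chain for single-cell Raman spectra.

The chain applied to every cell, in fixed order:
crop -> despike -> Savitzky-Golay smooth -> blank subtraction ->
baseline correction -> normalization.  Despiking precedes smoothing so cosmic
spikes are not smeared into neighbouring pixels; the baseline is estimated
after blank subtraction so it only has to absorb residual cell
autofluorescence.  All operations are purely functional: inputs are never
mutated.

Baseline estimation uses asymmetric least squares (ALS): a Whittaker smoother
whose weights are iteratively reweighted so positive residuals (peaks) are
nearly ignored while the fit hugs the lower envelope of the spectrum.  A
polynomial alternative is provided for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.signal import savgol_filter

from .spectra_io import Ramanome, Spectrum

__all__ = [
    "PreprocessParams",
    "smooth_savgol",
    "remove_spikes",
    "subtract_blank",
    "correct_baseline",
    "als_baseline",
    "normalize",
    "crop",
    "average_spectra",
    "preprocess_ramanome",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable parameters of the preprocessing chain.

    Set ``savgol_window=None``, ``spike_zscore=None``, ``crop_range=None`` or
    ``baseline_method="none"`` to disable the corresponding stage.
    """

    savgol_window: Optional[int] = 11
    savgol_polyorder: int = 3
    baseline_method: Literal["als", "poly", "none"] = "als"
    als_lambda: float = 1e5
    als_p: float = 0.01
    poly_degree: int = 5
    spike_zscore: Optional[float] = 8.0
    normalize_mode: Literal["area", "vector", "none"] = "none"
    crop_range: Optional[tuple] = (300.0, 3500.0)
    subtract_blanks: bool = True

    def __post_init__(self) -> None:
        if self.savgol_window is not None:
            if self.savgol_window % 2 == 0 or self.savgol_window < 5:
                raise ValueError("savgol_window must be odd and >= 5")
            if self.savgol_polyorder >= self.savgol_window:
                raise ValueError("savgol_polyorder must be < savgol_window")
        if self.als_lambda <= 0:
            raise ValueError("als_lambda must be > 0")
        if not 0 < self.als_p < 1:
            raise ValueError("als_p must be in (0, 1)")
        if self.spike_zscore is not None and self.spike_zscore <= 0:
            raise ValueError("spike_zscore must be > 0")


def _require_uniform_axis(s: Spectrum) -> None:
    steps = np.diff(s.wavenumber_cm1)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError(
            "non-uniform wavenumber axis; resample onto a uniform grid first"
        )


def smooth_savgol(s: Spectrum, params: PreprocessParams) -> Spectrum:
    """Savitzky-Golay smoothing (polynomial least-squares in a moving window).

    Exactly reproduces any polynomial of degree <= ``savgol_polyorder``.
    Requires a uniform axis; window must not exceed the spectrum length.
    """
    if params.savgol_window is None:
        return s
    _require_uniform_axis(s)
    if params.savgol_window > len(s):
        raise ValueError("savgol_window exceeds spectrum length")
    y = savgol_filter(s.intensity, params.savgol_window, params.savgol_polyorder)
    return s.with_intensity(y)


def remove_spikes(s: Spectrum, spike_zscore: float | None = 8.0) -> Spectrum:
    """Replace single-pixel cosmic spikes by linear interpolation.

    A pixel is flagged when the modified z-score (median/MAD based) of the
    second difference of the intensity exceeds ``spike_zscore``.  Because a
    noiseless band's curvature can also exceed any MAD-relative threshold,
    only flagged runs at most 4 pixels wide are corrected — cosmic spikes are
    one or two pixels, Raman bands many.  Spike-free spectra pass through
    unchanged.
    """
    if spike_zscore is None:
        return s
    y = s.intensity
    if len(y) < 5:
        raise ValueError("need at least 5 points to despike")
    d2 = np.diff(y, 2)
    mad = np.median(np.abs(d2 - np.median(d2)))
    if mad == 0:
        return s
    z = 0.6745 * (d2 - np.median(d2)) / mad
    flagged = np.zeros(len(y), dtype=bool)
    flagged[1:-1] = np.abs(z) > spike_zscore
    # drop runs wider than a cosmic spike can be
    boundaries = np.flatnonzero(np.diff(np.concatenate(([0], flagged.view(np.int8), [0]))))
    for start, stop in zip(boundaries[::2], boundaries[1::2]):
        if stop - start > 4:
            flagged[start:stop] = False
    if not flagged.any():
        return s
    # grow each run by one pixel so a spiked-but-unflagged neighbour (adjacent
    # spikes can mask each other in the second difference) is never used as an
    # interpolation anchor
    grown = flagged.copy()
    grown[:-1] |= flagged[1:]
    grown[1:] |= flagged[:-1]
    grown[0] = grown[-1] = False
    flagged = grown
    x = s.wavenumber_cm1
    good = ~flagged
    y_clean = y.copy()
    y_clean[flagged] = np.interp(x[flagged], x[good], y[good])
    return s.with_intensity(y_clean)


def subtract_blank(s: Spectrum, blanks: Sequence[Spectrum]) -> Spectrum:
    """Subtract the mean of the blank (medium-only) spectra; empty list is a no-op."""
    if not blanks:
        return s
    for b in blanks:
        if len(b) != len(s) or not np.allclose(
            b.wavenumber_cm1, s.wavenumber_cm1, rtol=1e-9, atol=1e-6
        ):
            raise ValueError("blank axis does not match spectrum axis")
    mean_blank = np.mean([b.intensity for b in blanks], axis=0)
    return s.with_intensity(s.intensity - mean_blank)


def als_baseline(
    y: np.ndarray, lam: float = 1e5, p: float = 0.01, n_iter: int = 10
) -> np.ndarray:
    """Asymmetric least squares baseline (Whittaker smoother, Eilers weights).

    Minimizes sum(w_i (y_i - z_i)^2) + lam * sum((Delta^2 z)^2) with weights
    w_i = p for y_i > z_i and 1 - p for y_i <= z_i, iterated to convergence.
    Small ``p`` makes the fit track the lower envelope under peaks.
    """
    if not 0 < p < 1:
        raise ValueError("als p must be in (0, 1)")
    n = len(y)
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = (lam * (d.T @ d)).tocsc()
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        lhs = (sparse.diags(w) + penalty).tocsc()
        z = splu(lhs).solve(w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def correct_baseline(s: Spectrum, params: PreprocessParams) -> Spectrum:
    """Subtract an estimated smooth background (ALS default, polynomial option)."""
    if params.baseline_method == "none":
        return s
    if len(s) <= 10:
        raise ValueError("spectrum too short for baseline estimation")
    y = s.intensity
    if params.baseline_method == "als":
        base = als_baseline(y, lam=params.als_lambda, p=params.als_p)
    elif params.baseline_method == "poly":
        # iteratively clipped polynomial fit: points above the fit are pulled
        # down to it so peaks do not drag the polynomial up
        x = s.wavenumber_cm1
        t = (x - x[0]) / (x[-1] - x[0])
        work = y.copy()
        for _ in range(10):
            coeffs = np.polynomial.polynomial.polyfit(t, work, params.poly_degree)
            fit = np.polynomial.polynomial.polyval(t, coeffs)
            work = np.minimum(work, fit)
        base = fit
    else:
        raise ValueError(f"unknown baseline method {params.baseline_method!r}")
    return s.with_intensity(y - base)


def normalize(s: Spectrum, mode: Literal["area", "vector", "none"]) -> Spectrum:
    """Normalize to unit trapezoidal area, unit Euclidean norm, or pass through."""
    if mode == "none":
        return s
    if mode == "area":
        denom = np.trapezoid(s.intensity, s.wavenumber_cm1)
    elif mode == "vector":
        denom = float(np.linalg.norm(s.intensity))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return s.with_intensity(s.intensity / denom)


def crop(s: Spectrum, lo_cm1: float, hi_cm1: float) -> Spectrum:
    """Keep points with lo <= wavenumber <= hi (closed interval)."""
    if not lo_cm1 < hi_cm1:
        raise ValueError("crop bounds must satisfy lo < hi")
    mask = (s.wavenumber_cm1 >= lo_cm1) & (s.wavenumber_cm1 <= hi_cm1)
    if not mask.any():
        raise ValueError(f"crop to [{lo_cm1}, {hi_cm1}] leaves no points")
    return Spectrum(s.wavenumber_cm1[mask], s.intensity[mask], dict(s.meta))


def average_spectra(r: Ramanome) -> Spectrum:
    """Pointwise mean spectrum of a ramanome (all cells on a common axis)."""
    if not r.spectra:
        raise ValueError("cannot average an empty ramanome")
    first = r.spectra[0]
    for s in r.spectra[1:]:
        if len(s) != len(first) or not np.allclose(
            s.wavenumber_cm1, first.wavenumber_cm1, rtol=1e-9, atol=1e-6
        ):
            raise ValueError("spectra are not on a common axis")
    mean = np.mean([s.intensity for s in r.spectra], axis=0)
    meta = {**r.condition, "cell_id": "average", "n_averaged": len(r.spectra)}
    return Spectrum(first.wavenumber_cm1, mean, meta)


def _preprocess_one(
    s: Spectrum, blanks: Sequence[Spectrum], params: PreprocessParams
) -> Spectrum:
    if params.crop_range is not None:
        s = crop(s, *params.crop_range)
    s = remove_spikes(s, params.spike_zscore)
    s = smooth_savgol(s, params)
    if params.subtract_blanks:
        s = subtract_blank(s, blanks)
    s = correct_baseline(s, params)
    s = normalize(s, params.normalize_mode)
    return s


def preprocess_ramanome(r: Ramanome, params: PreprocessParams | None = None) -> Ramanome:
    """Apply the full chain to every cell; blanks are cropped/despiked/smoothed
    identically before averaging.  Returns a new ramanome; input untouched."""
    params = params or PreprocessParams()
    prepped_blanks = []
    for b in r.blanks:
        bb = b
        if params.crop_range is not None:
            bb = crop(bb, *params.crop_range)
        bb = remove_spikes(bb, params.spike_zscore)
        bb = smooth_savgol(bb, params)
        prepped_blanks.append(bb)
    cells = []
    for s in r.spectra:
        try:
            cells.append(_preprocess_one(s, prepped_blanks, params))
        except ValueError as exc:
            raise ValueError(f"cell {s.cell_id!r}: {exc}") from exc
    return Ramanome(cells, dict(r.condition), prepped_blanks)
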