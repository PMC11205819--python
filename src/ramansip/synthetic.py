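"""Forward simulator for single-cell Raman spectra with controllable ^15N labeling.

Each simulated cell is a sum of pseudo-Voigt bands on a smooth fluorescence
baseline with additive Gaussian noise and optional single-pixel cosmic spikes.
Isotope labeling is modeled as a two-component isotopologue mixture: a
nitrogen-sensitive band with labeling fraction ``f`` contributes weight
``1 - f`` at its ^14N center and weight ``f`` at its ^15N (red-shifted)
center.  At ``f = 0`` the spectrum is the pure ^14N phenotype; at ``f = 1``
every sensitive band sits fully at its shifted position.

Determinism contract: one root seed; the random stream for cell ``i`` is
derived from ``(seed, i)`` so any single cell is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .spectra_io import BandReference, Ramanome, Spectrum

__all__ = [
    "SimBand",
    "SimulationConfig",
    "pseudo_voigt",
    "apply_isotope_shift",
    "simulate_spectrum",
    "simulate_blank",
    "simulate_ramanome",
    "bands_from_reference",
    "default_config",
]

_BLANK_STREAM_OFFSET = 1_000_000  # keeps blank RNG streams disjoint from cells


@dataclass(frozen=True)
class SimBand:
    """One simulated Raman band (unit-height pseudo-Voigt parameterization)."""

    center_cm1: float
    amplitude: float = 1.0
    fwhm_cm1: float = 12.0
    eta: float = 0.5
    nitrogen_associated: bool = False
    n15_center_cm1: Optional[float] = None

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.fwhm_cm1 <= 0:
            raise ValueError("fwhm must be > 0")
        if not 0 <= self.eta <= 1:
            raise ValueError("eta must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one simulated ramanome.

    Defaults mirror the acquisition they emulate: 300-3500 cm^-1 range at a
    1 cm^-1 step, additive noise at 5% of the unit band amplitude, and
    0.5 cm^-1 cell-to-cell band-center jitter.
    """

    bands: tuple
    grid_lo_cm1: float = 300.0
    grid_hi_cm1: float = 3500.0
    grid_step_cm1: float = 1.0
    baseline_coeffs: tuple = (0.3, 0.2, -0.1)  # polynomial in t=(x-lo)/(hi-lo)
    fluorescence_weight: float = 0.5  # weight of exp(-(x-lo)/1000) term
    noise_sd: float = 0.05
    spike_rate: float = 0.0
    label_fraction: float = 0.0
    center_jitter_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        if not self.bands:
            raise ValueError("band list must be non-empty")
        if not self.grid_lo_cm1 < self.grid_hi_cm1:
            raise ValueError("grid_lo must be < grid_hi")
        if self.grid_step_cm1 <= 0:
            raise ValueError("grid_step must be > 0")
        if len(self.baseline_coeffs) > 6:
            raise ValueError("baseline polynomial degree must be <= 5")
        if self.noise_sd < 0 or self.spike_rate < 0 or self.center_jitter_sd < 0:
            raise ValueError("noise_sd, spike_rate, center_jitter_sd must be >= 0")
        if not 0 <= self.label_fraction <= 1:
            raise ValueError("label_fraction must be in [0, 1]")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_hi_cm1 - self.grid_lo_cm1) / self.grid_step_cm1)) + 1
        return self.grid_lo_cm1 + self.grid_step_cm1 * np.arange(n)


def pseudo_voigt(
    x: np.ndarray, center: float, amplitude: float, fwhm: float, eta: float
) -> np.ndarray:
    """Unit-peak-height pseudo-Voigt: eta * Lorentzian + (1 - eta) * Gaussian.

    Gaussian and Lorentzian share the same full width at half maximum, the
    convention of the "GaussLor" profile used by Raman instrument software.
    """
    u = (x - center) / fwhm
    lorentz = 1.0 / (1.0 + 4.0 * u * u)
    gauss = np.exp(-4.0 * np.log(2.0) * u * u)
    return amplitude * (eta * lorentz + (1.0 - eta) * gauss)


def apply_isotope_shift(bands: Sequence[SimBand], f: float) -> list[SimBand]:
    """Split nitrogen-sensitive bands into a ^14N/^15N isotopologue mixture.

    A band with an ^15N center is replaced by up to two sub-bands: weight
    ``1 - f`` at the ^14N center and weight ``f`` at the ^15N center (widths
    and shape factors preserved; zero-weight sub-bands are dropped, so
    ``f = 0`` returns the input unchanged).  Total amplitude is conserved for
    every ``f``.
    """
    if not 0 <= f <= 1:
        raise ValueError(f"labeling fraction must be in [0, 1], got {f}")
    out: list[SimBand] = []
    for b in bands:
        if b.n15_center_cm1 is None or f == 0:
            out.append(b)
            continue
        if f < 1:
            out.append(replace(b, amplitude=b.amplitude * (1 - f)))
        out.append(
            replace(b, center_cm1=b.n15_center_cm1, amplitude=b.amplitude * f)
        )
    return out


def _baseline(config: SimulationConfig, x: np.ndarray) -> np.ndarray:
    t = (x - config.grid_lo_cm1) / (config.grid_hi_cm1 - config.grid_lo_cm1)
    base = np.polynomial.polynomial.polyval(t, config.baseline_coeffs)
    base = base + config.fluorescence_weight * np.exp(
        -(x - config.grid_lo_cm1) / 1000.0
    )
    return base


def _cell_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _noise_and_spikes(
    rng: np.random.Generator, config: SimulationConfig, n: int
) -> np.ndarray:
    y = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    if config.spike_rate > 0:
        n_spikes = rng.poisson(config.spike_rate)
        for _ in range(n_spikes):
            idx = rng.integers(0, n)
            scale = config.noise_sd if config.noise_sd > 0 else 0.01
            y[idx] += rng.uniform(10.0, 50.0) * scale
    return y


def simulate_spectrum(
    config: SimulationConfig, cell_index: int, meta: dict | None = None
) -> Spectrum:
    """Simulate one cell: bands + baseline + noise (+ cosmic spikes).

    Per-cell band-center jitter is drawn once per physical band and applied
    to both isotopologue sub-bands, so the ^14N -> ^15N separation is exact
    for every cell.  Deterministic given ``(config.seed, cell_index)``.
    """
    x = config.grid
    rng = _cell_rng(config.seed, cell_index)
    jitter = rng.normal(0.0, config.center_jitter_sd, size=len(config.bands))
    jittered = [
        replace(
            b,
            center_cm1=b.center_cm1 + dj,
            n15_center_cm1=None if b.n15_center_cm1 is None else b.n15_center_cm1 + dj,
        )
        for b, dj in zip(config.bands, jitter)
    ]
    mixture = apply_isotope_shift(jittered, config.label_fraction)
    y = _baseline(config, x)
    for b in mixture:
        y = y + pseudo_voigt(x, b.center_cm1, b.amplitude, b.fwhm_cm1, b.eta)
    y = y + _noise_and_spikes(rng, config, len(x))
    meta = dict(meta or {})
    meta.setdefault("cell_id", f"cell_{cell_index:03d}")
    return Spectrum(x, y, meta)


def simulate_blank(
    config: SimulationConfig, blank_index: int, meta: dict | None = None
) -> Spectrum:
    """Simulate one blank region: baseline + noise only, no cellular bands."""
    x = config.grid
    rng = _cell_rng(config.seed, _BLANK_STREAM_OFFSET + blank_index)
    y = _baseline(config, x) + _noise_and_spikes(rng, config, len(x))
    meta = dict(meta or {})
    meta.setdefault("cell_id", f"blank_{blank_index:03d}")
    meta["organism"] = "blank"
    meta["isotope"] = "none"
    return Spectrum(x, y, meta)


def simulate_ramanome(
    config: SimulationConfig,
    n_cells: int = 20,
    n_blanks: int = 4,
    organism: str = "ruegeria",
    isotope: str | None = None,
    replicate: int = 1,
) -> Ramanome:
    """Simulate one condition: ``n_cells`` cells plus ``n_blanks`` blanks.

    The default sizes (20 cells, 4 blanks) match the standard per-sample
    acquisition.  ``isotope`` defaults to N15 when any labeling is simulated.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_blanks < 0:
        raise ValueError("n_blanks must be >= 0")
    if isotope is None:
        isotope = "N15" if config.label_fraction > 0 else "N14"
    meta = {"organism": organism, "isotope": isotope, "replicate": replicate}
    cells = [simulate_spectrum(config, i, dict(meta)) for i in range(n_cells)]
    blanks = [simulate_blank(config, j) for j in range(n_blanks)]
    return Ramanome(cells, {"organism": organism, "isotope": isotope}, blanks)


def bands_from_reference(
    reference: BandReference,
    amplitude: float = 1.0,
    fwhm_cm1: float = 12.0,
    eta: float = 0.5,
) -> list[SimBand]:
    """Turn a band-reference table into simulator bands (uniform shape defaults)."""
    bands = []
    for row in reference:
        n15 = row.n15_center_cm1
        bands.append(
            SimBand(
                center_cm1=float(row.center_cm1),
                amplitude=amplitude,
                fwhm_cm1=fwhm_cm1,
                eta=eta,
                nitrogen_associated=bool(row.nitrogen_associated),
                n15_center_cm1=None if np.isnan(n15) else float(n15),
            )
        )
    return bands


def default_config(
    reference: BandReference,
    label_fraction: float = 0.0,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Standard study-condition config for an organism's reference bands."""
    return SimulationConfig(
        bands=tuple(bands_from_reference(reference)),
        label_fraction=label_fraction,
        seed=seed,
        **overrides,
    )
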