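"""Stick-spectrum scaling, Gaussian broadening, and uncertainty bands.

A computed IR spectrum is a list of (wavenumber, intensity) sticks.  Scale
factors shift the sticks; a Gaussian convolution then produces a continuous
trace comparable to experiment.  Broadening is amplitude-preserving: an
isolated peak's height equals its stick intensity (band positions and
shapes, not absolute absorbance, are what get compared against normalised
experimental traces).

Hybrid scaling applies the absolute factor to the X-H stretching region
(at or above a threshold, default 2000 cm^-1) and the relative factor to
the fingerprint region below it, the combination found to work best in
each region.  The region decision uses the UNSCALED wavenumber.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import EmptySpectrumError, InvalidScaleError, SchemaError

__all__ = [
    "StickSpectrum",
    "BroadenedSpectrum",
    "scale_uniform",
    "scale_hybrid",
    "gaussian_broaden",
    "uncertainty_band",
    "read_stick_spectrum",
    "write_spectrum",
]

# FWHM^2 = 8 ln2 sigma^2 for a Gaussian; the lineshape is written directly
# in terms of FWHM: exp(-4 ln2 (nu - nu0)^2 / FWHM^2).
_FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass
class StickSpectrum:
    """Line list: wavenumbers (cm^-1, > 0) and intensities (>= 0, a.u.)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities differ in length")
        if np.any(self.wavenumbers <= 0):
            raise ValueError("all wavenumbers must be > 0")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")

    @classmethod
    def from_lines(cls, lines: Iterable[tuple[float, float]], label: str = ""):
        arr = np.array(list(lines), dtype=float).reshape(-1, 2)
        return cls(arr[:, 0], arr[:, 1], label=label)

    @property
    def lines(self) -> list[tuple[float, float]]:
        return list(zip(self.wavenumbers.tolist(), self.intensities.tolist()))

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass
class BroadenedSpectrum:
    """Intensity evaluated on a uniform, strictly increasing wavenumber grid."""

    grid: np.ndarray
    intensity: np.ndarray
    fwhm: float
    label: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.shape != self.intensity.shape:
            raise ValueError("grid and intensity differ in length")
        if self.grid.size >= 2:
            steps = np.diff(self.grid)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
                raise ValueError("grid must be uniform and strictly increasing")


def _check_scale(s: float, name: str = "s") -> None:
    if not s > 0:
        raise InvalidScaleError(f"{name} must be > 0, got {s}")


def scale_uniform(spec: StickSpectrum, s: float) -> StickSpectrum:
    """Multiply every stick wavenumber by s; intensities unchanged."""
    _check_scale(s)
    return StickSpectrum(spec.wavenumbers * s, spec.intensities.copy(),
                         label=spec.label)


def scale_hybrid(
    spec: StickSpectrum,
    s_abs: float,
    s_rel: float,
    threshold: float = 2000.0,
) -> StickSpectrum:
    """Region-dependent scaling of a stick spectrum.

    Sticks whose unscaled wavenumber is at or above ``threshold`` (cm^-1)
    are multiplied by ``s_abs`` (absolute scaling, best in the X-H
    stretching region); sticks below it by ``s_rel`` (relative scaling,
    best in the fingerprint region).  The boundary is closed above:
    a line exactly at the threshold takes ``s_abs``.
    """
    _check_scale(s_abs, "s_abs")
    _check_scale(s_rel, "s_rel")
    _check_scale(threshold, "threshold")
    factor = np.where(spec.wavenumbers >= threshold, s_abs, s_rel)
    return StickSpectrum(spec.wavenumbers * factor, spec.intensities.copy(),
                         label=spec.label)


def gaussian_broaden(
    spec: StickSpectrum,
    fwhm: float,
    grid_step: float | None = None,
    pad: float | None = None,
) -> BroadenedSpectrum:
    """Convolve a stick spectrum with Gaussians of the given FWHM.

    The trace is the superposition

        I(nu) = sum_k A_k exp(-4 ln2 (nu - nu_k)^2 / FWHM^2)

    evaluated on a uniform grid spanning [min(nu_k) - pad, max(nu_k) + pad].
    Amplitude-preserving: an isolated peak reaches its stick intensity and
    falls to half of it at +-FWHM/2.

    Defaults ``grid_step = fwhm/10`` (resolves the lineshape) and
    ``pad = 5*fwhm`` (captures > 99.99% of each Gaussian's area).
    """
    if len(spec) == 0:
        raise EmptySpectrumError("cannot broaden an empty spectrum")
    if not fwhm > 0:
        raise InvalidScaleError(f"fwhm must be > 0, got {fwhm}")
    if grid_step is None:
        grid_step = fwhm / 10.0
    if pad is None:
        pad = 5.0 * fwhm
    if not grid_step > 0:
        raise InvalidScaleError(f"grid_step must be > 0, got {grid_step}")

    lo = spec.wavenumbers.min() - pad
    hi = spec.wavenumbers.max() + pad
    n = int(np.ceil((hi - lo) / grid_step))
    grid = lo + grid_step * np.arange(n + 1)

    # (n_grid, n_lines) outer difference; fine for typical line counts
    delta = grid[:, None] - spec.wavenumbers[None, :]
    profile = np.exp(-_FOUR_LN2 * delta**2 / fwhm**2)
    intensity = profile @ spec.intensities
    return BroadenedSpectrum(grid=grid, intensity=intensity, fwhm=fwhm,
                             label=spec.label)


def uncertainty_band(
    spec: BroadenedSpectrum, armsd: float
) -> tuple[BroadenedSpectrum, BroadenedSpectrum]:
    """Rigid +-aRMSD shifts of a broadened trace along the wavenumber axis.

    The aRMSD of a scale-factor fit quantifies the expected deviation of
    scaled band positions from experiment, so the band envelope for peak
    position is the trace shifted left and right by that amount.  Returns
    ``(shifted_down, shifted_up)``.
    """
    if armsd < 0:
        raise InvalidScaleError(f"armsd must be >= 0, got {armsd}")
    down = BroadenedSpectrum(spec.grid - armsd, spec.intensity.copy(),
                             fwhm=spec.fwhm, label=spec.label)
    up = BroadenedSpectrum(spec.grid + armsd, spec.intensity.copy(),
                           fwhm=spec.fwhm, label=spec.label)
    return down, up


# ---------------------------------------------------------------------------
# I/O: two-column text, '#' comments, whitespace/comma separated
# ---------------------------------------------------------------------------

def read_stick_spectrum(path: str | Path, label: str | None = None) -> StickSpectrum:
    """Read a two-column (wavenumber, intensity) CSV/TSV stick spectrum."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise SchemaError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise EmptySpectrumError(f"{path}: no spectral lines found")
    return StickSpectrum.from_lines(rows, label=label or str(path))


def write_spectrum(spec: StickSpectrum | BroadenedSpectrum, dest) -> None:
    """Write a spectrum as two-column TSV (wavenumber_cm-1, intensity).

    ``dest`` may be a path or an open text stream.
    """
    if isinstance(spec, BroadenedSpectrum):
        x, y = spec.grid, spec.intensity
    else:
        x, y = spec.wavenumbers, spec.intensities

    def _dump(fh):
        fh.write("# wavenumber_cm-1\tintensity\n")
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.6f}\t{yi:.8g}\n")

    if hasattr(dest, "write"):
        _dump(dest)
    else:
        with open(dest, "w") as fh:
            _dump(fh)
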