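"""1D NMR spectra: containers, delimited-text I/O, resampling, peak support.

A spectrum is a pair of equal-length vectors — frequencies in ppm on a
strictly ascending uniform grid, and nonnegative intensities.  The ppm axis
is stored ascending internally even though NMR spectra are conventionally
plotted with ppm decreasing to the right; readers reverse descending input
and writers emit ascending values, so there is exactly one canonical
orientation inside the package.

Peak support is the set of grid frequencies whose intensity strictly
exceeds a threshold ``tau``; it is what predicted chemical shifts are
aligned against.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "PeakSupport",
    "SpectrumError",
    "SpectrumFormatError",
    "NonUniformGridError",
    "NoPeaksAboveThreshold",
    "read_spectrum",
    "write_spectrum",
    "resample_to_grid",
    "threshold_peaks",
]

#: relative tolerance on grid-spacing deviations before a grid is rejected
GRID_RTOL = 1e-6


class SpectrumError(ValueError):
    """Invalid spectrum data."""


class SpectrumFormatError(SpectrumError):
    """A spectrum file could not be parsed."""


class NonUniformGridError(SpectrumError):
    """Frequency axis is not uniformly spaced; resample explicitly."""


class NoPeaksAboveThreshold(SpectrumError):
    """No intensity exceeds the peak-picking threshold tau."""


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """A 1D NMR spectrum on a uniform ppm grid.

    Parameters
    ----------
    frequencies : ndarray
        Strictly ascending, uniformly spaced ppm values, length >= 2.
    intensities : ndarray
        Nonnegative intensities, same length as `frequencies`.
    label : str, optional
        Opaque identifier (file stem, query name, ...).
    """

    frequencies: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.frequencies, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "frequencies", x)
        object.__setattr__(self, "intensities", y)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise SpectrumError(
                "frequencies and intensities must be 1D vectors of equal length"
            )
        if x.size < 2:
            raise SpectrumError(f"too few points: need at least 2, got {x.size}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise SpectrumError("spectrum contains non-finite values")
        d = np.diff(x)
        if np.any(d <= 0):
            raise SpectrumError("frequencies must be strictly ascending")
        step = (x[-1] - x[0]) / (x.size - 1)
        if np.max(np.abs(d - step)) > GRID_RTOL * step:
            raise NonUniformGridError(
                "frequency grid is not uniform within tolerance; "
                "resample_to_grid() must be applied explicitly"
            )
        if np.min(y) < 0:
            raise SpectrumError("intensities must be nonnegative")

    @property
    def grid_step(self) -> float:
        """Uniform grid spacing in ppm."""
        x = self.frequencies
        return float((x[-1] - x[0]) / (x.size - 1))

    def __len__(self) -> int:
        return int(self.frequencies.size)


@dataclasses.dataclass(frozen=True)
class PeakSupport:
    """Frequencies whose intensity lies strictly above a threshold.

    Attributes
    ----------
    threshold : float
        The peak-picking threshold tau (intensity units).
    support : ndarray
        Ascending subset of the spectrum's frequencies with y > tau.
    """

    threshold: float
    support: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.support, dtype=float)
        object.__setattr__(self, "support", s)
        if s.size == 0:
            raise NoPeaksAboveThreshold(
                f"no peaks above threshold tau={self.threshold}"
            )

    def __len__(self) -> int:
        return int(self.support.size)


def _sniff_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # any whitespace


def read_spectrum(
    path: str | Path,
    dialect: str = "auto",
    normalize: bool = True,
    label: str | None = None,
) -> Spectrum:
    """Read a two-column (ppm, intensity) delimited text file.

    The delimiter (comma, tab or whitespace) is auto-detected unless
    `dialect` forces one of ``csv``/``tsv``.  A single non-numeric header
    line is tolerated.  Input in descending ppm order is reversed to the
    canonical ascending orientation.

    Parameters
    ----------
    path : path-like
    dialect : {"auto", "csv", "tsv"}
    normalize : bool
        If True (default), divide intensities by their maximum so the
        strongest point has intensity 1.  The default peak threshold
        tau = 0.05 is defined on this normalized scale.
    label : str, optional
        Defaults to the file stem.
    """
    path = Path(path)
    if dialect not in ("auto", "csv", "tsv"):
        raise ValueError(f"unknown spectrum dialect: {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    rows: list[tuple[float, float]] = []
    delim = {"csv": ",", "tsv": "\t"}.get(dialect)
    sniffed = dialect != "auto"
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if not sniffed:
                delim = _sniff_delimiter(line)
                sniffed = True
            parts = line.split(delim) if delim else line.split()
            parts = [p for p in (q.strip() for q in parts) if p]
            if len(parts) < 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # single header line
                raise SpectrumFormatError(
                    f"{path}:{lineno}: non-numeric value in {parts[:2]!r}"
                ) from None
    if len(rows) < 2:
        raise SpectrumError(
            f"too few points in {path}: need at least 2 numeric rows, got {len(rows)}"
        )
    arr = np.array(rows, dtype=float)
    x, y = arr[:, 0], arr[:, 1]
    if x[0] > x[-1]:  # descending ppm convention on disk
        x, y = x[::-1].copy(), y[::-1].copy()
    if np.min(y) < 0:
        raise SpectrumFormatError(
            f"{path}: negative intensities present; baseline-correct before loading"
        )
    if normalize:
        ymax = float(np.max(y))
        if ymax <= 0:
            raise SpectrumError(f"{path}: all intensities are zero")
        y = y / ymax
    return Spectrum(x, y, label=label if label is not None else path.stem)


def write_spectrum(spectrum: Spectrum, path: str | Path, precision: int = 6) -> None:
    """Write a spectrum as tab-separated ``ppm\\tintensity`` with a header."""
    path = Path(path)
    fmt = f"%.{precision}f"
    with path.open("w") as fh:
        fh.write("ppm\tintensity\n")
        for x, y in zip(spectrum.frequencies, spectrum.intensities):
            fh.write(f"{fmt % x}\t{fmt % y}\n")


def resample_to_grid(spectrum: Spectrum, step: float) -> Spectrum:
    """Linearly interpolate a spectrum onto a uniform grid of spacing `step`.

    The new grid starts at the spectrum's minimum frequency and extends in
    steps of `step` up to (at most) its maximum; when `step` divides the
    span both endpoints are preserved exactly.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    x = spectrum.frequencies
    span = float(x[-1] - x[0])
    if step > span:
        raise SpectrumError(
            f"resampling step {step} exceeds spectrum span {span:.6g} ppm"
        )
    n = int(np.floor(span / step + 1e-9))
    grid = x[0] + step * np.arange(n + 1)
    y = np.interp(grid, x, spectrum.intensities)
    return Spectrum(grid, y, label=spectrum.label)


def threshold_peaks(spectrum: Spectrum, tau: float) -> PeakSupport:
    """Peak support: frequencies with intensity strictly above `tau`.

    Raises
    ------
    NoPeaksAboveThreshold
        If no intensity exceeds `tau`; callers scoring a candidate pool
        must treat this as a query-level failure, not a per-candidate one.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    mask = spectrum.intensities > tau
    return PeakSupport(threshold=float(tau), support=spectrum.frequencies[mask])
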