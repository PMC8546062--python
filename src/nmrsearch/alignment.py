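"""Alignment of predicted chemical shifts onto a spectrum's peak support.

Predicted shifts carry systematic errors of a ppm or more; before any
lineshape fitting they are snapped onto frequencies where the query
spectrum actually shows intensity.  The rule: the smallest shift goes to
the minimum of the above-threshold support, the largest to its maximum,
and every interior shift to its nearest support frequency.  Pinning the
extremes anchors the candidate's spectral span to the query's span; the
nearest-value rule absorbs moderate prediction error elsewhere.

The aligned vector is *not* re-sorted: the nearest-value rule can invert
the order of close interior shifts, and the ordering penalty in the
fitting objective is what discourages (but does not forbid) such
inversions.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from nmrsearch.shifts import ShiftSet
from nmrsearch.spectra import PeakSupport

__all__ = ["AlignmentResult", "align"]


@dataclasses.dataclass(frozen=True)
class AlignmentResult:
    """Aligned shifts and their per-element displacement.

    Attributes
    ----------
    aligned : ndarray
        Aligned shifts, ppm; every element is a member of the peak support
        used.  Positional order follows the source shifts.
    displacement : ndarray
        Elementwise ``|aligned - source|`` in ppm.
    """

    aligned: np.ndarray
    displacement: np.ndarray

    @property
    def max_displacement(self) -> float:
        return float(np.max(self.displacement))


def _nearest(values: np.ndarray, support: np.ndarray) -> np.ndarray:
    # nearest support element; exact midpoint ties go to the lower frequency
    idx = np.searchsorted(support, values)
    lo = np.clip(idx - 1, 0, support.size - 1)
    hi = np.clip(idx, 0, support.size - 1)
    d_lo = np.abs(values - support[lo])
    d_hi = np.abs(support[hi] - values)
    return np.where(d_lo <= d_hi, support[lo], support[hi])


def align(delta: ShiftSet | np.ndarray, peaks: PeakSupport) -> AlignmentResult:
    """Align predicted shifts to the above-threshold frequencies.

    Parameters
    ----------
    delta : ShiftSet or array
        Predicted chemical shifts, ascending.
    peaks : PeakSupport
        Nonempty above-threshold support of the query spectrum.

    Notes
    -----
    For a single shift (m = 1) the endpoint rules would name two targets;
    it is aligned to its nearest support element instead, the least
    displacement consistent with the interior rule.
    """
    shifts = delta.shifts if isinstance(delta, ShiftSet) else np.asarray(delta, float)
    if shifts.size == 0:
        raise ValueError("cannot align an empty shift set")
    support = peaks.support
    if support.size == 0:
        raise ValueError("peak support is empty")
    if shifts.size == 1:
        aligned = _nearest(shifts, support)
    else:
        aligned = np.empty_like(shifts)
        aligned[0] = support[0]
        aligned[-1] = support[-1]
        if shifts.size > 2:
            aligned[1:-1] = _nearest(shifts[1:-1], support)
    return AlignmentResult(aligned=aligned, displacement=np.abs(aligned - shifts))
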