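"""Matching score of a candidate molecule against a query spectrum.

The score pipeline per candidate: align the predicted shifts Delta onto
the query's peak support, apply two cheap filters, and only then run the
expensive lineshape fit.

Filter 1 (alignment distance): abstain if max_i |delta'_i - delta_i| > theta.
Filter 2 (peak coverage): abstain if some above-threshold frequency lies
farther than theta from every aligned shift.

A filtered (or unpredictable) candidate scores -C for a large constant C,
so it can never outrank a fitted candidate.  Otherwise

    score = cossim(y, yhat) - alpha * ||Delta* - Delta||

with Delta* the optimized peak centers; the penalty term keeps a
candidate from scoring well merely by scattering many shifts that the
optimizer then drags onto the query's peaks.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from nmrsearch.alignment import align
from nmrsearch.estimation import (
    EstimatedSpectrum,
    OptimizeConfig,
    cosine_similarity,
    optimize,
)
from nmrsearch.shifts import PROVENANCE_ORDER, ShiftSet
from nmrsearch.spectra import PeakSupport, Spectrum, threshold_peaks

__all__ = [
    "ScoringConfig",
    "MatchResult",
    "filter_alignment_distance",
    "filter_peak_coverage",
    "score_candidate",
    "best_of_predictions",
]


@dataclasses.dataclass(frozen=True)
class ScoringConfig:
    """The five method hyperparameters plus optimizer settings.

    tau : peak threshold on (normalized) intensity.
    theta : alignment tolerance, ppm, used by both filters.
    alpha : strength of the shift-displacement penalty.
    big_C : magnitude of the abstention score.
    norm : "l2" or "l1" norm for ||Delta* - Delta|| in the score.
    """

    tau: float = 0.05
    theta: float = 10.0
    alpha: float = 0.05
    big_C: float = 1e6
    norm: str = "l2"
    opt: OptimizeConfig = dataclasses.field(default_factory=OptimizeConfig)

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.big_C <= 0:
            raise ValueError("big_C must be positive")
        if self.norm not in ("l2", "l1"):
            raise ValueError("norm must be 'l2' or 'l1'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringConfig":
        """Load a flat YAML config (keys tau, theta, alpha, big_C, h, epsilon, ...)."""
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        # YAML 1.1 reads "1.0e6" (no sign) as a string; coerce numeric fields
        for key, value in raw.items():
            if key not in ("norm", "gradient") and isinstance(value, str):
                raw[key] = float(value)
        opt_keys = {f.name for f in dataclasses.fields(OptimizeConfig)}
        top_keys = {"tau", "theta", "alpha", "big_C", "norm"}
        unknown = set(raw) - opt_keys - top_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        opt = OptimizeConfig(**{k: v for k, v in raw.items() if k in opt_keys})
        return cls(opt=opt, **{k: v for k, v in raw.items() if k in top_keys})

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "tau": self.tau,
            "theta": self.theta,
            "alpha": self.alpha,
            "big_C": self.big_C,
            "norm": self.norm,
            "h": self.opt.h,
            "epsilon": self.opt.epsilon,
        }
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclasses.dataclass(frozen=True)
class MatchResult:
    """Per-candidate outcome of the scoring pipeline."""

    molecule_id: str
    provenance: str
    score: float
    filtered: bool
    filter_reason: str | None = None
    cossim_value: float | None = None
    alignment_penalty: float | None = None
    shifts: np.ndarray | None = None
    aligned: np.ndarray | None = None
    optimized: np.ndarray | None = None
    estimate: EstimatedSpectrum | None = None


def filter_alignment_distance(
    delta: np.ndarray, aligned: np.ndarray, theta: float
) -> bool:
    """True iff the largest alignment displacement strictly exceeds theta."""
    delta = np.asarray(delta, dtype=float)
    aligned = np.asarray(aligned, dtype=float)
    if delta.shape != aligned.shape:
        raise ValueError("delta and aligned must share a length")
    return bool(np.max(np.abs(aligned - delta)) > theta)


def filter_peak_coverage(
    aligned: np.ndarray, peaks: PeakSupport, theta: float
) -> bool:
    """True iff some above-threshold frequency is > theta from every aligned shift."""
    aligned = np.asarray(aligned, dtype=float)
    if aligned.size == 0:
        raise ValueError("aligned shift list is empty")
    dist = np.abs(peaks.support[:, None] - aligned[None, :]).min(axis=1)
    return bool(np.max(dist) > theta)


def _filtered(shift_set: ShiftSet | None, reason: str, cfg: ScoringConfig,
              molecule_id: str = "", **extra) -> MatchResult:
    return MatchResult(
        molecule_id=shift_set.molecule_id if shift_set is not None else molecule_id,
        provenance=shift_set.provenance if shift_set is not None else "other",
        score=-cfg.big_C,
        filtered=True,
        filter_reason=reason,
        **extra,
    )


def score_candidate(
    shift_set: ShiftSet | None,
    query: Spectrum,
    cfg: ScoringConfig | None = None,
    peaks: PeakSupport | None = None,
    molecule_id: str = "",
) -> MatchResult:
    """Score one shift set against a query spectrum.

    Parameters
    ----------
    shift_set : ShiftSet or None
        None marks an unpredictable molecule, which scores -C.
    peaks : PeakSupport, optional
        Precomputed support at cfg.tau; computed here when absent.  An
        empty support raises (a query-level failure — the whole search is
        meaningless without peaks), it is never a per-candidate -C.
    """
    cfg = cfg if cfg is not None else ScoringConfig()
    if peaks is None:
        peaks = threshold_peaks(query, cfg.tau)
    if shift_set is None or shift_set.m == 0:
        return _filtered(shift_set, "unpredictable", cfg, molecule_id=molecule_id)

    result = align(shift_set, peaks)
    common = dict(shifts=shift_set.shifts, aligned=result.aligned)
    if filter_alignment_distance(shift_set.shifts, result.aligned, cfg.theta):
        return _filtered(shift_set, "alignment_distance", cfg, **common)
    if filter_peak_coverage(result.aligned, peaks, cfg.theta):
        return _filtered(shift_set, "peak_coverage", cfg, **common)

    opt = optimize(result.aligned, query, cfg.opt)
    cos = cosine_similarity(query.intensities, opt.estimate.intensities)
    diff = opt.delta_star - shift_set.shifts
    penalty = float(np.linalg.norm(diff) if cfg.norm == "l2" else np.sum(np.abs(diff)))
    return MatchResult(
        molecule_id=shift_set.molecule_id,
        provenance=shift_set.provenance,
        score=cos - cfg.alpha * penalty,
        filtered=False,
        cossim_value=cos,
        alignment_penalty=penalty,
        optimized=opt.delta_star,
        estimate=opt.estimate,
        **common,
    )


def _provenance_rank(provenance: str) -> int:
    try:
        return PROVENANCE_ORDER.index(provenance)
    except ValueError:
        return len(PROVENANCE_ORDER)


def best_of_predictions(
    shift_sets: list[ShiftSet],
    query: Spectrum,
    cfg: ScoringConfig | None = None,
    peaks: PeakSupport | None = None,
) -> MatchResult:
    """Score every available prediction of one molecule; keep the best.

    A molecule may carry several shift sets (annotated table values,
    different predictors); the one with the higher matching score wins.
    Exact ties go to the earlier provenance in (table, hose, mpnn, other).
    """
    if not shift_sets:
        raise ValueError("shift_sets must be nonempty")
    ids = {ss.molecule_id for ss in shift_sets}
    if len(ids) > 1:
        raise ValueError(f"mixed molecule ids in one candidate: {sorted(ids)}")
    results = [score_candidate(ss, query, cfg, peaks=peaks) for ss in shift_sets]
    return min(results, key=lambda r: (-r.score, _provenance_rank(r.provenance)))
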