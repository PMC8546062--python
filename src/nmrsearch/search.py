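"""Ranking a candidate pool against a query spectrum, and top-K evaluation.

The search is an argmax of the matching score over the pool; in practice
the whole ranked list is kept so retrieval can be evaluated at several
depths K.  Candidates are scored independently, so pool order never
affects the result and scoring parallelizes trivially.
"""

from __future__ import annotations

import concurrent.futures
import dataclasses
import logging
import time
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from nmrsearch.scoring import (
    MatchResult,
    ScoringConfig,
    best_of_predictions,
    score_candidate,
)
from nmrsearch.shifts import ShiftSet
from nmrsearch.spectra import Spectrum, threshold_peaks

__all__ = [
    "RankedList",
    "EvalReport",
    "rank_candidates",
    "top_k_accuracy",
    "write_ranking",
    "format_ranking",
]

logger = logging.getLogger(__name__)

DEFAULT_KS = (1, 2, 3, 5, 10)


@dataclasses.dataclass(frozen=True)
class RankedList:
    """Candidates of one query sorted by score (descending)."""

    query_label: str
    entries: tuple[MatchResult, ...]
    rank_of: dict[str, int]

    def rank(self, molecule_id: str) -> int:
        """1-based rank of a molecule; KeyError if absent from the pool."""
        return self.rank_of[molecule_id]


@dataclasses.dataclass(frozen=True)
class EvalReport:
    """Retrieval evaluation: per-query ranks and top-K accuracies (percent)."""

    per_query_ranks: dict[str, int]
    topk: dict[int, float]


def _score_one(
    item: tuple[str, Sequence[ShiftSet]],
    query: Spectrum,
    cfg: ScoringConfig,
    peaks,
) -> MatchResult:
    mol_id, shift_sets = item
    t0 = time.perf_counter()
    if not shift_sets:  # unpredictable molecule: scored -C, never a hard error
        result = score_candidate(None, query, cfg, peaks=peaks, molecule_id=mol_id)
    else:
        result = best_of_predictions(list(shift_sets), query, cfg, peaks=peaks)
    logger.debug(
        "scored %s: score=%.6g filtered=%s reason=%s (%.1f ms)",
        mol_id, result.score, result.filtered, result.filter_reason,
        1e3 * (time.perf_counter() - t0),
    )
    return result


def rank_candidates(
    query: Spectrum,
    pool: Mapping[str, Sequence[ShiftSet]],
    cfg: ScoringConfig | None = None,
    workers: int = 1,
) -> RankedList:
    """Score every pool molecule against the query and sort by score.

    Ties on the score are broken by molecule id (ascending), so the
    ranking is deterministic and independent of pool iteration order.
    With ``workers > 1`` candidates are scored in a process pool; the
    result is identical to serial execution.
    """
    if not pool:
        raise ValueError("candidate pool is empty")
    cfg = cfg if cfg is not None else ScoringConfig()
    peaks = threshold_peaks(query, cfg.tau)  # query-level failure if empty
    items = list(pool.items())
    if workers > 1:
        with concurrent.futures.ProcessPoolExecutor(max_workers=workers) as ex:
            results = list(
                ex.map(_score_one, items, [query] * len(items),
                       [cfg] * len(items), [peaks] * len(items))
            )
    else:
        results = [_score_one(item, query, cfg, peaks) for item in items]
    n_filtered = sum(r.filtered for r in results)
    logger.debug(
        "query %s: %d candidates, %d filtered before optimization",
        query.label, len(results), n_filtered,
    )
    entries = tuple(sorted(results, key=lambda r: (-r.score, r.molecule_id)))
    rank_of = {r.molecule_id: i + 1 for i, r in enumerate(entries)}
    return RankedList(query_label=query.label, entries=entries, rank_of=rank_of)


def top_k_accuracy(
    records: Iterable[tuple[str, RankedList, str]],
    ks: Sequence[int] = DEFAULT_KS,
) -> EvalReport:
    """Fraction of queries (percent) whose true molecule ranks within K.

    Parameters
    ----------
    records : iterable of (query label, RankedList, true molecule id)
    ks : retrieval depths, default (1, 2, 3, 5, 10)
    """
    per_query: dict[str, int] = {}
    for label, ranked, true_id in records:
        if true_id not in ranked.rank_of:
            raise ValueError(f"true molecule {true_id!r} absent from ranking of {label!r}")
        per_query[label] = ranked.rank_of[true_id]
    if not per_query:
        raise ValueError("no queries to evaluate")
    ranks = np.array(list(per_query.values()))
    topk = {int(k): float(100.0 * np.mean(ranks <= k)) for k in ks}
    return EvalReport(per_query_ranks=per_query, topk=topk)


def format_ranking(ranked: RankedList, top: int | None = None) -> str:
    """Render a ranking as the canonical TSV (header + one row per candidate)."""
    lines = [
        "rank\tmolecule_id\tprovenance\tscore\tcossim\talignment_penalty\tfiltered\tfilter_reason"
    ]
    entries = ranked.entries[:top] if top is not None else ranked.entries
    for i, r in enumerate(entries, start=1):
        cos = f"{r.cossim_value:.9f}" if r.cossim_value is not None else "-"
        pen = f"{r.alignment_penalty:.9f}" if r.alignment_penalty is not None else "-"
        reason = r.filter_reason if r.filter_reason is not None else "-"
        lines.append(
            f"{i}\t{r.molecule_id}\t{r.provenance}\t{r.score:.9f}\t{cos}\t{pen}"
            f"\t{int(r.filtered)}\t{reason}"
        )
    return "\n".join(lines) + "\n"


def write_ranking(ranked: RankedList, path: str | Path, top: int | None = None) -> None:
    Path(path).write_text(format_ranking(ranked, top=top))
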