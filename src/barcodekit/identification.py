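"""Leave-one-out identification simulations and threshold optimization.

Every record is treated in turn as an unknown query against the rest of the
library, on a precomputed distance matrix, using three distance-based
criteria:

* nearest neighbour (k-NN): true iff a nearest non-self record shares the
  query's label at the requested rank (no threshold);
* best close match (BCM): only the closest record(s) are consulted, and only
  if they fall within the identification threshold — verdicts correct /
  incorrect / ambiguous / no_id;
* threshold-ID (BOLD-style): all records within the threshold are consulted,
  with the same verdict vocabulary.

The identification threshold itself is chosen by sweeping a grid and counting
true/false positives and negatives per query; the optimum is the smallest
threshold minimising cumulative error (false positives + false negatives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .library_io import LibraryError

__all__ = [
    "IdOutcome",
    "ThresholdTable",
    "knn_identify",
    "best_close_match",
    "thresh_identify",
    "optimize_threshold",
    "run_table1",
    "singleton_ids",
    "outcomes_to_frame",
    "default_grid",
    "TIE_RTOL",
]

# identical sequences must compare as tied nearest despite float rounding
TIE_RTOL = 1e-9
TIE_ATOL = 1e-12

DEFAULT_THRESHOLD = 0.01  # the 1% default of BLAST/BOLD-style identification


def default_grid() -> np.ndarray:
    """Threshold sweep 0.1%..2% in 0.1% steps."""
    return np.round(np.arange(1, 21) * 0.001, 6)


@dataclass(frozen=True)
class IdOutcome:
    query: str
    criterion: str  # knn | bcm | threshid
    rank: str
    verdict: str  # true/false (knn) or correct/incorrect/ambiguous/no_id
    matches: tuple[str, ...] = ()


def _check_labels(matrix: DistanceMatrix, labels: Mapping[str, str]) -> np.ndarray:
    missing = [i for i in matrix.ids if i not in labels]
    if missing:
        raise LibraryError(f"ids without label: {missing[:5]}")
    return np.array([labels[i] for i in matrix.ids])


def singleton_ids(labels: Mapping[str, str], ids: Sequence[str]) -> set[str]:
    """Records whose label at this rank has no other representative."""
    counts: dict[str, int] = {}
    for i in ids:
        counts[labels[i]] = counts.get(labels[i], 0) + 1
    return {i for i in ids if counts[labels[i]] == 1}


def _nearest_ties(row: np.ndarray, self_idx: int) -> np.ndarray:
    """Indices of non-self records tied at the minimum defined distance."""
    d = row.copy()
    d[self_idx] = np.nan
    if np.all(np.isnan(d)):
        return np.array([], dtype=int)
    dmin = np.nanmin(d)
    with np.errstate(invalid="ignore"):
        tied = np.isclose(d, dmin, rtol=TIE_RTOL, atol=TIE_ATOL)
    return np.flatnonzero(tied & ~np.isnan(d))


def knn_identify(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    rank: str = "species",
    tie_policy: str = "any",
    exclude_singletons: bool = False,
) -> tuple[list[IdOutcome], float]:
    """Nearest-neighbour leave-one-out identification.

    ``tie_policy='any'`` scores true when any tied nearest record shares the
    query's label; ``'strict'`` requires all of them to. With
    ``exclude_singletons`` the success rate is computed over non-singleton
    queries only (a singleton can never be identified correctly).
    """
    if len(matrix) < 2:
        raise LibraryError("need at least 2 records")
    if tie_policy not in ("any", "strict"):
        raise LibraryError(f"unknown tie_policy {tie_policy!r}")
    lab = _check_labels(matrix, labels)
    skip = singleton_ids(labels, matrix.ids) if exclude_singletons else set()

    outcomes: list[IdOutcome] = []
    n_true = 0
    n_scored = 0
    for idx, rid in enumerate(matrix.ids):
        if rid in skip:
            continue
        ties = _nearest_ties(matrix.data[idx], idx)
        tie_labels = lab[ties]
        if tie_labels.size == 0:
            verdict = "false"
        elif tie_policy == "any":
            verdict = "true" if (tie_labels == lab[idx]).any() else "false"
        else:
            verdict = "true" if (tie_labels == lab[idx]).all() else "false"
        outcomes.append(
            IdOutcome(rid, "knn", rank, verdict, tuple(matrix.ids[t] for t in ties))
        )
        n_scored += 1
        n_true += verdict == "true"
    return outcomes, (n_true / n_scored if n_scored else float("nan"))


def _close_match_verdict(match_labels: np.ndarray, query_label: str) -> str:
    same = match_labels == query_label
    if same.all():
        return "correct"
    if not same.any():
        return "incorrect"
    return "ambiguous"


def best_close_match(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    threshold: float,
    rank: str = "species",
) -> list[IdOutcome]:
    """Best-close-match: only the closest record(s), and only within the
    threshold. no_id when the nearest distance exceeds the threshold."""
    if threshold <= 0:
        raise LibraryError("threshold must be > 0")
    lab = _check_labels(matrix, labels)
    outcomes = []
    for idx, rid in enumerate(matrix.ids):
        ties = _nearest_ties(matrix.data[idx], idx)
        if ties.size == 0 or matrix.data[idx, ties[0]] > threshold:
            outcomes.append(IdOutcome(rid, "bcm", rank, "no_id"))
            continue
        verdict = _close_match_verdict(lab[ties], lab[idx])
        outcomes.append(
            IdOutcome(rid, "bcm", rank, verdict, tuple(matrix.ids[t] for t in ties))
        )
    return outcomes


def thresh_identify(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    threshold: float,
    rank: str = "species",
) -> list[IdOutcome]:
    """Threshold-ID: every non-self record within the threshold is consulted."""
    if threshold <= 0:
        raise LibraryError("threshold must be > 0")
    lab = _check_labels(matrix, labels)
    outcomes = []
    for idx, rid in enumerate(matrix.ids):
        row = matrix.data[idx]
        with np.errstate(invalid="ignore"):
            within = (row <= threshold) & ~np.isnan(row)
        within[idx] = False
        members = np.flatnonzero(within)
        if members.size == 0:
            outcomes.append(IdOutcome(rid, "threshid", rank, "no_id"))
            continue
        verdict = _close_match_verdict(lab[members], lab[idx])
        outcomes.append(
            IdOutcome(
                rid, "threshid", rank, verdict, tuple(matrix.ids[m] for m in members)
            )
        )
    return outcomes


@dataclass
class ThresholdTable:
    """Sweep of identification thresholds with per-threshold error counts."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    def __post_init__(self) -> None:
        totals = self.tp + self.fp + self.fn + self.tn
        if len(set(totals.tolist())) > 1:
            raise ValueError("per-threshold outcome counts are inconsistent")

    @property
    def cumulative_error(self) -> np.ndarray:
        return self.fp + self.fn

    @property
    def optimum(self) -> float:
        """Smallest threshold attaining the minimum cumulative error."""
        err = self.cumulative_error
        return float(self.thresholds[int(np.argmin(err))])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "fn": self.fn,
                "tn": self.tn,
                "cumulative_error": self.cumulative_error,
            }
        )


def optimize_threshold(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    grid: Sequence[float] | None = None,
    rank: str = "species",
) -> ThresholdTable:
    """Count TP/FP/FN/TN per grid threshold over leave-one-out queries.

    Per query with M = non-self records within the threshold and C = non-self
    records sharing the query's rank label: any other-rank record in M is a
    false positive; M non-empty and all same-rank is a true positive; M empty
    with C non-empty is a false negative (a conspecific existed but was out of
    reach); M and C both empty is a true negative (a singleton correctly
    unmatched). Ambiguous matches therefore count as false positives.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise LibraryError("grid must contain >= 2 strictly increasing thresholds")
    lab = _check_labels(matrix, labels)
    n = len(matrix)
    same = lab[:, None] == lab[None, :]
    np.fill_diagonal(same, False)
    has_conspecific = same.any(axis=1)

    tp = np.zeros(grid.size, dtype=int)
    fp = np.zeros(grid.size, dtype=int)
    fn = np.zeros(grid.size, dtype=int)
    tn = np.zeros(grid.size, dtype=int)
    for idx in range(n):
        row = matrix.data[idx].copy()
        row[idx] = np.nan
        defined = ~np.isnan(row)
        for g, thr in enumerate(grid):
            within = defined & (row <= thr)
            if within.any():
                if (within & ~same[idx]).any():
                    fp[g] += 1
                else:
                    tp[g] += 1
            elif has_conspecific[idx]:
                fn[g] += 1
            else:
                tn[g] += 1
    return ThresholdTable(grid, tp, fp, fn, tn)


def _verdict_counts(outcomes: Sequence[IdOutcome], vocab: Sequence[str]) -> dict:
    counts = {v: 0 for v in vocab}
    for o in outcomes:
        counts[o.verdict] += 1
    return counts


def run_table1(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    optimal_threshold: float,
    rank: str = "species",
    default_threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Identification-outcome grid: {singletons included, excluded} x
    {default threshold, optimized threshold} x {knn, bcm, threshid}.

    k-NN takes no threshold, so it is reported once per singleton setting
    (under the default-threshold rows). Excluding singletons drops them as
    queries; they remain in the reference each query is matched against.
    Counts in each cell sum to the number of queries in that cell.
    """
    rows = []
    singles = singleton_ids(labels, matrix.ids)
    for singleton_setting in ("included", "excluded"):
        exclude = singleton_setting == "excluded"
        skip = singles if exclude else set()
        n_queries = len(matrix) - len(skip)
        if n_queries == 0:
            continue
        for thr_name, thr in (("default", default_threshold), ("optimized", optimal_threshold)):
            if thr_name == "default":
                knn_out, rate = knn_identify(
                    matrix, labels, rank=rank, exclude_singletons=exclude
                )
                counts = _verdict_counts(knn_out, ("true", "false"))
                rows.append(
                    {
                        "singletons": singleton_setting,
                        "threshold": thr,
                        "threshold_setting": thr_name,
                        "criterion": "knn",
                        "n_queries": n_queries,
                        "success_rate": rate,
                        **counts,
                    }
                )
            for crit, fn in (("bcm", best_close_match), ("threshid", thresh_identify)):
                out = [o for o in fn(matrix, labels, thr, rank=rank) if o.query not in skip]
                counts = _verdict_counts(out, ("correct", "incorrect", "ambiguous", "no_id"))
                rows.append(
                    {
                        "singletons": singleton_setting,
                        "threshold": thr,
                        "threshold_setting": thr_name,
                        "criterion": crit,
                        "n_queries": n_queries,
                        "success_rate": counts["correct"] / n_queries,
                        **counts,
                    }
                )
    return pd.DataFrame(rows)


def outcomes_to_frame(outcomes: Sequence[IdOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query": o.query,
                "criterion": o.criterion,
                "rank": o.rank,
                "verdict": o.verdict,
                "matches": ";".join(o.matches),
            }
            for o in outcomes
        ]
    )
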