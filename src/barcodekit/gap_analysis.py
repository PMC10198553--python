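"""Barcode-gap assessment.

Two complementary views of species separability in a reference library:

1. Distribution comparison — all pairwise distances are split into
   intraspecific and interspecific sets, summarised, and compared with a
   Wilcoxon rank-sum (Mann–Whitney U) test.
2. Per-sequence gap — for every non-singleton record, the difference between
   its minimum distance to a heterospecific and its maximum distance to a
   conspecific. A positive difference is a barcode gap; the proportion of
   records (or species) with a gap measures library reliability.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distances import DistanceMatrix
from .library_io import LibraryError

__all__ = [
    "DistanceDistributions",
    "GapRecord",
    "split_distances",
    "rank_sum_test",
    "per_sequence_gap",
    "gap_proportion",
    "gap_records_to_frame",
    "distributions_to_json",
]

EXACT_LIMIT = 12  # exact null enumeration up to this combined sample size


def _summary(values: np.ndarray) -> dict | None:
    if values.size == 0:
        return None
    return {
        "n": int(values.size),
        "min": float(values.min()),
        "max": float(values.max()),
        "median": float(np.median(values)),
    }


@dataclass
class DistanceDistributions:
    intra: np.ndarray
    inter: np.ndarray

    @property
    def intra_summary(self) -> dict | None:
        return _summary(self.intra)

    @property
    def inter_summary(self) -> dict | None:
        return _summary(self.inter)


def split_distances(
    matrix: DistanceMatrix, species_labels: Mapping[str, str]
) -> DistanceDistributions:
    """Partition every defined unordered pair into intra- or interspecific."""
    missing = [i for i in matrix.ids if i not in species_labels]
    if missing:
        raise LibraryError(f"ids without species label: {missing[:5]}")
    labels = np.array([species_labels[i] for i in matrix.ids])
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(matrix), k=1)
    vals = matrix.data[iu]
    same_u = same[iu]
    defined = ~np.isnan(vals)
    return DistanceDistributions(
        intra=vals[defined & same_u], inter=vals[defined & ~same_u]
    )


def _exact_rank_sum_p(ranks: np.ndarray, nx: int, u_obs: float, alternative: str) -> float:
    """Exact null tail by enumerating all assignments of the midranks to x."""
    n = len(ranks)
    mu = nx * (n - nx) / 2.0
    offset = nx * (nx + 1) / 2.0
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n), nx):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if alternative == "two-sided":
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        elif alternative == "greater":
            hits += u >= u_obs - 1e-12
        else:
            hits += u <= u_obs + 1e-12
    return hits / total


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum / Mann–Whitney U test.

    Midranks handle ties. For combined sample sizes up to 12 the p-value is
    an exact enumeration over all rank assignments; larger samples use the
    normal approximation with tie-corrected variance and continuity
    correction. Returns (U statistic of x, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise LibraryError("rank_sum_test requires two non-empty samples")
    if alternative not in ("two-sided", "greater", "less"):
        raise LibraryError(f"unknown alternative {alternative!r}")

    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u_x = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)

    if x.size + y.size <= EXACT_LIMIT:
        p = _exact_rank_sum_p(ranks, x.size, u_x, alternative)
    else:
        _, p = stats.mannwhitneyu(
            x, y, alternative=alternative, method="asymptotic", use_continuity=True
        )
    return u_x, float(min(1.0, p))


@dataclass(frozen=True)
class GapRecord:
    record_id: str
    species: str
    max_intra: float
    min_inter: float

    @property
    def gap(self) -> float:
        return self.min_inter - self.max_intra

    @property
    def has_gap(self) -> bool:
        # strictly positive: a point exactly on the 1:1 line has no gap
        return self.gap > 0


def per_sequence_gap(
    matrix: DistanceMatrix, species_labels: Mapping[str, str]
) -> tuple[list[GapRecord], list[str]]:
    """Max-intraspecific and min-interspecific distance per record.

    Undefined pairs are ignored. Records with no defined conspecific distance
    (species singletons, or records isolated by saturation) cannot be scored
    and are returned in the singleton list.
    """
    missing = [i for i in matrix.ids if i not in species_labels]
    if missing:
        raise LibraryError(f"ids without species label: {missing[:5]}")
    labels = np.array([species_labels[i] for i in matrix.ids])
    if len(set(labels)) < 2:
        raise LibraryError("per_sequence_gap requires at least 2 species")

    records: list[GapRecord] = []
    singletons: list[str] = []
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    d = matrix.data
    for idx, rid in enumerate(matrix.ids):
        intra = d[idx, same[idx]]
        inter = d[idx, ~same[idx] & (np.arange(len(labels)) != idx)]
        intra = intra[~np.isnan(intra)]
        inter = inter[~np.isnan(inter)]
        if intra.size == 0:
            singletons.append(rid)
            continue
        if inter.size == 0:
            # no defined heterospecific distance: cannot assess the gap
            singletons.append(rid)
            continue
        records.append(
            GapRecord(rid, str(labels[idx]), float(intra.max()), float(inter.min()))
        )
    return records, singletons


def gap_proportion(gap_records: Sequence[GapRecord], level: str = "sequence") -> float:
    """Proportion of evaluable units with a (strictly positive) barcode gap.

    At ``level='sequence'`` every scored record counts. At ``level='species'``
    a species has a gap iff the minimum over its members' min-interspecific
    distances exceeds the maximum within-species distance (the max over its
    members' max-intraspecific values).
    """
    if level not in ("sequence", "species"):
        raise LibraryError(f"unknown level {level!r}")
    if not gap_records:
        raise LibraryError("no evaluable records")
    if level == "sequence":
        return sum(r.has_gap for r in gap_records) / len(gap_records)
    by_species: dict[str, list[GapRecord]] = {}
    for r in gap_records:
        by_species.setdefault(r.species, []).append(r)
    n_gap = sum(
        1
        for members in by_species.values()
        if min(m.min_inter for m in members) > max(m.max_intra for m in members)
    )
    return n_gap / len(by_species)


def gap_records_to_frame(
    gap_records: Sequence[GapRecord], singletons: Sequence[str] = ()
) -> pd.DataFrame:
    """Scatter-ready table: one row per record with max_intra, min_inter, gap."""
    df = pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "species": r.species,
                "max_intra": r.max_intra,
                "min_inter": r.min_inter,
                "gap": r.gap,
                "has_gap": r.has_gap,
            }
            for r in gap_records
        ],
        columns=["record_id", "species", "max_intra", "min_inter", "gap", "has_gap"],
    )
    if len(singletons):
        df = pd.concat(
            [df, pd.DataFrame({"record_id": list(singletons)})], ignore_index=True
        )
    return df


def distributions_to_json(dist: DistanceDistributions) -> str:
    return json.dumps(
        {"intraspecific": dist.intra_summary, "interspecific": dist.inter_summary},
        indent=2,
        sort_keys=True,
    )
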