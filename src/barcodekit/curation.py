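"""Record-selection quality rules for mined barcode candidates.

Public sequence databases are uneven in quality, so a reference library is
assembled from candidates under explicit rules: at most a fixed number of
individuals per species (default 3), no two selected records of a species
from the same herbarium, and preference for vouchered records with the
fewest ambiguous bases. Rejections carry machine-readable reason codes so
the curation step is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .library_io import (
    BarcodeRecord,
    LibraryError,
    ReferenceLibrary,
    count_ambiguous_symbols,
)

__all__ = ["count_ambiguous", "select_records", "Rejection", "rejections_to_frame"]

OVER_QUOTA = "over_quota"
DUPLICATE_HERBARIUM = "duplicate_herbarium"


def count_ambiguous(sequence: str) -> int:
    """Count ambiguity symbols (non-ACGT, non-gap IUPAC codes) in a sequence.

    Gaps are alignment artifacts, not base calls, and do not count.
    """
    return count_ambiguous_symbols(sequence)


@dataclass(frozen=True)
class Rejection:
    record_id: str
    species: str
    reason: str


def _priority_key(record: BarcodeRecord) -> tuple:
    # voucher-backed first, then fewest ambiguous bases, then stable id
    return (not record.has_voucher, record.ambiguous_count, record.record_id)


def select_records(
    candidates: Iterable[BarcodeRecord] | ReferenceLibrary,
    max_per_species: int = 3,
    herbarium_scope: str = "species",
) -> tuple[list[BarcodeRecord], list[Rejection]]:
    """Apply the per-species selection rules to candidate records.

    Within each species, candidates are ranked by (has_voucher, fewer
    ambiguous bases, lexicographic record_id) and taken greedily up to
    ``max_per_species``, skipping any candidate whose non-empty herbarium
    string was already used (within the species by default, or across the
    whole library with ``herbarium_scope='global'``). The ranking is
    content-based, so the outcome is independent of input order.

    Returns the selected records (library order of first appearance by
    species, priority order within species) and the rejections, each tagged
    ``over_quota`` or ``duplicate_herbarium``. Singleton species are kept.
    """
    if max_per_species < 1:
        raise LibraryError("max_per_species must be >= 1")
    if herbarium_scope not in ("species", "global"):
        raise LibraryError(f"unknown herbarium_scope {herbarium_scope!r}")

    records = list(candidates.records if isinstance(candidates, ReferenceLibrary) else candidates)
    by_species: dict[str, list[BarcodeRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)

    selected: list[BarcodeRecord] = []
    rejected: list[Rejection] = []
    global_herbaria: set[str] = set()
    for species in sorted(by_species):
        used = global_herbaria if herbarium_scope == "global" else set()
        taken = 0
        for rec in sorted(by_species[species], key=_priority_key):
            if rec.herbarium and rec.herbarium in used:
                rejected.append(Rejection(rec.record_id, species, DUPLICATE_HERBARIUM))
                continue
            if taken >= max_per_species:
                rejected.append(Rejection(rec.record_id, species, OVER_QUOTA))
                continue
            selected.append(rec)
            taken += 1
            if rec.herbarium:
                used.add(rec.herbarium)
    return selected, rejected


def rejections_to_frame(rejections: Sequence[Rejection]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.record_id, r.species, r.reason) for r in rejections],
        columns=["record_id", "species", "reason"],
    )
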