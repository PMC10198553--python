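"""Pairwise evolutionary distances under pairwise deletion.

Distances are computed from aligned sequences with per-pair exclusion of
sites carrying a gap or ambiguity code in either sequence (pairwise
deletion). Two substitution corrections are provided:

* Kimura two-parameter (K2P), which separates transitions (A<->G, C<->T,
  observed proportion P) from transversions (proportion Q):

      d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

* Jukes–Cantor (JC), from the overall differing proportion p:

      d = -3/4 ln(1 - 4p/3)

Saturated pairs (log argument <= 0) have no finite distance under the model;
they are recorded as undefined rather than coerced to a large value, so
downstream minima/maxima are never polluted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .library_io import LibraryError, ReferenceLibrary, encode_sequences, normalize_sequence

__all__ = [
    "PairwiseCounts",
    "DistanceMatrix",
    "SaturationError",
    "pair_counts",
    "k2p_distance",
    "k2p_from_pq",
    "jc_distance",
    "jc_from_p",
    "p_distance",
    "codes_to_distances",
    "distance_matrix",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

MODELS = ("K2P", "JC", "raw")

_PURINE = frozenset("AG")


class SaturationError(ValueError):
    """The observed divergence exceeds the model's invertible range."""


@dataclass(frozen=True)
class PairwiseCounts:
    """Site counts for one aligned sequence pair under pairwise deletion."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValueError("differences exceed compared sites")

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_compared if self.n_compared else float("nan")

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_compared if self.n_compared else float("nan")

    @property
    def p(self) -> float:
        """Raw differing proportion over compared sites."""
        if not self.n_compared:
            return float("nan")
        return (self.n_transitions + self.n_transversions) / self.n_compared


def _encode_pair(seq_a: str, seq_b: str) -> tuple[np.ndarray, np.ndarray]:
    a = normalize_sequence(seq_a)
    b = normalize_sequence(seq_b)
    if len(a) != len(b):
        raise LibraryError(f"unequal aligned lengths: {len(a)} vs {len(b)}")
    code = {c: i for i, c in enumerate("ACGT")}
    enc = lambda s: np.array([code.get(c, 255) for c in s], dtype=np.uint8)
    return enc(a), enc(b)


def pair_counts(seq_a: str, seq_b: str) -> PairwiseCounts:
    """Transition/transversion counts for one aligned pair.

    Sites with a gap or an ambiguity code in either sequence are excluded.
    ``n_compared == 0`` is returned as-is; distances on such a pair are
    undefined and must be handled downstream.
    """
    a, b = _encode_pair(seq_a, seq_b)
    valid = (a < 4) & (b < 4)
    av, bv = a[valid], b[valid]
    diff = av != bv
    # purines are codes {0, 2} (A, G); same parity <=> same purine/pyrimidine class
    same_class = (av % 2) == (bv % 2)
    n_ts = int(np.count_nonzero(diff & same_class))
    n_tv = int(np.count_nonzero(diff & ~same_class))
    return PairwiseCounts(int(valid.sum()), n_ts, n_tv)


def k2p_from_pq(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined for P={P:.4g}, Q={Q:.4g}")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def k2p_distance(counts: PairwiseCounts) -> float:
    """K2P distance from pairwise counts; raises SaturationError when undefined."""
    if counts.n_compared == 0:
        raise SaturationError("no comparable sites")
    return k2p_from_pq(counts.P, counts.Q)


def jc_from_p(p: float) -> float:
    w = 1.0 - 4.0 * p / 3.0
    if w <= 0.0:
        raise SaturationError(f"JC undefined for p={p:.4g}")
    return -0.75 * np.log(w)


def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes–Cantor distance for one aligned pair (pairwise deletion)."""
    c = pair_counts(seq_a, seq_b)
    if c.n_compared == 0:
        raise SaturationError("no comparable sites")
    return jc_from_p(c.p)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Raw proportion of differing compared sites."""
    c = pair_counts(seq_a, seq_b)
    if c.n_compared == 0:
        raise SaturationError("no comparable sites")
    return c.p


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over an ordered id list.

    Undefined (saturated or zero-overlap) pairs hold NaN in ``data`` and are
    listed in ``undefined_pairs``.
    """

    ids: list[str]
    data: np.ndarray
    model: str
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not np.allclose(np.nan_to_num(self.data), np.nan_to_num(self.data.T)):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("diagonal must be zero")
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def is_complete(self) -> bool:
        return not self.undefined_pairs

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.data[self._index[id_a], self._index[id_b]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        sub = self.data[np.ix_(idx, idx)]
        keep = set(ids)
        undef = [(a, b) for a, b in self.undefined_pairs if a in keep and b in keep]
        return DistanceMatrix(list(ids), sub, self.model, undef)


def codes_to_distances(codes: np.ndarray, model: str = "K2P") -> np.ndarray:
    """Distance kernel on an (n, L) encoded matrix (A..T=0..3, gap=4, ambig=5).

    Returns an (n, n) float matrix with NaN for undefined (saturated or
    zero-overlap) pairs. Pairwise deletion throughout.
    """
    if model not in MODELS:
        raise LibraryError(f"unknown model {model!r}")
    n = codes.shape[0]
    valid = codes < 4
    parity = codes % 2  # purines A,G have even codes
    d = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        n_comp = both.sum(axis=1).astype(float)
        diff = (codes[i] != codes[i + 1 :]) & both
        with np.errstate(divide="ignore", invalid="ignore"):
            if model == "K2P":
                ts = (diff & (parity[i] == parity[i + 1 :])).sum(axis=1)
                tv = diff.sum(axis=1) - ts
                P = ts / n_comp
                Q = tv / n_comp
                w1 = 1.0 - 2.0 * P - Q
                w2 = 1.0 - 2.0 * Q
                row = np.where(
                    (w1 > 0) & (w2 > 0),
                    -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                    - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                    np.nan,
                )
            else:
                p = diff.sum(axis=1) / n_comp
                if model == "JC":
                    w = 1.0 - 4.0 * p / 3.0
                    row = np.where(
                        w > 0, -0.75 * np.log(np.where(w > 0, w, 1.0)), np.nan
                    )
                else:
                    row = p
        row = np.where(n_comp > 0, row, np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


def distance_matrix(
    library: ReferenceLibrary,
    model: str = "K2P",
    within_family_only: bool = False,
) -> DistanceMatrix:
    """All-pairs distance matrix for an aligned library.

    ``within_family_only=True`` computes distances only inside each family
    and marks cross-family pairs undefined — the mode matching per-family
    alignments of gap-rich markers, where cross-family columns are not
    comparable.
    """
    if not library.aligned:
        raise LibraryError("distance_matrix requires an aligned library")
    if len(library) < 2:
        raise LibraryError("need at least 2 records")

    d = codes_to_distances(encode_sequences(library), model)
    ids = library.ids
    if within_family_only:
        families = np.array([r.family for r in library.records])
        cross = families[:, None] != families[None, :]
        d = np.where(cross, np.nan, d)
    n = len(ids)
    undefined = [
        (ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if np.isnan(d[i, j])
    ]
    return DistanceMatrix(ids, d, model, undefined)


def write_matrix_tsv(dm: DistanceMatrix, dest, lower_triangle: bool = False) -> None:
    """Write a square (or lower-triangle) TSV with an id header row."""
    df = dm.to_dataframe()
    if lower_triangle:
        masked = df.where(np.tril(np.ones(df.shape, dtype=bool)))
        masked.to_csv(dest, sep="\t", index_label="id")
    else:
        df.to_csv(dest, sep="\t", index_label="id")


def read_matrix_tsv(source, model: str = "K2P") -> DistanceMatrix:
    df = pd.read_csv(source, sep="\t", index_col=0)
    data = df.to_numpy(dtype=float)
    if np.isnan(data).any():  # stored lower triangle
        data = np.where(np.isnan(data), data.T, data)
    ids = [str(c) for c in df.columns]
    undef = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if np.isnan(data[i, j])
    ]
    return DistanceMatrix(ids, data, model, undef)
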