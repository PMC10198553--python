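"""Reading, writing and summarising taxonomy-annotated barcode libraries.

A reference library is a set of barcode records for one marker (e.g. rbcL or
trnL), each record carrying an accession/process ID, a family/genus/species
taxonomy, voucher and herbarium metadata, and an (optionally aligned) IUPAC
nucleotide sequence. Libraries travel as FASTA with pipe-delimited headers

    >record_id|marker|family|genus|species|voucher|herbarium

or as plain-ID FASTA plus a tab-separated taxonomy sidecar keyed on the ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BarcodeRecord",
    "ReferenceLibrary",
    "AlignmentSummary",
    "LibraryError",
    "DEFAULT_HEADER_FIELDS",
    "SIDECAR_COLUMNS",
    "parse_reference_fasta",
    "write_reference_fasta",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "alignment_summary",
    "encode_sequences",
]

DEFAULT_HEADER_FIELDS = (
    "record_id",
    "marker",
    "family",
    "genus",
    "species",
    "voucher",
    "herbarium",
)
SIDECAR_COLUMNS = [
    "record_id",
    "marker",
    "family",
    "genus",
    "species",
    "voucher",
    "herbarium",
]

# IUPAC nucleotide alphabet; '-' marks an alignment gap.
_UNAMBIGUOUS = frozenset("ACGT")
_AMBIGUOUS = frozenset("RYSWKMBDHVN")
_VALID = _UNAMBIGUOUS | _AMBIGUOUS | {"-"}

# Integer codes used by the numeric kernels: A,C,G,T -> 0..3, gap -> 4,
# any ambiguity code -> 5.
_CODE = {c: i for i, c in enumerate("ACGT")}
_CODE["-"] = 4
GAP_CODE = 4
AMBIG_CODE = 5


class LibraryError(ValueError):
    """Raised for malformed records or libraries."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map U to T; reject non-IUPAC symbols."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise LibraryError(f"non-IUPAC symbol(s) {sorted(bad)} in sequence")
    return s


def count_ambiguous_symbols(sequence: str) -> int:
    """Number of ambiguity symbols (non-ACGT, non-gap) in an IUPAC string."""
    s = normalize_sequence(sequence)
    return sum(1 for c in s if c in _AMBIGUOUS)


@dataclass(frozen=True)
class BarcodeRecord:
    """One barcode sequence with its taxonomy and provenance metadata."""

    record_id: str
    marker: str
    family: str
    genus: str
    species: str
    sequence: str
    has_voucher: bool = False
    herbarium: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise LibraryError("record_id must be non-empty")
        for rank in ("family", "genus", "species"):
            if not getattr(self, rank):
                raise LibraryError(
                    f"record {self.record_id!r}: missing {rank} in taxonomy"
                )
        if not self.sequence:
            raise LibraryError(f"record {self.record_id!r}: empty sequence")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    @property
    def ambiguous_count(self) -> int:
        """Count of ambiguity symbols, always recomputed from the sequence."""
        return sum(1 for c in self.sequence if c in _AMBIGUOUS)

    @property
    def ungapped_length(self) -> int:
        return sum(1 for c in self.sequence if c != "-")


@dataclass
class ReferenceLibrary:
    """An ordered collection of barcode records for a single marker."""

    marker: str
    records: list[BarcodeRecord] = field(default_factory=list)
    aligned: bool = False
    alignment_length: int | None = None

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise LibraryError(f"duplicate record_id(s): {dup}")
        self._check_taxonomy_consistency()
        if self.aligned:
            lengths = {len(r.sequence) for r in self.records}
            if len(lengths) > 1:
                raise LibraryError(
                    f"aligned library has unequal sequence lengths: {sorted(lengths)}"
                )
            if self.records:
                length = len(self.records[0].sequence)
                if self.alignment_length is None:
                    self.alignment_length = length
                elif self.alignment_length != length:
                    raise LibraryError(
                        "alignment_length does not match sequence length"
                    )
        else:
            self.alignment_length = None

    def _check_taxonomy_consistency(self) -> None:
        sp_map: dict[str, tuple[str, str]] = {}
        for r in self.records:
            key = r.species
            pair = (r.genus, r.family)
            if key in sp_map and sp_map[key] != pair:
                raise LibraryError(
                    f"species {key!r} maps to both {sp_map[key]} and {pair}"
                )
            sp_map[key] = pair

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BarcodeRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def labels(self, rank: str = "species") -> dict[str, str]:
        """Map record_id -> taxonomy label at the given rank."""
        if rank not in ("family", "genus", "species"):
            raise LibraryError(f"unknown rank {rank!r}")
        return {r.record_id: getattr(r, rank) for r in self.records}

    def rank_index(self, rank: str = "species") -> dict[str, list[BarcodeRecord]]:
        """Map taxonomy label at `rank` -> records carrying it."""
        index: dict[str, list[BarcodeRecord]] = {}
        for r in self.records:
            index.setdefault(getattr(r, rank), []).append(r)
        return index

    def subset(self, ids: Iterable[str]) -> "ReferenceLibrary":
        keep = set(ids)
        missing = keep - set(self.ids)
        if missing:
            raise LibraryError(f"unknown record_id(s): {sorted(missing)}")
        return ReferenceLibrary(
            marker=self.marker,
            records=[r for r in self.records if r.record_id in keep],
            aligned=self.aligned,
        )

    def counts(self) -> dict[str, int]:
        return {
            "n_records": len(self.records),
            "n_species": len(self.rank_index("species")),
            "n_genera": len(self.rank_index("genus")),
            "n_families": len(self.rank_index("family")),
        }


@dataclass(frozen=True)
class AlignmentSummary:
    n_sequences: int
    n_sites: int
    identical_sites: int
    identical_fraction: float
    mean_pairwise_identity: float


def _as_handle(source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def parse_reference_fasta(
    source,
    header_scheme: Sequence[str] = DEFAULT_HEADER_FIELDS,
    taxonomy: pd.DataFrame | Mapping[str, Mapping[str, str]] | None = None,
    force_aligned: bool | None = None,
) -> ReferenceLibrary:
    """Parse a reference-library FASTA.

    With the default ``header_scheme`` the description line is pipe-delimited
    (voucher field 'Y'/'N'; herbarium may be empty). If ``taxonomy`` is given
    (a DataFrame or mapping keyed by record_id with the sidecar columns),
    headers are treated as bare IDs and metadata comes from the sidecar.

    The library is marked aligned when all sequences have equal length and at
    least one gap character is present, or when ``force_aligned=True``.
    """
    handle, owned = _as_handle(source)
    try:
        entries = [(rec.description, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if owned:
            handle.close()

    if taxonomy is not None and not isinstance(taxonomy, pd.DataFrame):
        taxonomy = pd.DataFrame.from_dict(taxonomy, orient="index").rename_axis(
            "record_id"
        ).reset_index()

    records: list[BarcodeRecord] = []
    marker = None
    for header, seq in entries:
        if taxonomy is not None:
            rid = header.split()[0].split("|")[0]
            row = taxonomy.loc[taxonomy["record_id"] == rid]
            if row.empty:
                raise LibraryError(f"record {rid!r}: no taxonomy sidecar entry")
            row = row.iloc[0]
            meta = {f: str(row.get(f, "") or "") for f in DEFAULT_HEADER_FIELDS[1:]}
            meta["record_id"] = rid
        else:
            parts = header.split("|")
            if len(parts) < len(header_scheme) - 1:
                raise LibraryError(
                    f"header {header!r}: expected {len(header_scheme)} "
                    f"pipe-delimited fields {tuple(header_scheme)}"
                )
            # trailing empty herbarium may be dropped by FASTA writers
            parts += [""] * (len(header_scheme) - len(parts))
            meta = dict(zip(header_scheme, parts))
        for rank in ("family", "genus", "species"):
            if not meta.get(rank):
                raise LibraryError(
                    f"record {meta.get('record_id', header)!r}: missing {rank}"
                )
        records.append(
            BarcodeRecord(
                record_id=meta["record_id"],
                marker=meta.get("marker", ""),
                family=meta["family"],
                genus=meta["genus"],
                species=meta["species"],
                sequence=seq,
                has_voucher=str(meta.get("voucher", "N")).upper() in ("Y", "TRUE", "1"),
                herbarium=meta.get("herbarium", "") or "",
            )
        )
        marker = marker or records[-1].marker

    lengths = {len(r.sequence) for r in records}
    any_gap = any("-" in r.sequence for r in records)
    if force_aligned is None:
        aligned = len(records) > 0 and len(lengths) == 1 and any_gap
    else:
        aligned = force_aligned
    return ReferenceLibrary(marker=marker or "", records=records, aligned=aligned)


def write_reference_fasta(library: ReferenceLibrary, dest) -> None:
    """Write a library as pipe-header FASTA; round-trips with the parser."""
    handle, owned = _as_handle(dest, "w")
    try:
        seq_records = []
        for r in library:
            header = "|".join(
                [
                    r.record_id,
                    r.marker,
                    r.family,
                    r.genus,
                    r.species,
                    "Y" if r.has_voucher else "N",
                    r.herbarium,
                ]
            )
            seq_records.append(SeqRecord(Seq(r.sequence), id=header, description=""))
        SeqIO.write(seq_records, handle, "fasta")
    finally:
        if owned:
            handle.close()


def library_to_frame(library: ReferenceLibrary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "marker": r.marker,
                "family": r.family,
                "genus": r.genus,
                "species": r.species,
                "voucher": "Y" if r.has_voucher else "N",
                "herbarium": r.herbarium,
            }
            for r in library
        ],
        columns=SIDECAR_COLUMNS,
    )


def write_taxonomy_table(library: ReferenceLibrary, dest) -> None:
    library_to_frame(library).to_csv(dest, sep="\t", index=False)


def read_taxonomy_table(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    missing = set(SIDECAR_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise LibraryError(f"taxonomy table missing column(s): {sorted(missing)}")
    return df


def encode_sequences(library: ReferenceLibrary) -> np.ndarray:
    """Encode an aligned library as an (n, L) uint8 matrix.

    A,C,G,T -> 0..3; gap -> 4; ambiguity codes -> 5.
    """
    if not library.aligned:
        raise LibraryError("library must be aligned")
    n, L = len(library), library.alignment_length or 0
    mat = np.full((n, L), AMBIG_CODE, dtype=np.uint8)
    for i, r in enumerate(library):
        mat[i] = [_CODE.get(c, AMBIG_CODE) for c in r.sequence]
    return mat


def alignment_summary(
    library: ReferenceLibrary, gap_policy: str = "exclude"
) -> AlignmentSummary:
    """Column- and pair-level conservation statistics for an aligned library.

    identical_sites counts columns in which every unambiguous, non-gap residue
    is the same state and at least two rows are informative. Pairwise identity
    is computed per pair over sites where both rows are unambiguous residues
    (``gap_policy='exclude'``, pairwise deletion); with ``gap_policy='mismatch'``
    a gap opposite a residue counts as a compared, mismatching site.
    """
    if not library.aligned:
        raise LibraryError("alignment_summary requires an aligned library")
    if gap_policy not in ("exclude", "mismatch"):
        raise LibraryError(f"unknown gap_policy {gap_policy!r}")
    mat = encode_sequences(library)
    n, L = mat.shape
    if n == 0 or L == 0:
        raise LibraryError("empty library")

    informative = mat < 4  # unambiguous residue
    n_inf = informative.sum(axis=0)
    # max == min over informative rows <=> single state
    masked_min = np.where(informative, mat, 255).min(axis=0)
    masked_max = np.where(informative, mat, 0).max(axis=0)
    identical = (n_inf >= 2) & (masked_min == masked_max)
    identical_sites = int(identical.sum())

    total_ident = 0.0
    n_pairs = 0
    for i in range(n - 1):
        a = mat[i]
        rest = mat[i + 1 :]
        if gap_policy == "exclude":
            comp = (a < 4) & (rest < 4)
        else:
            a_res, r_res = a < 4, rest < 4
            comp = (a_res & r_res) | (a_res & (rest == GAP_CODE)) | ((a == GAP_CODE) & r_res)
        match = comp & (rest == a) & (a < 4)
        n_comp = comp.sum(axis=1)
        ok = n_comp > 0
        total_ident += float((match.sum(axis=1)[ok] / n_comp[ok]).sum())
        n_pairs += int(ok.sum())

    mean_pid = total_ident / n_pairs if n_pairs else 1.0
    return AlignmentSummary(
        n_sequences=n,
        n_sites=L,
        identical_sites=identical_sites,
        identical_fraction=identical_sites / L,
        mean_pairwise_identity=mean_pid,
    )
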