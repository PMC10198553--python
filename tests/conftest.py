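import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix
from barcodekit.library_io import BarcodeRecord, ReferenceLibrary


def make_record(rid, species="Themeda triandra", genus="Themeda", family="Poaceae",
                sequence="ACGTACGT", marker="rbcL", voucher=True, herbarium=""):
    return BarcodeRecord(
        record_id=rid, marker=marker, family=family, genus=genus,
        species=species, sequence=sequence, has_voucher=voucher, herbarium=herbarium,
    )


def make_library(seqs_by_id, species_by_id=None, aligned=True, **kwargs):
    """Small aligned library; species defaults to one species per record prefix."""
    records = []
    for rid, seq in seqs_by_id.items():
        sp = (species_by_id or {}).get(rid, rid[0])
        records.append(
            make_record(rid, species=f"Genus {sp}", genus=f"Genus{sp}",
                        family=f"Family{sp}", sequence=seq, **kwargs)
        )
    return ReferenceLibrary(marker="rbcL", records=records, aligned=aligned)


def matrix_from_array(d, ids=None, model="K2P"):
    d = np.asarray(d, dtype=float)
    ids = ids or [f"r{i}" for i in range(d.shape[0])]
    undef = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if np.isnan(d[i, j])
    ]
    return DistanceMatrix(list(ids), d, model, undef)


def random_distance_matrix(rng, n=30, n_labels=8, scale=0.05):
    """Random symmetric matrix with random rank labels, for oracle tests."""
    d = rng.uniform(0, scale, size=(n, n))
    d = np.triu(d, k=1)
    d = d + d.T
    ids = [f"q{i:02d}" for i in range(n)]
    labels = {i: f"sp{rng.integers(0, n_labels)}" for i in ids}
    return matrix_from_array(d, ids), labels


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
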