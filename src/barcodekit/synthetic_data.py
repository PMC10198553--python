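"""Synthetic reference libraries with known taxonomic structure.

Sequences evolve down a fixed family > genus > species > individual hierarchy
(a star topology within each level) under the Kimura two-parameter
substitution process, so intra- and interspecific divergences are controlled
directly by the per-level branch lengths. Two individuals of one species
diverge through their common species ancestor, so their expected distance is
about twice ``d_intra``; congeneric species pairs about ``2(d_species +
d_intra)``, and so on up the hierarchy. Defaults emulate a plant-barcode
library in which intraspecific distances have median ~0 and interspecific
distances median ~0.01.

Optionally, a fraction of species are reduced to singletons and a fraction of
records receive a wrong taxonomy (copied from a record in another family);
the accompanying truth table records the original labels so mislabel
detection can be scored.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .library_io import BarcodeRecord, LibraryError, ReferenceLibrary

__all__ = ["SimulationParams", "evolve_sequence", "simulate_library"]

_ALPHABET = np.array(list("ACGT"))
# transition partner: A<->G, C<->T
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
# the two transversion targets per base
_TRANSVERSION = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


@dataclass
class SimulationParams:
    """Study-condition knobs for library simulation.

    Branch lengths are expected substitutions per site on each hierarchy
    edge; ``kappa`` is the transition/transversion rate ratio.
    """

    n_families: int = 5
    genera_per_family: int = 2
    species_per_genus: int = 5
    individuals_per_species: int | Sequence[int] | Callable[[np.random.Generator], int] = 3
    singleton_fraction: float = 0.1
    seq_length: int = 600
    d_family: float = 0.004
    d_genus: float = 0.002
    d_species: float = 0.001
    d_intra: float = 0.0003
    kappa: float = 2.0
    mislabel_fraction: float = 0.0
    marker: str = "rbcL"
    seed: int | None = None
    strict_hierarchy: bool = True

    def __post_init__(self) -> None:
        for name in ("n_families", "genera_per_family", "species_per_genus", "seq_length"):
            if getattr(self, name) < 1:
                raise LibraryError(f"{name} must be >= 1")
        if isinstance(self.individuals_per_species, int) and self.individuals_per_species < 1:
            raise LibraryError("individuals_per_species must be >= 1")
        for name in ("singleton_fraction", "mislabel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise LibraryError(f"{name} must be in [0, 1]")
        rates = (self.d_family, self.d_genus, self.d_species, self.d_intra)
        if any(r < 0 for r in rates) or self.kappa < 0:
            raise LibraryError("branch lengths and kappa must be >= 0")
        if any(r >= 0.75 for r in rates):
            raise LibraryError("per-edge rates must be < 0.75")
        if self.strict_hierarchy and not (
            self.d_family > self.d_genus > self.d_species >= self.d_intra >= 0
        ):
            raise LibraryError(
                "strict hierarchy requires d_family > d_genus > d_species >= d_intra"
            )

    def to_json(self) -> str:
        d = asdict(self)
        if callable(d["individuals_per_species"]):
            d["individuals_per_species"] = "callable"
        return json.dumps(d, indent=2, sort_keys=True)


def _k2p_site_probs(branch_length: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-target transversion prob) at a branch length.

    With transition rate kappa*beta and each of the two transversions at rate
    beta, the expected substitutions per site are (kappa + 2) * beta * t, so
    beta*t = d / (kappa + 2).
    """
    bt = branch_length / (kappa + 2.0)
    at = kappa * bt
    e4b = np.exp(-4.0 * bt)
    p_ts = 0.25 + 0.25 * e4b - 0.5 * np.exp(-2.0 * (at + bt))
    p_tv_each = 0.25 - 0.25 * e4b
    return float(p_ts), float(p_tv_each)


def _evolve_codes(
    parent: np.ndarray, branch_length: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    if branch_length < 0:
        raise LibraryError("branch_length must be >= 0")
    if branch_length == 0:
        return parent.copy()
    p_ts, p_tv = _k2p_site_probs(branch_length, kappa)
    u = rng.random(parent.size)
    coin = rng.integers(0, 2, size=parent.size)
    child = parent.copy()
    ts = u < p_ts
    tv = (u >= p_ts) & (u < p_ts + 2.0 * p_tv)
    child[ts] = _TRANSITION[parent[ts]]
    child[tv] = _TRANSVERSION[parent[tv], coin[tv]]
    return child


def evolve_sequence(
    parent: str, branch_length: float, kappa: float, rng: np.random.Generator
) -> str:
    """Evolve a gapless ACGT sequence for a given expected substitutions/site.

    Sites are independent; each site substitutes according to the exact K2P
    transition probabilities at the branch length.
    """
    codes = np.array(["ACGT".index(c) for c in parent.upper()], dtype=np.uint8)
    return "".join(_ALPHABET[_evolve_codes(codes, branch_length, kappa, rng)])


def _n_individuals(params: SimulationParams, rng: np.random.Generator) -> int:
    ind = params.individuals_per_species
    if isinstance(ind, int):
        return ind
    if callable(ind):
        return max(1, int(ind(rng)))
    return max(1, int(rng.choice(np.asarray(ind))))


def simulate_library(params: SimulationParams) -> tuple[ReferenceLibrary, pd.DataFrame]:
    """Simulate a reference library plus its ground-truth table.

    Returns the (gapless, aligned) library and a truth table with one row per
    record: assigned and true family/genus/species and a mislabeled flag.
    The same params and seed reproduce the library bit-for-bit.
    """
    rng = np.random.default_rng(params.seed)
    root = rng.integers(0, 4, size=params.seq_length).astype(np.uint8)

    records: list[dict] = []
    species_sizes: list[tuple[int, int]] = []  # (species index, planned size)
    for f in range(params.n_families):
        fam_anc = _evolve_codes(root, params.d_family, params.kappa, rng)
        family = f"Family{f + 1:02d}"
        for g in range(params.genera_per_family):
            gen_anc = _evolve_codes(fam_anc, params.d_genus, params.kappa, rng)
            genus = f"{family}_Genus{g + 1:02d}"
            for s in range(params.species_per_genus):
                sp_anc = _evolve_codes(gen_anc, params.d_species, params.kappa, rng)
                species = f"{genus}_sp{s + 1:02d}"
                n_ind = _n_individuals(params, rng)
                species_sizes.append((len(species_sizes), n_ind))
                for k in range(n_ind):
                    seq = _evolve_codes(sp_anc, params.d_intra, params.kappa, rng)
                    records.append(
                        {
                            "record_id": f"F{f + 1:02d}G{g + 1:02d}S{s + 1:02d}_{k + 1:02d}",
                            "family": family,
                            "genus": genus,
                            "species": species,
                            "codes": seq,
                            "species_idx": len(species_sizes) - 1,
                        }
                    )

    # reduce a fraction of multi-individual species to singletons
    n_species = len(species_sizes)
    n_singletons = int(round(params.singleton_fraction * n_species))
    reducible = [i for i, size in species_sizes if size > 1]
    chosen = set(
        rng.choice(np.array(reducible), size=min(n_singletons, len(reducible)), replace=False).tolist()
        if reducible and n_singletons
        else []
    )
    if chosen:
        kept: list[dict] = []
        seen: set[int] = set()
        for rec in records:
            si = rec["species_idx"]
            if si in chosen and si in seen:
                continue
            seen.add(si)
            kept.append(rec)
        records = kept

    # inject mislabels: a record takes the taxonomy of a donor in another family
    n = len(records)
    n_mislabel = int(round(params.mislabel_fraction * n))
    truth_rows = []
    mislabeled = set()
    if n_mislabel:
        order = rng.permutation(n)
        for idx in order:
            if len(mislabeled) == n_mislabel:
                break
            donors = [r for r in records if r["family"] != records[idx]["family"]]
            if not donors:
                break
            donor = donors[int(rng.integers(0, len(donors)))]
            rec = records[idx]
            rec["true_taxonomy"] = (rec["family"], rec["genus"], rec["species"])
            rec["family"], rec["genus"], rec["species"] = (
                donor["family"],
                donor["genus"],
                donor["species"],
            )
            mislabeled.add(idx)

    barcode_records = []
    for idx, rec in enumerate(records):
        true_fam, true_gen, true_sp = rec.get(
            "true_taxonomy", (rec["family"], rec["genus"], rec["species"])
        )
        barcode_records.append(
            BarcodeRecord(
                record_id=rec["record_id"],
                marker=params.marker,
                family=rec["family"],
                genus=rec["genus"],
                species=rec["species"],
                sequence="".join(_ALPHABET[rec["codes"]]),
                has_voucher=True,
            )
        )
        truth_rows.append(
            {
                "record_id": rec["record_id"],
                "family": rec["family"],
                "genus": rec["genus"],
                "species": rec["species"],
                "true_family": true_fam,
                "true_genus": true_gen,
                "true_species": true_sp,
                "mislabeled": idx in mislabeled,
            }
        )

    library = ReferenceLibrary(
        marker=params.marker, records=barcode_records, aligned=True
    )
    truth = pd.DataFrame(truth_rows)
    return library, truth
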