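"""End-to-end report generation: curate -> distances -> tree -> gap -> identify.

``run_pipeline`` drives every stage from a single JSON-style config dict and
writes all module outputs plus one summary JSON. All randomness (simulation,
bootstrap) funnels through the run seed, so identical config + seed produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import curation, distances, gap_analysis, identification, library_io, phylogeny
from .library_io import LibraryError, ReferenceLibrary
from .synthetic_data import SimulationParams, simulate_library

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "marker": "rbcL",
    "rank": "species",  # rank for identification simulations
    "model": "K2P",
    "grid": {"start": 0.001, "stop": 0.020, "step": 0.001},
    "seed": 0,
    "curate": False,
    "max_per_species": 3,
    "bootstrap_reps": 0,  # 0 disables bootstrap (slow on large libraries)
    "outlier_k": 5,
    "clamp_negative_branches": False,
}


def _build_grid(spec: Mapping[str, float]) -> np.ndarray:
    start, stop, step = spec["start"], spec["stop"], spec["step"]
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 9)


def _load_library(config: Mapping[str, Any]) -> tuple[ReferenceLibrary, Any]:
    if "simulate" in config:
        sim_cfg = dict(config["simulate"])
        sim_cfg.setdefault("seed", config.get("seed", 0))
        sim_cfg.setdefault("marker", config.get("marker", "rbcL"))
        params = SimulationParams(**sim_cfg)
        return simulate_library(params)
    if "fasta" in config:
        lib = library_io.parse_reference_fasta(
            config["fasta"], force_aligned=config.get("force_aligned")
        )
        return lib, None
    raise LibraryError("config must contain a 'simulate' block or a 'fasta' path")


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict:
    """Execute the full validation pipeline and write the report bundle.

    Outputs under ``outdir``: the (possibly curated) library FASTA + taxonomy
    sidecar, rejection report, distance matrix TSV, newick tree, outlier-flag
    TSV, gap scatter TSV + distribution JSON, threshold table TSV, per-
    criterion outcome TSVs, the identification grid, and ``summary.json``.
    Returns the summary dict. On stage failure, outputs written so far remain
    and ``manifest.json`` lists them.
    """
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest.append(name)

    try:
        library, truth = _load_library(cfg)
        if truth is not None:
            emit("truth.tsv", lambda p: truth.to_csv(p, sep="\t", index=False))

        if cfg["curate"]:
            selected, rejected = curation.select_records(
                library, max_per_species=cfg["max_per_species"]
            )
            emit(
                "rejections.tsv",
                lambda p: curation.rejections_to_frame(rejected).to_csv(
                    p, sep="\t", index=False
                ),
            )
            keep = {r.record_id for r in selected}
            library = ReferenceLibrary(
                marker=library.marker,
                records=[r for r in library.records if r.record_id in keep],
                aligned=library.aligned,
            )
        emit("library.fasta", lambda p: library_io.write_reference_fasta(library, p))
        emit("taxonomy.tsv", lambda p: library_io.write_taxonomy_table(library, p))

        summary: dict[str, Any] = {
            "config": {k: v for k, v in cfg.items() if k != "simulate"},
            "seed": cfg["seed"],
            "counts": library.counts(),
        }
        if "simulate" in cfg:
            summary["config"]["simulate"] = dict(cfg["simulate"])
        fam_index = library.rank_index("family")
        summary["per_family"] = {
            fam: {
                "n_sequences": len(recs),
                "n_genera": len({r.genus for r in recs}),
                "n_species": len({r.species for r in recs}),
            }
            for fam, recs in sorted(fam_index.items())
        }

        if library.aligned:
            asum = library_io.alignment_summary(library)
            summary["alignment"] = {
                "n_sites": asum.n_sites,
                "identical_sites": asum.identical_sites,
                "identical_fraction": round(asum.identical_fraction, 6),
                "mean_pairwise_identity": round(asum.mean_pairwise_identity, 6),
            }

        dm = distances.distance_matrix(library, model=cfg["model"])
        emit("distance_matrix.tsv", lambda p: distances.write_matrix_tsv(dm, p))
        summary["n_undefined_pairs"] = len(dm.undefined_pairs)

        # tree + outlier flags need a complete matrix
        if dm.is_complete and len(dm) >= 3:
            if cfg["bootstrap_reps"] > 0:
                tree, n_skipped = phylogeny.bootstrap_support(
                    library,
                    model="JC",
                    n_reps=cfg["bootstrap_reps"],
                    seed=cfg["seed"],
                    clamp_negative=cfg["clamp_negative_branches"],
                )
                summary["bootstrap_skipped"] = n_skipped
            else:
                tree = phylogeny.neighbor_joining(
                    dm, clamp_negative=cfg["clamp_negative_branches"]
                )
            emit("tree.nwk", lambda p: phylogeny.write_newick(tree, p))
            summary["tree_total_branch_length"] = round(
                phylogeny.sum_branch_lengths(tree), 6
            )
            flags, skipped = phylogeny.flag_taxonomic_outliers(
                tree, library.labels("family"), k=cfg["outlier_k"]
            )
            emit(
                "outlier_flags.tsv",
                lambda p: _flags_to_tsv(flags, skipped, p),
            )
            summary["n_outlier_flags"] = len(flags)

        sp_labels = library.labels("species")
        dists = gap_analysis.split_distances(dm, sp_labels)
        emit(
            "distance_distributions.json",
            lambda p: p.write_text(gap_analysis.distributions_to_json(dists)),
        )
        summary["intraspecific"] = dists.intra_summary
        summary["interspecific"] = dists.inter_summary
        if dists.intra.size and dists.inter.size:
            u, pval = gap_analysis.rank_sum_test(
                dists.inter, dists.intra, alternative="greater"
            )
            summary["wilcoxon"] = {"U": u, "p_value": pval}

        gap_records, singletons = gap_analysis.per_sequence_gap(dm, sp_labels)
        emit(
            "gap_scatter.tsv",
            lambda p: gap_analysis.gap_records_to_frame(gap_records, singletons).to_csv(
                p, sep="\t", index=False
            ),
        )
        summary["gap_proportion"] = {
            "sequence": round(gap_analysis.gap_proportion(gap_records, "sequence"), 6),
            "species": round(gap_analysis.gap_proportion(gap_records, "species"), 6),
            "n_singletons_excluded": len(singletons),
        }

        rank_labels = library.labels(cfg["rank"])
        grid = _build_grid(cfg["grid"])
        table = identification.optimize_threshold(dm, rank_labels, grid=grid)
        emit(
            "threshold_table.tsv",
            lambda p: table.to_dataframe().to_csv(p, sep="\t", index=False),
        )
        summary["optimal_threshold"] = table.optimum
        summary["threshold_grid"] = dict(cfg["grid"])

        knn_out, knn_rate = identification.knn_identify(dm, rank_labels, rank=cfg["rank"])
        _, knn_rate_ns = identification.knn_identify(
            dm, rank_labels, rank=cfg["rank"], exclude_singletons=True
        )
        emit(
            "knn_outcomes.tsv",
            lambda p: identification.outcomes_to_frame(knn_out).to_csv(
                p, sep="\t", index=False
            ),
        )
        summary["knn_success_rate"] = round(knn_rate, 6)
        summary["knn_success_rate_excl_singletons"] = (
            round(knn_rate_ns, 6) if np.isfinite(knn_rate_ns) else None
        )

        grid_df = identification.run_table1(
            dm, rank_labels, table.optimum, rank=cfg["rank"]
        )
        emit(
            "identification_grid.tsv",
            lambda p: grid_df.to_csv(p, sep="\t", index=False),
        )
        summary["identification_grid"] = grid_df.to_dict(orient="records")

        emit(
            "summary.json",
            lambda p: p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n"),
        )
        (outdir / "manifest.json").write_text(
            json.dumps({"status": "ok", "outputs": manifest}, indent=2) + "\n"
        )
        return summary
    except Exception:
        (outdir / "manifest.json").write_text(
            json.dumps({"status": "failed", "outputs": manifest}, indent=2) + "\n"
        )
        raise


def _flags_to_tsv(flags, skipped, path: Path) -> None:
    import pandas as pd

    rows = [
        {
            "record_id": f.record_id,
            "label": f.label,
            "neighbour_labels": ";".join(f.neighbour_labels),
            "agreeing": f.agreeing,
            "status": "flagged",
        }
        for f in flags
    ] + [{"record_id": s, "status": "unassessable"} for s in skipped]
    pd.DataFrame(
        rows, columns=["record_id", "label", "neighbour_labels", "agreeing", "status"]
    ).to_csv(path, sep="\t", index=False)
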