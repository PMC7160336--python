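"""End-to-end orchestration: cohort → per-stage tables on disk.

``run_pipeline`` ties the library stages into the figure-level outputs a
repertoire study reports: per-sample sequencing statistics and their
correlations, evenness-profile correlation with clustering, per-patient
persistence tables, public-clone statistics and highly-shared-clone
matrices, LD-1 network exports with degree/connectivity summaries, k-mer
correlation with clustering, database-overlap summaries, and Wilcoxon
group-comparison tables annotated at p < 0.05 / p < 0.01.

Outputs are pure functions of (config, seed): no timestamps or absolute
paths are written, so re-running the same configuration into a different
directory produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .annotate import overlap_by_category
from .architecture import (
    build_ld1_network,
    connected_fraction,
    degree_distribution,
    kmer_correlation_matrix,
    kmer_profile,
    kmer_profiles_to_frame,
)
from .core import Repertoire, correlate_stats, summarize_repertoire
from .diversity import (
    evenness_profile,
    profile_correlation_matrix,
    profiles_to_frame,
)
from .io import load_cohort
from .simulate import CohortSpec, generate_annotation_db, generate_cohort
from .stats import comparisons_to_frame, group_compare, hierarchical_cluster
from .tracking import (
    classify_publicity,
    highly_shared_clones,
    persistence_table,
    public_clone_stats,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "stats", "diversity", "persistence", "publicity",
    "network", "kmers", "dboverlap", "compare",
)

DEFAULT_PARAMS = {
    "top_n": 10_000,
    "k": 3,
    "kmer_weighting": "unique_cdr3",
    "min_samples": 11,
    "sharing_unit": "sample",
    "pairing": "cross_subpopulation",
    "profile_linkage": "average",
    "export_graphml": True,
}


def default_config() -> dict:
    """Default synthetic-cohort configuration running every stage."""
    return {
        "cohort": {"source": "synthetic", "spec": {}},
        "stages": list(ALL_STAGES),
        "params": dict(DEFAULT_PARAMS),
        "databases": "synthetic",
    }


def _load_input_cohort(cohort_cfg: dict, seed: int | None) -> tuple[list[Repertoire], CohortSpec | None]:
    source = cohort_cfg.get("source", "synthetic")
    if source == "synthetic":
        spec_kwargs = dict(cohort_cfg.get("spec", {}))
        if "cdr3_length_range" in spec_kwargs:
            spec_kwargs["cdr3_length_range"] = tuple(spec_kwargs["cdr3_length_range"])
        if seed is not None:
            spec_kwargs["seed"] = seed
        spec = CohortSpec(**spec_kwargs)
        return generate_cohort(spec).repertoires, spec
    if source == "files":
        cohort = load_cohort(
            cohort_cfg["metadata"],
            cohort_cfg["clone_dir"],
            dialect=cohort_cfg.get("dialect", "airr"),
        )
        return cohort, None
    raise ValueError(f"unknown cohort source: {source!r}")


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix == ".csv" else "\t"
    df.to_csv(path, sep=sep, **kwargs)


def _clustering_frames(result) -> tuple[pd.DataFrame, pd.DataFrame]:
    merges = pd.DataFrame(
        result.merges, columns=["left", "right", "height", "n_members"]
    )
    leaves = pd.DataFrame({"order": range(len(result.leaf_order)),
                           "sample_id": result.leaf_order})
    return merges, leaves


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


def run_pipeline(config: dict | None = None, outdir: str | Path = "tcrtrace_out",
                 seed: int | None = None) -> dict:
    """Run the configured stages; returns the manifest written to disk."""
    config = config or default_config()
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    stages = list(config.get("stages", ALL_STAGES))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort, spec = _load_input_cohort(config.get("cohort", {}), seed)
    meta = pd.DataFrame(
        {
            "sample_id": r.sample_id,
            "patient_id": r.patient_id,
            "treatment": r.treatment,
            "subpopulation": r.subpopulation,
            "timepoint": r.timepoint,
            "hla_drb1_1501": r.hla_drb1_1501,
        }
        for r in cohort
    )

    # lazily computed shared intermediates
    cache: dict[str, object] = {}

    def publicity():
        if "publicity" not in cache:
            cache["publicity"] = classify_publicity(
                cohort, sharing_unit=params["sharing_unit"]
            )
        return cache["publicity"]

    def sample_stats() -> pd.DataFrame:
        if "sample_stats" not in cache:
            rows = []
            for r in cohort:
                s = summarize_repertoire(r)
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "n_cells": s.n_cells,
                        "n_reads": s.n_reads,
                        "n_clones": s.n_clones,
                        "shannon_evenness": s.shannon_evenness,
                    }
                )
            cache["sample_stats"] = meta.merge(pd.DataFrame(rows), on="sample_id")
        return cache["sample_stats"]

    def networks():
        if "networks" not in cache:
            pub = publicity()
            cache["networks"] = [
                build_ld1_network(r, top_n=params["top_n"], publicity=pub)
                for r in cohort
            ]
        return cache["networks"]

    def connectivity() -> pd.DataFrame:
        if "connectivity" not in cache:
            rows = []
            for net in networks():
                for cls in ("private", "public", "all"):
                    rows.append(
                        {
                            "sample_id": net.sample_id,
                            "clone_class": cls,
                            "connected_pct": connected_fraction(net, cls),
                        }
                    )
            cache["connectivity"] = pd.DataFrame(rows)
        return cache["connectivity"]

    def overlaps() -> pd.DataFrame:
        if "overlaps" not in cache:
            dbs = config.get("databases", "synthetic")
            frames = []
            if dbs == "synthetic":
                if spec is None:
                    raise ValueError(
                        "synthetic databases require a synthetic cohort; "
                        "configure 'databases' with file entries"
                    )
                db = generate_annotation_db(spec)
                frames.append(overlap_by_category(cohort, db))
            else:
                from .annotate import load_db

                for entry in dbs:
                    db = load_db(entry["path"], entry["dialect"])
                    df = overlap_by_category(cohort, db)
                    df["source"] = entry.get("name", entry["dialect"])
                    frames.append(df)
            cache["overlaps"] = pd.concat(frames, ignore_index=True)
        return cache["overlaps"]

    def run_stats(stage_dir: Path):
        stats_df = sample_stats()
        _write(stats_df, stage_dir / "sample_stats.tsv", index=False)
        fields = ["n_cells", "n_reads", "n_clones", "shannon_evenness"]
        rows = []
        for treatment, group in stats_df.groupby("treatment"):
            recs = group.to_dict("records")
            for i, x in enumerate(fields):
                for y in fields[i + 1:]:
                    rows.append(
                        {
                            "treatment": treatment,
                            "x": x,
                            "y": y,
                            "pearson_r": correlate_stats(recs, x, y),
                            "n": len(recs),
                        }
                    )
        _write(pd.DataFrame(rows), stage_dir / "stat_correlations.tsv", index=False)

    def run_diversity(stage_dir: Path):
        profiles = [evenness_profile(r) for r in cohort]
        _write(profiles_to_frame(profiles), stage_dir / "evenness_profiles.tsv",
               index=True, index_label="sample_id")
        corr = profile_correlation_matrix(profiles)
        _write(corr, stage_dir / "profile_correlation.csv", index=True,
               index_label="sample_id")
        clust = hierarchical_cluster(
            corr.fillna(0.0), distance="one_minus_pearson",
            linkage=params["profile_linkage"],
        )
        merges, leaves = _clustering_frames(clust)
        _write(merges, stage_dir / "profile_clustering_merges.tsv", index=False)
        _write(leaves, stage_dir / "profile_clustering_leaves.tsv", index=False)

    def run_persistence(stage_dir: Path):
        table = persistence_table(cohort, pairing=params["pairing"])
        _write(table, stage_dir / "persistence.tsv", index=False)

    def run_publicity(stage_dir: Path):
        pub = publicity()
        stats_df = public_clone_stats(cohort, records=pub)
        _write(stats_df, stage_dir / "public_clone_stats.tsv", index=False)
        hits, matrix = highly_shared_clones(
            cohort, min_samples=params["min_samples"], records=pub
        )
        _write(matrix, stage_dir / "highly_shared_matrix.csv", index=True,
               index_label="clone_key")
        hits_df = pd.DataFrame(
            {
                "clone_key": "|".join(rec.clone_key),
                "n_samples_sharing": len(rec.sample_ids),
                "publicity": rec.publicity,
            }
            for rec in hits
        )
        _write(hits_df, stage_dir / "highly_shared_clones.tsv", index=False)

    def run_network(stage_dir: Path):
        nets = networks()
        deg_rows = []
        for net in nets:
            dd = degree_distribution(net)
            dd.insert(0, "sample_id", net.sample_id)
            deg_rows.append(dd)
            edges = pd.DataFrame(sorted(net.graph.edges()), columns=["cdr3_a", "cdr3_b"])
            _write(edges, stage_dir / "edges" / f"{net.sample_id}.tsv", index=False)
            if params["export_graphml"]:
                gml_dir = stage_dir / "graphml"
                gml_dir.mkdir(parents=True, exist_ok=True)
                nx.write_graphml(net.graph, gml_dir / f"{net.sample_id}.graphml")
        deg_long = pd.concat(deg_rows, ignore_index=True)
        _write(deg_long, stage_dir / "degree_distributions.tsv", index=False)
        # samples × degree fraction matrix (degree heatmap input)
        deg_matrix = (
            deg_long.pivot(index="sample_id", columns="degree", values="fraction")
            .fillna(0.0)
            .sort_index()
        )
        _write(deg_matrix, stage_dir / "degree_matrix.tsv", index=True)
        clust = hierarchical_cluster(
            deg_matrix, distance="euclidean", linkage="average",
            labels=list(deg_matrix.index),
        )
        merges, leaves = _clustering_frames(clust)
        _write(merges, stage_dir / "degree_clustering_merges.tsv", index=False)
        _write(leaves, stage_dir / "degree_clustering_leaves.tsv", index=False)
        _write(connectivity(), stage_dir / "connected_fractions.tsv", index=False)

    def run_kmers(stage_dir: Path):
        profiles = [
            kmer_profile(r, k=params["k"], weighting=params["kmer_weighting"])
            for r in cohort
        ]
        _write(kmer_profiles_to_frame(profiles), stage_dir / "kmer_profiles.tsv",
               index=False)
        corr = kmer_correlation_matrix(profiles)
        _write(corr, stage_dir / "kmer_correlation.csv", index=True,
               index_label="sample_id")
        clust = hierarchical_cluster(
            corr.fillna(0.0), distance="one_minus_pearson",
            linkage=params["profile_linkage"],
        )
        merges, leaves = _clustering_frames(clust)
        _write(merges, stage_dir / "kmer_clustering_merges.tsv", index=False)
        _write(leaves, stage_dir / "kmer_clustering_leaves.tsv", index=False)

    def run_dboverlap(stage_dir: Path):
        df = overlaps()
        _write(df, stage_dir / "db_overlap.tsv", index=False)
        per_sample = df.drop_duplicates("sample_id")[
            ["sample_id", "treatment", "subpopulation", "timepoint",
             "source", "n_overlap", "pct_overlap"]
        ]
        _write(per_sample, stage_dir / "db_overlap_per_sample.tsv", index=False)

    def run_compare(stage_dir: Path):
        table = sample_stats().copy()
        extra_stats = ["shannon_evenness", "n_clones"]
        pub_stats = public_clone_stats(cohort, records=publicity())
        table = table.merge(pub_stats[["sample_id", "pct_public"]], on="sample_id")
        extra_stats.append("pct_public")
        if "network" in stages:  # reuse the already-built networks only
            conn = connectivity()
            conn_all = conn[conn["clone_class"] == "all"][
                ["sample_id", "connected_pct"]
            ]
            table = table.merge(conn_all, on="sample_id")
            extra_stats.append("connected_pct")
        if "dboverlap" in stages:
            ov = overlaps().drop_duplicates("sample_id")[["sample_id", "n_overlap"]]
            table = table.merge(ov, on="sample_id")
            extra_stats.append("n_overlap")

        comparisons = []
        shared_subpops = sorted(
            set(table.loc[table.treatment == "AHSCT", "subpopulation"])
            & set(table.loc[table.treatment == "NTZ", "subpopulation"])
        )
        for stat in extra_stats:
            # across treatments, per shared subpopulation and timepoint
            for subpop in shared_subpops:
                for tp in ("t0", "t24"):
                    sel = table[(table.subpopulation == subpop) & (table.timepoint == tp)]
                    a = sel.loc[sel.treatment == "AHSCT", stat].dropna()
                    b = sel.loc[sel.treatment == "NTZ", stat].dropna()
                    if len(a) and len(b):
                        comparisons.append(
                            group_compare(
                                a, b, test="rank_sum_unpaired",
                                statistic_name=stat,
                                group_a=f"AHSCT_{subpop}_{tp}",
                                group_b=f"NTZ_{subpop}_{tp}",
                            )
                        )
            # paired t0 vs t24 within treatment and subpopulation
            for (treatment, subpop), sel in table.groupby(["treatment", "subpopulation"]):
                wide = sel.pivot(index="patient_id", columns="timepoint", values=stat)
                if "t0" not in wide or "t24" not in wide:
                    continue
                wide = wide.dropna()
                if len(wide) < 2:
                    continue
                comparisons.append(
                    group_compare(
                        wide["t0"], wide["t24"], test="signed_rank_paired",
                        statistic_name=stat,
                        group_a=f"{treatment}_{subpop}_t0",
                        group_b=f"{treatment}_{subpop}_t24",
                    )
                )
        _write(comparisons_to_frame(comparisons),
               stage_dir / "group_comparisons.tsv", index=False)

    runners = {
        "stats": run_stats,
        "diversity": run_diversity,
        "persistence": run_persistence,
        "publicity": run_publicity,
        "network": run_network,
        "kmers": run_kmers,
        "dboverlap": run_dboverlap,
        "compare": run_compare,
    }
    unknown = set(stages) - set(runners)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    if spec is not None:
        from .simulate import SyntheticCohort, generate_public_pool, write_cohort

        bundle = SyntheticCohort(
            spec=spec, repertoires=cohort,
            metadata=pd.DataFrame(), public_pool=generate_public_pool(spec),
        )
        # re-derive metadata table for the emitted cohort
        bundle.metadata = pd.DataFrame(
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "treatment": r.treatment,
                "subpopulation": r.subpopulation,
                "timepoint": r.timepoint,
                "hla_drb1_1501": r.hla_drb1_1501,
                "filename": f"{r.sample_id}.tsv",
                "n_cells": r.n_cells,
            }
            for r in cohort
        )
        write_cohort(bundle, outdir / "cohort")

    for name in ALL_STAGES:
        if name not in stages:
            continue
        logger.info("stage %s: running", name)
        try:
            runners[name](outdir / name)
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    manifest = {
        "package": "tcrtrace",
        "version": __version__,
        "seed": seed if seed is not None else (spec.seed if spec else None),
        "config": {
            "cohort": {
                "source": config.get("cohort", {}).get("source", "synthetic"),
                "spec": dataclasses.asdict(spec) if spec else None,
            },
            "stages": stages,
            "params": params,
            "databases": "synthetic"
            if config.get("databases", "synthetic") == "synthetic"
            else [e.get("name", e["dialect"]) for e in config["databases"]],
        },
        "n_samples": len(cohort),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    return manifest
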