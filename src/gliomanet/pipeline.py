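"""End-to-end orchestration: expression seeds -> networks -> comparisons.

The workflow mirrors a differential-network study across disease subtypes:

1. filter the expression table to per-condition seed gene lists (absolute
   FPKM cutoff, then GO-keyword narrowing);
2. build one first-order PPI network per condition x interaction database,
   translating seed identifiers into each database's native space;
3. per database: merged intersection and union across conditions, a
   difference ("unique") network per condition, and a statistics table;
4. cohesiveness clustering of every disease network;
5. GO over-representation of every unique network against the database's
   gene universe;
6. cross-database hub consensus, per-database common isolated nodes, and
   Ensembl-keyed cross-database node merges.

All artifacts land under one run directory and a manifest records the
configuration, input checksums and per-stage counts.  Re-running with
unchanged inputs reproduces identical artifacts except the manifest
timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .annotations import AnnotationTable, IdMap, map_ids, merge_idmaps
from .clustering import (
    ClusteringResult,
    cluster_network,
    write_clusters_tsv,
    write_roles_tsv,
)
from .consensus import (
    ConsensusMatch,
    MergeReport,
    common_isolated,
    compare_stats_table,
    cross_db_merge,
    hub_consensus,
)
from .core import GeneSet, write_gene_list, write_gene_table
from .enrichment import EnrichmentRow, enrich, write_enrichment_tsv
from .expression import (
    filter_by_cutoff,
    filter_by_go_keyword,
    parse_expression_table,
    symbol_index,
)
from .graphops import HubList, difference_network, intersect_networks, top_hubs, union_networks
from .netbuild import (
    build_first_order_network,
    parse_interactions,
    write_edgelist_tsv,
    write_graphml,
    write_sif,
)

logger = logging.getLogger(__name__)

#: database name -> (dialect, native identifier space, uses confidence scores)
DATABASES = {
    "biogrid": ("biogrid_tab", "entrez", False),
    "string": ("string_links", "ensembl_protein", True),
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass
class PipelineConfig:
    """Paths and parameters driving one complete run."""

    expression: str
    biogrid: str
    string_links: str
    annotation_genes: str
    annotation_terms: str
    idmaps: list[str]
    outdir: str
    conditions: list[str] = field(default_factory=list)
    cutoff: float = 3.0
    go_keyword: str = "proliferation"
    min_score: float = 0.9
    taxon: int = 9606
    penalty: float = 2.0
    min_size: int = 3
    min_density: float = 0.5
    overlap_max: float = 0.8
    alpha: float = 0.05
    top_k: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("expression", "biogrid", "string_links",
                     "annotation_genes", "annotation_terms"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name} input not found: {getattr(self, name)}")
        for p in self.idmaps:
            if not Path(p).exists():
                raise FileNotFoundError(f"idmap input not found: {p}")
        if not 0.0 <= self.min_score <= 1.0:
            raise ValueError("min_score outside [0, 1]")
        if self.cutoff < 0:
            raise ValueError("cutoff must be non-negative")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Every in-memory product of a run, for scoring and inspection."""

    config: PipelineConfig
    seeds: dict[str, GeneSet]
    idmap: IdMap
    annotations: AnnotationTable
    networks: dict[tuple[str, str], object]
    intersections: dict[str, object]
    unions: dict[str, object]
    unique: dict[tuple[str, str], object]
    clusterings: dict[tuple[str, str], ClusteringResult]
    enrichments: dict[tuple[str, str], list[EnrichmentRow]]
    hubs: dict[tuple[str, str], HubList]
    hub_matches: dict[str, ConsensusMatch]
    common_isolated_by_db: dict[str, GeneSet]
    merge_reports: dict[str, MergeReport]
    outdir: Path


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute the whole workflow; see the module docstring for the stages."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "gliomanet",
        "version": __version__,
        "config": config.as_dict(),
        "started_at": datetime.now(timezone.utc).isoformat(),
        "inputs": {},
        "stages": {},
    }
    for name in ("expression", "biogrid", "string_links",
                 "annotation_genes", "annotation_terms"):
        manifest["inputs"][name] = _sha256(getattr(config, name))
    manifest["inputs"]["idmaps"] = [_sha256(p) for p in config.idmaps]

    # ----- stage: filter -------------------------------------------------
    try:
        records = parse_expression_table(config.expression)
        symbols = symbol_index(records)
        annotations = AnnotationTable.from_tsv_pair(
            config.annotation_genes, config.annotation_terms
        )
        conditions = config.conditions or sorted(records[0].values)
        seeds: dict[str, GeneSet] = {}
        for cond in conditions:
            by_cutoff = filter_by_cutoff(records, cond, config.cutoff)
            seeds[cond] = filter_by_go_keyword(by_cutoff, annotations, config.go_keyword)
            write_gene_list(seeds[cond], outdir / f"seeds_{cond}.txt")
            write_gene_table(seeds[cond], symbols, outdir / f"seeds_{cond}.tsv")
        manifest["stages"]["filter"] = {c: len(s) for c, s in seeds.items()}
    except (ValueError, KeyError, OSError) as exc:
        raise StageError("filter", str(exc)) from exc

    # ----- stage: idmap --------------------------------------------------
    try:
        idmap = merge_idmaps(
            [IdMap.from_tsv(p, provenance=Path(p).name) for p in config.idmaps]
        )
        manifest["stages"]["idmap"] = {
            "rows": len(idmap), "conflicts": len(idmap.conflicts)
        }
    except (ValueError, OSError) as exc:
        raise StageError("idmap", str(exc)) from exc

    # ----- stage: build --------------------------------------------------
    networks: dict[tuple[str, str], object] = {}
    build_counts: dict[str, dict] = {}
    try:
        for db, (dialect, space, scored) in DATABASES.items():
            path = config.biogrid if db == "biogrid" else config.string_links
            db_records = parse_interactions(path, dialect, organism=config.taxon)
            for cond in conditions:
                mapped, unmapped = map_ids(seeds[cond], idmap, space)
                if unmapped:
                    logger.warning(
                        "%s/%s: %d seed(s) not mappable to %s: %s",
                        db, cond, len(unmapped), space, unmapped[:5],
                    )
                g = build_first_order_network(
                    mapped,
                    db_records,
                    min_score=config.min_score if scored else None,
                    taxon=config.taxon,
                    label=f"{cond}_{db}",
                )
                networks[(db, cond)] = g
                write_graphml(g, outdir / f"network_{cond}_{db}.graphml")
                write_edgelist_tsv(g, outdir / f"network_{cond}_{db}.edges.tsv")
                write_sif(g, outdir / f"network_{cond}_{db}.sif")
                build_counts[f"{db}/{cond}"] = {
                    "nodes": g.number_of_nodes(),
                    "edges": g.number_of_edges(),
                    "unmapped_seeds": len(unmapped),
                }
        manifest["stages"]["build"] = build_counts
    except (ValueError, OSError) as exc:
        raise StageError("build", str(exc)) from exc

    # ----- stage: algebra + stats ----------------------------------------
    intersections: dict[str, object] = {}
    unions: dict[str, object] = {}
    unique: dict[tuple[str, str], object] = {}
    try:
        for db in DATABASES:
            nets = [networks[(db, cond)] for cond in conditions]
            intersections[db] = intersect_networks(nets, label=f"intersection_{db}")
            unions[db] = union_networks(nets, label=f"union_{db}")
            write_graphml(intersections[db], outdir / f"intersection_{db}.graphml")
            write_graphml(unions[db], outdir / f"union_{db}.graphml")
            for cond in conditions:
                u = difference_network(networks[(db, cond)], intersections[db])
                unique[(db, cond)] = u
                write_graphml(u, outdir / f"unique_{cond}_{db}.graphml")
            table = compare_stats_table(nets)
            table.to_csv(outdir / f"stats_{db}.tsv", sep="\t", index=False)
            with open(outdir / f"stats_{db}.json", "w", encoding="utf-8") as fh:
                json.dump(table.to_dict(orient="records"), fh, indent=2, sort_keys=True)
                fh.write("\n")
        manifest["stages"]["algebra"] = {
            db: {
                "intersection_nodes": intersections[db].number_of_nodes(),
                "union_nodes": unions[db].number_of_nodes(),
            }
            for db in DATABASES
        }
    except (ValueError, OSError) as exc:
        raise StageError("algebra", str(exc)) from exc

    # ----- stage: cluster ------------------------------------------------
    clusterings: dict[tuple[str, str], ClusteringResult] = {}
    try:
        for key, g in networks.items():
            db, cond = key
            result = cluster_network(
                g,
                penalty=config.penalty,
                min_size=config.min_size,
                min_density=config.min_density,
                overlap_max=config.overlap_max,
            )
            clusterings[key] = result
            write_clusters_tsv(result, outdir / f"clusters_{cond}_{db}.tsv")
            write_roles_tsv(result, outdir / f"roles_{cond}_{db}.tsv")
        manifest["stages"]["cluster"] = {
            f"{db}/{cond}": len(res.clusters)
            for (db, cond), res in clusterings.items()
        }
    except (ValueError, OSError) as exc:
        raise StageError("cluster", str(exc)) from exc

    # ----- stage: enrich -------------------------------------------------
    enrichments: dict[tuple[str, str], list[EnrichmentRow]] = {}
    try:
        for db, (dialect, space, scored) in DATABASES.items():
            # background: every gene of this database's input plus all seeds,
            # in Ensembl gene space
            universe_native = set(unions[db].nodes())
            path = config.biogrid if db == "biogrid" else config.string_links
            for rec in parse_interactions(path, dialect, organism=config.taxon):
                universe_native.add(rec.id_a)
                universe_native.add(rec.id_b)
            bg_mapped, _ = map_ids(
                GeneSet(frozenset(universe_native), space), idmap, "ensembl_gene"
            )
            background = GeneSet(
                bg_mapped.ids | frozenset(
                    g for cond in conditions for g in seeds[cond].ids
                ),
                "ensembl_gene",
            )
            for cond in conditions:
                u = unique[(db, cond)]
                study_mapped, study_unmapped = (
                    map_ids(GeneSet(frozenset(u.nodes()), space), idmap, "ensembl_gene")
                    if u.number_of_nodes()
                    else (GeneSet(frozenset(), "ensembl_gene"), [])
                )
                if study_unmapped:
                    logger.warning(
                        "%s/%s: %d unique-network node(s) not mappable to "
                        "ensembl_gene and excluded from enrichment",
                        db, cond, len(study_unmapped),
                    )
                study = study_mapped.intersection(background)
                rows = (
                    enrich(study, background, annotations, alpha=config.alpha)
                    if study.ids
                    else []
                )
                enrichments[(db, cond)] = rows
                write_enrichment_tsv(rows, outdir / f"enrichment_{cond}_{db}.tsv")
        manifest["stages"]["enrich"] = {
            f"{db}/{cond}": len(rows) for (db, cond), rows in enrichments.items()
        }
    except (ValueError, OSError) as exc:
        raise StageError("enrich", str(exc)) from exc

    # ----- stage: consensus ----------------------------------------------
    try:
        hubs = {key: top_hubs(g, config.top_k) for key, g in networks.items()}
        hub_matches = {
            cond: hub_consensus(hubs[("biogrid", cond)], hubs[("string", cond)], idmap)
            for cond in conditions
        }
        common_by_db = {
            db: common_isolated([networks[(db, cond)] for cond in conditions])
            for db in DATABASES
        }
        merge_reports = {
            cond: cross_db_merge(
                networks[("biogrid", cond)], networks[("string", cond)], idmap
            )
            for cond in conditions
        }
        report = {
            "hubs": {
                f"{db}/{cond}": hubs[(db, cond)].ranked
                for (db, cond) in sorted(hubs)
            },
            "hub_matches": {
                cond: {
                    "matched": sorted(m.matched.ids),
                    "match_count": m.match_count,
                    "unmapped_biogrid": m.unmapped_a,
                    "unmapped_string": m.unmapped_b,
                }
                for cond, m in hub_matches.items()
            },
            "common_isolated": {
                db: sorted(s.ids) for db, s in common_by_db.items()
            },
            "cross_db_merge": {
                cond: {
                    "intersecting_nodes": r.intersecting_nodes,
                    "union_nodes": r.union_nodes,
                    "unconnected_in_intersection": r.unconnected_in_intersection,
                }
                for cond, r in merge_reports.items()
            },
        }
        with open(outdir / "consensus.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["stages"]["consensus"] = {
            "hub_matches": {c: m.match_count for c, m in hub_matches.items()},
            "common_isolated": {db: len(s) for db, s in common_by_db.items()},
        }
    except (ValueError, OSError) as exc:
        raise StageError("consensus", str(exc)) from exc

    manifest["finished_at"] = datetime.now(timezone.utc).isoformat()
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        config=config,
        seeds=seeds,
        idmap=idmap,
        annotations=annotations,
        networks=networks,
        intersections=intersections,
        unions=unions,
        unique=unique,
        clusterings=clusterings,
        enrichments=enrichments,
        hubs=hubs,
        hub_matches=hub_matches,
        common_isolated_by_db=common_by_db,
        merge_reports=merge_reports,
        outdir=outdir,
    )


def config_for_dataset(paths: dict, outdir, **overrides) -> PipelineConfig:
    """Convenience: a PipelineConfig wired to files written by the generator."""
    defaults = dict(
        expression=str(paths["expression"]),
        biogrid=str(paths["biogrid"]),
        string_links=str(paths["string"]),
        annotation_genes=str(paths["annotations_genes"]),
        annotation_terms=str(paths["annotations_terms"]),
        idmaps=[str(paths["idmap_primary"]), str(paths["idmap_secondary"])],
        outdir=str(outdir),
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)
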