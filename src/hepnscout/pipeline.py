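"""End-to-end discovery: cluster -> two-stage search -> HEPN-dimer filter
-> CRISPR locus association -> structural phylogeny.

The pipeline mirrors how remote ribonuclease effectors are mined from
predicted-structure databases: a clustered database is searched with one or
more query structures (typically known HEPN dimers, or the two isolated
domains of one), hits are filtered for an intramolecular HEPN dimer,
hit proteins are located in genome sequence and tested for adjacency to a
CRISPR repeat-spacer array, and the surviving candidates are placed on a
structural tree. Every threshold is carried in an explicit config that is
embedded in the report, and all outputs are sorted so a rerun with the same
config and inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from Bio.SeqRecord import SeqRecord

from . import crispr as crispr_mod
from .cluster import ClusterSet, HitRule, greedy_cluster, two_stage_search
from .crispr import ArrayParams, LocusCall, associate_arrays_to_genes, find_crispr_arrays, find_orfs, orf_protein
from .hepn import HEPNDimerCall, classify_segment_order, detect_intramolecular_dimer, write_dimer_tsv
from .phylo import neighbor_joining, structural_distance_matrix, write_newick
from .structio import Structure
from .superpose import StructAlignment

__all__ = ["DiscoveryConfig", "DiscoveryReport", "run_discovery", "write_hits_tsv"]

logger = logging.getLogger("hepnscout.pipeline")


@dataclass
class DiscoveryConfig:
    """Every tunable of every stage, in one place.

    The resolved config is embedded in each report: the pipeline's claim to
    reproducibility is an explicit parameterization, not hidden defaults.
    """

    seed: int = 0
    cluster_threshold: float = 0.8
    prefilter_kmer: int = 3
    top_k: int = 50
    tm_min: float = 0.5
    z_min: float | None = 8.0
    z_null: int = 20
    site_threshold: float = 12.0
    canonical_reference: tuple[str, str] = ("HE", "HE")
    min_orf_aa: int = 100
    max_locus_distance: int = 3000
    array_params: ArrayParams = field(default_factory=ArrayParams)

    def validate(self) -> None:
        errors = []
        if not 0.0 <= self.cluster_threshold:
            errors.append("cluster_threshold must be >= 0")
        if self.prefilter_kmer < 1:
            errors.append("prefilter_kmer must be >= 1")
        if self.top_k < 1:
            errors.append("top_k must be >= 1")
        if not 0.0 <= self.tm_min <= 1.0:
            errors.append("tm_min must be in [0, 1]")
        if self.z_min is not None and self.z_null < 10:
            errors.append("z_null must be >= 10 when z_min is set")
        if self.site_threshold <= 0:
            errors.append("site_threshold must be positive")
        if self.min_orf_aa < 1:
            errors.append("min_orf_aa must be >= 1")
        if self.max_locus_distance < 0:
            errors.append("max_locus_distance must be >= 0")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["canonical_reference"] = list(self.canonical_reference)
        return d


@dataclass
class DiscoveryReport:
    config: dict
    clusters: ClusterSet
    per_query_hits: dict[str, list[StructAlignment]]
    hits: list[StructAlignment]               # union over queries, best per target
    shared_hit_ids: list[str]                 # targets hit by every query
    dimer_calls: dict[str, HEPNDimerCall]     # structure id -> call (dimer-positive)
    locus_calls: list[LocusCall]
    tree_newick: str | None
    stage_counts: dict[str, int]

    def to_dir(self, path: str | Path) -> None:
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        write_hits_tsv(self.hits, out / "hits.tsv")
        write_dimer_tsv(
            [self.dimer_calls[k] for k in sorted(self.dimer_calls)], out / "dimers.tsv"
        )
        lines = [
            "contig\tarray_start\tarray_end\torf_id\tdistance_bp\tcas13_candidate"
        ]
        for lc in self.locus_calls:
            lines.append(
                f"{lc.array.contig_id}\t{lc.array.span[0]}\t{lc.array.span[1]}\t"
                f"{lc.orf.id}\t{lc.distance_bp}\t{lc.cas13_candidate}"
            )
        (out / "loci.tsv").write_text("\n".join(lines) + "\n")
        if self.tree_newick is not None:
            (out / "tree.nwk").write_text(self.tree_newick)
        summary = {
            "config": self.config,
            "stage_counts": self.stage_counts,
            "shared_hit_ids": self.shared_hit_ids,
            "n_hits": len(self.hits),
            "n_dimer_calls": len(self.dimer_calls),
            "n_locus_calls": len(self.locus_calls),
            "n_cas13_candidates": sum(1 for lc in self.locus_calls if lc.cas13_candidate),
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def write_hits_tsv(hits: list[StructAlignment], path: str | Path) -> None:
    lines = ["query\ttarget\ttm_query\ttm_target\trmsd\tn_aligned\tzscore"]
    for h in hits:
        z = "" if h.zscore is None else f"{h.zscore:.3f}"
        lines.append(
            f"{h.query_id}\t{h.target_id}\t{h.tm_query:.4f}\t{h.tm_target:.4f}\t"
            f"{h.rmsd_aligned:.3f}\t{h.n_aligned}\t{z}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _protein_matches(protein: str, structure_seq: str) -> bool:
    # allow for the initiator Met absent from the structural model
    return protein == structure_seq or protein[1:] == structure_seq


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc_type is not None:
                logger.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline aborted in stage {name!r}: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - self.t0)
    return _Timer()


def run_discovery(
    queries: list[Structure],
    structure_db: list[Structure],
    genomes: list[SeqRecord] | None = None,
    config: DiscoveryConfig | None = None,
) -> DiscoveryReport:
    """Run the full discovery pipeline on in-memory inputs.

    Hits without genome context simply lack locus calls. The report's locus
    calls are restricted to ORFs whose protein matches a dimer-positive hit
    structure, so stage counts are conserved:
    hits >= dimer-positive hits >= candidate loci.
    """
    config = config or DiscoveryConfig()
    config.validate()
    if not queries:
        raise ValueError("need at least one query structure")
    if not structure_db:
        raise ValueError("empty structure database")
    genomes = genomes or []
    counts: dict[str, int] = {"queries": len(queries), "db": len(structure_db)}

    with _stage("cluster"):
        clusters = greedy_cluster(
            structure_db, threshold=config.cluster_threshold, k=config.prefilter_kmer
        )
        counts["clusters"] = len(clusters.clusters)

    by_id = {s.id: s for s in structure_db}
    per_query: dict[str, list[StructAlignment]] = {}
    with _stage("search"):
        rule = HitRule(
            tm_min=config.tm_min, z_min=config.z_min,
            z_null=config.z_null, seed=config.seed,
        )
        for q in sorted(queries, key=lambda s: s.id):
            per_query[q.id] = two_stage_search(
                q, clusters, by_id, top_k=config.top_k,
                hit_rule=rule, k=config.prefilter_kmer,
            )
        union: dict[str, StructAlignment] = {}
        for hits in per_query.values():
            for h in hits:
                if h.target_id not in union or h.tm_query > union[h.target_id].tm_query:
                    union[h.target_id] = h
        hit_list = sorted(union.values(), key=lambda h: (-h.tm_query, h.target_id))
        shared = sorted(
            set.intersection(*(set(h.target_id for h in hits) for hits in per_query.values()))
        )
        counts["hits"] = len(hit_list)
        counts["shared_hits"] = len(shared)

    with _stage("dimer_filter"):
        dimer_calls: dict[str, HEPNDimerCall] = {}
        for h in hit_list:
            s = by_id[h.target_id]
            call = detect_intramolecular_dimer(s, site_threshold=config.site_threshold)
            if call is not None:
                classify_segment_order(s, call, reference=config.canonical_reference)
                dimer_calls[s.id] = call
        counts["dimer_positive"] = len(dimer_calls)

    locus_calls: list[LocusCall] = []
    with _stage("crispr_association"):
        for genome in genomes:
            orfs = find_orfs(genome, min_aa=config.min_orf_aa)
            arrays = find_crispr_arrays(genome, params=config.array_params)
            hepn_by_orf: dict[str, HEPNDimerCall] = {}
            for orf in orfs:
                protein = orf_protein(genome, orf)
                for sid, call in dimer_calls.items():
                    if _protein_matches(protein, by_id[sid].sequence):
                        hepn_by_orf[orf.id] = call
                        break
            calls = associate_arrays_to_genes(
                arrays, orfs, hepn_by_orf, max_distance=config.max_locus_distance
            )
            locus_calls.extend(c for c in calls if c.hepn_dimer is not None)
        counts["cas13_candidates"] = sum(1 for c in locus_calls if c.cas13_candidate)

    tree_newick: str | None = None
    with _stage("phylogeny"):
        hit_structs = [by_id[h.target_id] for h in hit_list]
        if len(hit_structs) >= 3:
            dm = structural_distance_matrix(hit_structs)
            tree = neighbor_joining(dm)
            from .phylo import _to_newick  # shared serializer, proper quoting
            tree_newick = _to_newick(tree) + ";\n"

    return DiscoveryReport(
        config=config.to_dict(),
        clusters=clusters,
        per_query_hits=per_query,
        hits=hit_list,
        shared_hit_ids=shared,
        dimer_calls=dimer_calls,
        locus_calls=locus_calls,
        tree_newick=tree_newick,
        stage_counts=counts,
    )
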