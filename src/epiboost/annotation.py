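"""SNP-to-gene window annotation and gene co-selection network export.

Each selected SNP is mapped to every gene whose span intersects the window
[pos - w, pos + w] (closed intervals, both boundaries inclusive; default
w = 5,000 bp, searched upstream and downstream of the SNP, gene strand
ignored).  Gene models come from local GFF3 ("gene" features only) or BED
files; BED's 0-based half-open coordinates are converted to the 1-based
inclusive convention used internally.

The exported gene network connects genes whose SNPs were selected together
in at least one feature network, weighted by the number of co-selections;
curated interaction edges can be merged in from a user-supplied TSV.  The
graph is written as GraphML plus node/edge TSVs for external visualization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
from intervaltree import IntervalTree

from .cohort import SNPRecord

__all__ = [
    "GeneInterval",
    "SNPGeneMap",
    "load_annotation",
    "map_snps_to_genes",
    "export_gene_network",
]

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneInterval:
    """A gene span in 1-based inclusive coordinates."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class SNPGeneMap:
    """Per-SNP overlapping genes with signed distances.

    ``hits[snp_id]`` is a list of (GeneInterval, distance); distance is 0
    when the SNP lies inside the gene, positive when the gene starts
    downstream of the SNP, negative when it ends upstream.
    """

    hits: dict[str, list[tuple[GeneInterval, int]]]
    window: int

    def genes_of(self, snp_id: str) -> list[GeneInterval]:
        return [g for g, _ in self.hits.get(snp_id, [])]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": snp_id,
                "gene_id": g.gene_id,
                "gene_name": g.gene_name,
                "chrom": g.chrom,
                "gene_start": g.start,
                "gene_end": g.end,
                "distance": d,
            }
            for snp_id, pairs in self.hits.items()
            for g, d in pairs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "snp_id", "gene_id", "gene_name", "chrom",
                "gene_start", "gene_end", "distance",
            ],
        )


def load_annotation(path: str | Path, format: str | None = None) -> list[GeneInterval]:
    """Load gene intervals from GFF3 or BED.

    GFF3: only features of type "gene" are kept; duplicate gene_ids collapse
    to the union span.  BED: 0-based half-open converted to 1-based
    inclusive; column 4 (if present) is the gene id.
    """
    path = Path(path)
    if format is None:
        format = "bed" if path.suffix.lower() == ".bed" else "gff3"
    if format == "gff3":
        genes = _load_gff3(path)
    elif format == "bed":
        genes = _load_bed(path)
    else:
        raise AnnotationError(f"unknown annotation format {format!r}")
    if not genes:
        warnings.warn(f"{path}: no gene intervals found", stacklevel=2)
    return genes


def _load_gff3(path: Path) -> list[GeneInterval]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    by_id: dict[str, GeneInterval] = {}
    for feature in db.features_of_type("gene"):
        gene_id = feature.attributes.get("ID", [feature.id])[0]
        gene_name = feature.attributes.get("Name", [gene_id])[0]
        if feature.end < feature.start:
            raise AnnotationError(
                f"{path}: gene {gene_id} has end < start "
                f"({feature.start}-{feature.end})"
            )
        interval = GeneInterval(
            gene_id=gene_id,
            gene_name=gene_name,
            chrom=feature.seqid,
            start=feature.start,
            end=feature.end,
            strand=feature.strand or ".",
        )
        if gene_id in by_id:  # collapse duplicates to the union span
            prev = by_id[gene_id]
            interval = GeneInterval(
                gene_id=gene_id,
                gene_name=gene_name,
                chrom=prev.chrom,
                start=min(prev.start, interval.start),
                end=max(prev.end, interval.end),
                strand=prev.strand,
            )
        by_id[gene_id] = interval
    return list(by_id.values())


def _load_bed(path: Path) -> list[GeneInterval]:
    genes: dict[str, GeneInterval] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if end0 < start0:
                raise AnnotationError(f"{path}:{lineno}: end < start")
            gene_id = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end0}"
            strand = parts[5] if len(parts) > 5 else "."
            interval = GeneInterval(
                gene_id=gene_id,
                gene_name=gene_id,
                chrom=chrom,
                start=start0 + 1,  # 0-based half-open -> 1-based inclusive
                end=end0,
                strand=strand,
            )
            if gene_id in genes:
                prev = genes[gene_id]
                interval = GeneInterval(
                    gene_id=gene_id, gene_name=gene_id, chrom=prev.chrom,
                    start=min(prev.start, interval.start),
                    end=max(prev.end, interval.end), strand=prev.strand,
                )
            genes[gene_id] = interval
    return list(genes.values())


def map_snps_to_genes(
    snps: list[SNPRecord],
    genes: list[GeneInterval],
    window: int = 5000,
) -> SNPGeneMap:
    """Gene g maps to SNP s iff [g.start, g.end] intersects
    [s.pos - window, s.pos + window] (closed intervals, boundaries included).
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; +1 makes the gene end inclusive
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    snp_chroms = {s.chrom for s in snps}
    unmatched = snp_chroms - set(trees)
    if unmatched and trees:
        logger.warning(
            "%d SNP chromosome name(s) absent from the annotation: %s",
            len(unmatched),
            sorted(unmatched)[:5],
        )
    hits: dict[str, list[tuple[GeneInterval, int]]] = {}
    for s in snps:
        tree = trees.get(s.chrom)
        found: list[tuple[GeneInterval, int]] = []
        if tree is not None:
            lo = max(1, s.pos - window)
            for iv in tree.overlap(lo, s.pos + window + 1):
                g: GeneInterval = iv.data
                if g.start <= s.pos <= g.end:
                    dist = 0
                elif s.pos < g.start:
                    dist = g.start - s.pos
                else:
                    dist = g.end - s.pos  # negative
                found.append((g, dist))
        found.sort(key=lambda pair: (abs(pair[1]), pair[0].gene_id))
        hits[s.snp_id] = found
    return SNPGeneMap(hits=hits, window=window)


def export_gene_network(
    snp_gene_map: SNPGeneMap,
    networks,
    out_prefix: str | Path,
    extra_edges: str | Path | None = None,
) -> nx.Graph:
    """Build and write the gene co-selection graph.

    Nodes are the genes of selected SNPs; an edge joins two genes whenever
    their SNPs co-occur in at least one selected feature network, weighted
    by the co-occurrence count.  Curated edges from ``extra_edges`` (TSV:
    gene_a, gene_b[, kind]) are merged with kind="curated".  Writes
    ``<prefix>.graphml``, ``<prefix>.nodes.tsv`` and ``<prefix>.edges.tsv``.
    """
    graph = nx.Graph()
    for network in networks:
        snp_names = [d.name for d in network.features if d.source == "snp"]
        gene_sets: list[set[str]] = []
        for snp_id in snp_names:
            genes = snp_gene_map.genes_of(snp_id)
            if not genes:
                logger.info("SNP %s maps to no gene; skipped", snp_id)
                continue
            for g in genes:
                if not graph.has_node(g.gene_id):
                    graph.add_node(g.gene_id, gene_name=g.gene_name, chrom=g.chrom)
            gene_sets.append({g.gene_id for g in genes})
        network_genes = sorted(set().union(*gene_sets)) if gene_sets else []
        for i, a in enumerate(network_genes):
            for b in network_genes[i + 1:]:
                if graph.has_edge(a, b):
                    graph[a][b]["weight"] += 1
                else:
                    graph.add_edge(a, b, weight=1, kind="co-selection")

    if extra_edges is not None:
        curated = pd.read_csv(extra_edges, sep="\t")
        if len(curated):
            for row in curated.itertuples(index=False):
                a, b = str(row[0]), str(row[1])
                for node in (a, b):
                    if not graph.has_node(node):
                        graph.add_node(node, gene_name=node, chrom="")
                if not graph.has_edge(a, b):
                    graph.add_edge(a, b, weight=1, kind="curated")

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, f"{prefix}.graphml")
    pd.DataFrame(
        [
            {"gene_id": n, **data}
            for n, data in sorted(graph.nodes(data=True))
        ]
    ).to_csv(f"{prefix}.nodes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene_a": a, "gene_b": b, **data}
            for a, b, data in sorted(graph.edges(data=True))
        ]
    ).to_csv(f"{prefix}.edges.tsv", sep="\t", index=False)
    return graph
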