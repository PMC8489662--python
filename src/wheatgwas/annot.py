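"""Gene models inside hotspot physical intervals, from GFF3 annotation.

Overlap is closed-interval on 1-based GFF3 coordinates: a gene touching the
hotspot interval at a single bp is returned.  GO terms are read from the
``Ontology_term`` attribute; a term may carry its namespace inline as
``GO:NNNNNNN|namespace`` or be resolved through an optional term->namespace
mapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gffutils
import pandas as pd

__all__ = ["GeneModel", "load_annotation", "genes_in_hotspot", "go_summary"]

GO_NAMESPACES = ("molecular_function", "biological_process", "cellular_component")
_GO_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    strand: str
    go_terms: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("gene start must be <= end")


def load_annotation(gff3_path) -> gffutils.FeatureDB:
    """Parse a GFF3 file into an in-memory feature database."""
    return gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )


def _parse_go(feature, namespace_map: dict[str, str] | None) -> list[tuple[str, str]]:
    terms = []
    for raw in feature.attributes.get("Ontology_term", []):
        for item in raw.split(","):
            item = item.strip()
            if not item:
                continue
            term, _, ns = item.partition("|")
            if not _GO_RE.match(term):
                raise ValueError(f"malformed GO term {term!r} on {feature.id}")
            if not ns and namespace_map:
                ns = namespace_map.get(term, "")
            terms.append((term, ns))
    return terms


def genes_in_hotspot(
    hotspot,
    annotation: gffutils.FeatureDB,
    namespace_map: dict[str, str] | None = None,
) -> list[GeneModel]:
    """Genes whose [start, end] intersects the hotspot's physical interval.

    The interval is [min(left_bp, right_bp), max(left_bp, right_bp)] so
    flanking markers stored in descending physical order work unchanged.
    Results are ordered by start position, invariant to GFF3 record order.
    """
    chrom = hotspot.chromosome
    lo = min(hotspot.left_bp, hotspot.right_bp)
    hi = max(hotspot.left_bp, hotspot.right_bp)
    known = {f.seqid for f in annotation.all_features()}
    if chrom not in known:
        raise ValueError(f"chromosome {chrom!r} absent from annotation")
    genes = [
        GeneModel(
            gene_id=f.id,
            chromosome=f.seqid,
            start_bp=f.start,
            end_bp=f.end,
            strand=f.strand,
            go_terms=_parse_go(f, namespace_map),
        )
        for f in annotation.region((chrom, lo, hi), featuretype="gene", completely_within=False)
        # closed-interval check (region() is already inclusive; keep explicit)
        if f.end >= lo and f.start <= hi
    ]
    return sorted(genes, key=lambda g: (g.start_bp, g.gene_id))


def go_summary(genes: list[GeneModel]) -> pd.DataFrame:
    """Gene and term counts per GO namespace, plus unannotated genes.

    A gene is counted once per namespace in which it has at least one term;
    term counts sum the terms.  Genes without any GO term are reported under
    namespace ``unannotated`` (term count 0).
    """
    rows = {ns: {"genes": 0, "terms": 0} for ns in GO_NAMESPACES}
    unann = 0
    for g in genes:
        if not g.go_terms:
            unann += 1
            continue
        by_ns: dict[str, int] = {}
        for term, ns in g.go_terms:
            key = ns if ns in GO_NAMESPACES else "unknown"
            by_ns[key] = by_ns.get(key, 0) + 1
        for ns, cnt in by_ns.items():
            rows.setdefault(ns, {"genes": 0, "terms": 0})
            rows[ns]["genes"] += 1
            rows[ns]["terms"] += cnt
    out = pd.DataFrame(rows).T
    out.loc["unannotated"] = [unann, 0]
    out.index.name = "namespace"
    return out.astype(int)
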