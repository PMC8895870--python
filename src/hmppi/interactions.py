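"""Curated-interaction ingest and cluster-level network construction.

Reads MITAB-style tab-delimited exports of interspecies PPI records, keeps
only binary, experimentally determined human-bacteria interactions, and
lifts the retained protein pairs to HBNet edges: one human UniRef100/90
cluster x one bacterial UniRef50 cluster, with the experimentally verified
bacterial interactors attached as evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "ClusterEdge",
    "HBNet",
    "parse_interactions",
    "filter_binary_interspecies",
    "build_hbnet",
    "network_stats",
    "read_cluster_map",
    "write_network",
]

HUMAN_TAXON = 9606

#: Default MITAB column names; override via ``columns=`` in parse_interactions.
DEFAULT_COLUMNS = {
    "id_a": "id_a",
    "id_b": "id_b",
    "taxon_a": "taxon_a",
    "taxon_b": "taxon_b",
    "detection_method": "detection_method",
    "interaction_type": "interaction_type",
    "source_publication": "source_publication",
}


@dataclass(frozen=True)
class InteractionRecord:
    """One curated interspecies PPI record."""

    id_a: str
    id_b: str
    taxon_a: int
    taxon_b: int
    detection_method: str
    interaction_type: str
    source_publication: str = ""

    def __post_init__(self) -> None:
        if not self.id_a or not self.id_b:
            raise ValueError("interactor accessions must be non-empty")
        if self.taxon_a <= 0 or self.taxon_b <= 0:
            raise ValueError("taxon ids must be positive integers")


@dataclass
class ClusterEdge:
    """An HBNet edge: human cluster x bacterial UniRef50 cluster."""

    human_cluster: str
    bacterial_cluster: str
    evidence: list[str] = field(default_factory=list)
    verified_bacterial_members: list[str] = field(default_factory=list)
    putative_members: list[str] = field(default_factory=list)
    member_similarity: dict[str, float] = field(default_factory=dict)
    ungated: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.human_cluster, self.bacterial_cluster)


@dataclass
class HBNet:
    """The cluster-level human-bacteria interaction network."""

    edges: dict[tuple[str, str], ClusterEdge] = field(default_factory=dict)
    n_dropped_unmapped: int = 0

    def __iter__(self):
        return iter(self.edges.values())

    def __len__(self) -> int:
        return len(self.edges)

    def human_targets_of(self, bacterial_cluster: str) -> list[str]:
        return sorted(
            e.human_cluster for e in self if e.bacterial_cluster == bacterial_cluster
        )

    def bacterial_interactors_of(self, human_cluster: str) -> list[str]:
        return sorted(
            e.bacterial_cluster for e in self if e.human_cluster == human_cluster
        )


def _strip_isoform(accession: str) -> str:
    """UniRef maps canonical accessions; drop isoform suffixes (P12345-2)."""
    return accession.split("-")[0]


def parse_interactions(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[InteractionRecord]:
    """Read a MITAB-style tab-delimited interaction file.

    Rows whose mandatory fields cannot be parsed are skipped and counted in
    the log.  Raises ``FileNotFoundError`` for a missing file and
    ``ValueError`` when no row parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    records: list[InteractionRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        try:
            records.append(
                InteractionRecord(
                    id_a=str(row[cols["id_a"]]),
                    id_b=str(row[cols["id_b"]]),
                    taxon_a=int(row[cols["taxon_a"]]),
                    taxon_b=int(row[cols["taxon_b"]]),
                    detection_method=str(row[cols["detection_method"]]),
                    interaction_type=str(row[cols["interaction_type"]]),
                    source_publication=str(row.get(cols["source_publication"], "")),
                )
            )
        except (KeyError, TypeError, ValueError):
            n_skipped += 1
    if n_skipped:
        logger.warning("skipped %d unparseable interaction rows", n_skipped)
    if not records:
        raise ValueError(f"no parseable interaction rows in {path}")
    return records


def filter_binary_interspecies(
    records: Iterable[InteractionRecord],
    human_taxa: set[int] = frozenset({HUMAN_TAXON}),
    allowed_methods: set[str] | None = None,
    allowed_types: set[str] | None = None,
) -> list[InteractionRecord]:
    """Keep binary, experimentally determined interspecies human PPIs.

    A record is retained when its taxa differ, exactly one side is human,
    its detection method and interaction type are both whitelisted.  The
    survivors are deduplicated on the unordered accession pair (isoform
    suffixes stripped), keeping the first occurrence.
    """
    if allowed_methods is None or allowed_types is None:
        from .config import default_evidence_whitelists

        wl = default_evidence_whitelists()
        allowed_methods = allowed_methods or wl["detection_methods"]
        allowed_types = allowed_types or wl["interaction_types"]
    if not allowed_methods or not allowed_types:
        raise ValueError("evidence-code whitelists must be non-empty")

    human_taxa = set(human_taxa)
    out: list[InteractionRecord] = []
    seen: set[frozenset[str]] = set()
    for rec in records:
        if rec.taxon_a == rec.taxon_b:
            continue
        if (rec.taxon_a in human_taxa) == (rec.taxon_b in human_taxa):
            continue  # zero or two human sides
        if rec.detection_method not in allowed_methods:
            continue
        if rec.interaction_type not in allowed_types:
            continue
        key = frozenset((_strip_isoform(rec.id_a), _strip_isoform(rec.id_b)))
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def read_cluster_map(path: str | Path) -> dict[str, dict[int, tuple[str, str]]]:
    """Read a cluster-map TSV (protein_id, cluster_id, level, kingdom).

    Returns protein_id -> {level: (cluster_id, kingdom)}.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cmap: dict[str, dict[int, tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        cmap.setdefault(row.protein_id, {})[int(row.level)] = (
            row.cluster_id,
            getattr(row, "kingdom", "other"),
        )
    return cmap


def build_hbnet(
    records: Iterable[InteractionRecord],
    cluster_map: Mapping[str, Mapping[int, tuple[str, str]]],
    human_taxa: set[int] = frozenset({HUMAN_TAXON}),
    human_level: int = 90,
) -> HBNet:
    """Lift filtered records to cluster-level HBNet edges.

    The human side maps to its UniRef100/90 cluster (``human_level``), the
    bacterial side to its UniRef50 cluster.  Records whose proteins lack
    the required mapping are dropped with a logged count; evidence lists
    aggregate every supporting record per (human, bacterial) cluster pair.
    """
    net = HBNet()
    for idx, rec in enumerate(records):
        if rec.taxon_a in human_taxa:
            human_id, bact_id = _strip_isoform(rec.id_a), _strip_isoform(rec.id_b)
        else:
            human_id, bact_id = _strip_isoform(rec.id_b), _strip_isoform(rec.id_a)
        h = cluster_map.get(human_id, {}).get(human_level)
        b = cluster_map.get(bact_id, {}).get(50)
        if h is None or b is None:
            net.n_dropped_unmapped += 1
            continue
        edge = net.edges.setdefault(
            (h[0], b[0]), ClusterEdge(human_cluster=h[0], bacterial_cluster=b[0])
        )
        edge.evidence.append(rec.source_publication or f"record:{idx}")
        if bact_id not in edge.verified_bacterial_members:
            edge.verified_bacterial_members.append(bact_id)
    if net.n_dropped_unmapped:
        logger.warning("dropped %d records lacking cluster mappings", net.n_dropped_unmapped)
    return net


def network_stats(net: HBNet) -> dict[str, int]:
    """Distinct bacterial clusters, human clusters and edge count."""
    return {
        "n_bacterial_clusters": len({e.bacterial_cluster for e in net}),
        "n_human_clusters": len({e.human_cluster for e in net}),
        "n_edges": len(net),
    }


def write_network(net: HBNet, path: str | Path) -> None:
    """Write the edge list as TSV (members semicolon-joined)."""
    rows = [
        {
            "human_cluster": e.human_cluster,
            "bacterial_cluster": e.bacterial_cluster,
            "n_evidence": len(e.evidence),
            "verified_members": ";".join(e.verified_bacterial_members),
            "putative_members": ";".join(e.putative_members),
        }
        for e in sorted(net, key=lambda e: e.key)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> HBNet:
    """Read an edge-list TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    net = HBNet()
    for row in df.itertuples(index=False):
        edge = ClusterEdge(
            human_cluster=row.human_cluster,
            bacterial_cluster=row.bacterial_cluster,
            verified_bacterial_members=[m for m in row.verified_members.split(";") if m],
            putative_members=[m for m in getattr(row, "putative_members", "").split(";") if m],
        )
        edge.evidence = ["?"] * int(row.n_evidence) if hasattr(row, "n_evidence") else []
        net.edges[edge.key] = edge
    return net
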