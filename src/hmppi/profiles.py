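"""Metagenomic gene-family abundances -> per-sample human-target profiles.

Consumes HUMAnN3-style gene-family tables (rows = UniRef90 families,
columns = samples, community-level relative abundances; taxon-stratified
rows carrying ``|`` are ignored), QCs samples on read depth, collapses
UniRef90 families onto the network's UniRef50 clusters, and aggregates the
abundances of each human target's putative bacterial interactors into a
samples x targets matrix for the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .homology import local_align

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceMatrix",
    "TargetProfileMatrix",
    "read_genefamilies",
    "read_metadata",
    "qc_samples",
    "map_gene_families",
    "build_target_profiles",
    "prevalence_filter",
]


@dataclass
class AbundanceMatrix:
    """Samples x gene-families relative abundances plus per-sample metadata.

    ``values``: DataFrame indexed by sample id, columns = UniRef90 family
    ids.  ``sample_meta``: DataFrame indexed by sample id with at least
    ``label`` ("case"/"control") and ``read_count``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if not self.values.index.is_unique:
            raise ValueError("sample ids must be unique")
        self.sample_meta = self.sample_meta.loc[self.values.index]


@dataclass
class TargetProfileMatrix:
    """Samples x human-target aggregated abundances.

    ``provenance`` maps each human target to the bacterial UniRef50
    clusters that contributed to its column.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    provenance: dict[str, list[str]] = field(default_factory=dict)
    normalized: bool = False


def read_genefamilies(path: str | Path) -> pd.DataFrame:
    """Read a HUMAnN3-style genefamilies TSV into samples x families.

    The first column is the gene-family id (header ``# Gene Family``);
    taxon-stratified rows (ids containing ``|``) are dropped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df[~df.index.str.contains(r"\|")]
    return df.T  # samples x families


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta["read_count"] = meta["read_count"].astype(np.int64)
    return meta


def qc_samples(matrix: AbundanceMatrix, min_reads: float = 1e7) -> AbundanceMatrix:
    """Drop samples with abnormally low sequencing depth.

    Removal is strict: ``read_count < min_reads`` is removed, so a sample
    with exactly ``min_reads`` reads is retained.
    """
    keep = matrix.sample_meta["read_count"] >= min_reads
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("QC removed %d low-read samples", n_removed)
    if not keep.any():
        raise ValueError("sample QC removed every sample in the cohort")
    return AbundanceMatrix(
        values=matrix.values.loc[keep[keep].index],
        sample_meta=matrix.sample_meta.loc[keep[keep].index],
    )


def _alignment_identity_coverage(query: str, target: str) -> tuple[float, float, int]:
    """Identity over aligned columns and aligned fraction of the query."""
    aln = local_align(query, target)
    if not aln.aligned_pairs:
        return 0.0, 0.0, 0
    n_ident = sum(1 for i, j in aln.aligned_pairs if query[i] == target[j])
    identity = n_ident / len(aln.aligned_pairs)
    coverage = (aln.a_end - aln.a_start) / len(query)
    return identity, coverage, aln.sw_score


def map_gene_families(
    uniref90_seqs: Mapping[str, str],
    uniref50_reps: Mapping[str, str],
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
) -> dict[str, tuple[str, float, float]]:
    """Map UniRef90 families onto UniRef50 clusters by local alignment.

    For each UniRef90 sequence the best-scoring UniRef50 representative is
    retained if identity and query coverage both *exceed* the thresholds
    (strict, per the >90%/>90% rule).  Ties on score break by higher
    identity, then lexicographic UniRef50 id.  Returns
    uniref90_id -> (uniref50_id, identity, coverage); unmapped families are
    simply absent.  A precomputed mapping TSV can be loaded with
    :func:`read_mapping` instead.
    """
    out: dict[str, tuple[str, float, float]] = {}
    for qid, qseq in uniref90_seqs.items():
        best: tuple[int, float, str] | None = None  # (score, identity, -id)
        best_entry = None
        for tid in sorted(uniref50_reps):
            ident, cov, score = _alignment_identity_coverage(qseq, uniref50_reps[tid])
            cand = (score, ident)
            if best is None or cand > (best[0], best[1]):
                best = (score, ident, tid)
                best_entry = (tid, ident, cov)
        if best_entry is not None and best_entry[1] > min_identity and best_entry[2] > min_coverage:
            out[qid] = best_entry
        else:
            logger.debug("gene family %s unmapped", qid)
    return out


def read_mapping(path: str | Path) -> dict[str, tuple[str, float, float]]:
    """Read a precomputed uniref90->uniref50 mapping TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"uniref90_id": str, "uniref50_id": str})
    return {
        r.uniref90_id: (r.uniref50_id, float(r.identity), float(r.coverage))
        for r in df.itertuples(index=False)
    }


def build_target_profiles(
    matrix: AbundanceMatrix,
    network,
    map90to50: Mapping[str, tuple[str, float, float]] | None = None,
    normalize: bool = False,
) -> TargetProfileMatrix:
    """Aggregate bacterial abundances onto their human protein targets.

    Per sample, each human target's value is the sum over detected
    bacterial UniRef50 clusters that putatively interact with it.  With
    ``normalize=True`` each bacterial cluster's abundance is first divided
    by its number of human interactors, so total abundance mass is
    conserved across the projection.

    ``map90to50`` translates the matrix's UniRef90 columns to UniRef50
    cluster ids; pass ``None`` when the columns already are UniRef50 ids.
    """
    # Collapse gene families onto UniRef50 clusters.
    if map90to50 is not None:
        cols = {}
        for fam in matrix.values.columns:
            hit = map90to50.get(fam)
            if hit is not None:
                cols.setdefault(hit[0], []).append(fam)
        cluster_ab = pd.DataFrame(
            {u50: matrix.values[fams].sum(axis=1) for u50, fams in cols.items()},
            index=matrix.values.index,
        )
    else:
        cluster_ab = matrix.values

    targets_of: dict[str, list[str]] = {}
    for edge in network:
        if getattr(edge, "ungated", False):
            continue
        targets_of.setdefault(edge.bacterial_cluster, []).append(edge.human_cluster)

    common = [c for c in cluster_ab.columns if c in targets_of]
    if not common:
        raise ValueError("no overlap between abundance gene families and network clusters")

    profile: dict[str, np.ndarray] = {}
    provenance: dict[str, list[str]] = {}
    for bact in common:
        contrib = cluster_ab[bact].to_numpy(dtype=float)
        n_targets = len(targets_of[bact])
        if normalize:
            contrib = contrib / n_targets
        for tgt in targets_of[bact]:
            if tgt in profile:
                profile[tgt] = profile[tgt] + contrib
            else:
                profile[tgt] = contrib.copy()
            provenance.setdefault(tgt, []).append(bact)

    values = pd.DataFrame(profile, index=cluster_ab.index).sort_index(axis=1)
    return TargetProfileMatrix(
        values=values,
        sample_meta=matrix.sample_meta,
        provenance={k: sorted(v) for k, v in provenance.items()},
        normalized=normalize,
    )


def prevalence_filter(
    profiles: TargetProfileMatrix, min_prevalence: float = 0.05
) -> TargetProfileMatrix:
    """Drop human targets present in fewer than ``min_prevalence`` of samples.

    Presence means abundance strictly > 0; removal is strict ("fewer
    than"), so a target present in exactly 5% of samples is retained.
    """
    frac_present = (profiles.values > 0).mean(axis=0)
    keep = frac_present >= min_prevalence
    if not keep.any():
        raise ValueError("prevalence filter removed every target")
    kept_cols = profiles.values.columns[keep]
    return TargetProfileMatrix(
        values=profiles.values[kept_cols],
        sample_meta=profiles.sample_meta,
        provenance={t: profiles.provenance.get(t, []) for t in kept_cols},
        normalized=profiles.normalized,
    )
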