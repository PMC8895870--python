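"""Annotation binning and subset-comparison statistics.

Supports the comparisons made across the nested protein sets (full
network -> detected -> disease-associated): GO Cellular Component terms
collapsed into three compartments, gene-disease associations binned into
broad disease categories, 2x2 chi-square tests between subsets, one-sided
Fisher/hypergeometric gene-set enrichment, and Benjamini-Hochberg FDR
adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_DISEASE_BINS, DEFAULT_GO_COMPARTMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "bin_subcellular",
    "bin_disease",
    "subset_chisq",
    "fisher_enrichment",
    "bh_adjust",
    "read_gmt",
]


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int  # annotated members of the target set
    n: int  # target-set size
    K: int  # annotated members of the background
    N: int  # background size
    p: float
    p_adjusted: float = float("nan")
    enriched: bool = False

    def __post_init__(self) -> None:
        if not (self.k <= self.n and self.K <= self.N and self.k <= self.K):
            raise ValueError("inconsistent enrichment counts")


def bin_subcellular(
    go_terms: Mapping[str, Iterable[str]],
    compartments: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Collapse per-protein GO CC terms into three compartment flags.

    Returns a boolean DataFrame indexed by protein with columns
    Extracellular / Membrane / Intracellular plus ``exclusively_intracellular``
    (Intracellular and neither of the other two).  Terms outside the three
    groups are ignored with a log message.
    """
    comp = compartments or DEFAULT_GO_COMPARTMENTS
    known = set().union(*comp.values())
    rows = {}
    unknown: set[str] = set()
    for protein, terms in go_terms.items():
        terms = set(terms)
        unknown |= terms - known
        flags = {name: bool(terms & members) for name, members in comp.items()}
        flags["exclusively_intracellular"] = (
            flags.get("Intracellular", False)
            and not flags.get("Extracellular", False)
            and not flags.get("Membrane", False)
        )
        rows[protein] = flags
    if unknown:
        logger.info("ignored %d GO terms outside the compartment groups", len(unknown))
    return pd.DataFrame.from_dict(rows, orient="index").fillna(False)


def bin_disease(
    gda_rows: pd.DataFrame,
    bin_map: Mapping[str, str] | None = None,
    min_score: float = 0.1,
) -> tuple[pd.DataFrame, float]:
    """Bin gene-disease associations into broad disease categories.

    ``gda_rows`` needs columns ``protein``, ``disease`` and ``score``; rows
    with score strictly greater than ``min_score`` are kept.  ``bin_map``
    maps lower-cased disease-name substrings to category labels.  Returns
    (boolean flag table indexed by protein, fraction of flagged proteins
    carrying more than one category).
    """
    bin_map = dict(bin_map or DEFAULT_DISEASE_BINS)
    kept = gda_rows[gda_rows["score"] > min_score]
    categories = sorted(set(bin_map.values()))
    flags = pd.DataFrame(
        False, index=sorted(gda_rows["protein"].unique()), columns=categories
    )
    for row in kept.itertuples(index=False):
        name = str(row.disease).lower()
        for pattern, cat in bin_map.items():
            if pattern in name:
                flags.loc[row.protein, cat] = True
    n_cats = flags.sum(axis=1)
    flagged = n_cats > 0
    multi_fraction = float((n_cats[flagged] > 1).mean()) if flagged.any() else 0.0
    return flags, multi_fraction


def subset_chisq(
    set_a: Iterable[str], set_b: Iterable[str], flagged: Iterable[str]
) -> dict[str, float | bool]:
    """2x2 chi-square comparing an annotation's frequency in two protein sets.

    No continuity correction.  When any expected count falls below 5 a
    ``fisher_fallback`` flag is raised and the Fisher exact p reported
    alongside; a degenerate margin (every protein flagged, or none) yields
    statistic 0, p = 1, with a warning.
    """
    set_a, set_b, flagged = set(set_a), set(set_b), set(flagged)
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    table = np.array(
        [
            [len(set_a & flagged), len(set_a - flagged)],
            [len(set_b & flagged), len(set_b - flagged)],
        ]
    )
    if (table.sum(axis=0) == 0).any():
        warnings.warn("degenerate margin: annotation constant across both sets")
        return {"statistic": 0.0, "p": 1.0, "fisher_fallback": False, "fisher_p": 1.0}
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    fallback = bool((expected < 5).any())
    fisher_p = float(stats.fisher_exact(table)[1]) if fallback else float("nan")
    return {
        "statistic": float(chi2),
        "p": float(p),
        "fisher_fallback": fallback,
        "fisher_p": fisher_p,
    }


def fisher_enrichment(
    target_set: Iterable[str],
    background: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided over-representation test per gene set, BH-adjusted.

    p = P(X >= k) under the hypergeometric null with N = background size,
    K = gene-set members in the background, n = target-set size.  Gene
    sets with zero background overlap are skipped.  ``enriched`` flags
    adjusted p < ``alpha``.
    """
    target = set(target_set)
    bg = set(background)
    if not target <= bg:
        raise ValueError("target set must be a subset of the background")
    N, n = len(bg), len(target)
    partial: list[tuple[str, int, int, float]] = []
    for name, members in gene_sets.items():
        K = len(set(members) & bg)
        if K == 0:
            logger.info("gene set %s has no background overlap; skipped", name)
            continue
        k = len(set(members) & target)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        partial.append((name, k, K, p))
    if not partial:
        return []
    adjusted = bh_adjust([p for *_, p in partial])
    return [
        EnrichmentResult(
            category=name, k=k, n=n, K=K, N=N, p=p, p_adjusted=q, enriched=q < alpha
        )
        for (name, k, K, p), q in zip(partial, adjusted)
    ]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if (pvals < 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets
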