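"""Interactor-similarity scoring and cluster-member gating.

Putative bacterial interactors of a human protein are inferred by homology
to an experimentally verified interactor: every member of the verified
protein's UniRef50 cluster is scored against it and only members within a
similarity threshold (default 70%) are kept.

The similarity score is deliberately asymmetric: a Smith-Waterman local
alignment (BLOSUM62, affine gaps) is computed between the verified
interactor and the candidate, the aligned residue pairs with a
*non-negative* BLOSUM62 score (frequent substitutions) are tallied, and the
tally is divided by the length of the verified interactor.  A candidate can
therefore only reach 1.0 by aligning favourably along the verified
sequence's full length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "SequenceRecord",
    "AlignmentResult",
    "SimilarityScore",
    "local_align",
    "interactor_similarity",
    "gate_cluster_members",
    "select_representative",
    "blosum62_score",
]

# Default affine gap penalties: the classical pairing for BLOSUM62.
# A gap of length k costs GAP_OPEN + (k - 1) * GAP_EXTEND.
GAP_OPEN = 11
GAP_EXTEND = 1

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)  # "ARNDCQEGHILKMFPSTWYVBZX*"
_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_MATRIX = np.array(_BLOSUM62, dtype=np.int64)

# Selenocysteine / pyrrolysine have no BLOSUM62 column; treat as unknown.
_RESIDUE_ALIASES = {"U": "X", "O": "X", "J": "X", "*": "X"}


def _encode(sequence: str) -> np.ndarray:
    """Map an amino-acid string onto BLOSUM62 row indices."""
    out = np.empty(len(sequence), dtype=np.intp)
    for i, aa in enumerate(sequence):
        aa = _RESIDUE_ALIASES.get(aa, aa)
        try:
            out[i] = _INDEX[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} in sequence") from None
    return out


def blosum62_score(res_a: str, res_b: str) -> int:
    """BLOSUM62 substitution score for a single residue pair."""
    a = _RESIDUE_ALIASES.get(res_a, res_a)
    b = _RESIDUE_ALIASES.get(res_b, res_b)
    return int(_MATRIX[_INDEX[a], _INDEX[b]])


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with the metadata the gating pipeline needs."""

    id: str
    sequence: str
    review_status: str = "unreviewed"  # "reviewed" | "unreviewed"
    kingdom: str = "other"  # "bacteria" | "human" | "other"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal Smith-Waterman local alignment between two sequences.

    ``aligned_pairs`` lists the matched columns as (index_a, index_b)
    0-based coordinate pairs; gapped columns are excluded.  Coordinates
    ``a_start:a_end`` / ``b_start:b_end`` are half-open spans of the local
    alignment on each sequence.
    """

    aligned_pairs: tuple[tuple[int, int], ...]
    sw_score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int


@dataclass(frozen=True)
class SimilarityScore:
    """Fraction of favourably aligned columns over the verified length."""

    value: float
    n_favorable: int
    denominator: int


def local_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> AlignmentResult:
    """Smith-Waterman local alignment under BLOSUM62 with affine gaps.

    Uses the Gotoh three-matrix recurrence.  The traceback is
    deterministic: on ties the diagonal move is preferred, then the
    vertical (consume ``a``) move, then the horizontal (consume ``b``)
    move; the highest-scoring cell with the smallest (i, j) wins.
    """
    seq_a = a.sequence if isinstance(a, SequenceRecord) else a.upper()
    seq_b = b.sequence if isinstance(b, SequenceRecord) else b.upper()
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")

    ea, eb = _encode(seq_a), _encode(seq_b)
    n, m = len(ea), len(eb)
    NEG = -(10**9)

    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (left)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (up)

    sub = _MATRIX[ea][:, eb]  # n x m pair-score lookup
    for i in range(1, n + 1):
        Hi1, Hi, Ei, Fi1, Fi = H[i - 1], H[i], E[i], F[i - 1], F[i]
        si = sub[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] - gap_open, Ei[j - 1] - gap_extend)
            f = max(Hi1[j] - gap_open, Fi1[j] - gap_extend)
            h = Hi1[j - 1] + si[j - 1]
            best = h
            if f > best:
                best = f
            if e > best:
                best = e
            if best < 0:
                best = 0
            Ei[j], Fi[j], Hi[j] = e, f, best

    score = int(H.max())
    if score == 0:
        return AlignmentResult((), 0, 0, 0, 0, 0)
    end_i, end_j = np.unravel_index(int(np.argmax(H)), H.shape)

    # Traceback with explicit state; ties broken diagonal > up > left.
    pairs: list[tuple[int, int]] = []
    i, j, state = int(end_i), int(end_j), "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in b: consume a[i-1]
            prev_open = H[i - 1, j] - gap_open
            state = "H" if F[i, j] == prev_open else "F"
            i -= 1
        else:  # "E", gap in a: consume b[j-1]
            prev_open = H[i, j - 1] - gap_open
            state = "H" if E[i, j] == prev_open else "E"
            j -= 1

    pairs.reverse()
    return AlignmentResult(
        aligned_pairs=tuple(pairs),
        sw_score=score,
        a_start=i,
        a_end=int(end_i),
        b_start=j,
        b_end=int(end_j),
    )


def interactor_similarity(
    verified: SequenceRecord | str, candidate: SequenceRecord | str
) -> SimilarityScore:
    """Similarity of ``candidate`` to the experimentally verified interactor.

    Counts aligned pairs whose BLOSUM62 score is >= 0 in the optimal local
    alignment and divides by ``len(verified)``.
    """
    seq_v = verified.sequence if isinstance(verified, SequenceRecord) else verified.upper()
    seq_c = candidate.sequence if isinstance(candidate, SequenceRecord) else candidate.upper()
    aln = local_align(seq_v, seq_c)
    ev, ec = _encode(seq_v), _encode(seq_c)
    n_fav = sum(1 for i, j in aln.aligned_pairs if _MATRIX[ev[i], ec[j]] >= 0)
    denom = len(seq_v)
    return SimilarityScore(value=n_fav / denom, n_favorable=n_fav, denominator=denom)


def gate_cluster_members(
    edge,
    sequences: dict[str, SequenceRecord],
    threshold: float = 0.70,
):
    """Fill ``edge.putative_members`` with cluster members passing the gate.

    A member passes when its similarity to *any* verified interactor of the
    edge is >= ``threshold`` (each verified interactor independently
    evidences the interaction).  Verified members always pass.  Returns the
    edge with ``putative_members`` and ``member_similarity`` populated; if
    no verified member has a sequence the edge is flagged ungated
    (``edge.ungated = True``) for downstream exclusion.
    """
    verified_seqs = [
        sequences[pid] for pid in edge.verified_bacterial_members if pid in sequences
    ]
    if not verified_seqs:
        edge.ungated = True
        edge.putative_members = []
        return edge

    verified_ids = set(edge.verified_bacterial_members)
    putative: list[str] = []
    sims: dict[str, float] = {}
    for pid, rec in sequences.items():
        if pid in verified_ids:
            putative.append(pid)
            sims[pid] = 1.0
            continue
        best = max(interactor_similarity(v, rec).value for v in verified_seqs)
        sims[pid] = best
        if best >= threshold:
            putative.append(pid)
    edge.putative_members = sorted(putative)
    edge.member_similarity = sims
    edge.ungated = False
    return edge


def select_representative(members: Sequence[SequenceRecord]) -> SequenceRecord:
    """Pick the cluster representative used for annotation.

    Bacterial members take precedence; within the preferred pool the sort
    is reviewed-first, then longest, then lexicographic id.
    """
    if not members:
        raise ValueError("cannot select a representative from an empty member list")
    pool = [m for m in members if m.kingdom == "bacteria"] or list(members)
    return sorted(
        pool,
        key=lambda m: (m.review_status != "reviewed", -len(m.sequence), m.id),
    )[0]
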