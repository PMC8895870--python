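"""Interface residues and their conservation across cluster members.

Given a co-crystal structure of a bacterial-human complex, this module
matches protein sequences to chains, computes per-residue solvent
accessibility (Shrake-Rupley quadrature), calls surface residues
(relative SASA >= 15%) and interface residues (loss of accessible area
> 1 A^2 upon complex formation), and scores the conservation of interface
positions across a cluster's multiple sequence alignment via BLOSUM62
similarity fractions and per-column Jensen-Shannon divergence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .homology import blosum62_score, local_align

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "MsaBlock",
    "ChainMatch",
    "read_pdb",
    "read_msa",
    "match_chain",
    "sasa",
    "surface_residues",
    "interface_residues",
    "interface_conservation",
    "jensen_shannon_divergence",
    "VDW_RADII",
    "MAX_RESIDUE_SASA",
]

PROBE_RADIUS = 1.4  # water probe, Angstrom
N_SPHERE_POINTS = 960

#: Van der Waals radii (Angstrom) by element.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "FE": 1.47, "ZN": 1.39, "MG": 1.73,
}
DEFAULT_RADIUS = 1.70

#: Theoretical maximum residue SASA (Angstrom^2), Tien et al. 2013 values,
#: used as the denominator of relative SASA.
MAX_RESIDUE_SASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    radius: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("atom coordinates must be finite")
        if self.radius <= 0:
            raise ValueError("atom radius must be positive")


@dataclass
class Residue:
    name: str  # three-letter code
    index: int  # sequence position within the chain
    atoms: list[Atom] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.name, "X")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class StructureModel:
    chains: dict[str, Chain] = field(default_factory=dict)

    def atoms(self, chain_ids: Iterable[str] | None = None):
        """Flat (chain_id, residue_index, Atom) triples for a chain subset."""
        ids = list(chain_ids) if chain_ids is not None else list(self.chains)
        for cid in ids:
            for res in self.chains[cid].residues:
                for atom in res.atoms:
                    yield cid, res.index, atom


@dataclass(frozen=True)
class ChainMatch:
    chain_id: str
    identity: float
    coverage: float
    exclusive: bool


@dataclass
class MsaBlock:
    """An alignment block: equal-length rows with '-' gaps."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("MSA rows must have equal length")

    def reference_column_map(self, reference_id: str) -> dict[int, int]:
        """Ungapped residue index -> alignment column, for one row."""
        row = self.rows[reference_id]
        mapping, pos = {}, 0
        for col, aa in enumerate(row):
            if aa != "-":
                mapping[pos] = col
                pos += 1
        return mapping


def read_pdb(path: str | Path) -> StructureModel:
    """Parse a PDB-format file into a StructureModel (first model only)."""
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio = PDBParser(QUIET=True).get_structure("s", str(path))
    model = StructureModel()
    for bio_chain in next(iter(bio)):
        chain = Chain(id=bio_chain.id)
        for i, bio_res in enumerate(bio_chain):
            if bio_res.id[0] != " ":  # skip hetero/water
                continue
            res = Residue(name=bio_res.get_resname(), index=i)
            for bio_atom in bio_res:
                element = (bio_atom.element or bio_atom.get_name()[0]).upper()
                radius = VDW_RADII.get(element)
                if radius is None:
                    warnings.warn(f"unknown element {element!r}; using default radius")
                    radius = DEFAULT_RADIUS
                x, y, z = bio_atom.coord
                res.atoms.append(
                    Atom(bio_atom.get_name(), element, radius, float(x), float(y), float(z))
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            model.chains[chain.id] = chain
    return model


def read_msa(path: str | Path) -> MsaBlock:
    """Read an aligned FASTA into an MsaBlock."""
    from Bio import SeqIO

    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return MsaBlock(rows=rows)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    structure: StructureModel,
    chain_ids: Iterable[str] | None = None,
    probe_radius: float = PROBE_RADIUS,
    n_sphere_points: int = N_SPHERE_POINTS,
) -> pd.DataFrame:
    """Per-residue solvent-accessible surface area by Shrake-Rupley.

    Each atom is expanded by the probe radius and sampled with a fixed
    golden-spiral quadrature; a sample point is accessible when it falls
    outside every neighbouring atom's expanded sphere.  Returns a
    DataFrame indexed by (chain, residue_index) with columns
    ``residue``, ``sasa`` (absolute, A^2) and ``relative`` (fraction of
    the residue-type maximum; NaN for residue types without a reference).
    """
    triples = list(structure.atoms(chain_ids))
    if not triples:
        raise ValueError("no atoms in the selected chains")
    coords = np.array([[a.x, a.y, a.z] for _, _, a in triples])
    radii = np.array([a.radius for _, _, a in triples])
    expanded = radii + probe_radius
    unit = _sphere_points(n_sphere_points)

    per_atom = np.zeros(len(triples))
    for i in range(len(triples)):
        pts = coords[i] + expanded[i] * unit
        d = np.linalg.norm(coords - coords[i], axis=1)
        neigh = np.flatnonzero((d < expanded + expanded[i]) & (d > 0))
        accessible = np.ones(len(pts), dtype=bool)
        for j in neigh:
            accessible &= np.sum((pts - coords[j]) ** 2, axis=1) > expanded[j] ** 2
            if not accessible.any():
                break
        per_atom[i] = 4.0 * math.pi * expanded[i] ** 2 * accessible.mean()

    rows: dict[tuple[str, int], dict] = {}
    for (cid, ridx, atom), area in zip(triples, per_atom):
        key = (cid, ridx)
        if key not in rows:
            res_name = next(
                r.name for r in structure.chains[cid].residues if r.index == ridx
            )
            rows[key] = {"residue": res_name, "sasa": 0.0}
        rows[key]["sasa"] += area
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["chain", "residue_index"])
    df["relative"] = [
        row.sasa / MAX_RESIDUE_SASA[row.residue]
        if row.residue in MAX_RESIDUE_SASA
        else float("nan")
        for row in df.itertuples()
    ]
    return df


def surface_residues(sasa_result: pd.DataFrame, threshold: float = 0.15) -> set[tuple[str, int]]:
    """Residues with relative SASA >= threshold (inclusive)."""
    mask = sasa_result["relative"] >= threshold
    return set(sasa_result.index[mask])


def interface_residues(
    structure: StructureModel,
    chain_a: str,
    chain_b: str,
    delta_threshold: float = 1.0,
    probe_radius: float = PROBE_RADIUS,
    n_sphere_points: int = N_SPHERE_POINTS,
) -> dict[str, set[int]]:
    """Residues losing more than ``delta_threshold`` A^2 of SASA on binding.

    delta-SASA per residue = SASA(chain alone) - SASA(chain within the
    two-chain complex); chains that never contact simply give empty sets.
    """
    complex_sasa = sasa(structure, [chain_a, chain_b], probe_radius, n_sphere_points)
    out: dict[str, set[int]] = {}
    for cid in (chain_a, chain_b):
        alone = sasa(structure, [cid], probe_radius, n_sphere_points).loc[cid]
        delta = alone["sasa"] - complex_sasa.loc[cid]["sasa"]
        out[cid] = set(delta.index[delta > delta_threshold])
    return out


def match_chain(
    sequence: str,
    structure: StructureModel,
    min_identity: float = 0.70,
    min_coverage: float = 0.50,
) -> ChainMatch | None:
    """Best chain matching a query sequence (identity > 70%, coverage > 50%).

    Identity is computed over aligned columns of the optimal local
    alignment; coverage is the aligned fraction of the query.  The
    ``exclusive`` flag is set when exactly one chain passes the
    thresholds.  Returns None when no chain passes.
    """
    passing: list[tuple[int, str, float, float]] = []
    for cid in sorted(structure.chains):
        target = structure.chains[cid].sequence
        if not target:
            continue
        aln = local_align(sequence, target)
        if not aln.aligned_pairs:
            continue
        ident = sum(1 for i, j in aln.aligned_pairs if sequence[i] == target[j]) / len(
            aln.aligned_pairs
        )
        cov = (aln.a_end - aln.a_start) / len(sequence)
        if ident > min_identity and cov > min_coverage:
            passing.append((aln.sw_score, cid, ident, cov))
    if not passing:
        return None
    passing.sort(key=lambda t: (-t[0], t[1]))
    score, cid, ident, cov = passing[0]
    return ChainMatch(chain_id=cid, identity=ident, coverage=cov, exclusive=len(passing) == 1)


def jensen_shannon_divergence(
    p: Sequence[float], q: Sequence[float], base: float = 2.0
) -> float:
    """JSD between two distributions; in [0, 1] for base 2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p / p.sum()
    q = q / q.sum()
    return float(jensenshannon(p, q, base=base) ** 2)


def _column_distribution(column: Iterable[str], pseudocount: float = 0.0) -> np.ndarray | None:
    counts = np.full(len(AMINO_ACIDS), pseudocount, dtype=float)
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    n = 0
    for aa in column:
        if aa in idx:
            counts[idx[aa]] += 1
            n += 1
    if n == 0 and pseudocount == 0:
        return None
    return counts / counts.sum()


def interface_conservation(
    msa: MsaBlock,
    reference_id: str,
    interface_indices: Iterable[int],
    background: Sequence[float] | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Conservation of interface positions across an alignment.

    For each interface residue index (0-based, ungapped coordinates of the
    reference row) the corresponding MSA column is scored with:

    * ``similarity_fraction`` — fraction of rows whose residue scores
      BLOSUM62 >= 0 against the reference residue (gap rows excluded);
    * ``jsd`` — base-2 Jensen-Shannon divergence between the column's
      amino-acid frequency distribution (gaps excluded) and a background
      distribution (uniform over the 20 amino acids by default).

    Reference gaps cannot occur by construction of the index map; columns
    with no amino-acid content report NaN.
    """
    col_map = msa.reference_column_map(reference_id)
    bg = (
        np.asarray(background, dtype=float)
        if background is not None
        else np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    )
    bg = bg / bg.sum()
    ref_row = msa.rows[reference_id]
    records = []
    for ridx in sorted(set(interface_indices)):
        if ridx not in col_map:
            records.append({"residue_index": ridx, "column": -1,
                            "similarity_fraction": float("nan"), "jsd": float("nan")})
            continue
        col = col_map[ridx]
        ref_aa = ref_row[col]
        column = [row[col] for row in msa.rows.values()]
        residues = [aa for aa in column if aa != "-"]
        if not residues:
            sim = float("nan")
        else:
            sim = sum(1 for aa in residues if blosum62_score(ref_aa, aa) >= 0) / len(residues)
        dist = _column_distribution(column, pseudocount)
        jsd = jensen_shannon_divergence(dist, bg) if dist is not None else float("nan")
        records.append(
            {"residue_index": ridx, "column": col, "similarity_fraction": sim, "jsd": jsd}
        )
    return pd.DataFrame(records).set_index("residue_index")
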