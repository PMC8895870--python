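"""Synthetic inputs with ground-truth manifests for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and
returns both the artifact (in the same in-memory container or on-disk
format the pipeline consumes) and a manifest holding the planted ground
truth, so expected downstream counts can be computed without running the
pipeline.

The cohort generator emulates the statistical shape of community-level
gene-family profiles: sparse, heavy-tailed non-negative relative
abundances (log-normal baseline with zero inflation), with case/control
differences planted as a multiplicative fold change on the bacterial
interactors of chosen human targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .homology import (
    _MATRIX,
    _INDEX,
    SequenceRecord,
    interactor_similarity,
)
from .interactions import ClusterEdge, HBNet, InteractionRecord
from .profiles import AbundanceMatrix
from .structure import Atom, Chain, Residue, StructureModel, MsaBlock

__all__ = [
    "sim_interactions",
    "sim_cluster",
    "sim_cohort",
    "sim_toy_complex",
    "sim_msa",
    "write_mitab",
    "write_genefamilies",
    "write_pdb",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BACTERIAL_TAXA = [562, 1280, 28901, 632, 177416, 83332, 777, 813, 446, 13373]
_VALID_METHOD = "MI:0018"  # two hybrid
_VALID_TYPE = "MI:0407"  # direct interaction
_COMPLEX_TYPE = "MI:0914"  # association (co-complex)
_PREDICTED_METHOD = "MI:0063"  # interaction prediction


# ---------------------------------------------------------------- interactions


def sim_interactions(
    n_valid: int,
    n_same_taxon: int = 0,
    n_complex_type: int = 0,
    n_predicted: int = 0,
    seed: int = 0,
    n_cluster_pairs: int | None = None,
) -> tuple[list[InteractionRecord], dict[str, str], pd.DataFrame]:
    """Interaction records with a declared mix of decoy classes.

    Returns (records, cluster_map, manifest).  ``cluster_map`` is in the
    protein_id -> {level: (cluster_id, kingdom)} shape the network
    builder consumes; valid records are spread over ``n_cluster_pairs``
    distinct (human, bacterial) cluster pairs (default: one pair per
    record).  The manifest labels every row with its decoy class and, for
    valid rows, its cluster pair.
    """
    rng = np.random.default_rng(seed)
    if n_cluster_pairs is None:
        n_cluster_pairs = n_valid
    records: list[InteractionRecord] = []
    manifest_rows = []
    cluster_of: dict[str, tuple[str, int, str]] = {}

    for i in range(n_valid):
        pair = i % max(n_cluster_pairs, 1)
        human = f"HUM{i:04d}"
        bact = f"BAC{i:04d}"
        cluster_of[human] = (f"UniRef90_H{pair:03d}", 90, "human")
        cluster_of[bact] = (f"UniRef50_B{pair:03d}", 50, "bacteria")
        rec = InteractionRecord(
            id_a=human,
            id_b=bact,
            taxon_a=9606,
            taxon_b=int(rng.choice(_BACTERIAL_TAXA)),
            detection_method=_VALID_METHOD,
            interaction_type=_VALID_TYPE,
            source_publication=f"pubmed:{10000000 + i}",
        )
        records.append(rec)
        manifest_rows.append({"row": len(records) - 1, "klass": "valid",
                              "human_cluster": f"UniRef90_H{pair:03d}",
                              "bacterial_cluster": f"UniRef50_B{pair:03d}"})
    for i in range(n_same_taxon):
        records.append(
            InteractionRecord(
                id_a=f"STA{i:04d}", id_b=f"STB{i:04d}", taxon_a=9606, taxon_b=9606,
                detection_method=_VALID_METHOD, interaction_type=_VALID_TYPE,
                source_publication="pubmed:1",
            )
        )
        manifest_rows.append({"row": len(records) - 1, "klass": "same_taxon",
                              "human_cluster": "", "bacterial_cluster": ""})
    for i in range(n_complex_type):
        records.append(
            InteractionRecord(
                id_a=f"CXA{i:04d}", id_b=f"CXB{i:04d}", taxon_a=9606,
                taxon_b=int(rng.choice(_BACTERIAL_TAXA)),
                detection_method=_VALID_METHOD, interaction_type=_COMPLEX_TYPE,
                source_publication="pubmed:2",
            )
        )
        manifest_rows.append({"row": len(records) - 1, "klass": "complex_type",
                              "human_cluster": "", "bacterial_cluster": ""})
    for i in range(n_predicted):
        records.append(
            InteractionRecord(
                id_a=f"PRA{i:04d}", id_b=f"PRB{i:04d}", taxon_a=9606,
                taxon_b=int(rng.choice(_BACTERIAL_TAXA)),
                detection_method=_PREDICTED_METHOD, interaction_type=_VALID_TYPE,
                source_publication="pubmed:3",
            )
        )
        manifest_rows.append({"row": len(records) - 1, "klass": "predicted",
                              "human_cluster": "", "bacterial_cluster": ""})
    cmap = {pid: {lvl: (cid, kingdom)} for pid, (cid, lvl, kingdom) in cluster_of.items()}
    return records, cmap, pd.DataFrame(manifest_rows)


def write_mitab(records: Sequence[InteractionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id_a": r.id_a, "id_b": r.id_b,
                "taxon_a": r.taxon_a, "taxon_b": r.taxon_b,
                "detection_method": r.detection_method,
                "interaction_type": r.interaction_type,
                "source_publication": r.source_publication,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------------- clusters


def _hostile_substitution(aa: str, rng: np.random.Generator) -> str:
    """A residue scoring negatively against ``aa`` under BLOSUM62."""
    i = _INDEX[aa]
    hostile = [b for b in AMINO_ACIDS if b != aa and _MATRIX[i, _INDEX[b]] < 0]
    return str(rng.choice(hostile)) if hostile else ("G" if aa != "G" else "W")


def sim_cluster(
    seed_sequence: str,
    members: Sequence[float],
    seed: int = 0,
    tolerance: float = 0.03,
    max_steps: int | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Cluster members with planted similarity to a verified interactor.

    Each member starts as a copy of ``seed_sequence`` and accumulates
    point substitutions chosen to score negatively under BLOSUM62 against
    the original residue, until the measured interactor similarity falls
    within ``tolerance`` of its target (measured with the production
    scorer itself; the scorer is independently validated against a DP
    oracle).  Unreachable targets are recorded as failed and excluded.
    """
    seq = seed_sequence.upper()
    if len(seq) < 20:
        raise ValueError("seed sequence must be at least 20 residues")
    rng = np.random.default_rng(seed)
    verified = SequenceRecord(id="verified", sequence=seq, kingdom="bacteria")
    max_steps = max_steps or 4 * len(seq)

    out = [verified]
    rows = [{"member": "verified", "target": 1.0, "achieved": 1.0, "ok": True}]
    for mi, target in enumerate(members):
        current = list(seq)
        achieved = 1.0
        if abs(1.0 - target) <= tolerance:
            pass  # identical copy suffices
        else:
            positions = rng.permutation(len(seq))
            ok = False
            steps = 0
            for pos in positions:
                if steps >= max_steps:
                    break
                old = current[pos]
                current[pos] = _hostile_substitution(old, rng)
                steps += 1
                achieved = interactor_similarity(seq, "".join(current)).value
                if abs(achieved - target) <= tolerance:
                    ok = True
                    break
                if achieved < target - tolerance:
                    current[pos] = old  # overshot; revert and try elsewhere
                    achieved = interactor_similarity(seq, "".join(current)).value
                    if abs(achieved - target) <= tolerance:
                        ok = True
                        break
            if not ok:
                rows.append({"member": f"member{mi}", "target": target,
                             "achieved": achieved, "ok": False})
                continue
        member_id = f"member{mi}"
        out.append(SequenceRecord(id=member_id, sequence="".join(current), kingdom="bacteria"))
        rows.append({"member": member_id, "target": target,
                     "achieved": achieved, "ok": True})
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------- cohort


@dataclass
class CohortManifest:
    seed: int
    planted_targets: list[str]
    boosted_clusters: list[str]
    effect_fold: float
    zero_inflation: float
    targets_of: dict[str, list[str]] = field(default_factory=dict)
    low_read_samples: list[str] = field(default_factory=list)


def sim_cohort(
    n_case: int = 100,
    n_control: int = 100,
    n_bacterial_clusters: int = 300,
    n_human_targets: int = 200,
    network_density: float = 0.01,
    n_planted_targets: int = 10,
    effect_fold: float = 8.0,
    zero_inflation: float = 0.3,
    low_read_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[AbundanceMatrix, HBNet, CohortManifest]:
    """A zero-inflated case-control cohort with planted differential targets.

    Baseline abundances are log-normal(0, 1), independently zeroed with
    probability ``zero_inflation``.  A random bipartite map of the stated
    density links bacterial clusters to human targets (every cluster gets
    at least one target, every planted target at least one interactor);
    clusters interacting with planted targets are multiplied by
    ``effect_fold`` in cases.  Read counts are drawn around 2x10^7 with a
    ``low_read_fraction`` of samples planted below the 10^7 QC line.
    """
    if effect_fold < 1:
        raise ValueError("effect_fold must be >= 1")
    rng = np.random.default_rng(seed)
    bclusters = [f"UniRef50_B{i:04d}" for i in range(n_bacterial_clusters)]
    targets = [f"T{j:04d}" for j in range(n_human_targets)]
    samples = [f"case{i:03d}" for i in range(n_case)] + [
        f"ctrl{i:03d}" for i in range(n_control)
    ]
    labels = ["case"] * n_case + ["control"] * n_control

    # Bipartite interaction map.
    adj = rng.random((n_bacterial_clusters, n_human_targets)) < network_density
    for i in range(n_bacterial_clusters):  # every cluster interacts
        if not adj[i].any():
            adj[i, rng.integers(n_human_targets)] = True
    planted = sorted(rng.choice(targets, size=n_planted_targets, replace=False))
    planted_idx = [targets.index(t) for t in planted]
    for j in planted_idx:  # every planted target has an interactor
        if not adj[:, j].any():
            adj[rng.integers(n_bacterial_clusters), j] = True

    net = HBNet()
    targets_of: dict[str, list[str]] = {}
    for i, j in zip(*np.nonzero(adj)):
        edge = ClusterEdge(human_cluster=targets[j], bacterial_cluster=bclusters[i])
        edge.verified_bacterial_members = [f"{bclusters[i]}_rep"]
        edge.putative_members = [f"{bclusters[i]}_rep"]
        net.edges[edge.key] = edge
        targets_of.setdefault(bclusters[i], []).append(targets[j])

    boosted = sorted(
        b for b, ts in targets_of.items() if any(t in planted for t in ts)
    )
    boosted_idx = np.array([bclusters.index(b) for b in boosted], dtype=int)

    values = rng.lognormal(mean=0.0, sigma=1.0, size=(len(samples), n_bacterial_clusters))
    values[rng.random(values.shape) < zero_inflation] = 0.0
    if len(boosted_idx):
        values[:n_case, boosted_idx] *= effect_fold

    read_counts = rng.normal(2e7, 2e6, size=len(samples)).astype(np.int64)
    read_counts = np.clip(read_counts, int(1.1e7), None)
    n_low = int(round(low_read_fraction * len(samples)))
    low_samples: list[str] = []
    if n_low:
        low_pos = rng.choice(len(samples), size=n_low, replace=False)
        read_counts[low_pos] = rng.integers(1e6, 9.9e6, size=n_low)
        low_samples = sorted(samples[i] for i in low_pos)

    matrix = AbundanceMatrix(
        values=pd.DataFrame(values, index=samples, columns=bclusters),
        sample_meta=pd.DataFrame(
            {"label": labels, "read_count": read_counts, "study": "synthetic"},
            index=samples,
        ),
    )
    manifest = CohortManifest(
        seed=seed,
        planted_targets=list(planted),
        boosted_clusters=boosted,
        effect_fold=effect_fold,
        zero_inflation=zero_inflation,
        targets_of={k: sorted(v) for k, v in targets_of.items()},
        low_read_samples=low_samples,
    )
    return matrix, net, manifest


def write_genefamilies(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write abundances in HUMAnN3 genefamilies layout (families x samples)."""
    df = matrix.values.T
    df.index.name = "# Gene Family"
    df.to_csv(path, sep="\t")


# ------------------------------------------------------------- toy structures


def sim_toy_complex(
    n_contact_residues: int = 4,
    separation: float = 30.0,
    seed: int = 0,
    chain_length: int = 12,
    contact_distance: float = 4.0,
    spacing: float = 3.8,
) -> tuple[StructureModel, dict[str, list[int]]]:
    """Two single-atom-per-residue poly-alanine strands with planted contacts.

    Chain A lies on the x axis; chain B runs parallel at ``separation``
    except for a centred window of ``n_contact_residues`` residues pulled
    to ``contact_distance``.  The manifest lists the window indices for
    both chains.  Small seeded jitter (<0.05 A) keeps regeneration
    seed-faithful without moving any residue across the contact cutoff.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if n_contact_residues > chain_length:
        raise ValueError("contact window exceeds chain length")
    rng = np.random.default_rng(seed)
    start = (chain_length - n_contact_residues) // 2
    window = list(range(start, start + n_contact_residues))

    def _chain(cid: str, y_of) -> Chain:
        chain = Chain(id=cid)
        for i in range(chain_length):
            x = i * spacing + rng.uniform(-0.05, 0.05)
            y = y_of(i) + rng.uniform(-0.05, 0.05)
            z = rng.uniform(-0.05, 0.05)
            chain.residues.append(
                Residue(name="ALA", index=i, atoms=[Atom("CA", "C", 1.70, x, y, z)])
            )
        return chain

    model = StructureModel()
    model.chains["A"] = _chain("A", lambda i: 0.0)
    model.chains["B"] = _chain(
        "B", lambda i: contact_distance if i in window else separation
    )
    manifest = {"A": window, "B": list(window) if n_contact_residues else []}
    return model, manifest


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as minimal PDB-format ATOM records."""
    lines = []
    serial = 1
    for cid in sorted(model.chains):
        for res in model.chains[cid].residues:
            for atom in res.atoms:
                lines.append(
                    f"ATOM  {serial:5d} {atom.name:^4s}{res.name:>4s} {cid}"
                    f"{res.index + 1:4d}    {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                    f"  1.00  0.00          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------------ MSA


def sim_msa(
    reference: str,
    n_rows: int,
    conserved_columns: Sequence[int] | None = None,
    noisy_columns: Sequence[int] = (),
    seed: int = 0,
) -> tuple[MsaBlock, dict]:
    """A gap-free alignment with chosen column conservation.

    Row ``ref`` is the reference itself.  Conserved columns copy the
    reference in every row (the default for unlisted columns); noisy
    columns draw uniformly over the 20 amino acids.
    """
    reference = reference.upper()
    noisy = set(noisy_columns)
    if conserved_columns is not None and noisy & set(conserved_columns):
        raise ValueError("conserved and noisy column lists must be disjoint")
    rng = np.random.default_rng(seed)
    rows = {"ref": reference}
    for r in range(n_rows - 1):
        row = [
            str(rng.choice(list(AMINO_ACIDS))) if c in noisy else reference[c]
            for c in range(len(reference))
        ]
        rows[f"row{r}"] = "".join(row)
    manifest = {
        "noisy_columns": sorted(noisy),
        "conserved_columns": [c for c in range(len(reference)) if c not in noisy],
    }
    return MsaBlock(rows=rows), manifest
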