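"""Solvent accessibility, interface detection and conservation scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from hmppi.structure import (
    Atom,
    Chain,
    MsaBlock,
    Residue,
    StructureModel,
    interface_conservation,
    interface_residues,
    jensen_shannon_divergence,
    match_chain,
    read_msa,
    read_pdb,
    sasa,
    surface_residues,
)
from hmppi.simulate import sim_msa, sim_toy_complex, write_pdb


def _single_atom(radius=1.7, xyz=(0.0, 0.0, 0.0)):
    return StructureModel(
        chains={
            "A": Chain("A", [Residue("ALA", 0, [Atom("CA", "C", radius, *xyz)])])
        }
    )


def test_single_atom_matches_analytic_sphere():
    got = sasa(_single_atom())["sasa"].iloc[0]
    analytic = 4 * math.pi * (1.7 + 1.4) ** 2
    assert got == pytest.approx(analytic, rel=1e-6)  # every point accessible


def test_distant_atoms_are_additive():
    m = StructureModel(
        chains={
            "A": Chain(
                "A",
                [
                    Residue("ALA", 0, [Atom("CA", "C", 1.7, 0, 0, 0)]),
                    Residue("ALA", 1, [Atom("CA", "C", 1.7, 100, 0, 0)]),
                ],
            )
        }
    )
    per_res = sasa(m)["sasa"]
    isolated = 4 * math.pi * (1.7 + 1.4) ** 2
    assert per_res.iloc[0] == pytest.approx(isolated, rel=1e-6)
    assert per_res.iloc[1] == pytest.approx(isolated, rel=1e-6)


def test_buried_atom_has_negligible_sasa():
    # Surround one atom with a shell of 26 atoms on the unit cube corners/faces.
    atoms = [Atom("CA", "C", 1.7, 0, 0, 0)]
    shell = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) != (0, 0, 0):
                    shell.append((2.0 * dx, 2.0 * dy, 2.0 * dz))
    residues = [Residue("ALA", 0, atoms)]
    for i, xyz in enumerate(shell):
        residues.append(Residue("ALA", i + 1, [Atom("CA", "C", 1.7, *xyz)]))
    m = StructureModel(chains={"A": Chain("A", residues)})
    buried = sasa(m).loc[("A", 0), "sasa"]
    assert buried == pytest.approx(0.0, abs=1e-6)


def test_sasa_rigid_motion_invariant():
    # Per-residue invariance to 0.1% needs the quadrature error below that
    # level, hence the raised point count; translation alone is exact.
    n_points = 100000
    model, _ = sim_toy_complex(n_contact_residues=4, separation=12.0, seed=2)
    base = sasa(model, n_sphere_points=n_points)["sasa"].to_numpy()
    theta = 0.7
    rot = np.array(
        [
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    moved = StructureModel()
    for cid, chain in model.chains.items():
        new = Chain(cid)
        for res in chain.residues:
            new_atoms = []
            for a in res.atoms:
                x, y, z = rot @ np.array([a.x, a.y, a.z]) + np.array([5.0, -3.0, 2.0])
                new_atoms.append(Atom(a.name, a.element, a.radius, x, y, z))
            new.residues.append(Residue(res.name, res.index, new_atoms))
        moved.chains[cid] = new
    after = sasa(moved, n_sphere_points=n_points)["sasa"].to_numpy()
    assert np.allclose(after, base, rtol=1e-3)
    # total SASA is invariant to 0.1% already at the default resolution
    total_base = sasa(model)["sasa"].sum()
    total_after = sasa(moved)["sasa"].sum()
    assert total_after == pytest.approx(total_base, rel=1e-3)


def test_sasa_quadrature_converges_to_analytic():
    analytic = 4 * math.pi * (1.7 + 1.4) ** 2
    errs = [
        abs(sasa(_single_atom(), n_sphere_points=n)["sasa"].iloc[0] - analytic)
        for n in (60, 240, 960)
    ]
    assert errs[0] < analytic * 0.05
    # the quadrature error does not grow with resolution
    assert errs[2] <= errs[0] + 1e-9


def test_surface_threshold_inclusive():
    df = pd.DataFrame(
        {"residue": ["ALA"] * 3, "sasa": [19.35, 0.0, 60.0], "relative": [0.15, 0.0, 0.465]},
        index=pd.MultiIndex.from_tuples(
            [("A", 0), ("A", 1), ("A", 2)], names=["chain", "residue_index"]
        ),
    )
    assert surface_residues(df) == {("A", 0), ("A", 2)}


def test_interface_empty_for_distant_chains():
    model, _ = sim_toy_complex(n_contact_residues=0, separation=500.0, seed=0)
    iface = interface_residues(model, "A", "B")
    assert iface == {"A": set(), "B": set()}


def test_interface_contains_planted_contacts_within_one_neighbor():
    model, contacts = sim_toy_complex(n_contact_residues=4, separation=30.0, seed=1)
    iface = interface_residues(model, "A", "B")
    for cid in ("A", "B"):
        planted = set(contacts[cid])
        allowed = planted | {i - 1 for i in planted} | {i + 1 for i in planted}
        assert planted <= iface[cid] <= allowed


def test_interface_symmetric_in_chain_order():
    model, _ = sim_toy_complex(n_contact_residues=3, separation=25.0, seed=3)
    ab = interface_residues(model, "A", "B")
    ba = interface_residues(model, "B", "A")
    assert ab == ba


def test_delta_sasa_never_negative():
    model, _ = sim_toy_complex(n_contact_residues=4, separation=20.0, seed=4)
    complex_sasa = sasa(model, ["A", "B"])
    for cid in ("A", "B"):
        alone = sasa(model, [cid]).loc[cid]["sasa"]
        delta = alone - complex_sasa.loc[cid]["sasa"]
        assert (delta >= -1e-9).all()


def test_pdb_round_trip(tmp_path):
    model, _ = sim_toy_complex(n_contact_residues=2, separation=15.0, seed=5)
    p = tmp_path / "toy.pdb"
    write_pdb(model, p)
    back = read_pdb(p)
    assert set(back.chains) == {"A", "B"}
    assert len(back.chains["A"].residues) == len(model.chains["A"].residues)
    a0 = back.chains["A"].residues[0].atoms[0]
    m0 = model.chains["A"].residues[0].atoms[0]
    assert a0.x == pytest.approx(m0.x, abs=1e-3)


def _chain_from_seq(cid, seq, offset=0.0):
    residues = []
    one_to_three = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
                    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
                    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
                    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR"}
    for i, aa in enumerate(seq):
        residues.append(
            Residue(one_to_three[aa], i, [Atom("CA", "C", 1.7, 3.8 * i, offset, 0)])
        )
    return Chain(cid, residues)


def test_match_chain_prefers_true_chain_over_decoy():
    rng = np.random.default_rng(6)
    from conftest import random_peptide

    query = random_peptide(rng, 30)
    decoy = list(query)
    for pos in rng.choice(30, size=6, replace=False):  # 80%-identity decoy
        decoy[pos] = "W" if query[pos] != "W" else "G"
    model = StructureModel(
        chains={
            "T": _chain_from_seq("T", query),
            "D": _chain_from_seq("D", "".join(decoy), offset=50.0),
        }
    )
    hit = match_chain(query, model)
    assert hit.chain_id == "T" and hit.identity == pytest.approx(1.0)
    assert not hit.exclusive  # the 80% decoy also passes the 70% gate


def test_match_chain_none_when_nothing_passes():
    model = StructureModel(chains={"X": _chain_from_seq("X", "W" * 20)})
    assert match_chain("A" * 30, model) is None


def test_jsd_contract():
    rng = np.random.default_rng(7)
    for _ in range(100):
        p = rng.dirichlet(np.ones(20))
        q = rng.dirichlet(np.ones(20))
        jsd = jensen_shannon_divergence(p, q)
        # direct formula evaluation
        m = (p + q) / 2
        kl = lambda a, b: float(np.sum(a[a > 0] * np.log2(a[a > 0] / b[a > 0])))
        direct = 0.5 * kl(p, m) + 0.5 * kl(q, m)
        assert jsd == pytest.approx(direct, abs=1e-9)
        assert jsd == pytest.approx(jensen_shannon_divergence(q, p), abs=1e-12)
        assert 0.0 <= jsd <= 1.0
        assert jensen_shannon_divergence(p, p) == pytest.approx(0.0, abs=1e-12)
    point_a, point_b = np.zeros(20), np.zeros(20)
    point_a[0] = point_b[1] = 1.0
    assert jensen_shannon_divergence(point_a, point_b) == pytest.approx(1.0)


def test_interface_conservation_conserved_and_noisy_columns():
    rng = np.random.default_rng(8)
    from conftest import random_peptide

    ref = random_peptide(rng, 20)
    msa, manifest = sim_msa(ref, n_rows=40, noisy_columns=[2, 5, 9], seed=8)
    cons = interface_conservation(msa, "ref", range(len(ref)))
    conserved = [c for c in range(len(ref)) if c not in {2, 5, 9}]
    assert (cons.loc[conserved, "similarity_fraction"] == 1.0).all()
    # conserved (point-mass) columns diverge more from uniform than noisy ones
    assert cons.loc[conserved, "jsd"].min() > cons.loc[[2, 5, 9], "jsd"].max()


def test_interface_conservation_handles_gap_columns():
    msa = MsaBlock(rows={"ref": "AC-D", "r1": "A--D", "r2": "A--D"})
    cons = interface_conservation(msa, "ref", [0, 1, 2])
    assert cons.loc[0, "similarity_fraction"] == 1.0
    assert cons.loc[1, "similarity_fraction"] == 1.0  # only the reference row has C
    assert cons.loc[2, "similarity_fraction"] == 1.0  # the D column (ref index 2)


def test_read_msa_rejects_ragged(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">a\nACD\n>b\nAC\n")
    with pytest.raises(ValueError):
        read_msa(p)
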