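"""Interface residues of a toy complex and their conservation in an MSA.

Builds a two-chain toy structure with four planted contact residues,
detects the interface via the loss of solvent-accessible surface area on
complex formation (delta-SASA > 1 A^2), and scores the conservation of the
interface columns of a simulated cluster alignment with BLOSUM62
similarity fractions and Jensen-Shannon divergence against a uniform
background.
"""

import numpy as np

from hmppi.simulate import AMINO_ACIDS, sim_msa, sim_toy_complex
from hmppi.structure import interface_conservation, interface_residues, sasa, surface_residues

model, contacts = sim_toy_complex(n_contact_residues=4, separation=30.0, seed=0)
print(f"planted contact residues: {contacts}")

accessibility = sasa(model)
surface = surface_residues(accessibility, threshold=0.15)
print(f"surface residues (relative SASA >= 15%): {len(surface)} of "
      f"{len(accessibility)}")

interface = interface_residues(model, "A", "B", delta_threshold=1.0)
print(f"interface calls (delta-SASA > 1 A^2): "
      f"{ {c: sorted(r) for c, r in interface.items()} }")
print("the calls contain every planted contact, plus at most its direct "
      "lattice neighbours.")

rng = np.random.default_rng(0)
reference = "".join(rng.choice(list(AMINO_ACIDS), size=12))
msa, _ = sim_msa(reference, n_rows=60, noisy_columns=[1, 9], seed=0)
conservation = interface_conservation(msa, "ref", sorted(interface["B"]))
print("\nconservation of chain-B interface columns:")
print(conservation.to_string(float_format=lambda v: f"{v:.3f}"))
print("\nconserved columns score similarity 1.0 and high JSD vs the uniform "
      "background; the noisy column (if at the interface) drops on both.")
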