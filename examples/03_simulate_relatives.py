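"""Simulated allele sharing by relationship.

Simulates pairs for each relationship by pedigree gene dropping (coancestry
theta_true = 0) over 13 equi-frequent ten-allele loci and prints the mean
number of shared alleles per locus next to the kinship coefficient
psi = k1/4 + k2/2.  Sharing rises with kinship; unrelated pairs still share
alleles by chance.
"""

import numpy as np

from famlr import RELATIONSHIPS, generate_equifrequent_panel, kinship_coefficient
from famlr.pairsim import SimConfig, simulate_pairs

panel = generate_equifrequent_panel(13, 10, 200)
reps = 500

print(f"{'relationship':<18}{'kinship':>9}{'shared alleles/locus':>22}")
for rel in ("unrelated", "second-cousin", "first-cousin",
            "half-sibling", "sibling", "parent-offspring"):
    pairs = simulate_pairs(SimConfig(rel, "POP", 0.0, reps, seed=7), panel)
    sharing = np.mean([
        np.mean([p.shared_allele_count(l) for l in panel.loci]) for p in pairs
    ])
    print(f"{rel:<18}{kinship_coefficient(RELATIONSHIPS[rel]):>9.4f}{sharing:>22.3f}")
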