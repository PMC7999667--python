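"""Encode a few known milk-derived peptides as type-II PseAAC vectors.

Each peptide becomes 26 numbers: the 20 residue frequencies followed by
six sequence-order correlation factors (one per physicochemical scale at
lag 1), all divided by the same normalizer so the vector sums to 1.
"""

import numpy as np

from acescreen import Peptide, encode, load_default_property_table

table = load_default_property_table()

for seq in ("IPP", "VPP", "FFVAPFPEVFGK"):  # classic casein-derived ACE inhibitors
    vec = encode(Peptide(seq, seq), table)
    comp = vec.values[:20]
    corr = vec.values[20:]
    print(f"{seq:>14}  dim={len(vec.values)}  sum={vec.values.sum():.6f}")
    print(f"{'':>14}  composition block: {np.count_nonzero(comp)} nonzero entries, "
          f"max {comp.max():.4f}")
    print(f"{'':>14}  correlation block: "
          + " ".join(f"{t:+.4f}" for t in corr))

print("\nThe correlation entries are signed: adjacent residues with "
      "like-signed standardized property values push them positive.")
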