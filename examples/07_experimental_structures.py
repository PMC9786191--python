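"""Optional: fenestration-width comparison on experimental structures.

Needs locally downloaded coordinate files (none are shipped and nothing is
downloaded here).  With, e.g., the apo rat cardiac-channel structure and
the toxin-trapped resting-sensor structure saved as 6uz3.cif and 7k18.cif,
the activated-sensor state should show the larger Cbeta-Cbeta distance
across the I/IV fenestration (residues F399 / V1765 in human numbering).
"""

import sys
from pathlib import Path

from poremcm import DistancePair, compare_states, read_structure, superpose

FILES = {"activated": "6uz3.cif", "resting": "7k18.cif"}

missing = [f for f in FILES.values() if not Path(f).exists()]
if missing:
    print(f"structure files not found ({', '.join(missing)}); "
          "download them first, then re-run.")
    sys.exit(0)

activated = read_structure(FILES["activated"])
resting = read_structure(FILES["resting"])

# distances are superposition-invariant, but aligning on the P1 helices
# first makes saved overlays meaningful; pick any shared Calpha selection
shared = sorted(
    set(activated.residue_numbers()) & set(resting.residue_numbers())
)[:200]
transform, rmsd = superpose(resting, activated, shared)
print(f"P1-region alignment RMSD over {len(shared)} residues: {rmsd:.2f} A")

pair = DistancePair(399, 1765, "I/IV")  # explicit residue numbers
table = compare_states(activated, resting, [pair])
print(table.to_string(index=False))
print("delta > 0 means the activated-sensor structure has the wider window.")
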