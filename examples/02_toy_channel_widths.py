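"""Build synthetic pore domains at two fenestration widths and measure the
planted window with the same Cbeta-Cbeta operation used for real
structures."""

from poremcm import (
    DistancePair,
    SyntheticChannelSpec,
    compare_states,
    make_toy_channel,
    write_structure,
)
from poremcm.synthetic import toy_resnum

wide = make_toy_channel(SyntheticChannelSpec(fenestration_width=12.0))
narrow = make_toy_channel(SyntheticChannelSpec(fenestration_width=9.5))

pairs = [
    DistancePair(toy_resnum(r, "i", 6), toy_resnum(r % 4 + 1, "i", 9), f"{r}/{r % 4 + 1}")
    for r in (1, 2, 3, 4)
]
table = compare_states(wide, narrow, pairs)
print(table.to_string(index=False))
# d_a/d_b are the flank side-chain separations across each window (A);
# delta > 0 means the first (wide) model has the larger window — the
# geometry the activated-sensor state is expected to show.

write_structure(wide, "scratch_toy_wide.pdb")
print("\nwrote scratch_toy_wide.pdb (standard PDB, one chain per repeat)")
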