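"""Universal P-loop residue labels and the packaged hNav1.5 anchor table.

Labels name pore-domain residues in a channel-independent way:
repeat (1-4) + segment (k = S4-S5 linker, o = S5, p = P-loop, i = S6) +
position in the segment (P-loop positions are relative to the selectivity
filter at p50).
"""

from poremcm import hnav15_anchors, hnav15_segment_ranges, label_of, parse_label, resolve

anchors = hnav15_anchors()
ranges = hnav15_segment_ranges()

for text in ["4i15", "4o1", "4p49", "3p50", "1o29", "F4i15"]:
    label = parse_label(text)
    print(f"{text:>6} -> residue {resolve(label, anchors)}")

print()
for resnum in [1760, 1652, 1710, 1419]:
    print(f"residue {resnum} -> {label_of(resnum, anchors, ranges)}")
print(f"residue 1300 (voltage sensor) -> {label_of(1300, anchors, ranges)}")

# 4i15 is the S6 phenylalanine of repeat IV (F1760), the central
# drug-sensing residue; 4p49 is the P-loop serine S1710; labels resolve
# through a per-segment affine anchor table that users can replace for
# other channels.
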