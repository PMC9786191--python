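"""Random-start docking of the amine-plus-aromatic toy blocker into the
inner-pore region of a synthetic channel, with pose-stack clustering and a
ranked, labelled pose report."""

from poremcm import DockingConfig, MCMConfig, dock, make_toy_channel, make_toy_ligand, report_poses
from poremcm.synthetic import toy_anchor_table

channel = make_toy_channel()
ligand = make_toy_ligand()

# desk-scale settings; production runs use hundreds of starts and
# patience 1000
config = DockingConfig(
    n_starts=30,
    coarse_minimizations=8,
    n_refine=4,
    refine_patience=30,
    seed=7,
    mcm=MCMConfig(max_minimizer_iter=50),
)
stack = dock(channel, ligand, config)
print(f"stack: {len(stack)} clustered poses, "
      f"best total energy {stack.best.energy:.2f} kcal/mol")

table = report_poses(
    stack, window=10.0, structure=channel, ligand=ligand,
    anchors=toy_anchor_table(),
)
print(table.head(8).to_string(index=False))
# interaction_energy is the ligand-channel cross term only; class is the
# geometric pose family (ring in a fenestration = TB-like, ring in the
# inner pore = UDB-like); contacts are residues within 4 A, as universal
# labels where the residue is an annotated pore-domain position (plain
# numbers otherwise).  The cationic head seeks the electronegative spots:
# the p48/p50 carbonyl site at the outer-pore bottom and the interface
# attractor outside the fenestration; symmetric repeats give degenerate
# clusters with identical energies.
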