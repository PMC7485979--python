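"""Score docking decoys against a reference complex with CAPRI-style metrics.

Rigid-body perturbations of the native binder pose degrade gracefully:
f_nat (fraction of native contacts kept) falls and I-RMSD (backbone RMSD over
the reference interface) grows with the perturbation.
"""

from epimode import DecoySchedule, ToySpec, make_decoy_set, make_toy_complex, toy_partition

spec = ToySpec()
native = make_toy_complex(spec)
part = toy_partition(spec)

schedule = DecoySchedule(moves=(
    (0.0, (0.0, 0.0, 0.0)),    # the native pose itself
    (0.0, (0.0, 1.0, 0.0)),    # 1 A away from the target
    (0.0, (0.0, 2.0, 0.0)),
    (0.0, (8.0, 0.0, 0.0)),    # slid one residue along the epitope
    (180.0, (0.0, 0.0, 0.0)),  # flipped orientation
    (0.0, (0.0, 20.0, 0.0)),   # fully dissociated
))

print("decoy      rot_deg  translation         fnat   irmsd  iface_recovery")
for decoy, m in make_decoy_set(native, schedule, part):
    pert = decoy.meta["perturbation"]
    t = "({:5.1f},{:5.1f},{:4.1f})".format(*pert["translation"])
    print(f"{decoy.id}  {pert['rot_deg']:7.1f}  {t}  {m.fnat:5.2f} {m.irmsd:7.2f}   {m.interface_recovery:5.2f}")
# The identity decoy scores fnat 1.0 / I-RMSD 0.0; sliding along the chain
# keeps some interface residues (recovery > 0) but no exact contact pairs.
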