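"""Design a minimal panel of disruptive variants covering a docking ensemble.

Three hypothetical docking models place the binder on two distinct surface
patches of the target. The designer finds the smallest panel of multi-point
variants (max 3 mutations each, one patch per variant) such that every model
is tested by at least one variant, plus two alternate panels.
"""

from epimode import ToySpec, make_toy_complex, toy_partition
from epimode.paneldesign import cluster_patches, design_variant_panel, propose_mutations

spec = ToySpec(target_length=14)
target = make_toy_complex(spec)
part = toy_partition(spec)

T = lambda n: ("T", n, "")
epitopes = {
    "model_A": {T(2), T(3), T(4)},
    "model_B": {T(4), T(5), T(6)},
    "model_C": {T(11), T(12), T(13)},
}

patches = cluster_patches(epitopes, target, radius=8.5)
print(f"{len(patches)} spatial patches from {len(epitopes)} model epitopes")

mutations, disruption = {}, {}
for patch in patches:
    for pos, (mut, score) in propose_mutations(target, patch, part).items():
        mutations[pos], disruption[pos] = mut, score

panels = design_variant_panel(epitopes, patches, k=3, alternates=2,
                              disruption=disruption, mutations=mutations)
for i, panel in enumerate(panels):
    label = "optimal" if i == 0 else f"alternate {i}"
    variants = "; ".join(str(v) for v in panel.variants)
    print(f"{label}: {panel.objective[0]} variants  [{variants}]")
# The optimal panel needs one variant per patch: a single well-placed mutation
# set discriminates models A+B from model C.
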