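"""Build a synthetic binder-target complex and list its interface contacts.

The fixture generator plants an exact contact map: binder residues 2-4 touch
target residues 5-7 at under 5 A heavy-atom distance, everything else is far.
"""

from epimode import ToySpec, make_toy_complex, toy_partition
from epimode.interface import contact_table, epitope_of_model

spec = ToySpec(binder_length=6, target_length=12,
               contacts=((2, 5), (3, 6), (4, 7)), seed=0)
complex_ = make_toy_complex(spec)
part = toy_partition(spec)

print(contact_table(complex_, part).to_string(index=False))
epitope = sorted(n for _, n, _ in epitope_of_model(complex_, part))
print(f"\nepitope (target residues contacted by the binder): {epitope}")
# Each row is one residue pair across the interface with its minimum
# heavy-atom distance; the epitope is the target-side projection.
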