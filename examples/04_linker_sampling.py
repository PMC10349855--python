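"""Conformer-pool generation by random linker phi/psi rotations.

Each pass re-draws the long linker's torsions residue by residue, accepting
a rotation only if the molecule-wide steric energy stays within 10% of the
pass-start energy, then relaxes briefly.  The pool sweeps a wide range of
inter-domain arrangements while every rigid domain stays internally exact.
"""

import numpy as np

from prelink import SamplingConfig, generate_pool, make_toy_complex

conf, partition, _ = make_toy_complex()
pool = generate_pool(conf, partition, SamplingConfig(n_attempts=30, seed=0))

first = partition.rigid_segments()[0]
last = partition.rigid_segments()[-1]
distances = []
for member in pool.members:
    c1 = member.coords[partition.atom_mask(member, first.name)].mean(axis=0)
    c2 = member.coords[partition.atom_mask(member, last.name)].mean(axis=0)
    distances.append(float(np.linalg.norm(c1 - c2)))

print(f"accepted {pool.accepted}/{pool.attempted} randomization passes")
print(
    f"inter-domain center distance across the pool: "
    f"{min(distances):.1f} - {max(distances):.1f} A (template {distances[0]:.1f} A)"
)
print("the spread shows the linker sweeps arrangements from compact to extended;")
print("restraint-driven annealing then selects among them.")
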