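"""Restraint-driven annealing: recover the domain arrangement from data.

Runs one seed of the full recovery experiment: simulate PRE/CSP observables
at 5% ratio noise from the known bound structure, rebuild restraints from
them, randomize the linker, anneal, and measure how close the lowest-energy
ensemble centroid comes to the ground truth.  Takes ~30 s.
"""

from prelink.experiments import recover_domain_arrangement

result = recover_domain_arrangement(seed=4)

print(f"ensemble of {result.ensemble_size} lowest-energy refined conformers")
print(f"best restraint energy {result.best_energy:.1f} "
      f"(ground truth scores {result.truth_energy:.1f} under the same noisy data)")
print(f"centroid vs truth, rigid domains + RNA backbone: {result.rmsd_domains:.2f} A")
print(f"centroid vs truth, all backbone incl. flexible linker: {result.rmsd_global:.2f} A")
print("below ~3 A on the domain metric means the PRE + CSP restraint set")
print("pinned the mobile domain's position against the RNA-bound module.")
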