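# prelink

Integrative NMR/SAXS/ITC modeling of multidomain proteins with flexible
linkers, bound to short single-stranded RNA.

Many RNA-binding proteins are strings of small domains (RRMs, zinc fingers)
on flexible linkers. No single technique resolves how such a protein wraps
around its RNA: crystallography sees the rigid parts, NMR sees per-residue
contacts and dynamics, SAXS sees the overall envelope, ITC sees the binding
thermodynamics. `prelink` implements the desk-side computational workflow
that stitches these together into a structural model of the complex, for
structural biologists who have the tabulated data (peak lists, decay series,
intensity ratios, scattering curves, injection heats) and want the analysis
chain from raw tables to an ensemble of conformers:

- **CSP mapping** — combined amide shift changes
  Δδ = √(Δδ_H² + (α·Δδ_N)²) with α = 0.2; residues with Δδ > 0.08 ppm become
  binding-site reporters and, for domains without a complex structure,
  ambiguous heavy-atom distance restraints (4 ± 1 Å) to a window of
  nucleotides.
- **¹⁵N relaxation** — mono-exponential R₁/R₁ρ decay fits, offset correction
  R₁ρ = R₁cos²θ + R₂sin²θ with θ = tan⁻¹(ν₁/Δν), and rotational correlation
  times τ_c = √(6R₂/R₁ − 7)/(4πν_N), plus the empirical 0.6 ns/kDa
  expectation for globular proteins.
- **PRE restraints** — intensity ratios I_para/I_dia = R₂e^(−Γ₂t)/(R₂+Γ₂)
  inverted for Γ₂ and converted to distances through
  Γ₂ = K/r⁶·(4τ_c + 3τ_c/(1+ω_H²τ_c²)), K = 1.23×10⁻³² cm⁶s⁻², with
  flat-bottom classification (upper / quantitative ± 4 Å / lower).
- **Conformer sampling** — random φ/ψ rotations of the long linker between
  semi-rigid bodies, accepting a rotation only if the molecule-wide repulsive
  steric energy stays within 10% of the pass-start energy.
- **Restraint annealing** — three-stage Metropolis simulated annealing in
  linker-torsion + rigid-body space against PRE and ambiguous restraints
  (r⁻⁶-summed effective distances), then selection of the lowest-energy
  ensemble.
- **SAXS** — Debye curves from residue beads, Guinier fits, p(r)/D_max from
  coordinates or by regularized indirect transform, and reduced χ²
  model-vs-data fitting.
- **ITC** — one-site (Wiseman) isotherm simulation and fitting;
  ΔG = RT ln K_D, −TΔS = ΔG − ΔH.

A first-class synthetic-data generator builds a ground-truth toy complex
(three globular pseudo-atomic domains, a 7-residue and a sampled 20-residue
linker, a 12-mer RNA threaded across all three domains) and forward-simulates
every observable above, so the entire pipeline is testable end to end as a
parameter-recovery experiment.

## Worked example

```bash
python examples/05_restraint_annealing.py
```

prints (seed 4):

```
ensemble of 5 lowest-energy refined conformers
best restraint energy 3.9 (ground truth scores 5.4 under the same noisy data)
centroid vs truth, rigid domains + RNA backbone: 0.66 A
centroid vs truth, all backbone incl. flexible linker: 2.14 A
```

Meaning: observables were simulated from the known bound structure at 5%
PRE-ratio noise, restraints were rebuilt from those observables alone, and
restraint-driven annealing of randomized-linker conformers recovered the
domain arrangement to 0.66 Å over the ordered regions — the restraint energy
of the recovered ensemble is even slightly below the ground truth's own
score because noise shifts the effective minimum. The other examples
(`examples/01…08`) walk through each capability the same way; the CLI
(`prelink simulate|csp|relax|pre|sample|anneal|saxs|itc|run-all`) exposes
the same operations on files.

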