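# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Coordinate model and geometry

A `Conformer` is a flat numpy-backed atom table grouped by chain and
residue (Å, 1-based residue numbers). PDB I/O goes through gemmi;
insertion codes are rejected (the package targets renumbered models) and
alternate locations resolve to the first occurrence. Superposition is the
Kabsch least-squares fit (SVD with determinant correction, always a proper
rotation).

The steric term is purely repulsive, E = Σ k(r_min − r)⁴ for r < r_min,
with a single effective contact distance r_min = 3.2 Å and k = 1 for
pseudo-atomic beads (per-element-pair overrides possible). There is no
attractive component because the only role of the term is the sampler's
clash-acceptance rule; energies are package units, not comparable across
force fields. Bonded neighbors (same residue, adjacent residues in a
chain) are excluded. Evaluation uses a KD-tree: only pairs within r_min
contribute, which makes re-scoring ~0.2 ms for a ~400-atom complex.

Torsion setting follows the N→C propagation convention: a φ rotation about
N–CA moves the residue's own CB/C and everything later in the chain; a ψ
rotation about CA–C moves everything after C. Angles are right-handed
degrees; "set" is implemented as a relative rotation from the current
dihedral, so rigid-segment internal geometry is preserved to 1e-6 Å by
construction. Partner chains never move with torsions — an RNA bound to
the upstream module therefore rides with it.

## CSP analysis

Δδ = √(Δδ_H² + (α Δδ_N)²), α = 0.2. Selection is strictly greater than
the 0.08 ppm threshold; boundary values are excluded. Residues missing
from either peak table — including those broadened beyond detection in the
bound state — are omitted from the profile and logged; rows flagged
`unassigned`/`overlapped` are likewise dropped. The handling of such peaks
is a package decision; reasonable alternatives (e.g. treating vanished
peaks as maximal perturbation) would only add binding-site residues.
Ambiguous restraints are built one per selected residue, spanning all
heavy atoms of that residue against all heavy atoms of the listed
nucleotides, with a 4 ± 1 Å flat bottom.

## Relaxation analysis

Per-residue decays fit I(t) = I₀e^(−Rt) by weighted least squares; the
intensity noise floor comes from duplicate delays (half the absolute
difference per duplicated point, averaged), and the quoted rate error is
the weighted-fit covariance under that floor. Series whose total decay
over the sampled window is negligible are flagged non-decaying and
excluded downstream, as are non-convergent fits.

R₂ from R₁ρ: R₂ = (R₁ρ − R₁cos²θ)/sin²θ, θ = tan⁻¹(ν₁/Δν). When
sin²θ < 0.25 the spin-lock axis is too close to z and the correction is
refused (flagged) rather than returned.

τ_c uses the slow-tumbling estimator τ_c = √(6R₂/R₁ − 7)/(4πν_N) with
ν_N = 0.101329118 × ν_H; it requires R₂/R₁ > 7/6 and is monotone in the
ratio. The theoretical expectation for a globular protein is the
empirical rule τ_c ≈ 0.6 ns/kDa × MW (25 °C, water), reported to one
decimal. This linear rule is a documented package choice: it reproduces
the standard expectations for small globular proteins in this size range
(e.g. 8.4 ns at 14 kDa) and is used only as a reference line, never in a
fit. Domain averages are arithmetic mean ± sample SD over residues inside
each partition segment, requiring at least two valid residues.

## PRE restraints

The observable is I_para/I_dia = R₂e^(−Γ₂t)/(R₂ + Γ₂); the right side is
strictly decreasing in Γ₂, so inversion uses bracketing bisection
(Brent, 1e-10 relative). Γ₂ ↔ distance uses the nitroxide
Solomon–Bloembergen relation Γ₂ = K/r⁶ (4τ_c + 3τ_c/(1 + ω_H²τ_c²)) with
K = 1.23×10⁻³² cm⁶s⁻². The total transverse evolution time t and the
diamagnetic R₂ are required user parameters.

Classification thresholds 0.15/0.85 and the ±4 Å quantitative tolerance
follow the protocol-family conventions for nitroxide PRE restraints and
are configuration-exposed; ratios below 0.15 give upper-bound-only
restraints at r(0.15), above 0.85 lower-bound-only at r(0.85). The
classification is exhaustive and mutually exclusive over ratio ≥ 0.

The label's unpaired electron is placed at a fixed 6 Å offset from CA
along CA→CB of the attachment residue (CA itself when no CB exists).
This side-chain-proxy model matches the semi-rigid resolution of the
modeling; label-rotamer ensembles are out of scope. Back-calculation uses
the amide nitrogen as the proton-position proxy.

## Conformer sampling

One randomization pass walks the sampled linker N→C, drawing (φ, ψ)
uniform on (−180°, 180°] per residue; a rotation is kept only if the
molecule-wide steric energy stays ≤ (1 + tolerance) × the pass-start
energy (default 10%). The reference is fixed at the start of each pass,
not re-based per proposal — the rule reads as a guard against accumulating
clashes relative to the starting structure. When the start is exactly
clash-free (E = 0) a relative tolerance is undefined; the ceiling is then
the energy of a single 0.2 Å overlap. A short three-stage greedy torsion
minimization (amplitudes 30°/10°/3°) relaxes residual contacts, and a
final linker bond-length sanity check (> 3.0 Å fails) decides acceptance
of the whole pass. Pools are bit-for-bit reproducible: each pass draws
from its own child of the config seed.

## Restraint annealing

The energy model sums: flat-bottom distance restraints (zero inside
[lower, upper], weight·Δ² outside); ambiguous restraints on the
r⁻⁶-summed effective distance r_eff = (Σ r⁻⁶)^(−1/6) (NOE convention;
nearest-atom averaging would be the config alternative); the repulsive
steric term; and a harmonic linker-bond term that keeps the chain
covalently sensible when rigid bodies translate off the torsion manifold.
The decomposition is exact: the reported total equals the weighted term
sum.

Annealing is Metropolis Monte-Carlo over a three-stage schedule with
strictly decreasing temperature scales and per-stage-halving move
amplitudes. Moves are (a) φ/ψ perturbations of one sampled-linker
residue, which carry the downstream domain rigidly, and (b) small 6-DoF
moves of rigid segments downstream of the sampled linker. The anchored
module — and any partner chain bound to it — keeps its laboratory frame,
mirroring a template in which the RNA belongs to the module's rigid body;
moving the module against a fixed partner would break an arrangement no
restraint maintains. The best-seen conformer is returned, so results
never score worse than their start, and trajectories are deterministic
under a fixed generator.

Ensemble selection takes the k strictly-lowest total energies (stable
tie-break on provenance order) and reports the mean ± SD of all pairwise
backbone RMSDs.

## SAXS

Model curves use one bead per residue (CA, or C4'/P for nucleotides) with
effective weights roughly proportional to residue electron counts
(protein 54, nucleotide 110, arbitrary units). The Debye double sum is
exact for these beads; sin(x)/x is series-guarded so I(0) = (Σf)².
There is no hydration shell or excluded-volume correction, so χ² values
rank models against one curve but are not comparable to atomistic
predictors on an absolute scale.

Guinier fits are weighted linear fits of ln I vs q², shrinking the window
from high q until q_max·R_g < 1.3 (default). For clearly anisometric
particles the tighter 1.0 window is recommended and used in the package's
own validation: the toy complex (D_max/R_g ≈ 3.3) carries ≈2% Guinier
truncation bias at 1.0 and ≈3% at 1.3.

p(r) from coordinates is the weighted pair-distance histogram; D_max and
R_g are computed from the exact (unbinned) pair distances,
R_g² = Σf_if_jr_ij²/(2(Σf)²). p(r) from data is a regularized indirect
transform: p is a non-negative histogram on (0, D_max_trial), fitted to
I(q) = 4πΣp(r_k)sinc(qr_k)Δr by bounded least squares with a
second-difference smoothness penalty (auto-scaled unless given). A
histogram basis is used rather than a sine series precisely so that
p(r) ≥ 0 can be imposed as a bound. The transform reports misfit χ²,
an oscillation score and the edge fraction; a grossly small D_max_trial
flags itself through the misfit. Choosing D_max from data remains an
analyst-in-the-loop step, as in practice.

Model-vs-data χ² = (1/(N−1))Σ[(cI_m + b − I_e)/σ]² with scale and offset
by closed-form weighted least squares after linear interpolation of the
model onto the experimental grid; b can be fixed to zero.

## ITC

The one-site model computes the bound-complex concentration from the
binding quadratic with site concentration N·M_t. Injection displacement is
modeled as perfect-mixing overflow: each injection of volume v multiplies
all cell concentrations by e^(−v/V₀) and delivers titrant at the same
rate, conserving mass exactly; the measured heat of injection i is
V₀ΔH([MX]_i − [MX]_{i−1}e^(−v/V₀)). The same equations serve simulation
and fitting, so fit∘simulate is the identity on noiseless data (verified
to 4 significant figures over K_D = 10 nM–200 µM, with protocols scaled
to keep the Wiseman c-value informative and N fixed to 1 when c < 5, as
an experimentalist would for weak binders).

Fitting is Levenberg–Marquardt over (log₁₀K_D, ΔH, N) initialized by a
K_D grid scan with ΔH solved linearly at each node (the model is linear
in ΔH). Errors come from the Jacobian covariance. Thermodynamics:
ΔG = RT ln K_D (R = 1.987×10⁻³ kcal mol⁻¹K⁻¹), −TΔS = ΔG − ΔH, so
ΔG = ΔH + (−TΔS) closes exactly; defaults are 25 °C and kcal throughout.
One published tandem-domain replicate prints the magnitude of a favorable
(negative) −TΔS term; the consistency sweep therefore compares magnitudes.

## Synthetic toy complex and observables

The generator builds the study system all tests run on:

- three rigid pseudo-atomic domains (N/CA/C + CB centroid per residue) of
  24/10/24 residues. Domains of ≥16 residues are helix-turn-helix
  hairpins (turn torsions chosen by grid search for a clash-free
  fold-back), giving globular ~20 Å bodies; a straight helix would make
  36 Å rods whose inter-domain distances fall outside the PRE
  quantitative window.
- linkers of 7 (intra-module) and 20 residues (the sampled linker), built
  extended; the apo state keeps them extended, so apo D_max (~100 Å)
  strictly exceeds bound D_max (~70 Å).
- the bound state folds the terminal domain back to ~24–29 Å from the
  module center (seeded random search plus greedy torsion refinement,
  clash-free) and threads a 12-mer RNA (P/C4'/N1 beads per nucleotide)
  along a Bézier path past all three domains, pushing each nucleotide to
  van-der-Waals range (4 Å) of the nearest protein surface. All three
  domains contact the RNA, as in the compact architecture the workflow is
  designed to resolve.
- spin labels: one on the module domain flanking the sampled linker,
  three spread over the terminal domain (a one-plus-three labeling
  scheme). Ground-truth τ_c is 13/13/12 ns for the domains and 4 ns for
  linkers, with a complex-wide 12 ns used for PRE conversion; the
  affinity truth is K_D = 133 nM, ΔH = −19.1 kcal/mol, N = 1.

Observables are forward-simulated with configurable noise (defaults: 5%
absolute on PRE ratios, 2% relative on decay intensities and SAXS, 0.05
µcal per ITC injection): peak tables in which residues within 8 Å of RNA
receive CSPs of 0.12–0.40 ppm (contact labels, not chemical-shift
physics — CSPs function only as binding-site markers here); R₁/R₁ρ decay
series on the published-style delay grids with per-residue spin-lock
offsets; PRE ratio profiles per label site via the forward
Solomon–Bloembergen chain; a Debye SAXS curve; and a 26 × 1.5 µL
isotherm (c ≈ 75). At zero noise every stage recovers its truth —
relaxation rates to <0.1%, PRE distances to <0.1 Å, p(r)-route R_g to
<1%, ITC to 4 significant figures — which bounds what the pipeline itself
can add or lose. What the generator does *not* emulate: real chemical
shifts, spectral overlap, label rotamers, anisotropic tumbling,
hydration-layer scattering, baseline drifts. Passing tests therefore
demonstrate the correctness and self-consistency of the analysis chain,
not robustness to every artifact of real data.

## The recovery experiment

The headline validation simulates observables from the bound truth at 5%
PRE-ratio noise, rebuilds all restraints from those observables alone,
and searches conformer space: a pool of 12 randomized-linker conformers,
coarse annealing of the 8 best-scoring (scales 20/5/0.5, steps
1500/1500/800), fine refinement of the 5 coarse leaders (scales 3/1/0.2,
smaller amplitudes), then the centroid of the refined members within
2.5× + 5 energy units of the best (at most 5) — the scaled-down analogue
of selecting the lowest-energy structures from a large calculated pool.
These problem sizes keep a full 20-seed study at roughly ten minutes on
one CPU.

The recovery metric is the backbone RMSD over rigid domains + RNA after
superposition on those same atoms. The 20-residue linker is excluded
because no restraint constrains its path; ensemble RMSDs for proteins
with long flexible linkers conventionally cover the ordered regions.
Under these conditions the centroid lands within 3 Å of the truth in
≥80% of 20 seeds (typically ~95%, median ≈ 1.2 Å). Identifiability, not
search, is the limit: annealing started from the truth itself drifts
0.7–3 Å under the same noisy restraints, so the ±4 Å flat bottoms admit
a basin of roughly that width.

## Known limitations

- Energies are package-defined; absolute values are not comparable to
  molecular-mechanics force fields or to CRYSOL-style χ².
- The PRE model ignores Curie-spin and cross-correlation contributions
  and multi-state ensemble averaging.
- The indirect transform's D_max is analyst-confirmed, not automated.
- The toy complex is pseudo-atomic; conclusions about real systems
  require real data through the same chain.
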