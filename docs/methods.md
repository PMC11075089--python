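# Methods

## Scope and model

The package analyzes how the ionic strength of the solution environment
biases the conformation of the M20 loop of *E. coli* dihydrofolate
reductase. It does not run molecular dynamics; it implements everything
downstream of (or preparatory to) simulation: solution/box composition,
the conformational coordinate, free-energy estimation, electrostatic
potential profiles, and the structure survey — plus synthetic generators
that stand in for trajectories so the whole chain is verifiable against
known ground truth.

## The conformational coordinate R_c

Anchor points are Cα centroids: P1 (R44, H45, G97, R98) marks the
coenzyme-binding side, P2 (L28, A29, W30, F31) the substrate-binding
side; j is the centroid of the E17/N18 Cα (the loop "nose"), and each
tracked residue i ∈ {E17, N18, M20, P21} contributes the geometric center
of its side-chain heavy atoms (all non-hydrogens except backbone N, CA,
C, O, OXT; proline ring atoms count as side chain). The coordinate is

    R_c = (1/4) Σ_i [(d_{P1→j} − d_{P1→i}) + (d_{P2→i} − d_{P2→j})],

the mean displacement of the side-chain centers toward P1 and away from
P2, measured relative to the backbone turn. This combination of the four
named distances is the package's definition: it is rigid-motion
invariant, signed (occluded loops reach negative values), and
strictly increasing as the loop swings from the substrate side to the
coenzyme side. Disordered tracked residues (no side-chain heavy atoms,
as in some deposited occluded structures) are dropped from the average
with a warning rather than failing the computation.

Classification uses half-open R_c bands: occluded < 2.0 ≤ intermediate
< 4.0 ≤ open < 5.75 ≤ closed (Å). The 5.75 Å boundary closes the gap
between the observed open (≤ 5.7 Å) and closed (≥ 5.8 Å) ranges at its
midpoint; the 4.0 Å cutoff keeps noncanonical in-between structures
(R_c ≈ 4.1 Å) out of the occluded band. All four boundaries are
configurable. The reaction plane — through the helix-B, helix-C and
helix-F Cα group centroids, normal oriented toward the loop turn — is
provided for orientation analyses and is not part of R_c.

## Free-energy estimation

W(R_c) = −RT ln ρ(R_c) at T = 298.16 K with R = 1.9872×10⁻³
kcal/(mol·K), on uniform 0.2 Å bins over a default range of (−4, 9) Å;
profiles are shifted so the sampled minimum is zero and empty bins are
masked, never padded. Sample sets from simulations of identical
composition are pooled by summing bin counts before normalization
(exactly equivalent to concatenation). The umbrella bias is harmonic,
U = ½k(x−x₀)², with k = 10 kcal/(mol·Å²) and 0.2 Å window spacing as the
reference setup; a switch to the k(x−x₀)² convention exists for
cross-checking against front ends that fold in the ½. WHAM solves the
standard binned self-consistency for the window constants f_w to a
max|Δf| tolerance of 1e-7 (cap 100 000 iterations), requires adjacent
biased windows to share sampled bins, and reduces bit-exactly to direct
Boltzmann inversion when all biases are zero.

Barriers between two wells are measured from the **higher** (shallower)
minimum — the crossing cost out of the less stable state. Error bars
come from three contiguous time blocks (mirroring three independent
simulations): per-bin standard error of the per-block W, ddof = 1.

Numerical notes: bins are compared at their centers; with 0.2 Å bins the
discretization bias of −RT ln(bin-mean density) versus the center value
is below 0.01 kcal/mol wherever |dW/dx| ≲ 1 kcal/(mol·Å), which holds on
the landscapes used here. WHAM reconstructs reliably only inside the
interval scanned by the windows; bins beyond the outermost window center
receive only stray tail counts and are reported but not trusted.

## Electrostatic potentials

The loop reference point is the Cα centroid of E17/N18/M20 with charge
−1 e. Potentials are cumulative vacuum Coulomb sums over particles
within radius R (k_C = 332.0637 kcal·Å/(mol·e²)), minimum-image in a
cubic box, no Ewald images and no dielectric — consistent with summing
explicit solvent and ions as real particles. TIP3P partial charges
(O −0.834 e, H +0.417 e) define the solvent contribution. Frames with a
particle within 0.5 Å of the reference point are rejected with a warning
in both the particle-summation and the RDF routes, so the two see the
same ensemble; a particle exactly at the reference point is an error.

The RDF-integral route Φ(R) = Σ_X 4πρ_X q_X k_C ∫₀^R r g(r) dr uses the
per-shell midpoint rule, which treats each shell's count as sitting at
the shell center and therefore matches the particle sum to a relative
error of dr/(2r) per particle; Φ is reported at shell upper edges, the
cumulative radius of the particle sum. This dual-route agreement is the
operative definition of the potential and is enforced by tests. The
linear free-energy estimate ΔG = ½ q^α Φ^total(R_large) defaults to
R_large = 20 Å; the protein-atom contribution to Φ^total requires
force-field charges and is accepted as caller input rather than
computed.

## Solution and box utilities

I^M = ½ Σ c_i Z_i². Ion counts for a target concentration in a cubic box
are round-half-to-even of c·N_A·V with anion counts restored to exact
formula-unit stoichiometry; neutralization of a charged solute adjusts
monovalent counterions (anions first) by exact integer bookkeeping and
fails loudly when parity makes neutrality unreachable. Random sequential
ion placement enforces, by default, a ≥ 15 Å minimum-image distance to
*all* previously placed ions (strict mode, which suppresses artificial
ion clustering; a relaxed mode checks only the most recent ion) plus a
solvent-overlap exclusion, with a 10 000-attempt cap per ion. Note the
strict rule saturates well below close packing: at the 0.25 M CaCl₂
composition of a 93 Å box (363 ions) random sequential addition cannot
satisfy it, so high-salt setups use the relaxed mode. Water trimming
removes whole molecules with any atom within 2.8 Å of a protein heavy
atom.

The salt vocabulary is fixed (NaCl, KCl, CaCl₂, MgCl₂, MnCl₂ — the 1:1
and 2:1 chlorides of the crystallization buffers); the survey annotator
shares the species construction and I^M code path with the solution
module. The survey threshold defaults to 0.24 M (0.25 M available by
argument). Buffer components other than the named salt (PEG, Tris) are
not counted toward I^M.

## Synthetic generators: what they emulate, and what they do not

* `double_well` builds a double-Gaussian landscape (σ = 1.1 Å) with wells
  at the occluded (−0.17 Å) and closed (6.0 Å) R_c minima on the domain
  (−3, 8) Å; the amplitude is solved so the saddle sits exactly at the
  requested barrier (defaults mirror the 1.6 → 3.2 kcal/mol barrier
  increase between the 0.30 M and 0.75 M regimes). Outside the wells the
  landscape plateaus near the barrier height.
* `sample_rc` draws i.i.d. Boltzmann samples by inverse-CDF on a 10⁻³ Å
  grid. Real trajectories are autocorrelated; i.i.d. sampling makes
  estimator checks sharp but says nothing about MD sampling efficiency.
* `gen_umbrella_samples` runs one Metropolis chain per window on
  W + bias, discards the first 10% as burn-in, and tunes the step toward
  30–50% acceptance during burn-in. Chains are seeded per window.
* `embed_frames` realizes R_c samples as minimal 3-D pseudo-atom frames:
  coincident Cα pseudo-atoms at P1/P2/j and one side-chain pseudo-atom
  per tracked residue ride a straight path whose t → R_c map is
  precomputed, verified strictly monotone, and inverted with PCHIP
  interpolation (round trip < 0.01 Å). Only the points entering R_c are
  materialized — no sterics, no full protein.
* `gen_ionic_config` emits ideal-solution frames (Poisson counts,
  uniform positions, optional hard core). Uniform placement has no
  ion–loop correlations, so ensemble-mean potentials are zero within
  noise; these frames validate estimator normalization and the
  dual-route contract, not the structured Φ(r) of real simulations.
* `gen_toy_structure` writes a PDB-able pseudo-structure at a
  representative R_c of a requested class (synthetic stand-ins, not
  deposited coordinates).

Passing tests on these generators demonstrates that the estimators are
correct at the stated sample sizes; they do not demonstrate anything
about force fields, sampling convergence of MD, or real water structure.

## Problem sizes and defaults used in the shipped analyses

Drivers use 2×10⁵ samples per synthetic simulation (three simulations
pooled per regime), 3 000 samples per umbrella window at 0.2 Å spacing,
and 400–1 000 ideal-solution frames (~10⁵ particle-frames) for the
electrostatics checks; the acceptance-grade recovery tests use 10⁶
samples for the Boltzmann round trip and 10⁶ embedded frames for the
end-to-end barrier recovery. These sizes put estimator noise well below
the stated tolerances (0.1 kcal/mol round trip, 0.15 kcal/mol WHAM and
barrier recovery, 2%/0.5 kcal/(mol·e) dual-route agreement).

## Known limitations

* The deposited reference structures are consumed, not bundled; the test
  that pins R_c of the noncanonical occluded entry (4.1 Å) downloads
  from RCSB at run time and needs network access.
* WHAM error bars are not propagated through the self-consistency;
  uncertainty on joined profiles comes from block analysis of the
  unbiased segments.
* The electrostatics use minimum-image truncation, not Ewald summation;
  cumulative Φ(R) near R = L/2 carries the corresponding truncation
  ambiguity.
* Hierarchical-clustering conformer labels are accepted as survey input;
  the package classifies by R_c bands only.
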