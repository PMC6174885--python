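# Methods

This note documents the model implemented by `protevol`, the numerical
choices behind it, what the synthetic data emulate, and the limitations a
user should keep in mind.

## Stability model

A protein is represented by its native contact map: C_ij = 1 when residues
i and j have heavy atoms closer than 4.5 Å and |i−j| ≥ 3. Short-range pairs
are excluded because they form in essentially all conformations and cancel
in free-energy differences. The energy of a sequence A on any map C is the
sum of pairwise contact energies E(C, A) = Σ_{i<j} C_ij U(A_i, A_j).

Three states compete:

- **Native**: G_nat = E(C_nat, A); the conformational entropy of the folded
  state is neglected.
- **Unfolded**: G_U = −T·L·S_U, with S_U the conformational entropy per
  residue of an open chain and k_B = 1.
- **Misfolded**: the free energy of the ensemble of compact non-native maps
  is estimated with a random-energy-model (REM) expansion in the central
  moments of E over a decoy ensemble:

      G_misf = ⟨E⟩ − m₂/(2T) + m₃/(6T²) − L·S_C·T ,

  where m₂ and m₃ are the second and third central moments and L·S_C is the
  log-number of compact conformations. The expression is evaluated at
  T_eff = (T^p + T_f^p)^{1/p}, a smooth maximum (p = 16) of the physical
  temperature and the freezing temperature T_f = √(m₂ / (2·L·S_C)); below
  T_f the REM free energy is frozen at its transition value. Two numerical
  choices are deliberate. First, T_f comes from the quadratic REM even
  though the third moment is kept in the evaluated expression: the cubic
  stationarity condition can lose its positive root as the moments vary
  with sequence composition, which would make G_misf discontinuous. Second,
  the smooth p-norm replaces the hard max because the kink at T_f = T makes
  the mean-field self-consistency map non-differentiable exactly where
  buried hydrophobic options cross the freezing boundary; with the hard
  max the fixed-point iteration enters persistent limit cycles. At p = 16
  the deviation from the hard max is at most ≈ 4% of T_eff at the crossing
  and decays as the states move away from it.

Decoy statistics are exact, not separation-factorized: the (windowed) decoy
contact maps are stored and the moments of E are taken over the per-decoy
energies, which coincides with direct averaging over the set. The tabulated
mean contact probability by separation class is kept for reporting and
serialization. Decoys longer than the target chain contribute every
contiguous window of the target length, as in threading treatments.

The folding free energy combines the non-native states as a Boltzmann
average, ΔG = G_nat + T·log-sum-exp(−G_misf/T, −G_U/T) with a numerically
stable log-sum-exp, and fitness is the folded fraction
f = 1/(1 + e^{ΔG/kT}) with kT fixed to 1; the selection strength Λ (below)
absorbs the fitness scale.

Default thermodynamic parameters are T = 0.5, S_U = 0.140, S_C = 0.065 per
residue (k_B = 1), the scale used in the REM protein-folding literature this
model family builds on; all are configurable per run.

## Site-specific selection models

Both models assume independently evolving sites tied together by the global
stability constraint, with Lagrange multiplier Λ (monotonically related to
effective population size):

- **Wild-type (WT)**: P^i_a ∝ P^mut_a · exp(Λ·φ(mut(A_i→a))), where φ is
  the log-fitness of the single-point mutant of the fixed PDB sequence.
- **Mean-field (MF)**: the same functional form with φ evaluated at the
  mean-field ΔG of amino acid a at site i, in which every other site j
  contributes its distribution-averaged interaction Σ_b P^j_b U(a,b) to the
  native term and the misfolding moments are computed from
  distribution-averaged pair energies on each decoy map. Passing the
  mean-field ΔG through the fitness sigmoid before exponentiating keeps the
  MF and WT models on the same Λ scale and makes the exact sequence-level
  stationary distribution P(A) ∝ P^mut(A)·e^{(N−1)φ(A)} the quantity the MF
  factorization approximates, with Λ = N−1; this is verified against
  exhaustive enumeration on a small-alphabet toy.

The MF equations are solved by **Gauss–Seidel sweeps**: sites are updated
sequentially to their conditional distribution given the current field of
all others, with the field arrays maintained by rank-1 updates (O(K·L·n)
per site for K decoys and n amino-acid states) and refreshed from scratch
each sweep to prevent floating-point drift. Sequential relaxation is used
because synchronous (Jacobi-style) iteration is unstable here: the global
hydrophobicity mode couples all sites through the misfolding variance term
and acquires a complex multiplier outside the unit circle, producing limit
cycles that no damping factor removes. Convergence is declared when the
synchronous residual max|P_target − P| < 1e−8 (default), with a hard sweep
cap and an error carrying the last residual. Probabilities are floored at
1e−12 before renormalization so the Halpern–Bruno logarithms stay finite.

Λ is fitted by maximizing Σ_i log P^i(A_i^PDB): the upper bracket is doubled
until the likelihood decreases, then a bounded scalar minimization locates
the maximum; a flat likelihood (e.g. a zero potential) returns Λ = 0 with a
warning. For the WT model the φ matrix is computed once, so the fit costs
one field evaluation regardless of the number of Λ probes.

## Halpern–Bruno site processes

From P^i and the mutation background, selective factors F^i_a = P^i_a /
P^mut_a give the site exchangeability E^i_ab = E^mut_ab·(ln F_b − ln
F_a)/(F_b − F_a), with the l'Hôpital limit E^mut_ab/F_b applied when
|ln F_b − ln F_a| < 1e−9 (one shared tolerance across modules). Q^i_ab =
E^i_ab·P^i_b satisfies detailed balance; the pairwise flux factorizes into
the mutational flux P^mut_a P^mut_b E^mut_ab times a selective enhancement,
and the site rate is the total off-diagonal flux, equal to 1 at neutral
sites under any normalized mutation model. Entropies are reported in nats
(a flag converts to bits); diagonals of exchangeability matrices are stored
as zero.

## Mutation models

All models are normalized to unit neutral flux. The empirical model reads
WAG or JTT in PAML `.dat` layout (copies ship with the package). The flux
model divides the empirical pair flux by the site-averaged selective term of
a stability-constrained run, restoring the empirical flux when the model's
site-averaged flux is recomputed (exact up to the single normalization
constant). Its background frequencies default to the observed sequence
composition with a pseudocount of one per amino acid — a single sequence
leaves several amino acids unobserved, and the selective factors divide by
the background — with a flag to use the `.dat` frequencies instead.

The codon-level models place the standard genetic code over a
nucleotide-exchange process with frequencies f_nuc and
transition/transversion ratio κ (κ multiplies transitions; transversions
have factor 1). Mutations into stop codons carry fitness zero, so the
61-sense-codon chain is not exactly reversible and its stationary
distribution is computed numerically (null space of the generator
transpose, polished and cross-checked by power iteration, residual <
1e−10). Amino-acid frequencies sum the codon distribution; exchangeabilities
come from symmetrized equilibrium codon fluxes. `nuc_opt` maximizes the
multinomial log-likelihood Σ_a n_obs(a)·log P^mut_a by Nelder–Mead over a
softmax parameterization of the frequency simplex crossed with a fixed κ
grid (0.5–10), from fixed starting points, so it is deterministic. κ itself
is weakly identified by amino-acid composition alone; the frequencies are
what the recovery tests pin down. `nuc_var` takes f_nuc from the
equilibrium G+C content with strand symmetry (f_G = f_C = GC/2). A single
global frequency vector is used for all three codon positions.

## Synthetic data

The generator produces compact toy chains (persistent random walk with
excluded volume, confined to a globule radius 2.8·L^{1/3} Å), their contact
maps, decoy ensembles, and equilibrated sequences. Design choices that
matter for interpretation:

- Chains are single-pseudo-atom (Cβ-like) models, so the generator uses a
  6.0 Å contact cutoff to reproduce realistic per-residue contact numbers
  (mean ≈ 5, buried sites > 10); the 4.5 Å heavy-atom rule applies to real
  structures.
- Decoy ensembles for a study protein come from the same chain generator
  and are density-matched to the native (the closest of 3× candidates by
  total contact count). Without matching, random density fluctuations of
  the generator dominate the native-vs-misfolded energy gap, which no real
  compact decoy set exhibits.
- "Wild-type" sequences are produced by Gibbs sampling the sequence-level
  stationary distribution on the fixture structure (site conditionals with
  all other sites fixed), so the WT model sees a sequence actually shaped
  by the landscape, as a PDB sequence would be. A generating strength of
  Λ = 20 with the default energy scale yields marginally stable sequences
  (ΔG of a few kT) with realistic entropy spread.
- The shipped potential is synthetic: U = ε·h·hᵀ + small symmetric noise
  (ε = −4), with h a Kyte–Doolittle-derived scale rescaled to unit norm and
  uniform-distribution mean 0.14. It reproduces the rank-1 hydrophobicity
  structure that dominates knowledge-based contact potentials, but none of
  their pair-specific chemistry (no disulfide term, no charge pairing).

Consequently, passing tests demonstrate the internal consistency of the
machinery and the qualitative physics (hydrophobic burial, negative design,
entropy–rate decoupling, mutation-bias effects); they do not validate
quantitative rate predictions on real proteins, which would require the
empirically derived potential and real structures with their decoy sets.

## Degenerate inputs and edge cases

Zero potentials make all distributions collapse to the background and the Λ
likelihood flat (handled with a warning); one-decoy ensembles give zero
misfolding variance; chains shorter than min_separation+1 residues, missing
chains, and all-HETATM chains raise explicit errors; non-standard residues
are skipped with a warning and chain breaks are renumbered consecutively
(separations are measured on the renumbered indices, and this is logged).

## Known limitations

- Independent-site approximations: epistasis enters only through the mean
  field or the fixed wild type; covariation between sites is not modeled.
- The native contact map is fixed; structural relaxation after mutation is
  outside the model.
- The REM third-moment expansion is an approximation to the decoy partition
  function; with few decoys the moments themselves are noisy.
- Fitted Λ values are landscape-scale dependent and not converted to
  effective population sizes.
- Single chains only; no mmCIF, no multi-chain complexes.
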