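# Methods

`archhist` analyses the combinatorial chromatin state space that archaeal
histone paralogs can generate. This note documents the models, the
parameters that matter, the synthetic data the analyses run on, and the
numerical choices made where the design was genuinely open.

## The system

Archaeal histones are ~69-residue, single-fold proteins. Residues are
numbered 1..69 by positional orthology to HMfB (the *Methanothermus
fervidus* histone B); the core histone fold spans residues 2..65. The
minimal DNA-wrapping unit is a tetramer: two histone dimers joined at a
single dimer:dimer interface. A genome with *n* histone paralogs can in
principle assemble n⁴ ordered tetramers, so paralog exchange defines a
combinatorial space of histone–DNA complexes with distinct DNA-binding and
tetramerization strengths.

## Catalog curation

Candidate histone sequences are filtered to 60–80 residues inclusive (the
HMfB-length regime), sequence-identical redundancy is removed with one
seeded uniform survivor per identity class (deterministic given the seed,
independent of input order), and alignment columns in which more than 5% of
rows carry a gap are masked — the threshold is strict, so a column with
exactly 5% gaps is kept. Masking never rewrites the alignment matrix, so
original column indices remain recoverable and the operation is idempotent.
Gap characters are `-`; `.` is normalized on read. FASTA headers follow
`id|species_id`, falling back to the whole header when no `|` is present.

Residue numbering comes from the reference row: its *k*-th ungapped residue
defines position *k*, and columns where the reference is gapped are
unmapped. `core_fold_complete` checks that a row has no gap at any mapped
position in 2..65; it is the in-repo structural completeness filter.
Fold-domain screening by profile HMM is not reimplemented — fold status can
be carried as a per-record annotation from external tools.

## Energy bookkeeping

All complex energetics reduce to three identities, in any consistent energy
unit (kcal/mol throughout):

* ΔΔG = ΔG_mutant − ΔG_wildtype (positive = destabilized relative to the
  reference),
* ΔG_bind = ΔG_complex − ΔG_DNA − ΔG_histone,
* ΔG_tet = ΔG_tetramer − ΔG_dimer1 − ΔG_dimer2.

Entropic terms are carried only as optional metadata; bookkeeping defaults
ignore them. Every complex gets a (ΔΔG_bind, ΔΔG_tet) coordinate relative
to a named reference complex (a designated homotetramer), which sits at the
origin exactly.

**Backends.** Quantitative energies enter only through TSV tables exported
from external structure-based calculations, in two dialects auto-detected
by header: per-complex exact keys (`complex_key, ddG_bind, ddG_tet`) or
additive per-monomer terms (`monomer_id, bind_term, tet_term`) summed over
the four monomers. Values pass through unconverted.

The built-in **charge surrogate** exists so that every downstream stage is
testable from sequence alone. It assigns unit charges (D/E −1, K/R +1,
H +0.5 for partial protonation — chosen so H–H and E–E interface pairs
score differently; all values configurable) and scores

* the dimer:dimer interface as κ_tet · Σ_p q(inner1, p)·q(inner2, p) over
  interface positions {46, 49, 59, 62}, where the inner monomers (slot 2 of
  dimer 1, slot 3 of dimer 2) carry the single cross-dimer contact, and
* DNA binding as −κ_dna · Σ_monomers Σ_p q(m, p) over DNA-contacting loop
  positions {10, 19, 53, 54}.

Positive interface products are repulsive; positive loop charge strengthens
(lowers) binding. The surrogate reproduces *orderings* — a glutamate at
position 49 destabilizes the interface relative to histidine, removing loop
arginines weakens binding, interface repulsion grows monotonically with the
number of negatively charged capstone monomers at the interface — and is
never a source of absolute energies. Scaling the κ parameters rescales all
raw energies without changing any ordering.

## State space

Enumeration is ORDERED by default (all n⁴ ordered 4-tuples; 7 paralogs give
2,401 complexes), matching the counting convention of the full state space.
CANONICAL mode reduces by the symmetry group of the complex (within-dimer
swap and dimer-pair swap; 8 images per tuple) and carries each class's
multiplicity, which sums to n⁴ — energies are symmetry-invariant, so
sampling and averaging can work per class. Complexes are classified by
dominant paralog (an id occupying ≥3 of 4 slots, else MIXED), with
homotetramers flagged separately. A dosage series reports the energy
coordinates of all complexes with composition {(4−k)·a, k·b} for k = 0..4;
under additive energies the means are exactly linear in k with zero spread.

**Capstone classification** is a sequence-level rule on position 49:
aspartate/glutamate → CAPSTONE/NEGATIVE, a hydrophobic residue →
CAPSTONE/HYDROPHOBIC, gap or X → UNKNOWN, anything else (including the
ancestral histidine) → STANDARD. The hydrophobic set defaults to
{A, I, L, M, F, V, W} and is a parameter, not an assertion about any
specific published list.

## Diversity statistics

Per alignment column and sequence group, diversity is the Shannon index
H = −Σ p_i ln p_i over observed residues (gaps and X excluded; each aligned
row counts once). H is computed in nats; the between-group ratio H_A/H_B is
base-invariant, so the choice of base is immaterial for every reported
ratio (asserted numerically in the tests). When the denominator group is
perfectly conserved (H_B = 0) the ratio is reported as an explicit
UNDEFINED value with a both-zero subflag when H_A = 0 too — never as an
infinity or silent NaN. Jaccard overlap is intersection-over-union of the
residue sets observed per group.

**Ranking positions by ratio.** An undefined ratio with H_A > 0 is the most
extreme form of group-specific diversification (the residue-19 situation:
perfectly conserved in single-histone archaea, diverse in multi-histone
ones), so rankings use a regularized ratio H_A / max(H_B, H_min(n_B)),
where H_min(n) is the entropy of a single deviant among n sequences — the
smallest nonzero column entropy the group can show. This places such
positions above any column with comparable diversity and observed variation
in the denominator group, while both-zero positions rank last.

**Spearman correlation.** rho is the Pearson correlation of average ranks
(ties receive average ranks). For n ≤ 8 the two-sided p-value is exact, by
enumeration of all n! rank permutations (the cutoff is chosen so the
seven-paralog case is exact; 8! = 40,320 keeps enumeration instant); larger
n uses the t approximation. Constant inputs make rho explicitly undefined.

## Ensemble sampling

Monomer recruitment probabilities are mean replicate intensity per paralog,
normalized within a condition. Ensembles draw each complex as four
independent categorical draws (monomer-level recruitment implements random
dimerization; a dimer-preference extension point exists but is off).
Default ensemble size is 100,000 draws, deterministic given the seed. The
closed-form companion `expected_frequency` gives Π p(m_i) for ordered
complexes and the multinomial-weighted product for compositions; empirical
frequencies converge to it, which the tests check by chi-square.

Condition comparisons bin both ensembles on shared equal-width 50×50 edges
spanning the pooled energy coordinates and report per-bin
log2((c_B + 1)/(c_A + 1)); the pseudocount makes empty bins finite and
preserves exact antisymmetry under argument swap. Counts are normalized to
frequencies first if ensemble sizes differ. The scalar summary is the
difference in ensemble-mean ΔΔG_bind and ΔΔG_tet, with Monte-Carlo
standard errors.

## Synthetic data

The generator emulates the statistical structure the analyses assume:

* **Catalog**: a random 69-residue scaffold; 143 single-histone and 139
  multi-histone species (the curated-study group sizes), multi species
  carrying 2–7 paralogs. Every sequence mutates per column at a background
  rate of 0.08 substitutions/column (histone-scale divergence; chosen by an
  up-front power analysis so the smallest nonzero column entropies in the
  single-histone group stay well above the ratio's noise floor). Hot
  positions {10, 19, 49, 53, 54} mutate at 10× the background rate, in
  multi-paralog species only. Single-histone species keep R19 and H49
  invariant, mirroring their conservation in single-histone archaea. 30% of
  multi species receive one planted E49 capstone paralog. The alignment has
  no indels, so the position map is the identity — gap handling is tested
  separately on hand-built alignments.
* **Abundance**: condition-1 mean intensities lie on a geometric ladder
  spanning a 27-fold range, rank-coupled to homotetramer ΔΔG_tet through a
  Gaussian copula (ρ_Pearson = 2 sin(π·ρ_target/6)) so the expected
  Spearman correlation equals the planted −0.8. The second condition
  up-weights the two least stable paralogs 4-fold. Replicates (3 per
  condition) carry lognormal jitter (σ = 0.2) rescaled so each arithmetic
  mean equals its designed intensity exactly — the fold range and planted
  correlation survive replicate noise by construction.
* **Energies**: additive per-monomer terms from centered normals
  (σ = 2 kcal/mol), a +5 kcal/mol tetramerization penalty for capstone
  paralogs, and a zeroed reference row.

Outputs are byte-identical under a fixed (spec, seed), and every artifact
ships a truth record sufficient to score recovery without re-deriving
ground truth.

**What the generator does not emulate**: phylogenetic correlation between
species (every sequence mutates independently from the scaffold), indels
and alignment uncertainty, gene conversion, compositional biases of real
histones, absolute protein titers, and any physically meaningful energy
scale. Passing recovery tests therefore demonstrates that the estimators
and classifiers recover the signals they target under the assumed sampling
model — not that those signals are identifiable in real, phylogenetically
structured data.

## Problem sizes and determinism

Recovery analyses use 100 replicate catalogs (hot positions, capstones),
200 replicates for correlation recovery, 100 seeds for the sampling
goodness-of-fit, and 100,000-draw ensembles — sizes at which the planted
effects are comfortably resolvable while a full run stays in the tens of
seconds. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state.

## Known limitations

* Absolute energies exist only via external tables; the surrogate's units
  are arbitrary and only orderings are meaningful.
* The hydrophobic capstone set is a configurable convention.
* Diversity pooling is per sequence, not per species or per clade;
  phylogenetically corrected diversity is out of scope (a different
  `GroupLabeling` can express clade exclusions).
* Ratio-based rankings remain noisy where the denominator group's entropy
  is small; the H_min regularization bounds but does not remove this.
* Oligomers beyond the tetramer (and dimer-stacking effects) are not
  modeled.
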