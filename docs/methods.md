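# Model and methods

## The problem

The G_A/G_B system of *Streptococcus* protein G is the best-characterized
evolutionary fold switch: two 56-residue domains — the all-alpha
albumin-binding G_A fold and the alpha+beta IgG-binding G_B fold — are
connected by designed mutant series of increasing sequence identity, up to
the GA98/GB98 pair in which a single L45Y substitution flips the dominant
fold.  `foldswitch` implements a hybrid energy model for studying such
bi-stable systems: a deliberately weak, sequence-*independent* dual-basin
structure-based bias that makes both folds accessible, combined with a
sequence-*dependent* transferable energy that decides which fold (and how
strongly) a given sequence prefers.

## Dual-basin structure-based potential

For each fold a consensus native contact map is built from several
experimental conformers: two residues are in native contact when the
closest distance between any two non-hydrogen sidechain atoms, one from
each residue, is at most 6 Å (inclusive) and the residues are at least
three sequence positions apart (j − i ≥ 3); the consensus map keeps only
contacts common to *all* conformers.  Each kept contact (i, j) stores the
Cα–Cα distance d_ij^(s) in every conformer s, and contributes the
multi-Gaussian well

    E_ij(r) = ε · [ 1 − Π_s ( 1 − exp( −(r − d_ij^(s))² / 2w² ) ) ]

with well width w = 0.5 Å.  The per-contact energy equals ε (< 0) whenever
r matches any conformer's native distance and decays to zero away from all
wells, so every contributing native conformer sits at a minimum of the
same depth.  Compared with a summed Lennard-Jones construction, the
Gaussian form does not let the repulsion of a longer-distance well occlude
a shorter-distance one; the LJ construction is retained only as a test
oracle (`lj_multiwell_oracle`).

The fold energies E_A, E_B are sums over the two consensus maps and the
dual-basin potential is the plain sum E_SBM = E_A + E_B — no logarithmic
mixing, which would re-introduce native specificity we want to keep out of
this term.  Progress coordinates are Q_A = E_A/(n_A ε_A) and
Q_B = E_B/(n_B ε_B) (n_A, n_B = map sizes), continuum analogues of the
fraction of native contacts; both approach 1 in the respective native
basin and 0 for an expanded chain.

Sign convention: the per-contact well is written so its minimum is ε < 0.
Calibrated defaults are ε_B = −0.37 and ε_A = 0.96 ε_B (configurable;
sweeps over ε_B from −0.2 to −0.5 are supported), chosen so that neither
fold is favored by the structure bias itself and the native bias stays
weak relative to the transferable component.  Gaussian tails are evaluated
without truncation (they decay fast enough that no cutoff is needed at
these system sizes).

Glycine carries no heavy sidechain atom; by default its Cα serves as the
sidechain surrogate in the contact criterion (`gly_sidechain=calpha`),
with `none` (Gly contributes no contacts) as the alternative.  Both
conventions are first-class because published contact counts do not state
which was used.

## Transferable component

E_total = E_SBM + E_trans with
E_trans = E_local + E_EV + E_HB + E_SC + E_HP.  Energies are
dimensionless with k_B = 1.  The five-term decomposition is a *contract*:
any object returning the five named terms can drive the sampler.  Two
implementations ship:

* **null** — all terms zero (pure structure-based regime);
* **stand-in** — a simple physical model on the reduced representation
  (backbone N/Cα/C/O, Cβ, one sidechain-centroid pseudo-atom per residue):
  - E_local: Gaussian (φ, ψ) bias of depth k_local = 0.4 and width 25°
    toward the helical (−63°, −43°) and extended (−120°, 130°) basins;
  - E_EV: truncated r⁻¹² repulsion, σ = 2.5 Å, over nonbonded reduced-atom
    pairs (residue separation ≥ 2), distance clamped at 1.2 Å;
  - E_HB: backbone N(i)···O=C(j) term, Gaussian in the N···O distance
    (2.95 ± 0.3 Å) times a cos² alignment factor along the carbonyl axis,
    depth k_hb = 0.5;
  - E_SC: Debye-screened Coulomb between charged sidechain centroids
    (±1 for Asp/Glu/Lys/Arg, screening length 10 Å);
  - E_HP: −k_hp × (number of nonpolar sidechain pseudo-atom pairs within
    4.5 Å, residue separation ≥ 2), k_hp = 1 — the strength scales with
    the number of contacting nonpolar atoms.

  Every functional form and constant above is a design choice of this
  package, selected for qualitative plausibility at desk scale; none is a
  literature parameterization, and quantities that depend on a specific
  published transferable force field (absolute stabilization shares,
  absolute ΔF values, melting temperatures of the real 56-mers) are out of
  scope.

### Aromatic π–π override

A statistical potential for Phe/Tyr ring pairs is derived from structure
sets: ring-pair geometry is reduced to (r, θ, φ) — center-to-center
distance, acute tilt angle between ring normals, and acute angle between a
ring normal and the center–center vector, symmetrized over the two ring
orderings (the dislocation angle has no unique published formula; the
symmetrized definition makes the potential exchange-symmetric).
Occurrences are binned on a 30×30×30 grid (r ∈ [3, 12) Å in 0.3 Å bins;
θ, φ ∈ [0, 90)° in 3° bins; half-open bins) and converted to

    E_ππ(r, θ, φ) = −ε_ππ { 1 + ln[P/P_max] / |ln(P_min/P_max)| },

with E_ππ = 0 in zero-count bins, so the interaction is attractive and
bounded in [−ε_ππ, 0]; ε_ππ = 1.5 for all three pair classes (F-F, Y-Y,
F-Y).  If every occupied bin has the same count the normalizer vanishes;
the documented fallback sets occupied bins to −ε_ππ.  The override hook
replaces the hydrophobic pair term of F/Y pairs with E_ππ, leaving all
other pairs (and Trp) untouched.  On the reduced representation the "ring"
center is the sidechain centroid and the normal comes from the local
sidechain frame — a coarse proxy, adequate for the hook's contract but not
for deriving statistics; derivation uses real ring atoms from PDB input.

## Monte Carlo sampling

Chains live in torsion space: bond lengths and angles are fixed, so
coordinates are a deterministic function of (φ, ψ, χ); proline φ is frozen
at −65°.  One MC cycle performs `count_dof(sequence)` elementary
Metropolis updates so that, on average, every rotational degree of freedom
is perturbed once per cycle.  `count_dof` counts two backbone torsions per
residue (minus frozen proline φ) plus a per-residue-type sidechain rotor
table: heavy-atom χ angles plus terminal single-bond rotors (CH₃, OH, SH,
NH₃⁺), with planar groups (amide, carboxylate, guanidinium, aromatic
rings, proline ring) rigid.  Under this table the GA98 and GB98 sequences
carry 283 and 282 free torsions — the Leu→Tyr substitution at position 45
removes exactly one rotor (Leu: χ1, χ2 + two methyls = 4; Tyr: χ1, χ2 +
hydroxyl = 3).

The move set mixes single-torsion pivots (Gaussian step of 25° s.d., or a
full re-draw with 20% probability), sidechain-torsion rotations, and
correlated multi-torsion window moves — counter-rotating small steps on a
window of up to four consecutive residues, a semi-local stand-in for
biased Gaussian steps.  All proposals are symmetric, so the plain
Metropolis ratio min(1, e^(−ΔE/T)) preserves detailed balance; a move
producing a non-finite energy is rejected.  Runs start from random
torsions in sterically common ranges, relaxed by a two-cycle
zero-temperature descent.

Replica exchange attempts adjacent-pair swaps every `exchange_interval`
cycles (default 5000), alternating even/odd pairings.  Temperature
exchange accepts with min(1, e^{(β_i−β_j)(E_i−E_j)}); Hamiltonian exchange
over a ladder of SBM strengths ε_B at fixed T uses the cross-energy form
min(1, e^{−β[E_i(x_j)+E_j(x_i)−E_i(x_i)−E_j(x_j)]}).  Replica identity is
tracked and remains a permutation.  Production-scale defaults (32
replicas, 10⁷ cycles) are configuration values; shipped experiments and
tests run orders of magnitude smaller (12-mers, 10²–10³ cycles), which is
sufficient for the statistical checks they make.

## Thermodynamic analysis

C_V(T) = (⟨E²⟩ − ⟨E⟩²)/(k_B T²); the melting temperature T_m is the curve
maximum.  Multi-temperature runs are reweighted to a target temperature by
WHAM in its binless form: the self-consistent free-energy offsets f_k obey

    f_k = −ln Σ_x  e^{−β_k E_x} / Σ_l N_l e^{f_l − β_l E_x},

iterated to 10⁻¹⁰ and turned into per-sample weights at the target
temperature.  The binless formulation is the zero-bin-width limit of
histogram WHAM and removes the bin-width knob entirely; non-convergence
(e.g. non-overlapping energy histograms) raises a diagnostic error.  The
first 30% of every trajectory is discarded as burn-in by default.

Free-energy landscapes are −ln of the weighted population on a 100×100
grid over (Q_A, Q_B) ∈ [0, 1.05]² (the overshoot accommodates Q slightly
above 1 from overlapping wells), minimum-normalized to zero, with empty
bins at +∞; any display clipping (e.g. at 6 k_BT) is rendering only.
Native basins are G_A: Q_A ≥ 0.6 ∧ Q_B < 0.6 and G_B: Q_B ≥ 0.6 ∧
Q_A < 0.6, and ΔF(G_A−G_B) = −ln(P_A/P_B); an empty basin yields ±∞ with
a degeneracy flag rather than an exception.  ΔF may be computed from
WHAM-weighted (default) or raw counts.  Difference landscapes are per-bin
F₂ − F₁ with bins unoccupied in either input masked.  Unfolded-state boxes
for contact analyses (Q_A < 0.6 ∧ Q_B < 0.3) and the transition-state
boxes (TS-G_A: 0.66 < Q_A < 0.74, 0.12 < Q_B < 0.22; TS1-G_B:
0.3 < Q_A < 0.55, 0.35 < Q_B < 0.43; TS2-G_B: 0.28 < Q_A < 0.4,
0.58 < Q_B < 0.66 — open intervals) ship as presets.

## Conformational analysis

Each conformation is represented by a 4L-dimensional superposition vector:
per-residue Cα distances to a reference structure of fold A superposed
onto the conformation by Cα least squares (Kabsch), the same against a
fold-B reference, then the two Cβ blocks (Gly Cβ substitutes Cα by
default).  RMSD_sm between two conformations is the root mean square
difference of their vectors — equivalently the Euclidean distance
normalized by √(4L) — and is a true metric.  Pooled conformations are
clustered by seeded k-means (k-means++ initialization, k = 50 by default)
in this space; the centroid of a cluster is the actual member conformation
nearest the cluster mean.  Centroid pairs with RMSD_sm ≤ 5.75 Å form the
edges of the centroid graph.

Mutational analyses on a pooled clustering of two sequence variants with
equal sample counts report, per cluster, the sequence bias
ln[P(variant 2)/P(variant 1)] and the fold bias ln(mean Q_B / mean Q_A)
over cluster members (cluster means rather than centroid values; the
centroid variant is available).  Transition fluxes count macrostate
changes between consecutive trajectory records under a 3-state partition
(U, G_A, G_B from the basin boxes) or an 8-state refinement (the 3-state
split plus the transition/intermediate boxes and an extended-chain corner
— the 8-state boundaries are package presets, an interpretation rather
than a published partition).  Contact-frequency shifts between two
equal-size ensembles use the same 6 Å/≥3-separation contact criterion as
the native maps and classify each contact as nonnative, native-G_A,
native-G_B or native-both, with contact order |i−j| + 1.

## Synthetic data

`generate_fixture_set` emulates a set of structurally similar native
conformers of one fold: a torsion-built ideal topology (α-helix;
β-hairpin with a two-residue turn placed so the strands are in register;
or random coil) with independent Gaussian coordinate jitter per conformer
(σ = jitter_sd) imitating NMR-ensemble variation, a repeating Gly/Pro-free
sequence with aromatics, and Cβ plus one sidechain pseudo-atom per
residue.  What the fixtures do *not* emulate: real sidechain packing,
full-atom sterics, disordered termini, or the actual G_A/G_B geometry —
so tests passing on fixtures validate the machinery (contact logic,
energies, sampling, reweighting, clustering), not force-field accuracy on
real proteins.

The **switch-direction experiment** (`foldswitch.validation`) is the
desk-scale analogue of a fold-switch substitution: a 12-mer with a
dual-basin potential over a helix map (fold A, 15 contacts) and a hairpin
map (fold B, 10 contacts), and a transferable term reduced to excluded
volume plus the hydrophobic count (unit strength 1.5 here).  Variant "a"
(`SNQTSENKSQTN`) has no nonpolar residues, so its hydrophobic term
vanishes; variant "b" (`SLFTSENKLLFN`) places Leu/Phe at five positions
paired across the hairpin, so E_HP selectively stabilizes fold B.  The
fixture's SBM is first calibrated the way any dual-basin baseline must
be: with equal well depths the compact hairpin dominates even for the
neutral variant, so the helix-map wells are strengthened (ε_A = 1.2 ε_B,
swept once over a coarse grid) until variant "a" samples both basins with
comparable weight; the calibrated potential is then identical for both
variants.  Each variant is sampled by four independent parallel-tempering
runs over T ∈ {0.3, 0.42, 0.6, 0.85} with swaps every 15 cycles,
WHAM-reweighted to T = 0.42 and pooled before basin populations are
taken — single runs at this scale under-resolve the shift, which is why
the pooling is part of the experiment's definition.  Basin populations
carry a 1/n pseudocount so an unvisited basin yields a large finite ΔF
rather than an infinity.  The prediction is directional only:
ΔF(b) > ΔF(a); no magnitude is asserted.

## Numerical choices and degenerate inputs

* Contact cutoff comparison is inclusive (≤ 6 Å); separation rule is
  j − i ≥ 3.
* Landscape grid exactly 100×100 over [0, 1.05]².
* k-means ties broken by lowest index; duplicate vectors are benign.
* WHAM fixed point: tolerance 10⁻¹⁰, max 10⁵ iterations, logsumexp
  throughout.
* All-equal π-π histogram counts: occupied bins set to −ε_ππ (documented
  fallback for the vanishing normalizer).
* Altloc handling keeps blank/'A'; hydrogens excluded everywhere;
  nonstandard residues raise; multi-model files never mix models; only
  the first chain is read unless a chain id is given.
* PDB reference structures are taken at model 1 for multi-model (NMR)
  entries.

## Known limitations

* The stand-in transferable model is qualitative; it cannot reproduce
  published energetics of any specific force field, and sequences are
  discriminated only through coarse per-residue properties.
* The reduced representation has a single sidechain pseudo-atom, so the
  π-π override geometry on sampled chains is approximate.
* Landscape-derived kinetic statements (transition-state boxes, fluxes)
  are equilibrium-projection heuristics, not rate calculations.
* Consensus maps require all conformers to resolve the same chain length;
  residues missing from a conformer simply cannot carry contacts there.
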